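"""Heterochronous coalescent simulation with partial selfing and SSR mutation.

Simulates genealogies of serially sampled diploid individuals in a set of
gene pools connected by divergence (gene-pool replacement) events and pulse
admixture, then drops generalized-stepwise microsatellite mutations on the
tree to produce a :class:`~paleossr.genotypes.GenotypeDataset`.

Model
-----
Time is measured in generations before present (present = 0, increasing into
the past).  Each pool has a diploid effective size ``Ne`` and a selfing rate
``s``; partial selfing is treated with the standard two-phase approximation:

* at sampling, the two gene copies of an individual coalesce instantly with
  probability ``F = s / (2 - s)`` (the equilibrium inbreeding coefficient);
* surviving lineages coalesce within a pool with pairwise rate
  ``(1 + F) / (2 Ne)`` per generation, i.e. an effective size ``Ne/(1+F)``,
  in a continuous-time approximation.

A divergence event moves every lineage of a child pool into its parent
(looking backward in time); a pulse admixture event reassigns each lineage of
its target (a pool, or the lineages of one sampled group at their sampling
time) to the source pool independently with probability ``r``.

Mutation follows the generalized stepwise model: mutations arise as a
Poisson process of rate ``mu`` per generation on each branch; each mutation
moves the allele by a step whose magnitude is geometric with parameter
``1 - p_geom`` (``p_geom = 0`` recovers the strict stepwise model) and whose
sign is equiprobable, reflecting at the allele-size bounds.  Allele sizes
are expressed in repeat units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeDataset, Locus, SampleGroup

__all__ = [
    "Pool",
    "SamplingEvent",
    "DivergenceEvent",
    "AdmixtureEvent",
    "DemographicScenario",
    "MutationModel",
    "GroupDesign",
    "SamplingDesign",
    "ScenarioError",
    "build_scenario",
    "validate_scenario",
    "simulate_genealogy",
    "apply_mutations",
    "simulate_dataset",
    "Tree",
]


class ScenarioError(ValueError):
    """A demographic scenario is inconsistent or incompletely parameterized."""


def equilibrium_inbreeding(s: float) -> float:
    """Equilibrium inbreeding coefficient F = s / (2 - s) for selfing rate s."""
    return s / (2.0 - s)


@dataclass(frozen=True)
class Pool:
    """A gene pool with diploid effective size and selfing rate."""

    id: str
    ne: float
    selfing: float = 0.0

    @property
    def F(self) -> float:
        return equilibrium_inbreeding(self.selfing)


@dataclass(frozen=True)
class SamplingEvent:
    """n diploid individuals of one group sampled from a pool at a past time."""

    time: float
    group: str
    n: int
    pool: str
    seed_color: str = "white"


@dataclass(frozen=True)
class DivergenceEvent:
    """Backward in time, all lineages of ``child`` join ``parent`` at ``time``."""

    time: float
    child: str
    parent: str


@dataclass(frozen=True)
class AdmixtureEvent:
    """Pulse admixture: lineages of ``target`` move to ``source`` w.p. ``proportion``.

    ``target`` may be a pool id (applies to all its lineages at ``time``) or a
    sampled group label (applies to that group's lineages right at sampling).
    """

    time: float
    target: str
    source: str
    proportion: float


@dataclass
class DemographicScenario:
    """Pools plus time-ordered sampling/divergence/admixture events."""

    pools: list[Pool]
    events: list
    ancestral: str
    kind: str | None = None

    def pool(self, pid: str) -> Pool:
        for p in self.pools:
            if p.id == pid:
                return p
        raise KeyError(f"unknown pool {pid!r}")

    @property
    def sampling_events(self) -> list[SamplingEvent]:
        return [e for e in self.events if isinstance(e, SamplingEvent)]


@dataclass(frozen=True)
class MutationModel:
    """Generalized stepwise SSR mutation: rate, step geometry, size bounds."""

    mu: float = 5e-4
    p_geom: float = 0.0
    size_bounds: tuple[int, int] = (5, 50)

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mutation rate must be >= 0")
        if not (0 <= self.p_geom < 1):
            raise ValueError("p_geom must be in [0, 1)")
        if self.size_bounds[0] >= self.size_bounds[1]:
            raise ValueError("size bounds must satisfy min < max")


@dataclass(frozen=True)
class GroupDesign:
    """One sampled group: label, age, size and seed color."""

    label: str
    age_calBP: float
    n: int
    seed_color: str = "white"

    @property
    def type(self) -> str:
        return "modern" if self.age_calBP == 0 else "ancient"


@dataclass
class SamplingDesign:
    """The set of sampled groups and the calendar-to-generation mapping.

    ``generation_time`` is in years per generation; for an annual crop the
    default of 1 makes calibrated ages directly interpretable as generations.
    """

    groups: list[GroupDesign]
    generation_time: float = 1.0

    def time_of(self, g: GroupDesign) -> float:
        return g.age_calBP / self.generation_time

    def group(self, label: str) -> GroupDesign:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"unknown design group {label!r}")


# ---------------------------------------------------------------------------
# scenario construction (the six demographic hypotheses)


def _tiers(design: SamplingDesign, ancient_cutoff: float = 1000.0):
    """Partition design groups into modern / intermediate / ancient tiers.

    Modern: age 0.  Intermediate: 0 < age < cutoff.  Ancient: age >= cutoff.
    """
    modern = [g for g in design.groups if g.age_calBP == 0]
    intermediate = [g for g in design.groups if 0 < g.age_calBP < ancient_cutoff]
    ancient = [g for g in design.groups if g.age_calBP >= ancient_cutoff]
    return modern, intermediate, ancient


def _require(params: dict, keys: list[str], kind: str) -> None:
    for k in keys:
        if k not in params:
            raise ScenarioError(f"scenario {kind}: missing parameter {k!r}")


def build_scenario(kind: str, params: dict, design: SamplingDesign) -> DemographicScenario:
    """Build one of the six competing demographic scenarios.

    A: drift in a single population (all samples serial in one pool).
    B: replacement of all ancient samples' pool by the modern pool.
    C: modern + intermediate samples in one recent pool replacing the pool of
       the oldest samples.
    D: successive replacement — modern, intermediate and ancient pools in a
       chain of divergences.
    E: D plus a wild pool from which the dark-seeded groups are sampled.
    F: E, but dark-seeded groups are sampled from their sympatric cultivated
       pool with a pulse of admixture (proportion ``r_wild``) from the wild
       pool at their sampling time.

    Every scenario ends in an explicit ancestral pool entered at
    ``td_ancestral``.  Parameter names follow the pool names:
    ``ne_<pool>``, ``s_<pool>``, ``td_<pool>`` (+ ``r_wild`` for F).
    """
    kind = kind.upper()
    if kind not in "ABCDEF" or len(kind) != 1:
        raise ScenarioError(f"unknown scenario kind {kind!r}")
    modern, intermediate, ancient = _tiers(design)
    dark = [g for g in design.groups if g.seed_color == "dark"]

    pools: list[Pool] = []
    events: list = []

    def sample_into(groups, pool_id):
        for g in groups:
            events.append(
                SamplingEvent(design.time_of(g), g.label, g.n, pool_id, g.seed_color)
            )

    def add_pool(name):
        pools.append(Pool(name, params[f"ne_{name}"], params[f"s_{name}"]))

    if kind == "A":
        _require(params, ["ne_main", "s_main", "ne_ancestral", "s_ancestral", "td_ancestral"], kind)
        add_pool("main")
        add_pool("ancestral")
        sample_into(design.groups, "main")
        events.append(DivergenceEvent(params["td_ancestral"], "main", "ancestral"))
        anc = "ancestral"
    elif kind == "B":
        _require(params, ["ne_modern", "s_modern", "ne_ancient", "s_ancient",
                          "td_modern", "ne_ancestral", "s_ancestral", "td_ancestral"], kind)
        add_pool("modern")
        add_pool("ancient")
        add_pool("ancestral")
        sample_into(modern, "modern")
        sample_into(intermediate + ancient, "ancient")
        events.append(DivergenceEvent(params["td_modern"], "modern", "ancient"))
        events.append(DivergenceEvent(params["td_ancestral"], "ancient", "ancestral"))
        anc = "ancestral"
    elif kind == "C":
        _require(params, ["ne_recent", "s_recent", "ne_old", "s_old",
                          "td_recent", "ne_ancestral", "s_ancestral", "td_ancestral"], kind)
        add_pool("recent")
        add_pool("old")
        add_pool("ancestral")
        sample_into(modern + intermediate, "recent")
        sample_into(ancient, "old")
        events.append(DivergenceEvent(params["td_recent"], "recent", "old"))
        events.append(DivergenceEvent(params["td_ancestral"], "old", "ancestral"))
        anc = "ancestral"
    else:  # D, E, F share the three-pool chain
        base = ["ne_modern", "s_modern", "ne_intermediate", "s_intermediate",
                "ne_ancient", "s_ancient", "td_modern", "td_intermediate",
                "ne_ancestral", "s_ancestral", "td_ancestral"]
        if kind in "EF":
            base += ["ne_wild", "s_wild", "td_wild"]
        if kind == "F":
            base += ["r_wild"]
        _require(params, base, kind)
        add_pool("modern")
        add_pool("intermediate")
        add_pool("ancient")
        add_pool("ancestral")
        if kind in "EF":
            add_pool("wild")

        def cultivated_pool(g: GroupDesign) -> str:
            if g in modern:
                return "modern"
            if g in intermediate:
                return "intermediate"
            return "ancient"

        for g in design.groups:
            if kind == "E" and g in dark:
                sample_into([g], "wild")
            else:
                sample_into([g], cultivated_pool(g))
        if kind == "F":
            for g in dark:
                events.append(
                    AdmixtureEvent(design.time_of(g), g.label, "wild", params["r_wild"])
                )
        events.append(DivergenceEvent(params["td_modern"], "modern", "intermediate"))
        events.append(DivergenceEvent(params["td_intermediate"], "intermediate", "ancient"))
        if kind in "EF":
            events.append(DivergenceEvent(params["td_wild"], "wild", "ancient"))
        events.append(DivergenceEvent(params["td_ancestral"], "ancient", "ancestral"))
        anc = "ancestral"

    scen = DemographicScenario(pools=pools, events=events, ancestral=anc, kind=kind)
    problems = validate_scenario(scen)
    if problems:
        raise ScenarioError("; ".join(problems))
    return scen


def validate_scenario(scenario: DemographicScenario) -> list[str]:
    """Check structural invariants; returns all violations (empty = ok)."""
    problems: list[str] = []
    pool_ids = {p.id for p in scenario.pools}
    if len(pool_ids) != len(scenario.pools):
        problems.append("duplicate pool ids")
    if scenario.ancestral not in pool_ids:
        problems.append(f"ancestral pool {scenario.ancestral!r} not defined")
    for p in scenario.pools:
        if p.ne <= 0:
            problems.append(f"pool {p.id}: Ne must be > 0")
        if not (0 <= p.selfing <= 1):
            problems.append(f"pool {p.id}: selfing must be in [0, 1]")

    group_times: dict[str, float] = {}
    group_pool: dict[str, str] = {}
    divergences: dict[str, DivergenceEvent] = {}
    for e in scenario.events:
        if e.time < 0:
            problems.append(f"event {e} has negative time")
        if isinstance(e, SamplingEvent):
            if e.pool not in pool_ids:
                problems.append(f"sampling of {e.group!r} references unknown pool {e.pool!r}")
            group_times[e.group] = e.time
            group_pool[e.group] = e.pool
        elif isinstance(e, DivergenceEvent):
            if e.child in divergences:
                problems.append(f"pool {e.child!r} diverges more than once")
            divergences[e.child] = e
            for pid in (e.child, e.parent):
                if pid not in pool_ids:
                    problems.append(f"divergence references unknown pool {pid!r}")

    # pool lifetime ends at its divergence into its parent
    def end_time(pid: str) -> float:
        return divergences[pid].time if pid in divergences else math.inf

    for pid in pool_ids - {scenario.ancestral}:
        if pid not in divergences:
            problems.append(f"pool {pid!r} never coalesces into the ancestral pool")
    if scenario.ancestral in divergences:
        problems.append("ancestral pool must not diverge")

    # connectivity and parent lifetimes
    for pid, d in divergences.items():
        seen = {pid}
        cur = pid
        while cur != scenario.ancestral and cur in divergences:
            cur = divergences[cur].parent
            if cur in seen:
                problems.append(f"divergence cycle involving {pid!r}")
                break
            seen.add(cur)
        else:
            if cur != scenario.ancestral:
                problems.append(f"pool {pid!r} does not reach the ancestral pool")
        if d.parent in divergences and d.time > divergences[d.parent].time:
            problems.append(
                f"pool {d.child!r} merges into {d.parent!r} at {d.time} after the parent ended"
            )

    for e in scenario.events:
        if isinstance(e, SamplingEvent) and e.pool in divergences:
            if e.time > divergences[e.pool].time:
                problems.append(
                    f"group {e.group!r} sampled at {e.time} after pool {e.pool!r} "
                    f"diverged at {divergences[e.pool].time}"
                )
        if isinstance(e, AdmixtureEvent):
            if not (0 <= e.proportion <= 1):
                problems.append(f"admixture proportion {e.proportion} outside [0, 1]")
            if e.source not in pool_ids:
                problems.append(f"admixture references unknown source pool {e.source!r}")
            elif e.time > end_time(e.source):
                problems.append(f"admixture at {e.time} after source pool {e.source!r} ended")
            if e.target in pool_ids:
                if e.time > end_time(e.target):
                    problems.append(f"admixture at {e.time} after target pool {e.target!r} ended")
            elif e.target in group_times:
                if abs(e.time - group_times[e.target]) > 1e-9:
                    problems.append(
                        f"group-targeted admixture on {e.target!r} must occur at its "
                        f"sampling time {group_times[e.target]}"
                    )
            else:
                problems.append(f"admixture target {e.target!r} is neither a pool nor a group")
    return problems


# ---------------------------------------------------------------------------
# genealogy simulation


@dataclass
class Tree:
    """A rooted coalescent genealogy.

    Nodes are indexed in creation order, so every parent has a larger index
    than its children.  ``leaf_individual[i]`` is the diploid individual of
    leaf ``i`` (two leaves per individual), ``leaf_group[i]`` its group label.
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    leaf_individual: np.ndarray
    leaf_group: list[str]

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    def tmrca(self) -> float:
        return float(self.time[self.root])


def simulate_genealogy(
    scenario: DemographicScenario, rng: np.random.Generator
) -> Tree:
    """Simulate one locus genealogy under the scenario.

    Lineages enter at their sampling times (two per diploid; the pair
    coalesces immediately with probability F of its pool), coalesce within
    pools at rate ``k (k-1)/2 * (1+F)/(2 Ne)``, follow divergence and
    admixture events, and terminate at a single root in the ancestral pool.
    """
    events = sorted(
        scenario.events,
        key=lambda e: (
            e.time,
            0 if isinstance(e, SamplingEvent) else (1 if isinstance(e, AdmixtureEvent) else 2),
        ),
    )
    pools = {p.id: p for p in scenario.pools}

    times: list[float] = []
    parent: list[int] = []
    leaf_individual: list[int] = []
    leaf_group: list[str] = []
    active: dict[str, list[int]] = {p.id: [] for p in scenario.pools}
    group_lineages: dict[str, list[int]] = {}
    n_ind = 0

    def new_node(t: float) -> int:
        times.append(t)
        parent.append(-1)
        return len(times) - 1

    pool_ids = [p.id for p in scenario.pools]
    pool_coef = {p.id: (1.0 + p.F) / (2.0 * p.ne) for p in scenario.pools}

    def run_coalescent(t: float, until: float) -> float:
        while True:
            total = 0.0
            rates = []
            for pid in pool_ids:
                k = len(active[pid])
                if k >= 2:
                    rate = k * (k - 1) * 0.5 * pool_coef[pid]
                    rates.append((pid, rate))
                    total += rate
            if total == 0.0:
                return until
            wait = rng.exponential() / total
            if t + wait >= until:
                return until
            t += wait
            u = rng.random() * total
            acc = 0.0
            for pid, rate in rates:
                acc += rate
                if u <= acc:
                    lst = active[pid]
                    k = len(lst)
                    i = int(rng.integers(k))
                    j = int(rng.integers(k - 1))
                    if j >= i:
                        j += 1
                    node = new_node(t)
                    parent[lst[i]] = node
                    parent[lst[j]] = node
                    hi, lo = (i, j) if i > j else (j, i)
                    lst[hi] = lst[-1]
                    lst.pop()
                    if lo < len(lst):
                        lst[lo] = lst[-1]
                        lst.pop()
                    else:
                        lst.pop()
                    lst.append(node)
                    break

    t = 0.0
    n_leaves_total = 2 * sum(e.n for e in scenario.sampling_events)
    for ev in events:
        t = run_coalescent(t, ev.time)
        if isinstance(ev, SamplingEvent):
            F = pools[ev.pool].F
            lin: list[int] = []
            for _ in range(ev.n):
                a = new_node(ev.time)
                b = new_node(ev.time)
                leaf_individual.extend([n_ind, n_ind])
                leaf_group.extend([ev.group, ev.group])
                n_ind += 1
                if F > 0 and rng.random() < F:
                    node = new_node(ev.time)
                    parent[a] = node
                    parent[b] = node
                    lin.append(node)
                else:
                    lin.extend([a, b])
            active[ev.pool].extend(lin)
            group_lineages[ev.group] = lin
        elif isinstance(ev, AdmixtureEvent):
            if ev.target in active:  # pool target
                src_pool = ev.target
                candidates = list(active[src_pool])
            else:  # group target, right after its sampling
                candidates = [l for l in group_lineages.get(ev.target, [])]
                src_pool = None
            for lineage in candidates:
                if rng.random() < ev.proportion:
                    home = src_pool
                    if home is None:
                        # locate the pool currently holding this lineage
                        for pid, lst in active.items():
                            if lineage in lst:
                                home = pid
                                break
                    active[home].remove(lineage)
                    active[ev.source].append(lineage)
        elif isinstance(ev, DivergenceEvent):
            active[ev.parent].extend(active[ev.child])
            active[ev.child] = []

    # only the ancestral pool can hold lineages now; coalesce to the root
    leftovers = [pid for pid, lst in active.items() if lst and pid != scenario.ancestral]
    if leftovers:
        raise ScenarioError(f"lineages stranded in non-ancestral pool(s) {leftovers}")
    run_coalescent(t, math.inf)

    return Tree(
        parent=np.asarray(parent, dtype=np.int64),
        time=np.asarray(times, dtype=float),
        n_leaves=n_leaves_total,
        leaf_individual=np.asarray(leaf_individual, dtype=np.int64),
        leaf_group=leaf_group,
    )


def apply_mutations(tree: Tree, model: MutationModel, rng: np.random.Generator) -> np.ndarray:
    """Drop generalized-stepwise mutations on the tree; allele size per leaf.

    The root allele is the midpoint of the size bounds.  Mutations are
    Poisson on each branch; steps reflect at the bounds.
    """
    lo, hi = model.size_bounds
    n_nodes = len(tree.parent)
    alleles = np.empty(n_nodes, dtype=np.int64)
    root = tree.root
    alleles[root] = (lo + hi) // 2
    # Poisson mutation counts for every branch in one draw
    par = tree.parent[:-1]
    branch = tree.time[par] - tree.time[:-1]
    n_mut = rng.poisson(model.mu * branch) if model.mu > 0 else np.zeros(n_nodes - 1, dtype=np.int64)
    total_mut = int(n_mut.sum())
    if total_mut:
        mags = rng.geometric(1.0 - model.p_geom, size=total_mut) if model.p_geom > 0 \
            else np.ones(total_mut, dtype=np.int64)
        signs = rng.integers(0, 2, size=total_mut) * 2 - 1
        steps = mags * signs
    pos = 0
    # creation order guarantees parent index > child index: walk root-to-leaves
    for node in range(n_nodes - 2, -1, -1):
        allele = alleles[par[node]]
        for _ in range(n_mut[node]):
            allele += steps[pos]
            pos += 1
            # reflect at the bounds
            while allele < lo or allele > hi:
                allele = 2 * lo - allele if allele < lo else 2 * hi - allele
        alleles[node] = allele
    # leaves = childless nodes; their index order matches leaf creation order
    counts = np.bincount(tree.parent[tree.parent >= 0], minlength=n_nodes)
    return alleles[counts == 0]


def _leaf_indices(tree: Tree) -> np.ndarray:
    counts = np.bincount(tree.parent[tree.parent >= 0], minlength=len(tree.parent))
    return np.nonzero(counts == 0)[0]


def simulate_dataset(
    scenario: DemographicScenario,
    model: MutationModel,
    design: SamplingDesign,
    n_loci: int = 24,
    rng: np.random.Generator | None = None,
    locus_prefix: str = "L",
) -> GenotypeDataset:
    """Simulate ``n_loci`` independent SSR loci into a genotype dataset.

    Each locus gets its own genealogy (and its own instantaneous-selfing
    draws), so per-locus heterozygosity deficits are independent as in real
    multilocus data.  Group metadata comes from the design.
    """
    if rng is None:
        rng = np.random.default_rng()
    sampling = scenario.sampling_events
    n_ind = sum(e.n for e in sampling)
    calls = np.empty((n_ind, n_loci, 2), dtype=np.int32)
    for j in range(n_loci):
        tree = simulate_genealogy(scenario, rng)
        alleles = apply_mutations(tree, model, rng)
        leaves = _leaf_indices(tree)
        # map leaves back to (individual, slot)
        slot_seen: dict[int, int] = {}
        for leaf_pos, node in enumerate(leaves):
            ind = tree.leaf_individual[leaf_pos]
            slot = slot_seen.get(ind, 0)
            calls[ind, j, slot] = alleles[leaf_pos]
            slot_seen[ind] = slot + 1

    groups = []
    individual_ids = []
    individual_group = []
    seen_groups = set()
    for ev in sampling:
        if ev.group not in seen_groups:
            g = design.group(ev.group)
            groups.append(
                SampleGroup(
                    label=ev.group,
                    site="simulated",
                    type=g.type,
                    age_calBP=g.age_calBP,
                    seed_color=ev.seed_color,
                )
            )
            seen_groups.add(ev.group)
        for k in range(ev.n):
            individual_ids.append(f"{ev.group}_{k}")
            individual_group.append(ev.group)

    loci = [Locus(f"{locus_prefix}{j+1:02d}") for j in range(n_loci)]
    return GenotypeDataset(
        loci=loci,
        groups=groups,
        individual_ids=individual_ids,
        individual_group=individual_group,
        calls=calls,
    )
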