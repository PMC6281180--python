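"""Synthetic genotype generation for fixtures and pseudo-observed data.

Two generators are provided:

* a fast non-genealogical generator (:func:`dirichlet_group_genotypes`) that
  draws per-locus allele frequencies from a Dirichlet and genotypes with a
  chosen inbreeding coefficient — useful as an oracle for the diversity and
  selfing statistics because its parameters map directly onto them;
* :func:`make_pseudo_observed`, which wraps the coalescent simulator and the
  missingness injector to produce datasets with a known demographic truth.

The default sampling designs mirror an ancient-to-modern seed survey: a
seven-group temporal series at one locality (ages 0, 690, 796, 1364 and
1796 cal BP, with dark-seeded weedy groups alongside white-seeded ones at
796 and 1364 cal BP) and a wider 19-group survey of 157 seeds (81 modern,
76 ancient) genotyped at 24 loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeDataset, Locus, SampleGroup
from .simulate import (
    GroupDesign,
    MutationModel,
    SamplingDesign,
    build_scenario,
    simulate_dataset,
)

__all__ = [
    "GroupSpec",
    "GeneratorSpec",
    "dirichlet_group_genotypes",
    "forward_selfing_genotypes",
    "inject_missing",
    "temporal_series_design",
    "survey_design",
    "make_pseudo_observed",
]


@dataclass(frozen=True)
class GroupSpec:
    """Generator settings for one sample group."""

    label: str
    n: int
    inbreeding: float = 0.0
    missing_rate: float = 0.0
    age_calBP: float = 0.0
    seed_color: str = "white"
    alpha: float = 1.0  # Dirichlet concentration per allele
    n_alleles: int = 5

    @property
    def type(self) -> str:
        return "modern" if self.age_calBP == 0 else "ancient"


@dataclass
class GeneratorSpec:
    """A full synthetic-dataset specification: groups plus locus count."""

    groups: list[GroupSpec]
    n_loci: int = 24
    base_allele_size: int = 10


def _genotype_block(freqs: np.ndarray, n: int, F: float, rng: np.random.Generator) -> np.ndarray:
    """n diploid genotypes at one locus: autozygous w.p. F, else two draws."""
    k = len(freqs)
    auto = rng.random(n) < F
    a1 = rng.choice(k, size=n, p=freqs)
    a2 = rng.choice(k, size=n, p=freqs)
    a2[auto] = a1[auto]
    return np.stack([a1, a2], axis=1)


def dirichlet_group_genotypes(spec: GeneratorSpec, rng: np.random.Generator) -> GenotypeDataset:
    """Draw a dataset with independent Dirichlet frequencies per group x locus.

    With probability equal to the group's ``inbreeding`` an individual is
    autozygous at a locus (one allele drawn and copied), otherwise its two
    gene copies are independent draws — so the expected per-locus Fis equals
    the group's inbreeding coefficient.
    """
    n_total = sum(g.n for g in spec.groups)
    calls = np.empty((n_total, spec.n_loci, 2), dtype=np.int32)
    row = 0
    groups, ids, ind_group = [], [], []
    for g in spec.groups:
        groups.append(
            SampleGroup(g.label, site="synthetic", type=g.type,
                        age_calBP=g.age_calBP, seed_color=g.seed_color)
        )
        for j in range(spec.n_loci):
            freqs = rng.dirichlet(np.full(g.n_alleles, g.alpha))
            block = _genotype_block(freqs, g.n, g.inbreeding, rng)
            calls[row:row + g.n, j, :] = block + spec.base_allele_size
        for k in range(g.n):
            ids.append(f"{g.label}_{k}")
            ind_group.append(g.label)
        row += g.n
    ds = GenotypeDataset(
        loci=[Locus(f"L{j+1:02d}") for j in range(spec.n_loci)],
        groups=groups,
        individual_ids=ids,
        individual_group=ind_group,
        calls=calls,
    )
    rates = {g.label: g.missing_rate for g in spec.groups if g.missing_rate > 0}
    if rates:
        ds, _ = inject_missing(ds, rates, rng)
    return ds


def forward_selfing_genotypes(
    freqs: list[np.ndarray],
    s: float,
    n: int,
    rng: np.random.Generator,
    label: str = "pop",
    base_allele_size: int = 10,
) -> GenotypeDataset:
    """Forward-in-time partial-selfing generator (independent of the coalescent).

    Each individual's pedigree is: an outcrossed ancestor (two independent
    allele draws per locus from ``freqs``) followed by ``t`` generations of
    selfing, ``t`` geometric with success probability ``1 - s``.  Each
    selfing generation keeps a heterozygous locus heterozygous with
    probability 1/2, otherwise fixes one of its two alleles at random.
    """
    L = len(freqs)
    calls = np.empty((n, L, 2), dtype=np.int32)
    t_gen = np.zeros(n, dtype=int)
    if s > 0:
        t_gen = rng.geometric(1.0 - s, size=n) - 1
    for j, p in enumerate(freqs):
        k = len(p)
        a1 = rng.choice(k, size=n, p=p)
        a2 = rng.choice(k, size=n, p=p)
        for i in range(n):
            x, y = a1[i], a2[i]
            for _ in range(int(t_gen[i])):
                if x == y:
                    break
                if rng.random() < 0.5:  # heterozygosity lost this generation
                    x = y = x if rng.random() < 0.5 else y
            calls[i, j, 0] = x + base_allele_size
            calls[i, j, 1] = y + base_allele_size
    return GenotypeDataset(
        loci=[Locus(f"L{j+1:02d}") for j in range(L)],
        groups=[SampleGroup(label, site="synthetic", type="modern")],
        individual_ids=[f"{label}_{i}" for i in range(n)],
        individual_group=[label] * n,
        calls=calls,
    )


def inject_missing(
    dataset: GenotypeDataset,
    rates,
    rng: np.random.Generator,
) -> tuple[GenotypeDataset, np.ndarray]:
    """Set calls missing completely at random, per group.

    ``rates`` is a scalar rate for every group or a mapping
    ``{group label: rate}`` (absent groups keep rate 0).  Returns the new
    dataset and the boolean mask of injected missing cells, reusable to
    impose the same observation process on simulated data.
    """
    if np.isscalar(rates):
        rate_of = {g.label: float(rates) for g in dataset.groups}
    else:
        rate_of = {g.label: float(rates.get(g.label, 0.0)) for g in dataset.groups}
    for lab, r in rate_of.items():
        if not (0 <= r < 1):
            raise ValueError(f"missing rate for {lab!r} must be in [0, 1)")
    mask = np.zeros((dataset.n_individuals, dataset.n_loci), dtype=bool)
    for g in dataset.groups:
        rows = dataset.group_rows(g.label)
        r = rate_of[g.label]
        if r > 0 and len(rows):
            mask[rows] = rng.random((len(rows), dataset.n_loci)) < r
    out = dataset.copy()
    out.calls[mask] = MISSING
    return out, mask


def temporal_series_design(n_per_group: int = 10, generation_time: float = 1.0) -> SamplingDesign:
    """The seven-group temporal series at one locality.

    One modern white-seeded group (#12) and six ancient groups spanning
    ~18 centuries, with dark-seeded (weedy) groups #15 and #18 sampled
    alongside white-seeded groups of the same age.
    """
    n = n_per_group
    return SamplingDesign(
        groups=[
            GroupDesign("#12", 0.0, n, "white"),
            GroupDesign("#13", 690.0, n, "white"),
            GroupDesign("#14", 796.0, n, "white"),
            GroupDesign("#15", 796.0, n, "dark"),
            GroupDesign("#17", 1364.0, n, "white"),
            GroupDesign("#18", 1364.0, n, "dark"),
            GroupDesign("#19", 1796.0, n, "white"),
        ],
        generation_time=generation_time,
    )


def survey_design() -> list[GroupSpec]:
    """A 19-group survey emulating the full seed collection: 157 seeds,
    81 modern in 12 groups and 76 ancient in 7 groups, with heterogeneous
    selfing (high inbreeding overall) and ancient-DNA missingness."""
    rng_alpha = 0.4  # uneven allele frequencies, realistic for SSRs
    groups: list[GroupSpec] = []
    modern_sizes = [7, 7, 7, 7, 7, 7, 7, 7, 7, 6, 6, 6]  # 81
    for i, n in enumerate(modern_sizes, start=1):
        groups.append(GroupSpec(f"#{i}", n, inbreeding=0.85, missing_rate=0.02,
                                alpha=rng_alpha, n_alleles=6))
    ancient = [
        ("#13", 13, 690.0, "white"),
        ("#14", 13, 796.0, "white"),
        ("#15", 12, 796.0, "dark"),
        ("#16", 2, 1270.0, "white"),
        ("#17", 12, 1364.0, "white"),
        ("#18", 12, 1364.0, "dark"),
        ("#19", 12, 1796.0, "white"),
    ]  # 76
    for label, n, age, color in ancient:
        groups.append(GroupSpec(label, n, inbreeding=0.7, missing_rate=0.2,
                                age_calBP=age, seed_color=color,
                                alpha=rng_alpha, n_alleles=6))
    return groups


def make_pseudo_observed(
    kind: str,
    params: dict,
    design: SamplingDesign,
    missing_rates=0.0,
    rng: np.random.Generator | None = None,
    n_loci: int = 24,
    model: MutationModel | None = None,
):
    """Simulate a dataset of known demographic truth and degrade it.

    Returns ``(dataset, mask, truth)`` where ``truth`` records the scenario
    kind and parameters for recovery experiments.
    """
    if rng is None:
        rng = np.random.default_rng()
    if model is None:
        model = MutationModel()
    scen = build_scenario(kind, params, design)
    ds = simulate_dataset(scen, model, design, n_loci=n_loci, rng=rng)
    ds, mask = inject_missing(ds, missing_rates, rng)
    truth = {"kind": kind, "params": dict(params), "mutation": model}
    return ds, mask, truth
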