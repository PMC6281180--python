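"""ABC random forests: model choice among demographic scenarios and
parameter estimation from a simulated reference table.

Workflow (Pudlo et al. 2016; Raynal et al. 2019):

1. draw parameters from priors, simulate a dataset per draw, reduce it to a
   fixed vector of summary statistics -> the reference table;
2. train a random-forest classifier (summaries -> scenario); the fraction of
   trees voting for each scenario at the observed summaries is the vote
   vector, the out-of-bag misclassification rate is the prior error rate,
   and the posterior probability of the selected scenario is the prediction
   of a regression forest trained on the out-of-bag correctness indicators;
3. for the selected scenario, train one regression forest per parameter; the
   point estimate is the forest prediction at the observed summaries and the
   95% interval comes from weighted quantiles of the training responses,
   weighted by leaf co-occurrence with the observed vector.

Summary statistics (fixed order): per group — mean unbiased He, mean allele
count, mean allele-size variance, proportion of monomorphic loci, Fis; per
ordered group pair — Weir & Cockerham Fst and Goldstein's delta-mu^2.
Observed ancient-DNA missingness is imposed on every simulated dataset
(matched per-group rates) before summarization, so simulated and observed
summaries are affected by the same observation process.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .genotypes import MISSING, GenotypeDataset
from .simulate import MutationModel, SamplingDesign, build_scenario, simulate_dataset
from .synthetic import inject_missing

__all__ = [
    "LogUniform",
    "Uniform",
    "Fixed",
    "PriorSpec",
    "default_priors",
    "draw_from_priors",
    "summary_statistics",
    "summary_names",
    "ReferenceTable",
    "build_reference_table",
    "AbcResult",
    "ModelChoiceForest",
    "ParameterEstimator",
    "classify_models",
    "estimate_parameters",
]


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class LogUniform:
    low: float
    high: float

    def draw(self, rng) -> float:
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def draw(self, rng) -> float:
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class Fixed:
    value: float

    def draw(self, rng) -> float:
        return float(self.value)


@dataclass
class PriorSpec:
    """Named prior distributions plus pairwise ordering constraints.

    ``constraints`` is a list of ``(a, b)`` meaning a draw must satisfy
    ``params[a] <= params[b]``; violating draws are rejected and redrawn.
    """

    distributions: dict
    constraints: list[tuple[str, str]] = field(default_factory=list)

    def describe(self) -> dict:
        return {k: repr(v) for k, v in self.distributions.items()}


_POOLS_BY_KIND = {
    "A": ["main", "ancestral"],
    "B": ["modern", "ancient", "ancestral"],
    "C": ["recent", "old", "ancestral"],
    "D": ["modern", "intermediate", "ancient", "ancestral"],
    "E": ["modern", "intermediate", "ancient", "wild", "ancestral"],
    "F": ["modern", "intermediate", "ancient", "wild", "ancestral"],
}


def default_priors(kind: str, design: SamplingDesign,
                   ne_bounds=(10.0, 1e4), td_max: float = 1e4,
                   mu_bounds=(1e-4, 1e-3), p_geom_max: float = 0.6) -> PriorSpec:
    """Reference priors for one scenario kind under a sampling design.

    Ne per pool: log-uniform(10, 1e4).  Divergence times: log-uniform between
    the oldest sample age that depends on the pool (floored at 10
    generations) and 1e4 generations, with ordering constraints enforced by
    rejection.  Selfing per pool: uniform(0, 1).  Mutation rate:
    log-uniform(1e-4, 1e-3); geometric step parameter: uniform(0, 0.6);
    admixture proportion (scenario F): uniform(0, 1).
    """
    kind = kind.upper()
    ages = [g.age_calBP / design.generation_time for g in design.groups]
    oldest = max(ages)
    inter_ages = [a for a in ages if 0 < a < 1000] or [10.0]
    dark_ages = [g.age_calBP / design.generation_time
                 for g in design.groups if g.seed_color == "dark"] or [10.0]

    dists: dict = {}
    constraints: list[tuple[str, str]] = []
    for pool in _POOLS_BY_KIND[kind]:
        dists[f"ne_{pool}"] = LogUniform(*ne_bounds)
        dists[f"s_{pool}"] = Uniform(0.0, 1.0)

    def td(name, low):
        dists[name] = LogUniform(max(low, 10.0), td_max)

    td("td_ancestral", oldest)
    if kind == "B":
        td("td_modern", 10.0)
        constraints.append(("td_modern", "td_ancestral"))
    elif kind == "C":
        td("td_recent", max(a for a in ages if a < 1000))
        constraints.append(("td_recent", "td_ancestral"))
    elif kind in "DEF":
        td("td_modern", 10.0)
        td("td_intermediate", max(inter_ages))
        constraints += [("td_modern", "td_intermediate"),
                        ("td_intermediate", "td_ancestral")]
        if kind in "EF":
            td("td_wild", max(dark_ages))
            constraints.append(("td_wild", "td_ancestral"))
    dists["mu"] = LogUniform(*mu_bounds)
    dists["p_geom"] = Uniform(0.0, p_geom_max)
    if kind == "F":
        dists["r_wild"] = Uniform(0.0, 1.0)
    return PriorSpec(dists, constraints)


def draw_from_priors(spec: PriorSpec, rng: np.random.Generator,
                     max_tries: int = 1000) -> dict:
    """One parameter vector satisfying the ordering constraints (rejection)."""
    for _ in range(max_tries):
        params = {k: d.draw(rng) for k, d in spec.distributions.items()}
        if all(params[a] <= params[b] for a, b in spec.constraints):
            return params
    raise RuntimeError("prior constraints unsatisfiable after bounded retries")


# ---------------------------------------------------------------------------
# summary statistics


def summary_names(group_labels: list[str]) -> list[str]:
    names = []
    for lab in group_labels:
        names += [f"He:{lab}", f"Nall:{lab}", f"VarSize:{lab}",
                  f"PropMono:{lab}", f"Fis:{lab}"]
    for i, a in enumerate(group_labels):
        for b in group_labels[i + 1:]:
            names += [f"Fst:{a}|{b}", f"dmu2:{a}|{b}"]
    return names


def summary_statistics(dataset: GenotypeDataset, sentinel: float = 0.0) -> np.ndarray:
    """The fixed summary vector (length 5 G + 2 C(G,2)).

    Per group: mean unbiased He (monomorphic loci count as He = 0), mean
    allele count, mean allele-size variance, proportion of monomorphic loci,
    multilocus Fis; per pair: multilocus Weir & Cockerham Fst and
    delta-mu^2.  Statistics undefined on the data at hand (a group with no
    observed call, a pair with no joint polymorphism) are set to
    ``sentinel``.  Vectorized per locus over all groups and pairs.
    """
    G = len(dataset.group_labels)
    L = dataset.n_loci
    gidx = np.empty(dataset.n_individuals, dtype=np.intp)
    for gi, lab in enumerate(dataset.group_labels):
        gidx[dataset.group_rows(lab)] = gi
    pair_i, pair_j = np.triu_indices(G, k=1)
    P = len(pair_i)

    he_sum = np.zeros(G); nall_sum = np.zeros(G); var_sum = np.zeros(G)
    mono_cnt = np.zeros(G); data_cnt = np.zeros(G)
    fis_b = np.zeros(G); fis_c = np.zeros(G)
    pa = np.zeros(P); pb = np.zeros(P); pc = np.zeros(P)
    d2_sum = np.zeros(P); d2_cnt = np.zeros(P)

    for j in range(L):
        calls = dataset.calls[:, j, :]
        obs = calls[:, 0] != MISSING
        if not obs.any():
            continue
        flat = calls[obs].ravel()
        u, inv = np.unique(flat, return_inverse=True)
        A = u.size
        g_obs = gidx[obs]
        n_g = np.bincount(g_obs, minlength=G).astype(float)
        C = np.zeros((G, A))
        np.add.at(C, (np.repeat(g_obs, 2), inv), 1.0)
        het = obs & (calls[:, 0] != calls[:, 1])
        H = np.zeros((G, A))
        if het.any():
            hflat = np.searchsorted(u, calls[het].ravel())
            np.add.at(H, (np.repeat(gidx[het], 2), hflat), 1.0)

        has = n_g > 0
        ncop = 2.0 * n_g
        with np.errstate(divide="ignore", invalid="ignore"):
            p_full = C / ncop[:, None]
            m = (C @ u.astype(float)) / ncop
            msq = (C @ (u.astype(float) ** 2)) / ncop
            var = msq - m**2
            nall = (C > 0).sum(axis=1).astype(float)
            sum_p2 = (p_full**2).sum(axis=1)
            he = np.where(ncop > 1, ncop / np.maximum(ncop - 1, 1) * (1 - sum_p2), 0.0)
        data_cnt += has
        mono_cnt += has & (nall == 1)
        he_sum[has] += he[has]
        nall_sum[has] += nall[has]
        var_sum[has] += var[has]
        # single-group Weir & Cockerham Fis components
        ok = n_g >= 2
        if ok.any():
            n2 = n_g[ok][:, None]
            p2m = C[ok] / (2.0 * n2)
            hbar = H[ok] / n2
            b = (n2 / (n2 - 1)) * (p2m * (1 - p2m) - (2 * n2 - 1) / (4 * n2) * hbar)
            fis_b[ok] += b.sum(axis=1)
            fis_c[ok] += (hbar / 2.0).sum(axis=1)
        # pairwise components, vectorized over pairs
        n1, n2p = n_g[pair_i], n_g[pair_j]
        ok_pair = (n1 >= 1) & (n2p >= 1) & ((n1 + n2p) >= 3)
        if ok_pair.any():
            I, J = pair_i[ok_pair], pair_j[ok_pair]
            na, nb = n_g[I][:, None], n_g[J][:, None]
            p1, pZ = C[I] / (2 * na), C[J] / (2 * nb)
            h1, h2 = H[I] / na, H[J] / nb
            nbar = (na + nb) / 2.0
            nc = 2.0 * na * nb / (na + nb)
            pbar = (na * p1 + nb * pZ) / (2 * nbar)
            s2 = (na * (p1 - pbar) ** 2 + nb * (pZ - pbar) ** 2) / nbar
            hbar = (na * h1 + nb * h2) / (2 * nbar)
            inner = pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0
            a = (nbar / nc) * (s2 - inner / (nbar - 1))
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 / 2.0 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0
            pa[ok_pair] += a.sum(axis=1)
            pb[ok_pair] += b.sum(axis=1)
            pc[ok_pair] += c.sum(axis=1)
        both = has[pair_i] & has[pair_j]
        d2_sum[both] += (m[pair_i[both]] - m[pair_j[both]]) ** 2
        d2_cnt[both] += 1

    out = np.empty(5 * G + 2 * P)
    with np.errstate(divide="ignore", invalid="ignore"):
        for gi in range(G):
            d = data_cnt[gi]
            denom_f = fis_b[gi] + fis_c[gi]
            out[5 * gi: 5 * gi + 5] = [
                he_sum[gi] / d if d else sentinel,
                nall_sum[gi] / d if d else sentinel,
                var_sum[gi] / d if d else sentinel,
                mono_cnt[gi] / d if d else sentinel,
                1 - fis_c[gi] / denom_f if denom_f > 0 else sentinel,
            ]
        base = 5 * G
        tot = pa + pb + pc
        fst = np.where(tot != 0, pa / np.where(tot != 0, tot, 1.0), sentinel)
        d2 = np.where(d2_cnt > 0, d2_sum / np.maximum(d2_cnt, 1), sentinel)
        out[base::2] = fst
        out[base + 1::2] = d2
    return out


# ---------------------------------------------------------------------------
# reference table


@dataclass
class ReferenceTable:
    """Per-simulation (scenario kind, parameter vector, summary vector)."""

    kinds: np.ndarray
    params: pd.DataFrame
    summaries: np.ndarray
    stat_names: list[str]
    priors: dict
    design: SamplingDesign
    n_loci: int

    def rows_for(self, kind: str) -> np.ndarray:
        return np.nonzero(self.kinds == kind)[0]


def build_reference_table(
    kinds: list[str],
    design: SamplingDesign,
    n_per_scenario: int = 2000,
    n_loci: int = 24,
    seed: int | None = None,
    priors: dict | None = None,
    missing_rates=None,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate the ABC reference table.

    ``priors`` maps scenario kind -> :class:`PriorSpec` (defaults from
    :func:`default_priors`).  ``missing_rates`` (per-group) imposes the
    observed missingness process on every simulated dataset.
    """
    if len(kinds) < 2:
        raise ValueError("need at least 2 scenarios")
    rng = np.random.default_rng(seed)
    priors = priors or {}
    for kind in kinds:
        priors.setdefault(kind, default_priors(kind, design))
    rows_kind, rows_params, rows_sum = [], [], []
    labels = None
    for kind in kinds:
        spec = priors[kind]
        done = 0
        while done < n_per_scenario:
            params = draw_from_priors(spec, rng)
            model = MutationModel(mu=params["mu"], p_geom=params["p_geom"])
            try:
                scen = build_scenario(kind, params, design)
                ds = simulate_dataset(scen, model, design, n_loci=n_loci, rng=rng)
            except Exception:  # rare degenerate draw: retry with a fresh one
                continue
            if missing_rates is not None:
                ds, _ = inject_missing(ds, missing_rates, rng)
            if labels is None:
                labels = ds.group_labels
            rows_kind.append(kind)
            rows_params.append(params)
            rows_sum.append(summary_statistics(ds))
            done += 1
            if progress and done % 500 == 0:  # pragma: no cover
                print(f"scenario {kind}: {done}/{n_per_scenario}")
    return ReferenceTable(
        kinds=np.asarray(rows_kind),
        params=pd.DataFrame(rows_params),
        summaries=np.vstack(rows_sum),
        stat_names=summary_names(labels),
        priors={k: priors[k].describe() for k in kinds},
        design=design,
        n_loci=n_loci,
    )


# ---------------------------------------------------------------------------
# model choice and parameter estimation


@dataclass
class AbcResult:
    """Votes, selected scenario, posterior probability and error rate."""

    votes: dict[str, float]
    selected: str
    posterior_probability: float
    prior_error_rate: float
    parameter_estimates: dict[str, dict] = field(default_factory=dict)


class ModelChoiceForest:
    """Random-forest scenario classifier fitted on a reference table.

    Fit once, then query any number of observed summary vectors: votes are
    per-tree prediction frequencies, the prior error rate is the out-of-bag
    misclassification rate, and the posterior probability of the selected
    scenario is the prediction of a regression forest trained on the
    out-of-bag correctness indicators (the ABC-RF scheme of Pudlo et al.).
    """

    def __init__(self, table: ReferenceTable, n_trees: int = 500,
                 seed: int | None = None):
        kinds = np.unique(table.kinds)
        if kinds.size < 2:
            raise ValueError("reference table holds a single scenario")
        counts = {k: int((table.kinds == k).sum()) for k in kinds}
        if min(counts.values()) < 100:
            warnings.warn(f"fewer than 100 simulations for some scenario: {counts}")
        self.classifier = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # some rows may never be out-of-bag
            self.classifier.fit(table.summaries, table.kinds)
        self.prior_error_rate = 1.0 - float(self.classifier.oob_score_)
        oob = self.classifier.oob_decision_function_
        valid = ~np.isnan(oob).any(axis=1)
        oob_pred = self.classifier.classes_[np.argmax(oob[valid], axis=1)]
        correct = (oob_pred == table.kinds[valid]).astype(float)
        self._posterior_forest = RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        self._posterior_forest.fit(table.summaries[valid], correct)

    def votes(self, observed: np.ndarray) -> dict[str, float]:
        obs = np.asarray(observed, dtype=float).reshape(1, -1)
        clf = self.classifier
        tree_pred = np.array([t.predict(obs)[0] for t in clf.estimators_])
        return {str(k): float(np.mean(tree_pred == i))
                for i, k in enumerate(clf.classes_)}

    def predict(self, observed: np.ndarray) -> AbcResult:
        votes = self.votes(observed)
        selected = max(votes, key=votes.get)
        obs = np.asarray(observed, dtype=float).reshape(1, -1)
        post = float(np.clip(self._posterior_forest.predict(obs)[0], 0.0, 1.0))
        return AbcResult(
            votes=votes,
            selected=selected,
            posterior_probability=post,
            prior_error_rate=self.prior_error_rate,
        )

    def predict_kinds(self, observed_matrix: np.ndarray) -> np.ndarray:
        """Selected scenario for each row of a batch of summary vectors."""
        return self.classifier.predict(np.atleast_2d(observed_matrix))


def classify_models(
    table: ReferenceTable,
    observed: np.ndarray,
    n_trees: int = 500,
    seed: int | None = None,
) -> AbcResult:
    """One-shot model choice at a single observed summary vector."""
    return ModelChoiceForest(table, n_trees=n_trees, seed=seed).predict(observed)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return float(np.interp(q, cw, v))


class ParameterEstimator:
    """Regression forests for the parameters of one scenario, fit once.

    For each parameter the point estimate at an observed summary vector is
    the forest prediction; the "95% interval" is the weighted 2.5%/97.5%
    quantile of the training responses, with weights given by how often a
    training row shares a leaf with the observed vector across trees.
    """

    def __init__(self, table: ReferenceTable, kind: str,
                 parameters: list[str] | None = None,
                 n_trees: int = 500, seed: int | None = None):
        rows = table.rows_for(kind)
        if rows.size == 0:
            raise ValueError(f"no reference rows for scenario {kind!r}")
        if rows.size < 500:
            warnings.warn(f"only {rows.size} reference rows for scenario {kind!r}")
        self.kind = kind
        X = table.summaries[rows]
        self._X = X
        self.forests: dict[str, RandomForestRegressor] = {}
        self._y: dict[str, np.ndarray] = {}
        self._leaves: dict[str, np.ndarray] = {}
        cols = parameters or [c for c in table.params.columns
                              if table.params[c].iloc[rows].notna().all()]
        for name in cols:
            y = table.params[name].to_numpy()[rows]
            if np.nanstd(y) == 0:
                warnings.warn(f"parameter {name!r} is constant; skipped")
                continue
            rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
            rf.fit(X, y)
            self.forests[name] = rf
            self._y[name] = y
            self._leaves[name] = rf.apply(X)  # n_rows x n_trees leaf ids

    def estimate(self, observed: np.ndarray) -> dict[str, dict]:
        obs = np.asarray(observed, dtype=float).reshape(1, -1)
        out: dict[str, dict] = {}
        for name, rf in self.forests.items():
            y = self._y[name]
            leaves_train = self._leaves[name]
            leaves_obs = rf.apply(obs)[0]
            match = leaves_train == leaves_obs[None, :]
            sizes = match.sum(axis=0).astype(float)
            sizes[sizes == 0] = np.inf
            w = (match / sizes[None, :]).sum(axis=1)
            out[name] = {
                "point": float(rf.predict(obs)[0]),
                "q025": _weighted_quantile(y, w, 0.025),
                "median": _weighted_quantile(y, w, 0.5),
                "q975": _weighted_quantile(y, w, 0.975),
            }
        return out


def estimate_parameters(
    table: ReferenceTable,
    kind: str,
    observed: np.ndarray,
    n_trees: int = 500,
    seed: int | None = None,
    parameters: list[str] | None = None,
) -> dict[str, dict]:
    """One-shot posterior parameter summaries at a single observed vector."""
    est = ParameterEstimator(table, kind, parameters=parameters,
                             n_trees=n_trees, seed=seed)
    return est.estimate(observed)
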