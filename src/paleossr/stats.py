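"""Diversity, differentiation and selfing-related statistics for SSR data.

Implements the per-sample diversity surface (observed/unbiased expected
heterozygosity, mean and rarefied allelic richness, multilocus genotype
counts, inbreeding coefficient) and Weir & Cockerham (1984)
variance-component F-statistics with pairwise Fst, plus the allele-size
moments (Goldstein's delta-mu-squared) used as between-group summaries for
demographic inference.

Conventions
-----------
* Unbiased expected heterozygosity: He = n/(n-1) * (1 - sum p_i^2), with n
  the number of observed gene copies.
* Rarefied allelic richness at g gene copies: sum over alleles of
  1 - C(n - N_a, g) / C(n, g)  (ADZE-style expectation under sampling
  without replacement), with impossible draws contributing 0.
* Loci monomorphic across all analyzed groups are omitted from the
  F-statistic ratios (their variance components are undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, EmptyDataError, GenotypeDataset

__all__ = [
    "observed_heterozygosity",
    "expected_heterozygosity_unbiased",
    "rarefied_allele_count",
    "multilocus_genotype_count",
    "fstats_weir_cockerham",
    "fis_single_group",
    "pairwise_fst",
    "selfing_from_fis",
    "allele_size_moments",
    "delta_mu_squared",
    "diversity_table",
]


# ---------------------------------------------------------------------------
# per-locus heterozygosity and richness


def observed_heterozygosity(dataset: GenotypeDataset, group: str) -> tuple[np.ndarray, float]:
    """Per-locus observed heterozygosity Ho and its mean over scorable loci.

    Ho at a locus is the fraction of non-missing individuals carrying two
    distinct alleles.  Loci with no data in the group are NaN and excluded
    from the mean.  Raises :class:`EmptyDataError` if the group has no
    observed calls at any locus.
    """
    rows = dataset.group_rows(group)
    calls = dataset.calls[rows]
    obs = calls[..., 0] != MISSING
    if not obs.any():
        raise EmptyDataError(f"group {group!r} has no observed calls")
    het = (calls[..., 0] != calls[..., 1]) & obs
    with np.errstate(invalid="ignore"):
        per_locus = het.sum(axis=0) / obs.sum(axis=0)
    return per_locus, float(np.nanmean(per_locus))


def expected_heterozygosity_unbiased(frequencies, n: int) -> float:
    """Nei's unbiased gene diversity from a frequency table and n gene copies.

    He = n/(n-1) * (1 - sum p_i^2); requires n >= 2.
    """
    if n < 2:
        raise EmptyDataError("unbiased He needs at least 2 gene copies")
    p = np.asarray(list(frequencies.values()) if isinstance(frequencies, dict) else frequencies, dtype=float)
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def rarefied_allele_count(counts, g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    ``counts`` are per-allele copy counts at one locus (summing to n).  The
    expectation is exact under sampling without replacement:
    sum_a [1 - C(n - N_a, g) / C(n, g)].
    """
    counts = [int(c) for c in counts if c > 0]
    n = sum(counts)
    if g > n:
        raise ValueError(f"rarefaction size g={g} exceeds n={n} gene copies")
    if g < 2:
        raise ValueError("rarefaction size must be >= 2")
    denom = math.comb(n, g)
    total = 0.0
    for c in counts:
        absent = math.comb(n - c, g) if n - c >= g else 0
        total += 1.0 - absent / denom
    return total


def multilocus_genotype_count(dataset: GenotypeDataset, group: str) -> int:
    """Number of distinct multilocus genotypes (MLGs) in a group.

    Two individuals share an MLG iff their calls are equal (as unordered
    pairs) at every locus, with missing matching only missing.
    """
    rows = dataset.group_rows(group)
    if len(rows) == 0:
        return 0
    sorted_calls = np.sort(dataset.calls[rows], axis=2)
    seen = {tuple(sorted_calls[i].ravel()) for i in range(len(rows))}
    return len(seen)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components


def _locus_tallies(dataset: GenotypeDataset, groups: list[str], j: int):
    """Per-group allele counts, heterozygote-carrier counts and sample sizes.

    Returns (alleles u, counts C [r x A], het-carrier counts H [r x A],
    n individuals per group [r]) for locus index ``j``, or None if fewer
    than 2 distinct alleles are observed over the included groups.
    """
    per_group = []
    for lab in groups:
        rows = dataset.group_rows(lab)
        calls = dataset.calls[rows, j, :]
        calls = calls[calls[:, 0] != MISSING]
        per_group.append(calls)
    all_alleles = np.concatenate([c.ravel() for c in per_group]) if per_group else np.array([])
    u = np.unique(all_alleles)
    if u.size < 2:
        return None
    r = len(groups)
    A = u.size
    C = np.zeros((r, A))
    H = np.zeros((r, A))
    n = np.zeros(r)
    for gi, calls in enumerate(per_group):
        n[gi] = len(calls)
        if len(calls) == 0:
            continue
        idx = np.searchsorted(u, calls)
        C[gi] = np.bincount(idx.ravel(), minlength=A)
        het = calls[:, 0] != calls[:, 1]
        if het.any():
            hidx = np.searchsorted(u, calls[het])
            H[gi] = np.bincount(hidx.ravel(), minlength=A)
    return u, C, H, n


def _wc_components(C: np.ndarray, H: np.ndarray, n: np.ndarray):
    """Per-allele (a, b, c) variance components for one locus, r >= 2 groups.

    ``C``: gene-copy counts per group x allele, ``H``: heterozygous-carrier
    counts, ``n``: individuals per group.  Groups with no data are dropped.
    """
    keep = n > 0
    C, H, n = C[keep], H[keep], n[keep]
    r = len(n)
    if r < 2 or n.sum() == 0:
        return None
    p = C / (2.0 * n[:, None])
    h = H / n[:, None]
    nbar = n.mean()
    if nbar <= 1:
        return None
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    if nc <= 0:
        return None
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def fstats_weir_cockerham(dataset: GenotypeDataset, groups: list[str] | None = None) -> dict:
    """Weir & Cockerham (1984) Fis, Fst and Fit over >= 2 groups.

    Multi-locus estimates are ratios of variance components summed over
    alleles and loci.  Monomorphic loci (single allele over the included
    groups) are omitted and listed under ``"omitted_loci"``.
    """
    labels = groups if groups is not None else dataset.group_labels
    if len(labels) < 2:
        raise ValueError("Fst needs at least two groups")
    sum_a = sum_b = sum_c = 0.0
    per_locus = {}
    omitted = []
    for j, loc in enumerate(dataset.loci):
        tal = _locus_tallies(dataset, labels, j)
        if tal is None:
            omitted.append(loc.name)
            continue
        _, C, H, n = tal
        comp = _wc_components(C, H, n)
        if comp is None:
            omitted.append(loc.name)
            continue
        a, b, c = comp
        la, lb, lc = a.sum(), b.sum(), c.sum()
        sum_a += la
        sum_b += lb
        sum_c += lc
        denom = la + lb + lc
        per_locus[loc.name] = {
            "Fst": la / denom if denom != 0 else np.nan,
            "Fis": 1 - lc / (lb + lc) if (lb + lc) != 0 else np.nan,
        }
    total = sum_a + sum_b + sum_c
    return {
        "Fst": sum_a / total if total != 0 else np.nan,
        "Fis": 1 - sum_c / (sum_b + sum_c) if (sum_b + sum_c) != 0 else np.nan,
        "Fit": 1 - sum_c / total if total != 0 else np.nan,
        "per_locus": per_locus,
        "omitted_loci": omitted,
    }


def fis_single_group(dataset: GenotypeDataset, group: str) -> float:
    """Within-sample inbreeding coefficient Fis for a single group.

    Uses the single-population reduction of the Weir & Cockerham components:
    Fis = 1 - sum(c) / sum(b + c) over alleles and loci, with
    b = n/(n-1) [p(1-p) - (2n-1)/(4n) hbar] and c = hbar/2.
    """
    rows = dataset.group_rows(group)
    sum_b = sum_c = 0.0
    for j in range(dataset.n_loci):
        calls = dataset.calls[rows, j, :]
        calls = calls[calls[:, 0] != MISSING]
        n = len(calls)
        if n < 2:
            continue
        u, counts = np.unique(calls.ravel(), return_counts=True)
        if u.size < 2:
            continue
        p = counts / (2.0 * n)
        het = calls[:, 0] != calls[:, 1]
        H = np.zeros(u.size)
        if het.any():
            hidx = np.searchsorted(u, calls[het])
            H = np.bincount(hidx.ravel(), minlength=u.size).astype(float)
        hbar = H / n
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
        c = hbar / 2.0
        sum_b += b.sum()
        sum_c += c.sum()
    if sum_b + sum_c == 0:
        return float("nan")
    return float(1 - sum_c / (sum_b + sum_c))


def pairwise_fst(dataset: GenotypeDataset, groups: list[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise multi-locus Weir & Cockerham Fst."""
    labels = groups if groups is not None else dataset.group_labels
    if len(labels) < 2:
        raise ValueError("pairwise Fst needs at least two groups")
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            fst = fstats_weir_cockerham(dataset, [a, b])["Fst"]
            mat.loc[a, b] = mat.loc[b, a] = fst
    return mat


# ---------------------------------------------------------------------------
# selfing and allele-size moments


def selfing_from_fis(fis: float) -> float:
    """Equilibrium selfing rate implied by an inbreeding coefficient.

    Inverts Fis = s / (2 - s): s = 2 Fis / (1 + Fis), clipped to [0, 1];
    negative Fis (finite-sample noise) maps to 0.
    """
    if np.isnan(fis):
        return float("nan")
    if fis <= 0:
        return 0.0
    return float(min(1.0, 2.0 * fis / (1.0 + fis)))


def allele_size_moments(dataset: GenotypeDataset, group: str) -> pd.DataFrame:
    """Per-locus mean and variance of allele size over observed gene copies."""
    rows = dataset.group_rows(group)
    out = []
    for j, loc in enumerate(dataset.loci):
        alleles = dataset.calls[rows, j, :].ravel()
        alleles = alleles[alleles != MISSING]
        if alleles.size == 0:
            out.append((loc.name, np.nan, np.nan))
        else:
            out.append((loc.name, float(alleles.mean()), float(alleles.var())))
    return pd.DataFrame(out, columns=["locus", "mean_size", "var_size"]).set_index("locus")


def delta_mu_squared(dataset: GenotypeDataset, group_a: str, group_b: str) -> float:
    """Goldstein's (delta mu)^2: mean over shared loci of squared difference
    of mean allele size between two groups.  Loci missing in either group are
    excluded; no shared locus raises :class:`EmptyDataError`."""
    ma = allele_size_moments(dataset, group_a)["mean_size"]
    mb = allele_size_moments(dataset, group_b)["mean_size"]
    diff = (ma - mb) ** 2
    diff = diff.dropna()
    if diff.empty:
        raise EmptyDataError(f"no locus observed in both {group_a!r} and {group_b!r}")
    return float(diff.mean())


# ---------------------------------------------------------------------------
# the per-sample diversity table


def _group_locus_allele_counts(dataset: GenotypeDataset, rows: np.ndarray, j: int):
    alleles = dataset.calls[rows, j, :].ravel()
    alleles = alleles[alleles != MISSING]
    if alleles.size == 0:
        return None
    _, counts = np.unique(alleles, return_counts=True)
    return counts


def diversity_table(
    dataset: GenotypeDataset,
    groups: list[str] | None = None,
    rarefaction_g: int | None = None,
    selfing_ml: bool = True,
) -> pd.DataFrame:
    """Per-sample diversity and selfing summary.

    Columns: n, Ho, He, N_all (mean alleles/locus), N_all_rar (rarefied
    richness at ``rarefaction_g`` gene copies), MLG, Fis, s_Fis
    (equilibrium inversion of Fis) and, when ``selfing_ml``, the
    maximum-likelihood selfing estimate with its log-likelihood and the
    p-value of the likelihood-ratio test of s = 0.

    ``rarefaction_g`` defaults to twice the smallest per-group non-missing
    individual count at any locus, over the analyzed groups (so every group
    and locus can be rarefied), floored at 2.
    """
    from .selfing import selfing_maximum_likelihood  # local import, heavy module

    labels = groups if groups is not None else dataset.group_labels
    # smallest per-(group, locus) observed gene-copy count with any data
    if rarefaction_g is None:
        min_copies = None
        for lab in labels:
            rows = dataset.group_rows(lab)
            obs = (dataset.calls[rows, :, 0] != MISSING).sum(axis=0)
            nz = obs[obs > 0]
            if nz.size:
                m = 2 * int(nz.min())
                min_copies = m if min_copies is None else min(min_copies, m)
        rarefaction_g = max(2, min_copies or 2)

    records = []
    for lab in labels:
        rows = dataset.group_rows(lab)
        _, ho = observed_heterozygosity(dataset, lab)
        he_vals, nall, nrar = [], [], []
        for j in range(dataset.n_loci):
            counts = _group_locus_allele_counts(dataset, rows, j)
            if counts is None:
                continue
            n = int(counts.sum())
            nall.append(len(counts))
            if n >= 2:
                he_vals.append(expected_heterozygosity_unbiased(counts / n, n))
            if n >= rarefaction_g:
                nrar.append(rarefied_allele_count(counts, rarefaction_g))
        fis = fis_single_group(dataset, lab)
        rec = {
            "group": lab,
            "n": len(rows),
            "Ho": ho,
            "He": float(np.mean(he_vals)) if he_vals else np.nan,
            "N_all": float(np.mean(nall)) if nall else np.nan,
            "N_all_rar": float(np.mean(nrar)) if nrar else np.nan,
            "MLG": multilocus_genotype_count(dataset, lab),
            "Fis": fis,
            "s_Fis": selfing_from_fis(fis),
        }
        if selfing_ml:
            try:
                fit = selfing_maximum_likelihood(dataset, lab)
                rec.update(s_LnL=fit.s_hat, lnL=fit.loglik, p_s0=fit.p_value)
            except (EmptyDataError, ValueError):
                rec.update(s_LnL=np.nan, lnL=np.nan, p_s0=np.nan)
        records.append(rec)
    return pd.DataFrame(records).set_index("group")
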