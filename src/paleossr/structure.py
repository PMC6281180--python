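"""Population structure: PCA, k-means cluster-number inference, and DAPC.

Discriminant analysis of principal components (DAPC, Jombart et al. 2010)
summarizes genotypes as allele-dosage indicators, reduces them by centered
PCA, infers the number of clusters by running k-means on the retained
principal components over a range of k and scoring each solution with
BIC(k) = n ln(WSS_k / n) + k ln(n), then fits a linear discriminant
analysis on the retained components to obtain per-individual assignment
probabilities to the clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import MISSING, GenotypeDataset

__all__ = [
    "IndicatorMatrix",
    "ClusterSolution",
    "to_indicator_matrix",
    "pca",
    "find_clusters",
    "discriminant_assignments",
    "dapc",
]


@dataclass
class IndicatorMatrix:
    """Individuals x (locus, allele) allele-dosage matrix.

    Values are dosage/2 in {0, 0.5, 1}; missing calls are imputed by the
    column mean and flagged in ``imputed`` (per individual x locus).
    """

    values: np.ndarray
    columns: list[tuple[str, int]]
    imputed: np.ndarray


@dataclass
class ClusterSolution:
    """A k-means + discriminant solution on retained principal components."""

    k: int
    labels: np.ndarray
    bic_curve: dict[int, float]
    pc_scores: np.ndarray
    assignment_probs: np.ndarray | None = None
    da_coords: np.ndarray | None = None


def to_indicator_matrix(dataset: GenotypeDataset) -> IndicatorMatrix:
    """One column per observed allele per locus; dosage/2 per individual.

    For non-missing calls the dosages at a locus sum to 1 per individual
    (0.5 + 0.5 for a heterozygote, 1 for a homozygote).  Missing calls are
    mean-imputed so no individual is dropped.
    """
    n = dataset.n_individuals
    cols: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    imputed = dataset.missing_mask().copy()
    for j, loc in enumerate(dataset.loci):
        calls = dataset.calls[:, j, :]
        obs = calls[:, 0] != MISSING
        alleles = np.unique(calls[obs])
        if alleles.size == 0:
            continue
        block = np.zeros((n, alleles.size))
        for k, a in enumerate(alleles):
            block[:, k] = ((calls[:, 0] == a).astype(float) + (calls[:, 1] == a)) / 2.0
        if (~obs).any():
            col_mean = block[obs].mean(axis=0) if obs.any() else np.full(alleles.size, 1.0 / alleles.size)
            block[~obs] = col_mean
        cols.extend((loc.name, int(a)) for a in alleles)
        blocks.append(block)
    values = np.concatenate(blocks, axis=1) if blocks else np.zeros((n, 0))
    return IndicatorMatrix(values=values, columns=cols, imputed=imputed)


def pca(matrix: np.ndarray, n_axes: int | None = None):
    """Centered (not scaled) principal component analysis.

    Returns ``(scores, loadings, eigenvalues)`` with eigenvalues the
    variances along the axes (non-increasing); at full rank the scores and
    loadings reconstruct the centered matrix.
    """
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=0)
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    eig = svals**2 / n
    rank = int(np.sum(svals > svals[0] * 1e-12)) if svals.size and svals[0] > 0 else 0
    if rank == 0:
        warnings.warn("degenerate matrix: all rows equal; PCA has no axes")
        return np.zeros((n, 0)), np.zeros((X.shape[1], 0)), np.zeros(0)
    if n_axes is None:
        n_axes = rank
    if n_axes > rank:
        raise ValueError(f"n_axes={n_axes} exceeds rank {rank}")
    scores = U[:, :n_axes] * svals[:n_axes]
    loadings = Vt[:n_axes].T
    return scores, loadings, eig[:n_axes]


def retained_axes(eigenvalues: np.ndarray, n_individuals: int,
                  var_target: float = 0.9) -> int:
    """Default PC retention: smallest count explaining >= ``var_target`` of
    the variance, capped at n/3 (and at least 1)."""
    if eigenvalues.size == 0:
        return 0
    frac = np.cumsum(eigenvalues) / eigenvalues.sum()
    k = int(np.searchsorted(frac, var_target) + 1)
    return max(1, min(k, eigenvalues.size, max(1, n_individuals // 3)))


def find_clusters(
    pc_scores: np.ndarray,
    k_range=None,
    n_starts: int = 10,
    seed: int | None = None,
    k: int | None = None,
) -> ClusterSolution:
    """k-means over a range of cluster numbers, scored by BIC.

    ``BIC(k) = n ln(WSS_k / n) + k ln(n)``.  Labels are returned for ``k``
    when forced, else for the argmin of the BIC curve.
    """
    X = np.asarray(pc_scores, dtype=float)
    n = X.shape[0]
    if k_range is None:
        k_range = range(1, min(15, n - 1) + 1)
    k_range = [kk for kk in k_range if 1 <= kk <= n - 1]
    if not k_range:
        raise ValueError("empty k range")
    bic: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for kk in k_range:
        if kk == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
            labels_by_k[1] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=kk, n_init=n_starts, random_state=seed)
            lab = km.fit_predict(X)
            wss = float(km.inertia_)
            labels_by_k[kk] = lab
        wss = max(wss, 1e-300)
        bic[kk] = n * np.log(wss / n) + kk * np.log(n)
    chosen = k if k is not None else min(bic, key=bic.get)
    if chosen not in labels_by_k:
        km = KMeans(n_clusters=chosen, n_init=n_starts, random_state=seed)
        labels_by_k[chosen] = km.fit_predict(X)
    return ClusterSolution(k=chosen, labels=labels_by_k[chosen], bic_curve=bic, pc_scores=X)


def discriminant_assignments(
    pc_scores: np.ndarray,
    labels: np.ndarray,
    n_da: int | None = None,
):
    """Linear discriminant analysis of cluster labels on retained PCs.

    Returns ``(assignment_probs, da_coords)``; assignment-probability rows
    sum to 1.  A singular within-group covariance falls back to a shrunken
    (ridge-regularized) estimator with a warning.
    """
    X = np.asarray(pc_scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("discriminant analysis needs at least 2 clusters")
    n_da = n_da or min(classes.size - 1, X.shape[1])
    try:
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_da)
        lda.fit(X, y)
        probs = lda.predict_proba(X)
        coords = lda.transform(X)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-group covariance; using shrinkage LDA")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)
        probs = lda.predict_proba(X)
        coords = X[:, :n_da]
    return probs, coords


def dapc(
    dataset: GenotypeDataset,
    k: int | None = None,
    n_pcs: int | None = None,
    k_range=None,
    n_starts: int = 10,
    seed: int | None = None,
) -> ClusterSolution:
    """Full DAPC pipeline on a genotype dataset.

    Indicator coding, centered PCA (retaining ``n_pcs`` components, default
    enough for 90% of the variance capped at n/3), k-means cluster-number
    inference (or a forced ``k``), then discriminant assignment
    probabilities.
    """
    ind = to_indicator_matrix(dataset)
    scores, _, eig = pca(ind.values)
    if n_pcs is None:
        n_pcs = retained_axes(eig, dataset.n_individuals)
    scores = scores[:, :n_pcs]
    sol = find_clusters(scores, k_range=k_range, n_starts=n_starts, seed=seed, k=k)
    if sol.k >= 2:
        probs, coords = discriminant_assignments(scores, sol.labels)
        sol.assignment_probs = probs
        sol.da_coords = coords
    return sol
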