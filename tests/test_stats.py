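import itertools
import math

import numpy as np
import pytest

from paleossr.genotypes import SampleGroup
from paleossr.stats import (
    delta_mu_squared,
    diversity_table,
    expected_heterozygosity_unbiased,
    fis_single_group,
    fstats_weir_cockerham,
    multilocus_genotype_count,
    observed_heterozygosity,
    pairwise_fst,
    rarefied_allele_count,
    selfing_from_fis,
)
from conftest import build_dataset


def test_he_unbiased_closed_form():
    # p = (1/2, 1/2), n = 4 copies: (4/3) * (1 - 1/2) = 2/3
    assert expected_heterozygosity_unbiased([0.5, 0.5], 4) == pytest.approx(2 / 3)


def test_he_monomorphic_is_zero():
    assert expected_heterozygosity_unbiased([1.0], 10) == 0.0


def enumerate_rarefaction(counts, g):
    """Brute-force expectation of allele count in subsamples of size g."""
    pool = [a for a, c in enumerate(counts) for _ in range(c)]
    subs = list(itertools.combinations(range(len(pool)), g))
    total = sum(len({pool[i] for i in sub}) for sub in subs)
    return total / len(subs)


def test_rarefaction_hand_value():
    # counts (3,1), g=2: subsets {AA}=3, {AB}=3 -> (3*1 + 3*2)/6 = 1.5
    assert rarefied_allele_count([3, 1], 2) == pytest.approx(1.5)


def test_rarefaction_matches_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(20):
        k = rng.integers(1, 4)
        counts = rng.integers(1, 4, size=k)
        if counts.sum() < 2:
            counts[0] += 1
        n = int(counts.sum())
        g = int(rng.integers(2, n + 1))
        expect = enumerate_rarefaction(list(counts), g)
        assert rarefied_allele_count(counts, g) == pytest.approx(expect, abs=1e-12)


def test_rarefaction_full_sample_is_allele_count():
    assert rarefied_allele_count([5, 3, 2], 10) == pytest.approx(3.0)


def test_observed_heterozygosity(two_group_dataset):
    per_locus, mean = observed_heterozygosity(two_group_dataset, "p1")
    # p1: L01 het counts 1/3, L02 1/3
    assert per_locus == pytest.approx([1 / 3, 1 / 3])
    assert mean == pytest.approx(1 / 3)


def test_mlg_count():
    ds = build_dataset(
        [[(100, 102)], [(100, 102)], [(102, 100)], [(104, 104)], [None]],
    )
    # unordered genotypes: {100/102} x3, {104/104}, all-missing row
    assert multilocus_genotype_count(ds, "g1") == 3


def random_dataset(rng, n_groups=3, n_per=6, n_loci=4):
    groups = [SampleGroup(f"p{g}", site="x") for g in range(n_groups)]
    rows, labels = [], []
    for g in range(n_groups):
        for _ in range(n_per):
            row = []
            for _ in range(n_loci):
                if rng.random() < 0.1:
                    row.append(None)
                else:
                    row.append((int(rng.integers(100, 104)),
                                int(rng.integers(100, 104))))
            rows.append(row)
            labels.append(f"p{g}")
    return build_dataset(rows, groups=groups, group_of=labels)


def wc_oracle(ds, labels):
    """Independent per-allele ANOVA implementation of WC84 components."""
    sum_a = sum_b = sum_c = 0.0
    for j in range(ds.n_loci):
        # collect per-group allele counts / het counts for each allele
        group_calls = {}
        for lab in labels:
            rows = ds.group_rows(lab)
            calls = ds.calls[rows, j, :]
            calls = calls[calls[:, 0] != -1]
            if len(calls):
                group_calls[lab] = calls
        labs = [l for l in labels if l in group_calls]
        r = len(labs)
        if r < 2:
            continue
        alleles = sorted({int(a) for l in labs for a in group_calls[l].ravel()})
        if len(alleles) < 2:
            continue
        n = np.array([len(group_calls[l]) for l in labs], dtype=float)
        nbar = n.mean()
        nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
        for A in alleles:
            p = np.array([(group_calls[l] == A).mean() for l in labs])
            h = np.array([((group_calls[l] == A).sum(axis=1) == 1).mean()
                          for l in labs])
            pbar = (n * p).sum() / n.sum()
            hbar = (n * h).sum() / n.sum()
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            sum_a += a
            sum_b += b
            sum_c += c
    total = sum_a + sum_b + sum_c
    return sum_a / total, 1 - sum_c / (sum_b + sum_c)


def test_wc_matches_independent_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        ds = random_dataset(rng)
        labels = ds.group_labels
        got = fstats_weir_cockerham(ds, labels)
        fst_exp, fis_exp = wc_oracle(ds, labels)
        assert got["Fst"] == pytest.approx(fst_exp, abs=1e-10)
        assert got["Fis"] == pytest.approx(fis_exp, abs=1e-10)


def test_pairwise_fst_symmetric_and_consistent(two_group_dataset):
    mat = pairwise_fst(two_group_dataset)
    assert mat.loc["p1", "p2"] == pytest.approx(mat.loc["p2", "p1"])
    assert mat.loc["p1", "p1"] == 0.0
    full = fstats_weir_cockerham(two_group_dataset, ["p1", "p2"])
    assert mat.loc["p1", "p2"] == pytest.approx(full["Fst"])
    # disjoint allele pools -> clear differentiation
    assert mat.loc["p1", "p2"] > 0.3


def test_fis_single_group_extremes():
    all_hom = build_dataset([[(100, 100)], [(102, 102)], [(100, 100)]])
    assert fis_single_group(all_hom, "g1") == pytest.approx(1.0)
    # Fis for all-heterozygote sample is negative
    all_het = build_dataset([[(100, 102)], [(100, 102)], [(100, 102)]])
    assert fis_single_group(all_het, "g1") < 0


def test_selfing_from_fis_identity():
    for s in [0.0, 0.25, 0.5, 0.9, 1.0]:
        F = s / (2 - s)
        assert selfing_from_fis(F) == pytest.approx(s)
    assert selfing_from_fis(-0.2) == 0.0


def test_delta_mu_squared():
    groups = [SampleGroup("pa", site="x"), SampleGroup("pb", site="y")]
    ds = build_dataset(
        [[(100, 100)], [(100, 100)], [(106, 106)], [(106, 106)]],
        groups=groups, group_of=["pa", "pa", "pb", "pb"],
    )
    # mean sizes 100 vs 106 -> (6)^2 = 36
    assert delta_mu_squared(ds, "pa", "pb") == pytest.approx(36.0)
    assert delta_mu_squared(ds, "pb", "pa") == pytest.approx(36.0)


def test_diversity_table_columns(two_group_dataset):
    tab = diversity_table(two_group_dataset, selfing_ml=False)
    assert list(tab.index) == ["p1", "p2"]
    for col in ["n", "Ho", "He", "N_all", "N_all_rar", "MLG", "Fis", "s_Fis"]:
        assert col in tab.columns
    assert tab.loc["p1", "n"] == 3
    # He by hand for p1: L01 p=(5/6,1/6) n=6 -> 6/5*(1-25/36-1/36)=1/3
    # L02 p=(1/2,1/2) n=6 -> 6/5*(1/2)=0.6; mean = 0.4666...
    assert tab.loc["p1", "He"] == pytest.approx((1 / 3 + 0.6) / 2)
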