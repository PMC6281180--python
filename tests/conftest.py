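import numpy as np
import pytest

from paleossr.genotypes import GenotypeDataset, Locus, SampleGroup


def build_dataset(calls, groups=None, group_of=None, loci=None):
    """Small helper to assemble a dataset from a nested call list.

    ``calls``: list (individuals) of list (loci) of (a1, a2) or None.
    """
    calls = [[(-1, -1) if c is None else c for c in row] for row in calls]
    arr = np.asarray(calls, dtype=np.int32)
    n, L = arr.shape[0], arr.shape[1]
    if loci is None:
        loci = [Locus(f"L{j+1:02d}") for j in range(L)]
    if groups is None:
        groups = [SampleGroup("g1", site="test")]
    if group_of is None:
        group_of = [groups[0].label] * n
    return GenotypeDataset(
        loci=loci,
        groups=groups,
        individual_ids=[f"ind{i}" for i in range(n)],
        individual_group=list(group_of),
        calls=arr,
    )


@pytest.fixture
def toy_dataset():
    """2 individuals x 2 loci, one missing call."""
    return build_dataset(
        [[(101, 103), (140, 140)],
         [(101, 101), None]],
    )


@pytest.fixture
def two_group_dataset():
    """Two groups of 3 with distinct allele pools for differentiation tests."""
    g1 = SampleGroup("p1", site="a")
    g2 = SampleGroup("p2", site="b")
    return build_dataset(
        [
            [(100, 100), (200, 202)],
            [(100, 102), (200, 200)],
            [(100, 100), (202, 202)],
            [(110, 110), (210, 212)],
            [(110, 112), (210, 210)],
            [(112, 112), (212, 212)],
        ],
        groups=[g1, g2],
        group_of=["p1", "p1", "p1", "p2", "p2", "p2"],
    )
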