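import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleossr.genotypes import (
    FormatError,
    GenotypeDataset,
    Locus,
    SampleGroup,
    ValidationError,
    allele_frequencies,
    read_allelic_profiles,
    select,
    summarize_dataset,
    write_allelic_profiles,
)
from conftest import build_dataset

CSV = """individual_id,group,type,site,age_calBP,seed_color,SSR101.a1,SSR101.a2,SSR102.a1,SSR102.a2
s1,g1,modern,farm,0,white,101,103,140,140
s2,g1,modern,farm,0,white,101,101,NA,NA
s3,g2,ancient,cave,700,dark,103,103,142,144
"""


def test_read_basic(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text(CSV)
    ds = read_allelic_profiles(p)
    assert ds.n_individuals == 3
    assert ds.n_loci == 2
    assert ds.locus_names == ["SSR101", "SSR102"]
    assert ds.group_labels == ["g1", "g2"]
    assert ds.group("g2").age_calBP == 700
    assert ds.group("g2").type == "ancient"
    assert tuple(ds.calls[0, 0]) == (101, 103)
    assert tuple(ds.calls[1, 1]) == (-1, -1)


@pytest.mark.parametrize("token", ["NA", "-9", "", "0", "."])
def test_missing_tokens(tmp_path, token):
    p = tmp_path / "d.csv"
    p.write_text(
        "individual_id,group,type,site,age_calBP,seed_color,L1.a1,L1.a2\n"
        f"s1,g1,modern,farm,0,white,{token},{token}\n"
    )
    ds = read_allelic_profiles(p)
    assert tuple(ds.calls[0, 0]) == (-1, -1)


def test_half_missing_coerced(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text(
        "individual_id,group,type,site,age_calBP,seed_color,L1.a1,L1.a2\n"
        "s1,g1,modern,farm,0,white,101,NA\n"
    )
    ds, report = read_allelic_profiles(p, return_report=True)
    assert tuple(ds.calls[0, 0]) == (-1, -1)
    assert report.half_missing_coerced == 1


def test_duplicate_ids_rejected(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text(
        "individual_id,group,type,site,age_calBP,seed_color,L1.a1,L1.a2\n"
        "s1,g1,modern,farm,0,white,101,101\n"
        "s1,g1,modern,farm,0,white,103,103\n"
    )
    with pytest.raises(ValidationError):
        read_allelic_profiles(p)


def test_odd_allele_columns_rejected(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text(
        "individual_id,group,type,site,age_calBP,seed_color,L1.a1\n"
        "s1,g1,modern,farm,0,white,101\n"
    )
    with pytest.raises(FormatError):
        read_allelic_profiles(p)


def test_round_trip(tmp_path):
    p1 = tmp_path / "a.csv"
    p2 = tmp_path / "b.csv"
    p1.write_text(CSV)
    ds = read_allelic_profiles(p1)
    write_allelic_profiles(ds, p2)
    ds2 = read_allelic_profiles(p2)
    assert ds.equals(ds2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.data())
def test_round_trip_property(tmp_path_factory, data):
    n_loci = data.draw(st.integers(1, 4))
    n_groups = data.draw(st.integers(1, 3))
    rows, group_of = [], []
    for g in range(n_groups):
        n_ind = data.draw(st.integers(1, 3))
        for _ in range(n_ind):
            row = []
            for _ in range(n_loci):
                if data.draw(st.booleans()):
                    a = data.draw(st.integers(50, 300))
                    b = data.draw(st.integers(50, 300))
                    row.append((a, b))
                else:
                    row.append(None)
            rows.append(row)
            group_of.append(f"grp{g}")
    groups = []
    for g in range(n_groups):
        age = data.draw(st.integers(0, 3000))
        groups.append(SampleGroup(
            f"grp{g}", site=f"s{g}", age_calBP=age,
            type="modern" if age == 0 else "ancient",
        ))
    ds = build_dataset(rows, groups=groups, group_of=group_of)
    path = tmp_path_factory.mktemp("rt") / "x.csv"
    write_allelic_profiles(ds, path)
    assert read_allelic_profiles(path).equals(ds)


def test_summarize(toy_dataset):
    s = summarize_dataset(toy_dataset)
    assert s["n_individuals"] == 2
    assert s["n_loci"] == 2
    # one missing call out of 4 in group g1
    assert s["per_group"]["g1"]["missing_fraction"] == pytest.approx(0.25)
    assert s["per_locus_missing"]["L02"] == pytest.approx(0.5)


def test_select_groups_and_loci(two_group_dataset):
    sub = select(two_group_dataset, groups=["p2"], loci=["L02"])
    assert sub.n_individuals == 3
    assert sub.locus_names == ["L02"]
    assert sub.group_labels == ["p2"]
    with pytest.raises(KeyError):
        select(two_group_dataset, groups=["nope"])


def test_allele_frequencies_oracle(two_group_dataset):
    freqs, n = allele_frequencies(two_group_dataset, "p1", "L01")
    # p1 at L01: (100,100),(100,102),(100,100) -> 100 x5, 102 x1 of 6 copies
    assert n == 6
    assert freqs == pytest.approx({100: 5 / 6, 102: 1 / 6})
    assert sum(freqs.values()) == pytest.approx(1.0)


def test_frequencies_skip_missing(toy_dataset):
    freqs, n = allele_frequencies(toy_dataset, "g1", "L02")
    assert n == 2
    assert freqs == {140: 1.0}
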