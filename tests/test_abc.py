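import numpy as np
import pytest

from paleossr.abc import (
    LogUniform,
    ModelChoiceForest,
    ParameterEstimator,
    Uniform,
    build_reference_table,
    classify_models,
    default_priors,
    draw_from_priors,
    summary_names,
    summary_statistics,
)
from paleossr.genotypes import SampleGroup
from paleossr.stats import delta_mu_squared, fis_single_group, pairwise_fst
from paleossr.synthetic import temporal_series_design, make_pseudo_observed
from conftest import build_dataset

PARAMS_A = {"ne_main": 5000.0, "s_main": 0.3,
            "ne_ancestral": 5000.0, "s_ancestral": 0.3, "td_ancestral": 5000.0}
PARAMS_D = {
    "ne_modern": 200.0, "s_modern": 0.8,
    "ne_intermediate": 200.0, "s_intermediate": 0.8,
    "ne_ancient": 200.0, "s_ancient": 0.8,
    "td_modern": 3000.0, "td_intermediate": 5000.0,
    "ne_ancestral": 200.0, "s_ancestral": 0.8, "td_ancestral": 8000.0,
}


def test_log_uniform_median():
    rng = np.random.default_rng(0)
    draws = [LogUniform(10.0, 1000.0).draw(rng) for _ in range(4000)]
    assert np.median(draws) == pytest.approx(100.0, rel=0.12)
    assert min(draws) >= 10.0 and max(draws) <= 1000.0


def test_uniform_bounds():
    rng = np.random.default_rng(1)
    draws = [Uniform(0.25, 0.75).draw(rng) for _ in range(2000)]
    assert 0.25 <= min(draws) and max(draws) <= 0.75
    assert np.mean(draws) == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize("kind", list("ABCDEF"))
def test_default_priors_draw_satisfies_constraints(kind):
    design = temporal_series_design(n_per_group=4)
    spec = default_priors(kind, design)
    rng = np.random.default_rng(2)
    for _ in range(50):
        params = draw_from_priors(spec, rng)
        for a, b in spec.constraints:
            assert params[a] <= params[b]
        # oldest sample is 1796 generations old: the terminal divergence
        # must be older than that so the scenario stays buildable
        assert params["td_ancestral"] >= 1796.0


def test_summary_vector_length_and_names():
    design = temporal_series_design(n_per_group=3)
    ds, _, _ = make_pseudo_observed("A",
                                    {"ne_main": 300.0, "s_main": 0.5,
                                     "ne_ancestral": 300.0, "s_ancestral": 0.5,
                                     "td_ancestral": 5000.0},
                                    design, rng=np.random.default_rng(3), n_loci=8)
    stats = summary_statistics(ds)
    names = summary_names(ds.group_labels)
    G = len(ds.groups)
    expect = 5 * G + 2 * (G * (G - 1) // 2)
    assert stats.shape == (expect,)
    assert len(names) == expect
    assert np.all(np.isfinite(stats))


def test_summary_matches_generic_statistics():
    design = temporal_series_design(n_per_group=6)
    ds, _, _ = make_pseudo_observed("A",
                                    {"ne_main": 800.0, "s_main": 0.6,
                                     "ne_ancestral": 800.0, "s_ancestral": 0.6,
                                     "td_ancestral": 6000.0},
                                    design, missing_rates=0.1,
                                    rng=np.random.default_rng(4), n_loci=12)
    stats = summary_statistics(ds)
    names = summary_names(ds.group_labels)
    by_name = dict(zip(names, stats))
    fst = pairwise_fst(ds)
    labels = ds.group_labels
    for i, a in enumerate(labels):
        assert by_name[f"Fis:{a}"] == pytest.approx(
            np.nan_to_num(fis_single_group(ds, a)), abs=1e-9)
        for b in labels[i + 1:]:
            assert by_name[f"Fst:{a}|{b}"] == pytest.approx(fst.loc[a, b], abs=1e-9)
            assert by_name[f"dmu2:{a}|{b}"] == pytest.approx(
                delta_mu_squared(ds, a, b), abs=1e-9)


def test_duplicated_group_low_fst():
    # two groups drawn from the same pool should show near-zero Fst
    rng = np.random.default_rng(5)
    groups = [SampleGroup("x", site="s"), SampleGroup("y", site="s")]
    p = rng.dirichlet([1.0] * 4)
    rows, labs = [], []
    for lab in ("x", "y"):
        for _ in range(30):
            a, b = rng.choice(4, size=2, p=p)
            rows.append([(100 + 2 * a, 100 + 2 * b)])
            labs.append(lab)
    ds = build_dataset(rows, groups=groups, group_of=labs)
    stats = summary_statistics(ds)
    names = summary_names(ds.group_labels)
    fst = dict(zip(names, stats))["Fst:x|y"]
    assert abs(fst) < 0.05


@pytest.fixture(scope="module")
def small_table():
    design = temporal_series_design(n_per_group=5)
    return build_reference_table(["A", "D"], design, n_per_scenario=150,
                                 n_loci=12, seed=7)


def test_reference_table_shape(small_table):
    t = small_table
    assert t.summaries.shape == (300, len(t.stat_names))
    assert len(t.params) == 300
    assert sorted(set(t.kinds)) == ["A", "D"]
    assert len(t.rows_for("A")) == 150
    assert np.all(np.isfinite(t.summaries))
    # scenario-A rows never have D-only parameters
    assert t.params.loc[t.rows_for("A"), "ne_modern"].isna().all()
    assert t.params.loc[t.rows_for("D"), "ne_modern"].notna().all()


def test_reference_table_reproducible():
    design = temporal_series_design(n_per_group=4)
    t1 = build_reference_table(["A", "D"], design, n_per_scenario=20,
                               n_loci=6, seed=11)
    t2 = build_reference_table(["A", "D"], design, n_per_scenario=20,
                               n_loci=6, seed=11)
    assert np.array_equal(t1.summaries, t2.summaries)
    assert t1.params.equals(t2.params)


def test_model_choice_separates_contrasting_scenarios(small_table):
    design = small_table.design
    rng = np.random.default_rng(8)
    forest = ModelChoiceForest(small_table, n_trees=200, seed=0)
    assert 0.0 <= forest.prior_error_rate <= 0.5
    hits = 0
    for kind, params in (("A", PARAMS_A), ("D", PARAMS_D)):
        for _ in range(5):
            ds, _, _ = make_pseudo_observed(kind, params, design, rng=rng,
                                            n_loci=small_table.n_loci)
            res = forest.predict(summary_statistics(ds))
            hits += res.selected == kind
            assert res.votes[res.selected] == max(res.votes.values())
            assert 0.0 <= res.posterior_probability <= 1.0
    assert hits >= 8


def test_classify_models_wrapper(small_table):
    rng = np.random.default_rng(9)
    ds, _, _ = make_pseudo_observed("D", PARAMS_D, small_table.design,
                                    rng=rng, n_loci=small_table.n_loci)
    res = classify_models(small_table, summary_statistics(ds),
                          n_trees=200, seed=0)
    assert set(res.votes) == {"A", "D"}
    assert res.votes["A"] + res.votes["D"] == pytest.approx(1.0)


def test_parameter_estimator_interval_orders(small_table):
    rng = np.random.default_rng(10)
    ds, _, _ = make_pseudo_observed("D", PARAMS_D, small_table.design,
                                    rng=rng, n_loci=small_table.n_loci)
    est = ParameterEstimator(small_table, "D", n_trees=100, seed=0)
    out = est.estimate(summary_statistics(ds))
    assert "ne_modern" in out
    for rec in out.values():
        assert rec["q025"] <= rec["median"] <= rec["q975"]
    # ne estimates stay inside the prior support
    assert 10.0 <= out["ne_modern"]["median"] <= 1e4
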