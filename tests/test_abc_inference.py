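import numpy as np
import pandas as pd
import pytest

from triabc import (
    HeterogeneitySubmodel,
    LocusSpec,
    ScenarioCategory,
    SpeciesTrio,
    enumerate_models,
)
from triabc.abc_inference import (
    PARAM_COLUMNS,
    HierarchicalClassifier,
    ParameterRegressor,
    ReferenceTable,
    build_reference_table,
    classify,
    draw_from_estimates,
    estimate_parameters,
    hierarchical_inference,
    posterior_predictive_check,
)
from triabc.sumstats import SUMMARY_NAMES, SummaryVector
from triabc.synthetic_data import pod_summary
from triabc.coalsim import simulate_dataset

from conftest import isolation_draw


def synthetic_table(rng, labels, shift=0.0, n_rows=200):
    """A toy reference table with Gaussian statistics per label group."""
    rows = []
    for i, lab in enumerate(labels):
        x = rng.normal(i * shift, 1.0, size=(n_rows, len(SUMMARY_NAMES)))
        for r in x:
            row = {"category": lab, "submodel": "homNe-homM", "n_loci": 100}
            row.update({p: 1.0 for p in PARAM_COLUMNS})
            row.update(dict(zip(SUMMARY_NAMES, r)))
            rows.append(row)
    return ReferenceTable(pd.DataFrame(rows))


SMALL_TRIO = SpeciesTrio(n_seq_p1=6, n_seq_p2=6, n_seq_p3=4)


@pytest.fixture(scope="module")
def tiny_table():
    specs = [LocusSpec(450, locus_id=f"L{i}") for i in range(25)]
    return build_reference_table(enumerate_models(), 3, specs,
                                 trio=SMALL_TRIO, rng=101)


class TestReferenceTable:
    def test_row_counts_and_labels(self, tiny_table):
        df = tiny_table.df
        assert len(df) == 32 * 3
        assert df.groupby("category").size().eq(12).all()
        assert set(df["submodel"]) == {s.code for s in
                                       (HeterogeneitySubmodel(a, b)
                                        for a in (0, 1) for b in (0, 1))}

    def test_no_missing_statistics(self, tiny_table):
        assert np.isfinite(tiny_table.stats).all()

    def test_determinism_is_byte_identical(self, tmp_path):
        specs = [LocusSpec(450) for _ in range(10)]
        models = enumerate_models()[:2]
        paths = []
        for run in range(2):
            t = build_reference_table(models, 4, specs, trio=SMALL_TRIO,
                                      rng=55)
            p = tmp_path / f"t{run}.tsv"
            t.save(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_restrict_filters_category(self, tiny_table):
        sub = tiny_table.restrict("AM.SI")
        assert set(sub.df["category"]) == {"AM.SI"}
        assert len(sub.df) == 12


class TestClassify:
    def test_separable_groups_reach_high_posterior(self):
        rng = np.random.default_rng(0)
        table = synthetic_table(rng, ["A", "B"], shift=8.0)
        obs = SummaryVector(values=np.zeros(len(SUMMARY_NAMES)))
        res = classify(table, obs, n_trees=200, rng=1)
        assert res.winner == "A"
        assert res.oob_error <= 0.05
        assert res.posterior >= 0.9

    def test_identical_groups_are_uninformative(self):
        rng = np.random.default_rng(3)
        table = synthetic_table(rng, ["A", "B"], shift=0.0, n_rows=500)
        obs = SummaryVector(values=rng.normal(size=len(SUMMARY_NAMES)))
        res = classify(table, obs, n_trees=500, rng=4)
        assert abs(res.oob_error - 0.5) <= 0.1
        assert abs(res.posterior - 0.5) <= 0.1

    def test_training_row_recovers_its_label(self):
        rng = np.random.default_rng(5)
        table = synthetic_table(rng, ["A", "B"], shift=6.0, n_rows=50)
        obs = SummaryVector(values=table.stats[7])
        res = classify(table, obs, n_trees=100, rng=6)
        assert res.winner == table.categories[7]

    def test_vote_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        table = synthetic_table(rng, ["A", "B", "C"], shift=2.0, n_rows=60)
        obs = SummaryVector(values=np.zeros(len(SUMMARY_NAMES)))
        res = classify(table, obs, n_trees=100, rng=8)
        assert sum(res.vote_fractions.values()) == pytest.approx(1.0)
        assert 0.0 <= res.posterior <= 1.0

    def test_single_group_rejected(self):
        rng = np.random.default_rng(9)
        table = synthetic_table(rng, ["A"], n_rows=30)
        obs = SummaryVector(values=np.zeros(len(SUMMARY_NAMES)))
        with pytest.raises(ValueError):
            classify(table, obs)


class TestHierarchical:
    def test_shuffled_table_gives_identical_decisions(self, tiny_table):
        obs = SummaryVector(values=tiny_table.stats[5])
        res1 = hierarchical_inference(tiny_table, obs, n_trees=100, rng=11)
        shuffled = ReferenceTable(
            tiny_table.df.sample(frac=1.0, random_state=0)
            .reset_index(drop=True))
        res2 = hierarchical_inference(shuffled, obs, n_trees=100, rng=11)
        assert res1.inner.winner == res2.inner.winner
        assert res1.outer.winner == res2.outer.winner

    def test_missing_category_rejected(self, tiny_table):
        partial = ReferenceTable(
            tiny_table.df[tiny_table.df["category"] != "AM.SI"]
            .reset_index(drop=True))
        obs = SummaryVector(values=tiny_table.stats[0])
        with pytest.raises(ValueError, match="AM.SI"):
            hierarchical_inference(partial, obs, n_trees=50)

    def test_two_question_structure(self, tiny_table):
        obs = SummaryVector(values=tiny_table.stats[40])
        res = hierarchical_inference(tiny_table, obs, n_trees=100, rng=12)
        assert set(res.inner.vote_fractions) == {"AM", "SC"}
        assert set(res.outer.vote_fractions) == {"SI", "P3P1", "P3P2",
                                                 "P3BOTH"}
        assert res.winning_category.code == \
            f"{res.inner.winner}.{res.outer.winner}"


class TestParameterEstimation:
    def test_constant_parameter_has_zero_width_interval(self):
        rng = np.random.default_rng(13)
        table = synthetic_table(rng, ["A", "B"], shift=1.0, n_rows=40)
        obs = SummaryVector(values=np.zeros(len(SUMMARY_NAMES)))
        est = estimate_parameters(table, obs, parameters=("N_P1",),
                                  n_trees=50, rng=14)
        assert est.estimates["N_P1"] == (1.0, 1.0, 1.0)

    def test_interval_contains_point(self, tiny_table):
        obs = SummaryVector(values=tiny_table.stats[3])
        est = estimate_parameters(tiny_table, obs,
                                  parameters=("T_split123", "N_P1"),
                                  n_trees=100, rng=15)
        for name in ("T_split123", "N_P1"):
            point = est.point(name)
            lo, hi = est.interval(name)
            assert lo <= point <= hi

    def test_normalized_mode_reports_reference_size_one(self, tiny_table):
        obs = SummaryVector(values=tiny_table.stats[3])
        est = estimate_parameters(
            tiny_table, obs, parameters=("N_P1", "N_P2", "T_split123", "M12"),
            normalize=True, n_trees=100, rng=16)
        assert est.point("N_P1") == 1.0
        assert est.normalized

    def test_empty_table_rejected(self, tiny_table):
        empty = ReferenceTable(tiny_table.df.iloc[:0])
        obs = SummaryVector(values=np.zeros(len(SUMMARY_NAMES)))
        with pytest.raises(ValueError):
            estimate_parameters(empty, obs)


class TestPosteriorPredictive:
    def test_self_consistency_and_gross_misfit(self):
        draw = isolation_draw(50_000, t12=2e5, t123=2e6)
        specs = [LocusSpec(450) for _ in range(40)]
        rng = np.random.default_rng(17)
        loci = simulate_dataset(draw, specs, trio=SMALL_TRIO, rng=rng)
        obs = pod_summary(loci)
        tails = posterior_predictive_check(draw, specs, obs, n_rep=60,
                                           trio=SMALL_TRIO, rng=18)
        # the observed dataset is itself a draw from the model: across the
        # 65 statistics only a handful of spuriously extreme tails are
        # expected (P(tail = 0) is about 2/61 per statistic), and typical
        # tails are large
        flagged = sum(1 for v in tails.values() if v < 0.05)
        assert flagged <= 10
        assert np.median(list(tails.values())) > 0.2
        inflated = obs.values.copy()
        idx = SUMMARY_NAMES.index("pi_p1_mean")
        inflated[idx] *= 10
        tails2 = posterior_predictive_check(
            draw, specs, SummaryVector(values=inflated), n_rep=60,
            trio=SMALL_TRIO, rng=18)
        assert tails2["pi_p1_mean"] <= 0.05

    def test_single_replicate_is_degenerate_but_defined(self):
        draw = isolation_draw(20_000, t12=1e5, t123=1e6)
        specs = [LocusSpec(400) for _ in range(10)]
        loci = simulate_dataset(draw, specs, trio=SMALL_TRIO, rng=19)
        obs = pod_summary(loci)
        tails = posterior_predictive_check(draw, specs, obs, n_rep=1,
                                           trio=SMALL_TRIO, rng=20)
        assert set(np.round(list(tails.values()), 9)) <= {0.0, 1.0}


class TestDrawFromEstimates:
    def test_clipping_restores_valid_nesting(self):
        est_values = {p: (1.0, 0.5, 2.0) for p in PARAM_COLUMNS}
        est_values.update({
            "T_split123": (1e6, 0.0, 2e6),
            "T_split12": (2e6, 0.0, 3e6),  # exceeds T_split123
            "T_trans12": (5e5, 0.0, 1e6),
            "N_P1": (0.0, 0.0, 0.0),  # under the size floor
        })
        from triabc.abc_inference import ParameterEstimate
        est = ParameterEstimate(estimates=est_values)
        draw = draw_from_estimates(ScenarioCategory("AM", "SI"),
                                   HeterogeneitySubmodel(False, False), est)
        assert draw.T_split12 == draw.T_split123 == 1e6
        assert draw.N_P1 == 10.0
        assert draw.M13 == draw.M23 == 0.0
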