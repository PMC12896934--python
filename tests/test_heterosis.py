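import numpy as np
import pandas as pd
import pytest

from hetex import (DEGThresholds, PatternCallConfig, UsageError,
                   classify_patterns, compute_heterosis_stats,
                   intersect_upregulated, run_contrast, select_candidates)
from conftest import make_expr


def triple_expr(pa, pb, hy):
    """Constant-replicate matrix realizing exact group means for one gene."""
    return make_expr(
        {"parentA_1": [pa], "parentA_2": [pa],
         "parentB_1": [pb], "parentB_2": [pb],
         "hybrid_1": [hy], "hybrid_2": [hy]},
        ["g"],
    )


def fake_deg(genes, reference, calls):
    return pd.DataFrame(
        {"reference": reference, "test": "hybrid",
         "log2fc": 0.0, "p_value": 0.5, "p_adjusted": 0.5, "call": calls},
        index=genes,
    )


class TestHeterosisStats:
    @pytest.mark.parametrize(
        "pa,pb,hy,mpv,mph,bph",
        [
            (10, 20, 18, 15.0, 20.0, -10.0),
            (10, 20, 15, 15.0, 0.0, -25.0),
            (10, 20, 30, 15.0, 100.0, 50.0),
        ],
    )
    def test_formula_arithmetic(self, pa, pb, hy, mpv, mph, bph):
        rec = compute_heterosis_stats(triple_expr(pa, pb, hy)).loc["g"]
        assert rec["mpv"] == pytest.approx(mpv)
        assert rec["mph_pct"] == pytest.approx(mph)
        assert rec["bph_pct"] == pytest.approx(bph)
        assert rec["high_parent"] == "parentB"
        assert rec["mph_pct"] >= rec["bph_pct"]

    def test_mph_dominates_bph_on_randomized_triples(self, rng):
        pa, pb, hy = (rng.uniform(1, 1000, size=10_000) for _ in range(3))
        mpv = (pa + pb) / 2
        hp = np.maximum(pa, pb)
        mph = 100 * (hy - mpv) / mpv
        bph = 100 * (hy - hp) / hp
        assert (mph >= bph - 1e-9).all()
        # BPH > 0 exactly when the hybrid exceeds both parents
        np.testing.assert_array_equal(bph > 0, hy > hp)

    def test_low_mpv_genes_flagged_not_dropped(self):
        expr = triple_expr(0.2, 0.4, 50.0)
        rec = compute_heterosis_stats(expr, min_mpv=1.0)
        assert len(rec) == 1
        assert np.isnan(rec.loc["g", "mph_pct"])
        assert np.isnan(rec.loc["g", "bph_pct"])

    def test_parental_tie_goes_to_parentA(self):
        rec = compute_heterosis_stats(triple_expr(10, 10, 12)).loc["g"]
        assert rec["high_parent"] == "parentA"
        assert rec["mph_pct"] == pytest.approx(rec["bph_pct"])


class TestClassifyPatterns:
    def setup_method(self):
        genes = ["up_both", "down_a_only", "quiet_small_mph", "quiet_big_mph",
                 "down_both", "low_mpv"]
        self.stats = pd.DataFrame(
            {"mean_parentA": 10.0, "mean_parentB": 20.0, "mean_hybrid": 18.0,
             "mpv": [15, 15, 15, 15, 15, 0.2],
             "high_parent": "parentB",
             "mph_pct": [120.0, 30.0, 5.0, 80.0, -70.0, np.nan],
             "bph_pct": [80.0, 10.0, -5.0, 40.0, -80.0, np.nan]},
            index=genes,
        )
        self.deg_a = fake_deg(genes, "parentA",
                              ["up_in_test", "down_in_test", "not_significant",
                               "not_significant", "down_in_test", "up_in_test"])
        self.deg_b = fake_deg(genes, "parentB",
                              ["up_in_test", "not_significant", "not_significant",
                               "not_significant", "down_in_test", "up_in_test"])

    def test_rule_application(self):
        out = classify_patterns(self.stats, self.deg_a, self.deg_b)
        assert out.loc["up_both", "pattern"] == "transgressive_up"
        assert out.loc["down_a_only", "pattern"] == "dominant_like"
        assert out.loc["quiet_small_mph", "pattern"] == "additive_like"
        assert out.loc["quiet_big_mph", "pattern"] == "unclassified"
        assert out.loc["down_both", "pattern"] == "transgressive_down"
        assert out.loc["low_mpv", "pattern"] == "NA"  # excluded from classification
        assert bool(out.loc["up_both", "candidate"])
        assert not out.loc["down_both", "candidate"]

    def test_contrast_orientation_rejected(self):
        flipped = self.deg_a.assign(reference="hybrid", test="parentA")
        with pytest.raises(UsageError, match="hybrid"):
            classify_patterns(self.stats, flipped, self.deg_b)
        with pytest.raises(UsageError, match="parentB"):
            classify_patterns(self.stats, self.deg_a, self.deg_a)

    def test_patterns_partition_defined_universe(self, sim_expressed):
        cfg = PatternCallConfig()
        deg_a = run_contrast(sim_expressed, "parentA", "hybrid", cfg.thresholds)
        deg_b = run_contrast(sim_expressed, "parentB", "hybrid", cfg.thresholds)
        out = classify_patterns(compute_heterosis_stats(sim_expressed), deg_a, deg_b, cfg)
        defined = out["mph_pct"].notna()
        classes = {"transgressive_up", "transgressive_down", "additive_like",
                   "dominant_like", "unclassified"}
        assert set(out.loc[defined, "pattern"]) <= classes
        assert (out.loc[~defined, "pattern"] == "NA").all()
        assert out.loc[defined, "pattern"].value_counts().sum() == defined.sum()


class TestCandidatesAndIntersection:
    def test_candidate_rules_and_ordering(self):
        stats = pd.DataFrame(
            {"mph_pct": [50.0, 40.0, 90.0], "bph_pct": [35.0, 0.0, 80.0],
             "pattern": ["transgressive_up"] * 3,
             "candidate": [True, False, True]},
            index=["mid", "boundary", "top"],
        )
        assert select_candidates(stats) == ["top", "mid"]  # BPH exactly 0 excluded
        empty = stats.iloc[0:0]
        assert select_candidates(empty) == []

    def test_set_algebra(self):
        deg_a = fake_deg(list("ABCD"), "parentA",
                         ["up_in_test", "up_in_test", "up_in_test", "not_significant"])
        deg_b = fake_deg(list("ABCD"), "parentB",
                         ["not_significant", "up_in_test", "up_in_test", "up_in_test"])
        assert intersect_upregulated(deg_a, deg_b) == ["B", "C"]
        deg_b2 = fake_deg(list("ABCD"), "parentB", ["not_significant"] * 4)
        assert intersect_upregulated(deg_a, deg_b2) == []

    def test_intersection_equals_transgressive_up_on_simulation(self, sim_expressed):
        cfg = PatternCallConfig()
        deg_a = run_contrast(sim_expressed, "parentA", "hybrid", cfg.thresholds)
        deg_b = run_contrast(sim_expressed, "parentB", "hybrid", cfg.thresholds)
        out = classify_patterns(compute_heterosis_stats(sim_expressed), deg_a, deg_b, cfg)
        up_set = set(out.index[out["pattern"] == "transgressive_up"])
        defined = set(out.index[out["mph_pct"].notna()])
        assert up_set == set(intersect_upregulated(deg_a, deg_b)) & defined


class TestModeRecovery:
    def test_transgressive_recall_on_simulated_modes(self, sim_dataset, sim_expressed):
        _, truth = sim_dataset
        cfg = PatternCallConfig()
        deg_a = run_contrast(sim_expressed, "parentA", "hybrid", cfg.thresholds)
        deg_b = run_contrast(sim_expressed, "parentB", "hybrid", cfg.thresholds)
        out = classify_patterns(compute_heterosis_stats(sim_expressed), deg_a, deg_b, cfg)
        tr = truth.loc[out.index]
        od = tr["mode"] == "overdominant"
        ud = tr["mode"] == "underdominant"
        null = tr["mode"] == "null"
        up_recall = ((out["pattern"] == "transgressive_up") & od).sum() / od.sum()
        down_recall = ((out["pattern"] == "transgressive_down") & ud).sum() / ud.sum()
        false_rate = out.loc[null, "pattern"].isin(
            ["transgressive_up", "transgressive_down"]).mean()
        assert up_recall >= 0.8
        assert down_recall >= 0.8
        assert false_rate <= 0.1
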