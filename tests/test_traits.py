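from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hetex import (TraitSimSpec, UsageError, compact_letter_display,
                   correlate_genes_traits, filter_expressed, normalize_fpkm,
                   simulate_traits, summarize_traits, tukey_hsd)
from oracles import pearson_r_p, tukey_pairwise_p


def letters_sound_and_complete(result):
    """CLD soundness: shared letter <=> pair not significant at alpha."""
    for a, b in combinations(result.means, 2):
        p = result.p_values.get((a, b), result.p_values.get((b, a)))
        shared = set(result.letters[a]) & set(result.letters[b])
        if p < result.alpha:
            assert not shared, f"significant pair {a},{b} shares a letter"
        else:
            assert shared, f"non-significant pair {a},{b} shares no letter"


class TestTukeyHsd:
    def test_pairwise_p_matches_studentized_range_oracle(self):
        groups = {
            "parentA": [31.2, 29.8, 33.1, 30.5],
            "parentB": [17.0, 18.4, 16.2, 19.1],
            "hybrid": [32.0, 30.9, 34.2, 31.8],
        }
        result = tukey_hsd(groups)
        oracle = tukey_pairwise_p({k: np.array(v) for k, v in groups.items()})
        for pair, p in oracle.items():
            assert result.p_values[pair] == pytest.approx(p, abs=1e-6)

    def test_extreme_separation_gets_distinct_letter(self, rng):
        groups = {
            "a_grp": 0.0 + rng.normal(0, 0.01, 5),
            "b_grp": 0.0 + rng.normal(0, 0.01, 5),
            "c_grp": 100.0 + rng.normal(0, 0.01, 5),
        }
        result = tukey_hsd(groups)
        assert result.letters["c_grp"] == "a"  # highest mean gets 'a'
        assert set(result.letters["c_grp"]).isdisjoint(result.letters["a_grp"])
        assert result.letters["a_grp"] == result.letters["b_grp"]

    def test_null_groups_usually_share_a_letter(self):
        rng = np.random.default_rng(0)
        shared = 0
        n_sim = 100
        for _ in range(n_sim):
            groups = {g: rng.normal(0, 1, 5) for g in ("parentA", "parentB", "hybrid")}
            letters = tukey_hsd(groups).letters
            if set(letters["parentA"]) & set(letters["parentB"]) & set(letters["hybrid"]):
                shared += 1
        assert shared / n_sim >= 0.90

    def test_small_group_rejected(self):
        with pytest.raises(UsageError, match="fewer than 2"):
            tukey_hsd({"parentA": [1.0], "parentB": [1.0, 2.0]})

    def test_cld_property_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = rng.integers(3, 6)
            spread = rng.uniform(0, 3)
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, spread), 1, rng.integers(3, 8))
                for i in range(k)
            }
            letters_sound_and_complete(tukey_hsd(groups))


class TestCompactLetterDisplay:
    def test_no_significance_single_letter(self):
        letters = compact_letter_display(["x", "y", "z"], [])
        assert all(v == "a" for v in letters.values())

    def test_chain_structure(self):
        # x != z but y indistinguishable from both: y carries both letters
        letters = compact_letter_display(["x", "y", "z"], [("x", "z")])
        assert set(letters["y"]) == {"a", "b"}
        assert letters["x"] != letters["z"]


class TestCorrelations:
    def test_r_and_p_match_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.7, 12.3])
        r_o, p_o = pearson_r_p(x, y)
        r_s, p_s = sps.pearsonr(x, y)
        assert r_s == pytest.approx(r_o, abs=1e-10)
        assert p_s == pytest.approx(p_o, rel=1e-10)

    def test_noiseless_driver_trait_is_perfectly_correlated(self, sim_dataset):
        # analyse on the same total-count (CPM) scale the trait generator uses
        counts, _ = sim_dataset
        expr = filter_expressed(normalize_fpkm(counts))
        gene = expr.gene_ids[3]
        spec = TraitSimSpec({"up": [(gene, 1.0)], "down": [(gene, -1.0)]}, noise_sd=0.0)
        traits = simulate_traits(counts, spec, seed=0)
        corr = correlate_genes_traits(expr, traits, [gene])
        cells = corr.set_index("trait")
        assert cells.loc["up", "r"] == pytest.approx(1.0)
        assert cells.loc["down", "r"] == pytest.approx(-1.0)
        assert cells.loc["up", "stars"] == "***"

    def test_constant_vector_flagged_not_fabricated(self, sim_expressed):
        traits = pd.DataFrame(
            {"group": [sim_expressed.sample_groups[s] for s in sim_expressed.sample_ids],
             "flat": 1.0},
            index=sim_expressed.sample_ids,
        )
        corr = correlate_genes_traits(sim_expressed, traits, sim_expressed.gene_ids[:2])
        assert (~corr["defined"]).all()
        assert corr["r"].isna().all()
        assert (corr["stars"] == "").all()

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0, _ = sps.pearsonr(x, y)
        r_aff, _ = sps.pearsonr(3.0 * x + 7.0, y)
        r_neg, _ = sps.pearsonr(-2.0 * x, y)
        assert r_aff == pytest.approx(r0)
        assert r_neg == pytest.approx(-r0)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(2000):
            ps.append(sps.pearsonr(rng.normal(size=15), rng.normal(size=15)).pvalue)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_shared_samples_rejected(self, sim_expressed):
        traits = pd.DataFrame({"group": ["hybrid"], "t": [1.0]},
                              index=[sim_expressed.sample_ids[0]])
        with pytest.raises(UsageError, match="shared"):
            correlate_genes_traits(sim_expressed, traits, sim_expressed.gene_ids[:1])


class TestSummarizeTraits:
    @pytest.fixture
    def trait_table(self):
        samples = [f"{g}_{i}" for g in ("parentA", "parentB", "hybrid") for i in range(1, 6)]
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            {"group": [s.rsplit("_", 1)[0] for s in samples],
             "backfat": np.r_[rng.normal(35.7, 1, 5), rng.normal(17.2, 1, 5),
                              rng.normal(31.7, 1, 5)],
             "flat_trait": np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 3)},
            index=samples,
        )

    def test_means_match_hand_computation_and_letters_agree(self, trait_table):
        summary = summarize_traits(trait_table)
        backfat = summary[summary["trait"] == "backfat"].set_index("group")
        for g in ("parentA", "parentB", "hybrid"):
            expected = trait_table.loc[trait_table["group"] == g, "backfat"].mean()
            assert backfat.loc[g, "mean"] == pytest.approx(expected)
        oracle = tukey_hsd(
            {g: trait_table.loc[trait_table["group"] == g, "backfat"].to_numpy()
             for g in ("parentA", "parentB", "hybrid")}
        )
        assert dict(zip(backfat.index, backfat["letter"])) == oracle.letters

    def test_identical_groups_share_letter(self, trait_table):
        flat = summarize_traits(trait_table)
        flat = flat[flat["trait"] == "flat_trait"]
        assert flat["mean"].nunique() == 1
        assert flat["letter"].nunique() == 1
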