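import math

import numpy as np
import pandas as pd
import pytest

import syllogist as sy
from syllogist.enrichment import RESULT_COLUMNS

from .conftest import background_cohort
from .oracles import fisher_two_sided_enum


class TestExpressedGenes:
    def test_absolute_threshold_strict(self):
        values = pd.Series({"g1": 0.5, "g2": 2.0, "g3": 3.0})
        assert sy.expressed_genes(values, 1.0) == {"g2", "g3"}
        assert sy.expressed_genes(values, 3.0) == set()

    def test_all_zero_sample_empty(self):
        values = pd.Series({"g1": 0.0, "g2": 0.0})
        assert sy.expressed_genes(values, 0.0) == set()

    def test_quantile_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        values = pd.Series(rng.uniform(size=1000), index=[f"g{i}" for i in range(1000)])
        got = sy.expressed_genes(values, 0.5, mode="quantile")
        oracle = set(values.index[values > np.median(values)])
        assert got == oracle
        assert abs(len(got) - 500) <= 1

    @pytest.mark.parametrize(
        "threshold,mode", [(-1, "absolute"), (0.0, "quantile"), (1.5, "quantile"), (1, "nope")]
    )
    def test_invalid_threshold_rejected(self, threshold, mode):
        with pytest.raises(ValueError):
            sy.expressed_genes(pd.Series({"g": 1.0}), threshold, mode)


class TestHitCounting:
    def test_set_intersection_cases(self):
        sig = ["g1", "g2", "g3", "g4", "g5"]
        assert sy.count_signature_hits(sig, set()) == 0
        assert sy.count_signature_hits(sig, {"g2", "g4", "g9"}) == 2
        assert sy.count_signature_hits(sig, set(sig) | {"x"}) == 5


class TestNullModel:
    UNIVERSE = [f"g{i}" for i in range(1000)]

    def test_saturated_expressed_set_hits_m_exactly(self):
        null = sy.build_null_model(self.UNIVERSE, set(self.UNIVERSE), 50, 20, seed=1)
        assert null.k_null_mean == 20.0
        assert null.k_null == 20

    def test_disjoint_expressed_set_never_hits(self):
        null = sy.build_null_model(self.UNIVERSE, {"x", "y"}, 50, 20, seed=1)
        assert null.k_null_mean == 0.0

    def test_mean_within_three_se_of_hypergeometric(self):
        """|U|=1000, |E|=100, m=80: mean 8.0, SE ~ 0.081 at B=1000."""
        expressed = set(self.UNIVERSE[:100])
        null = sy.build_null_model(self.UNIVERSE, expressed, 1000, 80, seed=9)
        se = math.sqrt(80 * 0.1 * 0.9 * (920 / 999) / 1000)
        assert null.analytic_mean == pytest.approx(8.0)
        assert abs(null.k_null_mean - 8.0) < 3 * se

    def test_reproducible_given_seed(self):
        e = set(self.UNIVERSE[::3])
        a = sy.build_null_model(self.UNIVERSE, e, 200, 30, seed=4)
        b = sy.build_null_model(self.UNIVERSE, e, 200, 30, seed=4)
        assert a.k_null_mean == b.k_null_mean
        np.testing.assert_array_equal(a.hit_counts, b.hit_counts)

    def test_universe_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            sy.build_null_model(["a", "b"], {"a"}, 10, 5, seed=0)

    def test_half_up_integerization(self):
        null = sy.NullModel(100, 10, 1, 8, 0, k_null_mean=7.5, hit_counts=np.array([7]))
        assert null.k_null == 8
        null = sy.NullModel(100, 10, 1, 8, 0, k_null_mean=7.49, hit_counts=np.array([7]))
        assert null.k_null == 7


class TestFisherEnrichment:
    def test_no_hits_anywhere_is_null_result(self):
        p, or_ = sy.fisher_enrichment(0, 0, 80)
        assert (p, or_) == (1.0, 1.0)

    def test_known_table(self):
        p, or_ = sy.fisher_enrichment(12, 8, 80)
        assert or_ == pytest.approx((12 * 72) / (68 * 8), rel=1e-12)
        assert p == pytest.approx(fisher_two_sided_enum(12, 68, 8, 72), abs=1e-12)

    def test_monotone_in_observed_hits(self):
        """Past the null count, more observed hits mean larger OR and smaller p."""
        m, k_null = 40, 5
        last_or, last_p = None, None
        for k_obs in range(k_null + 1, m + 1):
            p, or_ = sy.fisher_enrichment(k_obs, k_null, m)
            if last_or is not None:
                assert or_ > last_or
                assert p <= last_p + 1e-12
            last_or, last_p = or_, p

    def test_out_of_range_counts_rejected(self):
        with pytest.raises(ValueError):
            sy.fisher_enrichment(81, 5, 80)
        with pytest.raises(ValueError):
            sy.fisher_enrichment(5, -1, 80)


class TestScoreSample:
    def test_empty_expressed_set_gives_unit_rows(self, small_atlas):
        ref, sig, _ = small_atlas
        values = pd.Series(0.0, index=ref.gene_ids)
        null = sy.build_null_model(list(ref.gene_ids), set(), 100, 20, seed=0)
        rows = sy.score_sample("s", values, sig, null, threshold=0.0)
        assert list(rows.columns) == RESULT_COLUMNS
        assert (rows["p_value"] == 1.0).all()
        assert (rows["odds_ratio"] == 1.0).all()

    def test_identical_samples_identical_rows(self, small_atlas):
        ref, sig, _ = small_atlas
        rng = np.random.default_rng(6)
        values = pd.Series(rng.lognormal(3, 1, len(ref.gene_ids)), index=ref.gene_ids)
        null = sy.build_null_model(list(ref.gene_ids), sy.expressed_genes(values, 0.5, "quantile"), 200, 20, seed=3)
        r1 = sy.score_sample("s", values, sig, null, threshold=0.5, threshold_mode="quantile")
        r2 = sy.score_sample("s", values, sig, null, threshold=0.5, threshold_mode="quantile")
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_lineage_dominates(self, small_atlas, intensity_config):
        """A sample expressing all markers of one lineage scores it first."""
        ref, sig, _ = small_atlas
        mix = sy.generate_mixture(
            ref.expression,
            sy.SyntheticMixtureSpec(weights={"L2": 1.0}, n_samples=1, noise_sigma=0.1, seed=8),
        )
        res = sy.score_cohort(mix, sig, intensity_config, universe=list(ref.gene_ids))
        by_or = res.table.sort_values("odds_ratio", ascending=False)
        assert by_or.iloc[0]["lineage_id"] == "L2"
        assert by_or.iloc[0]["p_value"] < 0.001


class TestNormalization:
    @staticmethod
    def _frame(or_by_sample_lineage):
        rows = [
            (s, l, 0, 0.0, 0, 1.0, v)
            for (s, l), v in or_by_sample_lineage.items()
        ]
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    def test_min_max_example(self):
        table = self._frame({("s1", "A"): 2.0, ("s2", "A"): 4.0, ("s3", "A"): 6.0})
        out = sy.normalize_odds_ratios(table)
        assert list(out["normalized_odds_ratio"]) == [0.0, 0.5, 1.0]

    def test_constant_lineage_maps_to_zero(self):
        table = self._frame({("s1", "A"): 3.0, ("s2", "A"): 3.0})
        out = sy.normalize_odds_ratios(table)
        assert list(out["normalized_odds_ratio"]) == [0.0, 0.0]

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(14)
        table = self._frame(
            {
                (f"s{i}", f"L{j}"): float(rng.uniform(0.5, 9))
                for i in range(6)
                for j in range(4)
            }
        )
        out = sy.normalize_odds_ratios(table)
        for lin in ("L0", "L1", "L2", "L3"):
            sub = out[out["lineage_id"] == lin]
            ors = list(sub["odds_ratio"])
            lo, hi = min(ors), max(ors)
            expected = [(v - lo) / (hi - lo) for v in ors]
            assert list(sub["normalized_odds_ratio"]) == pytest.approx(expected, abs=1e-12)
        assert out["normalized_odds_ratio"].between(0, 1).all()


class TestCompareGroups:
    @staticmethod
    def _table(values_by_sample):
        rows = []
        for s, lineage_values in values_by_sample.items():
            for l, v in lineage_values.items():
                rows.append((s, l, 0, 0.0, 0, 1.0, v))
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    def test_identical_groups_are_null(self):
        table = self._table(
            {f"s{i}": {"A": v} for i, v in enumerate([1.0, 2.0, 1.0, 2.0])}
        )
        groups = {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}
        out = sy.compare_groups(table, groups)
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p_value"] == 1.0
        assert out.loc[0, "p_adj"] == 1.0

    def test_known_unpaired_contrast(self):
        table = self._table(
            {f"s{i}": {"A": v} for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])}
        )
        groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        out = sy.compare_groups(table, groups)
        assert out.loc[0, "t"] == pytest.approx(-3.6742346141747673, rel=1e-10)
        assert out.loc[0, "df"] == 4
        assert out.loc[0, "p_value"] == pytest.approx(0.021311641128756713, rel=1e-9)

    def test_bh_applied_across_lineages(self):
        rng = np.random.default_rng(19)
        table = self._table(
            {
                f"s{i}": {f"L{j}": float(rng.normal(j * (i >= 3), 1)) for j in range(10)}
                for i in range(6)
            }
        )
        groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        out = sy.compare_groups(table, groups)
        expected = sy.bh_adjust(out["p_value"].to_numpy())
        assert out["p_adj"].to_numpy() == pytest.approx(expected, abs=1e-12)

    def test_degenerate_groupings_rejected(self):
        table = self._table({f"s{i}": {"A": float(i)} for i in range(4)})
        with pytest.raises(ValueError):
            sy.compare_groups(table, {"s0": "a", "s1": "a", "s2": "a", "s3": "b"})
        with pytest.raises(ValueError):
            sy.compare_groups(
                table, {"s0": "a", "s1": "b", "s2": "c", "s3": "a"}
            )
        with pytest.raises(ValueError):
            sy.compare_groups(
                table,
                {"s0": "a", "s1": "a", "s2": "b", "s3": "b", "s9": "b"},
            )


class TestCohortDeterminism:
    def test_rerun_with_same_seed_identical(self, small_atlas, intensity_config):
        ref, sig, _ = small_atlas
        cohort = background_cohort(ref, 3, seed=55)
        r1 = sy.score_cohort(cohort, sig, intensity_config, universe=list(ref.gene_ids))
        r2 = sy.score_cohort(cohort, sig, intensity_config, universe=list(ref.gene_ids))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_null_mean_converges_to_analytic(self, small_atlas, intensity_config):
        """k_null_mean across seeds stays within 4 SE of m|E∩U|/|U|."""
        ref, _, _ = small_atlas
        universe = list(ref.gene_ids)
        rng = np.random.default_rng(99)
        for rep in range(5):
            n_e = int(rng.integers(50, 400))
            expressed = set(rng.choice(universe, n_e, replace=False))
            m, B = 20, 1000
            null = sy.build_null_model(universe, expressed, B, m, seed=rep)
            n_u = len(universe)
            frac = n_e / n_u
            var = m * frac * (1 - frac) * (n_u - m) / (n_u - 1)
            se = math.sqrt(var / B)
            assert abs(null.k_null_mean - null.analytic_mean) < 4 * se
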