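"""Cell-means inference: marginal means, contrasts, impacts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bloomfit import (
    CellMeansModel,
    build_impact_tables,
    classify_direction,
    impact_percent,
)
from bloomfit.errors import (
    ConfigurationError,
    InsufficientReplicationError,
    SpecificationError,
    UndefinedImpactError,
)


def one_factor_frame(cells: dict) -> pd.DataFrame:
    rows = [{"inoculum": k, "growth": v}
            for k, vals in cells.items() for v in vals]
    return pd.DataFrame(rows)


def two_factor_frame(cells: dict) -> pd.DataFrame:
    rows = [{"inoculum": i, "vitamin": v, "growth": x}
            for (i, v), vals in cells.items() for x in vals]
    return pd.DataFrame(rows)


class TestCellMeansFit:
    def test_two_cell_pooled_computation_by_hand(self):
        res = CellMeansModel(one_factor_frame({"A": [1, 2, 3], "B": [2, 3, 4]}),
                             "growth", factors=("inoculum",)).fit()
        assert res.cell_means == {("A",): 2.0, ("B",): 3.0}
        assert res.sigma2 == pytest.approx(1.0)
        assert res.df_resid == 4

    def test_no_spread_gives_zero_pooled_variance(self):
        res = CellMeansModel(one_factor_frame({"A": [2, 2], "B": [2, 2]}),
                             "growth", factors=("inoculum",)).fit()
        assert res.sigma2 == 0.0

    def test_balanced_full_design_residual_df(self):
        cells = {(i, v): [0.1, 0.2, 0.3]
                 for i in "ABCDEF" for v in ("replete", "deficient")}
        res = CellMeansModel(two_factor_frame(cells), "growth").fit()
        assert res.df_resid == 24  # 36 observations - 12 cells

    def test_singleton_cell_raises(self):
        with pytest.raises(InsufficientReplicationError):
            CellMeansModel(one_factor_frame({"A": [1.0], "B": [2, 3]}),
                           "growth", factors=("inoculum",)).fit()

    def test_nonconverged_rows_are_excluded(self):
        df = one_factor_frame({"A": [1, 2, 3], "B": [2, 3, 4]})
        df["fit_converged"] = [True, True, False, True, True, True]
        res = CellMeansModel(df, "growth", factors=("inoculum",)).fit()
        assert res.cell_n[("A",)] == 2
        assert res.cell_means[("A",)] == pytest.approx(1.5)


class TestMarginalMeans:
    def test_single_cell_mean_and_se(self):
        res = CellMeansModel(one_factor_frame({"A": [2, 3, 4], "B": [1, 2, 3]}),
                             "growth", factors=("inoculum",)).fit()
        mean, se = res.marginal_mean({"inoculum": "A"})
        assert mean == pytest.approx(3.0)
        assert se == pytest.approx(np.sqrt(res.sigma2 / 3))

    def test_margin_averages_equal_n_cells(self):
        cells = {("A", "replete"): [1, 2], ("A", "deficient"): [3, 4],
                 ("B", "replete"): [5, 6], ("B", "deficient"): [7, 8]}
        res = CellMeansModel(two_factor_frame(cells), "growth").fit()
        mean, _ = res.marginal_mean({"inoculum": "A"})
        assert mean == pytest.approx((1.5 + 3.5) / 2)

    def test_empty_margin_raises(self):
        res = CellMeansModel(one_factor_frame({"A": [1, 2], "B": [2, 3]}),
                             "growth", factors=("inoculum",)).fit()
        with pytest.raises(SpecificationError):
            res.marginal_mean({"inoculum": "Z"})


class TestContrasts:
    def test_two_level_contrast_equals_pooled_t_test(self):
        res = CellMeansModel(one_factor_frame({"A": [1, 2, 3], "B": [2, 3, 4]}),
                             "growth", factors=("inoculum",)).fit()
        c = res.contrast({"inoculum": "A"}, {"inoculum": "B"})
        assert c.estimate == pytest.approx(-1.0)
        assert c.se == pytest.approx(0.8165, abs=1e-4)
        assert c.t == pytest.approx(-1.2247, abs=1e-4)
        assert c.df == 4
        t_ref = stats.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=True)
        assert c.t == pytest.approx(t_ref.statistic)
        assert c.p_unadjusted == pytest.approx(t_ref.pvalue)

    def test_identical_cells_null_contrast(self):
        res = CellMeansModel(one_factor_frame({"A": [5, 5], "B": [5, 5]}),
                             "growth", factors=("inoculum",)).fit()
        c = res.contrast({"inoculum": "A"}, {"inoculum": "B"})
        assert c.estimate == 0.0
        assert c.p_adjusted == 1.0
        assert c.p_adjusted >= c.p_unadjusted

    def test_family_of_one_is_unadjusted(self):
        res = CellMeansModel(one_factor_frame({"A": [1, 2, 3], "B": [2, 3, 4]}),
                             "growth", factors=("inoculum",)).fit()
        c = res.contrast({"inoculum": "A"}, {"inoculum": "B"},
                         adjust="tukey", family_size=1)
        assert c.p_adjusted == c.p_unadjusted

    def test_adjusted_p_monotone_in_family_size(self):
        res = CellMeansModel(one_factor_frame({"A": [1, 2, 3], "B": [2, 3, 4]}),
                             "growth", factors=("inoculum",)).fit()
        ps = [res.contrast({"inoculum": "A"}, {"inoculum": "B"},
                           adjust="tukey", family_size=f).p_adjusted
              for f in (1, 3, 6, 15)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_unknown_adjustment_rejected(self):
        res = CellMeansModel(one_factor_frame({"A": [1, 2], "B": [2, 3]}),
                             "growth", factors=("inoculum",)).fit()
        with pytest.raises(ConfigurationError):
            res.pairwise_contrasts("inoculum", adjust="bonferroni")

    def test_tukey_matches_statsmodels_reference(self):
        """Independent oracle: statsmodels' Tukey HSD on one-factor data."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        levels = list("ABCDE")
        df = one_factor_frame({k: rng.normal(size=4) + i * 0.5
                               for i, k in enumerate(levels)})
        res = CellMeansModel(df, "growth", factors=("inoculum",)).fit()
        ours = {(c.a[0], c.b[0]): c for c in
                res.pairwise_contrasts("inoculum", adjust="tukey")}
        ref = pairwise_tukeyhsd(df["growth"], df["inoculum"])
        from itertools import combinations
        pairs = list(combinations(ref.groupsunique, 2))
        for (g1, g2), diff, p_adj in zip(pairs, ref.meandiffs, ref.pvalues):
            c = ours[(g1, g2)]
            assert c.estimate == pytest.approx(-diff)  # orientation differs
            assert c.p_adjusted == pytest.approx(p_adj, abs=1e-6)

    def test_vitamin_contrast_sign_convention_and_family(self):
        cells = {("control", "replete"): [3, 3, 3],
                 ("control", "deficient"): [1, 1, 1.2],
                 ("A", "replete"): [2, 2.1, 2], ("A", "deficient"): [2, 2, 2.2]}
        res = CellMeansModel(two_factor_frame(cells), "growth").fit()
        c = res.vitamin_contrast("control")
        assert c.estimate == pytest.approx(3.0 - 16 / 15 * 1.0, abs=0.01)
        assert c.estimate > 0  # replete minus deficient
        assert c.family_size == 1
        assert c.p_adjusted == c.p_unadjusted

    def test_vitamin_contrast_recovers_planted_shift(self):
        rng = np.random.default_rng(21)
        delta = 0.8
        cells = {("control", "replete"): rng.normal(2 + delta, 0.1, 3),
                 ("control", "deficient"): rng.normal(2, 0.1, 3)}
        res = CellMeansModel(two_factor_frame(
            {k: list(v) for k, v in cells.items()}), "growth").fit()
        c = res.vitamin_contrast("control")
        assert abs(c.estimate - delta) < 3 * c.se


class TestImpactMetric:
    def test_hand_values(self):
        assert impact_percent(3.0, 3.0) == 0.0
        assert impact_percent(3.0, 1.0) == pytest.approx(100.0)

    @given(st.floats(min_value=0.01, max_value=1e4),
           st.floats(min_value=0.01, max_value=1e4))
    def test_antisymmetry_and_bound(self, a, b):
        assert impact_percent(a, b) == pytest.approx(-impact_percent(b, a))
        assert abs(impact_percent(a, b)) < 200.0

    @given(st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=50))
    def test_scale_invariance(self, a, b, c):
        assert impact_percent(c * a, c * b) == pytest.approx(
            impact_percent(a, b), abs=1e-8)

    def test_zero_average_is_undefined(self):
        with pytest.raises(UndefinedImpactError):
            impact_percent(1.0, -1.0)


class TestDirection:
    @pytest.mark.parametrize("response,sign,expected", [
        ("growth", 1, "beneficial"),
        ("growth", -1, "detrimental"),
        ("max_abundance", 1, "beneficial"),
        ("max_abundance", 0, "none"),
        ("decline", 1, "detrimental"),   # faster decline hurts
        ("decline", -1, "beneficial"),
    ])
    def test_mapping(self, response, sign, expected):
        assert classify_direction(response, sign) == expected

    def test_unknown_response_rejected(self):
        with pytest.raises(SpecificationError):
            classify_direction("lag", 1)


class TestImpactTables:
    def _null_table(self, seed=0, noise=0.02):
        rng = np.random.default_rng(seed)
        rows = []
        for inoc in ("A", "B", "control"):
            for vit in ("replete", "deficient"):
                for rep in range(3):
                    rows.append({
                        "host": "H", "inoculum": inoc, "vitamin": vit,
                        "replicate": str(rep),
                        "growth": 0.02 * rng.lognormal(0, noise),
                        "decline": 0.001 * rng.lognormal(0, noise),
                        "max_abundance": 7 * rng.lognormal(0, noise),
                        "fit_converged": True,
                    })
        return pd.DataFrame(rows)

    def test_alpha_one_keeps_everything(self):
        tables = build_impact_tables(self._null_table(), alpha=1.0)
        filt = tables.filtered()
        for name, df in tables.as_dict().items():
            pd.testing.assert_frame_equal(df, filt.as_dict()[name])

    def test_planted_depression_is_significant_and_detrimental(self):
        df = self._null_table(seed=1, noise=0.01)
        mask = ((df["inoculum"] == "A") & (df["vitamin"] == "deficient"))
        df.loc[mask, "growth"] *= 0.6
        tables = build_impact_tables(df, alpha=0.05)
        t2 = tables.inoculation_vs_control
        row = t2[(t2["response"] == "growth") & (t2["within"] == "deficient")
                 & (t2["comparison_a"] == "A")].iloc[0]
        assert bool(row["significant"])
        assert row["direction"] == "detrimental"
        assert row["impact_percent"] == pytest.approx(
            100 * (0.6 - 1) / 0.8, abs=8)
        # effector orientation: inoculation is always comparison_a
        assert (t2["comparison_b"] == "control").all()

    def test_row_ordering_is_stable(self):
        t = build_impact_tables(self._null_table()).inoculation_pairs
        key = list(zip(t["host"], t["response"], t["within"],
                       t["comparison_a"], t["comparison_b"]))
        assert key == sorted(key)
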