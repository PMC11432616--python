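"""Reliability statistics: CV, ICC, paired tests, percent change, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aortamorph as am
from aortamorph import datasets
from aortamorph.stats import (MeasurementTable, cohort_summary,
                              coefficient_of_variation, icc_two_way_random,
                              paired_t, percent_change)


def icc_oracle(matrix: np.ndarray) -> tuple[float, float]:
    """Brute-force two-way mean squares -> ICC(2,1) and ICC(2,k).

    Independent of the implementation: explicit sums over the subject x rater
    grid, following the standard variance-components decomposition.
    """
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((matrix - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc2k = (msr - mse) / (msr + (msc - mse) / n)
    return icc21, icc2k


def long_format(matrix: np.ndarray) -> pd.DataFrame:
    n, k = matrix.shape
    return pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile([f"r{j}" for j in range(k)], n),
        "value": matrix.ravel(),
    })


class TestCoefficientOfVariation:
    def test_equal_values_zero(self):
        assert coefficient_of_variation([7.0, 7.0, 7.0]) == 0.0

    def test_one_two_three_is_fifty_percent(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_constructed_ratio(self):
        """Five repeats built with SD/mean = 0.0117 give CV = 1.17."""
        mean, sd = 117.0, 117.0 * 0.0117
        # symmetric 5-point set with exactly this sample SD
        base = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        vals = mean + base * sd / base.std(ddof=1)
        assert coefficient_of_variation(vals) == pytest.approx(1.17, abs=1e-9)

    @given(st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, c):
        vals = np.array([10.0, 11.0, 12.5, 9.5])
        assert coefficient_of_variation(c * vals) == pytest.approx(
            coefficient_of_variation(vals), rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            coefficient_of_variation([-1.0, 1.0])


class TestIcc:
    def test_identical_raters_give_unity(self):
        m = np.column_stack([[1.0, 5.0, 9.0, 2.0]] * 2)
        rep = icc_two_way_random(long_format(m), form="single")
        assert rep.icc == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("form", ["single", "mean_k"])
    def test_matches_variance_component_oracle(self, form):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(4, 9)
            k = rng.integers(2, 5)
            m = rng.normal(50, 10, size=(n, 1)) + rng.normal(0, 3, size=(n, k))
            rep = icc_two_way_random(long_format(m), form=form)
            expected = icc_oracle(m)[0 if form == "single" else 1]
            assert rep.icc == pytest.approx(expected, abs=1e-9)

    def test_interobserver_table_reliability(self):
        """Two observers' ten paired angle readings give ICC ~ 0.96."""
        table = datasets.load_interobserver_table()
        long = table.melt(id_vars=["subject", "patient", "phase"],
                          value_vars=["observer1", "observer2"],
                          var_name="rater", value_name="value")
        rep = icc_two_way_random(long[["subject", "rater", "value"]],
                                 form="single")
        assert round(rep.icc, 2) == 0.96
        lo, hi = rep.icc_ci95
        assert lo <= rep.icc <= hi

    def test_unrelated_raters_near_zero(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, size=(12, 2))
        rep = icc_two_way_random(long_format(m), form="single")
        assert abs(rep.icc) < 0.5
        assert rep.icc_ci95[0] <= rep.icc <= rep.icc_ci95[1]

    def test_incomplete_layout_rejected(self):
        df = long_format(np.ones((3, 2)) + np.arange(6).reshape(3, 2)).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            icc_two_way_random(df)


class TestPairedT:
    def test_constant_shift_recovered(self):
        pre = np.array([10.0, 12.0, 9.0, 14.0])
        res = paired_t(pre, pre + 2.5 + np.array([0.1, -0.1, 0.05, -0.05]))
        assert res.mean_diff == pytest.approx(2.5)

    def test_antisymmetric_in_arguments(self):
        pre = [1.0, 4.0, 2.0, 8.0]
        post = [2.0, 3.0, 4.0, 9.0]
        a = paired_t(pre, post)
        b = paired_t(post, pre)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.mean_diff == pytest.approx(-b.mean_diff)
        assert a.t_stat == pytest.approx(-b.t_stat)

    def test_aneurysm_angle_increase_t_statistic(self):
        """Four aneurysm patients' pre/post angles give t ~ 3.47 (df = 3)."""
        t = datasets.load_aosa_table()
        grp = t[t["pathology"] == "aneurysm"]
        res = paired_t(grp["aosa_pre_mean"], grp["aosa_post_mean"])
        assert res.t_stat == pytest.approx(3.47, abs=0.01)
        assert res.n_pairs == 4
        assert res.p_value < 0.05

    def test_tortuosity_change_not_significant(self):
        g = datasets.load_geometry_table().pivot(index="patient",
                                                 columns="phase")
        res = paired_t(g[("tortuosity", "pre")], g[("tortuosity", "post")])
        assert res.p_value > 0.05

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestPercentChange:
    def test_no_change(self):
        assert percent_change(10.0, 10.0) == 0.0

    def test_dissection_decrease(self):
        assert round(percent_change(113.62, 107.83), 1) == -5.1

    def test_signed_increase(self):
        # printed as +2.91; exact recomputation gives 2.9153
        assert percent_change(108.05, 111.2) == pytest.approx(2.91, abs=0.01)

    def test_conventions_are_opposite(self):
        a = percent_change(50.0, 60.0, "signed_post_minus_pre")
        b = percent_change(50.0, 60.0, "pre_minus_post")
        assert a == -b == pytest.approx(20.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="pre = 0"):
            percent_change(0.0, 5.0)


class TestCohortSummary:
    def test_aneurysm_group_preop_angle(self):
        t = datasets.load_aosa_table()
        out = cohort_summary(t, "aosa_pre_mean", ["pathology"])
        row = out[out["pathology"] == "aneurysm"].iloc[0]
        assert row["mean"] == pytest.approx(112.36, abs=0.01)
        assert row["sd"] == pytest.approx(8.21, abs=0.01)
        assert row["n"] == 4

    def test_outer_line_preop(self):
        g = datasets.load_geometry_table()
        out = cohort_summary(g, "outer_line", ["phase"])
        row = out[out["phase"] == "pre"].iloc[0]
        assert row["mean"] == pytest.approx(102.21, abs=0.005)
        assert row["sd"] == pytest.approx(10.17, abs=0.005)

    def test_singleton_group_flagged(self):
        df = pd.DataFrame({"g": ["a", "b", "b"], "v": [1.0, 2.0, 4.0]})
        out = cohort_summary(df, "v", ["g"])
        a = out[out["g"] == "a"].iloc[0]
        assert not a["sd_defined"]
        assert a["mean"] == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary(pd.DataFrame(columns=["g", "v"]), "v", ["g"])


class TestMeasurementTable:
    def _frame(self):
        return pd.DataFrame({
            "patient": [1, 1], "phase": ["pre", "pre"],
            "observer": [1, 1], "repeat": [1, 2],
            "metric": ["aosa", "aosa"], "value": [117.1, 117.4],
        })

    def test_round_trip(self, tmp_path):
        t = MeasurementTable(self._frame())
        path = tmp_path / "m.csv"
        t.to_csv(path)
        back = MeasurementTable.from_csv(path)
        assert back.data["value"].tolist() == [117.1, 117.4]

    def test_duplicate_key_rejected(self):
        df = self._frame()
        df.loc[1, "repeat"] = 1
        with pytest.raises(ValueError, match="unique"):
            MeasurementTable(df)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            MeasurementTable(self._frame().drop(columns=["observer"]))

    def test_nonfinite_value_rejected(self):
        df = self._frame()
        df.loc[0, "value"] = np.inf
        with pytest.raises(ValueError, match="finite"):
            MeasurementTable(df)
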