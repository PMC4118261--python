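import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungfavc import (
    bland_altman,
    f_test_cov,
    load_reference_subjects,
    mean_sd_cov,
    paired_t,
    pearson_r,
    repeatability_cov,
    summarize_cohort,
)
from lungfavc.cohort_stats import StatsError, averaged_cov


class TestReferenceTable:
    def test_eleven_subjects_with_covariates(self):
        df = load_reference_subjects()
        assert len(df) == 11
        assert set(df.columns) == {
            "subject", "height_cm", "weight_kg", "fev1_l", "frc_ml"
        }
        assert df["weight_kg"].isna().sum() == 1  # one missing weight

    def test_frc_summary_matches_published_cohort(self):
        # helium-dilution FRC of the 11 healthy males: mean 3332 ml,
        # inter-subject COV 19.9% (sample sd)
        df = load_reference_subjects()
        s = mean_sd_cov(df["frc_ml"])
        assert round(s.mean) == 3332
        assert s.cov_percent == pytest.approx(19.9, abs=0.05)


class TestMeanSdCov:
    def test_constant_list_zero_cov(self):
        s = mean_sd_cov([5, 5, 5])
        assert s.sd == 0.0 and s.cov_percent == 0.0

    def test_uses_sample_sd(self):
        s = mean_sd_cov([1.0, 3.0])
        assert s.sd == pytest.approx(np.sqrt(2))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 20, 12)
        s1 = mean_sd_cov(x)
        s2 = mean_sd_cov(7.0 * x)
        assert s2.mean == pytest.approx(7.0 * s1.mean)
        assert s2.sd == pytest.approx(7.0 * s1.sd)
        assert s2.cov_percent == pytest.approx(s1.cov_percent)

    def test_single_value_rejected(self):
        with pytest.raises(StatsError):
            mean_sd_cov([1.0])

    @given(
        st.lists(st.floats(1.0, 1e6), min_size=2, max_size=30),
        st.floats(0.01, 1e3),
    )
    @settings(max_examples=50, derandomize=True)
    def test_cov_invariant_under_positive_scaling(self, xs, k):
        s1 = mean_sd_cov(xs)
        s2 = mean_sd_cov([k * x for x in xs])
        assert s2.cov_percent == pytest.approx(s1.cov_percent, rel=1e-9, abs=1e-9)


class TestRepeatabilityCov:
    def test_identical_visits_give_zero(self):
        x = [1000.0, 1200.0, 900.0, 1500.0]
        assert repeatability_cov(x, x) == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_absorbed_by_intercept(self):
        x = np.array([1000.0, 1200.0, 900.0, 1500.0])
        assert repeatability_cov(x, x + 57.0) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_residual_sd(self):
        rng = np.random.default_rng(123)
        n = 200
        sigma = 5.0
        x = rng.normal(100.0, 10.0, n)
        y = x + rng.normal(0.0, sigma, n)
        got = repeatability_cov(x, y)
        expected = 100.0 * sigma / np.concatenate([x, y]).mean()
        assert got == pytest.approx(expected, rel=0.10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(50, 5, 20)
        y = x + rng.normal(0, 2, 20)
        # adding a constant to both visits shifts the grand mean, so the
        # percentage changes, but the SEE itself is shift-invariant:
        see1 = repeatability_cov(x, y) * np.concatenate([x, y]).mean()
        see2 = repeatability_cov(x + 10, y + 10) * np.concatenate([x + 10, y + 10]).mean()
        assert see1 == pytest.approx(see2, rel=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatsError):
            repeatability_cov([1.0, 2.0], [1.0, 2.0])


class TestPairedT:
    def test_identical_lists(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(StatsError):
            paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_textbook_example(self):
        # differences (1, 2, 3, 2): mean 2, sd sqrt(2/3),
        # t = 2 / (sd/2) = 4.898979...
        x = np.array([11.0, 12.0, 13.0, 12.0])
        y = np.zeros(4) + np.array([10.0, 10.0, 10.0, 10.0])
        t, p = paired_t(x, y)
        sd = np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(2.0 / (sd / 2.0))
        from scipy import stats as ss
        assert p == pytest.approx(2 * ss.t.sf(t, df=3))

    def test_sign_flips_when_swapped(self):
        x = [1.0, 2.0, 4.0, 3.0]
        y = [2.0, 2.5, 3.0, 5.0]
        t1, _ = paired_t(x, y)
        t2, _ = paired_t(y, x)
        assert t1 == pytest.approx(-t2)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_recovers_population_rho(self):
        rng = np.random.default_rng(99)
        rho = 0.78
        n = 5000
        z = rng.multivariate_normal(
            [0, 0], [[1, rho], [rho, 1]], size=n
        )
        assert pearson_r(z[:, 0], z[:, 1]) == pytest.approx(rho, abs=0.02)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFTest:
    def test_equal_variance_gives_unity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        f, p = f_test_cov(x, [10.0, 11.0, 12.0, 13.0])
        assert f == pytest.approx(1.0)

    def test_constructed_variance_ratio(self):
        a = np.array([0.0, 2.0, 4.0, 6.0])
        b = a / 2.0
        f, _ = f_test_cov(a, b)
        assert f == pytest.approx(4.0)

    def test_p_matches_f_distribution_sf(self):
        from scipy import stats as ss

        rng = np.random.default_rng(3)
        a = rng.normal(0, 2, 10)
        b = rng.normal(0, 1, 8)
        f, p = f_test_cov(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        big, dfn, dfd = (va / vb, 9, 7) if va > vb else (vb / va, 7, 9)
        assert p == pytest.approx(min(1.0, 2 * ss.f.sf(big, dfn, dfd)))

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            f_test_cov([1.0, 2.0], [3.0, 3.0])


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([(5.0, 5.0), (7.0, 7.0)])
        assert res["bias"] == 0.0
        assert res["loa_low"] == 0.0 and res["loa_high"] == 0.0

    def test_small_arithmetic_example(self):
        res = bland_altman([(10.0, 12.0), (20.0, 18.0)])
        np.testing.assert_allclose(res["means"], [11.0, 19.0])
        np.testing.assert_allclose(res["differences"], [-2.0, 2.0])
        assert res["bias"] == 0.0

    def test_limits_match_direct_recomputation(self):
        rng = np.random.default_rng(11)
        pairs = rng.normal(100, 10, (30, 2))
        res = bland_altman(pairs)
        d = pairs[:, 0] - pairs[:, 1]
        assert res["loa_high"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert res["loa_low"] == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))


class TestSummarize:
    @staticmethod
    def _table():
        rng = np.random.default_rng(5)
        rows = []
        for i in range(6):
            for visit in (1, 2):
                for lung, base in (("right", 1000.0), ("left", 850.0)):
                    air = base + rng.normal(0, 50)
                    rows.append({
                        "subject": f"S{i}", "visit": visit, "lung": lung,
                        "space_ml": air / 0.68, "air_ml": air,
                        "favc": 0.68, "cp": 0.1,
                    })
        return pd.DataFrame(rows)

    def test_summary_shape_and_zero_variance_params(self):
        summary = summarize_cohort(self._table())
        assert len(summary) == 8  # 2 lungs x 4 parameters
        favc_rows = summary[summary["parameter"] == "favc"]
        np.testing.assert_allclose(favc_rows["sd"], 0.0)

    def test_duplicate_rows_rejected(self):
        t = self._table()
        with pytest.raises(StatsError):
            summarize_cohort(pd.concat([t, t.iloc[[0]]]))

    def test_averaged_cov_is_two_value_mean(self):
        assert averaged_cov(27.1, 36.5) == pytest.approx(31.8)
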