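"""Concentration-dependence classification and rate-constant extraction."""

import numpy as np
import pytest
from scipy import stats

from trelax import (
    KineticScenario,
    classify_dependence,
    critical_r,
    fit_rate_vs_concentration,
    kd_from_rates,
    pearson_r,
    pool_slow_rates,
    summarize_enzyme,
)
from trelax.binding import BindingParameters, free_concentrations
from trelax.transients import ExpFitResult

from conftest import run_titration


def critical_r_beta_oracle(confidence: float, df: int) -> float:
    """Independent oracle: under the null, r^2 ~ Beta(1/2, df/2)."""
    return float(np.sqrt(stats.beta.ppf(confidence, 0.5, df / 2.0)))


class TestPearson:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),          # y = 2x + 1
        ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),     # y = -x
        ([1, 2, 3, 4], [1, 3, 2, 5], 0.8315),       # hand covariance formula
    ])
    def test_examples(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-4)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


class TestCriticalR:
    @pytest.mark.parametrize("confidence, expected", [
        (0.99, 0.505), (0.90, 0.337), (0.80, 0.265),
    ])
    def test_reference_thresholds_df23(self, confidence, expected):
        assert round(critical_r(confidence, 23), 3) == expected

    def test_matches_beta_distribution_oracle(self):
        for df in range(3, 101):
            for conf in (0.99, 0.95, 0.90, 0.80):
                assert critical_r(conf, df) == pytest.approx(
                    critical_r_beta_oracle(conf, df), abs=1e-6)

    def test_monotone_in_df_and_confidence(self):
        vals_df = [critical_r(0.95, df) for df in range(3, 60)]
        assert np.all(np.diff(vals_df) < 0)
        vals_conf = [critical_r(c, 23) for c in (0.5, 0.8, 0.9, 0.95, 0.99)]
        assert np.all(np.diff(vals_conf) > 0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            critical_r(1.5, 23)
        with pytest.raises(ValueError):
            critical_r(0.99, 0)


class TestClassifyDependence:
    @pytest.mark.parametrize("r, verdict", [
        (0.954, "dependent"),
        (0.366, "weakly_dependent"),
        (0.124, "independent"),
        (-0.659, "independent"),   # negative correlation is nonphysical
    ])
    def test_verdicts_at_n25(self, r, verdict):
        test = classify_dependence(r, 25)
        assert test.verdict == verdict
        assert test.df == 23

    def test_critical_values_decrease_with_confidence(self):
        test = classify_dependence(0.5, 25)
        assert test.confidence_levels == (0.99, 0.90, 0.80)
        assert list(test.critical_values) == sorted(test.critical_values,
                                                    reverse=True)


class TestRateLine:
    def test_exact_line_recovers_kon_koff(self):
        x = np.array([20.0, 50.0, 80.0, 110.0, 140.0])
        y = 31.0 * x + 1100.0
        slope, intercept, s_se, i_se = fit_rate_vs_concentration(x, y)
        assert slope == pytest.approx(31.0, rel=1e-12)
        assert intercept == pytest.approx(1100.0, rel=1e-12)
        assert s_se == pytest.approx(0.0, abs=1e-9)

    def test_all_equal_x_raises(self):
        with pytest.raises(ValueError):
            fit_rate_vs_concentration([50.0] * 5, [1.0, 2, 3, 4, 5])

    def test_noisy_line_within_two_standard_errors(self):
        rng = np.random.default_rng(3)
        x = np.repeat([20.0, 50.0, 80.0, 110.0, 140.0], 5)
        y = 31.0 * x + 1100.0
        y = y + rng.normal(0, 0.01 * y)
        slope, intercept, s_se, i_se = fit_rate_vs_concentration(x, y)
        assert abs(slope - 31.0) < 2 * s_se
        assert abs(intercept - 1100.0) < 2 * i_se


class TestKdAndPooling:
    @pytest.mark.parametrize("k_on, k_off, expected", [
        (31.0, 1100.0, 35.5), (50.0, 500.0, 10.0), (31.0, 0.0, 0.0),
    ])
    def test_kd_from_rates(self, k_on, k_off, expected):
        assert kd_from_rates(k_on, k_off) == pytest.approx(expected, abs=0.05)

    def test_kd_rejects_nonpositive_kon(self):
        with pytest.raises(ValueError):
            kd_from_rates(0.0, 100.0)

    def test_pool_identical_values(self):
        mean, sd, n = pool_slow_rates([400.0] * 25)
        assert (mean, sd, n) == (400.0, 0.0, 25)
        assert n - 2 == 23  # DF for the companion correlation

    def test_pool_small_sample(self):
        mean, sd, n = pool_slow_rates([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_pool_rejects_single_value(self):
        with pytest.raises(ValueError):
            pool_slow_rates([1.0])


def _fit(kf, ks, conc, rep=0):
    return ExpFitResult(k_fast=kf, k_slow=ks, amp_fast=10, amp_slow=8,
                        baseline=100, k_fast_se=1, k_slow_se=1, amp_fast_se=0,
                        amp_slow_se=0, baseline_se=0, rms=0.1, converged=True,
                        enzyme_total=100.0, ligand_total=conc, replicate=rep)


class TestSummarizeEnzyme:
    def test_full_synthetic_scenario_verdicts(self, wt_scenario, wt_titration):
        """Fast phase classified dependent, slow independent, by construction."""
        _, fits = wt_titration
        s = summarize_enzyme(fits, wt_scenario.binding, kd_itc=4.7)
        assert s.fast_test.verdict == "dependent"
        assert s.slow_test.verdict == "independent"
        assert s.slow_n == 25 and s.fast_test.df == 23
        assert s.kd_tjump == pytest.approx(s.k_off / s.k_on, rel=1e-12)

    def test_constant_fast_rate_withholds_rate_constants(self):
        # jitter is mean-zero within each concentration group, so the
        # correlation with concentration is exactly zero
        jitter = [-2.0, -1.0, 0.0, 1.0, 2.0]
        fits = [_fit(3000.0 + jitter[r], 400.0 + 10 * jitter[r], c, r)
                for c in (25.0, 50.0, 100.0, 150.0, 200.0) for r in range(5)]
        params = BindingParameters(kd_ref=4.7, delta_H=-10.0, T_ref=302.15)
        s = summarize_enzyme(fits, params, kd_itc=4.7)
        assert s.fast_test.verdict == "independent"
        assert np.isnan(s.k_on) and np.isnan(s.k_off) and np.isnan(s.kd_tjump)

    def test_kd_discrepancy_ratio(self):
        # printed-value check: 35.5/4.7 is "approximately an order of magnitude"
        assert kd_from_rates(31.0, 1100.0) / 4.7 == pytest.approx(7.55, abs=0.05)

    def test_end_to_end_recovery_over_repeated_simulations(self):
        """Mean recovered k_on/k_off/slow rate across seeded repetitions."""
        kons, koffs, slows = [], [], []
        for seed in range(1, 21):
            sc = KineticScenario(seed=seed)
            _, fits = run_titration(sc)
            s = summarize_enzyme(fits, sc.binding, kd_itc=4.7)
            kons.append(s.k_on)
            koffs.append(s.k_off)
            slows.append(s.slow_mean)
        assert np.mean(kons) == pytest.approx(31.0, rel=0.15)
        assert np.mean(koffs) == pytest.approx(1100.0, rel=0.20)
        assert np.mean(slows) == pytest.approx(400.0, rel=0.10)
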