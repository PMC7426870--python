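"""Profile confidence intervals and the F-based chi2_N threshold."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import betainc

from blifit import GlobalKineticsFit
from blifit.confidence import (
    ProfileScan,
    ci_from_profile,
    confidence_threshold,
    normalized_chisq,
    profile_parameter,
)
from blifit.exceptions import (
    DomainError,
    InconsistentProfileError,
    PerfectFitError,
)
from blifit.simulate import simulate_dataset

from conftest import make_small_design


class TestNormalizedChisq:
    def test_ratio_basics(self):
        assert normalized_chisq(1.0, 1.0) == 1.0
        assert normalized_chisq(2.0, 1.0) == 2.0

    def test_residual_rescaling_cancels(self):
        # multiplying all residuals by c scales both SSEs by c^2
        r = np.array([0.3, -1.2, 0.5])
        r_opt = np.array([0.1, -0.2, 0.05])
        for c in (0.1, 3.0, 250.0):
            assert normalized_chisq(
                float((c * r) @ (c * r)), float((c * r_opt) @ (c * r_opt))
            ) == pytest.approx(normalized_chisq(float(r @ r), float(r_opt @ r_opt)),
                               rel=1e-12)

    def test_perfect_fit_raises(self):
        with pytest.raises(PerfectFitError, match="noiseless"):
            normalized_chisq(1.0, 0.0)


def _f_quantile_oracle(alpha, d1, d2):
    """Upper-alpha F quantile by numeric inversion of the regularized
    incomplete-beta CDF (independent of scipy.stats.f.ppf)."""

    def cdf(x):
        return betainc(d1 / 2, d2 / 2, d1 * x / (d1 * x + d2))

    return brentq(lambda x: cdf(x) - (1 - alpha), 1e-9, 1e6, xtol=1e-12)


class TestThreshold:
    def test_printed_calibration(self):
        spec = confidence_threshold(35, 2800, 0.05)
        assert spec.f_quantile == pytest.approx(1.43, abs=5e-3)
        assert spec.chi2n_threshold == pytest.approx(1.018, abs=5e-4)

    def test_small_design_example(self):
        spec = confidence_threshold(2, 10, 0.05)
        # F_0.05(2, 10) ~ 4.10; threshold 1 + 0.2 * F
        assert spec.f_quantile == pytest.approx(4.10, abs=5e-3)
        assert spec.chi2n_threshold == pytest.approx(1.821, abs=2e-3)

    def test_threshold_tends_to_one_for_huge_datasets(self):
        assert confidence_threshold(35, 10**8, 0.05).chi2n_threshold < 1.001

    def test_agrees_with_independent_f_quantile_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 60))
            df = int(rng.integers(n + 10, 5000))
            alpha = float(rng.uniform(0.005, 0.2))
            spec = confidence_threshold(n, df, alpha)
            assert spec.f_quantile == pytest.approx(
                _f_quantile_oracle(alpha, n, df), rel=1e-6
            )

    @pytest.mark.parametrize("n,df,alpha", [(0, 10, 0.05), (10, 10, 0.05),
                                            (5, 100, 0.0), (5, 100, 1.0)])
    def test_invalid_inputs_rejected(self, n, df, alpha):
        with pytest.raises(DomainError):
            confidence_threshold(n, df, alpha)


def _quadratic_scan(n_grid=41):
    grid = np.geomspace(0.25, 4.0, n_grid)
    chi = 1.0 + (grid - 1.0) ** 2
    return ProfileScan(
        parameter_name="k_on",
        fixed_values=grid,
        chi2n_values=chi,
        best_value=1.0,
        sse_opt=1.0,
        evaluate=lambda v: 1.0 + (v - 1.0) ** 2,
    )


class TestCIFromProfile:
    def test_quadratic_profile_closed_form_endpoints(self):
        thr = confidence_threshold(35, 2800, 0.05)  # 1.018
        ci = ci_from_profile(_quadratic_scan(), thr)
        root = np.sqrt(thr.chi2n_threshold - 1.0)  # ~0.1342
        assert ci.lower == pytest.approx(1.0 - root, rel=3e-3)
        assert ci.upper == pytest.approx(1.0 + root, rel=3e-3)
        assert ci.half_width == pytest.approx(root, rel=3e-2)
        assert not (ci.censored_low or ci.censored_high)

    def test_flat_profile_censors_both_sides(self):
        grid = np.geomspace(0.25, 4.0, 21)
        scan = ProfileScan("k_off", grid, np.ones_like(grid), 1.0, 1.0)
        ci = ci_from_profile(scan, confidence_threshold(35, 2800, 0.05))
        assert ci.lower == pytest.approx(0.25) and ci.upper == pytest.approx(4.0)
        assert ci.censored_low and ci.censored_high

    def test_all_above_threshold_is_inconsistent(self):
        grid = np.geomspace(0.25, 4.0, 9)
        scan = ProfileScan("k_on", grid, np.full_like(grid, 5.0), 1.0, 1.0)
        with pytest.raises(InconsistentProfileError):
            ci_from_profile(scan, confidence_threshold(35, 2800, 0.05))

    def test_interval_contains_best_value(self, small_dataset, small_fit):
        ci = small_fit.confidence_intervals(parameters=("k_on",), n_grid=11)["k_on"]
        assert ci.lower <= ci.best_value <= ci.upper
        assert ci.half_width >= 0
        assert ci.half_width == max(ci.best_value - ci.lower, ci.upper - ci.best_value)

    def test_table_style_rendering(self):
        from blifit.io import format_estimate

        assert format_estimate(0.2639, 0.0184) == "0.26 ± 0.02"


class TestProfileScanOnData:
    def test_chi2n_at_center_reproduces_optimum(self, small_dataset, small_fit):
        scan = profile_parameter(small_dataset, small_fit.result_, "k_on", n_grid=9)
        center = np.argmin(np.abs(scan.fixed_values - scan.best_value))
        assert scan.chi2n_values[center] == pytest.approx(1.0, abs=1e-6)
        # refits can never beat the optimum beyond numerical noise
        assert np.all(scan.chi2n_values >= 1.0 - 1e-6)

    def test_profile_monotone_away_from_optimum_low_noise(self, lam8):
        ds = simulate_dataset(lam8, make_small_design(seed=6, noise_sigma=1e-5))
        fit = GlobalKineticsFit().fit(ds)
        scan = profile_parameter(ds, fit.result_, "k_off", n_grid=9)
        center = int(np.argmin(np.abs(scan.fixed_values - scan.best_value)))
        left = scan.chi2n_values[: center + 1]
        right = scan.chi2n_values[center:]
        assert np.all(np.diff(left) <= 1e-9)  # decreasing toward center
        assert np.all(np.diff(right) >= -1e-9)

    def test_kd_reparameterization_consistent_with_koff(self, small_dataset, small_fit):
        """Fixing K_D at k_off_best/k_on_best must reproduce the optimum SSE
        (same (k_on, k_off) point reachable in both parameterizations)."""
        scan = profile_parameter(small_dataset, small_fit.result_, "K_D", n_grid=9)
        center = np.argmin(np.abs(scan.fixed_values - scan.best_value))
        assert scan.chi2n_values[center] == pytest.approx(1.0, abs=1e-6)

    def test_half_width_shrinks_with_noise(self, lam8):
        widths = []
        for sigma in (0.02, 0.01, 0.005):
            ds = simulate_dataset(lam8, make_small_design(seed=17, noise_sigma=sigma))
            est = GlobalKineticsFit().fit(ds)
            ci = est.confidence_intervals(parameters=("k_on",), n_grid=11)["k_on"]
            widths.append(ci.half_width)
        assert widths[0] > widths[1] > widths[2]
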