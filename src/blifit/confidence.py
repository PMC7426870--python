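"""Profile-likelihood confidence intervals via an F-statistic threshold.

A single rate parameter (k_on, k_off, or K_D) is fixed on a log-spaced grid
spanning a 4-fold range below and above its best-fit value; all remaining
parameters are refit at each grid point, warm-started from the global
optimum (and from the neighbouring grid point's solution when that start
has lower SSE).  The normalized chi-squared

    chi2_N(p) = chi2(p) / chi2(p_opt) = SSE(p) / SSE(p_opt)

is compared with the threshold

    chi2_N_threshold = 1 + (n / DF) * F_alpha(n, DF)

where n is the number of free parameters of the full fit and DF the total
number of data points.  The reported half-width is the maximum accepted
deviation from the best-fit value, so the interval is an upper bound on
the 95% confidence interval.  Any constant scaling of the assumed data
uncertainty sigma_data cancels in the chi2_N ratio.

When profiling K_D the model is reparameterized to (k_on, K_D, k_leak)
with k_off := k_on * K_D so that K_D can be held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import BLIDataset
from .exceptions import (
    DomainError,
    InconsistentProfileError,
    PerfectFitError,
    StructuralError,
)
from .fitting import (
    FitOptions,
    GlobalFitResult,
    ParameterVector,
    default_bounds,
    fit_global,
    sse as compute_sse,
)
from .model import KineticParameters

__all__ = [
    "ThresholdSpec",
    "ProfileScan",
    "ConfidenceInterval",
    "normalized_chisq",
    "confidence_threshold",
    "profile_parameter",
    "ci_from_profile",
    "confidence_interval",
    "value_in_confidence_region",
]

PROFILE_PARAMETERS = ("k_on", "k_off", "K_D")
FOLD_RANGE = 4.0
_BISECT_RTOL = 1e-3
# SSE per data point below which a fit is treated as noiseless: the
# chi2_N ratio is then dominated by optimizer termination noise and the
# data identify the parameters exactly
NOISELESS_SSE_PER_POINT = 1e-12


@dataclass(frozen=True)
class ThresholdSpec:
    """Normalized chi-squared cutoff for the (1 - alpha) confidence region."""

    n_params: int
    n_data: int
    alpha: float
    f_quantile: float
    chi2n_threshold: float


@dataclass
class ProfileScan:
    """Fixed-parameter refit grid for one profiled parameter.

    ``evaluate`` (optional) maps a fixed parameter value to its refit
    chi2_N; when present it enables bisection refinement of the CI
    endpoints beyond the grid resolution.
    """

    parameter_name: str
    fixed_values: np.ndarray
    chi2n_values: np.ndarray
    best_value: float
    sse_opt: float = np.nan
    evaluate: object = field(default=None, repr=False)


@dataclass
class ConfidenceInterval:
    parameter_name: str
    best_value: float
    lower: float
    upper: float
    half_width: float
    censored_low: bool = False
    censored_high: bool = False

    def __str__(self) -> str:  # "best +/- half_width", Table-style
        return f"{self.parameter_name} = {self.best_value:.3g} ± {self.half_width:.2g}"


def normalized_chisq(sse_p: float, sse_opt: float) -> float:
    """chi2_N = SSE(p) / SSE(p_opt); sigma_data cancels in the ratio."""
    if sse_opt <= 0:
        raise PerfectFitError(
            "SSE at the optimum is zero (noiseless data): the normalized "
            "chi-squared is undefined; use noiseless round-trip checks "
            "instead of profile confidence intervals"
        )
    return sse_p / sse_opt


def confidence_threshold(
    n_params: int, n_data: int, alpha: float = 0.05
) -> ThresholdSpec:
    """F-based chi2_N cutoff: 1 + (n/DF) * F_alpha(n, DF).

    The F quantile is the upper-``alpha`` quantile with numerator degrees
    of freedom ``n_params`` and denominator degrees of freedom ``n_data``
    (the total data-point count).
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha!r}")
    if not 0 < n_params < n_data:
        raise DomainError(
            f"need 0 < n_params < n_data, got n_params={n_params}, n_data={n_data}"
        )
    f_q = float(stats.f.ppf(1.0 - alpha, n_params, n_data))
    return ThresholdSpec(
        n_params=n_params,
        n_data=n_data,
        alpha=alpha,
        f_quantile=f_q,
        chi2n_threshold=1.0 + (n_params / n_data) * f_q,
    )


def _shared_index(name: str) -> int:
    return {"k_on": 0, "k_off": 1, "K_D": 1}[name]


def _profile_refitter(dataset: BLIDataset, fit: GlobalFitResult, name: str):
    """Return f(fixed_value, starts) -> (sse, solution ParameterVector).

    For k_on / k_off the packed entry is simply held fixed.  For K_D the
    packed k_off entry is tied to k_on via k_off = k_on * K_D by refitting
    in the reparameterized space.
    """
    opts = fit.options
    bounds = default_bounds(dataset, opts)

    if name in ("k_on", "k_off"):
        idx = _shared_index(name)

        def refit(value: float, starts):
            best = None
            for start in starts:
                r = fit_global(
                    dataset, start=start, opts=opts, bounds=bounds,
                    fixed={idx: value},
                )
                if best is None or r.sse_opt < best.sse_opt:
                    best = r
            return best.sse_opt, best.params_opt

        return refit

    if name != "K_D":
        raise StructuralError(
            f"parameter_name must be one of {PROFILE_PARAMETERS}, got {name!r}"
        )

    # K_D fixed: substitute k_off = k_on * K_D and optimize (k_on, k_leak,
    # nuisances).  Reuse fit_global's machinery through a thin dataset-level
    # objective by wrapping the parameter array.
    from scipy.optimize import least_squares

    from .fitting import residuals as compute_residuals

    lo, hi = bounds

    def refit(kd_value: float, starts):
        # free vector: [k_on, k_leak, nuisances...]
        keep = np.r_[0, np.arange(2, lo.size)]

        def expand(x):
            full = np.empty(lo.size)
            full[0] = x[0]
            full[1] = x[0] * kd_value
            full[2:] = x[1:]
            return full

        def fun(x):
            return compute_residuals(
                dataset, ParameterVector.from_array(expand(x))
            )

        best = None
        for start in starts:
            x0 = np.clip(start.to_array()[keep], lo[keep], hi[keep])
            res = least_squares(
                fun,
                x0,
                bounds=(lo[keep], hi[keep]),
                method="trf",
                ftol=opts.tolerance,
                xtol=opts.tolerance,
                gtol=max(opts.tolerance, 1e-14),
                max_nfev=opts.max_iterations,
                x_scale="jac",
            )
            if best is None or 2 * res.cost < best[0]:
                best = (float(2 * res.cost), ParameterVector.from_array(expand(res.x)))
        return best

    return refit


def _best_of(name: str, kin: KineticParameters) -> float:
    if name == "k_on":
        return kin.k_on
    if name == "k_off":
        return kin.k_off
    if name == "K_D":
        return kin.kd
    raise StructuralError(
        f"parameter_name must be one of {PROFILE_PARAMETERS}, got {name!r}"
    )


def profile_parameter(
    dataset: BLIDataset,
    fit: GlobalFitResult,
    parameter_name: str,
    n_grid: int = 41,
) -> ProfileScan:
    """Scan chi2_N over a log-spaced 4-fold range around the best-fit value.

    At each grid value the named parameter is fixed and all remaining
    parameters are refit, warm-started from the global optimum and from
    the neighbouring grid point's solution (whichever start is better).
    """
    if n_grid < 5:
        raise StructuralError(f"n_grid must be >= 5, got {n_grid}")
    if fit.sse_opt <= NOISELESS_SSE_PER_POINT * fit.n_data:
        raise PerfectFitError(
            "optimum SSE is at the noiseless floor: chi2_N is dominated by "
            "round-off; the confidence interval degenerates to the best-fit "
            "value (use confidence_interval(), which applies this shortcut)"
        )
    best = _best_of(parameter_name, fit.params_opt.kin)
    if best <= 0:
        raise DomainError(
            f"cannot profile {parameter_name}: best-fit value {best!r} is not > 0"
        )
    refit = _profile_refitter(dataset, fit, parameter_name)
    sse_opt = fit.sse_opt

    grid = np.geomspace(best / FOLD_RANGE, best * FOLD_RANGE, n_grid)
    chi2n = np.empty(n_grid)
    center = n_grid // 2  # symmetric log grid: grid[center] == best

    def evaluate(value: float, neighbor=None) -> float:
        starts = [fit.params_opt]
        if neighbor is not None:
            if compute_sse(dataset, neighbor) < compute_sse(dataset, fit.params_opt):
                starts = [neighbor]
        s, sol = refit(value, starts)
        return normalized_chisq(s, sse_opt), sol

    # walk outward from the center on each side, carrying the neighbour
    # solution as an alternative warm start
    chi2n[center], _ = evaluate(grid[center])
    for indices in (range(center - 1, -1, -1), range(center + 1, n_grid)):
        prev_sol = None
        for i in indices:
            chi2n[i], prev_sol = evaluate(grid[i], prev_sol)

    return ProfileScan(
        parameter_name=parameter_name,
        fixed_values=grid,
        chi2n_values=chi2n,
        best_value=best,
        sse_opt=sse_opt,
        evaluate=lambda v: evaluate(v)[0],
    )


def _refine(evaluate, accepted: float, rejected: float, thr: float) -> float:
    """Log-scale bisection of the threshold crossing between an accepted and
    a rejected fixed value, to ~1e-3 relative precision."""
    lo, hi = accepted, rejected
    while abs(hi - lo) > _BISECT_RTOL * min(abs(lo), abs(hi)):
        mid = float(np.sqrt(lo * hi))
        if evaluate(mid) < thr:
            lo = mid
        else:
            hi = mid
    return lo


def ci_from_profile(scan: ProfileScan, threshold: ThresholdSpec) -> ConfidenceInterval:
    """Interval of accepted fixed values: on each side of the best-fit value
    the outermost grid value with chi2_N below the threshold, bisection-
    refined when the scan carries an evaluator; censored flags mark sides
    where the whole 4-fold half-range stays below the threshold."""
    thr = threshold.chi2n_threshold
    grid = np.asarray(scan.fixed_values, float)
    chi = np.asarray(scan.chi2n_values, float)
    below = chi < thr
    if not below.any():
        raise InconsistentProfileError(
            f"profile of {scan.parameter_name} lies entirely above the "
            f"threshold {thr:.4g}: the optimum was not reproduced"
        )
    best = scan.best_value
    center = int(np.argmin(np.abs(np.log(grid / best))))

    def endpoint(side: str):
        if side == "low":
            idx = np.nonzero(below[: center + 1])[0]
            if idx.size == 0:
                raise InconsistentProfileError(
                    f"profile of {scan.parameter_name}: no accepted value at "
                    "or below the optimum (optimum not reproduced)"
                )
            outer = idx[0]
            censored = outer == 0
            bracket = outer - 1
        else:
            idx = center + np.nonzero(below[center:])[0]
            if idx.size == 0:
                raise InconsistentProfileError(
                    f"profile of {scan.parameter_name}: no accepted value at "
                    "or above the optimum (optimum not reproduced)"
                )
            outer = idx[-1]
            censored = outer == grid.size - 1
            bracket = outer + 1
        value = float(grid[outer])
        if not censored:
            if scan.evaluate is not None:
                value = _refine(scan.evaluate, value, float(grid[bracket]), thr)
            else:  # log-linear interpolation of the crossing
                g0, g1 = grid[outer], grid[bracket]
                c0, c1 = chi[outer], chi[bracket]
                frac = (thr - c0) / (c1 - c0) if c1 != c0 else 0.0
                value = float(np.exp(np.log(g0) + frac * (np.log(g1) - np.log(g0))))
        return value, bool(censored)

    lower, cen_lo = endpoint("low")
    upper, cen_hi = endpoint("high")
    half = max(best - lower, upper - best)
    return ConfidenceInterval(
        parameter_name=scan.parameter_name,
        best_value=best,
        lower=lower,
        upper=upper,
        half_width=half,
        censored_low=cen_lo,
        censored_high=cen_hi,
    )


def confidence_interval(
    dataset: BLIDataset,
    fit: GlobalFitResult,
    parameter_name: str,
    alpha: float = 0.05,
    n_grid: int = 41,
) -> ConfidenceInterval:
    """Profile + threshold + endpoint extraction in one call.

    Noiseless data (SSE at the per-point floor) identify the parameters
    exactly; the interval then degenerates to the best-fit value instead
    of profiling a round-off-dominated chi2_N surface.
    """
    if fit.sse_opt <= NOISELESS_SSE_PER_POINT * fit.n_data:
        best = _best_of(parameter_name, fit.params_opt.kin)
        return ConfidenceInterval(
            parameter_name=parameter_name,
            best_value=best,
            lower=best,
            upper=best,
            half_width=0.0,
        )
    scan = profile_parameter(dataset, fit, parameter_name, n_grid=n_grid)
    thr = confidence_threshold(fit.n_params, fit.n_data, alpha=alpha)
    return ci_from_profile(scan, thr)


def value_in_confidence_region(
    dataset: BLIDataset,
    fit: GlobalFitResult,
    parameter_name: str,
    value: float,
    alpha: float = 0.05,
) -> bool:
    """Whether ``value`` lies in the profile confidence interval.

    Equivalent to membership in the scan-based interval for any value
    inside the 4-fold range (the interval is delimited by the outermost
    accepted values), but needs a single profiled refit.
    """
    best = _best_of(parameter_name, fit.params_opt.kin)
    if fit.sse_opt <= NOISELESS_SSE_PER_POINT * fit.n_data:
        return bool(np.isclose(value, best, rtol=1e-6))
    if not best / FOLD_RANGE <= value <= best * FOLD_RANGE:
        return False
    refit = _profile_refitter(dataset, fit, parameter_name)
    s, _ = refit(value, [fit.params_opt])
    thr = confidence_threshold(fit.n_params, fit.n_data, alpha=alpha)
    return normalized_chisq(s, fit.sse_opt) < thr.chi2n_threshold
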