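"""Global nonlinear least-squares fit of a sensorgram series.

All curves of a dilution series are fit simultaneously: the kinetic rates
(k_on, k_off, k_leak) are shared, while each curve carries its own
amplitude/baseline nuisances (a_on, b_on, a_off, b_off), so a fit over n
curves has 4n + 3 free parameters.  The optimizer is a bounded
trust-region-reflective least-squares method (monotone in the cost),
deterministic for a given (dataset, start, options).

Residual ordering (fixed so the SSE is bit-reproducible): curves in dataset
order, association before dissociation, time ascending within a phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dataset import BLIDataset
from .exceptions import (
    DegenerateDesignError,
    DomainError,
    FitDivergenceError,
    StructuralError,
)
from .model import CurveNuisance, KineticParameters, eval_binding, eval_unbinding

__all__ = [
    "ParameterVector",
    "FitOptions",
    "GlobalFitResult",
    "residuals",
    "sse",
    "initial_guess",
    "fit_global",
    "default_bounds",
]

N_SHARED = 3  # k_on, k_off, k_leak
N_PER_CURVE = 4  # a_on, b_on, a_off, b_off


@dataclass
class ParameterVector:
    """Shared kinetics plus one nuisance block per curve (4n + 3 values)."""

    kin: KineticParameters
    nuisances: list

    @property
    def n_params(self) -> int:
        return N_SHARED + N_PER_CURVE * len(self.nuisances)

    def to_array(self) -> np.ndarray:
        out = [self.kin.k_on, self.kin.k_off, self.kin.k_leak]
        for nui in self.nuisances:
            out.extend([nui.a_on, nui.b_on, nui.a_off, nui.b_off])
        return np.array(out)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        if (x.size - N_SHARED) % N_PER_CURVE != 0:
            raise StructuralError(f"parameter vector length {x.size} != 4n+3")
        kin = KineticParameters(k_on=x[0], k_off=x[1], k_leak=x[2])
        nuis = [
            CurveNuisance(a_on=x[i], b_on=x[i + 1], a_off=x[i + 2], b_off=x[i + 3])
            for i in range(N_SHARED, x.size, N_PER_CURVE)
        ]
        return cls(kin=kin, nuisances=nuis)


@dataclass
class FitOptions:
    """Optimizer settings.

    ``sigma_data`` is the assumed measurement uncertainty (signal units); it
    is used only when reporting a chi-squared and cancels in the normalized
    chi-squared ratio, so it does not affect point estimates or confidence
    intervals.
    """

    rate_bounds: tuple = (0.0, 1e3)
    amplitude_factor: float = 10.0  # upper amplitude bound = factor * max|signal|
    baseline_factor: float = 10.0
    tolerance: float = 1e-10  # relative SSE convergence threshold
    max_iterations: int = 5000
    sigma_data: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise DomainError(f"tolerance must be > 0, got {self.tolerance!r}")
        if self.rate_bounds[0] > self.rate_bounds[1]:
            raise DomainError("rate_bounds lower > upper")


@dataclass
class GlobalFitResult:
    """Outcome of :func:`fit_global`."""

    params_opt: ParameterVector
    sse_opt: float
    residuals: np.ndarray
    n_data: int
    n_params: int
    converged: bool
    n_iterations: int
    message: str = ""
    options: FitOptions = field(default_factory=FitOptions)

    def chi2(self, sigma_data: float | None = None) -> float:
        """SSE / sigma_data^2 (sigma defaults to options.sigma_data, else 1)."""
        sigma = sigma_data if sigma_data is not None else self.options.sigma_data
        if sigma is None:
            sigma = 1.0
        return self.sse_opt / sigma**2


def _check_consistency(dataset: BLIDataset, params: ParameterVector) -> None:
    if len(params.nuisances) != dataset.n_curves:
        raise StructuralError(
            f"{len(params.nuisances)} nuisance blocks for {dataset.n_curves} curves"
        )


def residuals(dataset: BLIDataset, params: ParameterVector) -> np.ndarray:
    """Concatenated (data - model) in the documented fixed order."""
    _check_consistency(dataset, params)
    parts = []
    for curve, nui in zip(dataset.curves, params.nuisances):
        parts.append(
            curve.assoc_y
            - eval_binding(curve.assoc_t, curve.concentration, params.kin, nui)
        )
        parts.append(curve.dissoc_y - eval_unbinding(curve.dissoc_t, params.kin, nui))
    return np.concatenate(parts)


def sse(dataset: BLIDataset, params: ParameterVector) -> float:
    """Sum of squared residuals (squared Euclidean norm of residuals())."""
    r = residuals(dataset, params)
    return float(r @ r)


def default_bounds(dataset: BLIDataset, opts: FitOptions | None = None):
    """(lower, upper) arrays for the packed 4n+3 parameter vector.

    Rates in ``opts.rate_bounds``; amplitudes in [0, factor*max|signal|];
    baselines in +/- factor*max|signal|.
    """
    opts = opts or FitOptions()
    scale = max(dataset.max_abs_signal, 1e-30)
    a_hi = opts.amplitude_factor * scale
    b_hi = opts.baseline_factor * scale
    lo = [opts.rate_bounds[0]] * N_SHARED
    hi = [opts.rate_bounds[1]] * N_SHARED
    for _ in range(dataset.n_curves):
        lo.extend([0.0, -b_hi, 0.0, -b_hi])
        hi.extend([a_hi, b_hi, a_hi, b_hi])
    return np.array(lo), np.array(hi)


def _single_exp_rate(t: np.ndarray, y: np.ndarray):
    """Provisional observed rate for one association trace.

    For each candidate rate k the model a*(1-exp(-k t)) + b is linear in
    (a, b); scan a log grid of k and keep the least-squares best.
    Returns (k, a, b).
    """
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    k_grid = np.geomspace(0.05 / span, 200.0 / span, 80)
    best = (k_grid[0], 0.0, float(y[0]), np.inf)
    ones = np.ones_like(t)
    for k in k_grid:
        rise = -np.expm1(-k * t)
        A = np.column_stack([rise, ones])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        err = float(np.sum((A @ coef - y) ** 2))
        if err < best[3]:
            best = (float(k), float(coef[0]), float(coef[1]), err)
    return best[0], best[1], best[2]


def _leak_guess(dataset: BLIDataset) -> float:
    """Terminal-slope leak estimate from a zero-concentration curve.

    The control's association signal is b_on*exp(-k_leak*t); use the
    log-linear slope when the trace is positive and clearly decaying,
    otherwise fall back to 1e-4 s^-1.
    """
    fallback = 1e-4
    for curve in dataset.curves:
        if curve.concentration == 0:
            y = curve.assoc_y
            if np.all(y > 0) and y[0] > 10 * np.std(np.diff(y)):
                slope = np.polyfit(curve.assoc_t, np.log(y), 1)[0]
                if -slope > 0:
                    return float(min(-slope, 1.0))
            return fallback
    return fallback


def initial_guess(
    dataset: BLIDataset, opts: FitOptions | None = None
) -> ParameterVector:
    """Data-driven starting point for the global fit.

    Per curve: a single-exponential fit of the association phase gives a
    provisional observed rate; regressing observed rate on concentration
    gives slope -> k_on and intercept -> k_off (floored at small positive
    values).  k_leak comes from the zero-concentration control's terminal
    slope when present.  Baselines come from phase endpoints, amplitudes
    from phase signal spans; everything is clipped into the default bounds.
    """
    opts = opts or FitOptions()
    if dataset.n_curves < 2:
        raise DegenerateDesignError("global fit needs >= 2 curves")
    concs = dataset.concentrations
    if np.unique(concs).size < 2 or np.all(concs == 0):
        raise DegenerateDesignError(
            "concentration series is degenerate: need >= 2 distinct "
            "concentrations with at least one nonzero"
        )

    k_obs = []
    nuisances = []
    for curve in dataset.curves:
        k, a, b = _single_exp_rate(curve.assoc_t, curve.assoc_y)
        k_obs.append(k)
        a_on = max(a, 0.0)
        b_on = float(curve.assoc_y[0])
        b_off = float(curve.dissoc_y[-1])
        a_off = max(float(curve.dissoc_y[0]) - b_off, 0.0)
        nuisances.append(CurveNuisance(a_on=a_on, b_on=b_on, a_off=a_off, b_off=b_off))

    # weight by association amplitude: near-zero-amplitude curves (the
    # control) carry no rate information
    amps = np.array([n.a_on for n in nuisances])
    w = amps / max(amps.max(), 1e-30) + 1e-3
    slope, intercept = np.polyfit(concs, np.array(k_obs), 1, w=w)
    kin = KineticParameters(
        k_on=max(float(slope), 1e-6),
        k_off=max(float(intercept), 1e-6),
        k_leak=_leak_guess(dataset),
    )
    guess = ParameterVector(kin=kin, nuisances=nuisances)
    lo, hi = default_bounds(dataset, opts)
    return ParameterVector.from_array(np.clip(guess.to_array(), lo, hi))


def fit_global(
    dataset: BLIDataset,
    start: ParameterVector | None = None,
    opts: FitOptions | None = None,
    bounds: tuple | None = None,
    fixed: dict | None = None,
) -> GlobalFitResult:
    """Bounded global least-squares fit with shared rates.

    Parameters
    ----------
    dataset
        The concentration series to fit (>= 2 curves).
    start
        Starting :class:`ParameterVector`; defaults to :func:`initial_guess`.
    opts
        :class:`FitOptions`; the ``tolerance`` is the relative SSE change
        at which the optimizer declares convergence.
    bounds
        Optional (lower, upper) arrays overriding :func:`default_bounds`.
    fixed
        Optional mapping of packed-index -> value to hold individual
        entries of the parameter vector fixed (used by profiling).

    Returns
    -------
    GlobalFitResult
        With ``converged=False`` (not an exception) when the iteration
        budget runs out.
    """
    opts = opts or FitOptions()
    if dataset.n_curves < 2:
        raise DegenerateDesignError("global fit needs >= 2 curves")
    if start is None:
        start = initial_guess(dataset, opts)
    _check_consistency(dataset, start)

    lo, hi = bounds if bounds is not None else default_bounds(dataset, opts)
    x0_full = start.to_array()
    fixed = fixed or {}
    free_idx = np.array(
        [i for i in range(x0_full.size) if i not in fixed], dtype=int
    )
    if free_idx.size < 1:
        raise StructuralError("no free parameters left to optimize")

    template = x0_full.copy()
    for i, v in fixed.items():
        template[i] = v

    def expand(x_free: np.ndarray) -> np.ndarray:
        full = template.copy()
        full[free_idx] = x_free
        return full

    def fun(x_free: np.ndarray) -> np.ndarray:
        r = residuals(dataset, ParameterVector.from_array(expand(x_free)))
        if not np.all(np.isfinite(r)):
            raise FitDivergenceError(
                f"non-finite model values at parameters {expand(x_free)!r}"
            )
        return r

    x0 = np.clip(x0_full[free_idx], lo[free_idx], hi[free_idx])
    tol = opts.tolerance
    res = least_squares(
        fun,
        x0,
        bounds=(lo[free_idx], hi[free_idx]),
        method="trf",
        ftol=tol,
        xtol=tol,
        gtol=max(tol, 1e-14),
        max_nfev=opts.max_iterations,
        x_scale="jac",
    )
    params_opt = ParameterVector.from_array(expand(res.x))
    return GlobalFitResult(
        params_opt=params_opt,
        sse_opt=float(2 * res.cost),
        residuals=res.fun.copy(),
        n_data=dataset.n_data,
        n_params=N_SHARED + N_PER_CURVE * dataset.n_curves,
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
        message=str(res.message),
        options=opts,
    )
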