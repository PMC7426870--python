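"""scikit-learn-style estimator wrapping the global kinetic fit.

`GlobalKineticsFit` follows the sklearn estimator contract (``get_params``
/ ``set_params``, ``fit``/``predict``/``score``, fitted attributes with a
trailing underscore) so it composes with sklearn tooling; the numerical
work is done by :mod:`blifit.fitting` and :mod:`blifit.confidence`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .confidence import confidence_interval, confidence_threshold
from .dataset import BLIDataset
from .exceptions import StructuralError
from .fitting import FitOptions, fit_global, initial_guess
from .io import FitRecord, ParameterEstimate
from .model import eval_binding, eval_unbinding

__all__ = ["GlobalKineticsFit"]


def _as_dataset(X) -> BLIDataset:
    if isinstance(X, BLIDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return BLIDataset.from_frame(X)
    raise StructuralError(
        "X must be a BLIDataset or a canonical long-format DataFrame "
        "(curve_id, phase, time_s, signal, concentration_uM)"
    )


class GlobalKineticsFit(BaseEstimator):
    """Global 1:1 binding-kinetics fit over a sensorgram dilution series.

    Kinetic rates (k_on, k_off, k_leak) are shared across curves;
    per-curve amplitudes and baselines are nuisance parameters, giving
    4n + 3 free parameters for n curves.

    Parameters
    ----------
    tolerance : float, default 1e-10
        Relative SSE change at which the optimizer declares convergence.
    max_iterations : int, default 5000
        Optimizer evaluation budget.
    rate_bounds : tuple, default (0, 1e3)
        Box bounds for all three rates in their natural units.
    amplitude_factor, baseline_factor : float, default 10
        Amplitude/baseline bounds as multiples of the largest |signal|.
    sigma_data : float or None
        Assumed measurement uncertainty, used only for chi-squared
        reporting; cancels in normalized chi-squared.

    Attributes
    ----------
    k_on_, k_off_, k_leak_, kd_ : float
        Best-fit shared rates and derived K_D (uM).
    nuisances_ : list of CurveNuisance
        Per-curve amplitudes/baselines, in curve order.
    sse_ : float
        Sum of squared residuals at the optimum.
    n_params_, n_data_ : int
        Free-parameter count (4n+3) and total data points (DF).
    converged_ : bool
    result_ : GlobalFitResult
        Full fit result (residuals, diagnostics, options).

    Examples
    --------
    >>> from blifit.simulate import optonb_scenarios, simulate_dataset, SimulationDesign
    >>> scn = optonb_scenarios()["LaM8"]
    >>> data = simulate_dataset(scn.kinetics, SimulationDesign(seed=7))
    >>> est = GlobalKineticsFit().fit(data)
    >>> round(est.kd_, 2)
    0.26
    """

    def __init__(
        self,
        tolerance: float = 1e-10,
        max_iterations: int = 5000,
        rate_bounds: tuple = (0.0, 1e3),
        amplitude_factor: float = 10.0,
        baseline_factor: float = 10.0,
        sigma_data: float | None = None,
    ):
        self.tolerance = tolerance
        self.max_iterations = max_iterations
        self.rate_bounds = rate_bounds
        self.amplitude_factor = amplitude_factor
        self.baseline_factor = baseline_factor
        self.sigma_data = sigma_data

    def _options(self) -> FitOptions:
        return FitOptions(
            rate_bounds=tuple(self.rate_bounds),
            amplitude_factor=self.amplitude_factor,
            baseline_factor=self.baseline_factor,
            tolerance=self.tolerance,
            max_iterations=self.max_iterations,
            sigma_data=self.sigma_data,
        )

    def fit(self, X, y=None, start=None):
        """Fit the global model.

        X is a :class:`BLIDataset` or a canonical long-format DataFrame;
        ``y`` is ignored (signals live in X). ``start`` optionally
        overrides the data-driven initial guess.
        """
        dataset = _as_dataset(X)
        opts = self._options()
        if start is None:
            start = initial_guess(dataset, opts)
        result = fit_global(dataset, start=start, opts=opts)
        kin = result.params_opt.kin
        self.dataset_ = dataset
        self.result_ = result
        self.k_on_ = kin.k_on
        self.k_off_ = kin.k_off
        self.k_leak_ = kin.k_leak
        self.kd_ = kin.kd
        self.nuisances_ = list(result.params_opt.nuisances)
        self.sse_ = result.sse_opt
        self.n_params_ = result.n_params
        self.n_data_ = result.n_data
        self.converged_ = result.converged
        return self

    def predict(self, X) -> np.ndarray:
        """Model signal for each row of a canonical long-format table
        (or each point of a BLIDataset, in residual order)."""
        check_is_fitted(self, "result_")
        df = X.to_frame() if isinstance(X, BLIDataset) else X
        by_curve = {
            c.curve_id: nui
            for c, nui in zip(self.dataset_.curves, self.nuisances_)
        }
        kin = self.result_.params_opt.kin
        out = np.empty(len(df))
        for i, (_, row) in enumerate(df.iterrows()):
            nui = by_curve.get(str(row["curve_id"]))
            if nui is None:
                raise StructuralError(f"unknown curve_id {row['curve_id']!r}")
            t = float(row["time_s"])
            if row["phase"] == "association":
                out[i] = eval_binding(t, float(row["concentration_uM"]), kin, nui)
            else:
                out[i] = eval_unbinding(t, kin, nui)
        return out

    def score(self, X, y=None) -> float:
        """Coefficient of determination R^2 of the model signal."""
        check_is_fitted(self, "result_")
        df = X.to_frame() if isinstance(X, BLIDataset) else X
        y_true = df["signal"].to_numpy(float)
        y_pred = self.predict(df)
        ss_res = float(np.sum((y_true - y_pred) ** 2))
        ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    def confidence_intervals(
        self,
        parameters=("k_on", "k_off", "K_D"),
        alpha: float = 0.05,
        n_grid: int = 41,
    ) -> dict:
        """Profile 95% CIs for the requested shared parameters."""
        check_is_fitted(self, "result_")
        return {
            name: confidence_interval(
                self.dataset_, self.result_, name, alpha=alpha, n_grid=n_grid
            )
            for name in parameters
        }

    def to_record(self, variant: str, cis: dict | None = None) -> FitRecord:
        """Table-style record of this fit (optionally with profile CIs)."""
        check_is_fitted(self, "result_")
        cis = cis or {}

        def est(name: str, best: float) -> ParameterEstimate:
            ci = cis.get(name)
            if ci is None:
                return ParameterEstimate(best=best)
            return ParameterEstimate(
                best=ci.best_value,
                half_width=ci.half_width,
                lower=ci.lower,
                upper=ci.upper,
                censored_low=ci.censored_low,
                censored_high=ci.censored_high,
            )

        thr = confidence_threshold(self.n_params_, self.n_data_)
        return FitRecord(
            variant=variant,
            k_on=est("k_on", self.k_on_),
            k_off=est("k_off", self.k_off_),
            kd=est("K_D", self.kd_),
            n_params=self.n_params_,
            n_data=self.n_data_,
            sse=self.sse_,
            converged=self.converged_,
            chi2n_threshold=thr.chi2n_threshold,
            f_quantile=thr.f_quantile,
        )
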