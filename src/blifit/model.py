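"""Mass-action 1:1 binding model with a multiplicative probe-leak factor.

The association ("binding") phase of a sensorgram at analyte concentration
``C`` follows pseudo-first-order kinetics with observed rate
``k_obs = k_on*C + k_off``; the dissociation ("unbinding") phase decays at
``k_off``.  Both phases are additionally multiplied by ``exp(-k_leak*t)``,
modelling the slow loss of His-tagged ligand from the Ni-NTA probe tip.
Time is phase-local: ``t`` restarts at 0 at the start of each phase, and the
leak factor uses phase-local ``t`` in both phases.

Units project-wide: concentration in uM, time in s, k_on in uM^-1 s^-1,
k_off and k_leak in s^-1, K_D = k_off/k_on in uM; signal is in instrument
units (nm shift) treated as an arbitrary linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, UndefinedKDError

__all__ = [
    "KineticParameters",
    "CurveNuisance",
    "eval_binding",
    "eval_unbinding",
    "observed_rate",
    "equilibrium_kd",
]


@dataclass(frozen=True)
class KineticParameters:
    """Shared kinetic rates of a global fit.

    Parameters
    ----------
    k_on : float
        Association rate constant, uM^-1 s^-1. Shared across all curves.
    k_off : float
        Dissociation rate constant, s^-1.
    k_leak : float
        Probe-leak decay rate, s^-1 (slow unbinding of the His-tagged
        ligand from the sensor tip).
    """

    k_on: float
    k_off: float
    k_leak: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_leak"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise DomainError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise DomainError(f"{name} must be >= 0, got {value!r}")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant K_D = k_off / k_on, uM."""
        return equilibrium_kd(self)


@dataclass(frozen=True)
class CurveNuisance:
    """Per-curve amplitude/baseline parameters.

    ``a_on`` is the total signal change due to analyte binding for the
    curve; ``b_on``/``b_off`` are phase baselines (unrestricted in sign),
    ``a_off`` the dissociation-phase amplitude.
    """

    a_on: float
    b_on: float = 0.0
    a_off: float = 0.0
    b_off: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_on", "a_off"):
            value = getattr(self, name)
            if value < 0:
                raise DomainError(f"{name} must be >= 0, got {value!r}")
        for name in ("a_on", "b_on", "a_off", "b_off"):
            if not np.isfinite(getattr(self, name)):
                raise DomainError(f"{name} must be finite")


def _check_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0 (phase-local time)")
    return t


def eval_binding(
    t,
    concentration: float,
    kin: KineticParameters,
    nui: CurveNuisance,
):
    """Association-phase model signal.

    ``[a_on*(1 - exp(-(k_on*C + k_off)*t)) + b_on] * exp(-k_leak*t)``

    Parameters
    ----------
    t : array_like
        Phase-local time, s (>= 0).
    concentration : float
        Analyte concentration C, uM (>= 0).
    kin, nui
        Shared rates and per-curve amplitudes/baselines.

    Returns
    -------
    ndarray or float
        Model signal, same shape as ``t``.
    """
    t = _check_time(t)
    if concentration < 0:
        raise DomainError(f"concentration must be >= 0, got {concentration!r}")
    k_obs = kin.k_on * concentration + kin.k_off
    # -expm1 keeps 1 - exp(-x) accurate for small k_obs*t
    rise = -np.expm1(-k_obs * t)
    return (nui.a_on * rise + nui.b_on) * np.exp(-kin.k_leak * t)


def eval_unbinding(t, kin: KineticParameters, nui: CurveNuisance):
    """Dissociation-phase model signal.

    ``[a_off*exp(-k_off*t) + b_off] * exp(-k_leak*t)``
    with ``t`` phase-local (restarting at 0 at the phase boundary).
    """
    t = _check_time(t)
    return (nui.a_off * np.exp(-kin.k_off * t) + nui.b_off) * np.exp(
        -kin.k_leak * t
    )


def observed_rate(kin: KineticParameters, concentration: float) -> float:
    """Pseudo-first-order observed association rate k_obs = k_on*C + k_off.

    Affine in concentration with slope ``k_on`` and intercept ``k_off``;
    at C = 0 it reduces to ``k_off``.
    """
    if concentration < 0:
        raise DomainError(f"concentration must be >= 0, got {concentration!r}")
    return kin.k_on * concentration + kin.k_off


def equilibrium_kd(kin: KineticParameters) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on, uM.

    Raises
    ------
    UndefinedKDError
        If ``k_on`` is zero.
    """
    if kin.k_on <= 0:
        raise UndefinedKDError("K_D = k_off/k_on is undefined for k_on = 0")
    return kin.k_off / kin.k_on
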