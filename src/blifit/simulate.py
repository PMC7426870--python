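"""Synthetic sensorgram generation.

Emulates what the analysis assumes about instrument data: an 8-member
two-fold dilution series with a 0 uM control, association and dissociation
phases on uniform time grids, association amplitudes that saturate with
concentration as a_on = a_max * C / (C + K_D), a slow multiplicative
probe-leak decay, and additive i.i.d. Gaussian measurement noise.

A single integer seed deterministically derives one noise substream per
curve (keyed by curve index), so adding or removing curves does not
reshuffle the noise of the remaining ones.

The scenario library carries the published best-fit rates for the LaM8
anti-mCherry nanobody and its light-switchable LOV-insertion variants
(GG15 and AK74 insertion sites; C450V pseudo-dark and I532E/A536E
pseudo-lit mutants, plus measurements under 450 nm illumination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import BLIDataset, Sensorgram
from .exceptions import DegenerateScenarioError, DomainError, StructuralError
from .model import (
    CurveNuisance,
    KineticParameters,
    eval_binding,
    eval_unbinding,
)

__all__ = [
    "SimulationDesign",
    "Scenario",
    "simulate_sensorgram",
    "simulate_dataset",
    "optonb_scenarios",
    "DEFAULT_K_LEAK",
]

DEFAULT_K_LEAK = 5e-4  # s^-1; slow probe leak, a declared assumption

# 7-point two-fold dilution from 8 uM plus the 0 uM control
_DEFAULT_CONCENTRATIONS = (8.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.125, 0.0)


@dataclass
class SimulationDesign:
    """Experimental design of a simulated dilution series.

    Defaults give 8 curves x 2 phases x 175 samples = 2,800 data points,
    the size of a typical global fit; noise_sigma defaults to 0.5% of the
    saturating amplitude a_max.
    """

    concentrations: tuple = _DEFAULT_CONCENTRATIONS
    assoc_duration: float = 300.0
    dissoc_duration: float = 300.0
    samples_per_phase: int = 175
    noise_sigma: float = 0.005
    a_max: float = 1.0
    baseline: float = 0.0
    seed: int = 0
    continuity: bool = True  # a_off matches the noiseless association endpoint

    def __post_init__(self) -> None:
        if self.assoc_duration <= 0 or self.dissoc_duration <= 0:
            raise DomainError("phase durations must be > 0")
        if self.samples_per_phase < 4:
            raise StructuralError("samples_per_phase must be >= 4")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise StructuralError("concentrations must be distinct")
        if any(c < 0 for c in self.concentrations):
            raise DomainError("concentrations must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """A named kinetic parameter set with its published K_D (uM)."""

    name: str
    kinetics: KineticParameters
    published_kd: float
    illumination: str = "none"


def _curve_rng(seed: int, index: int) -> np.random.Generator:
    # substream keyed by curve index: stable under curve-count changes
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_sensorgram(
    kin: KineticParameters,
    nui: CurveNuisance,
    concentration: float,
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
    curve_id: str | None = None,
) -> Sensorgram:
    """One noisy curve pair on uniform phase-local time grids."""
    rng = rng if rng is not None else _curve_rng(design.seed, 0)
    t_on = np.linspace(0.0, design.assoc_duration, design.samples_per_phase)
    t_off = np.linspace(0.0, design.dissoc_duration, design.samples_per_phase)
    y_on = eval_binding(t_on, concentration, kin, nui)
    y_off = eval_unbinding(t_off, kin, nui)
    if design.noise_sigma > 0:
        y_on = y_on + rng.normal(0.0, design.noise_sigma, size=t_on.size)
        y_off = y_off + rng.normal(0.0, design.noise_sigma, size=t_off.size)
    return Sensorgram(
        curve_id=curve_id if curve_id is not None else f"C{concentration:g}uM",
        concentration=concentration,
        assoc_t=t_on,
        assoc_y=y_on,
        dissoc_t=t_off,
        dissoc_y=y_off,
    )


def simulate_dataset(kin: KineticParameters, design: SimulationDesign) -> BLIDataset:
    """Full dilution series with saturating amplitudes.

    Per-curve association amplitude a_on = a_max * C / (C + K_D) (0 for
    the control); the dissociation amplitude continues the noiseless
    association endpoint when ``design.continuity`` is set, and both
    baselines equal ``design.baseline``.
    """
    if kin.k_on <= 0 and any(c > 0 for c in design.concentrations):
        raise DegenerateScenarioError(
            "saturation amplitudes need k_on > 0 (K_D undefined at k_on = 0)"
        )
    curves = []
    for i, conc in enumerate(design.concentrations):
        a_on = design.a_max * conc / (conc + kin.kd) if conc > 0 else 0.0
        nui = CurveNuisance(
            a_on=a_on, b_on=design.baseline, a_off=0.0, b_off=design.baseline
        )
        if design.continuity:
            end = float(
                eval_binding(design.assoc_duration, conc, kin, nui)
            )
            a_off = max(end - design.baseline, 0.0)
        else:
            a_off = a_on
        nui = CurveNuisance(
            a_on=a_on, b_on=design.baseline, a_off=a_off, b_off=design.baseline
        )
        curves.append(
            simulate_sensorgram(
                kin,
                nui,
                conc,
                design,
                rng=_curve_rng(design.seed, i),
                curve_id=f"curve{i:02d}",
            )
        )
    return BLIDataset(curves=curves)


def optonb_scenarios(k_leak: float = DEFAULT_K_LEAK) -> dict:
    """Published best-fit rates for the LaM8 OptoNB variants.

    Returns a name -> :class:`Scenario` mapping; every entry's
    k_off / k_on agrees with its published K_D within the rounding of the
    published rates.  k_leak is a declared default (no leak rates were
    published) and can be overridden.
    """
    rows = [
        # name, k_on (uM^-1 s^-1), k_off (s^-1), published K_D (uM), illumination
        ("LaM8", 0.072, 0.019, 0.26, "none"),
        ("LaM8-GG15-pseudo-dark", 0.039, 0.021, 0.53, "none"),
        ("LaM8-GG15-pseudo-lit", 0.038, 0.12, 3.1, "none"),
        ("LaM8-GG15-lit", 0.038, 0.096, 2.5, "450 nm"),
        ("LaM8-AK74-pseudo-dark", 0.018, 0.52, 29.0, "none"),
        ("LaM8-AK74-pseudo-lit", 0.034, 0.14, 4.1, "none"),
        ("LaM8-AK74-lit", 0.021, 0.16, 7.4, "450 nm"),
    ]
    return {
        name: Scenario(
            name=name,
            kinetics=KineticParameters(k_on=k_on, k_off=k_off, k_leak=k_leak),
            published_kd=kd,
            illumination=illum,
        )
        for name, k_on, k_off, kd, illum in rows
    }
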