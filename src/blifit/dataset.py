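"""Sensorgram containers.

A :class:`Sensorgram` is one association/dissociation curve pair measured at
a known analyte concentration; a :class:`BLIDataset` is the dilution series
of sensorgrams that is fit jointly.  Both validate their invariants on
construction and convert to/from the canonical long-format table
(``curve_id, phase, time_s, signal, concentration_uM``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, StructuralError

__all__ = ["Sensorgram", "BLIDataset", "CANONICAL_COLUMNS", "PHASES"]

CANONICAL_COLUMNS = ("curve_id", "phase", "time_s", "signal", "concentration_uM")
PHASES = ("association", "dissociation")

_MIN_SAMPLES = 4


def _validate_phase(name: str, t: np.ndarray, y: np.ndarray, curve_id: str):
    if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
        raise StructuralError(
            f"curve {curve_id!r}: {name} time/signal must be 1-d and equal length"
        )
    if t.size < _MIN_SAMPLES:
        raise StructuralError(
            f"curve {curve_id!r}: {name} phase needs >= {_MIN_SAMPLES} samples, "
            f"got {t.size}"
        )
    if t[0] < 0:
        raise DomainError(f"curve {curve_id!r}: {name} time starts below 0")
    if np.any(np.diff(t) <= 0):
        raise DomainError(
            f"curve {curve_id!r}: {name} time must be strictly increasing"
        )
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise DomainError(f"curve {curve_id!r}: non-finite {name} samples")


@dataclass
class Sensorgram:
    """One curve pair (association + dissociation) at a fixed concentration.

    Times are phase-local seconds (each phase starts at >= 0, strictly
    increasing); concentration is uM.
    """

    curve_id: str
    concentration: float
    assoc_t: np.ndarray
    assoc_y: np.ndarray
    dissoc_t: np.ndarray
    dissoc_y: np.ndarray

    def __post_init__(self) -> None:
        self.assoc_t = np.asarray(self.assoc_t, dtype=float)
        self.assoc_y = np.asarray(self.assoc_y, dtype=float)
        self.dissoc_t = np.asarray(self.dissoc_t, dtype=float)
        self.dissoc_y = np.asarray(self.dissoc_y, dtype=float)
        if self.concentration < 0 or not np.isfinite(self.concentration):
            raise DomainError(
                f"curve {self.curve_id!r}: concentration must be finite and >= 0"
            )
        _validate_phase("association", self.assoc_t, self.assoc_y, self.curve_id)
        _validate_phase("dissociation", self.dissoc_t, self.dissoc_y, self.curve_id)

    @property
    def n_points(self) -> int:
        return self.assoc_t.size + self.dissoc_t.size


@dataclass
class BLIDataset:
    """Ordered concentration series of sensorgrams fit jointly."""

    curves: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.curve_id for c in self.curves]
        if len(set(ids)) != len(ids):
            raise StructuralError(f"duplicate curve_ids: {ids}")

    @property
    def n_curves(self) -> int:
        return len(self.curves)

    @property
    def n_data(self) -> int:
        """Total residual point count DF across all phases and curves."""
        return sum(c.n_points for c in self.curves)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c.concentration for c in self.curves])

    @property
    def max_abs_signal(self) -> float:
        return max(
            float(max(np.max(np.abs(c.assoc_y)), np.max(np.abs(c.dissoc_y))))
            for c in self.curves
        )

    def to_frame(self) -> pd.DataFrame:
        """Canonical long-format table (curve order, association first)."""
        parts = []
        for c in self.curves:
            for phase, t, y in (
                ("association", c.assoc_t, c.assoc_y),
                ("dissociation", c.dissoc_t, c.dissoc_y),
            ):
                parts.append(
                    pd.DataFrame(
                        {
                            "curve_id": c.curve_id,
                            "phase": phase,
                            "time_s": t,
                            "signal": y,
                            "concentration_uM": c.concentration,
                        }
                    )
                )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BLIDataset":
        """Build a dataset from a canonical long-format table.

        Assumes the table has already been schema-validated (see
        :func:`blifit.io.read_sensorgrams` for file-level validation with
        line-numbered errors).
        """
        curves = []
        for curve_id in pd.unique(df["curve_id"]):
            sub = df[df["curve_id"] == curve_id]
            conc = float(sub["concentration_uM"].iloc[0])
            phases = {}
            for phase in PHASES:
                block = sub[sub["phase"] == phase]
                phases[phase] = (
                    block["time_s"].to_numpy(float),
                    block["signal"].to_numpy(float),
                )
            curves.append(
                Sensorgram(
                    curve_id=str(curve_id),
                    concentration=conc,
                    assoc_t=phases["association"][0],
                    assoc_y=phases["association"][1],
                    dissoc_t=phases["dissociation"][0],
                    dissoc_y=phases["dissociation"][1],
                )
            )
        return cls(curves=curves)
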