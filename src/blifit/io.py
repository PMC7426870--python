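"""File formats and Table-style reporting.

Canonical sensorgram exchange format: long-format CSV with columns
``curve_id, phase, time_s, signal, concentration_uM`` (order- and
case-insensitive header).  Fit reports serialize to JSON (full precision)
and CSV; display strings follow the "best ± half_width" convention with
the half-width rounded to one significant digit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .dataset import BLIDataset, CANONICAL_COLUMNS, PHASES
from .exceptions import DomainError, ParseError

__all__ = [
    "read_sensorgrams",
    "write_sensorgrams",
    "ParameterEstimate",
    "FitRecord",
    "FitReport",
    "write_report",
    "read_report",
    "compare_states",
    "FoldChange",
    "format_estimate",
    "file_digest",
]

log = logging.getLogger("blifit")


def file_digest(path) -> str:
    """SHA-256 hex digest of a file (for run manifests)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_sensorgrams(path) -> BLIDataset:
    """Read and validate a canonical sensorgram CSV.

    Header matching is case- and order-insensitive.  Times carried on a
    global clock (a phase starting after 0) are re-zeroed to phase-local
    origin with a log notice.  Validation failures raise :class:`ParseError`
    naming the file and, where determinable, the offending curve or line.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    rename = {}
    lower = {c.lower(): c for c in df.columns}
    for col in CANONICAL_COLUMNS:
        if col.lower() not in lower:
            raise ParseError(f"{path}: missing required column {col!r}")
        rename[lower[col.lower()]] = col
    df = df.rename(columns=rename)[list(CANONICAL_COLUMNS)]

    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        line = int(df.index[bad_phase][0]) + 2  # header + 1-based
        raise ParseError(
            f"{path}:{line}: phase must be one of {PHASES}, "
            f"got {df.loc[df.index[bad_phase][0], 'phase']!r}"
        )
    for col in ("time_s", "signal", "concentration_uM"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(df.index[vals.isna()][0]) + 2
            raise ParseError(f"{path}:{line}: non-numeric value in {col!r}")
        df[col] = vals

    for curve_id, sub in df.groupby("curve_id", sort=False):
        concs = sub["concentration_uM"].unique()
        if concs.size != 1:
            raise ParseError(
                f"{path}: curve {curve_id!r} has inconsistent concentrations {concs}"
            )
        if concs[0] < 0:
            raise ParseError(
                f"{path}: curve {curve_id!r} has negative concentration {concs[0]}"
            )
        present = set(sub["phase"])
        for phase in PHASES:
            if phase not in present:
                raise ParseError(
                    f"{path}: curve {curve_id!r} lacks the {phase} phase"
                )
        for phase in PHASES:
            block = sub[sub["phase"] == phase]
            t = block["time_s"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                line = int(block.index[np.argmax(np.diff(t) <= 0) + 1]) + 2
                raise ParseError(
                    f"{path}:{line}: non-monotone time in curve {curve_id!r} "
                    f"{phase} phase"
                )
            if t.size < 4:
                raise ParseError(
                    f"{path}: curve {curve_id!r} {phase} phase has only "
                    f"{t.size} samples (need >= 4)"
                )
            if t[0] > 0:
                log.info(
                    "%s: curve %r %s phase starts at t=%g s; re-zeroing to "
                    "phase-local origin",
                    path, curve_id, phase, t[0],
                )
                df.loc[block.index, "time_s"] = t - t[0]

    return BLIDataset.from_frame(df)


def write_sensorgrams(dataset: BLIDataset, path) -> None:
    """Write the canonical long-format CSV (full float precision)."""
    dataset.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fit reports


@dataclass
class ParameterEstimate:
    """Best-fit value with its profile CI, Table-style."""

    best: float
    half_width: float | None = None
    lower: float | None = None
    upper: float | None = None
    censored_low: bool = False
    censored_high: bool = False

    @property
    def display(self) -> str:
        return format_estimate(self.best, self.half_width)


@dataclass
class FitRecord:
    """One variant's kinetic estimates plus fit diagnostics."""

    variant: str
    k_on: ParameterEstimate
    k_off: ParameterEstimate
    kd: ParameterEstimate
    n_params: int = 0
    n_data: int = 0
    sse: float = float("nan")
    converged: bool = True
    chi2n_threshold: float | None = None
    f_quantile: float | None = None


@dataclass
class FitReport:
    """Collection of fit records plus provenance metadata."""

    records: list = field(default_factory=list)
    software_version: str = ""
    seed: int | None = None
    input_digest: str | None = None


def format_estimate(best: float, half_width: float | None) -> str:
    """Render "best ± half_width" with the half-width rounded to one
    significant digit and the value to the same decimal place
    (e.g. 0.2639, 0.0184 -> "0.26 ± 0.02")."""
    if half_width is None or not math.isfinite(half_width) or half_width <= 0:
        return f"{float(f'{best:.2g}'):g}"
    exponent = math.floor(math.log10(half_width))
    hw = round(half_width, -exponent)
    if round(hw / 10**exponent) >= 10:  # rounding bumped a digit, e.g. 0.95 -> 1
        exponent += 1
        hw = round(half_width, -exponent)
    # the best value keeps at least two significant digits even when the
    # half-width is coarser (e.g. "29 ± 10", not "30 ± 10")
    best_exp = exponent
    if best > 0:
        best_exp = min(exponent, math.floor(math.log10(abs(best))) - 1)
    hw_digits = max(-exponent, 0)
    best_digits = max(-best_exp, 0)
    return f"{round(best, -best_exp):.{best_digits}f} ± {hw:.{hw_digits}f}"


_NUM_FIELDS = ("best", "half_width", "lower", "upper")
_FLAG_FIELDS = ("censored_low", "censored_high")


def _record_to_row(rec: FitRecord) -> dict:
    row = {
        "variant": rec.variant,
        "n_params": rec.n_params,
        "n_data": rec.n_data,
        "sse": rec.sse,
        "converged": rec.converged,
        "chi2n_threshold": rec.chi2n_threshold,
        "f_quantile": rec.f_quantile,
    }
    for pname in ("k_on", "k_off", "kd"):
        est: ParameterEstimate = getattr(rec, pname)
        for f in _NUM_FIELDS:
            row[f"{pname}_{f}"] = getattr(est, f)
        for f in _FLAG_FIELDS:
            row[f"{pname}_{f}"] = getattr(est, f)
        row[f"{pname}_display"] = est.display
    return row


def _row_to_record(row: dict) -> FitRecord:
    def opt_float(v):
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    def as_bool(v):
        return str(v).strip().lower() in ("true", "1")

    ests = {}
    for pname in ("k_on", "k_off", "kd"):
        ests[pname] = ParameterEstimate(
            best=float(row[f"{pname}_best"]),
            half_width=opt_float(row.get(f"{pname}_half_width")),
            lower=opt_float(row.get(f"{pname}_lower")),
            upper=opt_float(row.get(f"{pname}_upper")),
            censored_low=as_bool(row.get(f"{pname}_censored_low", False)),
            censored_high=as_bool(row.get(f"{pname}_censored_high", False)),
        )
    return FitRecord(
        variant=str(row["variant"]),
        k_on=ests["k_on"],
        k_off=ests["k_off"],
        kd=ests["kd"],
        n_params=int(row.get("n_params", 0) or 0),
        n_data=int(row.get("n_data", 0) or 0),
        sse=float(row.get("sse", float("nan"))),
        converged=as_bool(row.get("converged", True)),
        chi2n_threshold=opt_float(row.get("chi2n_threshold")),
        f_quantile=opt_float(row.get("f_quantile")),
    )


def write_report(report: FitReport, path, format: str = "json") -> None:
    """Serialize a report; bit-stable for identical inputs.

    JSON keeps full precision (and is the round-trip master); CSV carries
    the same full-precision numeric fields flattened to columns plus the
    rounded display strings.
    """
    if format == "json":
        payload = asdict(report)
        for rec, full in zip(payload["records"], report.records):
            for pname in ("k_on", "k_off", "kd"):
                rec[pname]["display"] = getattr(full, pname).display
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        rows = [_record_to_row(r) for r in report.records]
        cols = list(_record_to_row(_EMPTY_RECORD).keys())
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    else:
        raise DomainError(f"format must be 'json' or 'csv', got {format!r}")


_EMPTY_RECORD = FitRecord(
    variant="", k_on=ParameterEstimate(0.0), k_off=ParameterEstimate(0.0),
    kd=ParameterEstimate(0.0),
)


def read_report(path, format: str | None = None) -> FitReport:
    """Read a report written by :func:`write_report` (JSON or CSV)."""
    fmt = format or ("csv" if str(path).endswith(".csv") else "json")
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        records = []
        for rec in payload.get("records", []):
            ests = {
                p: ParameterEstimate(
                    **{k: v for k, v in rec[p].items() if k != "display"}
                )
                for p in ("k_on", "k_off", "kd")
            }
            records.append(
                FitRecord(
                    variant=rec["variant"],
                    k_on=ests["k_on"],
                    k_off=ests["k_off"],
                    kd=ests["kd"],
                    n_params=rec.get("n_params", 0),
                    n_data=rec.get("n_data", 0),
                    sse=rec.get("sse", float("nan")),
                    converged=rec.get("converged", True),
                    chi2n_threshold=rec.get("chi2n_threshold"),
                    f_quantile=rec.get("f_quantile"),
                )
            )
        return FitReport(
            records=records,
            software_version=payload.get("software_version", ""),
            seed=payload.get("seed"),
            input_digest=payload.get("input_digest"),
        )
    df = pd.read_csv(path)
    return FitReport(records=[_row_to_record(row) for _, row in df.iterrows()])


@dataclass(frozen=True)
class FoldChange:
    """K_D ratio between two states (weaker / tighter, >= 1)."""

    fold: float
    tighter: str
    weaker: str

    def __str__(self) -> str:
        return (
            f"{self.fold:.2g}-fold affinity change; "
            f"{self.tighter} binds tighter than {self.weaker}"
        )


def compare_states(record_a: FitRecord, record_b: FitRecord) -> FoldChange:
    """Fold-change in affinity between two fitted states.

    Returns weaker-K_D / tighter-K_D (>= 1) and which state binds tighter
    (smaller K_D = tighter binding).
    """
    kd_a, kd_b = record_a.kd.best, record_b.kd.best
    for name, kd in ((record_a.variant, kd_a), (record_b.variant, kd_b)):
        if not (math.isfinite(kd) and kd > 0):
            raise DomainError(f"record {name!r} has nonpositive K_D {kd!r}")
    if kd_a <= kd_b:
        return FoldChange(fold=kd_b / kd_a, tighter=record_a.variant,
                          weaker=record_b.variant)
    return FoldChange(fold=kd_a / kd_b, tighter=record_b.variant,
                      weaker=record_a.variant)
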