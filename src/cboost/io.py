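"""Readers and writers for survival tables, coefficients and reports.

Survival tables are plain CSV/TSV files with one observed-time column, one
event-status column (1 = event observed, 0 = right-censored) and any
number of numeric marker columns; column names are configurable through a
:class:`ColumnMap`.  Fitted coefficient vectors round-trip through a CSV
(one row per marker) plus a JSON sidecar carrying the offset, the
selection history and the risk path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boosting import CoefficientVector
from .data import SurvivalSample, ValidationError
from .pipeline import EvaluationReport


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from file columns to the survival-sample contract.

    ``status_values`` remaps alternative event encodings, e.g.
    ``{"dead": 1, "alive": 0}`` or ``{2: 1, 1: 0}``; by default the status
    column must already be coded 1 = event, 0 = censored.
    """

    time: str = "time"
    status: str = "status"
    status_values: dict = field(default_factory=dict)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_survival_table(path: str | Path, column_map: ColumnMap | None = None) -> SurvivalSample:
    """Load and validate a survival table from CSV/TSV.

    Raises :class:`cboost.data.ValidationError` naming the offending rows
    or columns on malformed input.
    """
    cm = column_map or ColumnMap()
    df = _read_table(path)
    for col in (cm.time, cm.status):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if cm.status_values:
        df[cm.status] = df[cm.status].map(cm.status_values).astype(float)
        if df[cm.status].isna().any():
            rows = df.index[df[cm.status].isna()].tolist()
            raise ValidationError(f"{path}: unmapped status values in rows {rows}")
    bad = ~df[cm.status].isin((0, 1))
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(
            f"{path}: status must be 0 or 1 (row {row} has {df[cm.status][row]!r})"
        )
    try:
        return SurvivalSample.from_dataframe(df, time_col=cm.time, status_col=cm.status)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_survival_table(
    sample: SurvivalSample, path: str | Path, column_map: ColumnMap | None = None
) -> None:
    cm = column_map or ColumnMap()
    df = sample.to_dataframe(time_col=cm.time, status_col=cm.status)
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)


def write_coefficients(coefs: CoefficientVector, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (per-marker table) and ``<prefix>.json`` (run record)."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    counts = np.zeros(coefs.beta.shape[0], dtype=int)
    for _, comp in coefs.selection_history:
        counts[comp] += 1
    pd.DataFrame(
        {
            "marker": list(coefs.marker_names),
            "beta_standardized": coefs.beta,
            "beta_raw": coefs.beta_raw,
            "n_selections": counts,
        }
    ).to_csv(csv_path, index=False)
    json_path.write_text(
        json.dumps(
            {
                "offset": coefs.offset,
                "final_risk": coefs.final_risk,
                "selection_history": [[int(m), int(c)] for m, c in coefs.selection_history],
                "risk_path": coefs.risk_path.tolist(),
            }
        )
    )
    return csv_path, json_path


def read_coefficients(prefix: str | Path) -> CoefficientVector:
    """Rebuild a :class:`CoefficientVector` written by :func:`write_coefficients`."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return CoefficientVector(
        beta=df["beta_standardized"].to_numpy(),
        beta_raw=df["beta_raw"].to_numpy(),
        offset=float(meta["offset"]),
        selection_history=tuple((int(m), int(c)) for m, c in meta["selection_history"]),
        risk_path=np.asarray(meta["risk_path"], dtype=float),
        final_risk=float(meta["final_risk"]),
        marker_names=tuple(df["marker"].astype(str)),
    )


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Write an evaluation report as CSV; medians are recomputable from it."""
    df = pd.DataFrame(
        {"split": np.arange(report.per_split_c.shape[0]), "c_test": report.per_split_c}
    )
    df["c_apparent"] = report.apparent_c
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path) -> EvaluationReport:
    df = pd.read_csv(path)
    return EvaluationReport(
        df["c_test"].to_numpy(), float(df["c_apparent"].iloc[0])
    )


def run_metadata(seed, config_obj) -> dict:
    """A reproducibility record: package version, seed and configuration."""
    from . import __version__

    def as_jsonable(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: as_jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, (np.ndarray, tuple, list)):
            return [as_jsonable(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return {"version": __version__, "seed": seed, "config": as_jsonable(config_obj)}
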