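"""Core data container for right-censored survival samples.

A :class:`SurvivalSample` couples, for ``n`` subjects, the observed
follow-up time ``observed_time`` (the minimum of the event time and an
independent censoring time), the event indicator ``event`` (1 = the event
was observed, 0 = the subject was right-censored) and an ``n x p`` matrix
of numeric marker values.  All estimation and evaluation routines in this
package consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when input data violate the survival-sample contract."""


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival data for ``n`` subjects with ``p`` markers.

    Parameters
    ----------
    observed_time
        Positive observed follow-up times, length ``n``.
    event
        Binary event indicators (1 = event observed, 0 = right-censored).
    markers
        ``n x p`` matrix of marker/covariate values, no missing entries.
    marker_names
        Optional ``p`` labels; defaults to ``x1 .. xp``.
    """

    observed_time: np.ndarray
    event: np.ndarray
    markers: np.ndarray
    marker_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        t = np.asarray(self.observed_time, dtype=float)
        e = np.asarray(self.event, dtype=float)
        m = np.asarray(self.markers, dtype=float)
        if m.ndim == 1:
            m = m[:, None]
        if m.ndim != 2:
            raise ValidationError("markers must be a 2-d matrix")
        n = t.shape[0]
        if e.shape[0] != n or m.shape[0] != n:
            raise ValidationError(
                f"length mismatch: {n} times, {e.shape[0]} events, "
                f"{m.shape[0]} marker rows"
            )
        if n < 2:
            raise ValidationError("a survival sample needs at least 2 subjects")
        if not np.all(np.isfinite(t)):
            raise ValidationError("observed_time contains non-finite values")
        if np.any(t <= 0):
            bad = int(np.flatnonzero(t <= 0)[0])
            raise ValidationError(f"observed_time must be > 0 (row {bad})")
        if not np.isin(e, (0.0, 1.0)).all():
            bad = int(np.flatnonzero(~np.isin(e, (0.0, 1.0)))[0])
            raise ValidationError(
                f"event must be 0 or 1 (row {bad} has value {e[bad]!r})"
            )
        if not np.all(np.isfinite(m)):
            bad = int(np.flatnonzero(~np.isfinite(m).all(axis=1))[0])
            raise ValidationError(f"markers contain missing/non-finite values (row {bad})")
        names = tuple(self.marker_names) or tuple(f"x{j + 1}" for j in range(m.shape[1]))
        if len(names) != m.shape[1]:
            raise ValidationError(
                f"{len(names)} marker names for {m.shape[1]} marker columns"
            )
        object.__setattr__(self, "observed_time", t)
        object.__setattr__(self, "event", e.astype(np.int8))
        object.__setattr__(self, "markers", m)
        object.__setattr__(self, "marker_names", names)

    @property
    def n(self) -> int:
        return self.observed_time.shape[0]

    @property
    def p(self) -> int:
        return self.markers.shape[1]

    @property
    def censoring_rate(self) -> float:
        """Fraction of right-censored subjects."""
        return float(1.0 - self.event.mean())

    def take(self, indices) -> "SurvivalSample":
        """Row subset (new sample with the selected subjects)."""
        idx = np.asarray(indices)
        return SurvivalSample(
            self.observed_time[idx], self.event[idx], self.markers[idx], self.marker_names
        )

    def select_markers(self, columns) -> "SurvivalSample":
        """Column subset keeping all subjects."""
        cols = np.asarray(columns)
        return SurvivalSample(
            self.observed_time,
            self.event,
            self.markers[:, cols],
            tuple(self.marker_names[int(c)] for c in cols),
        )

    def to_dataframe(self, time_col: str = "time", status_col: str = "status") -> pd.DataFrame:
        df = pd.DataFrame(self.markers, columns=list(self.marker_names))
        df.insert(0, status_col, self.event)
        df.insert(0, time_col, self.observed_time)
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_col: str = "time", status_col: str = "status"
    ) -> "SurvivalSample":
        missing = {time_col, status_col} - set(df.columns)
        if missing:
            raise ValidationError(f"missing required columns: {sorted(missing)}")
        marker_cols = [c for c in df.columns if c not in (time_col, status_col)]
        mk = df[marker_cols]
        non_numeric = [c for c in marker_cols if not np.issubdtype(mk[c].dtype, np.number)]
        if non_numeric:
            raise ValidationError(f"non-numeric marker columns: {non_numeric}")
        if mk.isna().any().any():
            rows = sorted(mk.index[mk.isna().any(axis=1)].tolist())
            raise ValidationError(f"missing marker values in rows {rows}")
        return cls(
            df[time_col].to_numpy(dtype=float),
            df[status_col].to_numpy(dtype=float),
            mk.to_numpy(dtype=float),
            tuple(marker_cols),
        )
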