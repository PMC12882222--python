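"""Minute-level light/activity recordings: loading, transforms, and 24-h segmentation.

Raw actigraph output arrives as one sample per minute of illuminance (lux) and
activity intensity (device counts).  Before any rhythm analysis the two signals
are made comparable: lux is saturated at 10,000 lux (the circadian system's
response is effectively ceiling-limited well below outdoor daylight) and both
signals are log10(x + 1) transformed.  The record is then cut into consecutive
24-hour days aligned to the midnight-anchored minute grid, low-quality days are
dropped, and each surviving day is standardized to zero mean / unit variance so
that downstream circular correlations are true correlation coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Illuminance above this level is treated as saturating (lux).
LIGHT_SATURATION_LUX = 10_000.0

#: Default fraction of valid minutes a day must retain to be analyzed.
DEFAULT_MIN_VALID_FRACTION = 0.8

#: Default minimum number of QC-passed days per participant.
DEFAULT_MIN_DAYS = 4

MINUTES_PER_DAY = 1440


class FormatError(ValueError):
    """Raised when an input file violates the minute-grid contract."""


class ConfigurationError(ValueError):
    """Raised when declared columns or dialects do not match the file."""


@dataclass
class LightActivityRecording:
    """A participant's minute-grid light and activity record.

    Attributes
    ----------
    participant_id : str
        Identifier carried through every downstream table.
    lux : ndarray
        Raw illuminance per minute (lux, >= 0 where valid).
    activity : ndarray
        Raw activity intensity per minute (device counts, >= 0 where valid).
    valid : ndarray of bool
        Per-minute wear/quality flag.  Invalid minutes are retained (the grid
        is never compacted) and interpolated during segmentation.
    minutes_per_day : int
        Grid resolution; the first sample is assumed midnight-anchored.
    """

    participant_id: str
    lux: np.ndarray
    activity: np.ndarray
    valid: np.ndarray
    minutes_per_day: int = MINUTES_PER_DAY

    def __post_init__(self) -> None:
        self.lux = np.asarray(self.lux, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.lux)
        if not (len(self.activity) == len(self.valid) == n):
            raise ValueError("lux, activity and valid must have equal lengths")
        if self.minutes_per_day < 24:
            raise ValueError("minutes_per_day must be >= 24")
        # out-of-range samples are flagged invalid, never dropped
        bad = ~np.isfinite(self.lux) | ~np.isfinite(self.activity)
        bad |= (self.lux < 0) | (self.activity < 0)
        if bad.any():
            self.valid = self.valid & ~bad

    def __len__(self) -> int:
        return len(self.lux)

    @property
    def n_days(self) -> int:
        return len(self) // self.minutes_per_day


@dataclass
class DayPair:
    """One QC-passed 24-hour day: transformed, standardized light and activity.

    Both vectors have zero mean and unit (population) variance, which makes the
    circular cross-correlation downstream a genuine correlation coefficient.
    """

    light_t: np.ndarray
    activity_t: np.ndarray
    valid_fraction: float
    day_index: int

    def __post_init__(self) -> None:
        for name, v in (("light_t", self.light_t), ("activity_t", self.activity_t)):
            v = np.asarray(v, dtype=float)
            if abs(v.mean()) > 1e-9 or abs(v.std() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be standardized (zero mean, unit variance)")
        if not 0.0 <= self.valid_fraction <= 1.0:
            raise ValueError("valid_fraction must lie in [0, 1]")


def transform_light(lux):
    """Saturating log transform for illuminance: ``log10(min(lux, 10000) + 1)``.

    Monotone nondecreasing, zero at zero lux, and constant above the 10,000-lux
    saturation threshold.  Accepts scalars or arrays.
    """
    lux = np.asarray(lux, dtype=float)
    if np.any(lux < 0):
        raise ValueError("lux must be nonnegative")
    out = np.log10(np.minimum(lux, LIGHT_SATURATION_LUX) + 1.0)
    return out if out.ndim else float(out)


def transform_activity(counts):
    """Log transform for activity intensity: ``log10(counts + 1)`` (no saturation)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("activity counts must be nonnegative")
    out = np.log10(counts + 1.0)
    return out if out.ndim else float(out)


def _interpolate_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate invalid minutes within a day (edges held at nearest valid)."""
    if valid.all():
        return values
    idx = np.arange(len(values))
    return np.interp(idx, idx[valid], values[valid])


def segment_and_qc(
    rec: LightActivityRecording,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
    min_days: int = DEFAULT_MIN_DAYS,
) -> list[DayPair]:
    """Cut a recording into midnight-aligned days, QC-filter, transform, standardize.

    A day survives when at least ``min_valid_fraction`` of its minutes are valid
    and both transformed signals have nonzero within-day variance (a record of
    constant darkness carries no rhythm information).  Invalid minutes of a
    surviving day are linearly interpolated *before* transformation so nonwear
    gaps do not inject spurious 24-h power.  Returns an empty list (exclusion
    signal, logged) when fewer than ``min_days`` days survive.
    """
    m = rec.minutes_per_day
    if len(rec) < m:
        raise ValueError("recording shorter than one day")
    days: list[DayPair] = []
    for d in range(rec.n_days):
        sl = slice(d * m, (d + 1) * m)
        valid = rec.valid[sl]
        frac = float(valid.mean())
        if frac < min_valid_fraction:
            logger.info("participant %s day %d dropped: valid fraction %.3f < %.3f",
                        rec.participant_id, d, frac, min_valid_fraction)
            continue
        lux = _interpolate_invalid(rec.lux[sl], valid)
        act = _interpolate_invalid(rec.activity[sl], valid)
        lt = transform_light(lux)
        at = transform_activity(act)
        if lt.std() < 1e-12 or at.std() < 1e-12:
            logger.info("participant %s day %d dropped: zero variance after transform",
                        rec.participant_id, d)
            continue
        lt = (lt - lt.mean()) / lt.std()
        at = (at - at.mean()) / at.std()
        days.append(DayPair(light_t=lt, activity_t=at, valid_fraction=frac, day_index=d))
    if len(days) < min_days:
        logger.info("participant %s excluded: only %d QC-passed days (< %d required)",
                    rec.participant_id, len(days), min_days)
        return []
    return days


# ---------------------------------------------------------------------------
# I/O: minute-level CSV and SAS-transport dialects
# ---------------------------------------------------------------------------

#: Default column names for the CSV minute dialect.
CSV_COLUMNS = {
    "participant_id": "participant_id",
    "minute": "minute",
    "lux": "lux",
    "activity": "activity",
    "valid": "valid",
}


def load_minute_records(
    path,
    dialect: str = "csv-minute",
    columns: dict | None = None,
    minutes_per_day: int = MINUTES_PER_DAY,
) -> LightActivityRecording:
    """Read one participant's minute file into a validated recording.

    Parameters
    ----------
    path : str or Path
        Minute-level file.  ``csv-minute`` expects columns for participant id,
        minute index (or ISO timestamp), lux, activity and (optionally) a valid
        flag; ``xpt-minute`` reads a SAS-transport file with the same logical
        columns under configurable names.
    dialect : {"csv-minute", "xpt-minute"}
    columns : dict, optional
        Overrides for the logical-to-physical column mapping (keys as in
        :data:`CSV_COLUMNS`).

    Non-numeric or out-of-range samples are flagged invalid rather than
    dropped, so the minute grid is preserved.
    """
    cols = dict(CSV_COLUMNS)
    if columns:
        cols.update(columns)
    if dialect == "csv-minute":
        df = pd.read_csv(path)
    elif dialect == "xpt-minute":
        df = pd.read_sas(path, format="xport")
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")

    for logical in ("participant_id", "minute", "lux", "activity"):
        if cols[logical] not in df.columns:
            raise ConfigurationError(
                f"required column {cols[logical]!r} (for {logical}) missing from {path}"
            )

    minute = df[cols["minute"]]
    if not pd.api.types.is_numeric_dtype(minute):
        # ISO-8601 timestamps: convert to minutes since the first sample
        ts = pd.to_datetime(minute, errors="coerce")
        if ts.isna().any():
            raise FormatError("timestamp column is neither numeric nor parseable ISO-8601")
        minute = (ts - ts.iloc[0]).dt.total_seconds() / 60.0
    minute = np.asarray(minute, dtype=float)
    steps = np.diff(minute)
    if len(steps) and (np.any(steps <= 0) or np.ptp(steps) > 1e-9):
        raise FormatError("timestamps must be strictly increasing with a constant 1-minute step")

    lux = pd.to_numeric(df[cols["lux"]], errors="coerce").to_numpy()
    act = pd.to_numeric(df[cols["activity"]], errors="coerce").to_numpy()
    if cols["valid"] in df.columns:
        valid = df[cols["valid"]].astype(bool).to_numpy()
    else:
        valid = np.ones(len(df), dtype=bool)

    pid = str(df[cols["participant_id"]].iloc[0])
    return LightActivityRecording(
        participant_id=pid, lux=lux, activity=act, valid=valid,
        minutes_per_day=minutes_per_day,
    )


def write_minute_csv(rec: LightActivityRecording, path, columns: dict | None = None) -> None:
    """Write a recording in the CSV minute dialect (round-trips with the loader)."""
    cols = dict(CSV_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.DataFrame({
        cols["participant_id"]: rec.participant_id,
        cols["minute"]: np.arange(len(rec)),
        cols["lux"]: rec.lux,
        cols["activity"]: rec.activity,
        cols["valid"]: rec.valid.astype(int),
    })
    df.to_csv(path, index=False)
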