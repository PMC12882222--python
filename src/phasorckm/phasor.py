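"""Phasor analysis of circadian light-activity synchronization.

The central quantity is the *behavioral synchronization correlation function*:
for each 24-hour day the standardized (log-transformed) light and activity
signals are circularly cross-correlated over all cyclic lags, the per-day
correlation functions are averaged, and the 24-hour Fourier component of the
average is extracted as a complex phasor

    P = (2/N) * sum_tau r(tau) * exp(-i * 2*pi*tau / N).

``|P|`` (the phasor magnitude) measures the strength and day-to-day regularity
of light-activity coupling; a perfectly phase-locked sinusoidal pair scores
exactly 1.  The phasor angle, re-expressed in hours as the *acrophase*, gives
the time offset of activity relative to light: positive values mean activity
lags light (evening preference), negative values mean activity leads light
(morning preference).

Normalization convention: signals are standardized per day with population
variance, so |r(tau)| <= 1 by Cauchy-Schwarz and the magnitude is bounded by
4/pi (the fundamental of a unit-bounded square wave); a phase-locked pure
sinusoid attains magnitude exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DayPair, MINUTES_PER_DAY

__all__ = [
    "CorrelationFunction",
    "PhasorResult",
    "circular_xcorr",
    "fundamental_component",
    "compute_phasor",
    "assign_quartiles",
    "weighted_quantile",
    "wrap_hours",
]

#: Hard Fourier bound on the magnitude of the 24-h component of any |r| <= 1 function.
MAGNITUDE_BOUND = 4.0 / np.pi


def wrap_hours(hours: float) -> float:
    """Wrap a clock offset into the half-open interval (-12, 12]."""
    w = -((-hours + 12.0) % 24.0 - 12.0)
    return 12.0 if w == -12.0 else w


@dataclass
class CorrelationFunction:
    """Circular cross-correlation r(tau), tau in {0, ..., N-1} minutes."""

    r: np.ndarray
    n_days: int = 1

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(np.abs(self.r) > 1.0 + 1e-9):
            raise ValueError("|r(tau)| must not exceed 1 for standardized signals")

    def __len__(self) -> int:
        return len(self.r)


@dataclass
class PhasorResult:
    """Phasor summary of one participant's light-activity coupling."""

    magnitude: float
    acrophase_hours: float
    phasor: complex
    n_days_used: int
    per_day_phasors: list[complex] | None = None

    def __post_init__(self) -> None:
        if abs(self.magnitude - abs(self.phasor)) > 1e-9:
            raise ValueError("magnitude must equal |phasor|")
        if self.magnitude > MAGNITUDE_BOUND + 1e-9:
            raise ValueError("magnitude exceeds the 4/pi Fourier bound")
        if not (-12.0 < self.acrophase_hours <= 12.0):
            raise ValueError("acrophase_hours must lie in (-12, 12]")

    @property
    def acrophase_degrees(self) -> float:
        """Acrophase as a polar angle in degrees, (-180, 180]."""
        return self.acrophase_hours * 15.0


def _check_standardized(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if abs(v.mean()) > 1e-6 or abs(v.std() - 1.0) > 1e-6:
        raise ValueError(f"{name} must be standardized to zero mean, unit variance")
    return v


def circular_xcorr(x, y) -> CorrelationFunction:
    """Circular cross-correlation of two standardized signals.

    Returns ``r(tau) = (1/N) * sum_t x(t) * y((t + tau) mod N)``, computed via
    FFT.  Both inputs must already be standardized; the result is then a true
    correlation coefficient at every lag (|r| <= 1).
    """
    x = _check_standardized(x, "x")
    y = _check_standardized(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal lengths")
    n = len(x)
    r = np.fft.irfft(np.conj(np.fft.rfft(x)) * np.fft.rfft(y), n) / n
    # guard against femto-scale FFT overshoot at |r| = 1
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationFunction(r=r, n_days=1)


def fundamental_component(cf: CorrelationFunction, harmonic: int = 1) -> complex:
    """24-hour Fourier component of a correlation function.

    ``P = (2/N) * sum_tau r(tau) * exp(-i 2 pi * harmonic * tau / N)``.  For a
    single-day correlation function the first harmonic is the 24-h component;
    for a correlation function over a concatenated multi-day record the 24-h
    component is harmonic = n_days.
    """
    r = cf.r
    n = len(r)
    tau = np.arange(n)
    return complex((2.0 / n) * np.sum(r * np.exp(-2j * np.pi * harmonic * tau / n)))


def compute_phasor(
    days: list[DayPair],
    keep_per_day: bool = False,
    method: str = "per-day-average",
) -> PhasorResult | None:
    """Phasor magnitude and acrophase from a participant's QC-passed days.

    ``per-day-average`` (default) averages the per-day circular correlation
    functions and takes the 24-h component of the average -- by linearity this
    equals the mean of the per-day phasors.  ``concatenated`` computes one
    correlation function over the concatenated record and reads off the
    component at the 24-h frequency.

    Returns ``None`` (exclusion signal, not an exception) for an empty day list.
    """
    if not days:
        return None
    if method == "per-day-average":
        per_day = [
            fundamental_component(circular_xcorr(d.light_t, d.activity_t)) for d in days
        ]
        p = complex(np.mean(per_day))
    elif method == "concatenated":
        lt = np.concatenate([d.light_t for d in days])
        at = np.concatenate([d.activity_t for d in days])
        lt = (lt - lt.mean()) / lt.std()
        at = (at - at.mean()) / at.std()
        cf = circular_xcorr(lt, at)
        p = fundamental_component(cf, harmonic=len(days))
        per_day = None
    else:
        raise ValueError(f"unknown method {method!r}")
    acro = wrap_hours(-np.angle(p) * 24.0 / (2.0 * np.pi))
    return PhasorResult(
        magnitude=abs(p),
        acrophase_hours=acro,
        phasor=p,
        n_days_used=len(days),
        per_day_phasors=per_day if keep_per_day else None,
    )


def phasor_table(results: dict) -> pd.DataFrame:
    """Tidy per-participant phasor table (participant_id, magnitude, acrophase, days)."""
    rows = [
        {
            "participant_id": pid,
            "magnitude": res.magnitude,
            "acrophase_hours": res.acrophase_hours,
            "n_days_used": res.n_days_used,
        }
        for pid, res in results.items()
        if res is not None
    ]
    return pd.DataFrame(rows, columns=["participant_id", "magnitude", "acrophase_hours", "n_days_used"])


# ---------------------------------------------------------------------------
# Quantiles and quartile grouping
# ---------------------------------------------------------------------------

def weighted_quantile(values, q, weights=None, interpolate: bool = False):
    """Weighted quantile(s) of ``values``.

    Default is the left-continuous step definition: the smallest observed value
    v with cumulative weight fraction >= q.  ``interpolate=True`` instead
    interpolates linearly on the cumulative-weight midpoints (used for spline
    knot placement, where a smooth estimate is preferable).
    """
    values = np.asarray(values, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    if interpolate:
        mid = (cw - 0.5 * w) / total
        out = np.interp(q, mid, v)
    else:
        idx = np.searchsorted(cw / total, q, side="left")
        out = v[np.minimum(idx, len(v) - 1)]
    return out if out.size > 1 else float(out[0])


class DegenerateGroupingError(ValueError):
    """Raised when values cannot be split into four nonempty quartiles."""


def assign_quartiles(values, weights=None):
    """Quartile labels (1..4, Q1 = lowest) and the 25/50/75 cutpoints.

    Cutpoints are weighted percentiles when weights are given.  A value equal
    to a cutpoint is assigned to the *lower* quartile.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 4 or len(np.unique(values[finite])) < 4:
        raise DegenerateGroupingError("need at least 4 distinct finite values to form quartiles")
    cuts = np.asarray(
        weighted_quantile(values[finite], [0.25, 0.5, 0.75],
                          None if weights is None else np.asarray(weights)[finite])
    )
    if len(np.unique(cuts)) < 3:
        raise DegenerateGroupingError("quartile cutpoints are not distinct")
    labels = np.where(finite, np.searchsorted(cuts, values, side="left") + 1, np.nan)
    return labels, cuts
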