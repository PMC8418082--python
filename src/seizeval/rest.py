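"""Actigraphy rest/activity segmentation.

The wrist accelerometer magnitude is band-pass filtered (0.25-3 Hz by
default, removing gravity and high-frequency noise), activity counts are
the number of upward crossings of a small acceleration threshold
accumulated over 30-s epochs, and rest is declared wherever a centered
30-min moving average of the counts falls below a count threshold. Rest
periods closer than 2 h are merged, treating the gap as a rest
interruption. Detected rest is a proxy for sleep plus long quiescent
wakefulness and is used to stratify detector performance.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .core import TimeInterval, UndefinedResultError, ensure_utc


@dataclass(frozen=True)
class RestConfig:
    """Parameters of the count-threshold rest detector.

    The band corners, crossing threshold and rest count threshold are
    deliberately configurable: defaults recover nightly sleep blocks in
    the synthetic actigraphy generator.
    """

    epoch_length_s: float = 30.0
    smoothing_window_min: float = 30.0
    merge_gap_h: float = 2.0
    band_hz: tuple[float, float] = (0.25, 3.0)
    crossing_threshold_g: float = 0.02
    rest_count_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.epoch_length_s <= 0 or self.merge_gap_h <= 0:
            raise ValueError("epoch_length_s and merge_gap_h must be positive")
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band corners must satisfy 0 < low < high")


@dataclass(frozen=True)
class RestInterval:
    """A detected rest period with its mean raw activity count."""

    start_s: float
    end_s: float
    mean_counts: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0

    def to_time_interval(self, t0: _dt.datetime) -> TimeInterval:
        t0 = ensure_utc(t0)
        return TimeInterval(
            t0 + _dt.timedelta(seconds=self.start_s),
            t0 + _dt.timedelta(seconds=self.end_s),
        )


def bandpass_magnitude(
    acm: np.ndarray, fs: float, band_hz: tuple[float, float]
) -> np.ndarray:
    """Zero-phase band-pass of the tri-axial magnitude (gravity removed)."""
    acm = np.asarray(acm, dtype=float)
    if acm.ndim != 2 or acm.shape[1] != 3:
        raise ValueError("acm must have shape (n_samples, 3)")
    mag = np.linalg.norm(acm, axis=1)
    lo, hi = band_hz
    nyq = fs / 2.0
    sos = _signal.butter(3, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    # zero-phase to avoid biasing rest onset/offset times
    return _signal.sosfiltfilt(sos, mag)


def activity_counts(
    acm: np.ndarray,
    fs: float = 32.0,
    config: RestConfig | None = None,
) -> pd.Series:
    """Per-epoch activity counts from a uniformly sampled tri-axial record.

    Counts are upward crossings of the filtered magnitude through
    ``crossing_threshold_g`` accumulated over ``epoch_length_s`` epochs;
    the returned Series is indexed by epoch start time in seconds. A
    trailing partial epoch is discarded.
    """
    config = config or RestConfig()
    if fs <= 0:
        raise ValueError("fs must be positive")
    filtered = bandpass_magnitude(acm, fs, config.band_hz)
    samples_per_epoch = int(round(config.epoch_length_s * fs))
    n_epochs = len(filtered) // samples_per_epoch
    if n_epochs < 1:
        raise ValueError("need at least one full epoch of data")
    thr = config.crossing_threshold_g
    below = filtered[:-1] < thr
    above = filtered[1:] >= thr
    crossing_idx = np.nonzero(below & above)[0] + 1
    epoch_of = crossing_idx // samples_per_epoch
    counts = np.bincount(epoch_of[epoch_of < n_epochs], minlength=n_epochs)
    index = np.arange(n_epochs) * config.epoch_length_s
    return pd.Series(counts.astype(float), index=index, name="counts")


def detect_rest(
    counts: pd.Series, config: RestConfig | None = None
) -> list[RestInterval]:
    """Segment an epoch count series into rest intervals.

    A centered moving average over ``smoothing_window_min`` is compared to
    ``rest_count_threshold``; runs of sub-threshold epochs become rest
    intervals, and intervals separated by less than ``merge_gap_h`` are
    merged. Missing epochs (NaN) never count as rest.
    """
    config = config or RestConfig()
    if counts.empty or counts.isna().all():
        warnings.warn("all epochs missing: no rest detected", stacklevel=2)
        return []
    window = max(1, int(round(config.smoothing_window_min * 60 / config.epoch_length_s)))
    smooth = counts.rolling(window=window, center=True, min_periods=1).mean()
    rest_mask = (smooth < config.rest_count_threshold) & counts.notna()

    epoch = config.epoch_length_s
    idx = counts.index.to_numpy(dtype=float)
    raw: list[tuple[float, float]] = []
    run_start: Optional[float] = None
    prev_t: Optional[float] = None
    for t, is_rest in zip(idx, rest_mask.to_numpy()):
        if is_rest:
            if run_start is None:
                run_start = t
            prev_t = t
        else:
            if run_start is not None:
                raw.append((run_start, prev_t + epoch))
                run_start = None
    if run_start is not None:
        raw.append((run_start, prev_t + epoch))

    merged: list[tuple[float, float]] = []
    gap_s = config.merge_gap_h * 3600.0
    for start, end in raw:
        if merged and start - merged[-1][1] < gap_s:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    out = []
    for start, end in merged:
        in_iv = (idx >= start) & (idx < end)
        mean_counts = float(np.nanmean(counts.to_numpy(dtype=float)[in_iv]))
        out.append(RestInterval(start_s=start, end_s=end, mean_counts=mean_counts))
    return out


@dataclass(frozen=True)
class RestSummary:
    total_hours: float
    fraction_of_wear: float
    median_duration_h: Optional[float]
    median_periods_per_day: float
    flags: tuple[str, ...] = ()


def rest_fraction(rest_hours: float, total_hours: float) -> float:
    """Fraction of wear time spent at rest, from pooled hour totals."""
    if total_hours <= 0:
        raise UndefinedResultError("total_hours must be positive")
    return rest_hours / total_hours


def rest_summary(
    intervals_by_session: Sequence[Sequence[RestInterval]],
    wear_hours_by_session: Sequence[float],
) -> RestSummary:
    """Cohort-level rest statistics.

    ``intervals_by_session`` and ``wear_hours_by_session`` are parallel:
    one entry per recording session. Periods per day are computed per
    session as count / (wear hours / 24) and summarized by the median.
    """
    if len(intervals_by_session) != len(wear_hours_by_session):
        raise ValueError("per-session inputs must be parallel")
    total_wear = float(sum(wear_hours_by_session))
    if total_wear <= 0:
        raise UndefinedResultError("no wear time")
    durations = [
        iv.duration_h for session in intervals_by_session for iv in session
    ]
    total_rest = float(sum(durations))
    flags: tuple[str, ...] = ()
    if durations:
        median_duration = float(np.median(durations))
    else:
        median_duration = None
        flags = ("no_rest_detected",)
    per_day = [
        len(session) / (hours / 24.0) if hours > 0 else 0.0
        for session, hours in zip(intervals_by_session, wear_hours_by_session)
    ]
    return RestSummary(
        total_hours=total_rest,
        fraction_of_wear=total_rest / total_wear,
        median_duration_h=median_duration,
        median_periods_per_day=float(np.median(per_day)) if per_day else 0.0,
        flags=flags,
    )
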