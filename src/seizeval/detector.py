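"""Transparent surrogate for the proprietary on-device detection algorithm.

The commercial classifier (40 selected features, pre-trained model) is
unpublished; this module reproduces only its published *architecture* —
10-s windows with 75% overlap over wrist accelerometer (ACM, 32 Hz) and
electrodermal activity (EDA, 4 Hz) streams, a per-window probability
score, and a thresholded decision rule with a high-sensitivity
("FDA-cleared") and a high-specificity ("Active") operating point — so
that the evaluation pipeline (scoring, curves, stratification) can be
exercised end to end. Its absolute sensitivity/FAR are properties of the
surrogate, not of the commercial device.

The window score is a logistic combination of transparent features:
clonic-band (2-6 Hz) ACM energy, a rhythmicity score based on the
regularity of zero-crossing intervals (phase-sensitive, so a
phase-scrambled burst with identical energy scores lower), and the EDA
level and slope (the post-ictal sympathetic surge). The score is monotone
in the clonic-band energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .core import Mode, OperatingPoint


@dataclass(frozen=True)
class DetectorConfig:
    window_length_s: float = 10.0
    overlap_fraction: float = 0.75
    threshold_fda: float = 0.5
    threshold_active: float = 0.85
    refractory_s: float = 180.0
    clonic_band_hz: tuple[float, float] = (2.0, 6.0)

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not self.threshold_fda < self.threshold_active:
            raise ValueError(
                "FDA-cleared threshold must be below the Active threshold"
            )

    @property
    def stride_s(self) -> float:
        return self.window_length_s * (1 - self.overlap_fraction)

    def operating_point(self, mode: Mode) -> OperatingPoint:
        mode = Mode(mode)
        thr = self.threshold_fda if mode is Mode.FDA_CLEARED else self.threshold_active
        return OperatingPoint(name=mode, threshold=thr)


def windows(
    signal_duration_s: float, config: DetectorConfig | None = None
) -> list[tuple[float, float]]:
    """Start/end times of consecutive overlapped windows covering a record.

    ``count = floor((duration - window) / stride) + 1``; a record shorter
    than one window yields an empty list.
    """
    config = config or DetectorConfig()
    w, s = config.window_length_s, config.stride_s
    if signal_duration_s < w:
        return []
    n = int(math.floor((signal_duration_s - w) / s + 1e-9)) + 1
    return [(i * s, i * s + w) for i in range(n)]


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def rhythmicity(filtered: np.ndarray, fs: float) -> float:
    """Local regularity of upward zero-crossing intervals, in [0, 1].

    ``1 - 3 * jitter`` floored at 0, where jitter is the mean absolute
    successive difference of inter-crossing intervals divided by the mean
    interval. A coherent oscillation — even one whose frequency drifts
    slowly, as clonic jerks slow over a seizure — has near-identical
    neighboring intervals (score near 1); band-limited noise or a
    phase-scrambled burst with the same power spectrum has irregular
    crossings (score near 0). The statistic depends on phase, not only on
    the spectrum.
    """
    x = np.asarray(filtered, dtype=float)
    ups = np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0]
    if len(ups) < 4:
        return 0.0
    gaps = np.diff(ups) / fs
    jitter = float(np.mean(np.abs(np.diff(gaps))) / np.mean(gaps))
    return max(0.0, 1.0 - 3.0 * jitter)


@dataclass(frozen=True)
class WindowFeatures:
    clonic_rms_g: float
    rhythmicity: float
    eda_level_us: float
    eda_slope_us_per_s: float


def window_features(
    acm_window: np.ndarray,
    eda_window: np.ndarray,
    fs_acm: float = 32.0,
    fs_eda: float = 4.0,
    config: DetectorConfig | None = None,
) -> WindowFeatures:
    config = config or DetectorConfig()
    acm_window = np.asarray(acm_window, dtype=float)
    if acm_window.ndim == 1:
        acm_window = acm_window[:, None]
    lo, hi = config.clonic_band_hz
    nyq = fs_acm / 2.0
    sos = _signal.butter(3, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    # per-axis filtering: gravity drops out and the clonic oscillation keeps
    # its sign (the vector magnitude would rectify it to twice the frequency)
    filtered = _signal.sosfiltfilt(sos, acm_window, axis=0)
    rms = float(np.sqrt(np.mean(np.sum(filtered**2, axis=1))))
    dominant = int(np.argmax(filtered.std(axis=0)))
    rhythm = rhythmicity(filtered[:, dominant], fs_acm)
    eda = np.asarray(eda_window, dtype=float)
    t = np.arange(len(eda)) / fs_eda
    slope = float(np.polyfit(t, eda, 1)[0]) if len(eda) >= 2 else 0.0
    return WindowFeatures(
        clonic_rms_g=rms,
        rhythmicity=rhythm,
        eda_level_us=float(np.mean(eda)),
        eda_slope_us_per_s=slope,
    )


# logistic weights of the surrogate score; chosen so that flat input scores
# well below 0.1 and an injected clonic burst with an EDA surge scores
# above 0.9, with monotonicity in the clonic-band RMS
_W_ENERGY = 6.0
_RMS_REF_G = 0.05
_W_RHYTHM = 2.5
_W_EDA_SLOPE = 3.0
_EDA_SLOPE_REF = 0.1
_BIAS = -5.0


def score_from_features(f: WindowFeatures) -> float:
    """Logistic surrogate probability; strictly increasing in clonic RMS."""
    z = (
        _W_ENERGY * math.log1p(f.clonic_rms_g / _RMS_REF_G)
        + _W_RHYTHM * f.rhythmicity
        + _W_EDA_SLOPE * min(max(f.eda_slope_us_per_s, 0.0) / _EDA_SLOPE_REF, 2.0)
        + _BIAS
    )
    return _sigmoid(z)


def window_score(
    acm_window: np.ndarray,
    eda_window: np.ndarray,
    fs_acm: float = 32.0,
    fs_eda: float = 4.0,
    config: DetectorConfig | None = None,
) -> float:
    """Surrogate seizure probability for one complete window pair."""
    if acm_window is None or eda_window is None or len(eda_window) == 0:
        raise ValueError("both modalities are required for a window score")
    return score_from_features(
        window_features(acm_window, eda_window, fs_acm, fs_eda, config)
    )


def score_stream(
    acm: np.ndarray,
    eda: np.ndarray,
    fs_acm: float = 32.0,
    fs_eda: float = 4.0,
    config: DetectorConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Score every window of a recording.

    Returns (window end times in seconds, scores). The detection time of
    a window is its end (the moment the device has seen the full window),
    so latencies are non-negative and quantized to the stride.
    """
    config = config or DetectorConfig()
    duration = len(np.atleast_2d(acm)) / fs_acm if np.asarray(acm).ndim == 2 else len(acm) / fs_acm
    acm = np.asarray(acm, dtype=float)
    duration = acm.shape[0] / fs_acm
    wins = windows(duration, config)
    times = np.empty(len(wins))
    scores = np.empty(len(wins))
    for i, (t0, t1) in enumerate(wins):
        a = acm[int(round(t0 * fs_acm)) : int(round(t1 * fs_acm))]
        e = np.asarray(eda, dtype=float)[
            int(round(t0 * fs_eda)) : int(round(t1 * fs_eda))
        ]
        times[i] = t1
        scores[i] = window_score(a, e, fs_acm, fs_eda, config)
    return times, scores


def decide(
    times: np.ndarray,
    scores: np.ndarray,
    threshold: float,
    refractory_s: float = 180.0,
) -> list[float]:
    """Alarm times: first supra-threshold window of each excursion, with
    alarms suppressed during the refractory period after a previous alarm."""
    alarms: list[float] = []
    last: Optional[float] = None
    for t, s in zip(times, scores):
        if s >= threshold and (last is None or t - last >= refractory_s):
            alarms.append(float(t))
            last = float(t)
    return alarms


def max_score_per_interval(
    times: np.ndarray,
    scores: np.ndarray,
    intervals: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Maximum window score inside each [on, off) interval (-inf if none)."""
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    out = np.full(len(intervals), -np.inf)
    for i, (on, off) in enumerate(intervals):
        mask = (times >= on) & (times < off)
        if mask.any():
            out[i] = scores[mask].max()
    return out


class SurrogateDetector:
    """Convenience wrapper: signals in, alarms out, sweepable by threshold."""

    def __init__(self, config: DetectorConfig | None = None) -> None:
        self.config = config or DetectorConfig()

    def scores(
        self, acm: np.ndarray, eda: np.ndarray, fs_acm: float = 32.0, fs_eda: float = 4.0
    ) -> tuple[np.ndarray, np.ndarray]:
        return score_stream(acm, eda, fs_acm, fs_eda, self.config)

    def alarms_at(
        self, times: np.ndarray, scores: np.ndarray, threshold: float
    ) -> list[float]:
        return decide(times, scores, threshold, self.config.refractory_s)

    def alarms(
        self,
        acm: np.ndarray,
        eda: np.ndarray,
        mode: Mode,
        fs_acm: float = 32.0,
        fs_eda: float = 4.0,
    ) -> list[float]:
        times, scores = self.scores(acm, eda, fs_acm, fs_eda)
        return self.alarms_at(times, scores, self.config.operating_point(mode).threshold)

    def sweep_counts(
        self,
        times: np.ndarray,
        scores: np.ndarray,
        labels: Sequence[tuple[float, float]],
        duration_s: float,
        slot_duration_s: float,
    ):
        """Monotone per-threshold counts for curve construction.

        Returns ``counts_at(threshold) -> (n_detected, n_false_alarms)``
        where a labeled event is detected when its maximum window score
        reaches the threshold, and a false alarm is a pseudo-negative
        slot (non-seizure time tiled at ``slot_duration_s``) whose
        maximum window score reaches it. Both counts are non-increasing
        in the threshold, unlike alarm streams shaped by the refractory
        rule.
        """
        times = np.asarray(times, dtype=float)
        scores = np.asarray(scores, dtype=float)
        event_max = max_score_per_interval(times, scores, labels)
        in_label = np.zeros(len(times), dtype=bool)
        for on, off in labels:
            in_label |= (times >= on) & (times < off)
        neg_times = times[~in_label]
        neg_scores = scores[~in_label]
        slot = np.floor(neg_times / slot_duration_s).astype(int)
        slot_max: dict[int, float] = {}
        for k, s in zip(slot, neg_scores):
            if s > slot_max.get(k, -np.inf):
                slot_max[k] = s
        neg_max = np.array(sorted(slot_max.values()))

        def counts_at(threshold: float) -> tuple[int, int]:
            det = int(np.sum(event_max >= threshold))
            fa = int(len(neg_max) - np.searchsorted(neg_max, threshold, side="left"))
            return det, fa

        return counts_at

    @staticmethod
    def counts_against_labels(
        alarm_times: Sequence[float], labels: Sequence[tuple[float, float]]
    ) -> tuple[int, int]:
        """(detected events, false alarms) for alarms vs labeled [on, off) events."""
        detected = 0
        for on, off in labels:
            if any(on <= t < off for t in alarm_times):
                detected += 1
        fa = sum(
            1
            for t in alarm_times
            if not any(on <= t < off for on, off in labels)
        )
        return detected, fa
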