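"""ROC, precision-recall and sensitivity/FAR curves for a monitoring stream.

Specificity is ill-defined for continuous monitoring because there is no
natural count of "non-seizure events". Following the pseudo-negative
construction, the non-seizure recording time is represented as a sequence
of non-overlapping negative events whose duration equals the mean
duration of the consensus seizures; specificity at a threshold is then
``1 - FA / n_negative_events``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .cluster_stats import IntervalEstimate, far_normal_ci, wilson
from .core import UndefinedResultError


@dataclass(frozen=True)
class NegativeEventModel:
    """Pseudo-negative events tiling the non-seizure time."""

    mean_event_duration_s: float
    n_negative_events: int


def pseudo_negatives(
    total_hours: float, seizure_hours: float, mean_cs_duration_s: float
) -> NegativeEventModel:
    """Number of mean-CS-duration slices tiling the non-seizure time (floor)."""
    if mean_cs_duration_s <= 0:
        raise ValueError("mean_cs_duration_s must be positive")
    if total_hours < seizure_hours:
        raise ValueError("total_hours must be >= seizure_hours")
    n = int(math.floor((total_hours - seizure_hours) * 3600.0 / mean_cs_duration_s))
    return NegativeEventModel(mean_event_duration_s=mean_cs_duration_s, n_negative_events=n)


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    n_detected: int
    n_false_alarms: int
    sensitivity: float
    specificity: Optional[float]
    precision: Optional[float]
    far: float
    sensitivity_ci: IntervalEstimate
    specificity_ci: Optional[IntervalEstimate]
    precision_ci: Optional[IntervalEstimate]
    far_ci: IntervalEstimate
    flags: tuple[str, ...] = ()


#: Detector interface for sweeps: threshold -> (n_detected, n_false_alarms).
CountsAtThreshold = Callable[[float], tuple[int, int]]


def sweep(
    counts_at: CountsAtThreshold,
    n_events: int,
    negatives: NegativeEventModel,
    hours: float,
    thresholds: Sequence[float],
    confidence: float = 0.95,
) -> list[CurvePoint]:
    """Evaluate the detector over a strictly increasing threshold grid.

    Per point: sensitivity with a Wilson interval, specificity against the
    pseudo-negative count, precision (None when there are no alerts), and
    FAR with a Poisson normal-approximation interval.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold grid must be non-empty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if n_events < 1:
        raise UndefinedResultError("sweep requires >= 1 positive event")
    if hours <= 0:
        raise UndefinedResultError("sweep requires positive exposure hours")

    points: list[CurvePoint] = []
    for thr in thresholds:
        det, fa = counts_at(thr)
        flags: list[str] = []
        sens = det / n_events
        sens_ci = wilson(det, n_events, confidence)
        if negatives.n_negative_events > 0:
            fa_clip = min(fa, negatives.n_negative_events)
            spec = 1.0 - fa_clip / negatives.n_negative_events
            spec_ci = wilson(
                negatives.n_negative_events - fa_clip,
                negatives.n_negative_events,
                confidence,
            )
            if fa > negatives.n_negative_events:
                flags.append("false_alarms_exceed_negatives")
        else:
            spec, spec_ci = None, None
            flags.append("specificity_undefined")
        if det + fa > 0:
            prec = det / (det + fa)
            prec_ci = wilson(det, det + fa, confidence)
        else:
            prec, prec_ci = None, None
            flags.append("no_alerts")
        far_ci = far_normal_ci(fa, hours, confidence)
        points.append(
            CurvePoint(
                threshold=thr,
                n_detected=det,
                n_false_alarms=fa,
                sensitivity=sens,
                specificity=spec,
                precision=prec,
                far=far_ci.estimate,
                sensitivity_ci=sens_ci,
                specificity_ci=spec_ci,
                precision_ci=prec_ci,
                far_ci=far_ci,
                flags=tuple(flags),
            )
        )
    return points


def default_threshold_grid(n: int = 101) -> list[float]:
    """Evenly spaced probability thresholds in [0, 1]."""
    return [i / (n - 1) for i in range(n)]


def pr_curve(points: Sequence[CurvePoint]) -> list[tuple[float, float]]:
    """(recall, precision) pairs; thresholds with no alerts are dropped."""
    return [(p.sensitivity, p.precision) for p in points if p.precision is not None]


def roc_curve(points: Sequence[CurvePoint]) -> list[tuple[float, float]]:
    """(1 - specificity, sensitivity) pairs; undefined-specificity points dropped."""
    return [
        (1.0 - p.specificity, p.sensitivity)
        for p in points
        if p.specificity is not None
    ]


def curve_frame(points: Sequence[CurvePoint]):
    """Tabulate a sweep as a pandas DataFrame (curves.csv layout)."""
    import pandas as pd

    rows = []
    for p in points:
        rows.append(
            {
                "threshold": p.threshold,
                "n_detected": p.n_detected,
                "n_false_alarms": p.n_false_alarms,
                "sensitivity": p.sensitivity,
                "sensitivity_lo": p.sensitivity_ci.lower,
                "sensitivity_hi": p.sensitivity_ci.upper,
                "specificity": p.specificity,
                "specificity_lo": p.specificity_ci.lower if p.specificity_ci else None,
                "specificity_hi": p.specificity_ci.upper if p.specificity_ci else None,
                "precision": p.precision,
                "precision_lo": p.precision_ci.lower if p.precision_ci else None,
                "precision_hi": p.precision_ci.upper if p.precision_ci else None,
                "far": p.far,
                "far_lo": p.far_ci.lower,
                "far_hi": p.far_ci.upper,
            }
        )
    return pd.DataFrame(rows)


def plot_curves(points: Sequence[CurvePoint], out_prefix: str) -> list[str]:
    """Write ROC, PR and sensitivity/FAR-vs-threshold panels as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    roc = roc_curve(points)
    if roc:
        fig, ax = plt.subplots()
        ax.plot([f for f, _ in roc], [s for _, s in roc], marker="o")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title("ROC (pseudo-negative events)")
        path = f"{out_prefix}_roc.png"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    pr = pr_curve(points)
    if pr:
        fig, ax = plt.subplots()
        ax.plot([r for r, _ in pr], [p for _, p in pr], marker="o")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title("Precision-recall")
        path = f"{out_prefix}_pr.png"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    fig, ax = plt.subplots()
    thr = [p.threshold for p in points]
    ax.plot(thr, [p.sensitivity for p in points], label="sensitivity")
    ax2 = ax.twinx()
    ax2.plot(thr, [p.far for p in points], color="tab:orange", label="FAR")
    ax.set_xlabel("threshold")
    ax.set_ylabel("sensitivity")
    ax2.set_ylabel("FAR per 24 h")
    path = f"{out_prefix}_sens_far.png"
    fig.savefig(path)
    plt.close(fig)
    written.append(path)
    return written
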