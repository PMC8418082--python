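"""Inference for clustered binary outcomes and exposure-based event rates.

Multiple convulsive seizures from the same patient are correlated, which
inflates naive pooled sensitivity estimates. The machinery here follows
the classical survey-statistics route:

* intraclass correlation ``rho`` from a one-way ANOVA (Fleiss-type)
  estimator on per-event binary detection indicators grouped by patient;
* design effect ``DE = 1 + (m_bar - 1) * rho`` with ``m_bar`` the mean
  cluster size, applied as *effective counts* ``x/DE`` of ``n/DE``;
* Wilson score intervals on the (possibly effective) counts, with the
  Wilson midpoint ``(x + z^2/2) / (n + z^2)`` as the cluster-corrected
  point estimate;
* Laplace's rule of succession ``(s+1)/(n+2)`` for precision when no
  false alarms were observed;
* patient-level percentile bootstrap for false-alarm-rate intervals;
* exposure-adjusted conditional-binomial rate-ratio test and a
  normal-reference test on the difference of corrected sensitivities.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import ClusterOutcome, UndefinedResultError


class IntervalMethod(str, enum.Enum):
    WILSON = "wilson"
    WILSON_CLUSTER = "wilson_cluster"
    BOOTSTRAP_PERCENTILE = "bootstrap_percentile"
    NORMAL_APPROX = "normal_approx"
    LAPLACE = "laplace"


@dataclass(frozen=True)
class IntervalEstimate:
    estimate: float
    lower: float
    upper: float
    confidence: float = 0.95
    method: IntervalMethod = IntervalMethod.WILSON
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate + 1e-12 and self.estimate <= self.upper + 1e-12):
            raise ValueError(
                f"interval must bracket the estimate: "
                f"[{self.lower}, {self.upper}] vs {self.estimate}"
            )


@dataclass(frozen=True)
class ClusterSummary:
    """Cluster structure of a set of per-patient detection outcomes."""

    n_clusters: int
    n_events: int
    n_detected: int
    mean_cluster_size: float
    icc: float
    design_effect: float


@dataclass(frozen=True)
class BootstrapConfig:
    n_iterations: int = 100_000
    percentiles: tuple[float, float] = (2.5, 97.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1000:
            raise ValueError("n_iterations must be >= 1000")
        lo, hi = self.percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("percentiles must satisfy 0 <= lo < hi <= 100")


@dataclass(frozen=True)
class RateTestResult:
    p_value: float
    statistic: float
    flags: tuple[str, ...] = ()


def _zcrit(confidence: float) -> float:
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    return float(stats.norm.ppf((1 + confidence) / 2))


def wilson(x: float, n: float, confidence: float = 0.95) -> IntervalEstimate:
    """Wilson score interval; the reported estimate is the Wilson midpoint.

    Accepts non-integer (effective) counts so the same code path serves
    the design-effect-deflated case.
    """
    if n <= 0:
        raise UndefinedResultError("wilson requires n >= 1")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    z = _zcrit(confidence)
    z2 = z * z
    center = (x + z2 / 2) / (n + z2)
    halfwidth = z / (n + z2) * math.sqrt(x * (n - x) / n + z2 / 4)
    return IntervalEstimate(
        estimate=center,
        lower=max(0.0, center - halfwidth),
        upper=min(1.0, center + halfwidth),
        confidence=confidence,
        method=IntervalMethod.WILSON,
    )


def wilson_halfwidth(x: float, n: float, confidence: float = 0.95) -> float:
    z = _zcrit(confidence)
    z2 = z * z
    return z / (n + z2) * math.sqrt(x * (n - x) / n + z2 / 4)


def icc_anova(outcomes: Sequence[ClusterOutcome]) -> float:
    """One-way ANOVA (Fleiss-type) ICC on binary detection indicators.

    Clamped to [0, 1]; returns 0 when every cluster has a single event or
    the between-cluster mean square does not exceed the within-cluster one.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise UndefinedResultError("icc_anova requires at least one cluster")
    sizes = np.array([o.n_events for o in outcomes], dtype=float)
    x = np.array([o.n_detected for o in outcomes], dtype=float)
    k = len(outcomes)
    N = sizes.sum()
    if N <= k or np.all(sizes == 1):
        return 0.0
    grand = x.sum() / N
    means = x / sizes
    # sums of squares for 0/1 data: within-cluster SS = x_i (1 - x_i/m_i) ... etc.
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(np.sum(x * (1 - means) ** 2 + (sizes - x) * means**2))
    if k < 2:
        return 0.0
    msb = ss_between / (k - 1)
    msw = ss_within / (N - k)
    if msb <= msw:
        return 0.0
    n0 = (N - float(np.sum(sizes**2)) / N) / (k - 1)
    rho = (msb - msw) / (msb + (n0 - 1) * msw)
    return float(min(1.0, max(0.0, rho)))


def cluster_summary(outcomes: Sequence[ClusterOutcome]) -> ClusterSummary:
    outcomes = list(outcomes)
    if not outcomes:
        raise UndefinedResultError("no cluster outcomes")
    sizes = [o.n_events for o in outcomes]
    n = sum(sizes)
    x = sum(o.n_detected for o in outcomes)
    m_bar = n / len(outcomes)
    rho = icc_anova(outcomes)
    de = 1.0 + (m_bar - 1.0) * rho
    return ClusterSummary(
        n_clusters=len(outcomes),
        n_events=n,
        n_detected=x,
        mean_cluster_size=m_bar,
        icc=rho,
        design_effect=de,
    )


def corrected_sensitivity(
    outcomes: Sequence[ClusterOutcome], confidence: float = 0.95
) -> IntervalEstimate:
    """Cluster-corrected sensitivity: Wilson on design-effect-deflated counts.

    With ``DE = 1`` (singleton clusters, or no excess within-patient
    homogeneity) this reduces exactly to :func:`wilson` on the raw counts.
    """
    summ = cluster_summary(outcomes)
    if summ.n_events < 1:
        raise UndefinedResultError("corrected_sensitivity requires >= 1 event")
    n_eff = summ.n_events / summ.design_effect
    x_eff = summ.n_detected / summ.design_effect
    base = wilson(x_eff, n_eff, confidence)
    return IntervalEstimate(
        estimate=base.estimate,
        lower=base.lower,
        upper=base.upper,
        confidence=confidence,
        method=IntervalMethod.WILSON_CLUSTER,
    )


def laplace_estimate(successes: int) -> float:
    """Rule of succession point estimate (s+1)/(s+2) for an all-success run."""
    return (successes + 1) / (successes + 2)


def precision_estimate(
    n_true_alerts: int, n_false_alerts: int, confidence: float = 0.95
) -> IntervalEstimate:
    """Precision TP/(TP+FA) with Wilson interval; Laplace-corrected when FA = 0.

    A run of alerts that are all true positives gives an observed precision
    of exactly 1; the rule of succession ``(s+1)/(n+2)`` replaces that with
    a conservative estimate, and the interval comes from the Wilson score
    on the Laplace-adjusted counts.
    """
    tp, fa = int(n_true_alerts), int(n_false_alerts)
    if tp < 0 or fa < 0:
        raise ValueError("counts must be non-negative")
    n = tp + fa
    if n < 1:
        raise UndefinedResultError("precision undefined with zero alerts")
    if fa > 0:
        base = wilson(tp, n, confidence)
        return IntervalEstimate(
            estimate=tp / n,
            lower=base.lower,
            upper=base.upper,
            confidence=confidence,
            method=IntervalMethod.WILSON,
        )
    est = laplace_estimate(tp)
    base = wilson(tp + 1, n + 2, confidence)
    return IntervalEstimate(
        estimate=est,
        lower=min(base.lower, est),
        upper=max(base.upper, est),
        confidence=confidence,
        method=IntervalMethod.LAPLACE,
    )


def pooled_far_from_arrays(false_alarms: np.ndarray, hours: np.ndarray) -> float:
    return 24.0 * float(false_alarms.sum()) / float(hours.sum())


def far_bootstrap_ci(
    sessions: Iterable, config: BootstrapConfig | None = None
) -> IntervalEstimate:
    """Patient-level percentile bootstrap for the pooled false-alarm rate.

    *sessions* may be any objects exposing ``n_false_alarms`` and ``hours``
    attributes (e.g. :class:`seizeval.scoring.ScoredSession`) or
    ``(false_alarms, hours)`` pairs. Sessions are resampled with
    replacement at the patient level, the pooled FAR recomputed per
    replicate, and the interval taken as the configured percentiles.
    """
    config = config or BootstrapConfig()
    fa, hours = _fa_hours(sessions)
    if len(fa) == 0 or hours.sum() <= 0:
        raise UndefinedResultError("bootstrap requires >= 1 session with hours > 0")
    point = pooled_far_from_arrays(fa, hours)
    flags: tuple[str, ...] = ()
    if len(fa) == 1:
        return IntervalEstimate(
            estimate=point,
            lower=point,
            upper=point,
            confidence=(config.percentiles[1] - config.percentiles[0]) / 100,
            method=IntervalMethod.BOOTSTRAP_PERCENTILE,
            flags=("single_session_degenerate",),
        )
    rng = np.random.default_rng(config.seed)
    k = len(fa)
    B = config.n_iterations
    # chunk to bound memory at ~10^7 draws per block
    block = max(1, min(B, int(1e7) // k))
    reps = np.empty(B, dtype=float)
    done = 0
    while done < B:
        b = min(block, B - done)
        idx = rng.integers(0, k, size=(b, k))
        reps[done : done + b] = 24.0 * fa[idx].sum(axis=1) / hours[idx].sum(axis=1)
        done += b
    lo, hi = np.percentile(reps, config.percentiles)
    return IntervalEstimate(
        estimate=point,
        lower=float(min(lo, point)),
        upper=float(max(hi, point)),
        confidence=(config.percentiles[1] - config.percentiles[0]) / 100,
        method=IntervalMethod.BOOTSTRAP_PERCENTILE,
        flags=flags,
    )


def _fa_hours(sessions: Iterable) -> tuple[np.ndarray, np.ndarray]:
    fa_list, hr_list = [], []
    for s in sessions:
        if hasattr(s, "n_false_alarms"):
            fa_list.append(s.n_false_alarms)
            hr_list.append(s.hours)
        else:
            f, h = s
            fa_list.append(f)
            hr_list.append(h)
    return np.asarray(fa_list, dtype=float), np.asarray(hr_list, dtype=float)


def far_normal_ci(
    false_alarms: float, hours: float, confidence: float = 0.95
) -> IntervalEstimate:
    """Poisson normal approximation ``24 (FA ± z sqrt(FA)) / hours``.

    Used for per-point confidence bands on curve sweeps; the headline FAR
    interval is the patient-level bootstrap instead.
    """
    if hours <= 0:
        raise UndefinedResultError("hours must be positive")
    z = _zcrit(confidence)
    est = 24.0 * false_alarms / hours
    hw = 24.0 * z * math.sqrt(max(false_alarms, 0.0)) / hours
    return IntervalEstimate(
        estimate=est,
        lower=max(0.0, est - hw),
        upper=est + hw,
        confidence=confidence,
        method=IntervalMethod.NORMAL_APPROX,
    )


def far_ratio_test(
    group1: tuple[float, float],
    group2: tuple[float, float],
    method: str = "normal",
) -> RateTestResult:
    """Exposure-adjusted test that two groups share the same event rate.

    Conditional on the total count ``N = fa1 + fa2``, the group-1 count is
    Binomial(N, T1/(T1+T2)) under the null of equal rates. The default is
    a continuity-corrected normal approximation; ``method="exact"`` uses
    the central two-sided binomial (twice the smaller tail), the exact
    counterpart of the same tail convention.
    """
    fa1, t1 = group1
    fa2, t2 = group2
    if t1 <= 0 or t2 <= 0:
        raise ValueError("both groups need positive exposure hours")
    n_total = fa1 + fa2
    if n_total < 1:
        return RateTestResult(p_value=1.0, statistic=0.0, flags=("zero_events",))
    pi = t1 / (t1 + t2)
    if method == "exact":
        x, n = int(round(fa1)), int(round(n_total))
        lower = float(stats.binom.cdf(x, n, pi))
        upper = float(stats.binom.sf(x - 1, n, pi))
        p = min(1.0, 2 * min(lower, upper))
        return RateTestResult(p_value=p, statistic=float(fa1))
    sd = math.sqrt(n_total * pi * (1 - pi))
    dev = max(0.0, abs(fa1 - n_total * pi) - 0.5)  # continuity correction
    z = math.copysign(dev / sd, fa1 - n_total * pi)
    p = 2 * float(stats.norm.sf(abs(z)))
    return RateTestResult(p_value=min(1.0, p), statistic=z)


def clustered_diff_test(
    group_a: Sequence[ClusterOutcome],
    group_b: Sequence[ClusterOutcome],
    confidence: float = 0.95,
) -> tuple[IntervalEstimate, float]:
    """Difference of cluster-corrected sensitivities with a normal reference.

    The variance of each group's corrected estimate is the binomial
    variance at the Wilson midpoint with the design-effect-deflated
    effective denominator; the null of equal sensitivities is rejected
    when 0 falls outside the returned interval.
    """
    if not group_a or not group_b:
        raise UndefinedResultError("both groups must be non-empty")
    flags: list[str] = []
    ests, variances, mles = [], [], []
    for outcomes in (group_a, group_b):
        summ = cluster_summary(outcomes)
        est = corrected_sensitivity(outcomes, confidence)
        n_eff = summ.n_events / summ.design_effect
        ests.append(est.estimate)
        variances.append(est.estimate * (1 - est.estimate) / n_eff)
        mles.append(summ.n_detected / summ.n_events)
    diff = ests[0] - ests[1]
    var = sum(variances)
    z = _zcrit(confidence)
    if mles[0] in (0.0, 1.0) and mles[0] == mles[1]:
        # both observed proportions at the same boundary: no evidence of a
        # difference and zero observed binomial variance
        flags.append("degenerate_zero_variance")
        interval = IntervalEstimate(
            estimate=diff,
            lower=min(diff, diff - z * math.sqrt(var)),
            upper=max(diff, diff + z * math.sqrt(var)),
            confidence=confidence,
            method=IntervalMethod.NORMAL_APPROX,
            flags=tuple(flags),
        )
        return interval, 1.0
    if var <= 0:
        flags.append("degenerate_zero_variance")
        interval = IntervalEstimate(
            estimate=diff,
            lower=diff,
            upper=diff,
            confidence=confidence,
            method=IntervalMethod.NORMAL_APPROX,
            flags=tuple(flags),
        )
        return interval, 1.0
    se = math.sqrt(var)
    interval = IntervalEstimate(
        estimate=diff,
        lower=diff - z * se,
        upper=diff + z * se,
        confidence=confidence,
        method=IntervalMethod.NORMAL_APPROX,
        flags=tuple(flags),
    )
    p = 2 * float(stats.norm.sf(abs(diff) / se))
    return interval, min(1.0, p)


def min_clusters_for_sensitivity(
    expected_sens: float,
    ci_halfwidth: float,
    icc: float,
    mean_cluster_size: float = 1.0,
    confidence: float = 0.95,
    max_clusters: int = 1_000_000,
) -> int:
    """Smallest number of seizing patients meeting a CI-halfwidth target.

    For ``k`` clusters of mean size ``m_bar`` with intraclass correlation
    ``icc``, the effective number of events is ``k * m_bar / DE`` with
    ``DE = 1 + (m_bar - 1) * icc``; the answer is the smallest ``k`` whose
    cluster-corrected Wilson interval at the expected sensitivity has a
    half-width no larger than ``ci_halfwidth``. Monotone non-increasing in
    ``ci_halfwidth`` and non-decreasing in ``icc``.
    """
    if not 0 < expected_sens < 1:
        raise ValueError("expected_sens must be in (0, 1)")
    if ci_halfwidth <= 0:
        raise ValueError("ci_halfwidth must be positive")
    if mean_cluster_size < 1:
        raise ValueError("mean_cluster_size must be >= 1")
    if not 0 <= icc <= 1:
        raise ValueError("icc must be in [0, 1]")
    de = 1.0 + (mean_cluster_size - 1.0) * icc
    for k in range(1, max_clusters + 1):
        n_eff = k * mean_cluster_size / de
        hw = wilson_halfwidth(expected_sens * n_eff, n_eff, confidence)
        if hw <= ci_halfwidth:
            return k
    return max_clusters
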