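"""Alarm-to-seizure matching and pooled endpoint quantities.

A consensus seizure counts as detected (true positive) when at least one
alarm of the evaluated operating mode falls inside its clinical interval
``[onset, offset)``; the detection latency is the time from clinical
onset to the first such alarm. Every alarm not inside any consensus
seizure is exactly one false alarm; extra alarms inside an already
detected seizure are absorbed (neither true positives nor false alarms).

Pooled quantities: sensitivity = detected / total seizures; false-alarm
rate (FAR) = 24 * false alarms / recording hours.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    AgeGroup,
    Mode,
    RecordingSession,
    TimeInterval,
    UndefinedResultError,
)


@dataclass(frozen=True)
class SeizureOutcome:
    """Detection outcome of one consensus seizure."""

    interval: TimeInterval
    seizure_type: str
    detected: bool
    latency_s: Optional[float] = None


@dataclass
class ScoredSession:
    """Per-session scoring result for one operating mode."""

    patient_id: str
    hours: float
    seizure_outcomes: list[SeizureOutcome] = field(default_factory=list)
    false_alarm_times: list[_dt.datetime] = field(default_factory=list)
    age_group: Optional[AgeGroup] = None

    @property
    def n_seizures(self) -> int:
        return len(self.seizure_outcomes)

    @property
    def n_detected(self) -> int:
        return sum(1 for o in self.seizure_outcomes if o.detected)

    @property
    def latencies(self) -> list[float]:
        return [o.latency_s for o in self.seizure_outcomes if o.detected]

    @property
    def n_false_alarms(self) -> int:
        return len(self.false_alarm_times)

    @property
    def seizure_durations_s(self) -> list[float]:
        return [o.interval.duration_s for o in self.seizure_outcomes]


@dataclass
class CohortScore:
    """Scored sessions for one cohort/stratum plus pooled totals."""

    sessions: list[ScoredSession]

    @property
    def n_seizures(self) -> int:
        return sum(s.n_seizures for s in self.sessions)

    @property
    def n_detected(self) -> int:
        return sum(s.n_detected for s in self.sessions)

    @property
    def n_false_alarms(self) -> int:
        return sum(s.n_false_alarms for s in self.sessions)

    @property
    def hours(self) -> float:
        return sum(s.hours for s in self.sessions)

    @property
    def latencies(self) -> list[float]:
        return [lat for s in self.sessions for lat in s.latencies]

    @property
    def seizure_durations_s(self) -> list[float]:
        return [d for s in self.sessions for d in s.seizure_durations_s]

    def duration_summary(self) -> tuple[float, float]:
        """Mean and sample SD of consensus-seizure durations, seconds."""
        return _mean_sd(self.seizure_durations_s)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    if not values:
        raise UndefinedResultError("no values to summarize")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def score_session(session: RecordingSession, mode: Mode) -> ScoredSession:
    """Match a session's alarms (of *mode*) against its consensus seizures."""
    mode = Mode(mode)
    alarms = sorted(session.alarms_in_mode(mode), key=lambda a: a.timestamp)
    seizures = sorted(session.seizures, key=lambda sz: sz.clinical_interval.start)

    outcomes: list[SeizureOutcome] = []
    matched: set[int] = set()
    for sz in seizures:
        iv = sz.clinical_interval
        first = None
        for i, alarm in enumerate(alarms):
            if alarm.timestamp >= iv.end:
                break
            if iv.contains(alarm.timestamp):
                first = alarm
                break
        if first is not None:
            latency = (first.timestamp - iv.start).total_seconds()
            outcomes.append(
                SeizureOutcome(iv, sz.seizure_type.value, True, latency)
            )
        else:
            outcomes.append(SeizureOutcome(iv, sz.seizure_type.value, False, None))

    seizure_ivs = [sz.clinical_interval for sz in seizures]
    fa_times = [
        a.timestamp
        for a in alarms
        if not any(iv.contains(a.timestamp) for iv in seizure_ivs)
    ]
    return ScoredSession(
        patient_id=session.patient_id,
        hours=session.total_hours,
        seizure_outcomes=outcomes,
        false_alarm_times=fa_times,
        age_group=session.age_group,
    )


def score_cohort(sessions: Iterable[RecordingSession], mode: Mode) -> CohortScore:
    return CohortScore([score_session(s, mode) for s in sessions])


def pooled_sensitivity(cohort: CohortScore) -> float:
    if cohort.n_seizures < 1:
        raise UndefinedResultError("sensitivity undefined with zero seizures")
    return cohort.n_detected / cohort.n_seizures


def pooled_far(cohort: CohortScore) -> float:
    """False alarms per 24 h of wear, pooled over the cohort."""
    if cohort.hours <= 0:
        raise UndefinedResultError("FAR undefined with zero recording hours")
    return 24.0 * cohort.n_false_alarms / cohort.hours


@dataclass(frozen=True)
class LatencySummary:
    mean_s: float
    sd_s: float
    median_s: float
    n: int
    flags: tuple[str, ...] = ()


def latency_summary(cohort: CohortScore) -> LatencySummary:
    """Mean, sample SD and median of detection latencies, seconds.

    A single detection yields SD 0 with a flag rather than NaN.
    """
    lats = cohort.latencies
    if not lats:
        raise UndefinedResultError("no detections: latency summary undefined")
    mean, sd = _mean_sd(lats)
    ordered = sorted(lats)
    n = len(ordered)
    median = (
        ordered[n // 2]
        if n % 2 == 1
        else (ordered[n // 2 - 1] + ordered[n // 2]) / 2
    )
    flags = ("single_detection_sd_zero",) if n == 1 else ()
    return LatencySummary(mean_s=mean, sd_s=sd, median_s=median, n=n, flags=flags)


def cluster_outcomes(cohort: CohortScore):
    """Per-patient (events, detections) pairs for ICC/design-effect inference."""
    from .core import ClusterOutcome

    return [
        ClusterOutcome(s.patient_id, s.n_seizures, s.n_detected)
        for s in cohort.sessions
        if s.n_seizures >= 1
    ]


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def stratify_by_age(
    sessions: Sequence[RecordingSession], mode: Mode
) -> dict[AgeGroup, CohortScore]:
    """Disjoint, exhaustive pediatric/adult strata of scored sessions."""
    out: dict[AgeGroup, list[RecordingSession]] = {
        AgeGroup.PEDIATRIC: [],
        AgeGroup.ADULT: [],
    }
    for s in sessions:
        out[s.age_group].append(s)
    return {grp: score_cohort(sess, mode) for grp, sess in out.items()}


def _hours_in(intervals: Sequence[TimeInterval], within: Sequence[TimeInterval]) -> float:
    total = 0.0
    for a in intervals:
        for b in within:
            inter = a.intersection(b)
            if inter is not None:
                total += inter.duration_h
    return total


def _split_scored(
    scored: ScoredSession,
    session: RecordingSession,
    rest_intervals: Sequence[TimeInterval],
) -> tuple[ScoredSession, ScoredSession]:
    """Split one scored session into rest / active strata.

    Stratum membership: a seizure belongs to rest iff its clinical onset
    lies inside a rest interval; a false alarm by its timestamp; exposure
    hours by overlap of wear time with the rest intervals. Detection
    status and latency are decided globally, then assigned to a stratum.
    """
    rest_hours = _hours_in(session.wear_intervals, rest_intervals)
    active_hours = scored.hours - rest_hours

    def in_rest(ts) -> bool:
        return any(iv.contains(ts) for iv in rest_intervals)

    rest_out = [o for o in scored.seizure_outcomes if in_rest(o.interval.start)]
    act_out = [o for o in scored.seizure_outcomes if not in_rest(o.interval.start)]
    rest_fa = [t for t in scored.false_alarm_times if in_rest(t)]
    act_fa = [t for t in scored.false_alarm_times if not in_rest(t)]
    rest = ScoredSession(
        patient_id=scored.patient_id,
        hours=rest_hours,
        seizure_outcomes=rest_out,
        false_alarm_times=rest_fa,
        age_group=scored.age_group,
    )
    active = ScoredSession(
        patient_id=scored.patient_id,
        hours=max(0.0, active_hours),
        seizure_outcomes=act_out,
        false_alarm_times=act_fa,
        age_group=scored.age_group,
    )
    return rest, active


def stratify_by_rest(
    sessions: Sequence[RecordingSession],
    mode: Mode,
    rest_by_patient: Mapping[str, Sequence[TimeInterval]],
) -> dict[str, CohortScore]:
    """Rest vs active strata; keys ``"rest"`` and ``"active"``.

    Sessions without rest intervals contribute zero hours to the rest
    stratum. The two strata partition seizures, false alarms and hours.
    """
    rest_sessions, active_sessions = [], []
    for s in sessions:
        scored = score_session(s, mode)
        rest_ivs = list(rest_by_patient.get(s.patient_id, []))
        rest, active = _split_scored(scored, s, rest_ivs)
        rest_sessions.append(rest)
        active_sessions.append(active)
    return {"rest": CohortScore(rest_sessions), "active": CohortScore(active_sessions)}
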