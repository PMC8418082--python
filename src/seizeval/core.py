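"""Domain types and time conventions shared by all pipeline stages.

Conventions
-----------
* Timestamps are timezone-aware UTC :class:`datetime.datetime` objects
  (ISO 8601 on disk).
* Time intervals are half-open ``[start, end)`` so that an alarm raised
  exactly at a seizure offset is *not* inside the event and boundary
  alarms are never double counted.
* Durations are carried in seconds and converted to hours only at the
  reporting boundary.

The unit of the sensitivity denominator is the adjudicated
:class:`ConsensusSeizure`; the unit of bootstrap resampling for
false-alarm rates is the :class:`RecordingSession` (one patient's
monitored period).
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

UTC = _dt.timezone.utc

#: Minimum age covered by the device indication; younger patients are out
#: of indication and rejected at load time.
MIN_AGE_YEARS = 6
#: Oldest age counted as pediatric (inclusive); 21+ is adult.
MAX_PEDIATRIC_AGE_YEARS = 20


class OutOfIndicationError(ValueError):
    """Raised for patients outside the device's intended population."""


class UndefinedResultError(ValueError):
    """Raised when a statistic is requested on an empty denominator."""


class AgeGroup(str, enum.Enum):
    PEDIATRIC = "pediatric"
    ADULT = "adult"


class SeizureType(str, enum.Enum):
    """Seizure type vocabulary.

    GTC (generalized onset tonic-clonic) and FBTC (focal onset to
    bilateral tonic-clonic) are the convulsive types evaluated; any other
    annotated type is carried as OTHER and never reaches consensus.
    """

    GTC = "GTC"
    FBTC = "FBTC"
    OTHER = "OTHER"


#: Types that count as convulsive seizures (CS).
CONVULSIVE_TYPES = frozenset({SeizureType.GTC, SeizureType.FBTC})


class Device(str, enum.Enum):
    E4 = "E4"
    EMBRACE = "EMBRACE"


class Mode(str, enum.Enum):
    """Named operating modes of the decision rule.

    FDA_CLEARED is the high-sensitivity (lower threshold) configuration;
    ACTIVE trades sensitivity for a lower false-alarm burden.
    """

    FDA_CLEARED = "fda_cleared"
    ACTIVE = "active"


def ensure_utc(ts: _dt.datetime) -> _dt.datetime:
    """Validate that *ts* is timezone aware and return it in UTC."""
    if not isinstance(ts, _dt.datetime):
        raise TypeError(f"expected datetime, got {type(ts).__name__}")
    if ts.tzinfo is None:
        raise ValueError(f"naive timestamp not allowed: {ts!r}")
    return ts.astimezone(UTC)


def parse_timestamp(text: str) -> _dt.datetime:
    """Parse an ISO 8601 timestamp (``Z`` suffix accepted) into UTC."""
    ts = _dt.datetime.fromisoformat(str(text).replace("Z", "+00:00"))
    return ensure_utc(ts)


def format_timestamp(ts: _dt.datetime) -> str:
    return ensure_utc(ts).isoformat()


@dataclass(frozen=True, order=True)
class TimeInterval:
    """Half-open time interval ``[start, end)`` with ``end > start``."""

    start: _dt.datetime
    end: _dt.datetime

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", ensure_utc(self.start))
        object.__setattr__(self, "end", ensure_utc(self.end))
        if not self.end > self.start:
            raise ValueError(f"interval end must exceed start: {self}")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0

    def contains(self, ts: _dt.datetime) -> bool:
        ts = ensure_utc(ts)
        return self.start <= ts < self.end

    def overlaps(self, other: "TimeInterval") -> bool:
        return self.start < other.end and other.start < self.end

    def intersection(self, other: "TimeInterval") -> Optional["TimeInterval"]:
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        if hi > lo:
            return TimeInterval(lo, hi)
        return None


@dataclass(frozen=True)
class OperatingPoint:
    """A named decision-rule configuration (mode name + probability threshold)."""

    name: Mode
    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1): {self.threshold}")


@dataclass(frozen=True)
class ReviewerAnnotation:
    """One reviewer's labeling of one seizure event from v-EEG."""

    reviewer_id: str
    patient_id: str
    clinical_interval: TimeInterval
    seizure_type: SeizureType
    eeg_interval: Optional[TimeInterval] = None
    pges_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pges_duration_s is not None and self.pges_duration_s < 0:
            raise ValueError("pges_duration_s must be >= 0 when present")
        object.__setattr__(self, "seizure_type", SeizureType(self.seizure_type))


@dataclass(frozen=True)
class ConsensusSeizure:
    """An adjudicated convulsive seizure (>= 2 of 3 reviewers agree)."""

    patient_id: str
    clinical_interval: TimeInterval
    seizure_type: SeizureType
    n_supporting: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "seizure_type", SeizureType(self.seizure_type))
        if self.seizure_type not in CONVULSIVE_TYPES:
            raise ValueError(
                f"consensus seizures must be convulsive (GTC/FBTC), got {self.seizure_type}"
            )
        if self.n_supporting not in (2, 3):
            raise ValueError(f"n_supporting must be 2 or 3, got {self.n_supporting}")

    @property
    def duration_s(self) -> float:
        return self.clinical_interval.duration_s


@dataclass(frozen=True)
class Alarm:
    """A device alert issued at *timestamp* while operating in *mode*."""

    timestamp: _dt.datetime
    mode: Mode

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", ensure_utc(self.timestamp))
        object.__setattr__(self, "mode", Mode(self.mode))


@dataclass(frozen=True)
class ClusterOutcome:
    """Per-patient (events, detections) pair; the unit of ICC estimation."""

    patient_id: str
    n_events: int
    n_detected: int

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0 <= self.n_detected <= self.n_events:
            raise ValueError("need 0 <= n_detected <= n_events")


def derive_age_group(age_years: int) -> AgeGroup:
    """Map an enrollment age to the pediatric/adult stratum.

    Ages 6-20 inclusive are pediatric, 21+ adult; below 6 is outside the
    device indication and raises :class:`OutOfIndicationError`.
    """
    if age_years < MIN_AGE_YEARS:
        raise OutOfIndicationError(
            f"age {age_years} is below the minimum indicated age {MIN_AGE_YEARS}"
        )
    if age_years <= MAX_PEDIATRIC_AGE_YEARS:
        return AgeGroup.PEDIATRIC
    return AgeGroup.ADULT


def _check_disjoint(intervals: Sequence[TimeInterval], what: str) -> None:
    ordered = sorted(intervals, key=lambda iv: iv.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValueError(f"{what} overlap: {prev} and {cur}")


@dataclass
class RecordingSession:
    """One patient's monitored period: wear time, alarms, consensus seizures.

    Wear intervals must be pairwise disjoint and alarms must fall inside
    wear time (data errors are surfaced at construction, not dropped).
    """

    patient_id: str
    age_years: int
    device: Device
    wear_intervals: list[TimeInterval]
    alarms: list[Alarm] = field(default_factory=list)
    seizures: list[ConsensusSeizure] = field(default_factory=list)
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        self.device = Device(self.device)
        if not self.wear_intervals:
            raise ValueError(f"session {self.patient_id}: no wear intervals")
        _check_disjoint(self.wear_intervals, f"session {self.patient_id} wear intervals")
        self.wear_intervals = sorted(self.wear_intervals, key=lambda iv: iv.start)
        derive_age_group(self.age_years)  # validates the age floor
        for alarm in self.alarms:
            if not any(iv.contains(alarm.timestamp) for iv in self.wear_intervals):
                raise ValueError(
                    f"session {self.patient_id}: alarm at {alarm.timestamp.isoformat()}"
                    " outside wear intervals"
                )
        for sz in self.seizures:
            if sz.patient_id != self.patient_id:
                raise ValueError(
                    f"session {self.patient_id}: seizure from patient {sz.patient_id}"
                )

    @property
    def age_group(self) -> AgeGroup:
        return derive_age_group(self.age_years)

    @property
    def total_hours(self) -> float:
        return sum(iv.duration_h for iv in self.wear_intervals)

    def alarms_in_mode(self, mode: Mode) -> list[Alarm]:
        mode = Mode(mode)
        return [a for a in self.alarms if a.mode == mode]


def total_hours(session: RecordingSession) -> float:
    """Total worn hours of a session (sum of disjoint wear intervals)."""
    return session.total_hours


def cohort_hours(sessions: Sequence[RecordingSession]) -> float:
    return sum(s.total_hours for s in sessions)
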