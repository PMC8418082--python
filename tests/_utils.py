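"""Shared helpers for the test suite: compact interval/timestamp builders."""

import datetime as dt

from seizeval.core import (
    UTC,
    Alarm,
    ConsensusSeizure,
    Mode,
    RecordingSession,
    SeizureType,
    TimeInterval,
)

T0 = dt.datetime(2021, 1, 1, tzinfo=UTC)


def ts(seconds: float) -> dt.datetime:
    return T0 + dt.timedelta(seconds=seconds)


def iv(start_s: float, end_s: float) -> TimeInterval:
    return TimeInterval(ts(start_s), ts(end_s))


def iv_h(start_h: float, end_h: float) -> TimeInterval:
    return TimeInterval(T0 + dt.timedelta(hours=start_h), T0 + dt.timedelta(hours=end_h))


def make_session(
    patient_id="P0",
    age_years=30,
    wear=((0.0, 24.0),),
    alarm_s=(),
    seizure_s=(),
    mode=Mode.FDA_CLEARED,
):
    """Session with wear intervals in hours and alarm/seizure times in seconds."""
    seizures = [
        ConsensusSeizure(
            patient_id=patient_id,
            clinical_interval=iv(a, b),
            seizure_type=SeizureType.GTC,
            n_supporting=3,
        )
        for a, b in seizure_s
    ]
    alarms = [Alarm(ts(s), mode) for s in alarm_s]
    return RecordingSession(
        patient_id=patient_id,
        age_years=age_years,
        device="E4",
        wear_intervals=[iv_h(a, b) for a, b in wear],
        alarms=alarms,
        seizures=seizures,
    )
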