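"""Interchange formats: sessions.json, annotations.csv, alarms.csv, consensus.csv, rest.csv.

All timestamps are written as ISO 8601 UTC strings. Reading a cohort back
from the three event-level files yields sessions identical to the ones
written (round-trip identity), which the test suite asserts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core import (
    Alarm,
    ConsensusSeizure,
    Mode,
    RecordingSession,
    ReviewerAnnotation,
    SeizureType,
    TimeInterval,
    format_timestamp,
    parse_timestamp,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# sessions.json
# ---------------------------------------------------------------------------

def sessions_to_records(sessions: Sequence[RecordingSession]) -> list[dict]:
    records = []
    for s in sessions:
        records.append(
            {
                "patient_id": s.patient_id,
                "age_years": s.age_years,
                "sex": s.sex,
                "device": s.device.value,
                "wear_intervals": [
                    [format_timestamp(iv.start), format_timestamp(iv.end)]
                    for iv in s.wear_intervals
                ],
            }
        )
    return records


def write_sessions_json(sessions: Sequence[RecordingSession], path: PathLike) -> None:
    Path(path).write_text(json.dumps(sessions_to_records(sessions), indent=1) + "\n")


def read_sessions_json(path: PathLike) -> list[RecordingSession]:
    records = json.loads(Path(path).read_text())
    sessions = []
    for r in records:
        sessions.append(
            RecordingSession(
                patient_id=str(r["patient_id"]),
                age_years=int(r["age_years"]),
                device=r["device"],
                sex=r.get("sex"),
                wear_intervals=[
                    TimeInterval(parse_timestamp(a), parse_timestamp(b))
                    for a, b in r["wear_intervals"]
                ],
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# alarms.csv (patient_id, timestamp, mode)
# ---------------------------------------------------------------------------

def write_alarms_csv(
    alarms_by_patient: Mapping[str, Sequence[Alarm]], path: PathLike
) -> None:
    rows = [
        {
            "patient_id": pid,
            "timestamp": format_timestamp(a.timestamp),
            "mode": a.mode.value,
        }
        for pid, alarms in alarms_by_patient.items()
        for a in alarms
    ]
    pd.DataFrame(rows, columns=["patient_id", "timestamp", "mode"]).to_csv(
        path, index=False
    )


def read_alarms_csv(path: PathLike) -> dict[str, list[Alarm]]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    out: dict[str, list[Alarm]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.patient_id, []).append(
            Alarm(timestamp=parse_timestamp(row.timestamp), mode=Mode(row.mode))
        )
    return out


# ---------------------------------------------------------------------------
# consensus.csv (patient_id, onset, offset, type, n_supporting)
# ---------------------------------------------------------------------------

def write_consensus_csv(seizures: Sequence[ConsensusSeizure], path: PathLike) -> None:
    rows = [
        {
            "patient_id": sz.patient_id,
            "onset": format_timestamp(sz.clinical_interval.start),
            "offset": format_timestamp(sz.clinical_interval.end),
            "type": sz.seizure_type.value,
            "n_supporting": sz.n_supporting,
        }
        for sz in seizures
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "onset", "offset", "type", "n_supporting"]
    ).to_csv(path, index=False)


def read_consensus_csv(path: PathLike) -> list[ConsensusSeizure]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return [
        ConsensusSeizure(
            patient_id=row.patient_id,
            clinical_interval=TimeInterval(
                parse_timestamp(row.onset), parse_timestamp(row.offset)
            ),
            seizure_type=SeizureType(row.type),
            n_supporting=int(row.n_supporting),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# annotations.csv
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = [
    "reviewer_id",
    "patient_id",
    "clinical_onset",
    "clinical_offset",
    "eeg_onset",
    "eeg_offset",
    "seizure_type",
    "pges_s",
]


def write_annotations_csv(
    annotations: Sequence[ReviewerAnnotation], path: PathLike
) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "reviewer_id": a.reviewer_id,
                "patient_id": a.patient_id,
                "clinical_onset": format_timestamp(a.clinical_interval.start),
                "clinical_offset": format_timestamp(a.clinical_interval.end),
                "eeg_onset": format_timestamp(a.eeg_interval.start)
                if a.eeg_interval
                else "",
                "eeg_offset": format_timestamp(a.eeg_interval.end)
                if a.eeg_interval
                else "",
                "seizure_type": a.seizure_type.value,
                "pges_s": "" if a.pges_duration_s is None else a.pges_duration_s,
            }
        )
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, index=False)


def read_annotations_csv(path: PathLike) -> list[ReviewerAnnotation]:
    df = pd.read_csv(path, dtype={"patient_id": str, "reviewer_id": str})
    out = []
    for row in df.itertuples(index=False):
        eeg = None
        if isinstance(row.eeg_onset, str) and row.eeg_onset:
            eeg = TimeInterval(
                parse_timestamp(row.eeg_onset), parse_timestamp(row.eeg_offset)
            )
        pges = None if pd.isna(row.pges_s) else float(row.pges_s)
        out.append(
            ReviewerAnnotation(
                reviewer_id=row.reviewer_id,
                patient_id=row.patient_id,
                clinical_interval=TimeInterval(
                    parse_timestamp(row.clinical_onset),
                    parse_timestamp(row.clinical_offset),
                ),
                seizure_type=SeizureType(row.seizure_type),
                eeg_interval=eeg,
                pges_duration_s=pges,
            )
        )
    return out


# ---------------------------------------------------------------------------
# rest.csv (patient_id, onset, offset)
# ---------------------------------------------------------------------------

def write_rest_csv(
    rest_by_patient: Mapping[str, Sequence[TimeInterval]], path: PathLike
) -> None:
    rows = [
        {
            "patient_id": pid,
            "onset": format_timestamp(iv.start),
            "offset": format_timestamp(iv.end),
        }
        for pid, ivs in rest_by_patient.items()
        for iv in ivs
    ]
    pd.DataFrame(rows, columns=["patient_id", "onset", "offset"]).to_csv(
        path, index=False
    )


def read_rest_csv(path: PathLike) -> dict[str, list[TimeInterval]]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    out: dict[str, list[TimeInterval]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.patient_id, []).append(
            TimeInterval(parse_timestamp(row.onset), parse_timestamp(row.offset))
        )
    return out


# ---------------------------------------------------------------------------
# cohort round trip
# ---------------------------------------------------------------------------

def write_cohort(
    sessions: Sequence[RecordingSession],
    directory: PathLike,
    rest_by_patient: Optional[Mapping[str, Sequence[TimeInterval]]] = None,
) -> dict[str, Path]:
    """Write a full cohort (sessions + alarms + consensus [+ rest]) to *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "sessions": directory / "sessions.json",
        "alarms": directory / "alarms.csv",
        "consensus": directory / "consensus.csv",
    }
    write_sessions_json(sessions, paths["sessions"])
    write_alarms_csv({s.patient_id: s.alarms for s in sessions}, paths["alarms"])
    write_consensus_csv(
        [sz for s in sessions for sz in s.seizures], paths["consensus"]
    )
    if rest_by_patient is not None:
        paths["rest"] = directory / "rest.csv"
        write_rest_csv(rest_by_patient, paths["rest"])
    return paths


def read_cohort(directory: PathLike) -> list[RecordingSession]:
    """Read a cohort directory back into fully populated sessions."""
    directory = Path(directory)
    sessions = read_sessions_json(directory / "sessions.json")
    alarms_path = directory / "alarms.csv"
    consensus_path = directory / "consensus.csv"
    alarms = read_alarms_csv(alarms_path) if alarms_path.exists() else {}
    seizures: dict[str, list[ConsensusSeizure]] = {}
    if consensus_path.exists():
        for sz in read_consensus_csv(consensus_path):
            seizures.setdefault(sz.patient_id, []).append(sz)
    out = []
    for s in sessions:
        out.append(
            RecordingSession(
                patient_id=s.patient_id,
                age_years=s.age_years,
                device=s.device,
                sex=s.sex,
                wear_intervals=list(s.wear_intervals),
                alarms=alarms.get(s.patient_id, []),
                seizures=seizures.get(s.patient_id, []),
            )
        )
    return out
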