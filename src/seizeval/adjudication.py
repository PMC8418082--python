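"""Merge three independent reviewers' annotations under a 2-of-3 majority rule.

Three board-certified reviewers independently mark seizure onset/offset and
type from synchronized video-EEG. An event enters the reference standard
when annotations from at least ``min_supporting`` distinct reviewers
mutually overlap in time (any positive intersection, grouped by transitive
closure) and a majority agrees on a convulsive type. The consensus
interval pools the supporting annotations element-wise (median by default).
"""

from __future__ import annotations

import datetime as _dt
import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import (
    CONVULSIVE_TYPES,
    ConsensusSeizure,
    ReviewerAnnotation,
    SeizureType,
    TimeInterval,
    UTC,
)


class ConsensusTime(str, enum.Enum):
    MEDIAN = "median"
    EARLIEST = "earliest"


@dataclass(frozen=True)
class AdjudicationConfig:
    """Knobs of the majority rule.

    ``match_types`` controls whether reviewers must agree on the seizure
    *type* for their annotations to group (True), or only on presence,
    with the type then decided by majority within the group (False).
    """

    min_supporting: int = 2
    consensus_time: ConsensusTime = ConsensusTime.MEDIAN
    match_types: bool = True

    def __post_init__(self) -> None:
        if self.min_supporting not in (2, 3):
            raise ValueError("min_supporting must be 2 or 3")
        object.__setattr__(self, "consensus_time", ConsensusTime(self.consensus_time))


def _median_dt(stamps: Sequence[_dt.datetime]) -> _dt.datetime:
    """Element-wise median of datetimes (mean of the middle pair when even)."""
    ordered = sorted(stamps)
    n = len(ordered)
    if n % 2 == 1:
        return ordered[n // 2]
    a, b = ordered[n // 2 - 1], ordered[n // 2]
    return a + (b - a) / 2


def _consensus_interval(
    members: Sequence[ReviewerAnnotation], rule: ConsensusTime
) -> TimeInterval:
    starts = [m.clinical_interval.start for m in members]
    ends = [m.clinical_interval.end for m in members]
    if rule is ConsensusTime.MEDIAN:
        return TimeInterval(_median_dt(starts), _median_dt(ends))
    return TimeInterval(min(starts), min(ends))


def _overlap_groups(
    annotations: Sequence[ReviewerAnnotation],
) -> list[list[ReviewerAnnotation]]:
    """Group annotations by transitive closure of pairwise temporal overlap."""
    order = sorted(range(len(annotations)), key=lambda i: annotations[i].clinical_interval.start)
    groups: list[list[ReviewerAnnotation]] = []
    group_end: _dt.datetime | None = None
    for i in order:
        ann = annotations[i]
        iv = ann.clinical_interval
        # half-open intervals: touching endpoints do not overlap
        if group_end is not None and iv.start < group_end:
            groups[-1].append(ann)
            group_end = max(group_end, iv.end)
        else:
            groups.append([ann])
            group_end = iv.end
    return groups


def _validate(annotations: Sequence[ReviewerAnnotation]) -> None:
    reviewers = sorted({a.reviewer_id for a in annotations})
    if len(reviewers) > 3:
        raise ValueError(f"more than 3 reviewer_ids present: {reviewers}")
    per_reviewer: dict[tuple[str, str], list[ReviewerAnnotation]] = {}
    for a in annotations:
        per_reviewer.setdefault((a.reviewer_id, a.patient_id), []).append(a)
    for (rid, pid), anns in per_reviewer.items():
        ordered = sorted(anns, key=lambda a: a.clinical_interval.start)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.clinical_interval.start < prev.clinical_interval.end:
                raise ValueError(
                    f"reviewer {rid} has overlapping events for patient {pid}"
                )


def adjudicate(
    annotations: Iterable[ReviewerAnnotation],
    config: AdjudicationConfig | None = None,
) -> list[ConsensusSeizure]:
    """Produce the consensus seizure list from three reviewers' annotations.

    Only convulsive types (GTC/FBTC) can form a consensus event; OTHER
    annotations participate in grouping when ``match_types`` is False but
    never yield an output event. The output is sorted by onset and
    non-overlapping (cross-type collisions resolved in favor of the
    earlier onset, with a warning).
    """
    config = config or AdjudicationConfig()
    annotations = list(annotations)
    _validate(annotations)

    by_patient: dict[str, list[ReviewerAnnotation]] = {}
    for a in annotations:
        by_patient.setdefault(a.patient_id, []).append(a)

    consensus: list[ConsensusSeizure] = []
    for pid, anns in sorted(by_patient.items()):
        candidate_groups: list[list[ReviewerAnnotation]] = []
        if config.match_types:
            for stype in CONVULSIVE_TYPES:
                typed = [a for a in anns if a.seizure_type == stype]
                candidate_groups.extend(_overlap_groups(typed))
        else:
            candidate_groups.extend(_overlap_groups(anns))

        for group in candidate_groups:
            # majority type among the group (per-reviewer, one vote each)
            votes: dict[SeizureType, set[str]] = {}
            for a in group:
                votes.setdefault(a.seizure_type, set()).add(a.reviewer_id)
            stype, supporters = max(
                votes.items(), key=lambda kv: (len(kv[1]), kv[0].value)
            )
            if stype not in CONVULSIVE_TYPES:
                continue
            if len(supporters) < config.min_supporting:
                continue
            members = [a for a in group if a.seizure_type == stype]
            # one annotation per reviewer in a group by the non-overlap
            # precondition; guard anyway by keeping the earliest per reviewer
            seen: dict[str, ReviewerAnnotation] = {}
            for m in sorted(members, key=lambda a: a.clinical_interval.start):
                seen.setdefault(m.reviewer_id, m)
            members = list(seen.values())
            consensus.append(
                ConsensusSeizure(
                    patient_id=pid,
                    clinical_interval=_consensus_interval(
                        members, config.consensus_time
                    ),
                    seizure_type=stype,
                    n_supporting=len(members),
                )
            )

    consensus.sort(key=lambda sz: (sz.patient_id, sz.clinical_interval.start))
    # enforce non-overlapping output per patient (possible only across types)
    kept: list[ConsensusSeizure] = []
    for sz in consensus:
        if kept and kept[-1].patient_id == sz.patient_id and kept[
            -1
        ].clinical_interval.overlaps(sz.clinical_interval):
            warnings.warn(
                f"dropping consensus event overlapping an earlier one for "
                f"patient {sz.patient_id}",
                stacklevel=2,
            )
            continue
        kept.append(sz)
    return kept
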