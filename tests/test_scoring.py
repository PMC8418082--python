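import numpy as np
import pytest

from seizeval.core import Mode, UndefinedResultError
from seizeval.scoring import (
    CohortScore,
    ScoredSession,
    latency_summary,
    pooled_far,
    pooled_sensitivity,
    score_cohort,
    score_session,
    stratify_by_age,
    stratify_by_rest,
)
from seizeval.simulate import CohortGenParams, simulate_event_cohort

from _utils import iv, iv_h, make_session


def test_alarm_inside_seizure_is_tp_with_latency():
    s = make_session(alarm_s=(137.0, 150.0), seizure_s=((100.0, 180.0),))
    scored = score_session(s, Mode.FDA_CLEARED)
    assert scored.n_detected == 1
    assert scored.latencies == [37.0]
    assert scored.n_false_alarms == 0  # second alarm absorbed


def test_alarms_without_seizures_are_false_alarms():
    s = make_session(alarm_s=(100.0, 5000.0, 60000.0))
    scored = score_session(s, Mode.FDA_CLEARED)
    assert scored.n_detected == 0
    assert scored.n_false_alarms == 3


def test_pre_onset_alarm_is_a_false_alarm():
    s = make_session(alarm_s=(99.9,), seizure_s=((100.0, 180.0),))
    scored = score_session(s, Mode.FDA_CLEARED)
    assert scored.n_detected == 0
    assert scored.n_false_alarms == 1


def test_half_open_boundaries():
    at_onset = score_session(
        make_session(alarm_s=(100.0,), seizure_s=((100.0, 180.0),)), Mode.FDA_CLEARED
    )
    assert at_onset.n_detected == 1 and at_onset.latencies == [0.0]
    at_offset = score_session(
        make_session(alarm_s=(180.0,), seizure_s=((100.0, 180.0),)), Mode.FDA_CLEARED
    )
    assert at_offset.n_detected == 0 and at_offset.n_false_alarms == 1


def test_pooled_quantities():
    cohort = CohortScore(
        [
            ScoredSession("P0", hours=48.0, false_alarm_times=[]),
            ScoredSession("P1", hours=48.0, false_alarm_times=[]),
        ]
    )
    assert pooled_far(cohort) == 0.0
    with pytest.raises(UndefinedResultError):
        pooled_sensitivity(cohort)  # zero seizures
    zero = score_cohort(
        [make_session(seizure_s=((100.0, 180.0), (4000.0, 4100.0)))], Mode.FDA_CLEARED
    )
    assert pooled_sensitivity(zero) == 0.0


def test_far_is_exposure_homogeneous():
    base = [ScoredSession("P0", hours=24.0, false_alarm_times=[object()] * 6)]
    doubled = [ScoredSession("P0", hours=48.0, false_alarm_times=[object()] * 6)]
    assert pooled_far(CohortScore(doubled)) == pytest.approx(
        pooled_far(CohortScore(base)) / 2
    )


def test_latency_summary():
    from seizeval.scoring import SeizureOutcome

    cohort = CohortScore(
        [
            ScoredSession(
                "P0",
                hours=24.0,
                seizure_outcomes=[
                    SeizureOutcome(iv(1000 * k, 1000 * k + 90), "GTC", True, lat)
                    for k, lat in enumerate((30.0, 40.0, 50.0))
                ],
            )
        ]
    )
    summary = latency_summary(cohort)
    assert summary.mean_s == pytest.approx(40.0)
    assert summary.sd_s == pytest.approx(10.0)
    assert summary.median_s == pytest.approx(40.0)

    single = CohortScore(
        [
            score_session(
                make_session(alarm_s=(137.0,), seizure_s=((100.0, 180.0),)),
                Mode.FDA_CLEARED,
            )
        ]
    )
    s = latency_summary(single)
    assert s.sd_s == 0.0 and "single_detection_sd_zero" in s.flags

    with pytest.raises(UndefinedResultError):
        latency_summary(CohortScore([ScoredSession("P0", hours=1.0)]))


def test_rest_stratification_partitions_everything():
    # 24 h wear; rest covers hours 0-8; seizure onsets at 1 h (rest) and 12 h
    # (active); false alarms at 2 h (rest) and 20 h (active)
    s = make_session(
        alarm_s=(3600.0 + 40, 2 * 3600.0, 12 * 3600.0 + 40, 20 * 3600.0),
        seizure_s=((3600.0, 3600.0 + 90), (12 * 3600.0, 12 * 3600.0 + 90)),
    )
    rest = {"P0": [iv_h(0, 8)]}
    strata = stratify_by_rest([s], Mode.FDA_CLEARED, rest)
    r, a = strata["rest"], strata["active"]
    assert r.hours == pytest.approx(8.0) and a.hours == pytest.approx(16.0)
    assert r.n_seizures == 1 and a.n_seizures == 1
    assert r.n_detected == 1 and a.n_detected == 1
    assert r.n_false_alarms == 1 and a.n_false_alarms == 1


def test_rest_stratification_edge_cases():
    s = make_session(alarm_s=(5000.0,))
    none = stratify_by_rest([s], Mode.FDA_CLEARED, {})
    assert none["rest"].hours == 0.0
    assert none["active"].hours == pytest.approx(24.0)
    all_rest = stratify_by_rest([s], Mode.FDA_CLEARED, {"P0": [iv_h(0, 24)]})
    assert all_rest["active"].hours == pytest.approx(0.0)
    assert all_rest["rest"].n_false_alarms == 1


def test_strata_sum_to_overall_totals_on_simulated_cohort():
    sessions, truth = simulate_event_cohort(CohortGenParams(n_patients=30, seed=21))
    overall = score_cohort(sessions, Mode.FDA_CLEARED)
    by_age = stratify_by_age(sessions, Mode.FDA_CLEARED)
    for attr in ("n_seizures", "n_detected", "n_false_alarms", "hours"):
        got = sum(getattr(c, attr) for c in by_age.values())
        assert got == pytest.approx(getattr(overall, attr))
    by_rest = stratify_by_rest(sessions, Mode.FDA_CLEARED, truth.rest_by_patient)
    for attr in ("n_seizures", "n_detected", "n_false_alarms", "hours"):
        got = sum(getattr(c, attr) for c in by_rest.values())
        assert got == pytest.approx(getattr(overall, attr))


def _brute_force(session, mode):
    """Independent oracle: enumerate every (alarm, seizure) pair."""
    alarms = [a.timestamp for a in session.alarms if a.mode == mode]
    seizures = [sz.clinical_interval for sz in session.seizures]
    detected, latencies = 0, []
    for sz in seizures:
        hits = [t for t in alarms if sz.start <= t < sz.end]
        if hits:
            detected += 1
            latencies.append((min(hits) - sz.start).total_seconds())
    fa = [t for t in alarms if not any(sz.start <= t < sz.end for sz in seizures)]
    return detected, sorted(latencies), len(fa)


def test_matching_agrees_with_brute_force_oracle():
    rng = np.random.default_rng(17)
    for _ in range(300):
        n_sz = int(rng.integers(0, 6))
        onsets = np.sort(rng.uniform(0, 80000, n_sz))
        seizures = []
        last_end = -1.0
        for onset in onsets:
            onset = max(onset, last_end + 1.0)
            dur = float(rng.uniform(30, 200))
            seizures.append((onset, onset + dur))
            last_end = onset + dur
        alarms = tuple(float(t) for t in rng.uniform(0, 86000, int(rng.integers(0, 11))))
        s = make_session(alarm_s=alarms, seizure_s=tuple(seizures))
        scored = score_session(s, Mode.FDA_CLEARED)
        det, lats, fa = _brute_force(s, Mode.FDA_CLEARED)
        assert scored.n_detected == det
        assert sorted(scored.latencies) == pytest.approx(lats)
        assert scored.n_false_alarms == fa
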