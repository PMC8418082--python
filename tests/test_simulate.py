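import numpy as np
import pytest

from seizeval.adjudication import adjudicate
from seizeval.cluster_stats import icc_anova
from seizeval.core import Mode
from seizeval.detector import SurrogateDetector
from seizeval.rest import activity_counts, detect_rest
from seizeval.scoring import pooled_far, pooled_sensitivity, score_cohort
from seizeval.simulate import (
    CohortGenParams,
    SignalGenParams,
    reviewer_noise,
    simulate_event_cohort,
    simulate_signals,
)
from seizeval.io import sessions_to_records


def test_seed_determinism():
    params = CohortGenParams(n_patients=20, seed=77)
    s1, t1 = simulate_event_cohort(params)
    s2, t2 = simulate_event_cohort(params)
    assert sessions_to_records(s1) == sessions_to_records(s2)
    assert [s.alarms for s in s1] == [s.alarms for s in s2]
    assert [p.fa_rate_per_24h for p in t1.patients] == [
        p.fa_rate_per_24h for p in t2.patients
    ]
    s3, _ = simulate_event_cohort(CohortGenParams(n_patients=20, seed=78))
    assert [s.alarms for s in s1] != [s.alarms for s in s3]


def test_perfect_detector_no_false_alarms_end_to_end():
    params = CohortGenParams(
        n_patients=30, fa_rate_mean=0.0, detection_prob_mean=1.0, detection_icc=0.0,
        seed=5,
    )
    sessions, _ = simulate_event_cohort(params)
    cohort = score_cohort(sessions, Mode.FDA_CLEARED)
    assert cohort.n_seizures > 0
    assert pooled_sensitivity(cohort) == 1.0
    assert pooled_far(cohort) == 0.0


def test_generated_outcomes_match_ground_truth_when_scored():
    sessions, truth = simulate_event_cohort(CohortGenParams(n_patients=40, seed=9))
    cohort = score_cohort(sessions, Mode.FDA_CLEARED)
    by_pid = {s.patient_id: s for s in cohort.sessions}
    for p in truth.patients:
        scored = by_pid[p.patient_id]
        assert scored.n_seizures == p.n_events
        assert scored.n_detected == p.n_detected


def test_zero_icc_cohort_estimates_near_zero():
    params = CohortGenParams(
        n_patients=420, p_seizing=0.5, events_mean=2.5, detection_prob_mean=0.8,
        detection_icc=0.0, seed=31,
    )
    _, truth = simulate_event_cohort(params)
    outcomes = truth.cluster_outcomes
    assert len(outcomes) >= 150
    assert icc_anova(outcomes) == pytest.approx(0.0, abs=0.1)


def test_pooled_far_estimates_generator_mean_over_replicates():
    params_base = dict(n_patients=40, fa_rate_mean=0.83)
    estimates = []
    for seed in range(60):
        sessions, _ = simulate_event_cohort(CohortGenParams(seed=seed, **params_base))
        estimates.append(pooled_far(score_cohort(sessions, Mode.FDA_CLEARED)))
    mean = np.mean(estimates)
    mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(mean - 0.83) <= 2 * mc_se + 0.02


def test_reviewer_noise_identity_and_redundancy():
    sessions, _ = simulate_event_cohort(CohortGenParams(n_patients=25, seed=2))
    true_events = [sz for s in sessions for sz in s.seizures]
    assert true_events
    clean = reviewer_noise(true_events, jitter_sd_s=0.0, miss_prob=0.0, seed=0)
    consensus = adjudicate(clean)
    assert len(consensus) == len(true_events)
    got = {(sz.patient_id, sz.clinical_interval, sz.seizure_type) for sz in consensus}
    want = {(sz.patient_id, sz.clinical_interval, sz.seizure_type) for sz in true_events}
    assert got == want

    # one fully blind reviewer: 2-of-3 still recovers every event
    partial = reviewer_noise(true_events, 0.0, 0.0, seed=0, reviewer_ids=("R1", "R2"))
    assert len(adjudicate(partial)) == len(true_events)


def test_high_miss_rate_shrinks_consensus():
    sessions, _ = simulate_event_cohort(
        CohortGenParams(n_patients=60, p_seizing=0.8, events_mean=2.0, seed=3)
    )
    true_events = [sz for s in sessions for sz in s.seizures]
    noisy = reviewer_noise(true_events, jitter_sd_s=3.0, miss_prob=0.6, seed=1)
    consensus = adjudicate(noisy)
    # P(>= 2 of 3 reviewers see an event) = 3*0.4^2*0.6 + 0.4^3 = 0.352
    assert len(consensus) < len(true_events)
    assert len(consensus) == pytest.approx(0.352 * len(true_events), rel=0.35)


def test_all_rest_no_seizure_signal_is_one_rest_interval():
    rec = simulate_signals(
        SignalGenParams(duration_h=2.0, schedule=(("rest", 2.0),), seed=11)
    )
    counts = activity_counts(rec.acm, fs=rec.fs_acm)
    out = detect_rest(counts)
    assert len(out) == 1
    assert out[0].start_s == 0.0
    assert out[0].end_s == pytest.approx(2 * 3600.0, abs=60.0)


def test_injected_motif_detected_end_to_end():
    rec = simulate_signals(
        SignalGenParams(
            duration_h=0.5, schedule=(("rest", 0.5),), seizure_times_s=(600.0,), seed=12
        )
    )
    det = SurrogateDetector()
    alarms = det.alarms(rec.acm, rec.eda, Mode.FDA_CLEARED, rec.fs_acm, rec.fs_eda)
    detected, fa = det.counts_against_labels(alarms, rec.labels)
    assert detected == 1
    assert fa == 0


def test_seizure_outside_record_rejected():
    with pytest.raises(ValueError):
        simulate_signals(
            SignalGenParams(duration_h=0.1, seizure_times_s=(1000.0,), seed=1)
        )


def test_signal_determinism():
    params = SignalGenParams(duration_h=0.05, seed=42)
    a = simulate_signals(params)
    b = simulate_signals(params)
    assert np.array_equal(a.acm, b.acm)
    assert np.array_equal(a.eda, b.eda)
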