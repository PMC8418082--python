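import numpy as np
import pandas as pd
import pytest

from seizeval.rest import (
    RestConfig,
    RestInterval,
    activity_counts,
    detect_rest,
    rest_fraction,
    rest_summary,
)

FS = 32.0


def acm_from_mag(mag):
    # oscillation along the gravity axis so it survives in the magnitude
    # (motion orthogonal to gravity enters the magnitude only at second order)
    acm = np.zeros((len(mag), 3))
    acm[:, 2] = 1.0 + mag
    return acm


def test_constant_signal_yields_zero_counts():
    counts = activity_counts(acm_from_mag(np.zeros(int(FS * 120))))
    assert (counts == 0).all()
    assert len(counts) == 4


def test_sinusoid_crossings_per_epoch():
    # 1 Hz sinusoid at twice the crossing threshold: one upward crossing
    # per period -> 30 per 30-s epoch (band-pass ripple allows +/- 2)
    t = np.arange(int(FS * 300)) / FS
    counts = activity_counts(acm_from_mag(0.04 * np.sin(2 * np.pi * 1.0 * t)))
    inner = counts.iloc[1:-1]
    assert ((inner >= 28) & (inner <= 32)).all()


def test_out_of_band_component_is_attenuated():
    t = np.arange(int(FS * 300)) / FS
    counts = activity_counts(acm_from_mag(0.04 * np.sin(2 * np.pi * 10.0 * t)))
    # 10 Hz is far outside the 0.25-3 Hz band: essentially no crossings
    assert counts.mean() < 2


def _counts_series(blocks, epoch=30.0):
    """blocks: list of (level, n_epochs) -> Series indexed by epoch start."""
    values = np.concatenate([np.full(n, level, dtype=float) for level, n in blocks])
    return pd.Series(values, index=np.arange(len(values)) * epoch)


def test_uniformly_low_counts_one_interval():
    counts = _counts_series([(0.0, 480)])  # 4 h of quiet
    out = detect_rest(counts)
    assert len(out) == 1
    assert out[0].start_s == 0.0
    assert out[0].end_s == 480 * 30.0


def test_blocks_closer_than_merge_gap_are_merged():
    quiet, loud = 0.0, 100.0
    counts = _counts_series([(quiet, 240), (loud, 180), (quiet, 240)])  # 1.5 h gap
    out = detect_rest(counts)
    assert len(out) == 1


def test_blocks_farther_than_merge_gap_stay_separate():
    counts = _counts_series([(0.0, 240), (100.0, 360), (0.0, 240)])  # 3 h gap
    out = detect_rest(counts)
    assert len(out) == 2
    gap_h = (out[1].start_s - out[0].end_s) / 3600.0
    assert gap_h >= 2.0


def test_merge_closure_invariant():
    rng = np.random.default_rng(4)
    levels = rng.choice([0.0, 50.0], size=2000, p=[0.5, 0.5])
    out = detect_rest(pd.Series(levels, index=np.arange(2000) * 30.0))
    for a, b in zip(out, out[1:]):
        assert b.start_s - a.end_s >= 2 * 3600.0


def test_detection_is_idempotent_on_a_detected_interval():
    counts = _counts_series([(100.0, 120), (0.0, 480), (100.0, 120)])
    out = detect_rest(counts)
    assert len(out) == 1
    inner = counts[(counts.index >= out[0].start_s) & (counts.index < out[0].end_s)]
    again = detect_rest(inner)
    assert len(again) == 1
    assert again[0].start_s == out[0].start_s
    assert again[0].end_s == out[0].end_s


def test_lower_threshold_never_increases_rest_time():
    rng = np.random.default_rng(5)
    levels = rng.gamma(2.0, 5.0, size=1500)
    counts = pd.Series(levels, index=np.arange(1500) * 30.0)
    totals = []
    for thr in (20.0, 10.0, 5.0, 2.0):
        out = detect_rest(counts, RestConfig(rest_count_threshold=thr))
        totals.append(sum(iv.duration_s for iv in out))
    assert all(b <= a for a, b in zip(totals, totals[1:]))


def test_all_missing_counts_warns_and_returns_empty():
    counts = pd.Series(np.full(100, np.nan), index=np.arange(100) * 30.0)
    with pytest.warns(UserWarning):
        assert detect_rest(counts) == []


def test_rest_fraction_from_pooled_totals():
    assert rest_fraction(3995.0, 10296.0) == pytest.approx(0.388, abs=0.001)
    with pytest.raises(Exception):
        rest_fraction(1.0, 0.0)


def test_rest_summary_statistics():
    sessions = [
        [RestInterval(0.0, 7 * 3600.0, 1.0)],
        [RestInterval(0.0, 8 * 3600.0, 1.0), RestInterval(12 * 3600.0, 18 * 3600.0, 1.0)],
        [],
    ]
    wear = [24.0, 48.0, 24.0]
    summary = rest_summary(sessions, wear)
    assert summary.total_hours == pytest.approx(21.0)
    assert summary.fraction_of_wear == pytest.approx(21.0 / 96.0)
    assert summary.median_duration_h == pytest.approx(7.0)
    assert summary.median_periods_per_day == pytest.approx(1.0)

    empty = rest_summary([[], []], [24.0, 24.0])
    assert empty.total_hours == 0.0
    assert empty.median_duration_h is None
    assert "no_rest_detected" in empty.flags


def test_nightly_sleep_duration_recovered_from_counts():
    # 3 days with a 7 h quiet block per night
    rng = np.random.default_rng(6)
    blocks = []
    for _ in range(3):
        blocks.append((0.0, int(7 * 120)))  # 7 h quiet
        blocks.append((40.0, int(17 * 120)))  # 17 h active
    values = np.concatenate(
        [np.full(n, lv) + rng.uniform(0, 1, n) for lv, n in blocks]
    )
    counts = pd.Series(values, index=np.arange(len(values)) * 30.0)
    out = detect_rest(counts)
    assert len(out) == 3
    durations = [iv.duration_h for iv in out]
    assert np.median(durations) == pytest.approx(7.0, abs=0.5)
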