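"""Smoothing, segmentation, exponential fitting, gate, baseline correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alesense.preprocess import (
    PHASE_BATCH,
    PHASE_DRAIN,
    PHASE_REFILL,
    ProcessSeries,
    baseline_correct,
    fit_exponential,
    fit_exponential_joint,
    moving_average,
    quality_gate,
    segment_batches,
)
import pandas as pd


# ---------------------------------------------------------------- smoothing

def test_moving_average_constant_unchanged():
    np.testing.assert_allclose(moving_average(np.full(10, 3.3), 6), 3.3)


def test_moving_average_hand_computed():
    np.testing.assert_allclose(
        moving_average([0, 6, 0, 6, 0, 6], 2), [0, 3, 3, 3, 3, 3]
    )


def test_moving_average_window_one_is_identity():
    x = np.array([1.0, -2.0, 5.0])
    np.testing.assert_array_equal(moving_average(x, 1), x)


def test_moving_average_empty_series_errors():
    with pytest.raises(ValueError):
        moving_average([], 3)


@settings(max_examples=40, derandomize=True)
@given(shift=st.floats(-5, 5), window=st.integers(1, 8))
def test_moving_average_commutes_with_additive_shift(shift, window):
    rng = np.random.default_rng(7)
    x = rng.normal(size=30)
    np.testing.assert_allclose(
        moving_average(x + shift, window), moving_average(x, window) + shift,
        atol=1e-12,
    )


# ------------------------------------------------------------------ fitting

def test_fit_exponential_recovers_exact_parameters():
    t = np.arange(0, 3600, 15.0)
    y = 2.0 * np.exp(1e-4 * t) + 0.04
    fit = fit_exponential(t, y)
    assert fit.a == pytest.approx(2.0, rel=1e-6)
    assert fit.b == pytest.approx(1e-4, rel=1e-6)
    assert fit.c == pytest.approx(0.04, rel=1e-4)
    assert fit.r2 == pytest.approx(1.0, abs=1e-10)


def test_fit_exponential_on_noise_fails_gate(rng):
    t = np.arange(0, 4 * 3600, 15.0)
    fit = fit_exponential(t, rng.normal(0.04, 0.01, len(t)))
    assert fit.r2 < 0.98


def test_fit_exponential_constant_series_degenerate():
    t = np.arange(0, 600, 15.0)
    fit = fit_exponential(t, np.full(len(t), 0.2))
    assert fit.b == 0.0
    assert fit.r2 == 0.0


def test_fit_exponential_needs_four_samples():
    with pytest.raises(ValueError):
        fit_exponential([0, 15, 30], [1, 2, 3])


def test_fit_exponential_decreasing_trace():
    t = np.arange(0, 7200, 15.0)
    y = -1.5 * np.exp(2e-4 * t) + 20.9
    fit = fit_exponential(t, y)
    assert fit.a == pytest.approx(-1.5, rel=1e-5)
    assert fit.b == pytest.approx(2e-4, rel=1e-5)


def test_joint_fit_shares_rate_constant(rng):
    t = np.arange(0, 7200, 15.0)
    y1 = -1.5 * np.exp(1.6e-4 * t) + 20.9 + rng.normal(0, 0.02, len(t))
    y2 = 1.1 * np.exp(1.6e-4 * t) + 0.04 + rng.normal(0, 0.01, len(t))
    f1, f2 = fit_exponential_joint(t, y1, y2)
    assert f1.b == f2.b
    assert f1.b == pytest.approx(1.6e-4, rel=1e-2)


@pytest.mark.parametrize("r2, keep", [(0.99, True), (0.98, True), (0.97, False)])
def test_quality_gate_inclusive_boundary(r2, keep):
    fit = fit_exponential(np.arange(5) * 15.0, np.exp(np.arange(5) / 2))
    fit = type(fit)(a=fit.a, b=fit.b, c=fit.c, r2=r2, t0=fit.t0)
    assert quality_gate(fit) is keep


# -------------------------------------------------------- baseline correction

def test_baseline_correct_start_anchor_matches_shift_definition():
    t = np.arange(0, 600, 15.0)
    fit = fit_exponential(t, 0.02 * np.exp(1e-4 * t) + 0.04)  # f(0) = 0.06
    corrected = baseline_correct(fit, 0.04, anchor="start")
    assert corrected.predict(0.0) == pytest.approx(0.04, abs=1e-9)
    # whole curve shifted by -(f(0)-inflow); rate constant preserved
    np.testing.assert_allclose(corrected.predict(t), fit.predict(t) - 0.02,
                               atol=1e-9)
    assert corrected.b == fit.b


def test_baseline_correct_noop_when_already_anchored():
    t = np.arange(0, 600, 15.0)
    fit = fit_exponential(t, 0.02 * np.exp(1e-4 * t) + 0.04)
    same = baseline_correct(fit, fit.c, anchor="baseline")
    np.testing.assert_allclose(same.predict(t), fit.predict(t), atol=1e-12)


def test_baseline_correct_offset_anchor_sets_c():
    t = np.arange(0, 600, 15.0)
    fit = fit_exponential(t, 0.02 * np.exp(1e-4 * t) + 0.06)
    corrected = baseline_correct(fit, 0.04, anchor="baseline")
    assert corrected.c == pytest.approx(0.04, abs=1e-9)
    assert corrected.b == fit.b


# -------------------------------------------------------------- segmentation

def test_segmentation_matches_annotations_exactly(default_run):
    segs = segment_batches(default_run.series)
    batch_segs = [s for s in segs if s.phase == PHASE_BATCH]
    truth = default_run.batches
    assert len(batch_segs) == len(truth)
    for seg, (_, row) in zip(batch_segs, truth.iterrows()):
        assert seg.i_start == row.i_start
        assert seg.i_end == row.i_end
        assert seg.complete
    # segments tile the recording without gaps
    assert segs[0].i_start == 0
    for a, b in zip(segs, segs[1:]):
        assert a.i_end == b.i_start
    assert segs[-1].i_end == len(default_run.series)


def test_do_fallback_segmentation_close_to_truth(default_run):
    series = default_run.series
    stripped = ProcessSeries(
        t=series.t,
        data=series.data.drop(columns=["phase"]),
        metadata={},
    )
    segs = [s for s in segment_batches(stripped) if s.phase == PHASE_BATCH]
    truth = default_run.batches
    assert len(segs) == len(truth)
    for seg, (_, row) in zip(segs, truth.iterrows()):
        assert abs(seg.i_end - row.i_end) <= 6


def test_single_batch_without_trigger_is_flagged_incomplete():
    t = np.arange(0, 3600 * 2, 15.0)
    do = np.full(len(t), 50.0)  # never spikes
    series = ProcessSeries(t=t, data=pd.DataFrame({"do_pct": do}))
    segs = segment_batches(series)
    assert len(segs) == 1
    assert segs[0].phase == PHASE_BATCH
    assert not segs[0].complete


def test_no_spurious_split_while_do_high_early():
    """DO above threshold during the first hour must not end the batch."""
    t = np.arange(0, 3600 * 3, 15.0)
    do = np.where(t < 3600, 95.0, 40.0)  # high early, low afterwards
    series = ProcessSeries(t=t, data=pd.DataFrame({"do_pct": do}))
    segs = segment_batches(series)
    assert len(segs) == 1 and not segs[0].complete


def test_segmentation_requires_a_usable_channel():
    t = np.arange(0, 600, 15.0)
    series = ProcessSeries(t=t, data=pd.DataFrame({"ph": np.full(len(t), 7.0)}))
    with pytest.raises(ValueError):
        segment_batches(series)


def test_process_series_validates_grid():
    with pytest.raises(ValueError):
        ProcessSeries(t=np.array([0.0, 15.0, 45.0]),
                      data=pd.DataFrame({"do_pct": [1.0, 2.0, 3.0]}))
    with pytest.raises(ValueError):
        ProcessSeries(t=np.array([0.0, 15.0]),
                      data=pd.DataFrame({"do_pct": [1.0, 2.0, 3.0]}))
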