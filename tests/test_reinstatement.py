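"""Replay-rate metrics, the between-track difference regression, controls."""

import numpy as np
import pytest

from ratereplay.reinstatement import (RegressionFit, _KERNEL, fit_from_summary,
                                      peak_instantaneous_rate,
                                      reinstatement_regression,
                                      summarize_cell_rates,
                                      windowed_regressions)
from ratereplay.replay import CandidateEvent


# ---------------------------------------------------------------------------
# peak instantaneous rate
# ---------------------------------------------------------------------------

def test_single_spike_peak_matches_convolution_oracle():
    # direct oracle: 1 ms train with one spike, convolved with the window
    start, end = 0.0, 0.3
    spike_t = 0.15
    train = np.zeros(300)
    train[150] = 1.0
    oracle = (np.convolve(train, _KERNEL, mode="same") * 1000.0).max()
    got = peak_instantaneous_rate(np.array([spike_t]), start, end)
    assert got == pytest.approx(oracle, rel=1e-12)
    # the unit-sum window makes this 1000 * max(kernel)
    assert got == pytest.approx(1000.0 * _KERNEL.max(), rel=1e-12)


def test_coincident_spikes_double_the_peak():
    one = peak_instantaneous_rate(np.array([0.1]), 0.0, 0.2)
    two = peak_instantaneous_rate(np.array([0.1, 0.1]), 0.0, 0.2)
    assert two == pytest.approx(2 * one, rel=1e-12)


def test_distant_spikes_do_not_stack():
    one = peak_instantaneous_rate(np.array([0.1]), 0.0, 0.5)
    far = peak_instantaneous_rate(np.array([0.1, 0.4]), 0.0, 0.5)
    assert far == pytest.approx(one, rel=1e-9)  # kernels 300 ms apart


def test_zero_spikes_is_callers_contract_violation():
    with pytest.raises(ValueError):
        peak_instantaneous_rate(np.array([]), 0.0, 0.2)


# ---------------------------------------------------------------------------
# OLS regression
# ---------------------------------------------------------------------------

def test_exact_linear_data():
    fit = reinstatement_regression([-2, 0, 2], [-1, 0, 1])
    assert fit.B == pytest.approx(0.5)
    assert fit.r2 == pytest.approx(1.0)


def test_closed_form_worked_example():
    fit = reinstatement_regression([0, 1, 2], [0, 0, 3])
    assert fit.B == pytest.approx(1.5, abs=1e-10)
    assert fit.r2 == pytest.approx(0.75, abs=1e-10)
    assert fit.F == pytest.approx(3.0, abs=1e-10)
    assert fit.df == (1, 1)


def test_degenerate_predictor_and_small_n():
    with pytest.raises(ValueError, match="degenerate predictor"):
        reinstatement_regression([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
    with pytest.raises(ValueError):
        reinstatement_regression([0.0, 1.0], [0.0, 1.0])


# ---------------------------------------------------------------------------
# cell summaries
# ---------------------------------------------------------------------------

def _event(t0, cells, rng=None, dur=0.2):
    spikes = {cid: np.sort(np.linspace(t0 + 0.01, t0 + dur - 0.01, 3))
              for cid in cells}
    return CandidateEvent.from_spikes(t0, t0 + dur, spikes, epoch="POST")


def _field_stats(cells, peak1=5.0, peak2=3.0):
    return {(cid, tr): {"peak": peak1 if tr == 1 else peak2, "auc": 10.0}
            for cid in cells for tr in (1, 2)}


def test_cell_without_events_on_one_track_excluded():
    cells = ["a", "b", "c"]
    spikes = {cid: np.array([0.05, 1.05, 2.05]) for cid in cells}
    spikes["c"] = np.array([0.05])  # never fires in track-2 events
    ev1 = CandidateEvent.from_spikes(0.0, 0.2, spikes, epoch="POST")
    ev2 = CandidateEvent.from_spikes(1.0, 1.2, spikes, epoch="POST")
    ev3 = CandidateEvent.from_spikes(2.0, 2.2, spikes, epoch="POST")
    summary = summarize_cell_rates(spikes, {1: [ev1], 2: [ev2, ev3]},
                                   _field_stats(cells))
    row = summary[summary.cell_id == "c"].iloc[0]
    assert not row.included
    assert "participation" in row.reason
    assert summary[summary.cell_id == "a"].iloc[0].included


def test_low_field_peak_excluded():
    cells = ["a"]
    spikes = {"a": np.array([0.05, 1.05])}
    ev1 = CandidateEvent.from_spikes(0.0, 0.2, spikes, epoch="POST")
    ev2 = CandidateEvent.from_spikes(1.0, 1.2, spikes, epoch="POST")
    stats = _field_stats(cells, peak1=0.8, peak2=3.0)
    summary = summarize_cell_rates(spikes, {1: [ev1], 2: [ev2]}, stats)
    assert not summary.iloc[0].included
    assert "field peak" in summary.iloc[0].reason


def test_identical_event_sets_give_zero_diffs():
    cells = ["a", "b"]
    spikes = {cid: np.array([0.05, 0.10, 0.15]) for cid in cells}
    ev = CandidateEvent.from_spikes(0.0, 0.2, spikes, epoch="POST")
    summary = summarize_cell_rates(spikes, {1: [ev], 2: [ev]},
                                   _field_stats(cells, peak1=4.0, peak2=4.0))
    for m in ("peak_instantaneous_rate_diff", "median_rate_diff",
              "mean_spikes_diff", "field_peak_diff"):
        np.testing.assert_allclose(summary[m], 0.0)


def test_constant_rate_offset_cancels_in_diffs():
    """Adding a constant to both tracks' field peaks leaves the regression
    unchanged: the between-track differencing removes excitability offsets."""
    cells = [f"c{i}" for i in range(6)]
    rng = np.random.default_rng(0)
    spikes = {}
    evs1, evs2 = [], []
    for k in range(4):
        t0 = float(k)
        for cid in cells:
            n = rng.integers(1, 5)
            s = np.sort(rng.uniform(t0, t0 + 0.2, n))
            spikes.setdefault(cid, []).append(s)
        (evs1 if k % 2 == 0 else evs2).append((t0, t0 + 0.2))
    spikes = {cid: np.concatenate(v) for cid, v in spikes.items()}
    events = {1: [CandidateEvent.from_spikes(a, b, spikes, epoch="POST")
                  for a, b in evs1],
              2: [CandidateEvent.from_spikes(a, b, spikes, epoch="POST")
                  for a, b in evs2]}
    peaks = {cid: (2.0 + i, 3.0 + 0.5 * i) for i, cid in enumerate(cells)}
    stats = {(cid, tr): {"peak": peaks[cid][tr - 1], "auc": 1.0}
             for cid in cells for tr in (1, 2)}
    shifted = {(cid, tr): {"peak": peaks[cid][tr - 1] + 7.5, "auc": 1.0}
               for cid in cells for tr in (1, 2)}
    fit_a = fit_from_summary(summarize_cell_rates(spikes, events, stats))
    fit_b = fit_from_summary(summarize_cell_rates(spikes, events, shifted))
    assert fit_a.B == pytest.approx(fit_b.B, rel=1e-12)
    assert fit_a.F == pytest.approx(fit_b.F, rel=1e-9)


def test_blocks_mode_window_count():
    cells = [f"c{i}" for i in range(6)]
    rng = np.random.default_rng(1)
    spikes = {cid: [] for cid in cells}
    assigned = []
    for k in range(140):
        t0 = float(k)
        for cid in cells:
            spikes[cid].append(np.sort(rng.uniform(t0, t0 + 0.2, rng.integers(1, 4))))
    spikes = {cid: np.concatenate(v) for cid, v in spikes.items()}
    for k in range(140):
        ev = CandidateEvent.from_spikes(float(k), float(k) + 0.2, spikes,
                                        epoch="POST")
        assigned.append((ev, 1 if k % 2 == 0 else 2))
    stats = {(cid, tr): {"peak": 2.0 + i + tr, "auc": 1.0}
             for i, cid in enumerate(cells) for tr in (1, 2)}
    fits = windowed_regressions(assigned, spikes, stats, cells, mode="blocks",
                                block_size=70)
    assert len(fits) == 2  # 140 events -> exactly two 70-event blocks


def test_laps_mode_skips_underpowered_windows():
    cells = [f"c{i}" for i in range(3)]
    spikes = {cid: np.array([0.05]) for cid in cells}
    ev = CandidateEvent.from_spikes(0.0, 0.2, spikes, epoch="RUN1")
    ev.lap = 0
    stats = {(cid, tr): {"peak": 2.0, "auc": 1.0}
             for cid in cells for tr in (1, 2)}
    out = windowed_regressions([(ev, 1)], spikes, stats, cells, mode="laps")
    assert out[0]["fit"] is None
    assert "insufficient" in out[0]["reason"]
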