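"""Log odds, track-label shuffle z-scoring, manipulations, ROC, DeLong."""

import numpy as np
import pytest

from ratereplay.decoding import DecoderModel, PosteriorMatrix, decode_posterior
from ratereplay.sequenceless import (EventDecoding, apply_manipulation,
                                     compute_log_odds, delong_compare,
                                     rate_fixed_model, roc_auc,
                                     session_log_odds_significance,
                                     zscore_log_odds)
import pandas as pd


def _model(rates, tau=0.02):
    rates = np.asarray(rates, float)
    Pb = rates.shape[1] // 2
    return DecoderModel(rates=rates, cell_ids=list(range(rates.shape[0])),
                        track_of_bin=np.concatenate([np.ones(Pb, int),
                                                     np.full(Pb, 2, int)]),
                        bin_centers=np.concatenate([(np.arange(Pb) + .5) * 10] * 2),
                        tau=tau, bin_size=10.0)


def _posterior(p1, p2):
    prob = np.array([[p1], [p2]])
    return PosteriorMatrix(prob=prob, track_of_bin=np.array([1, 2]),
                           bin_centers=np.array([0.0, 0.0]))


def test_log_odds_symmetry_and_analytic_value():
    assert compute_log_odds(_posterior(0.5, 0.5)) == pytest.approx(0.0)
    assert compute_log_odds(_posterior(0.8, 0.2)) == pytest.approx(np.log(4))


def test_log_odds_antisymmetric_under_track_swap(rng):
    f = rng.uniform(0.01, 10.0, size=(5, 12))
    counts = rng.poisson(1.0, size=(5, 6)).astype(float)
    m = _model(f)
    swapped = m.with_rates(np.concatenate([f[:, 6:], f[:, :6]], axis=1))
    lo = compute_log_odds(decode_posterior(m, counts))
    lo_swapped = compute_log_odds(decode_posterior(swapped, counts))
    assert lo_swapped == pytest.approx(-lo, rel=1e-10)


def test_zscore_degenerate_when_tracks_identical(rng):
    half = rng.uniform(0.1, 5.0, size=(4, 6))
    m = _model(np.concatenate([half, half], axis=1))
    counts = rng.poisson(1.0, size=(4, 5)).astype(float)
    raw, z, shuffled, degen = zscore_log_odds(m, counts, n=100, seed=0)
    assert degen
    assert z == 0.0
    assert raw == pytest.approx(0.0, abs=1e-9)


def test_zscore_deterministic_per_seed(rng):
    f = rng.uniform(0.01, 10.0, size=(5, 12))
    m = _model(f)
    counts = rng.poisson(1.0, size=(5, 5)).astype(float)
    a = zscore_log_odds(m, counts, n=100, seed=3, key=7)
    b = zscore_log_odds(m, counts, n=100, seed=3, key=7)
    assert a[0] == b[0] and a[1] == b[1]


def test_rate_fixed_model_is_fixed_point_for_equal_peaks(rng):
    half = rng.uniform(0.1, 5.0, size=(3, 8))
    m = _model(np.concatenate([half, half * 2], axis=1))
    m_eq = _model(np.concatenate([half, half[:, ::-1]], axis=1))  # equal peaks
    fixed = rate_fixed_model(m_eq)
    np.testing.assert_allclose(fixed.rates, m_eq.rates, rtol=1e-12)
    # unequal peaks are rescaled so both tracks share the mean peak
    fixed2 = rate_fixed_model(m)
    raw = fixed2.rates - fixed2.rate_floor
    Pb = 8
    np.testing.assert_allclose(raw[:, :Pb].max(axis=1), raw[:, Pb:].max(axis=1),
                               rtol=1e-12)


def test_place_removed_is_timing_invariant(rng):
    """With one position bin per track and one time bin per event, permuting
    spike times within the event cannot change the log odds."""
    mean_rates = rng.uniform(0.5, 8.0, size=(6, 2))
    m = _model(rng.uniform(0.01, 10, size=(6, 12)))
    c1 = rng.poisson(1.0, size=(6, 10)).astype(float)
    c2 = np.stack([rng.permutation(row) for row in c1])  # same totals
    ev1 = EventDecoding(1, "POST", 1, c1, 0.2)
    ev2 = EventDecoding(1, "POST", 1, c2, 0.2)
    pairs = apply_manipulation(m, [ev1, ev2], "place_removed",
                               mean_rates=mean_rates)
    lo = [zscore_log_odds(mm, ee.counts, n=50, seed=0)[0] for mm, ee in pairs]
    assert lo[0] == pytest.approx(lo[1], rel=1e-12)


def test_rate_fixed_counts_flatten_per_event_rates(rng):
    """After the event-rate rescaling every cell fires at its own mean rate
    in every event it participates in: the across-event (and hence
    between-track) rate variation is removed."""
    from ratereplay.sequenceless import rate_fixed_counts
    base = [EventDecoding(k, "POST", 1,
                          rng.poisson(2.0, size=(4, 8)).astype(float) + 0.1,
                          0.16) for k in range(3)]
    fixed = rate_fixed_counts(base)
    rates = np.array([ev.counts.sum(axis=1) / ev.duration for ev in fixed])
    for cell_rates in rates.T:
        np.testing.assert_allclose(cell_rates, cell_rates[0], rtol=1e-10)


def test_negative_control_modes_run(rng):
    m = _model(rng.uniform(0.01, 10, size=(5, 12)))
    mean_rates = rng.uniform(0.5, 8.0, size=(5, 2))
    evs = [EventDecoding(k, "POST", 1 + k % 2,
                         rng.poisson(1.0, size=(5, 8)).astype(float), 0.16)
           for k in range(4)]
    for mode in ("rate_fixed_place_randomized", "place_removed_rate_randomized"):
        pairs = apply_manipulation(m, evs, mode, seed=1, mean_rates=mean_rates)
        assert len(pairs) == 4
        # originals untouched
        assert evs[0].counts.shape == (5, 8)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def test_auc_perfect_and_chance():
    roc = roc_auc(np.array([2.0, 3.0, 0.0, 1.0]),
                  np.array([True, True, False, False]), n_boot=50, seed=0)
    assert roc.auc == 1.0
    roc2 = roc_auc(np.array([1.0, 2.0, 1.0, 2.0]),
                   np.array([True, True, False, False]), n_boot=50, seed=0)
    assert roc2.auc == 0.5  # identical score multisets: half credit for ties


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    scores = rng.standard_normal(100)
    labels = rng.random(100) < 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    roc = roc_auc(scores, labels, n_boot=10, seed=0)
    assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_random_scores_near_chance(rng):
    scores = rng.standard_normal(200)
    labels = np.arange(200) % 2 == 0
    roc = roc_auc(scores, labels, n_boot=10, seed=0)
    assert 0.4 < roc.auc < 0.6


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc(np.array([1.0, 2.0]), np.array([True, True]), n_boot=10)


def test_roc_curve_monotone(rng):
    scores = rng.standard_normal(50)
    labels = rng.random(50) < 0.5
    labels[0], labels[1] = True, False
    roc = roc_auc(scores, labels, n_boot=10, seed=0)
    assert np.all(np.diff(roc.fpr) >= 0)
    assert np.all(np.diff(roc.tpr) >= 0)
    assert 0.0 <= roc.auc <= 1.0


def test_delong_self_comparison_is_null(rng):
    scores = rng.standard_normal(60)
    labels = np.arange(60) % 2 == 0
    roc = roc_auc(scores, labels, n_boot=200, seed=1)
    cmp = delong_compare(roc, roc)
    assert cmp.z == 0.0 and cmp.p == 1.0


def test_delong_antisymmetric_and_powered(rng):
    n = 200
    labels = np.arange(n) % 2 == 0
    sep = np.where(labels, 1.0, 0.0) + 0.1 * rng.standard_normal(n)
    rand = rng.standard_normal(n)
    idx = np.random.default_rng(5).integers(0, n, size=(500, n))
    ra = roc_auc(sep, labels, boot_indices=idx, boot_tag=9)
    rb = roc_auc(rand, labels, boot_indices=idx, boot_tag=9)
    ab = delong_compare(ra, rb)
    ba = delong_compare(rb, ra)
    assert ab.z == pytest.approx(-ba.z, rel=1e-12)
    assert ab.p < 0.05
    mismatched = roc_auc(rand, labels, n_boot=500, seed=2, boot_tag=10)
    with pytest.raises(ValueError, match="not aligned"):
        delong_compare(ra, mismatched)


def test_session_delta_sign_flips_with_labels(rng):
    z = rng.standard_normal(40) + np.where(np.arange(40) % 2 == 0, 1.0, 0.0)
    tr = np.where(np.arange(40) % 2 == 0, 1, 2)
    df = pd.DataFrame({"session": "s0", "event_id": np.arange(40),
                       "epoch": "POST", "track": tr, "manipulation": "original",
                       "raw": z, "z": z, "degenerate": False})
    res = session_log_odds_significance(df, n=200, seed=0)
    df_sw = df.copy()
    df_sw["track"] = 3 - df_sw["track"]
    res_sw = session_log_odds_significance(df_sw, n=200, seed=0)
    assert res_sw["mean_delta"] == pytest.approx(-res["mean_delta"], rel=1e-12)


def test_session_without_both_tracks_dropped():
    df = pd.DataFrame({"session": "s0", "event_id": [0, 1], "epoch": "POST",
                       "track": [1, 1], "manipulation": "original",
                       "raw": [0.1, 0.2], "z": [0.1, 0.2], "degenerate": False})
    with pytest.raises(ValueError):
        session_log_odds_significance(df)
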