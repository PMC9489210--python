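"""Replay detection: MUA/ripple traces, candidate filters, weighted
correlation, shuffle nulls, track assignment, rank order."""

import numpy as np
import pytest

from ratereplay import pipeline, replay
from ratereplay.decoding import DecoderModel
from ratereplay.replay import (CandidateEvent, SHUFFLE_MODES, assign_track,
                               compute_smoothed_mua, detect_candidate_events,
                               empirical_p, rank_order_score, ripple_power_z,
                               score_weighted_correlation,
                               shuffle_null_distribution, _null_scores)
from ratereplay.session import PositionTrace, child_rng


# ---------------------------------------------------------------------------
# MUA / ripple
# ---------------------------------------------------------------------------

def test_injected_burst_crosses_z3(rng):
    spikes = {f"c{i}": np.sort(rng.uniform(0, 10, 50)) for i in range(10)}
    burst = rng.uniform(5.0, 5.15, 400)  # 10x burst of 150 ms
    spikes["burst"] = np.sort(burst)
    t, z = compute_smoothed_mua(spikes, (0, 10))
    inside = (t >= 5.0) & (t <= 5.15)
    assert z[inside].max() > 3
    assert z[~inside].max() < z[inside].max()


def test_empty_epoch_mua_is_error():
    with pytest.raises(ValueError):
        compute_smoothed_mua({"a": np.array([])}, (0.0, 1.0))


def test_constant_ripple_power_z_is_zero():
    t = np.arange(0, 10, 0.004)
    z = ripple_power_z(t, np.full(t.size, 3.3))
    np.testing.assert_allclose(z, 0.0)


def test_rectangular_ripple_burst_localized(rng):
    t = np.arange(0, 60, 0.004)
    p = 1 + 0.3 * rng.standard_normal(t.size)
    burst = (t >= 30) & (t <= 30.2)
    p[burst] += 10
    z = ripple_power_z(t, p)
    pad = (t >= 29.8) & (t <= 30.4)  # allow smoothing spill-over
    assert z[burst].max() > 3
    assert z[~pad].max() < 3


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------

def _mua_with_bursts(bursts, total=10.0, dt=0.001):
    t = np.arange(0, total, dt) + dt / 2
    z = np.full(t.size, -0.5)
    for a, b in bursts:
        z[(t >= a) & (t < b)] = 5.0
    return t, z


def _quiet_position(total=10.0):
    t = np.arange(0, total, 0.025)
    return PositionTrace(t=t, x=np.zeros(t.size), track=np.zeros(t.size, int),
                         speed=np.zeros(t.size))


def _spikes(n_cells, interval, rng, rate=30.0):
    a, b = interval
    return {f"c{i}": np.sort(rng.uniform(a, b, max(1, int(rate * (b - a)))))
            for i in range(n_cells)}


def test_event_with_few_active_cells_rejected(rng):
    t, z = _mua_with_bursts([(5.0, 5.2)])
    spikes = _spikes(4, (5.0, 5.2), rng)
    evs = detect_candidate_events(t, z, _quiet_position(), spikes)
    assert evs == []
    spikes = _spikes(8, (5.0, 5.2), rng)
    evs = detect_candidate_events(t, z, _quiet_position(), spikes)
    assert len(evs) == 1 and evs[0].n_active == 8


def test_short_event_rejected(rng):
    t, z = _mua_with_bursts([(5.0, 5.09)])  # 90 ms
    spikes = _spikes(8, (5.0, 5.09), rng, rate=100)
    assert detect_candidate_events(t, z, _quiet_position(), spikes) == []


def test_nearby_bursts_merge(rng):
    # two bursts 30 ms apart combine into one 230 ms event
    t, z = _mua_with_bursts([(5.0, 5.1), (5.13, 5.23)])
    spikes = _spikes(8, (5.0, 5.23), rng)
    evs = detect_candidate_events(t, z, _quiet_position(), spikes)
    assert len(evs) == 1
    assert evs[0].duration == pytest.approx(0.23, abs=0.01)


def test_long_burst_not_a_seed(rng):
    t, z = _mua_with_bursts([(5.0, 5.4)])  # 400 ms > 300 ms max burst
    spikes = _spikes(8, (5.0, 5.4), rng)
    assert detect_candidate_events(t, z, _quiet_position(), spikes) == []


def test_moving_animal_rejected(rng):
    t, z = _mua_with_bursts([(5.0, 5.2)])
    pos = _quiet_position()
    pos.speed[:] = 10.0
    spikes = _spikes(8, (5.0, 5.2), rng)
    assert detect_candidate_events(t, z, pos, spikes) == []


# ---------------------------------------------------------------------------
# weighted correlation
# ---------------------------------------------------------------------------

def test_diagonal_posterior_scores_one():
    prob = np.eye(6) / 6
    assert score_weighted_correlation(prob) == pytest.approx(1.0)


def test_two_by_two_worked_example():
    prob = np.array([[0.4, 0.1], [0.1, 0.4]])
    assert score_weighted_correlation(prob) == pytest.approx(0.6, abs=1e-12)


def test_uniform_posterior_scores_zero_and_degenerate_is_nan():
    # uniform mass: cov(x, t) = 0 -> score 0, far from any null's tail
    prob = np.full((5, 4), 1 / 20)
    assert score_weighted_correlation(prob) == pytest.approx(0.0, abs=1e-12)
    # all mass in one position row: zero weighted variance -> undefined,
    # which routes to the not-significant path
    degenerate = np.zeros((5, 4))
    degenerate[2] = 0.25
    score = score_weighted_correlation(degenerate)
    assert np.isnan(score)
    assert empirical_p(score, np.array([0.1, 0.2])) == 1.0


def test_weighted_correlation_matches_triple_sum_oracle(rng):
    def oracle(prob):
        P, T = prob.shape
        tot = prob.sum()
        mx = sum(prob[i, j] * i for i in range(P) for j in range(T)) / tot
        mt = sum(prob[i, j] * j for i in range(P) for j in range(T)) / tot
        cxt = sum(prob[i, j] * (i - mx) * (j - mt)
                  for i in range(P) for j in range(T)) / tot
        cxx = sum(prob[i, j] * (i - mx) ** 2
                  for i in range(P) for j in range(T)) / tot
        ctt = sum(prob[i, j] * (j - mt) ** 2
                  for i in range(P) for j in range(T)) / tot
        return cxt / np.sqrt(cxx * ctt)

    for _ in range(50):
        prob = rng.uniform(0, 1, size=(rng.integers(2, 7), rng.integers(2, 7)))
        np.testing.assert_allclose(score_weighted_correlation(prob),
                                   oracle(prob), atol=1e-12)


# ---------------------------------------------------------------------------
# shuffles
# ---------------------------------------------------------------------------

class _IdentityRng:
    """Stub rng whose integer draws are all congruent to 0 mod the axis."""

    def integers(self, lo, hi, size=None):
        return np.full(size, hi)  # hi % axis_len == 0 for full-axis draws

    def random(self, size=None):
        return np.zeros(size)


def _toy_model(rng, C=6, Pb=10, tau=0.02):
    f = rng.uniform(0.01, 12.0, size=(C, 2 * Pb))
    track = np.concatenate([np.ones(Pb, int), np.full(Pb, 2, int)])
    centers = np.concatenate([(np.arange(Pb) + 0.5) * 10] * 2)
    return DecoderModel(rates=f, cell_ids=[f"c{i}" for i in range(C)],
                        track_of_bin=track, bin_centers=centers, tau=tau,
                        bin_size=10.0)


def test_identity_shifts_reproduce_original_score(rng):
    """Forcing every circular shift to a full revolution leaves each
    shuffle score equal to the observed score (mass conservation check)."""
    model = _toy_model(rng)
    counts = rng.poisson(1.5, size=(6, 8)).astype(float)
    from ratereplay.decoding import decode_posterior
    post = decode_posterior(model, counts)
    for mode in ("spike_train_circular", "place_field_shift"):
        null = _null_scores(model, counts, mode, 5, _IdentityRng())
        for tr in (1, 2):
            obs = score_weighted_correlation(post.prob[model.track_of_bin == tr])
            np.testing.assert_allclose(null[tr], obs, atol=1e-10)


def test_shuffle_scores_bounded_and_seeded(rng):
    model = _toy_model(rng)
    counts = rng.poisson(1.5, size=(6, 8)).astype(float)
    ev = CandidateEvent(start=1.0, end=1.16, epoch="POST", spikes={},
                        n_active=6)
    for mode in SHUFFLE_MODES:
        d1 = shuffle_null_distribution(ev, model, mode, n=50, seed=4,
                                       counts=counts)
        d2 = shuffle_null_distribution(ev, model, mode, n=50, seed=4,
                                       counts=counts)
        for tr in (1, 2):
            s = d1[tr].scores
            finite = s[np.isfinite(s)]
            assert np.all(np.abs(finite) <= 1 + 1e-12)
            np.testing.assert_array_equal(s, d2[tr].scores)


def test_empirical_p_never_zero(rng):
    null = rng.uniform(-1, 1, 999)
    p = empirical_p(2.0, null)  # observed beats every shuffle
    assert p == pytest.approx(1.0 / 1000.0)


# ---------------------------------------------------------------------------
# track assignment rules
# ---------------------------------------------------------------------------

def test_both_significant_low_bias_discarded():
    reg, lo = assign_track({1: True, 2: True}, {1: 0.55, 2: 0.45})
    assert reg is None and lo is None


def test_both_significant_high_bias_assigned_regression_only():
    reg, lo = assign_track({1: True, 2: True}, {1: 0.70, 2: 0.30})
    assert reg == 1 and lo is None


def test_single_track_assigned_to_both_cohorts():
    reg, lo = assign_track({1: False, 2: True}, {1: 0.2, 2: 0.8})
    assert reg == 2 and lo == 2


# ---------------------------------------------------------------------------
# rank order
# ---------------------------------------------------------------------------

def _ordered_event(order, t0=0.0):
    spikes = {f"c{i}": np.array([t0 + 0.02 * k]) for k, i in enumerate(order)}
    return CandidateEvent.from_spikes(t0, t0 + 0.02 * len(order) + 0.02,
                                      spikes, epoch="POST")


def test_rank_order_perfect_forward_and_reverse():
    loc = {f"c{i}": 10.0 * (i + 1) for i in range(5)}
    ev = _ordered_event([0, 1, 2, 3, 4])
    rho, p = rank_order_score(ev, loc, n_perm=200, seed=1)
    assert rho == pytest.approx(1.0)
    assert p < 0.05
    ev_rev = _ordered_event([4, 3, 2, 1, 0])
    rho_r, p_r = rank_order_score(ev_rev, loc, n_perm=200, seed=1)
    assert rho_r == pytest.approx(-1.0)
    assert p_r < 0.05


def test_rank_order_requires_five_cells():
    loc = {f"c{i}": 10.0 * i for i in range(4)}
    ev = _ordered_event([0, 1, 2, 3])
    with pytest.raises(ValueError, match="insufficient cells"):
        rank_order_score(ev, loc)
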