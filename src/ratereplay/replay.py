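"""Candidate replay-event detection, scoring and shuffle significance.

Candidates are multi-unit activity (MUA) bursts: the pooled 1 ms spike
histogram is Gaussian-smoothed (sigma = 5 ms) and z-scored; bursts above
z = 3 lasting at most 300 ms seed events, bursts within 50 ms are merged,
and surviving events must last 100-750 ms, contain at least five active
units, occur below 5 cm/s, and (when a ripple-power trace is available)
coincide with z > 3 ripple power after a 0.1 s moving average.

Each event is decoded in 20 ms bins and scored per track with the weighted
correlation between position and time under the posterior. Significance
requires the observed score to exceed the 95th percentile of each of three
1000-fold shuffle distributions (spike-train circular shift, place-field
circular shift, per-time-bin circular shift of the posterior). Every
candidate is additionally split at the MUA minimum in its middle third and
each qualifying half is tested at p < 0.025; an event counts as significant
for a track if the whole event or either half passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.stats import rankdata

from .config import DetectionConfig, ShuffleConfig
from .decoding import DecoderModel, PosteriorMatrix, bin_spike_counts, _softmax_columns
from .session import PositionTrace, child_rng

SHUFFLE_MODES = ("spike_train_circular", "place_field_shift", "posterior_circular")


@dataclass
class CandidateEvent:
    start: float
    end: float
    epoch: str
    spikes: dict  # cell_id -> spike times within [start, end]
    n_active: int
    peak_mua_z: float = np.nan
    peak_ripple_z: float = np.nan
    mua_t: Optional[np.ndarray] = None  # 1 ms grid inside the event
    mua_z: Optional[np.ndarray] = None
    lap: int = -1

    @property
    def duration(self) -> float:
        return self.end - self.start

    @classmethod
    def from_spikes(cls, start, end, spikes_by_cell, epoch="POST", **kw):
        inside = {
            cid: np.asarray(s)[(np.asarray(s) >= start) & (np.asarray(s) < end)]
            for cid, s in spikes_by_cell.items()
        }
        n_active = sum(1 for s in inside.values() if s.size > 0)
        return cls(start=start, end=end, epoch=epoch, spikes=inside,
                   n_active=n_active, **kw)

    def counts(self, cell_ids, tau: float):
        return bin_spike_counts(self.spikes, cell_ids, self.start, self.end, tau)


@dataclass
class ShuffleDistribution:
    mode: str
    scores: np.ndarray  # n_shuffles (per track handled by caller)
    seed: int


@dataclass
class ReplayResult:
    event: CandidateEvent
    score: dict  # track -> weighted correlation (whole event)
    p_values: dict  # (track, mode) -> p
    significant: dict  # track -> bool
    segment_passed: dict  # track -> set of segments that passed
    bayesian_bias: dict  # track -> share of summed posterior
    assigned_track: Optional[int]  # regression cohort (60% bias rule)
    assigned_track_logodds: Optional[int]  # both-track events excluded

    def to_row(self) -> dict:
        row = {
            "start": self.event.start, "end": self.event.end,
            "epoch": self.event.epoch, "lap": self.event.lap,
            "n_active": self.event.n_active,
        }
        for tr in (1, 2):
            row[f"score_T{tr}"] = self.score.get(tr, np.nan)
            for mode in SHUFFLE_MODES:
                row[f"p_{mode}_T{tr}"] = self.p_values.get((tr, mode), np.nan)
            row[f"significant_T{tr}"] = self.significant.get(tr, False)
            row[f"bias_T{tr}"] = self.bayesian_bias.get(tr, np.nan)
            row[f"segments_T{tr}"] = "+".join(sorted(self.segment_passed.get(tr, ())))
        row["assigned_track"] = self.assigned_track or 0
        row["assigned_track_logodds"] = self.assigned_track_logodds or 0
        return row


def results_to_frame(results: list[ReplayResult]) -> pd.DataFrame:
    if not results:
        cols = ["start", "end", "epoch", "lap", "n_active", "assigned_track",
                "assigned_track_logodds"]
        for tr in (1, 2):
            cols += [f"score_T{tr}"] + [f"p_{m}_T{tr}" for m in SHUFFLE_MODES] + \
                [f"significant_T{tr}", f"bias_T{tr}", f"segments_T{tr}"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.to_row() for r in results])


# ---------------------------------------------------------------------------
# MUA / ripple traces and candidate extraction
# ---------------------------------------------------------------------------

def compute_smoothed_mua(spikes_by_cell: dict, interval: tuple[float, float],
                         bin_ms: float = 1.0, sigma_ms: float = 5.0):
    """Z-scored, Gaussian-smoothed multi-unit rate on a 1 ms grid."""
    a, b = interval
    if not b > a:
        raise ValueError("empty epoch")
    dt = bin_ms / 1000.0
    edges = np.arange(a, b + dt / 2, dt)
    allspk = np.concatenate([np.asarray(s) for s in spikes_by_cell.values()]) \
        if spikes_by_cell else np.array([])
    allspk = allspk[(allspk >= a) & (allspk < edges[-1])]
    hist = np.histogram(allspk, bins=edges)[0].astype(float)
    if hist.sum() == 0:
        raise ValueError("no spikes in epoch: MUA z-score undefined")
    sm = gaussian_filter1d(hist, sigma_ms / bin_ms)
    sd = sm.std()
    if sd == 0:
        raise ValueError("constant MUA: z-score undefined")
    z = (sm - sm.mean()) / sd
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, z


def ripple_power_z(t: np.ndarray, power: np.ndarray,
                   window_s: float = 0.1) -> np.ndarray:
    """Moving-average-smoothed, z-scored ripple-band power."""
    dt = float(t[1] - t[0])
    w = max(1, int(round(window_s / dt)))
    sm = uniform_filter1d(np.asarray(power, float), size=w)
    sd = sm.std()
    if sd == 0:
        return np.zeros_like(sm)
    return (sm - sm.mean()) / sd


def detect_candidate_events(
    mua_t: np.ndarray,
    mua_z: np.ndarray,
    position: PositionTrace,
    spikes_by_cell: dict,
    ripple: Optional[tuple[np.ndarray, np.ndarray]] = None,
    cfg: DetectionConfig = None,
    epoch: str = "POST",
) -> list[CandidateEvent]:
    """MUA bursts filtered by duration, speed, participation and ripple power.

    ``ripple`` is an already z-scored (t, z) pair; when absent the ripple
    criterion is skipped (the analysis also supports the no-ripple variant).
    """
    cfg = cfg or DetectionConfig()
    dt = float(mua_t[1] - mua_t[0])
    above = mua_z > cfg.mua_z_threshold
    runs = _runs(above)
    # seed bursts: over-threshold stretches no longer than 300 ms
    bursts = [(i0, i1) for i0, i1 in runs
              if (i1 - i0) * dt <= cfg.max_burst_ms / 1000.0]
    merged = []
    for i0, i1 in bursts:
        if merged and (i0 - merged[-1][1]) * dt < cfg.merge_gap_ms / 1000.0:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    events = []
    rip_z = ripple[1] if ripple is not None else None
    rip_t = ripple[0] if ripple is not None else None
    for i0, i1 in merged:
        start, end = mua_t[i0] - dt / 2, mua_t[i1 - 1] + dt / 2
        dur = end - start
        if not (cfg.min_duration_ms / 1000.0 <= dur <= cfg.max_duration_ms / 1000.0):
            continue
        at = position.sample_at(np.array([start, 0.5 * (start + end), end]))
        if np.max(at["speed"]) >= cfg.max_speed_cm_s:
            continue
        ev = CandidateEvent.from_spikes(
            start, end, spikes_by_cell, epoch=epoch,
            peak_mua_z=float(mua_z[i0:i1].max()),
            mua_t=mua_t[i0:i1], mua_z=mua_z[i0:i1],
        )
        if ev.n_active < cfg.min_active_cells:
            continue
        if rip_z is not None and cfg.require_ripple:
            m = (rip_t >= start) & (rip_t <= end)
            ev.peak_ripple_z = float(rip_z[m].max()) if m.any() else -np.inf
            if ev.peak_ripple_z <= cfg.ripple_z_threshold:
                continue
        events.append(ev)
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# weighted correlation
# ---------------------------------------------------------------------------

def score_weighted_correlation(prob: np.ndarray) -> float:
    """Weighted correlation between position and time bins under ``prob``.

    Direct evaluation of the weighted mean / covariance / correlation sums
    with x and t the bin indices. Returns NaN when the total mass is zero or
    either marginal has zero weighted variance.
    """
    s = _stack_weighted_correlation(np.asarray(prob, float)[None])
    return float(s[0])


def _stack_weighted_correlation(w: np.ndarray) -> np.ndarray:
    """Vectorized weighted correlation over a stack (n, P, T)."""
    n, P, T = w.shape
    x = np.arange(P, dtype=float)
    t = np.arange(T, dtype=float)
    tot = w.sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = np.einsum("npt,p->n", w, x) / tot
        mt = np.einsum("npt,t->n", w, t) / tot
        cxt = np.einsum("npt,p,t->n", w, x, t) / tot - mx * mt
        cxx = np.einsum("npt,p->n", w, x * x) / tot - mx * mx
        ctt = np.einsum("npt,t->n", w, t * t) / tot - mt * mt
        denom = np.sqrt(cxx * ctt)
        r = np.where(denom > 0, cxt / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.where(tot > 0, r, np.nan)
    return r


# ---------------------------------------------------------------------------
# shuffles
# ---------------------------------------------------------------------------

def _score_tracks(prob: np.ndarray, track_of_bin: np.ndarray) -> dict[int, float]:
    return {tr: float(_stack_weighted_correlation(prob[None, track_of_bin == tr])[0])
            for tr in (1, 2)}


def _null_scores(model: DecoderModel, counts: np.ndarray, mode: str,
                 n: int, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Per-track null weighted-correlation scores for one shuffle mode.

    All three shuffles conserve mass: spike-train shifts preserve each
    cell's event spike count, place-field shifts preserve each map's values,
    and posterior shifts preserve each column's (and track block's) sum.
    """
    C, T = counts.shape
    P = model.n_bins
    lnf = np.log(np.maximum(model.rates, 1e-300))
    base = -model.tau * model.rates.sum(axis=0)  # (P,)

    if mode == "posterior_circular":
        prob = _softmax_columns(lnf.T @ counts + base[:, None])
        out = {}
        for tr in (1, 2):
            block = prob[model.track_of_bin == tr]  # (Pb, T)
            Pb = block.shape[0]
            shifts = rng.integers(0, Pb, size=(n, T))
            p_idx = (np.arange(Pb)[None, :, None] - shifts[:, None, :]) % Pb
            stack = np.take_along_axis(
                np.broadcast_to(block, (n, Pb, T)), p_idx, axis=1
            )
            out[tr] = _stack_weighted_correlation(stack)
        return out

    if mode == "spike_train_circular":
        active = np.flatnonzero(counts.sum(axis=1) > 0)
        shifts = rng.integers(1, max(T, 2), size=(n, C)) % T
        sel = counts[active]  # (A, T)
        t_idx = (np.arange(T)[None, None, :] - shifts[:, active, None]) % T
        counts_s = np.take_along_axis(
            np.broadcast_to(sel, (n, active.size, T)), t_idx, axis=2
        )
        ll = np.einsum("sat,ap->spt", counts_s, lnf[active]) + base[:, None]
        return _score_stack(ll, model.track_of_bin)

    if mode == "place_field_shift":
        # independent circular shift of each cell's each-track ratemap
        idx = np.broadcast_to(np.arange(P), (n, C, P)).copy()
        for tr in (1, 2):
            cols = np.flatnonzero(model.track_of_bin == tr)
            Pb = cols.size
            shifts = rng.integers(1, max(Pb, 2), size=(n, C)) % Pb
            local = (np.arange(Pb)[None, None, :] - shifts[:, :, None]) % Pb
            idx[:, :, cols] = cols[local]
        f_s = model.rates[np.arange(C)[None, :, None], idx]  # (n, C, P)
        lnf_s = lnf[np.arange(C)[None, :, None], idx]
        active = np.flatnonzero(counts.sum(axis=1) > 0)
        ll = np.einsum("scp,ct->spt", lnf_s[:, active], counts[active]) \
            - model.tau * f_s.sum(axis=1)[:, :, None]
        return _score_stack(ll, model.track_of_bin)

    raise ValueError(f"unknown shuffle mode {mode!r}")


def _score_stack(ll: np.ndarray, track_of_bin: np.ndarray) -> dict[int, np.ndarray]:
    m = ll.max(axis=1, keepdims=True)
    p = np.exp(ll - m)
    p /= p.sum(axis=1, keepdims=True)
    return {tr: _stack_weighted_correlation(p[:, track_of_bin == tr, :])
            for tr in (1, 2)}


def shuffle_null_distribution(event: CandidateEvent, model: DecoderModel,
                              mode: str, n: int = 1000, seed: int = 0,
                              counts: Optional[np.ndarray] = None,
                              rng: Optional[np.random.Generator] = None) -> dict[int, ShuffleDistribution]:
    """Null score distribution for one event under one shuffle mode."""
    if counts is None:
        counts, _ = event.counts(model.cell_ids, model.tau)
    if rng is None:
        rng = child_rng(seed, f"shuffle-{mode}", int(round(event.start * 1000)))
    null = _null_scores(model, counts, mode, n, rng)
    return {tr: ShuffleDistribution(mode=mode, scores=null[tr], seed=seed)
            for tr in (1, 2)}


def empirical_p(observed: float, null_scores: np.ndarray) -> float:
    """(1 + #{|shuffle| >= |observed|}) / (1 + n).

    The comparison is on magnitudes so forward and reverse trajectory sweeps
    are both detectable; NaN scores (degenerate posteriors) are never
    significant and NaN shuffles are excluded from the null.
    """
    if not np.isfinite(observed):
        return 1.0
    null = np.abs(null_scores[np.isfinite(null_scores)])
    return float(1 + np.sum(null >= abs(observed))) / (1 + null.size)


# ---------------------------------------------------------------------------
# event evaluation
# ---------------------------------------------------------------------------

def _segment_scores(model: DecoderModel, counts: np.ndarray, n_shuffles: int,
                    seed: int, key: int):
    prob = _softmax_columns(
        np.log(np.maximum(model.rates, 1e-300)).T @ counts
        - model.tau * model.rates.sum(axis=0)[:, None]
    )
    scores = _score_tracks(prob, model.track_of_bin)
    pvals = {}
    for mode in SHUFFLE_MODES:
        rng = child_rng(seed, f"shuffle-{mode}", key)
        null = _null_scores(model, counts, mode, n_shuffles, rng)
        for tr in (1, 2):
            pvals[(tr, mode)] = empirical_p(scores[tr], null[tr])
    return prob, scores, pvals


def _split_point(event: CandidateEvent) -> Optional[float]:
    """MUA minimum within the middle third of the event."""
    if event.mua_t is None or event.mua_z is None or event.mua_t.size < 3:
        return None
    d = event.duration
    lo, hi = event.start + d / 3.0, event.start + 2.0 * d / 3.0
    m = (event.mua_t >= lo) & (event.mua_t <= hi)
    if not m.any():
        return None
    return float(event.mua_t[m][np.argmin(event.mua_z[m])])


def evaluate_event(
    event: CandidateEvent,
    model: DecoderModel,
    cfg: ShuffleConfig = None,
    det: DetectionConfig = None,
    seed: int = 0,
    count_scale: Optional[np.ndarray] = None,
) -> ReplayResult:
    """Score one candidate: whole event at p < 0.05, MUA-split halves at
    p < 0.025, against all three shuffle nulls per track.

    ``count_scale`` (per-cell multiplicative factors on the 20 ms count
    matrix) supports the rate-randomizing re-detection controls. The
    Bayesian bias and track assignment follow the 60% rule for the
    regression cohort; events significant for both tracks are excluded from
    the log-odds cohort.
    """
    cfg = cfg or ShuffleConfig()
    det = det or DetectionConfig()
    counts, _ = event.counts(model.cell_ids, model.tau)
    if count_scale is not None:
        counts = counts * np.asarray(count_scale, float)[:, None]
    key = int(round(event.start * 1000))
    prob, scores, pvals = _segment_scores(model, counts, cfg.n_shuffles, seed, key)

    passed = {tr: set() for tr in (1, 2)}
    for tr in (1, 2):
        if all(pvals[(tr, m)] < cfg.alpha for m in SHUFFLE_MODES):
            passed[tr].add("whole")

    t_split = _split_point(event)
    if t_split is not None:
        halves = [(event.start, t_split, "first_half"),
                  (t_split, event.end, "second_half")]
        for a, b, name in halves:
            dur = b - a
            if not (det.min_duration_ms / 1000.0 <= dur
                    <= det.max_duration_ms / 1000.0):
                continue
            sub = CandidateEvent.from_spikes(a, b, event.spikes, epoch=event.epoch)
            if sub.n_active < det.min_active_cells:
                continue
            c_half, _ = sub.counts(model.cell_ids, model.tau)
            if c_half.shape[1] < 2:
                continue
            if count_scale is not None:
                c_half = c_half * np.asarray(count_scale, float)[:, None]
            _, s_half, p_half = _segment_scores(
                model, c_half, cfg.n_shuffles, seed, key + (1 if name == "first_half" else 2)
            )
            for tr in (1, 2):
                if all(p_half[(tr, m)] < cfg.alpha_split for m in SHUFFLE_MODES):
                    passed[tr].add(name)

    significant = {tr: len(passed[tr]) > 0 for tr in (1, 2)}
    tot = prob.sum()
    bias = {tr: float(prob[model.track_of_bin == tr].sum() / tot) for tr in (1, 2)}
    assigned, assigned_lo = assign_track(significant, bias, cfg.bias_threshold)
    return ReplayResult(
        event=event, score=scores, p_values=pvals, significant=significant,
        segment_passed=passed, bayesian_bias=bias,
        assigned_track=assigned, assigned_track_logodds=assigned_lo,
    )


def assign_track(significant: dict, bias: dict, bias_threshold: float = 0.60):
    """Track assignment for the two analysis cohorts.

    Regression cohort: a single-track-significant event gets that track; an
    event significant for both tracks is kept only if its Bayesian bias for
    the preferred track exceeds the threshold (60%), otherwise discarded.
    Log-odds cohort: both-track-significant events are excluded outright.
    Returns ``(regression_track, logodds_track)`` with None for excluded.
    """
    sig_tracks = [tr for tr in (1, 2) if significant.get(tr)]
    if len(sig_tracks) == 1:
        return sig_tracks[0], sig_tracks[0]
    if len(sig_tracks) == 2:
        best = max((1, 2), key=lambda tr: bias[tr])
        if bias[best] > bias_threshold:
            return best, None
    return None, None


# ---------------------------------------------------------------------------
# rank-order (Spearman) alternative
# ---------------------------------------------------------------------------

def rank_order_score(event: CandidateEvent, field_peak_loc: dict,
                     n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Spearman correlation between median spike times and field order.

    ``field_peak_loc`` maps cell_id -> field peak location (cm) on one
    track, restricted to cells with a field there. Significance comes from a
    within-event cell-identity permutation null (two-sided on |rho|, so
    forward and reverse sequences both count). Requires >= 5 participating
    cells.
    """
    cells = [cid for cid, s in event.spikes.items()
             if s.size > 0 and cid in field_peak_loc]
    if len(cells) < 5:
        raise ValueError("insufficient cells")
    med = np.array([np.median(event.spikes[cid]) for cid in cells])
    loc = np.array([field_peak_loc[cid] for cid in cells])
    rt = rankdata(med)
    rl = rankdata(loc)
    rho = _pearson(rt, rl)
    rng = child_rng(seed, "rank-order", int(round(event.start * 1000)))
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _pearson(rt, rl[rng.permutation(len(cells))])
    p = (1 + np.sum(np.abs(null) >= abs(rho))) / (1 + n_perm)
    return float(rho), float(p)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / den) if den > 0 else np.nan
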