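"""Sequenceless log-odds discrimination of replayed context.

For each replay event the posterior is summed over time and over each
track's position bins; the raw log odds ln(sum Prob(T1) / sum Prob(T2)) is
z-scored against a ratemap track-label shuffle (each cell independently
keeps or swaps its Track 1 / Track 2 ratemaps with probability 1/2, 1000
permutations, re-decoding each time). Information-restriction manipulations
(rate fixed, place removed, and their randomized negative controls) probe
which representation carries the context signal; session-level significance
uses the replay-track-identity shuffle with a one-tailed rank-sum test, and
binary discriminability is quantified by ROC/AUC with paired bootstrap and
DeLong comparisons.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, rankdata

from .decoding import DecoderModel, PosteriorMatrix, _softmax_columns
from .session import child_rng

MANIPULATIONS = (
    "original",
    "rate_fixed",
    "place_removed",
    "rate_fixed_place_randomized",
    "place_removed_rate_randomized",
)


@dataclass
class LogOddsRecord:
    event_id: int
    epoch: str
    true_track: int  # sequence-assigned track
    manipulation: str
    raw: float
    z: float
    shuffle_n: int
    degenerate: bool = False  # sd of the label shuffle was zero


# ---------------------------------------------------------------------------
# raw log odds and the track-label shuffle
# ---------------------------------------------------------------------------

def compute_log_odds(posterior: PosteriorMatrix, eps: float = 1e-300) -> float:
    """ln of the ratio of summed posterior probability, Track 1 over Track 2."""
    p1 = posterior.summed_probability(1)
    p2 = posterior.summed_probability(2)
    return float(np.log(max(p1, eps)) - np.log(max(p2, eps)))


def _cell_loglik(model: DecoderModel, counts: np.ndarray) -> np.ndarray:
    """Per-cell log-likelihood contributions, (cells, positions, time bins)."""
    lnf = np.log(np.maximum(model.rates, 1e-300))
    return counts[:, None, :] * lnf[:, :, None] - model.tau * model.rates[:, :, None]


def _swap_axis(model: DecoderModel) -> np.ndarray:
    """Index map exchanging the Track 1 and Track 2 position blocks."""
    n1 = int(np.sum(model.track_of_bin == 1))
    n2 = int(np.sum(model.track_of_bin == 2))
    if n1 != n2:
        raise ValueError("track blocks must have equal size for the label swap")
    return np.concatenate([np.arange(n1, n1 + n2), np.arange(n1)])


def zscore_log_odds(model: DecoderModel, counts: np.ndarray, n: int = 1000,
                    seed: int = 0, key: int = 0,
                    rng: Optional[np.random.Generator] = None):
    """Raw and z-scored log odds under the ratemap track-label shuffle.

    Each of ``n`` permutations independently keeps or swaps every cell's
    per-track ratemaps (probability 1/2) and re-decodes the event. When the
    shuffle distribution has zero spread (all cells' maps identical across
    tracks) z is defined as 0 and flagged.
    """
    rng = child_rng(seed, "label-shuffle", key) if rng is None else rng
    C = model.n_cells
    per_cell = _cell_loglik(model, counts)  # (C, P, T)
    total = per_cell.sum(axis=0)  # (P, T)
    raw = _log_odds_from_ll(total[None], model.track_of_bin)[0]

    swap = _swap_axis(model)
    delta = per_cell[:, swap, :] - per_cell  # (C, P, T)
    S = rng.random((n, C)) < 0.5
    ll = total[None] + np.einsum("sc,cpt->spt", S.astype(float), delta)
    shuffled = _log_odds_from_ll(ll, model.track_of_bin)
    mu, sd = float(shuffled.mean()), float(shuffled.std())
    degenerate = sd == 0.0
    z = 0.0 if degenerate else (raw - mu) / sd
    return float(raw), float(z), shuffled, degenerate


def _log_odds_from_ll(ll: np.ndarray, track_of_bin: np.ndarray) -> np.ndarray:
    """Log odds for a stack of log-likelihood matrices (n, P, T)."""
    m = ll.max(axis=1, keepdims=True)
    p = np.exp(ll - m)
    p /= p.sum(axis=1, keepdims=True)
    s1 = p[:, track_of_bin == 1, :].sum(axis=(1, 2))
    s2 = p[:, track_of_bin == 2, :].sum(axis=(1, 2))
    tiny = 1e-300
    return np.log(np.maximum(s1, tiny)) - np.log(np.maximum(s2, tiny))


# ---------------------------------------------------------------------------
# manipulations
# ---------------------------------------------------------------------------

@dataclass
class EventDecoding:
    """One event's inputs to the sequenceless analysis under a manipulation."""
    event_id: int
    epoch: str
    true_track: int
    counts: np.ndarray  # cells x time bins (real-valued after rescaling)
    duration: float


def rate_fixed_model(model: DecoderModel) -> DecoderModel:
    """Rescale each cell's per-track map so both peaks equal their mean."""
    raw = model.rates - model.rate_floor
    new = raw.copy()
    b1 = model.track_of_bin == 1
    b2 = model.track_of_bin == 2
    p1 = raw[:, b1].max(axis=1)
    p2 = raw[:, b2].max(axis=1)
    target = 0.5 * (p1 + p2)
    for b, pk in ((b1, p1), (b2, p2)):
        scale = np.where(pk > 0, target / np.where(pk > 0, pk, 1.0), 1.0)
        new[:, b] = raw[:, b] * scale[:, None]
    return model.with_rates(new + model.rate_floor)


def rate_fixed_counts(events: list[EventDecoding]) -> list[EventDecoding]:
    """Rescale each cell's spike count per event to its mean event rate."""
    C = events[0].counts.shape[0]
    rates = [[] for _ in range(C)]
    for ev in events:
        tot = ev.counts.sum(axis=1)
        for i in range(C):
            if tot[i] > 0:
                rates[i].append(tot[i] / ev.duration)
    mean_rate = np.array([np.mean(r) if r else 0.0 for r in rates])
    out = []
    for ev in events:
        tot = ev.counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(tot > 0, mean_rate * ev.duration / np.where(tot > 0, tot, 1.0), 1.0)
        out.append(EventDecoding(ev.event_id, ev.epoch, ev.true_track,
                                 ev.counts * scale[:, None], ev.duration))
    return out


def place_removed_model(mean_rates: np.ndarray, rate_floor: float = 0.01,
                        tau: float = 1.0) -> DecoderModel:
    """Single-position-bin-per-track decoder from per-track mean rates.

    ``mean_rates`` is (cells, 2): each cell's mean firing rate on each track
    while the animal ran above 5 cm/s.
    """
    return DecoderModel(
        rates=np.asarray(mean_rates, float) + rate_floor,
        cell_ids=list(range(mean_rates.shape[0])),
        track_of_bin=np.array([1, 2]),
        bin_centers=np.array([0.0, 0.0]),
        tau=tau, bin_size=0.0, rate_floor=rate_floor,
    )


def apply_manipulation(model: DecoderModel, events: list[EventDecoding],
                       mode: str, seed: int = 0,
                       mean_rates: Optional[np.ndarray] = None,
                       place_removed_base: Optional[DecoderModel] = None):
    """Return (per-event model, per-event EventDecoding list) for a mode.

    The original model and events are never mutated. ``place_removed``
    collapses decoding to one position bin per track (cells' speed-filtered
    mean rates) and one time bin per event, which makes the result exactly
    invariant to within-event spike timing.
    """
    rng = child_rng(seed, f"manipulation-{mode}")
    if mode == "original":
        return [(model, ev) for ev in events]
    if mode == "rate_fixed":
        m = rate_fixed_model(model)
        return [(m, ev) for ev in rate_fixed_counts(events)]
    if mode == "place_removed":
        if place_removed_base is None:
            if mean_rates is None:
                raise ValueError("place_removed requires mean_rates")
            place_removed_base = place_removed_model(mean_rates, model.rate_floor)
        out = []
        for ev in events:
            tot = ev.counts.sum(axis=1, keepdims=True)
            m = place_removed_base.with_tau(ev.duration)
            out.append((m, EventDecoding(ev.event_id, ev.epoch, ev.true_track,
                                         tot, ev.duration)))
        return out
    if mode == "rate_fixed_place_randomized":
        m = rate_fixed_model(model)
        fixed = rate_fixed_counts(events)
        out = []
        for ev in fixed:
            perm = rng.permutation(model.n_cells)  # cell ID shuffle per event
            out.append((m.with_rates(m.rates[perm]), ev))
        return out
    if mode == "place_removed_rate_randomized":
        if place_removed_base is None:
            if mean_rates is None:
                raise ValueError("place_removed requires mean_rates")
            place_removed_base = place_removed_model(mean_rates, model.rate_floor)
        raw = place_removed_base.rates - place_removed_base.rate_floor
        new = raw.copy()
        for col in (0, 1):
            pool = raw[:, col][raw[:, col] > 0]
            draws = rng.choice(pool, size=raw.shape[0], replace=True)
            new[:, col] = draws
        base = place_removed_base.with_rates(new + place_removed_base.rate_floor)
        out = []
        for ev in events:
            tot = ev.counts.sum(axis=1, keepdims=True)
            out.append((base.with_tau(ev.duration),
                        EventDecoding(ev.event_id, ev.epoch, ev.true_track,
                                      tot, ev.duration)))
        return out
    raise ValueError(f"unknown manipulation {mode!r}")


def score_pairs(pairs, mode: str, n_shuffles: int = 1000,
                seed: int = 0) -> list[LogOddsRecord]:
    records = []
    for m, ev in pairs:
        raw, z, _, degen = zscore_log_odds(m, ev.counts, n=n_shuffles,
                                           seed=seed, key=ev.event_id)
        records.append(LogOddsRecord(
            event_id=ev.event_id, epoch=ev.epoch, true_track=ev.true_track,
            manipulation=mode, raw=raw, z=z, shuffle_n=n_shuffles,
            degenerate=degen,
        ))
    return records


def records_to_frame(records: list[LogOddsRecord], session: str = "s0") -> pd.DataFrame:
    return pd.DataFrame([{
        "session": session, "event_id": r.event_id, "epoch": r.epoch,
        "track": r.true_track, "manipulation": r.manipulation,
        "raw": r.raw, "z": r.z, "degenerate": r.degenerate,
    } for r in records])


# ---------------------------------------------------------------------------
# session-level significance
# ---------------------------------------------------------------------------

def session_log_odds_significance(records: pd.DataFrame, n: int = 1000,
                                  seed: int = 0):
    """Mean z-scored log-odds track difference per session, with a pooled
    one-tailed rank-sum test against the replay-track-identity shuffle.

    Per session, Delta-z = mean z over Track 1 events minus mean z over
    Track 2 events. The null resamples each session's events with
    replacement ``n`` times, assigns track identities at random, and the
    across-session means of the shuffled differences form the comparison
    sample. Sessions lacking events of either track are dropped.
    """
    deltas = {}
    shuffled = {}
    for s, grp in records.groupby("session"):
        z = grp.z.to_numpy()
        tr = grp.track.to_numpy()
        if not ((tr == 1).any() and (tr == 2).any()):
            continue
        deltas[s] = float(z[tr == 1].mean() - z[tr == 2].mean())
        rng = child_rng(seed, "track-id-shuffle", zlib.crc32(str(s).encode()) % (2**31))
        idx = rng.integers(0, z.size, size=(n, z.size))
        lab = rng.random((n, z.size)) < 0.5
        zz = z[idx]
        with np.errstate(invalid="ignore"):
            m1 = np.where(lab, zz, np.nan)
            m2 = np.where(~lab, zz, np.nan)
            shuffled[s] = np.nanmean(m1, axis=1) - np.nanmean(m2, axis=1)
    if not deltas:
        raise ValueError("no session with events of both tracks")
    obs = np.array(list(deltas.values()))
    # variance-matched null: pool each session's shuffled differences
    null_pool = np.concatenate([shuffled[s][np.isfinite(shuffled[s])]
                                for s in deltas])
    stat, p = mannwhitneyu(obs, null_pool, alternative="greater")
    return {"per_session": deltas, "mean_delta": float(obs.mean()),
            "se_delta": float(obs.std(ddof=1) / np.sqrt(obs.size)) if obs.size > 1 else np.nan,
            "p": float(p), "null_pool": null_pool}


# ---------------------------------------------------------------------------
# ROC / AUC and DeLong comparison
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    scores: np.ndarray
    labels: np.ndarray  # True for Track 1
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    boot_aucs: np.ndarray
    boot_tag: int  # identifies the bootstrap index set for pairing


@dataclass
class RocComparison:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float


def _auc_rank(scores: np.ndarray, pos: np.ndarray) -> float:
    """Trapezoidal AUC via the rank statistic (half credit for ties)."""
    r = rankdata(scores)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    return (r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(scores: np.ndarray, labels: np.ndarray, n_boot: int = 1000,
            seed: int = 0, boot_indices: Optional[np.ndarray] = None,
            boot_tag: Optional[int] = None) -> RocCurve:
    """ROC curve by threshold sweep with trapezoidal AUC and bootstrap.

    ``labels`` marks Track 1 events (the positive class; higher scores mean
    a Track 1 bias). Bootstrap resamples (score, label) pairs with
    replacement; passing a shared ``boot_indices`` matrix keeps resamples
    aligned across conditions so DeLong comparisons can pair them.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
    tpr = np.array([(scores[pos] >= th).mean() for th in thresholds])
    fpr = np.array([(scores[~pos] >= th).mean() for th in thresholds])
    auc = _auc_rank(scores, pos)
    if boot_indices is None:
        rng = child_rng(seed, "roc-bootstrap")
        boot_indices = rng.integers(0, scores.size, size=(n_boot, scores.size))
        boot_tag = boot_tag if boot_tag is not None else seed
    boot = np.array([
        _auc_rank(scores[idx], pos[idx]) for idx in boot_indices
    ])
    return RocCurve(scores=scores, labels=pos, fpr=fpr, tpr=tpr, auc=float(auc),
                    boot_aucs=boot, boot_tag=0 if boot_tag is None else boot_tag)


def delong_compare(roc_a: RocCurve, roc_b: RocCurve) -> RocComparison:
    """Paired comparison of two AUCs.

    z = (AUC_A - AUC_B) / sqrt(var_A + var_B - 2 cov_AB), with variance and
    covariance estimated from the paired 1000-fold bootstrap AUC samples;
    two-tailed p from the normal tail. Identical inputs give z = 0, p = 1.
    """
    if roc_a.boot_aucs.size != roc_b.boot_aucs.size:
        raise ValueError("bootstrap samples are not aligned")
    if roc_a.boot_tag != roc_b.boot_tag:
        raise ValueError("bootstrap samples are not aligned (different index sets)")
    a = roc_a.boot_aucs
    b = roc_b.boot_aucs
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    cov = float(np.cov(a, b, ddof=1)[0, 1])
    denom = var_a + var_b - 2 * cov
    diff = roc_a.auc - roc_b.auc
    if denom <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(denom)
    p = 1.0 if z == 0 else float(2 * norm.sf(abs(z)))
    if np.isinf(z):
        p = 0.0
    return RocComparison(auc_a=roc_a.auc, auc_b=roc_b.auc, var_a=var_a,
                         var_b=var_b, cov_ab=cov, z=float(z), p=p)
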