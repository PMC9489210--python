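"""Two-track naive Bayes position decoding.

The posterior over position x given spike-count vector n in a window tau is

    P(x | n)  ∝  prod_i f_i(x)^{n_i} · exp(-tau · sum_i f_i(x))

with a uniform prior, evaluated in log space with per-column max subtraction,
and normalized so each time bin sums to 1 across the concatenated position
bins of BOTH tracks. A small rate floor (0.01 Hz, added when the model is
built) keeps the likelihood strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .session import PositionTrace


@dataclass
class DecoderModel:
    rates: np.ndarray  # cells x (nPos(T1) + nPos(T2)), Hz, floor applied
    cell_ids: list
    track_of_bin: np.ndarray  # 1 or 2 per concatenated bin
    bin_centers: np.ndarray  # cm within the bin's own track
    tau: float  # time-bin width, s
    bin_size: float  # cm
    rate_floor: float = 0.01

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("negative rates")

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    def track_slice(self, track: int) -> np.ndarray:
        return self.track_of_bin == track

    def with_rates(self, rates: np.ndarray) -> "DecoderModel":
        return replace(self, rates=np.asarray(rates, dtype=float))

    def with_tau(self, tau: float) -> "DecoderModel":
        return replace(self, tau=float(tau))

    @classmethod
    def from_ratemaps(cls, ratemaps: dict, cell_ids, *, tau: float,
                      bin_size: float = 10.0, rate_floor: float = 0.01,
                      sources=("whole",)) -> "DecoderModel":
        """Concatenate each cell's Track 1 and Track 2 unsmoothed maps.

        ``ratemaps`` maps (cell_id, track, source) -> Ratemap. The rate floor
        is added here, once, so downstream likelihoods are strictly positive.
        """
        src = sources[0]
        rows = []
        for cid in cell_ids:
            r1 = ratemaps[(cid, 1, src)].rate
            r2 = ratemaps[(cid, 2, src)].rate
            rows.append(np.concatenate([r1, r2]))
        rates = np.asarray(rows, dtype=float) + rate_floor
        n1 = ratemaps[(cell_ids[0], 1, src)].rate.size
        n2 = ratemaps[(cell_ids[0], 2, src)].rate.size
        track_of_bin = np.concatenate([np.ones(n1, int), np.full(n2, 2, int)])
        centers1 = (np.arange(n1) + 0.5) * bin_size
        centers2 = (np.arange(n2) + 0.5) * bin_size
        return cls(rates=rates, cell_ids=list(cell_ids),
                   track_of_bin=track_of_bin,
                   bin_centers=np.concatenate([centers1, centers2]),
                   tau=tau, bin_size=bin_size, rate_floor=rate_floor)


@dataclass
class PosteriorMatrix:
    prob: np.ndarray  # positions x time bins, columns sum to 1
    track_of_bin: np.ndarray
    bin_centers: np.ndarray
    time_edges: Optional[np.ndarray] = None  # len T+1, s

    @property
    def n_time_bins(self) -> int:
        return self.prob.shape[1]

    @property
    def time_centers(self) -> np.ndarray:
        return 0.5 * (self.time_edges[:-1] + self.time_edges[1:])

    def track_block(self, track: int) -> np.ndarray:
        return self.prob[self.track_of_bin == track]

    def summed_probability(self, track: int) -> float:
        return float(self.track_block(track).sum())


def log_likelihood(model: DecoderModel, counts: np.ndarray) -> np.ndarray:
    """Log likelihood over (position bins x time bins)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative spike counts")
    lnf = np.log(np.maximum(model.rates, 1e-300))
    return lnf.T @ counts - model.tau * model.rates.sum(axis=0)[:, None]


def decode_posterior(model: DecoderModel, counts: np.ndarray,
                     time_edges: Optional[np.ndarray] = None) -> PosteriorMatrix:
    """Column-normalized posterior across both tracks' position bins."""
    ll = log_likelihood(model, counts)
    prob = _softmax_columns(ll)
    return PosteriorMatrix(prob=prob, track_of_bin=model.track_of_bin,
                           bin_centers=model.bin_centers, time_edges=time_edges)


def _softmax_columns(ll: np.ndarray) -> np.ndarray:
    m = ll.max(axis=0, keepdims=True)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("all-zero likelihood column")
    p = np.exp(ll - m)
    return p / p.sum(axis=0, keepdims=True)


def bin_spike_counts(spikes_by_cell: dict, cell_ids, t0: float, t1: float,
                     tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Spike-count matrix on bins of exactly ``tau`` anchored at ``t0``.

    A trailing remainder shorter than ``tau`` is discarded.
    """
    n_bins = int(np.floor((t1 - t0) / tau + 1e-9))
    edges = t0 + tau * np.arange(n_bins + 1)
    counts = np.zeros((len(cell_ids), n_bins))
    for i, cid in enumerate(cell_ids):
        s = np.asarray(spikes_by_cell.get(cid, ()), dtype=float)
        s = s[(s >= t0) & (s < edges[-1])]
        if s.size:
            counts[i] = np.histogram(s, bins=edges)[0]
    return counts, edges


def _argmax_per_column(prob: np.ndarray) -> np.ndarray:
    # ties broken toward the lowest concatenated bin index (np.argmax rule)
    return prob.argmax(axis=0)


def decode_run_epoch(model: DecoderModel, session, track: int,
                     tau: float = 0.25) -> PosteriorMatrix:
    """Decode a RUN epoch at behavioral resolution."""
    a, b = session.epochs[f"RUN{track}"]
    spikes = session.epoch_spikes(f"RUN{track}")
    counts, edges = bin_spike_counts(spikes, model.cell_ids, a, b, tau)
    return decode_posterior(model.with_tau(tau), counts, time_edges=edges)


def _bin_truth(posterior: PosteriorMatrix, position: PositionTrace,
               speed_window=(4.0, 50.0)):
    tc = posterior.time_centers
    at = position.sample_at(tc)
    ok = (at["track"] > 0) & (at["speed"] >= speed_window[0]) & \
        (at["speed"] <= speed_window[1])
    return at, ok


def decoding_error_summary(posterior: PosteriorMatrix, position: PositionTrace,
                           speed_window=(4.0, 50.0)) -> dict[int, float]:
    """Median |decoded - true| position error (cm) per track.

    Behavioral time bins are kept when the animal is on a track within the
    run speed window; the error is defined for bins whose maximum-likelihood
    position lies on the true track.
    """
    at, ok = _bin_truth(posterior, position, speed_window)
    if not ok.any():
        raise ValueError("no RUN bins")
    idx = _argmax_per_column(posterior.prob)
    dec_track = posterior.track_of_bin[idx]
    dec_x = posterior.bin_centers[idx]
    out = {}
    for track in (1, 2):
        m = ok & (at["track"] == track) & (dec_track == track)
        out[track] = float(np.median(np.abs(dec_x[m] - at["x"][m]))) if m.any() else np.nan
    return out


def track_classification_accuracy(posterior: PosteriorMatrix,
                                  position: PositionTrace,
                                  speed_window=(4.0, 50.0)) -> dict[int, float]:
    """Fraction of qualifying time bins decoded to the animal's current track."""
    at, ok = _bin_truth(posterior, position, speed_window)
    if not ok.any():
        raise ValueError("no RUN bins")
    idx = _argmax_per_column(posterior.prob)
    dec_track = posterior.track_of_bin[idx]
    out = {}
    for track in (1, 2):
        m = ok & (at["track"] == track)
        out[track] = float(np.mean(dec_track[m] == track)) if m.any() else np.nan
    return out
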