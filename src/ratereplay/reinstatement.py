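"""Rate-reinstatement analysis: does a cell's between-track field-rate
difference predict its between-track replay-rate difference?

Per cell, the field side contributes the peak in-field firing rate (and the
field's trapezoidal area under the curve) on each track; the replay side
contributes, over the significant events assigned to each track in which the
cell fired at least one spike, (1) the mean peak instantaneous rate (1 ms
binned spike train filtered with a 100-ms Gaussian window, sigma = 20 ms),
(2) the median event rate (spikes / duration), and (3) the mean spike count
per event. Track 1 - Track 2 differences enter an ordinary least-squares
regression; between-track differencing removes slow per-cell excitability
offsets, so adding a constant to a cell's rates on both tracks leaves the
fit unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.signal.windows import gaussian as gaussian_window

from .config import RegressionConfig, ShuffleConfig, DetectionConfig
from .replay import CandidateEvent, ReplayResult, evaluate_event
from .session import child_rng

REPLAY_METRICS = ("peak_instantaneous_rate", "median_rate", "mean_spikes")
FIELD_METRICS = ("field_peak", "field_auc")


# ---------------------------------------------------------------------------
# per-event / per-cell rate metrics
# ---------------------------------------------------------------------------

def _smoothing_kernel() -> np.ndarray:
    # 100-ms-long Gaussian, sigma = 20 ms, on the 1 ms grid; unit sum so a
    # single spike integrates to one. 101 taps keeps the window symmetric
    # (zero-phase convolution; peak values are lag-invariant for symmetric
    # kernels).
    w = gaussian_window(101, std=20.0)
    return w / w.sum()


_KERNEL = _smoothing_kernel()


def peak_instantaneous_rate(spike_times: np.ndarray, start: float, end: float) -> float:
    """Peak of the smoothed instantaneous rate (Hz) within one event."""
    s = np.asarray(spike_times, dtype=float)
    s = s[(s >= start) & (s < end)]
    if s.size == 0:
        raise ValueError("peak_instantaneous_rate requires at least one spike")
    n_bins = max(1, int(np.ceil((end - start) / 0.001 - 1e-9)))
    idx = np.minimum(((s - start) / 0.001).astype(int), n_bins - 1)
    train = np.bincount(idx, minlength=n_bins).astype(float)
    inst = np.convolve(train, _KERNEL, mode="same") * 1000.0
    return float(inst.max())


@dataclass
class RegressionFit:
    B: float  # slope
    intercept: float
    F: float
    df: tuple[int, int]
    p: float
    r2: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "B": self.B, "intercept": self.intercept, "F": self.F,
            "df1": self.df[0], "df2": self.df[1], "p": self.p,
            "R2": self.r2, "n": self.n,
        }])


def summarize_cell_rates(
    cell_spikes: dict,
    events_by_track: dict[int, list[CandidateEvent]],
    field_stats: dict,
    cohort: Optional[list] = None,
    min_field_peak: float = 1.0,
) -> pd.DataFrame:
    """Per-cell field and replay rate metrics with Track 1 - Track 2 diffs.

    ``field_stats`` maps (cell_id, track) -> {"peak": Hz, "auc": Hz*cm}.
    Cells must participate (>= 1 spike) in at least one assigned event per
    track and have a field peak >= 1 Hz on both tracks; others are returned
    with ``included=False`` and a reason.
    """
    rows = []
    cells = cohort if cohort is not None else sorted(cell_spikes)
    for cid in cells:
        spk = np.asarray(cell_spikes[cid], dtype=float)
        row: dict = {"cell_id": cid, "included": True, "reason": ""}
        peaks = {tr: field_stats.get((cid, tr), {}).get("peak", 0.0) for tr in (1, 2)}
        aucs = {tr: field_stats.get((cid, tr), {}).get("auc", 0.0) for tr in (1, 2)}
        if min(peaks.values()) < min_field_peak:
            row["included"] = False
            row["reason"] = "field peak < 1 Hz on a track"
        per_track: dict[int, dict] = {}
        for tr in (1, 2):
            pis, rates, counts = [], [], []
            for ev in events_by_track.get(tr, ()):
                inside = spk[(spk >= ev.start) & (spk < ev.end)]
                if inside.size == 0:
                    continue
                pis.append(peak_instantaneous_rate(inside, ev.start, ev.end))
                rates.append(inside.size / ev.duration)
                counts.append(inside.size)
            per_track[tr] = {
                "n_events": len(counts),
                "peak_instantaneous_rate": float(np.mean(pis)) if pis else np.nan,
                "median_rate": float(np.median(rates)) if rates else np.nan,
                "mean_spikes": float(np.mean(counts)) if counts else np.nan,
            }
            row[f"n_events_T{tr}"] = len(counts)
            row[f"field_peak_T{tr}"] = peaks[tr]
            row[f"field_auc_T{tr}"] = aucs[tr]
            for m in REPLAY_METRICS:
                row[f"{m}_T{tr}"] = per_track[tr][m]
        if per_track[1]["n_events"] < 1 or per_track[2]["n_events"] < 1:
            row["included"] = False
            row["reason"] = (row["reason"] + "; " if row["reason"] else "") + \
                "no replay participation on a track"
        row["field_peak_diff"] = peaks[1] - peaks[2]
        row["field_auc_diff"] = aucs[1] - aucs[2]
        for m in REPLAY_METRICS:
            row[f"{m}_diff"] = per_track[1][m] - per_track[2][m]
        rows.append(row)
    return pd.DataFrame(rows)


def reinstatement_regression(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS of replay-rate diffs on field-rate diffs with an F-test of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        B=float(res.params[1]), intercept=float(res.params[0]),
        F=float(res.fvalue), df=(1, int(res.df_resid)),
        p=float(res.f_pvalue), r2=float(res.rsquared), n=int(x.size),
    )


def fit_from_summary(summary: pd.DataFrame,
                     replay_metric: str = "peak_instantaneous_rate",
                     field_metric: str = "field_peak") -> RegressionFit:
    inc = summary[summary.included]
    return reinstatement_regression(
        inc[f"{field_metric}_diff"].to_numpy(),
        inc[f"{replay_metric}_diff"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# rate-insensitive re-detection controls
# ---------------------------------------------------------------------------

def rate_insensitive_redetection(
    candidates: list[CandidateEvent],
    model,
    mode: str,
    cell_spikes: dict,
    field_stats: dict,
    cohort: list,
    seed: int = 0,
    shuffle_cfg: ShuffleConfig = None,
    det_cfg: DetectionConfig = None,
    min_field_peak: float = 1.0,
) -> tuple[list[ReplayResult], RegressionFit]:
    """Re-detect replay with rate-randomized inputs, then re-fit on originals.

    ``track_rate_shuffle`` rescales each decoder cell's per-track ratemap so
    its peak equals a draw (with replacement) from the cohort's empirical
    peak-rate distribution on that track; ``replay_rate_shuffle`` rescales
    each cell's event spike-count rows so its mean event rate equals a draw
    from the cohort's empirical mean-event-rate distribution. The re-detected
    significant events then enter the regression with the ORIGINAL spikes and
    ORIGINAL field peaks.
    """
    shuffle_cfg = shuffle_cfg or ShuffleConfig()
    det_cfg = det_cfg or DetectionConfig()
    rng = child_rng(seed, f"redetect-{mode}")
    count_scale = None
    model_used = model

    if mode == "track_rate_shuffle":
        raw = model.rates - model.rate_floor
        new = raw.copy()
        for tr in (1, 2):
            cols = model.track_of_bin == tr
            peaks = raw[:, cols].max(axis=1)
            pool = peaks[peaks > 0]
            draws = rng.choice(pool, size=model.n_cells, replace=True)
            scale = np.where(peaks > 0, draws / np.where(peaks > 0, peaks, 1.0), 1.0)
            new[:, cols] = raw[:, cols] * scale[:, None]
        model_used = model.with_rates(new + model.rate_floor)
    elif mode == "replay_rate_shuffle":
        mean_rates = _mean_event_rates(candidates, model.cell_ids)
        pool = mean_rates[mean_rates > 0]
        draws = rng.choice(pool, size=len(model.cell_ids), replace=True)
        count_scale = np.where(mean_rates > 0,
                               draws / np.where(mean_rates > 0, mean_rates, 1.0), 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    results = [
        evaluate_event(ev, model_used, cfg=shuffle_cfg, det=det_cfg, seed=seed,
                       count_scale=count_scale)
        for ev in candidates
    ]
    events_by_track = {tr: [r.event for r in results if r.assigned_track == tr]
                       for tr in (1, 2)}
    summary = summarize_cell_rates(cell_spikes, events_by_track, field_stats,
                                   cohort=cohort, min_field_peak=min_field_peak)
    fit = fit_from_summary(summary)
    return results, fit


def _mean_event_rates(candidates: list[CandidateEvent], cell_ids) -> np.ndarray:
    """Per-cell mean firing rate over the events in which the cell fired."""
    out = np.zeros(len(cell_ids))
    for i, cid in enumerate(cell_ids):
        rates = []
        for ev in candidates:
            s = ev.spikes.get(cid, np.array([]))
            if s.size:
                rates.append(s.size / ev.duration)
        out[i] = np.mean(rates) if rates else 0.0
    return out


# ---------------------------------------------------------------------------
# temporal analyses
# ---------------------------------------------------------------------------

def windowed_regressions(
    assigned_events: list[tuple[CandidateEvent, int]],
    cell_spikes: dict,
    field_stats: dict,
    cohort: list,
    mode: str = "blocks",
    block_size: int = 70,
    min_cells: int = 3,
    min_field_peak: float = 1.0,
) -> list[dict]:
    """Cumulative-by-lap or independent 70-event-block regressions.

    ``assigned_events`` pairs each significant event with its assigned
    track; events must be time-ordered. Cells re-qualify (>= 1 event per
    track) within every window; windows with fewer than ``min_cells``
    qualifying cells are reported as skipped.
    """
    out = []
    if mode == "blocks":
        windows = [
            (f"block{k}", assigned_events[k * block_size:(k + 1) * block_size])
            for k in range(len(assigned_events) // block_size)
        ]
    elif mode == "laps":
        laps = sorted({ev.lap for ev, _tr in assigned_events if ev.lap >= 0})
        windows = [
            (f"lap{lap}", [(ev, tr) for ev, tr in assigned_events
                           if 0 <= ev.lap <= lap])
            for lap in laps
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for name, evs in windows:
        by_track = {tr: [ev for ev, t in evs if t == tr] for tr in (1, 2)}
        summary = summarize_cell_rates(cell_spikes, by_track, field_stats,
                                       cohort=cohort, min_field_peak=min_field_peak)
        n_inc = int(summary.included.sum())
        if n_inc < min_cells:
            out.append({"window": name, "fit": None, "n_cells": n_inc,
                        "reason": "insufficient qualifying cells"})
            continue
        try:
            fit = fit_from_summary(summary)
        except ValueError as exc:
            out.append({"window": name, "fit": None, "n_cells": n_inc,
                        "reason": str(exc)})
            continue
        out.append({"window": name, "fit": fit, "n_cells": n_inc, "reason": ""})
    return out
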