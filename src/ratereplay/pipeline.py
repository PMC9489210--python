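"""End-to-end pipeline: ratemaps -> selection -> decoding -> candidate
detection -> replay significance -> rate-reinstatement regression -> log
odds -> ROC.

Each stage is reproducible given ``config.seed`` (stochastic stages derive
independent child streams keyed by stage name, so stage order does not
matter) and failures are re-raised with the stage name attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import decoding, placefields, replay, reinstatement, sequenceless
from .config import PipelineConfig
from .io import write_results
from .session import Session, child_rng


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    cell_labels: pd.DataFrame
    ratemaps: pd.DataFrame
    decoding_summary: pd.DataFrame
    replay_events: pd.DataFrame
    cell_rate_summary: pd.DataFrame
    regressions: pd.DataFrame
    log_odds: pd.DataFrame
    roc_summary: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def tables(self) -> dict:
        return {
            "cell_labels": self.cell_labels,
            "ratemaps": self.ratemaps,
            "decoding_summary": self.decoding_summary,
            "replay_events": self.replay_events,
            "cell_rate_summary": self.cell_rate_summary,
            "regressions": self.regressions,
            "log_odds": self.log_odds,
            "roc_summary": self.roc_summary,
        }

    def write(self, path) -> None:
        write_results(self.tables(), path)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:  # annotate and re-raise
                raise StageError(name, exc) from exc
        return wrapped
    return deco


# ---------------------------------------------------------------------------
# stage helpers (also used piecemeal by the CLI and the acceptance script)
# ---------------------------------------------------------------------------

def build_ratemaps(session: Session, config: PipelineConfig):
    return placefields.compute_session_ratemaps(
        session, bin_size=config.binning.pos_bin_cm,
        speed_window=(config.binning.run_speed_lo, config.binning.run_speed_hi),
    )


def build_decoder(session: Session, ratemaps, labels: pd.DataFrame,
                  config: PipelineConfig, cohort: str = "any_track"):
    """Decoder from place cells (field on >= 1 track) or the stable cohort."""
    if cohort == "any_track":
        keep = labels[labels.place_T1 | labels.place_T2].cell_id.tolist()
    elif cohort == "stable_both":
        keep = labels[labels.stable_both].cell_id.tolist()
    else:
        raise ValueError(cohort)
    if not keep:
        raise ValueError("no cells qualify for decoding")
    return decoding.DecoderModel.from_ratemaps(
        ratemaps, keep, tau=config.binning.tau_replay_s,
        bin_size=config.binning.pos_bin_cm,
        rate_floor=config.binning.rate_floor_hz,
    )


def field_statistics(ratemaps, labels: pd.DataFrame,
                     config: PipelineConfig) -> dict:
    """Per (cell, track): peak in-field rate and field AUC.

    The per-cell scalar is the global maximum of the unsmoothed map; the AUC
    is that of the detected field containing the peak (whole-map trapezoid
    when no field passes the detector).
    """
    stats = {}
    for cid in labels.cell_id:
        for tr in (1, 2):
            rm = ratemaps[(cid, tr, "whole")]
            fields = placefields.detect_fields(rm)
            peak = rm.peak_rate
            auc = float(np.trapezoid(rm.rate, dx=rm.bin_edges[1] - rm.bin_edges[0]))
            for f in fields:
                if f.extent[0] <= int(np.argmax(rm.rate)) <= f.extent[1]:
                    auc = f.auc
                    break
            stats[(cid, tr)] = {"peak": peak, "auc": auc}
    return stats


def detect_epoch_candidates(session: Session, epoch: str,
                            config: PipelineConfig) -> list:
    spikes = session.epoch_spikes(epoch)
    det = config.detection
    mua_t, mua_z = replay.compute_smoothed_mua(
        spikes, session.epochs[epoch], bin_ms=det.mua_bin_ms,
        sigma_ms=det.mua_sigma_ms,
    )
    ripple = None
    if session.ripple_power is not None:
        t, p = session.ripple_power
        a, b = session.epochs[epoch]
        m = (t >= a) & (t < b)
        if m.any():
            ripple = (t[m], replay.ripple_power_z(t[m], p[m], det.ripple_ma_window_s))
    events = replay.detect_candidate_events(
        mua_t, mua_z, session.position, spikes, ripple=ripple, cfg=det,
        epoch=epoch,
    )
    if epoch.startswith("RUN"):
        track = int(epoch[-1])
        laps = placefields.segment_laps(session.position, track,
                                        session.track_length)
        ends = np.array([b for _a, b in laps]) if laps else np.array([])
        for ev in events:
            ev.lap = int(np.searchsorted(ends, ev.start))
    return events


def mean_track_rates(session: Session, cell_ids,
                     speed_min: float = 5.0) -> np.ndarray:
    """(cells, 2) mean firing rate per track while speed > 5 cm/s."""
    pos = session.position
    out = np.zeros((len(cell_ids), 2))
    for j, tr in enumerate((1, 2)):
        m = (pos.track == tr) & (pos.speed > speed_min)
        dwell = m.sum() * pos.dt
        if dwell <= 0:
            continue
        for i, cid in enumerate(cell_ids):
            s = session.cell(cid).spikes
            at = pos.sample_at(s)
            out[i, j] = np.sum((at["track"] == tr) & (at["speed"] > speed_min)) / dwell
    return out


def ground_truth_candidates(session: Session, epoch: str) -> list[tuple]:
    """(CandidateEvent, true track) pairs from a synthetic session's truth.

    Used by recovery analyses that probe a downstream stage in isolation,
    bypassing MUA-based candidate extraction.
    """
    if session.ground_truth is None:
        raise ValueError("session has no ground truth")
    spikes = {c.cell_id: c.spikes for c in session.cells}
    gt = session.ground_truth.events
    out = []
    for _, row in gt[gt.epoch == epoch].iterrows():
        ev = replay.CandidateEvent.from_spikes(
            row.t_start, row.t_end, spikes, epoch=epoch,
            lap=int(row.lap) if "lap" in row else -1)
        out.append((ev, int(row.track)))
    return out


def match_to_truth(candidates: list, gt_events: pd.DataFrame) -> list:
    """True track per candidate by interval overlap (None if ambiguous)."""
    out = []
    for ev in candidates:
        m = (gt_events.t_start < ev.end) & (gt_events.t_end > ev.start)
        tracks = gt_events[m].track.unique()
        out.append(int(tracks[0]) if tracks.size == 1 else None)
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_full_pipeline(session: Session, config: PipelineConfig,
                      out_dir=None, session_id: str = "s0") -> ReportBundle:
    seed = config.seed

    ratemaps = _stage("ratemaps")(build_ratemaps)(session, config)
    labels = _stage("cell_selection")(placefields.select_place_cells)(
        session, ratemaps)
    fstats = _stage("field_statistics")(field_statistics)(
        ratemaps, labels, config)

    rm_rows = [
        {"cell_id": cid, "track": tr, "bin": i, "rate": r}
        for (cid, tr, src), rm in ratemaps.items() if src == "whole"
        for i, r in enumerate(rm.rate)
    ]
    ratemap_df = pd.DataFrame(rm_rows)

    model = _stage("decoder")(build_decoder)(session, ratemaps, labels, config)

    @_stage("run_decoding")
    def _run_decoding():
        rows = []
        for tr in (1, 2):
            post = decoding.decode_run_epoch(model, session, tr,
                                             tau=config.binning.tau_run_s)
            err = decoding.decoding_error_summary(post, session.position)
            acc = decoding.track_classification_accuracy(post, session.position)
            rows.append({"track": tr, "median_error_cm": err[tr],
                         "classification_accuracy": acc[tr]})
        return pd.DataFrame(rows)

    decoding_summary = _run_decoding()

    @_stage("replay_detection")
    def _replay():
        results = []
        for epoch in ("PRE", "RUN1", "RUN2", "POST"):
            candidates = detect_epoch_candidates(session, epoch, config)
            for ev in candidates:
                results.append(replay.evaluate_event(
                    ev, model, cfg=config.shuffles, det=config.detection,
                    seed=seed))
        return results

    results = _replay()
    replay_df = replay.results_to_frame(results)

    # local awake replay: content matches the track being run
    def _epoch_events(epoch_prefix: str, cohort: str = "regression"):
        attr = "assigned_track" if cohort == "regression" else "assigned_track_logodds"
        out = {1: [], 2: []}
        for r in results:
            tr = getattr(r, attr)
            if tr is None:
                continue
            if epoch_prefix == "RUN":
                if not r.event.epoch.startswith("RUN"):
                    continue
                if int(r.event.epoch[-1]) != tr:  # local only
                    continue
            elif r.event.epoch != epoch_prefix:
                continue
            out[tr].append(r.event)
        return out

    cohort = labels[labels.stable_both].cell_id.tolist()
    cell_spikes = {c.cell_id: c.spikes for c in session.cells}

    @_stage("rate_reinstatement")
    def _regressions():
        reg_rows = []
        summaries = []
        for epoch in ("PRE", "RUN", "POST"):
            by_track = _epoch_events(epoch)
            summary = reinstatement.summarize_cell_rates(
                cell_spikes, by_track, fstats, cohort=cohort,
                min_field_peak=config.regression.min_field_peak_hz)
            summary.insert(0, "epoch", epoch)
            summaries.append(summary)
            for metric in reinstatement.REPLAY_METRICS:
                try:
                    fit = reinstatement.fit_from_summary(summary, replay_metric=metric)
                except ValueError as exc:
                    reg_rows.append({"epoch": epoch, "metric": metric,
                                     "error": str(exc)})
                    continue
                reg_rows.append({"epoch": epoch, "metric": metric, "B": fit.B,
                                 "F": fit.F, "df1": fit.df[0], "df2": fit.df[1],
                                 "p": fit.p, "R2": fit.r2, "n": fit.n, "error": ""})
        return pd.DataFrame(reg_rows), pd.concat(summaries, ignore_index=True)

    regressions, cell_rate_summary = _regressions()

    @_stage("log_odds")
    def _log_odds():
        lo_model = build_decoder(session, ratemaps, labels, config,
                                 cohort="stable_both")
        mean_rates = mean_track_rates(session, lo_model.cell_ids)
        lo_cfg = config.logodds
        all_records = []
        roc_rows = []
        for epoch in ("PRE", "RUN", "POST"):
            by_track = _epoch_events(epoch, cohort="logodds")
            events = []
            eid = 0
            for tr in (1, 2):
                for ev in by_track[tr]:
                    counts, _ = ev.counts(lo_model.cell_ids, lo_model.tau)
                    if counts.shape[1] < 1:
                        continue
                    events.append(sequenceless.EventDecoding(
                        event_id=int(round(ev.start * 1000)), epoch=epoch,
                        true_track=tr, counts=counts, duration=ev.duration))
                    eid += 1
            if len(events) < 4 or len({e.true_track for e in events}) < 2:
                continue
            boot_rng = child_rng(seed, "roc-bootstrap-indices",
                                 {"PRE": 0, "RUN": 1, "POST": 2}[epoch])
            n_ev = len(events)
            boot_idx = boot_rng.integers(0, n_ev, size=(lo_cfg.n_bootstrap, n_ev))
            for mode in sequenceless.MANIPULATIONS:
                records = _score_manipulation(
                    lo_model, events, mode, mean_rates, lo_cfg, seed)
                all_records.append(sequenceless.records_to_frame(
                    records, session=session_id))
                z = np.array([r.z for r in records])
                lab = np.array([r.true_track == 1 for r in records])
                roc = sequenceless.roc_auc(z, lab, n_boot=lo_cfg.n_bootstrap,
                                           boot_indices=boot_idx,
                                           boot_tag={"PRE": 0, "RUN": 1, "POST": 2}[epoch])
                lo, hi = np.percentile(roc.boot_aucs[np.isfinite(roc.boot_aucs)],
                                       [2.5, 97.5])
                roc_rows.append({"epoch": epoch, "manipulation": mode,
                                 "auc": roc.auc, "auc_ci_lo": lo, "auc_ci_hi": hi,
                                 "n_events": n_ev})
        lo_df = pd.concat(all_records, ignore_index=True) if all_records else \
            pd.DataFrame(columns=["session", "event_id", "epoch", "track",
                                  "manipulation", "raw", "z", "degenerate"])
        return lo_df, pd.DataFrame(roc_rows)

    log_odds_df, roc_df = _log_odds()

    bundle = ReportBundle(
        cell_labels=labels, ratemaps=ratemap_df,
        decoding_summary=decoding_summary, replay_events=replay_df,
        cell_rate_summary=cell_rate_summary, regressions=regressions,
        log_odds=log_odds_df, roc_summary=roc_df,
        extras={"model": model, "results": results, "field_stats": fstats,
                "cohort": cohort, "ratemap_objects": ratemaps},
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _score_manipulation(model, events, mode, mean_rates, lo_cfg, seed):
    """Score one manipulation; negative controls run 10 times and report the
    run whose session-mean track difference is nearest the median."""
    def one(run_seed):
        pairs = sequenceless.apply_manipulation(
            model, events, mode, seed=run_seed, mean_rates=mean_rates)
        return sequenceless.score_pairs(pairs, mode,
                                        n_shuffles=lo_cfg.n_label_shuffles,
                                        seed=run_seed)

    if mode in ("rate_fixed_place_randomized", "place_removed_rate_randomized"):
        runs = [one(seed + 1000 * (k + 1)) for k in range(lo_cfg.n_negative_control_runs)]
        deltas = []
        for rec in runs:
            z = np.array([r.z for r in rec])
            t = np.array([r.true_track for r in rec])
            deltas.append(z[t == 1].mean() - z[t == 2].mean())
        order = np.argsort(deltas)
        median_run = order[len(order) // 2]
        return runs[median_run]
    return one(seed)
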