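"""Synthetic two-track session generator.

Emulates the statistical structure the replay analyses assume: two 2 m linear
tracks with globally remapped Gaussian place fields, per-cell peak-rate
modulation between tracks, inhomogeneous-Poisson run spiking over
back-and-forth laps, and rest-epoch replay events in which a virtual position
sweeps along a track in 20 ms steps at a configurable compression. The degree
to which a cell's between-track field-rate difference is reinstated in its
replay rates is controlled by ``reinstatement_slope`` (0 = null, 1 = full
reinstatement). PRE events are built identically but with per-cell intensity
profiles assigned through a fresh random cell-identity permutation, so
neither sequence nor rate structure matches the cells' own fields.

Ripple-band power is generated directly as a power trace with bursts
co-located with each replay event; raw LFP synthesis is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session import CellRecord, GroundTruth, PositionTrace, Session, child_rng

TIME_BIN_S = 0.02  # replay sweep step


@dataclass
class SimConfig:
    seed: int = 0
    n_cells: int = 50
    track_length_cm: float = 200.0
    # Gaussian field model
    field_sigma_cm: float = 15.0
    peak_rate_log_mean: float = float(np.log(8.0))  # log-normal peak rates, Hz
    peak_rate_log_sd: float = 0.4
    remap_mode: str = "global"  # global | none
    rate_modulation_sd: float = 0.5  # sd of log peak-rate ratio between tracks
    # replay / reinstatement
    reinstatement_slope: float = 1.0
    compression_cm_per_bin: float = 10.0  # cm of virtual travel per 20 ms bin
    replay_gain: float = 5.0  # population burst gain during events
    sweep_length_range: tuple = (80.0, 140.0)  # cm
    sweep_edge_margin_cm: float = 40.0  # sweeps may overhang the track ends
    n_events_pre: int = 100  # total PRE events (split across tracks)
    n_events_post_per_track: int = 100
    event_spacing_s: float = 4.0
    # behavior
    n_laps: int = 20  # per track
    run_speed_cm_s: float = 30.0
    pause_s: float = 2.0  # reward pause at each track end
    awake_events_per_lap: float = 1.0
    pos_sample_hz: float = 40.0
    # background / ripple
    mua_background_hz: float = 25.0  # summed over the population
    ripple_sample_hz: float = 250.0
    ripple_burst_amp: float = 8.0
    ripple_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.reinstatement_slope < 0:
            raise ValueError("reinstatement_slope must be >= 0")
        if self.remap_mode not in ("global", "none"):
            raise ValueError(f"unknown remap_mode {self.remap_mode!r}")
        if abs(self.track_length_cm % 10.0) > 1e-9:
            raise ValueError("track_length_cm must be divisible by the 10 cm bin")


# ---------------------------------------------------------------------------
# field parameters
# ---------------------------------------------------------------------------

def generate_field_params(config: SimConfig, rng=None) -> pd.DataFrame:
    """Per-cell, per-track Gaussian field parameters.

    Track 1 centers and peak rates are drawn independently per cell; under
    ``remap_mode='global'`` Track 2 centers are fresh uniform draws, while
    Track 2 peak rates equal Track 1 rates times ``exp(N(0, rate_modulation_sd))``.
    """
    rng = child_rng(config.seed, "fields") if rng is None else rng
    L = config.track_length_cm
    n = config.n_cells
    c1 = rng.uniform(0, L, n)
    p1 = np.exp(rng.normal(config.peak_rate_log_mean, config.peak_rate_log_sd, n))
    if config.remap_mode == "global":
        c2 = rng.uniform(0, L, n)
    else:
        c2 = c1.copy()
    p2 = p1 * np.exp(rng.normal(0.0, config.rate_modulation_sd, n)) \
        if config.rate_modulation_sd > 0 else p1.copy()
    # per-cell baseline replay amplitude, independent of the field peaks:
    # at reinstatement_slope = 0 replay rates carry no field-rate information
    base = np.exp(rng.normal(config.peak_rate_log_mean, config.peak_rate_log_sd, n))
    rows = []
    for i in range(n):
        rows.append(("cell%03d" % i, 1, c1[i], config.field_sigma_cm, p1[i], base[i]))
        rows.append(("cell%03d" % i, 2, c2[i], config.field_sigma_cm, p2[i], base[i]))
    return pd.DataFrame(rows, columns=["cell_id", "track", "center_cm",
                                       "sigma_cm", "peak_hz", "replay_base_hz"])


def _field_rate(fields: pd.DataFrame, track: int, x: np.ndarray) -> np.ndarray:
    """Rate of every cell at positions x on one track: (n_cells, len(x))."""
    f = fields[fields.track == track].sort_values("cell_id")
    c = f.center_cm.to_numpy()[:, None]
    s = f.sigma_cm.to_numpy()[:, None]
    p = f.peak_hz.to_numpy()[:, None]
    return p * np.exp(-0.5 * ((np.asarray(x)[None, :] - c) / s) ** 2)


def _replay_peaks(fields: pd.DataFrame, track: int, slope: float) -> np.ndarray:
    """Per-cell replay peak amplitudes on one track.

    Geometric interpolation between the track's own field peak (slope = 1,
    full reinstatement) and a per-cell baseline amplitude drawn
    independently of the field peaks (slope = 0: replay rates carry no
    field-rate information, the null of the reinstatement analysis). The
    log replay-rate ratio between tracks equals ``slope`` times the log
    field-rate ratio.
    """
    f = fields[fields.track == track].sort_values("cell_id")
    own = f.peak_hz.to_numpy()
    base = f.replay_base_hz.to_numpy()
    return own**slope * base ** (1.0 - slope)


# ---------------------------------------------------------------------------
# RUN epochs
# ---------------------------------------------------------------------------

def _lap_schedule(config: SimConfig, t0: float) -> tuple[list, float]:
    """Piecewise-linear trajectory: [(t_start, t_end, x0, x1)] per segment."""
    L = config.track_length_cm
    v = config.run_speed_cm_s
    run_dur = L / v
    segs = []
    t = t0
    x = 0.0
    for lap in range(config.n_laps):
        segs.append((t, t + config.pause_s, x, x, lap))  # pause before traversal
        t += config.pause_s
        x1 = L - x
        segs.append((t, t + run_dur, x, x1, lap))
        t += run_dur
        x = x1
    segs.append((t, t + config.pause_s, x, x, config.n_laps - 1))
    t += config.pause_s
    return segs, t


def simulate_run_epoch(fields: pd.DataFrame, config: SimConfig, track: int,
                       t0: float, rng) -> dict:
    """Back-and-forth laps with inhomogeneous-Poisson place-field spiking.

    Each cell spikes with intensity equal to its field rate at the animal's
    current position (turn-around pauses included; the speed filter downstream
    removes them from ratemaps). Awake local replay events are injected
    during reward pauses. Returns the trajectory sampler, spikes, lap
    intervals and awake ground-truth events.
    """
    segs, t_end = _lap_schedule(config, t0)
    dt = 1.0 / config.pos_sample_hz
    t = np.arange(t0, t_end, dt)
    x = np.zeros_like(t)
    speed = np.zeros_like(t)
    for (a, b, x0, x1, _lap) in segs:
        m = (t >= a) & (t < b)
        if b > a:
            frac = (t[m] - a) / (b - a)
            x[m] = x0 + frac * (x1 - x0)
            speed[m] = abs(x1 - x0) / (b - a)
    # Poisson spiking from the field intensity along the trajectory
    lam = _field_rate(fields, track, x)  # cells x samples
    counts = rng.poisson(lam * dt)
    spikes = _counts_to_spikes(counts, t, dt, rng)

    laps = [(a, b) for (a, b, x0, x1, _lap) in segs if x0 != x1]
    # awake replay during pauses
    events = []
    ev_spikes = {cid: [] for cid in sorted(fields.cell_id.unique())}
    pauses = [(a, b, lap) for (a, b, x0, x1, lap) in segs if x0 == x1]
    for (a, b, lap) in pauses:
        if rng.random() >= config.awake_events_per_lap:
            continue
        t_mid = 0.5 * (a + b)
        ev = _make_sweep_event(fields, config, track, t_mid, rng,
                               epoch=f"RUN{track}", lap=lap)
        if ev["t_end"] > b or ev["t_start"] < a:
            continue
        events.append(ev)
        for cid, st in ev.pop("spikes").items():
            ev_spikes[cid].append(st)
    return {
        "t": t, "x": x, "speed": speed, "track": np.full(t.size, track, dtype=int),
        "spikes": spikes, "event_spikes": ev_spikes, "laps": laps,
        "events": events, "t_end": t_end,
    }


def _counts_to_spikes(counts: np.ndarray, t: np.ndarray, dt: float, rng) -> list:
    spikes = []
    for row in counts:
        idx = np.repeat(np.arange(row.size), row)
        st = t[idx] + rng.uniform(0, dt, idx.size)
        spikes.append(np.sort(st))
    return spikes


# ---------------------------------------------------------------------------
# replay events and rest epochs
# ---------------------------------------------------------------------------

def _make_sweep_event(fields, config: SimConfig, track: int, t_center: float,
                      rng, epoch: str, lap: int = -1, permute_cells: bool = False):
    L = config.track_length_cm
    length = rng.uniform(*config.sweep_length_range)
    n_bins = max(2, int(round(length / config.compression_cm_per_bin)))
    duration = n_bins * TIME_BIN_S
    direction = rng.choice([-1, 1])
    span = n_bins * config.compression_cm_per_bin
    # allowing a bounded overhang beyond the track ends evens out positional
    # coverage (strictly on-track sweeps over-sample the track center, which
    # couples a field's eccentricity into its replay participation)
    m = min(config.sweep_edge_margin_cm, span / 2.0)
    x0 = rng.uniform(-m, L - span + m)
    if direction < 0:
        x0 = x0 + span
    xs = x0 + direction * config.compression_cm_per_bin * (np.arange(n_bins) + 0.5)
    t_start = t_center - duration / 2.0
    lam = config.replay_gain * _field_rate(fields, track, xs)  # cells x bins
    own_peak = fields[fields.track == track].sort_values("cell_id").peak_hz.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(own_peak > 0,
                         _replay_peaks(fields, track, config.reinstatement_slope)
                         / np.where(own_peak > 0, own_peak, 1.0), 0.0)
    lam = lam * scale[:, None]
    if permute_cells:
        lam = lam[rng.permutation(lam.shape[0])]
    counts = rng.poisson(lam * TIME_BIN_S)
    cell_ids = sorted(fields.cell_id.unique())
    spikes = {}
    for i, cid in enumerate(cell_ids):
        idx = np.repeat(np.arange(n_bins), counts[i])
        st = t_start + idx * TIME_BIN_S + rng.uniform(0, TIME_BIN_S, idx.size)
        spikes[cid] = np.sort(st)
    return {
        "epoch": epoch, "track": track, "t_start": t_start,
        "t_end": t_start + duration, "x_start": xs[0], "x_end": xs[-1],
        "direction": direction, "lap": lap, "spikes": spikes,
    }


def simulate_rest_epoch(fields: pd.DataFrame, config: SimConfig, epoch: str,
                        t0: float, rng) -> dict:
    """Rest epoch with replay sweeps, ripple bursts, and quiet background.

    POST events sweep a virtual position along their track with per-cell
    reinstatement scaling; PRE events use the same construction with the
    per-cell intensity profiles randomly permuted across cells per event.
    """
    if epoch == "PRE":
        n_events = config.n_events_pre
        tracks = np.where(np.arange(n_events) % 2 == 0, 1, 2)
        permute = True
    else:
        n_events = 2 * config.n_events_post_per_track
        tracks = np.where(np.arange(n_events) % 2 == 0, 1, 2)
        permute = False
    rng.shuffle(tracks)
    duration = n_events * config.event_spacing_s + 20.0
    centers = t0 + 10.0 + np.arange(n_events) * config.event_spacing_s \
        + rng.uniform(-0.3, 0.3, n_events)
    events = []
    cell_ids = sorted(fields.cell_id.unique())
    ev_spikes = {cid: [] for cid in cell_ids}
    for k in range(n_events):
        ev = _make_sweep_event(fields, config, int(tracks[k]), centers[k], rng,
                               epoch=epoch, permute_cells=permute)
        for cid, st in ev.pop("spikes").items():
            ev_spikes[cid].append(st)
        events.append(ev)
    return {"t_start": t0, "t_end": t0 + duration, "events": events,
            "event_spikes": ev_spikes}


def _ripple_trace(config: SimConfig, t_end: float, events: list, rng):
    dt = 1.0 / config.ripple_sample_hz
    t = np.arange(0.0, t_end, dt)
    power = 1.0 + config.ripple_noise_sd * rng.standard_normal(t.size)
    for ev in events:
        m = (t >= ev["t_start"] - 0.01) & (t <= ev["t_end"] + 0.01)
        power[m] += config.ripple_burst_amp
    return t, np.maximum(power, 0.0)


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def make_session(config: SimConfig) -> Session:
    """Assemble PRE / RUN1 / RUN2 / POST into a validated Session.

    Deterministic per ``config.seed``; ground truth (field parameters and
    per-event epoch/track/trajectory) is attached for recovery tests.
    """
    fields = generate_field_params(config)
    cell_ids = sorted(fields.cell_id.unique())
    gap = 5.0

    rng_pre = child_rng(config.seed, "rest-PRE")
    rng_r1 = child_rng(config.seed, "run-1")
    rng_r2 = child_rng(config.seed, "run-2")
    rng_post = child_rng(config.seed, "rest-POST")
    rng_bg = child_rng(config.seed, "background")
    rng_rip = child_rng(config.seed, "ripple")

    pre = simulate_rest_epoch(fields, config, "PRE", 0.0, rng_pre)
    run1 = simulate_run_epoch(fields, config, 1, pre["t_end"] + gap, rng_r1)
    run2 = simulate_run_epoch(fields, config, 2, run1["t_end"] + gap, rng_r2)
    post = simulate_rest_epoch(fields, config, "POST", run2["t_end"] + gap, rng_post)

    epochs = {
        "PRE": (0.0, pre["t_end"]),
        "RUN1": (pre["t_end"] + gap, run1["t_end"]),
        "RUN2": (run1["t_end"] + gap, run2["t_end"]),
        "POST": (run2["t_end"] + gap, post["t_end"]),
    }
    t_end = post["t_end"]

    # position trace on one uniform grid across the whole session
    dt = 1.0 / config.pos_sample_hz
    t = np.arange(0.0, t_end, dt)
    x = np.zeros_like(t)
    track = np.zeros(t.size, dtype=int)
    speed = np.zeros_like(t)
    for run in (run1, run2):
        m = (t >= run["t"][0]) & (t < run["t"][-1])
        # sample-and-hold lookup onto the session grid
        idx = np.clip(np.searchsorted(run["t"], t[m], side="right") - 1, 0,
                      run["t"].size - 1)
        x[m] = run["x"][idx]
        track[m] = run["track"][idx]
        speed[m] = run["speed"][idx]
    position = PositionTrace(t=t, x=x, track=track, speed=speed)

    # combine spikes per cell: run fields + replay events + background
    bg_rate = config.mua_background_hz / config.n_cells
    spikes = []
    for i, cid in enumerate(cell_ids):
        parts = [run1["spikes"][i], run2["spikes"][i]]
        for src in (pre, post, run1, run2):
            parts.extend(src["event_spikes"][cid])
        n_bg = rng_bg.poisson(bg_rate * t_end)
        parts.append(np.sort(rng_bg.uniform(0.0, t_end, n_bg)))
        st = np.unique(np.concatenate(parts))
        spikes.append(st)

    all_events = pre["events"] + run1["events"] + run2["events"] + post["events"]
    ripple = _ripple_trace(config, t_end, all_events, rng_rip)

    cells = [
        CellRecord(
            cell_id=cid, spikes=spikes[i], cell_class="pyramidal",
            mean_rate=spikes[i].size / t_end, waveform_hwhm=700.0,
        )
        for i, cid in enumerate(cell_ids)
    ]
    events_df = pd.DataFrame(
        [{k: v for k, v in ev.items()} for ev in all_events]
    ).sort_values("t_start").reset_index(drop=True)
    laps_meta = {
        1: run1["laps"], 2: run2["laps"],
    }
    session = Session(
        cells=cells, position=position, epochs=epochs, ripple_power=ripple,
        meta={"track_length_cm": config.track_length_cm,
              "position_step_s": dt, "seed": config.seed},
        ground_truth=GroundTruth(fields=fields, events=events_df),
    )
    session.meta["laps"] = laps_meta  # not serialized; recomputable from position
    return session


# ---------------------------------------------------------------------------
# structureless events (null calibration)
# ---------------------------------------------------------------------------

def simulate_structureless_events(fields: pd.DataFrame, config: SimConfig,
                                  n_events: int, rng,
                                  duration_range=(0.15, 0.4)) -> list[dict]:
    """Homogeneous-Poisson candidate events with no structure of any kind.

    Every cell fires at the same constant rate — ``replay_gain`` times the
    population-average mean field rate (field integral / track length,
    averaged across tracks and cells) — so position, sequence AND rate carry
    no information. Used to calibrate the shuffle-based significance tests.
    (Keeping per-cell rate heterogeneity would bias the spatial shuffles:
    posterior columns then concentrate where the high-rate cells' fields
    sit, deflating the x-variance of the observed score relative to the
    shuffled nulls.)
    """
    L = config.track_length_cm
    cell_ids = sorted(fields.cell_id.unique())
    f1 = fields[fields.track == 1].sort_values("cell_id")
    f2 = fields[fields.track == 2].sort_values("cell_id")
    mean_rate = 0.5 * sum(
        f.peak_hz.to_numpy() * f.sigma_cm.to_numpy() * np.sqrt(2 * np.pi) / L
        for f in (f1, f2)
    )
    lam = np.full(len(cell_ids), config.replay_gain * float(mean_rate.mean()))
    out = []
    t0 = 0.0
    for _ in range(n_events):
        dur = TIME_BIN_S * max(5, int(round(rng.uniform(*duration_range) / TIME_BIN_S)))
        spikes = {}
        for i, cid in enumerate(cell_ids):
            n = rng.poisson(lam[i] * dur)
            spikes[cid] = np.sort(rng.uniform(t0, t0 + dur, n))
        out.append({"t_start": t0, "t_end": t0 + dur, "spikes": spikes})
        t0 += dur + 1.0
    return out
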