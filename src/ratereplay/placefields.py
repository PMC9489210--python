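"""Ratemaps, place-cell selection, field detection and remapping measures.

A ratemap is the speed-filtered spike histogram divided by the speed-filtered
dwell time in each position bin. Only unsmoothed maps feed the decoder;
smoothing (Gaussian, sigma = one bin) exists for display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .session import PositionTrace, Session, child_rng


class NoOccupancyError(ValueError):
    pass


@dataclass
class Ratemap:
    cell_id: str
    track_id: int
    bin_edges: np.ndarray  # cm
    rate: np.ndarray  # Hz per bin
    counts: np.ndarray
    dwell: np.ndarray  # s per bin
    smoothed: bool = False
    source: str = "whole"  # whole | first_half | second_half | lap_subset

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def zero_dwell(self) -> np.ndarray:
        return self.dwell <= 0

    @property
    def peak_rate(self) -> float:
        return float(self.rate.max()) if self.rate.size else 0.0

    def smooth(self, sigma_bins: float = 1.0) -> "Ratemap":
        """Display-only smoothed copy; never used for decoding."""
        sm = gaussian_filter1d(self.rate, sigma_bins, mode="nearest")
        return Ratemap(self.cell_id, self.track_id, self.bin_edges, sm,
                       self.counts, self.dwell, smoothed=True, source=self.source)


@dataclass
class PlaceField:
    track_id: int
    peak_rate: float
    peak_bin: int
    extent: tuple[int, int]  # [first, last] bin, inclusive
    auc: float  # Hz*cm, trapezoidal over the extent


@dataclass
class RemappingClassification:
    cell_id: str
    rate_modulated: bool
    place_modulated: bool
    bounds: dict = dc_field(default_factory=dict)


def _as_intervals(interval) -> list[tuple[float, float]]:
    if interval is None:
        return []
    if isinstance(interval, tuple) and len(interval) == 2 and np.isscalar(interval[0]):
        return [interval]
    return list(interval)


def compute_ratemap(
    spikes: np.ndarray,
    position: PositionTrace,
    *,
    track_id: int,
    track_length: float,
    bin_size: float = 10.0,
    speed_window: tuple[float, float] = (4.0, 50.0),
    interval=None,
    source: str = "whole",
) -> Ratemap:
    """Occupancy-normalized spatial firing rate on one track.

    Position samples and spikes are restricted to ``interval`` (one
    ``(start, end)`` pair or a list of them), to the requested track, and to
    the 4-50 cm/s speed window. Bins with zero dwell get rate 0 (flagged via
    ``zero_dwell``) rather than NaN.
    """
    intervals = _as_intervals(interval)
    lo, hi = speed_window
    mask = position.track == track_id
    mask &= (position.speed >= lo) & (position.speed <= hi)
    if intervals:
        tmask = np.zeros(position.t.size, dtype=bool)
        for a, b in intervals:
            tmask |= (position.t >= a) & (position.t < b)
        mask &= tmask
    if not mask.any():
        raise NoOccupancyError("no occupancy")
    edges = np.arange(0.0, track_length + bin_size / 2, bin_size)
    dwell = np.histogram(position.x[mask], bins=edges)[0] * position.dt

    spikes = np.asarray(spikes, dtype=float)
    if intervals and spikes.size:
        smask = np.zeros(spikes.size, dtype=bool)
        for a, b in intervals:
            smask |= (spikes >= a) & (spikes < b)
        spikes = spikes[smask]
    at = position.sample_at(spikes)
    keep = (at["track"] == track_id) & (at["speed"] >= lo) & (at["speed"] <= hi)
    counts = np.histogram(at["x"][keep], bins=edges)[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(dwell > 0, counts / np.where(dwell > 0, dwell, 1.0), 0.0)
    return Ratemap(cell_id="", track_id=track_id, bin_edges=edges,
                   rate=rate, counts=counts, dwell=dwell, source=source)


def run_interval(session: Session, track_id: int, half: Optional[str] = None):
    a, b = session.epochs[f"RUN{track_id}"]
    if half is None:
        return (a, b)
    mid = 0.5 * (a + b)
    return (a, mid) if half == "first" else (mid, b)


def compute_session_ratemaps(session: Session, bin_size: float = 10.0,
                             speed_window=(4.0, 50.0)) -> dict:
    """Unsmoothed ratemaps for every cell on both tracks (whole + halves)."""
    maps = {}
    for track in (1, 2):
        for src, half in (("whole", None), ("first_half", "first"),
                          ("second_half", "second")):
            iv = run_interval(session, track, half)
            for c in session.cells:
                rm = compute_ratemap(
                    c.spikes, session.position, track_id=track,
                    track_length=session.track_length, bin_size=bin_size,
                    speed_window=speed_window, interval=iv, source=src,
                )
                rm.cell_id = c.cell_id
                maps[(c.cell_id, track, src)] = rm
    return maps


def select_place_cells(session: Session, ratemaps: dict,
                       min_peak_hz: float = 1.0,
                       pyramidal_max_rate: float = 5.0,
                       hwhm_min_us: float = 500.0) -> pd.DataFrame:
    """Cell screening and cohort labels.

    Putative pyramidal cells need waveform HWHM > 500 µs (when available) and
    session mean rate < 5 Hz. A place cell on a track has an unsmoothed peak
    rate > 1 Hz; stability further requires > 1 Hz in both the first and
    second half of the run. The regression cohort is stable on BOTH tracks.
    Pyramidal cells below 1 Hz on both tracks are the non-spatial controls.
    """
    rows = []
    for c in session.cells:
        if c.cell_class == "interneuron":
            pyramidal = False
        elif c.waveform_hwhm is not None:
            pyramidal = (c.waveform_hwhm > hwhm_min_us) and (c.mean_rate < pyramidal_max_rate)
        else:
            pyramidal = (c.cell_class == "pyramidal") and (c.mean_rate < pyramidal_max_rate)
        peaks = {}
        stable = {}
        for track in (1, 2):
            peaks[track] = ratemaps[(c.cell_id, track, "whole")].peak_rate
            stable[track] = (
                ratemaps[(c.cell_id, track, "first_half")].peak_rate > min_peak_hz
                and ratemaps[(c.cell_id, track, "second_half")].peak_rate > min_peak_hz
            )
        place1 = pyramidal and peaks[1] > min_peak_hz
        place2 = pyramidal and peaks[2] > min_peak_hz
        rows.append(
            {
                "cell_id": c.cell_id,
                "pyramidal": pyramidal,
                "interneuron": not pyramidal,
                "peak_T1": peaks[1],
                "peak_T2": peaks[2],
                "place_T1": place1,
                "place_T2": place2,
                "stable_T1": place1 and stable[1],
                "stable_T2": place2 and stable[2],
                "stable_both": place1 and place2 and stable[1] and stable[2],
                "non_spatial": pyramidal and peaks[1] < min_peak_hz and peaks[2] < min_peak_hz,
            }
        )
    return pd.DataFrame(rows)


def population_vector_correlation(stack_a: np.ndarray, stack_b: np.ndarray):
    """Mean Pearson r between per-position-bin population vectors.

    ``stack_a``/``stack_b`` are (n_bins, n_cells). Bins where either vector
    has zero variance are excluded from the mean (their r is undefined).
    Returns ``(mean_r, per_bin_r)`` with NaN marking excluded bins.
    """
    a = np.asarray(stack_a, dtype=float)
    b = np.asarray(stack_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("stacks must have identical shape")
    r = np.full(a.shape[0], np.nan)
    for i in range(a.shape[0]):
        va, vb = a[i], b[i]
        if np.std(va) == 0 or np.std(vb) == 0:
            continue
        r[i] = np.corrcoef(va, vb)[0, 1]
    valid = ~np.isnan(r)
    mean_r = float(np.mean(r[valid])) if valid.any() else np.nan
    return mean_r, r


def detect_fields(ratemap: Ratemap, min_peak_hz: float = 1.0,
                  min_width_bins: int = 2, min_separation_bins: int = 4) -> list[PlaceField]:
    """Place fields from an unsmoothed 10 cm ratemap.

    Local maxima above 1 Hz are candidate peaks; peaks closer than four bins
    (40 cm) are merged into the larger one; a field's extent is the
    contiguous run of bins above the 1 Hz in-field criterion around its peak,
    and fields narrower than two bins (20 cm) are dropped.
    """
    r = ratemap.rate
    n = r.size
    peaks = [
        i for i in range(n)
        if r[i] > min_peak_hz
        and (i == 0 or r[i] >= r[i - 1])
        and (i == n - 1 or r[i] > r[i + 1])
    ]
    # merge close peaks into the larger
    peaks = sorted(peaks, key=lambda i: (-r[i], i))
    kept: list[int] = []
    for i in peaks:
        if all(abs(i - j) >= min_separation_bins for j in kept):
            kept.append(i)
    fields = []
    for i in sorted(kept):
        lo = i
        while lo > 0 and r[lo - 1] > min_peak_hz:
            lo -= 1
        hi = i
        while hi < n - 1 and r[hi + 1] > min_peak_hz:
            hi += 1
        if hi - lo + 1 < min_width_bins:
            continue
        dx = float(ratemap.bin_edges[1] - ratemap.bin_edges[0])
        auc = float(np.trapezoid(r[lo:hi + 1], dx=dx))
        fields.append(PlaceField(track_id=ratemap.track_id, peak_rate=float(r[i]),
                                 peak_bin=i, extent=(lo, hi), auc=auc))
    return fields


def segment_laps(position: PositionTrace, track_id: int, track_length: float,
                 hysteresis: float = 10.0) -> list[tuple[float, float]]:
    """End-to-end traversals, detected from the position extrema.

    A lap runs from the last sample inside one end zone (within
    ``hysteresis`` cm of a track end) to the first sample inside the
    opposite zone.
    """
    m = position.track == track_id
    t = position.t[m]
    x = position.x[m]
    if t.size == 0:
        return []
    zone = np.zeros(x.size, dtype=int)
    zone[x <= hysteresis] = -1
    zone[x >= track_length - hysteresis] = 1
    laps = []
    cur = 0
    t_leave = t[0]
    for i in range(x.size):
        if zone[i] == 0:
            continue
        if cur == 0:
            cur = zone[i]
            t_leave = t[i]
        elif zone[i] == cur:
            t_leave = t[i]
        else:
            laps.append((t_leave, t[i]))
            cur = zone[i]
            t_leave = t[i]
    return laps


def bootstrap_remapping_classification(
    session: Session,
    cell_id: str,
    laps_by_track: dict[int, Sequence[tuple[float, float]]],
    n_boot: int = 1000,
    seed: int = 0,
    bin_size: float = 10.0,
) -> RemappingClassification:
    """Lap-bootstrap test for between-track rate and place modulation.

    For each track, ratemaps are rebuilt from N-of-N laps resampled with
    replacement (1000 iterations); the bootstrap distributions of peak rate
    and peak location are summarized, and a parameter counts as modulated iff
    one track's median lies strictly outside the other's [5th, 95th]
    percentile interval (either direction).
    """
    spikes = session.cell(cell_id).spikes
    stats: dict[int, dict[str, np.ndarray]] = {}
    for track, laps in laps_by_track.items():
        laps = list(laps)
        if len(laps) < 2:
            raise ValueError("insufficient laps")
        per_lap_counts = []
        per_lap_dwell = []
        for lap in laps:
            rm = compute_ratemap(
                spikes, session.position, track_id=track,
                track_length=session.track_length, bin_size=bin_size,
                interval=lap, source="lap_subset",
            )
            per_lap_counts.append(rm.counts)
            per_lap_dwell.append(rm.dwell)
        counts = np.array(per_lap_counts, dtype=float)
        dwell = np.array(per_lap_dwell, dtype=float)
        rng = child_rng(seed, "remap-bootstrap", track)
        idx = rng.integers(0, len(laps), size=(n_boot, len(laps)))
        c = counts[idx].sum(axis=1)
        d = dwell[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(d > 0, c / np.where(d > 0, d, 1.0), 0.0)
        peak = rates.max(axis=1)
        centers = 0.5 * (np.arange(rates.shape[1]) * 2 + 1) * bin_size / 1.0
        loc = centers[rates.argmax(axis=1)] if rates.size else np.zeros(n_boot)
        stats[track] = {"peak": peak, "loc": loc}

    def _modulated(param: str) -> tuple[bool, dict]:
        a, b = stats[1][param], stats[2][param]
        med_a, med_b = np.median(a), np.median(b)
        lo_a, hi_a = np.percentile(a, [5, 95])
        lo_b, hi_b = np.percentile(b, [5, 95])
        flag = (med_a > hi_b) or (med_a < lo_b) or (med_b > hi_a) or (med_b < lo_a)
        return bool(flag), {
            "median_T1": med_a, "median_T2": med_b,
            "ci_T1": (lo_a, hi_a), "ci_T2": (lo_b, hi_b),
        }

    rate_flag, rate_bounds = _modulated("peak")
    place_flag, place_bounds = _modulated("loc")
    return RemappingClassification(
        cell_id=cell_id, rate_modulated=rate_flag, place_modulated=place_flag,
        bounds={"peak": rate_bounds, "loc": place_bounds},
    )
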