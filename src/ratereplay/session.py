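"""Session data model for two-track linear-track recordings.

A :class:`Session` bundles everything the analysis pipeline consumes: per-cell
spike trains, a linearized position trace, the PRE / RUN1 / RUN2 / POST epoch
boundaries, an optional ripple-band power trace, and (for synthetic sessions)
the generator's ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

EPOCH_NAMES = ("PRE", "RUN1", "RUN2", "POST")

# canonical epoch order in time: PRE first, POST last, RUN epochs in between
_EPOCH_RANK = {"PRE": 0, "RUN1": 1, "RUN2": 1, "POST": 2}


class SessionError(ValueError):
    """Raised when a session bundle violates the data-model contract."""


@dataclass
class CellRecord:
    """One unit: spike times plus the metadata used for cell screening."""

    cell_id: str
    spikes: np.ndarray  # sorted spike times, s
    cell_class: str = "unclassified"  # pyramidal | interneuron | unclassified
    mean_rate: float = 0.0  # Hz over the whole session
    waveform_hwhm: Optional[float] = None  # half-width-half-max, µs

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=float)
        if self.spikes.ndim != 1:
            raise SessionError(f"cell {self.cell_id}: spikes must be 1-D")
        if self.spikes.size > 1 and np.any(np.diff(self.spikes) <= 0):
            raise SessionError(f"invalid spike train for cell {self.cell_id}")
        if self.mean_rate < 0:
            raise SessionError(f"cell {self.cell_id}: negative mean rate")


@dataclass
class PositionTrace:
    """Linearized position at a uniform sampling step.

    ``track`` is 0 off-track and 1 or 2 while the animal is on a track;
    ``x`` is the linearized position in cm, ``speed`` in cm/s.
    """

    t: np.ndarray
    x: np.ndarray
    track: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.track = np.asarray(self.track, dtype=int)
        self.speed = np.asarray(self.speed, dtype=float)
        n = self.t.size
        if not (self.x.size == self.track.size == self.speed.size == n):
            raise SessionError("position arrays must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise SessionError("position time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise SessionError("position time step must be uniform")
        if np.any(self.speed < 0):
            raise SessionError("speed must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else np.nan

    def sample_at(self, times: np.ndarray) -> dict[str, np.ndarray]:
        """Nearest-sample lookup of x / track / speed at arbitrary times."""
        idx = np.clip(np.searchsorted(self.t, times) - 0, 0, self.t.size - 1)
        # snap to the nearer of the two neighbouring samples
        left = np.clip(idx - 1, 0, self.t.size - 1)
        use_left = np.abs(self.t[left] - times) < np.abs(self.t[idx] - times)
        idx = np.where(use_left, left, idx)
        return {
            "x": self.x[idx],
            "track": self.track[idx],
            "speed": self.speed[idx],
        }


@dataclass
class GroundTruth:
    """Generator-side truth for synthetic sessions.

    ``fields`` has one row per (cell, track) with the true Gaussian field
    parameters; ``events`` one row per injected replay event with its epoch,
    true track, trajectory endpoints and lap index (awake events).
    """

    fields: pd.DataFrame
    events: pd.DataFrame


@dataclass
class Session:
    cells: list[CellRecord]
    position: PositionTrace
    epochs: dict[str, tuple[float, float]]
    ripple_power: Optional[tuple[np.ndarray, np.ndarray]] = None  # (t, power)
    meta: dict = field(default_factory=dict)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        missing = [e for e in EPOCH_NAMES if e not in self.epochs]
        if missing:
            raise SessionError(f"invalid epochs: missing {missing}")
        ivals = sorted(self.epochs.items(), key=lambda kv: kv[1][0])
        for name, (a, b) in ivals:
            if not b > a:
                raise SessionError(f"invalid epochs: {name} has end <= start")
        for (n1, (_, e1)), (n2, (s2, _)) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise SessionError(f"invalid epochs: {n1} overlaps {n2}")
            if _EPOCH_RANK[n1] > _EPOCH_RANK[n2]:
                raise SessionError("invalid epochs: order must be PRE < RUN < POST")
        t0, t1 = self.time_span
        for c in self.cells:
            if c.spikes.size and (c.spikes[0] < t0 - 1e-9 or c.spikes[-1] > t1 + 1e-9):
                raise SessionError(f"cell {c.cell_id}: spikes outside session span")
        track_len = float(self.meta.get("track_length_cm", 200.0))
        on = self.position.track > 0
        if np.any(on):
            x = self.position.x[on]
            if x.min() < -1e-9 or x.max() > track_len + 1e-9:
                raise SessionError("position outside track bounds")

    @property
    def time_span(self) -> tuple[float, float]:
        starts = [s for s, _ in self.epochs.values()]
        ends = [e for _, e in self.epochs.values()]
        return min(min(starts), float(self.position.t[0])), max(
            max(ends), float(self.position.t[-1])
        )

    @property
    def track_length(self) -> float:
        return float(self.meta.get("track_length_cm", 200.0))

    def cell(self, cell_id: str) -> CellRecord:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    def epoch_spikes(self, epoch: str) -> dict[str, np.ndarray]:
        """Per-cell spike times restricted to one epoch."""
        a, b = self.epochs[epoch]
        out = {}
        for c in self.cells:
            s = c.spikes
            out[c.cell_id] = s[(s >= a) & (s < b)]
        return out


def child_rng(seed: int, stage: str, key: int = 0) -> np.random.Generator:
    """Derive an independent stream keyed by (stage, key) from a global seed.

    Results are invariant to the order stages execute in because every stream
    is seeded from the same (seed, stage-hash, key) triple.
    """
    stage_hash = np.uint32(zlib.crc32(stage.encode()) % (2**31))
    return np.random.default_rng([np.uint32(seed % (2**31)), stage_hash, np.uint32(key % (2**31))])
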