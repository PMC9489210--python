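"""Plain-text session-bundle and result I/O.

A session bundle is a directory of TSV files:

``cells.tsv``        cell_id, cell_class, hwhm_us, mean_rate_hz
``spikes.tsv``       cell_id, t_s
``position.tsv``     t_s, x_cm, track, speed_cm_s
``epochs.tsv``       name, start_s, end_s
``ripple_power.tsv`` t_s, power            (optional)
``ground_truth_fields.tsv`` / ``ground_truth_events.tsv`` (synthetic only)

Floats are written at full precision so write -> read is the identity.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .session import CellRecord, GroundTruth, PositionTrace, Session, SessionError

_REQUIRED = ("cells.tsv", "spikes.tsv", "position.tsv", "epochs.tsv")


def write_session_bundle(session: Session, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cells = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in session.cells],
            "cell_class": [c.cell_class for c in session.cells],
            "hwhm_us": [np.nan if c.waveform_hwhm is None else c.waveform_hwhm
                        for c in session.cells],
            "mean_rate_hz": [c.mean_rate for c in session.cells],
        }
    )
    _write(cells, path / "cells.tsv")
    spikes = pd.DataFrame(
        {
            "cell_id": np.concatenate(
                [[c.cell_id] * c.spikes.size for c in session.cells]
            ) if any(c.spikes.size for c in session.cells) else [],
            "t_s": np.concatenate([c.spikes for c in session.cells])
            if any(c.spikes.size for c in session.cells) else [],
        }
    )
    _write(spikes, path / "spikes.tsv")
    pos = session.position
    _write(
        pd.DataFrame(
            {"t_s": pos.t, "x_cm": pos.x, "track": pos.track, "speed_cm_s": pos.speed}
        ),
        path / "position.tsv",
    )
    _write(
        pd.DataFrame(
            [(n, s, e) for n, (s, e) in session.epochs.items()],
            columns=["name", "start_s", "end_s"],
        ),
        path / "epochs.tsv",
    )
    if session.ripple_power is not None:
        t, p = session.ripple_power
        _write(pd.DataFrame({"t_s": t, "power": p}), path / "ripple_power.tsv")
    meta_scalar = {
        k: v for k, v in session.meta.items() if np.isscalar(v) or isinstance(v, str)
    }
    if meta_scalar:
        _write(
            pd.DataFrame(
                [(k, v) for k, v in meta_scalar.items()], columns=["key", "value"]
            ),
            path / "meta.tsv",
        )
    if session.ground_truth is not None:
        _write(session.ground_truth.fields, path / "ground_truth_fields.tsv")
        _write(session.ground_truth.events, path / "ground_truth_events.tsv")


def read_session_bundle(path) -> Session:
    path = Path(path)
    for f in _REQUIRED:
        if not (path / f).exists():
            raise SessionError(f"bundle incomplete: missing {f}")
    cells_df = pd.read_csv(path / "cells.tsv", sep="\t", dtype={"cell_id": str}, float_precision="round_trip")
    spikes_df = pd.read_csv(path / "spikes.tsv", sep="\t", dtype={"cell_id": str}, float_precision="round_trip")
    by_cell = dict(iter(spikes_df.groupby("cell_id")["t_s"])) if len(spikes_df) else {}
    cells = []
    for _, row in cells_df.iterrows():
        s = np.asarray(by_cell.get(row.cell_id, pd.Series(dtype=float)), dtype=float)
        hwhm = None if pd.isna(row.hwhm_us) else float(row.hwhm_us)
        cells.append(
            CellRecord(
                cell_id=row.cell_id,
                spikes=s,
                cell_class=str(row.cell_class),
                mean_rate=float(row.mean_rate_hz),
                waveform_hwhm=hwhm,
            )
        )
    pos_df = pd.read_csv(path / "position.tsv", sep="\t", float_precision="round_trip")
    position = PositionTrace(
        t=pos_df.t_s.to_numpy(),
        x=pos_df.x_cm.to_numpy(),
        track=pos_df.track.to_numpy(),
        speed=pos_df.speed_cm_s.to_numpy(),
    )
    ep_df = pd.read_csv(path / "epochs.tsv", sep="\t", float_precision="round_trip")
    epochs = {r["name"]: (float(r.start_s), float(r.end_s)) for _, r in ep_df.iterrows()}
    ripple = None
    if (path / "ripple_power.tsv").exists():
        rp = pd.read_csv(path / "ripple_power.tsv", sep="\t", float_precision="round_trip")
        ripple = (rp.t_s.to_numpy(), rp.power.to_numpy())
    meta = {}
    if (path / "meta.tsv").exists():
        m = pd.read_csv(path / "meta.tsv", sep="\t")
        for _, r in m.iterrows():
            try:
                meta[r.key] = float(r.value)
            except (TypeError, ValueError):
                meta[r.key] = r.value
    gt = None
    if (path / "ground_truth_events.tsv").exists():
        gt = GroundTruth(
            fields=pd.read_csv(path / "ground_truth_fields.tsv", sep="\t", float_precision="round_trip"),
            events=pd.read_csv(path / "ground_truth_events.tsv", sep="\t", float_precision="round_trip"),
        )
    return Session(
        cells=cells, position=position, epochs=epochs, ripple_power=ripple,
        meta=meta, ground_truth=gt,
    )


def _write(df: pd.DataFrame, path) -> None:
    # 17 significant digits round-trip IEEE doubles bit-for-bit
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_results(results, path) -> None:
    """Write pipeline outputs as deterministic TSV tables.

    ``results`` may be a DataFrame, a mapping name -> DataFrame, or an object
    with a ``to_frame()`` method. Directories are created as needed.
    """
    path = Path(path)
    if isinstance(results, dict):
        path.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            write_results(df, path / f"{name}.tsv")
        return
    if hasattr(results, "to_frame") and not isinstance(results, pd.DataFrame):
        results = results.to_frame()
    if not isinstance(results, pd.DataFrame):
        raise TypeError(f"cannot serialize result of type {type(results)!r}")
    os.makedirs(path.parent, exist_ok=True)
    _write(results, path)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
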