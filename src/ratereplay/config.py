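"""Pipeline configuration.

Every numeric default is the published analysis value: 10 cm decoding bins,
250 ms / 20 ms time bins for behavior / replay, the 4-50 cm/s run speed
window, MUA burst thresholds, the three 1000-shuffle significance nulls, the
60% Bayesian-bias assignment rule, and the 1000-fold shuffles and bootstraps
of the sequenceless log-odds analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class BinningConfig:
    pos_bin_cm: float = 10.0  # decoding grid
    display_bin_cm: float = 2.0  # visualization-only ratemaps
    tau_run_s: float = 0.25
    tau_replay_s: float = 0.02
    rate_floor_hz: float = 0.01  # epsilon added to decoding ratemaps
    run_speed_lo: float = 4.0  # cm/s, ratemap speed filter
    run_speed_hi: float = 50.0


@dataclass
class DetectionConfig:
    mua_bin_ms: float = 1.0
    mua_sigma_ms: float = 5.0
    mua_z_threshold: float = 3.0
    max_burst_ms: float = 300.0
    merge_gap_ms: float = 50.0
    max_speed_cm_s: float = 5.0
    min_active_cells: int = 5
    min_duration_ms: float = 100.0
    max_duration_ms: float = 750.0
    ripple_ma_window_s: float = 0.1
    ripple_z_threshold: float = 3.0
    require_ripple: bool = True


@dataclass
class ShuffleConfig:
    n_shuffles: int = 1000
    alpha: float = 0.05
    alpha_split: float = 0.025  # adjusted threshold for MUA-split halves
    bias_threshold: float = 0.60  # Bayesian bias needed to assign 2-track events


@dataclass
class RegressionConfig:
    min_field_peak_hz: float = 1.0  # exclude fields with peak < 1 Hz either track
    min_cells: int = 3
    block_size: int = 70  # events per block for temporal analysis


@dataclass
class LogOddsConfig:
    n_label_shuffles: int = 1000  # ratemap track-label swap
    n_track_id_shuffles: int = 1000  # replay track identity shuffle
    n_bootstrap: int = 1000  # ROC bootstrap
    n_negative_control_runs: int = 10  # repeat count; report the median run


@dataclass
class PipelineConfig:
    seed: int = 0
    binning: BinningConfig = field(default_factory=BinningConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    shuffles: ShuffleConfig = field(default_factory=ShuffleConfig)
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    logodds: LogOddsConfig = field(default_factory=LogOddsConfig)
    simulation: dict = field(default_factory=dict)  # SimConfig overrides

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        section_types = {f.name: f.type for f in fields(cls)}
        for f in fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            typ = {
                "binning": BinningConfig,
                "detection": DetectionConfig,
                "shuffles": ShuffleConfig,
                "regression": RegressionConfig,
                "logodds": LogOddsConfig,
            }.get(f.name)
            kwargs[f.name] = typ(**val) if typ and isinstance(val, dict) else val
        return cls(**kwargs)
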