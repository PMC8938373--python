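"""Run configuration: one validated, text-serializable object for the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class RunConfig(BaseModel):
    """Everything a pipeline run needs; round-trips losslessly through YAML.

    Unknown keys are rejected at load time, so a typo in a config file fails
    fast instead of silently running defaults.
    """

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "nbackerp_out"
    seed: int = 0

    # cohort
    n_per_group: int = 16
    # EEG task design: fixed block order and per-block trial counts
    blocks: tuple[int, ...] = (1, 2, 2, 1)
    n_trials_per_block: int = 100
    n_targets_per_block: int = 25

    # preprocessing
    highpass_hz: float = 0.1
    lowpass_hz: float = 120.0
    notch_band_hz: tuple[float, float] = (48.0, 52.0)
    target_rate_hz: float = 200.0
    epoch_window_ms: tuple[float, float] = (-600.0, 1400.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    crop_ms: tuple[float, float] = (-100.0, 900.0)
    erp_lowpass_hz: float = 30.0

    # cleaning
    n_components: int = 32
    ic_z_threshold: float = 2.0
    confirm_min_abs_corr: float = 0.2
    bad_channel_z: float = 4.0
    force_bad_channels: tuple[str, ...] = ("TP7",)

    # ERP measurement
    rejection_threshold_uv: float = 120.0
    windows_ms: dict[str, tuple[float, float]] = {
        "full": (300.0, 700.0),
        "early": (300.0, 500.0),
        "late": (500.0, 700.0),
    }

    # statistics
    alpha: float = 0.05
    fdr_q: float = 0.10

    # noise overrides for the simulator (field name -> value)
    noise: dict[str, float] = {}

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def demo_config(out_dir: str = "nbackerp_demo", seed: int = 0) -> RunConfig:
    """Small configuration for smoke tests: 4 subjects/group, two short blocks."""
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        n_per_group=4,
        blocks=(1, 2),
        n_trials_per_block=40,
        n_targets_per_block=10,
    )
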