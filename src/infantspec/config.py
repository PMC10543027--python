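"""Validated pipeline configuration with the study's analysis defaults."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = ["PipelineConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PsdConfig(_Strict):
    n_tapers: int = 3
    time_half_bandwidth: float = 2.0
    segment_length: float = 2.0


class QcConfig(_Strict):
    min_segments: int = 20
    min_pct_good_channels: float = 80.0
    max_pct_ics_rejected: float = 80.0
    max_mean_artifact_prob: float = 0.3
    min_pct_variance_retained: float = 25.0


class SpecparamConfig(_Strict):
    fit_range: tuple[float, float] = (2.5, 50.0)
    max_n_peaks: int = 7
    peak_threshold: float = 2.0
    peak_width_limits: tuple[float, float] = (0.5, 18.0)
    min_peak_height: float = 0.0
    robust_percentile: float = 2.5
    variant: str = "modified"

    @field_validator("variant")
    @classmethod
    def _variant_ok(cls, v: str) -> str:
        if v not in ("modified", "original"):
            raise ValueError("variant must be 'modified' or 'original'")
        return v


class FeaturesConfig(_Strict):
    target_resolution: float = 0.1
    savgol_window: int = 101
    savgol_polyorder: int = 8
    min_peak_amplitude: float = 0.0
    integrate_smoothed: bool = False


class TrajectoriesConfig(_Strict):
    k: int = 4
    alpha: float = 0.05
    random_slope: bool = True
    extrema_order: int = 100


class CoherenceConfig(_Strict):
    alpha_band: tuple[float, float] = (8.0, 13.0)
    epoch_length: float = 30.0
    k_sd: float = 3.0
    window_length: float = 6.0
    time_bandwidth: float = 3.0
    n_tapers: int = 5
    sevo_window: float = 120.0
    sevo_tol: float = 0.2


class PipelineConfig(_Strict):
    """All stage parameters; defaults are the study's analysis settings."""

    psd: PsdConfig = PsdConfig()
    qc: QcConfig = QcConfig()
    specparam: SpecparamConfig = SpecparamConfig()
    features: FeaturesConfig = FeaturesConfig()
    trajectories: TrajectoriesConfig = TrajectoriesConfig()
    coherence: CoherenceConfig = CoherenceConfig()
    seed: int = 0


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
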