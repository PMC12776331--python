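"""Pipeline configuration: a validated YAML block shared by CLI subcommands."""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["PipelineConfig", "SpectralConfig", "BandConfig", "SDConfig",
           "MSLTConfig", "StatsConfig", "load_config"]


class BandConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lo_hz: float
    hi_hz: float

    @model_validator(mode="after")
    def _ordered(self):
        if not self.lo_hz < self.hi_hz:
            raise ValueError("band lo_hz must be < hi_hz")
        return self


class SpectralConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fs: float = 500.0
    nfft: int = 8192
    window_fn: str = "hann"
    f_min: float = 0.5
    f_max: float = 60.0
    exclusion_epochs: int = 2


class SDConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sd_start_zt_h: float = 0.0
    sd_duration_h: float = 6.0
    rs_window: tuple[float, float] = (6.0, 11.0)
    followup_dark_window: tuple[float, float] = (12.0, 24.0)


class MSLTConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nap_windows: list[tuple[float, float]] = Field(
        default_factory=lambda: [(7200.0 + i * 7200.0, 1200.0) for i in range(5)])


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    welch: bool = False
    family_range_hz: tuple[float, float] | None = None


class PipelineConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected with a clear message."""

    model_config = ConfigDict(extra="forbid")
    epoch_s: float = 10.0
    lights_on_h: float = 0.0
    lights_off_h: float = 12.0
    spectral: SpectralConfig = Field(default_factory=SpectralConfig)
    bands: dict[str, BandConfig] = Field(default_factory=lambda: {
        "delta": BandConfig(lo_hz=0.5, hi_hz=4.0),
        "theta": BandConfig(lo_hz=6.0, hi_hz=9.0),
        "alpha": BandConfig(lo_hz=9.0, hi_hz=12.0),
        "beta": BandConfig(lo_hz=12.0, hi_hz=30.0),
        "low_gamma": BandConfig(lo_hz=30.0, hi_hz=60.0),
    })
    sd: SDConfig = Field(default_factory=SDConfig)
    mslt: MSLTConfig = Field(default_factory=MSLTConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    seed: int = 0

    def spectral_params(self):
        from .spectral import SpectralParams
        return SpectralParams(fs=self.spectral.fs, nfft=self.spectral.nfft,
                              window_fn=self.spectral.window_fn,
                              f_min=self.spectral.f_min, f_max=self.spectral.f_max)

    def band_definitions(self):
        from .spectral import BandDefinition
        return {n: BandDefinition(n, b.lo_hz, b.hi_hz) for n, b in self.bands.items()}


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; a missing file or bad key raises."""
    import yaml
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)
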