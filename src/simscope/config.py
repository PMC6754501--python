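"""Run configuration: validated structured-text (YAML/JSON) config with CLI
overrides.  Unknown keys are rejected with their location; the seed and a
config hash are recorded in every artifact the CLI writes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["OpticsConfig", "ReconConfig", "RunConfig", "StreamConfig",
           "TimingSection", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class OpticsConfig(_Strict):
    na: float = 1.33
    em_wavelengths_um: list[float] = Field(default_factory=lambda: [0.515])
    pixel_size_um: float = 0.08

    @field_validator("na")
    @classmethod
    def _na_range(cls, v: float) -> float:
        if not 0 < v < 2:
            raise ValueError("na must be in (0, 2)")
        return v


class IlluminationConfig(_Strict):
    k_fraction: float = 0.8  # pattern frequency as a fraction of the cutoff
    modulation: float = 0.9
    angle_offset_deg: float = 10.0


class ReconConfig(_Strict):
    wiener_w: float = 0.05
    attenuation_on: bool = False
    attenuation_strength: float = 0.99
    attenuation_fwhm: float = 1.2
    apodization: str = "ideal-otf"
    clip_negative: bool = True


class TimingSection(_Strict):
    exposure_ms: float = 1.0
    n_channels: int = 1
    roi_lines: int = 512
    slm_switch_ms: float = 0.44
    interframe_delay_ms: float = 0.0
    overhead_ms: float = 0.0


class StreamConfig(_Strict):
    ring_capacity: int = 8
    port: int = 0
    n_links: int = 1


class RunConfig(_Strict):
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    illumination: IlluminationConfig = Field(default_factory=IlluminationConfig)
    recon: ReconConfig = Field(default_factory=ReconConfig)
    timing: TimingSection = Field(default_factory=TimingSection)
    stream: StreamConfig = Field(default_factory=StreamConfig)
    seed: int = 0
    output_dir: str = "."
    sample_metadata: dict[str, str] = Field(default_factory=dict)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML/JSON config file; keyword overrides win."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    for key, value in overrides.items():
        if value is None:
            continue
        section, _, leaf = key.partition(".")
        if leaf:
            data.setdefault(section, {})[leaf] = value
        else:
            data[key] = value
    return RunConfig.model_validate(data)
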