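"""Run configuration: validated, serializable, reject-unknown-keys."""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from fullersim.bonds import VARIANTS

__all__ = ["MDSettings", "AnalysisSettings", "RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MDSettings(_Strict):
    dt_fs: float = 1.0
    duration_ps: float = 100.0
    T_K: float = 298.0
    tau_fs: float = 100.0
    stride: int = 10
    seed: int = 7

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ps * 1000.0 / self.dt_fs))


class AnalysisSettings(_Strict):
    bin_width_A: float = 0.01
    prominence: float = 0.005  # raw peak listing (permissive)
    spectrum_segments: int = 8  # Welch averaging of the Rg periodogram
    band_min_sep_THz: float = 0.5  # peaks closer than this are one mode
    band_floor_factor: float = 5.0  # candidate height over the noise floor
    band_rel_power: float = 0.3  # prominence fraction for a distinct mode
    entropy_source: str = "minimized"  # or "trajectory" (pooled frames)
    esp_extent_A: float = 16.0
    esp_spacing_A: float = 0.25
    charge_model: str = "formal"  # "formal" (all-zero) or "increment"
    charge_delta_e: float = 0.01


class RunConfig(_Strict):
    variants: list[str] = list(VARIANTS)
    edge_length_A: float = 1.44
    ff: dict[str, float | str] = {}
    md: MDSettings = MDSettings()
    analysis: AnalysisSettings = AnalysisSettings()
    output_dir: str = "runs"

    @field_validator("variants")
    @classmethod
    def _known_variants(cls, v):
        for name in v:
            if name not in VARIANTS:
                raise ValueError(f"unknown variant {name!r}")
        return v

    # -- serialization -------------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
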