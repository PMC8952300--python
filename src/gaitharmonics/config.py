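"""Pipeline configuration with the published default parameter values."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError
from .orientation import GiofConfig
from .synthetic import GaitSimConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline defaults.

    The defaults are the values the method was established with: 100 Hz
    sampling, 2000-point stride resampling, five significant harmonics for
    the thigh angle and nine for the gyro signal, a 1 % median-amplitude
    significance cutoff, a 2.5 % RMSE template-grouping cutoff, and a
    four-fold stride cascade before the per-stride FFT.
    """

    sampling_rate_hz: float = 100.0
    resample_points: int = 2000
    n_harmonics_angle: int = 5
    n_harmonics_gyro: int = 9
    significance_cutoff: float = 0.01
    template_rmse_cutoff: float = 0.025
    cascade_copies: int = 4
    orientation: GiofConfig = field(default_factory=GiofConfig)
    simulation: GaitSimConfig = field(default_factory=GaitSimConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["pattern_sequence"] = list(self.simulation.pattern_sequence)
        d["simulation"]["angle_range_deg"] = list(self.simulation.angle_range_deg)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        try:
            if "orientation" in data:
                data["orientation"] = GiofConfig(**data["orientation"])
            if "simulation" in data:
                sim = dict(data["simulation"])
                if "pattern_sequence" in sim:
                    sim["pattern_sequence"] = tuple(sim["pattern_sequence"])
                if "angle_range_deg" in sim:
                    sim["angle_range_deg"] = tuple(sim["angle_range_deg"])
                data["simulation"] = GaitSimConfig(**sim)
            return cls(**data)
        except TypeError as exc:
            raise FormatError(f"invalid pipeline configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: expected a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
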