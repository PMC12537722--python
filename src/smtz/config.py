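"""Flat pipeline configuration, serialized as key: value YAML."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .compare import SeasonWindow
from .headspace import JarGeometry, LabConditions

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every constant the pipeline stages consume, in one flat record."""

    # jar geometry (mL) and porosity
    jar_volume: float = 600.0
    sediment_volume: float = 133.0
    water_added: float = 200.0
    headspace_volume: float = 200.0
    porosity: float = 0.8
    # lab equilibration conditions
    lab_temperature_k: float = 294.15
    lab_pressure_atm: float = 1.0
    henry_constant: float = 1.4e-3
    henry_ref_temperature_k: float = 298.15
    henry_vant_hoff_k: float = 1700.0
    include_dissolved: bool = True
    # diffusion / flux
    d0_m0: float = 4.88
    d0_m1: float = 0.232
    r2_threshold: float = 0.90
    include_porosity_factor: bool = True
    # sediment temperatures (degC) used for D0 per (bay, season)
    temp_control_summer: float = 19.9
    temp_control_winter: float = 2.7
    temp_heated_summer: float = 23.9
    temp_heated_winter: float = 9.5
    # season windows (ISO dates)
    summer_start: str = "2021-06-01"
    summer_end: str = "2021-09-22"
    winter_start: str = "2021-12-21"
    winter_end: str = "2022-03-20"
    # comparisons
    detection_floor_mm: float = 1e-4
    fold_change_depth_cm: float = 4.0
    # community
    n_permutations: int = 999
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        # consuming constructors revalidate; fail fast on the obvious ones
        self.jar_geometry()
        self.lab_conditions()
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.detection_floor_mm <= 0:
            raise ValueError("detection_floor_mm must be positive")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be at least 99")

    def jar_geometry(self) -> JarGeometry:
        return JarGeometry(
            jar_volume=self.jar_volume,
            sediment_volume=self.sediment_volume,
            water_added=self.water_added,
            headspace_volume=self.headspace_volume,
            porosity=self.porosity,
        )

    def lab_conditions(self) -> LabConditions:
        return LabConditions(
            temperature=self.lab_temperature_k,
            pressure=self.lab_pressure_atm,
            henry_constant=self.henry_constant,
            henry_ref_temperature=self.henry_ref_temperature_k,
            henry_vant_hoff=self.henry_vant_hoff_k,
        )

    def season_windows(self) -> dict[str, SeasonWindow]:
        return {
            "summer": SeasonWindow("summer", self.summer_start, self.summer_end),
            "winter": SeasonWindow("winter", self.winter_start, self.winter_end),
        }

    def temperature_for(self, bay: str, season: str) -> float:
        try:
            return getattr(self, f"temp_{bay}_{season}")
        except AttributeError:
            raise ValueError(f"no configured temperature for bay={bay!r}, season={season!r}") from None

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance headers."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
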