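"""Experiment configuration: one structured file drives the whole pipeline.

Defaults reproduce the reference study conditions: 60 Gy in 30 x 2 Gy
fractions, PTV = CTV + 5 mm, 10 mm ring, 3 mm spot spacing and in-air sigma,
1 MeV energy resolution, 1% energy spread, energy-margin distance d = 6 mm,
setup error sigma 2 mm with a +/-4 mm per-axis cutoff and 6 mm 3D bound.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._engine import EngineParams
from .fluence_opt import PlanObjectives
from .phantom import PhantomSpec
from .proton_dose import RangeEnergyModel

__all__ = ["PlanningConfig", "CourseConfig", "OptimizerConfig",
           "ExperimentConfig"]


@dataclass
class PlanningConfig:
    arrangement: str = "full_arc"
    start_angle: float = 0.0
    spot_spacing: float = 3.0
    d: float = 6.0
    neighborhood: str = "box"
    sigma_air: float = 3.0
    energy_spread: float = 0.01


@dataclass
class OptimizerConfig:
    iters: int = 200
    tol: float = 1e-7
    sample_fraction: float = 0.1
    threshold: float = 0.005
    sample_seed: int = 0


@dataclass
class CourseConfig:
    n_fractions: int = 30
    sigma: float = 2.0
    cutoff: float = 4.0
    max_3d: float | None = 6.0
    seed: int = 1234


@dataclass
class ExperimentConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    planning: PlanningConfig = field(default_factory=PlanningConfig)
    objectives: PlanObjectives = field(default_factory=PlanObjectives)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    course: CourseConfig = field(default_factory=CourseConfig)
    range_alpha: float = 0.0022
    range_p: float = 1.77
    mcs_fraction: float = 0.02

    def engine_params(self) -> EngineParams:
        return EngineParams(
            model=RangeEnergyModel(alpha=self.range_alpha, p=self.range_p),
            sigma_air=self.planning.sigma_air,
            energy_spread=self.planning.energy_spread,
            mcs_fraction=self.mcs_fraction,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance stamps."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d or {})
        kwargs = {}
        if "phantom" in d:
            kwargs["phantom"] = PhantomSpec.from_dict(d.pop("phantom"))
        for key, sub in (("planning", PlanningConfig),
                         ("objectives", PlanObjectives),
                         ("optimizer", OptimizerConfig),
                         ("course", CourseConfig)):
            if key in d:
                kwargs[key] = sub(**d.pop(key))
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
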