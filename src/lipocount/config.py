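"""Generative specification for synthetic particle populations.

The configuration captures everything the simulator needs to emulate a
negative-stain EM counting experiment on lipoprotein/CETP mixtures: per-class
diameter distributions, per-condition binding propensities, the multiplicity
split among bound particles, ternary (HDL-CETP-LDL bridge) targets, the rod
protrusion length governing projection occlusion, measurement noise, and the
HDL shrinkage time course.  ``default_config()`` returns the configuration
whose truths match the study conditions this package is tested against.

Configs round-trip through YAML (`load_config` / `save_config`) and validate
eagerly via pydantic, reporting every offending field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

CONDITION_NAMES = ("control", "Torcetrapib", "Dalcetrapib", "Anacetrapib")


class ClassSpec(BaseModel):
    """One lipoprotein class: diameter distribution and multiplicity split."""

    name: str
    diameter_mean: float = Field(gt=0, description="mean diameter, nm")
    diameter_sd: float = Field(ge=0, description="diameter SD, nm")
    multiplicity: dict[int, float] = Field(
        default={1: 1.0},
        description="distribution of CETPs per bound particle (count -> prob)",
    )

    @field_validator("multiplicity")
    @classmethod
    def _check_multiplicity(cls, v: dict[int, float]) -> dict[int, float]:
        if not v:
            raise ValueError("multiplicity distribution may not be empty")
        if any(k < 1 for k in v):
            raise ValueError("multiplicity counts must be >= 1")
        if any(p < 0 for p in v.values()):
            raise ValueError("multiplicity probabilities must be non-negative")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("multiplicity probabilities must sum to 1")
        return v


class ConditionSpec(BaseModel):
    """One experimental condition: per-class binding propensities."""

    name: str
    propensity: dict[str, float] = Field(
        description="class name -> probability a particle binds >= 1 CETP"
    )

    @field_validator("propensity")
    @classmethod
    def _check_propensity(cls, v: dict[str, float]) -> dict[str, float]:
        for k, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"propensity[{k}]={p} outside [0, 1]")
        return v


class TernarySpec(BaseModel):
    """Targets for the two-lipoprotein (HDL + LDL) bridging experiment.

    ``hdl_fraction`` is the baseline (control) probability that an HDL ends up
    in a ternary bridge; per-condition ``modulation`` scales it multiplicatively
    (the inhibitors' observed suppression of bridging).  ``ldl_fraction`` sets
    the target ternary fraction on the LDL side per condition, which fixes the
    simulated HDL:LDL particle-count ratio.  ``bridge_given_bound`` is the
    probability that a CETP-bound HDL in the mixture actually bridges an LDL;
    the mixture bound fraction is therefore
    ``hdl_fraction * modulation / bridge_given_bound``.
    """

    hdl_fraction: float = Field(default=0.122, ge=0, le=1)
    ldl_fraction: dict[str, float] = Field(
        default={
            "control": 0.195,
            "Torcetrapib": 0.175,
            "Dalcetrapib": 0.174,
            "Anacetrapib": 0.166,
        }
    )
    modulation: dict[str, float] = Field(
        default={
            "control": 1.0,
            "Torcetrapib": 0.566,
            "Dalcetrapib": 0.795,
            "Anacetrapib": 0.534,
        }
    )
    bridge_given_bound: float = Field(default=0.8, gt=0, le=1)

    @field_validator("ldl_fraction")
    @classmethod
    def _check_ldl(cls, v: dict[str, float]) -> dict[str, float]:
        for k, p in v.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"ldl_fraction[{k}]={p} outside (0, 1]")
        return v

    @field_validator("modulation")
    @classmethod
    def _check_mod(cls, v: dict[str, float]) -> dict[str, float]:
        for k, m in v.items():
            if m <= 0:
                raise ValueError(f"modulation[{k}]={m} must be > 0")
        return v

    def hdl_ternary_fraction(self, condition: str) -> float:
        f = self.hdl_fraction * self.modulation.get(condition, 1.0)
        if f > 1.0:
            raise ValueError(
                f"effective HDL ternary fraction {f:.3f} for {condition!r} exceeds 1"
            )
        return f


class TimecourseSpec(BaseModel):
    """Fractional HDL diameter decrease per condition at each time point.

    ``times_min`` must be non-negative and strictly increasing, starting at 0;
    ``decreases[condition]`` aligns with ``times_min`` and gives the expected
    fractional decrease of the mean HDL diameter (0.17 means a 17% shrinkage).
    """

    times_min: list[float] = Field(default=[0.0, 15.0, 40.0, 120.0, 480.0])
    decreases: dict[str, list[float]] = Field(
        default={
            "control": [0.0, 0.0, 0.17, 0.21, 0.30],
            "Torcetrapib": [0.0, 0.0, 0.0, 0.10, 0.25],
            "Dalcetrapib": [0.0, 0.0, 0.17, 0.21, 0.30],
            "Anacetrapib": [0.0, 0.0, 0.0, 0.10, 0.25],
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "TimecourseSpec":
        t = self.times_min
        if not t or t[0] != 0.0:
            raise ValueError("times_min must start at 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times_min must be strictly increasing")
        if any(x < 0 for x in t):
            raise ValueError("times_min must be non-negative")
        for cond, dec in self.decreases.items():
            if len(dec) != len(t):
                raise ValueError(
                    f"decreases[{cond}] has {len(dec)} entries for {len(t)} times"
                )
            if any(not 0.0 <= d < 1.0 for d in dec):
                raise ValueError(f"decreases[{cond}] must lie in [0, 1)")
            if dec[0] != 0.0:
                raise ValueError(f"decreases[{cond}] must be 0 at time 0")
        return self

    def decrease_at(self, condition: str, time_min: float) -> float:
        """Piecewise-linear interpolation of the fractional decrease."""
        import numpy as np

        if condition not in self.decreases:
            raise KeyError(f"no time course configured for condition {condition!r}")
        return float(
            np.interp(time_min, self.times_min, self.decreases[condition])
        )


class GeometrySpec(BaseModel):
    """One rod-on-sphere geometry to evaluate in reports."""

    sphere_diameter: float = Field(gt=0)
    rod_length: float = Field(default=8.0, ge=0)
    rod_diameter: float = Field(default=2.5, gt=0)
    merged_length: float = Field(default=5.0, ge=0)


class SimulationConfig(BaseModel):
    """Full generative specification for a synthetic particle population."""

    classes: list[ClassSpec]
    conditions: list[ConditionSpec]
    ternary: Optional[TernarySpec] = None
    timecourse: Optional[TimecourseSpec] = None
    geometries: list[GeometrySpec] = Field(default_factory=list)
    rod_length: float = Field(default=8.0, gt=0, description="protrusion length, nm")
    measurement_noise_sd: float = Field(default=0.4, ge=0, description="nm per axis")
    n_particles: int = Field(default=400, ge=1, description="per class per condition")
    seed: int = 0

    @model_validator(mode="after")
    def _cross_check(self) -> "SimulationConfig":
        class_names = {c.name for c in self.classes}
        for cond in self.conditions:
            unknown = set(cond.propensity) - class_names
            if unknown:
                raise ValueError(
                    f"condition {cond.name!r} names unknown classes {sorted(unknown)}"
                )
        return self

    def class_spec(self, name: str) -> ClassSpec:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(f"no class named {name!r}")

    def condition_spec(self, name: str) -> ConditionSpec:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(f"no condition named {name!r}")


def default_config(seed: int = 0, n_particles: int = 400) -> SimulationConfig:
    """The paper-parameterized configuration: class diameter distributions,
    per-condition binding propensities, ternary bridging targets, and the HDL
    shrinkage time course used as simulator ground truth throughout."""
    return SimulationConfig(
        classes=[
            ClassSpec(
                name="HDL", diameter_mean=12.28, diameter_sd=1.91,
                multiplicity={1: 0.80, 2: 0.15, 3: 0.05},
            ),
            ClassSpec(
                name="LDL", diameter_mean=23.6, diameter_sd=1.3,
                multiplicity={1: 0.85, 2: 0.12, 3: 0.03},
            ),
            ClassSpec(
                name="VLDL", diameter_mean=38.28, diameter_sd=7.12,
                multiplicity={1: 0.40, 2: 0.35, 3: 0.25},
            ),
        ],
        conditions=[
            ConditionSpec(
                name="control",
                propensity={"HDL": 0.099, "LDL": 0.129, "VLDL": 0.351},
            ),
            ConditionSpec(
                name="Torcetrapib",
                propensity={"HDL": 0.505, "LDL": 0.218, "VLDL": 0.463},
            ),
            ConditionSpec(
                name="Dalcetrapib",
                propensity={"HDL": 0.292, "LDL": 0.226, "VLDL": 0.470},
            ),
            ConditionSpec(
                name="Anacetrapib",
                propensity={"HDL": 0.431, "LDL": 0.234, "VLDL": 0.500},
            ),
        ],
        ternary=TernarySpec(),
        timecourse=TimecourseSpec(),
        geometries=[
            GeometrySpec(sphere_diameter=10.0, rod_length=8.0,
                         rod_diameter=2.5, merged_length=5.0),
            GeometrySpec(sphere_diameter=30.0, rod_length=8.0,
                         rod_diameter=2.5, merged_length=5.0),
        ],
        seed=seed,
        n_particles=n_particles,
    )


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML config file and validate it."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ValueError(f"empty config file: {path}")
    return SimulationConfig.model_validate(raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as YAML (round-trips through `load_config`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
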