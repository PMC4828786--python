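"""Run configuration: schema-validated, unit-tagged YAML/JSON documents.

One document describes a complete run: balloon design, materials,
optional phantom, inflation protocol, solver options and noise spec.
All quantities carry their unit in the field name; unknown keys are
rejected.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import InvalidInputError
from .geometry import BalloonDesign, InflationProtocol
from .materials import LinearElasticModel, OgdenModel
from .solver import SolverOptions
from .synthetic import NoiseSpec
from .vessel import CylinderPhantom


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignCfg(_Strict):
    nominal_diameter_mm: float = Field(23.0, gt=0)
    cylinder_length_mm: float = Field(40.0, gt=0)
    total_length_mm: float = Field(75.0, gt=0)
    thickness_mm: float = Field(0.09, gt=0)
    shaft_radius_mm: float = Field(3.0, gt=0)
    head_exponent: float = Field(1.0, gt=0)

    def to_design(self) -> BalloonDesign:
        return BalloonDesign(**self.model_dump())


class OgdenCfg(_Strict):
    type: Literal["ogden"] = "ogden"
    N: int = Field(3, ge=1)
    mu: list[float]
    alpha: list[float]
    delta: list[float] | None = None
    units: str = "MPa"
    poisson: float = Field(0.45, ge=0, le=0.5)

    @field_validator("mu")
    @classmethod
    def _positive_shear(cls, v):
        if sum(v) <= 0:
            raise ValueError("sum(mu) must be positive (initial shear modulus)")
        return v

    def to_material(self) -> OgdenModel:
        if len(self.mu) != self.N:
            raise InvalidInputError("len(mu) must equal N")
        return OgdenModel(
            mu=tuple(self.mu),
            alpha=tuple(self.alpha),
            delta=tuple(self.delta) if self.delta is not None else None,
            poisson=self.poisson,
            units=self.units,
        )


class LinearCfg(_Strict):
    type: Literal["linear"] = "linear"
    young_modulus_mpa: float = Field(gt=0)
    poisson: float = Field(0.25, ge=0, lt=0.5)

    def to_material(self) -> LinearElasticModel:
        return LinearElasticModel(
            young_modulus=self.young_modulus_mpa, poisson=self.poisson
        )


MaterialCfg = Union[OgdenCfg, LinearCfg]


class PhantomCfg(_Strict):
    inner_diameter_mm: float = Field(gt=0)
    thickness_mm: float = Field(gt=0)
    length_mm: float = Field(gt=0)
    end_band_mm: float = Field(0.0, ge=0)
    label: str | None = None
    material: LinearCfg | Literal["rigid"] = "rigid"

    def to_phantom(self) -> CylinderPhantom:
        return CylinderPhantom(
            inner_diameter_mm=self.inner_diameter_mm,
            thickness_mm=self.thickness_mm,
            length_mm=self.length_mm,
            end_band_mm=self.end_band_mm,
            label=self.label,
        )

    def to_material(self) -> LinearElasticModel | None:
        if self.material == "rigid":
            return None
        return self.material.to_material()


class ProtocolCfg(_Strict):
    flow_rate_ml_h: float = Field(40.0, gt=0)
    sampling_interval_s: float = Field(15.0, gt=0)
    initial_volume_ml: float | None = Field(None, gt=0)
    injected_volume_ml: float = Field(3.0, gt=0)

    def to_protocol(self) -> InflationProtocol:
        return InflationProtocol(**self.model_dump())


class SolverCfg(_Strict):
    n_elements: int = Field(200, ge=20)
    ftol: float = Field(1e-8, gt=0)
    vtol: float = Field(1e-9, gt=0)
    max_step_ml: float = Field(0.25, gt=0)
    penalty_scale: float = Field(1e3, gt=0)

    def to_options(self) -> SolverOptions:
        return SolverOptions(
            ftol=self.ftol,
            vtol=self.vtol,
            max_step_ml=self.max_step_ml,
            penalty_scale=self.penalty_scale,
        )


class NoiseCfg(_Strict):
    pressure_std_mmhg: float = Field(10.0, ge=0)
    pressure_quantum_mmhg: float = Field(152.0, ge=0)
    diameter_quantum_mm: float = Field(0.5, ge=0)
    stress_std: float = Field(0.0, ge=0)
    strain_std: float = Field(0.0, ge=0)
    volume_std_ml: float = Field(0.0, ge=0)
    seed: int = 0

    def to_noise(self, seed: int | None = None) -> NoiseSpec:
        data = self.model_dump()
        if seed is not None:
            data["seed"] = seed
        return NoiseSpec(**data)


class RunConfig(_Strict):
    """Validated, unit-tagged description of one simulation/bench run."""

    schema_version: int = 1
    design: DesignCfg = DesignCfg()
    material: MaterialCfg = Field(
        discriminator="type",
        default_factory=lambda: OgdenCfg(
            mu=[-4715.57, 2480.94, 2479.35],
            alpha=[4.89, 6.90, 1.13],
            delta=[1.38, 0.0, 0.0],
        ),
    )
    phantom: PhantomCfg | None = None
    protocol: ProtocolCfg = ProtocolCfg()
    solver: SolverCfg = SolverCfg()
    noise: NoiseCfg = NoiseCfg()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        raise InvalidInputError(f"empty config file: {path}")
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def default_config(name: str = "free_inflation") -> RunConfig:
    """Load one of the packaged example configurations."""
    from importlib import resources

    ref = resources.files("balloonmech").joinpath(f"configs/{name}.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)
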