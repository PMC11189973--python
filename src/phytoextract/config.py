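"""Validated run configuration (YAML/JSON) for the command-line interface."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .core import SoilCompartment
from .datasets import load_dataset
from .distributions import DistributionSpec
from .monte_carlo import DEFAULT_SEED, SimulationConfig

__all__ = ["SoilBlock", "SpecBlock", "ScenarioBlock", "RunConfig"]


class SoilBlock(BaseModel):
    c_soil_i: float = Field(gt=0)
    c_target: float = Field(default=1.0, ge=0)
    rho: float = Field(default=1500.0, gt=0)
    depth: float = Field(default=0.35, gt=0)
    area: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _target_below_initial(self) -> "SoilBlock":
        if self.c_target >= self.c_soil_i:
            raise ValueError("c_target must be below c_soil_i")
        return self

    def to_compartment(self) -> SoilCompartment:
        return SoilCompartment(
            c_soil_i=self.c_soil_i,
            c_soil_f=self.c_target,
            rho=self.rho,
            depth=self.depth,
            area=self.area,
        )


class SpecBlock(BaseModel):
    kind: Literal["pert", "normal", "point"]
    params: dict[str, float]
    truncate_at_zero: bool = False

    def to_spec(self) -> DistributionSpec:
        return DistributionSpec.from_dict(self.model_dump())


class ScenarioBlock(BaseModel):
    name: Literal["a", "b", "c"]
    horizon: float = Field(default=25.0, gt=0)
    baf_values: list[float] = Field(default=[8, 10, 12, 14, 16, 18])
    c_values: list[float] = Field(default=[10, 9, 8, 7, 6, 5, 4, 3, 2])


class RunConfig(BaseModel):
    """Full description of a run; validated before any computation."""

    dataset: Optional[str] = None
    input_specs: Optional[dict[str, SpecBlock]] = None
    soil: SoilBlock = SoilBlock(c_soil_i=10.0)
    model: Literal["linear", "exponential", "both"] = "both"
    n_iterations: int = Field(default=10_000, ge=100)
    seed: int = DEFAULT_SEED
    efficiency: float = Field(default=1.0, gt=0)
    scenario: Optional[ScenarioBlock] = None

    @model_validator(mode="after")
    def _has_inputs(self) -> "RunConfig":
        if self.dataset is None and self.input_specs is None:
            raise ValueError("either a dataset name or inline input_specs is required")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.model_validate(data)

    def resolved_specs(self) -> dict[str, DistributionSpec]:
        specs: dict[str, DistributionSpec] = {}
        if self.dataset is not None:
            specs = load_dataset(self.dataset).specs()
        if self.input_specs is not None:
            specs.update({k: v.to_spec() for k, v in self.input_specs.items()})
        return specs

    def to_simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            soil=self.soil.to_compartment(),
            input_specs=self.resolved_specs(),
            n_iterations=self.n_iterations,
            seed=self.seed,
            model=self.model,
            efficiency=self.efficiency,
        )

    @classmethod
    def from_result_meta(cls, meta: dict) -> "RunConfig":
        """Rebuild an equivalent config from a result's config echo."""
        soil = meta["soil"]
        return cls(
            input_specs={
                k: SpecBlock.model_validate(v) for k, v in meta["input_specs"].items()
            },
            soil=SoilBlock(
                c_soil_i=soil["c_soil_i"],
                c_target=soil["c_soil_f"],
                rho=soil["rho"],
                depth=soil["depth"],
                area=soil["area"],
            ),
            model=meta["model"],
            n_iterations=meta["n_iterations"],
            seed=meta["seed"],
            efficiency=meta["efficiency"],
        )
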