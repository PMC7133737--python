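"""Structured run configuration (YAML/JSON) for the CLI and pipeline.

One config file describes a run in sections — ``compound``, ``physiology``,
``clearance``, ``dose``, ``simulation``, ``saliva``, and optionally
``population`` and ``sensitivity``.  Unknown keys anywhere are hard errors
(``extra="forbid"``): a typo in a parameter name must never silently fall
back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .compound import ClearanceSpec, Compound, get_compound
from .model import DEFAULT_K_SAL_PER_HR, SimulationConfig
from .physiology import Physiology, get_species_physiology, scale_physiology
from .population import PopulationSpec
from .sensitivity import (
    DEFAULT_COMPARTMENTS,
    DEFAULT_DOSES_MG_KG,
    DEFAULT_FACTORS,
    DEFAULT_OUTPUTS,
    PARAMETER_ALIASES,
)

__all__ = ["RunConfig", "load_run_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CompoundSection(_StrictModel):
    """Either a shipped fixture reference (plus required fu) or explicit values."""

    fixture: str | None = None
    name: str = "compound"
    molecular_weight_g_mol: float | None = None
    logP: float | None = None
    pKa: float | None = None
    solubility_pH74_mg_ml: float | None = None
    fu_plasma: float | None = None
    binding_protein: str = "albumin"

    def build(self) -> Compound:
        if self.fixture is not None:
            return get_compound(self.fixture, fu_plasma=self.fu_plasma)
        required = {
            "molecular_weight_g_mol": self.molecular_weight_g_mol,
            "logP": self.logP,
            "pKa": self.pKa,
            "solubility_pH74_mg_ml": self.solubility_pH74_mg_ml,
            "fu_plasma": self.fu_plasma,
        }
        missing = [k for k, v in required.items() if v is None]
        if missing:
            raise ValueError(f"compound section missing required fields: {missing}")
        return Compound(
            name=self.name,
            binding_protein=self.binding_protein,
            **required,
        )


class PhysiologySection(_StrictModel):
    species: str
    body_weight_kg: float | None = None  # rescale the reference if set
    overrides: dict = Field(default_factory=dict)

    def build(self) -> Physiology:
        phys = get_species_physiology(self.species, self.overrides or None)
        if self.body_weight_kg is not None:
            phys = scale_physiology(phys, self.body_weight_kg)
        return phys


class ClearanceSection(_StrictModel):
    mode: Literal["calibrated_total", "enzymatic"] = "calibrated_total"
    total_plasma_clearance_ml_min_kg: float | None = None
    vmax_ng_min: float | None = None
    km_ng_ml: float | None = None

    def build(self) -> ClearanceSpec:
        return ClearanceSpec(
            mode=self.mode,
            total_plasma_clearance_ml_min_kg=self.total_plasma_clearance_ml_min_kg,
            vmax_ng_min=self.vmax_ng_min,
            km_ng_ml=self.km_ng_ml,
        )


class DoseSection(_StrictModel):
    amount_mg_per_kg: float
    route: Literal["iv_bolus"] = "iv_bolus"
    time_hr: float = 0.0


class SimulationSection(_StrictModel):
    t_start_hr: float = 0.0
    t_end_hr: float = 24.0
    grid_step_hr: float = 0.05
    rtol: float = 1e-9
    atol_ng: float | None = None
    method: str = "LSODA"
    seed: int | None = None

    def build(self) -> SimulationConfig:
        return SimulationConfig(
            t_start_hr=self.t_start_hr,
            t_end_hr=self.t_end_hr,
            grid_step_hr=self.grid_step_hr,
            rtol=self.rtol,
            atol_ng=self.atol_ng,
            method=self.method,
            seed=self.seed,
        )


class SalivaSection(_StrictModel):
    k_sal_per_hr: float = DEFAULT_K_SAL_PER_HR
    k_saliva: float | None = None  # None -> fu_plasma


class PopulationSection(_StrictModel):
    n: int = 100
    weight_range_kg: tuple[float, float] | None = None
    age_range_yr: tuple[float, float] | None = None
    sex_ratio_female: float = 0.5
    seed: int = 0
    weight_distribution: Literal["uniform", "gaussian"] = "uniform"

    def build(self, species: str) -> PopulationSpec:
        return PopulationSpec(
            species=species,
            n=self.n,
            weight_range_kg=self.weight_range_kg,
            age_range_yr=self.age_range_yr,
            sex_ratio_female=self.sex_ratio_female,
            seed=self.seed,
            weight_distribution=self.weight_distribution,
        )


class SensitivitySection(_StrictModel):
    parameters: list[str] = Field(default_factory=lambda: list(PARAMETER_ALIASES))
    factors: list[float] = Field(default_factory=lambda: list(DEFAULT_FACTORS))
    doses_mg_per_kg: list[float] = Field(default_factory=lambda: list(DEFAULT_DOSES_MG_KG))
    outputs: list[str] = Field(default_factory=lambda: list(DEFAULT_OUTPUTS))
    compartments: list[str] = Field(default_factory=lambda: list(DEFAULT_COMPARTMENTS))


class RunConfig(_StrictModel):
    """Top-level run description."""

    compound: CompoundSection
    physiology: PhysiologySection
    clearance: ClearanceSection
    dose: DoseSection
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    saliva: SalivaSection = Field(default_factory=SalivaSection)
    population: PopulationSection | None = None
    sensitivity: SensitivitySection | None = None

    def build_kwargs(self) -> dict:
        return {
            "k_sal_per_hr": self.saliva.k_sal_per_hr,
            "k_saliva": self.saliva.k_saliva,
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.model_validate(payload)
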