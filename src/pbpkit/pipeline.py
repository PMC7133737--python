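"""End-to-end study pipeline: both species' population PK plus sensitivity.

``run_study`` executes the full workflow on the shipped references — a
0.1 mg/kg IV bolus of AT-RvD1 in n-individual NOD/ShiLtJ mouse and adult
human virtual populations over 0–24 hr, per-individual NCA, population
summary tables (the eight standard PK parameters), concentration percentile
bands, and a variation-factor sensitivity screen on the human model — and
writes tidy CSVs plus a run manifest recording the seed, configuration hash,
package version and every assumed (non-measured) parameter in play.

Rerunning with the same seed reproduces every CSV byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compound import ClearanceSpec, get_compound
from .model import DoseEvent, SimulationConfig
from .population import (
    PopulationSpec,
    generate_population,
    simulate_population,
)
from .sensitivity import (
    DEFAULT_DOSES_MG_KG,
    DEFAULT_FACTORS,
    ModelInputs,
    sensitivity_screen,
)
from .physiology import get_species_physiology

__all__ = ["RunManifest", "run_study"]

#: Total plasma clearances (ml/min/kg) used by the calibrated study models.
STUDY_CLEARANCE_ML_MIN_KG = {"mouse": 4.58, "human": 14.02}
STUDY_DOSE_MG_PER_KG = 0.1


@dataclass
class RunManifest:
    """Reproducibility record of one study run."""

    config_hash: str
    seed: int
    package_version: str
    assumptions: list[str]
    stage_timings_s: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "package_version": self.package_version,
            "assumptions": self.assumptions,
            "stage_timings_s": self.stage_timings_s,
            "outputs": self.outputs,
        }


def run_study(
    out_dir: str | Path,
    *,
    seed: int = 2019,
    n: int = 100,
    fu_plasma: float = 0.05,
    dose_mg_per_kg: float = STUDY_DOSE_MG_PER_KG,
    t_end_hr: float = 24.0,
    grid_step_hr: float = 0.05,
    run_sensitivity: bool = True,
    sensitivity_factors=DEFAULT_FACTORS,
    sensitivity_doses=DEFAULT_DOSES_MG_KG,
) -> RunManifest:
    """Run the full two-species study and write CSVs + manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    settings = {
        "seed": seed,
        "n": n,
        "fu_plasma": fu_plasma,
        "dose_mg_per_kg": dose_mg_per_kg,
        "t_end_hr": t_end_hr,
        "grid_step_hr": grid_step_hr,
        "clearance_ml_min_kg": STUDY_CLEARANCE_ML_MIN_KG,
        "run_sensitivity": run_sensitivity,
        "sensitivity_factors": list(sensitivity_factors),
        "sensitivity_doses": list(sensitivity_doses),
    }
    config_hash = hashlib.sha256(
        json.dumps(settings, sort_keys=True).encode("utf-8")
    ).hexdigest()

    compound = get_compound("at_rvd1", fu_plasma=fu_plasma)
    sim_config = SimulationConfig(t_end_hr=t_end_hr, grid_step_hr=grid_step_hr)
    dose = DoseEvent(amount_mg_per_kg=dose_mg_per_kg)

    assumptions: list[str] = [
        f"fu_plasma={fu_plasma}: assumed (no measured plasma free fraction exists)",
        "calibrated_total clearance mode: whole-body plasma clearance fixed to the "
        "reported species values (mouse 4.58, human 14.02 ml/min/kg) and split over "
        "liver+kidney by blood flow",
        "saliva coupling: first-order equilibration, k_sal=10/hr, "
        "k_saliva=fu_plasma (saliva tracks unbound plasma): package defaults",
        "human clearance age factor: -0.5%/yr beyond 35 y, floor 0.70 (package default)",
    ]
    assumptions.extend(compound.assumed_parameters)

    manifest = RunManifest(
        config_hash=config_hash,
        seed=seed,
        package_version=__version__,
        assumptions=assumptions,
    )

    for i, species in enumerate(("mouse", "human")):
        t0 = time.perf_counter()
        base = get_species_physiology(species)
        assumptions.extend(f"{base.species}: {a}" for a in base.assumed_parameters)
        spec = PopulationSpec(species=species, n=n, seed=seed + i)
        individuals = generate_population(spec, base)
        clearance = ClearanceSpec(
            mode="calibrated_total",
            total_plasma_clearance_ml_min_kg=STUDY_CLEARANCE_ML_MIN_KG[species],
        )
        result = simulate_population(individuals, compound, clearance, dose, sim_config)

        nca_path = out / f"{species}_nca_individual.csv"
        result.nca.to_csv(nca_path, index=False)
        summary_path = out / f"{species}_pk_summary.csv"
        result.summary.parameters.to_csv(summary_path)
        bands_path = out / f"{species}_concentration_bands.csv"
        result.summary.concentration_bands.to_csv(bands_path, index=False)
        manifest.outputs.extend(p.name for p in (nca_path, summary_path, bands_path))
        manifest.stage_timings_s[f"population_{species}"] = round(
            time.perf_counter() - t0, 3
        )

    if run_sensitivity:
        t0 = time.perf_counter()
        inputs = ModelInputs(
            physiology=get_species_physiology("human"),
            compound=compound,
            clearance=ClearanceSpec(
                mode="calibrated_total",
                total_plasma_clearance_ml_min_kg=STUDY_CLEARANCE_ML_MIN_KG["human"],
            ),
        )
        screen = sensitivity_screen(
            inputs,
            doses_mg_per_kg=sensitivity_doses,
            factors=sensitivity_factors,
            config=sim_config,
        )
        screen_path = out / "sensitivity_screen.csv"
        screen.to_csv(screen_path, index=False)
        manifest.outputs.append(screen_path.name)
        manifest.stage_timings_s["sensitivity_screen"] = round(time.perf_counter() - t0, 3)

    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    return manifest
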