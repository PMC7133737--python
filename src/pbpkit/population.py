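"""Virtual populations and batch simulation with summary statistics.

The mouse population varies body weight only (uniform on 12–30 g by default,
matching the strain's reported range); each weight is mapped to a full
physiology by allometric rescaling of the strain reference.  The human
population samples age uniformly on 20–80 years with an exactly equal sex
split, maps (age, sex) to body weight through a shipped piecewise-linear
table anchored at the 80.35 kg reference adult, and additionally scales the
per-kg plasma clearance by a piecewise-linear senescence factor
(−0.5 %/year beyond age 35, floor 0.70) so that age — not just weight —
contributes inter-individual PK variability, as it does in survey-based
virtual populations.

All randomness flows from the spec's single seed through one generator, so
populations, profiles and summaries are reproducible end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compound import ClearanceSpec, Compound
from .model import DoseEvent, SimulationConfig, build_model, simulate
from .nca import pk_summary
from .physiology import Physiology, get_species_physiology, scale_physiology

__all__ = [
    "PopulationSpec",
    "Individual",
    "PopulationSummary",
    "PopulationResult",
    "generate_population",
    "simulate_population",
    "age_clearance_factor",
    "DEFAULT_COMPARTMENTS",
]

#: Compartments summarized by default: plasma, saliva and the highly
#: perfused organs followed in the study design.
DEFAULT_COMPARTMENTS = ("plasma", "saliva", "brain", "heart", "lung", "liver", "kidney", "spleen")

#: NCA parameters reported in population summaries (the study's PK table).
SUMMARY_PARAMETERS = (
    "cmax_ng_ml",
    "tmax_hr",
    "t_half_hr",
    "ke_per_hr",
    "auc_0_inf_ng_hr_ml",
    "mrt_hr",
    "cl_ml_min_kg",
    "vd_l_kg",
)

_CLEARANCE_AGE_ONSET_YR = 35.0
_CLEARANCE_DECLINE_PER_YR = 0.005
_CLEARANCE_FLOOR = 0.70


@dataclass(frozen=True)
class PopulationSpec:
    """Virtual population specification."""

    species: str
    n: int
    weight_range_kg: tuple[float, float] | None = None
    age_range_yr: tuple[float, float] | None = None
    sex_ratio_female: float = 0.5
    seed: int = 0
    weight_distribution: str = "uniform"  # or "gaussian" (truncated)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        for rng_name in ("weight_range_kg", "age_range_yr"):
            rng = getattr(self, rng_name)
            if rng is not None and not rng[0] < rng[1]:
                raise ValueError(f"{rng_name} must satisfy min < max")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ValueError("sex_ratio_female must be in [0, 1]")
        if self.weight_distribution not in ("uniform", "gaussian"):
            raise ValueError("weight_distribution must be 'uniform' or 'gaussian'")


@dataclass(frozen=True)
class Individual:
    """One virtual subject: physiology plus sampled covariates."""

    individual_id: str
    physiology: Physiology
    body_weight_kg: float
    age_yr: float | None = None
    sex: str | None = None
    clearance_scale: float = 1.0


def age_clearance_factor(age_yr: float) -> float:
    """Multiplier on per-kg plasma clearance: 1.0 up to 35 y, then −0.5 %/y."""
    decline = max(0.0, age_yr - _CLEARANCE_AGE_ONSET_YR) * _CLEARANCE_DECLINE_PER_YR
    return max(_CLEARANCE_FLOOR, 1.0 - decline)


def _human_weight_table() -> dict:
    path = resources.files("pbpkit.data").joinpath("human_weight_by_age.json")
    with path.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def weight_for_age_sex(age_yr: float, sex: str) -> float:
    """Piecewise-linear body weight (kg) from the shipped age/sex table."""
    table = _human_weight_table()
    ages = np.asarray(table["age_yr"], dtype=float)
    weights = np.asarray(table["weight_kg"][sex], dtype=float)
    return float(np.interp(age_yr, ages, weights))


def generate_population(spec: PopulationSpec, base: Physiology | None = None) -> list[Individual]:
    """Sample ``spec.n`` individuals and scale the reference physiology.

    Deterministic for a fixed seed: the same spec always yields the same
    population.
    """
    base = base or get_species_physiology(spec.species)
    rng = np.random.default_rng(spec.seed)
    is_human = base.species.startswith("human")

    individuals: list[Individual] = []
    if is_human:
        lo, hi = spec.age_range_yr or (20.0, 80.0)
        ages = rng.uniform(lo, hi, spec.n)
        n_female = int(round(spec.n * spec.sex_ratio_female))
        sexes = np.array(["female"] * n_female + ["male"] * (spec.n - n_female))
        rng.shuffle(sexes)
        table = _human_weight_table()
        tab_ages = np.asarray(table["age_yr"], dtype=float)
        for i, (age, sex) in enumerate(zip(ages, sexes)):
            weight = float(
                np.interp(age, tab_ages, np.asarray(table["weight_kg"][sex], dtype=float))
            )
            individuals.append(
                Individual(
                    individual_id=f"{base.species}_{i:04d}",
                    physiology=scale_physiology(base, weight, age_yr=age, sex=sex),
                    body_weight_kg=weight,
                    age_yr=float(age),
                    sex=str(sex),
                    clearance_scale=age_clearance_factor(float(age)),
                )
            )
    else:
        lo, hi = spec.weight_range_kg or (0.012, 0.030)
        if spec.weight_distribution == "uniform":
            weights = rng.uniform(lo, hi, spec.n)
        else:
            mid, sd = 0.5 * (lo + hi), 0.25 * (hi - lo)
            weights = np.clip(rng.normal(mid, sd, spec.n), lo, hi)
        for i, weight in enumerate(weights):
            individuals.append(
                Individual(
                    individual_id=f"{base.species}_{i:04d}",
                    physiology=scale_physiology(base, float(weight)),
                    body_weight_kg=float(weight),
                )
            )
    return individuals


@dataclass(frozen=True)
class PopulationSummary:
    """Mean/SD/percentiles of NCA parameters and concentration bands."""

    parameters: pd.DataFrame  # index: parameter; columns: mean, sd, p5, p95
    concentration_bands: pd.DataFrame  # compartment, time_hr, p5, p50, p95, mean
    n_individuals: int
    n_failures: int


@dataclass(frozen=True)
class PopulationResult:
    profiles: pd.DataFrame  # tidy: individual_id, compartment, time_hr, conc_ng_per_ml
    nca: pd.DataFrame  # one row per individual
    summary: PopulationSummary
    failures: tuple[str, ...]


def _scaled_clearance(clearance: ClearanceSpec | None, scale: float) -> ClearanceSpec | None:
    if clearance is None or scale == 1.0:
        return clearance
    if clearance.mode == "calibrated_total":
        return replace(
            clearance,
            total_plasma_clearance_ml_min_kg=clearance.total_plasma_clearance_ml_min_kg * scale,
        )
    return replace(clearance, vmax_ng_min=clearance.vmax_ng_min * scale)


def simulate_population(
    individuals: Sequence[Individual],
    compound: Compound,
    clearance: ClearanceSpec | None,
    dose: DoseEvent,
    config: SimulationConfig | None = None,
    *,
    compartments: Sequence[str] = DEFAULT_COMPARTMENTS,
    nca_compartment: str = "plasma",
    build_kwargs: Mapping | None = None,
) -> PopulationResult:
    """Simulate every individual, run per-individual NCA, and summarize.

    Individuals whose integration or NCA fails are recorded in ``failures``
    and excluded from the summary (a warning count, not an abort).  The
    per-kg dose is applied to each individual's own body weight.
    """
    if not individuals:
        raise ValueError("population must be non-empty")
    config = config or SimulationConfig()
    build_kwargs = dict(build_kwargs or {})

    profile_frames: list[pd.DataFrame] = []
    nca_rows: list[dict] = []
    failures: list[str] = []
    for ind in individuals:
        try:
            model = build_model(
                ind.physiology,
                compound,
                _scaled_clearance(clearance, ind.clearance_scale),
                **build_kwargs,
            )
            result = simulate(model, dose, config, individual_id=ind.individual_id)
            row = {
                "individual_id": ind.individual_id,
                "body_weight_kg": ind.body_weight_kg,
                "age_yr": ind.age_yr,
                "sex": ind.sex,
            }
            row.update(pk_summary(result[nca_compartment], dose.amount_mg_per_kg).as_dict())
        except Exception as exc:  # noqa: BLE001 - per-individual isolation
            failures.append(f"{ind.individual_id}: {exc}")
            continue
        nca_rows.append(row)
        keep = [c for c in compartments if c in result.profiles]
        profile_frames.append(
            pd.concat([result[c].to_frame() for c in keep], ignore_index=True)
        )

    if not nca_rows:
        raise RuntimeError(f"every individual failed: {failures}")

    profiles = pd.concat(profile_frames, ignore_index=True)
    nca = pd.DataFrame(nca_rows)

    stats = nca[list(SUMMARY_PARAMETERS)].agg(["mean", "std"]).T
    stats.columns = ["mean", "sd"]
    stats["sd"] = stats["sd"].fillna(0.0)
    quant = nca[list(SUMMARY_PARAMETERS)].quantile([0.05, 0.95]).T
    stats["p5"] = quant[0.05]
    stats["p95"] = quant[0.95]
    stats.index.name = "parameter"

    bands = (
        profiles.groupby(["compartment", "time_hr"])["conc_ng_per_ml"]
        .agg(
            p5=lambda s: s.quantile(0.05),
            p50="median",
            p95=lambda s: s.quantile(0.95),
            mean="mean",
        )
        .reset_index()
    )

    summary = PopulationSummary(
        parameters=stats,
        concentration_bands=bands,
        n_individuals=len(nca_rows),
        n_failures=len(failures),
    )
    return PopulationResult(
        profiles=profiles, nca=nca, summary=summary, failures=tuple(failures)
    )
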