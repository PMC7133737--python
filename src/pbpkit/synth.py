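"""Synthetic concentration–time profiles and toy model builders.

Everything needed to exercise the pipeline without external data: exact or
noisy mono-/bi-exponential decays (multiplicative lognormal noise with unit
mean, so noisy profiles are unbiased on the concentration scale), profiles
sampled from a PBPK simulation, estimator-recovery summaries, and reduced
physiologies (one-compartment, few-organ) whose behaviour has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .compound import ClearanceSpec, Compound
from .model import (
    ConcentrationTimeProfile,
    DoseEvent,
    PBPKModel,
    SimulationConfig,
    build_model,
    default_output_grid,
    simulate,
)
from .nca import pk_summary
from .physiology import OrganParameters, Physiology

__all__ = [
    "SyntheticProfileSpec",
    "generate_profile",
    "recovery_suite",
    "one_compartment_inputs",
    "reduced_physiology",
    "water_compound",
]


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Specification of a synthetic concentration–time profile.

    ``model`` selects the generator:

    ``mono_exponential``
        ``C(t) = c0 · exp(−ke·t)``.
    ``bi_exponential``
        ``C(t) = a · exp(−alpha·t) + b · exp(−beta·t)``.
    ``from_pbpk``
        One compartment of a PBPK simulation (``pbpk_model``, ``dose`` and
        ``compartment`` required).

    Noise is multiplicative lognormal with coefficient of variation
    ``noise_cv`` and unit mean (``additive_gaussian`` is available but can
    produce negatives, which are clipped to zero).
    """

    model: str = "mono_exponential"
    c0_ng_ml: float = 100.0
    ke_per_hr: float = 0.1
    a_ng_ml: float = 5.0
    alpha_per_hr: float = 2.0
    b_ng_ml: float = 1.0
    beta_per_hr: float = 0.1
    grid_hr: np.ndarray = field(default_factory=lambda: default_output_grid(0.0, 24.0, 0.05))
    noise_cv: float = 0.0
    noise_model: str = "lognormal"
    seed: int = 0
    pbpk_model: PBPKModel | None = None
    dose: DoseEvent | None = None
    compartment: str = "plasma"
    individual_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.model not in ("mono_exponential", "bi_exponential", "from_pbpk"):
            raise ValueError(f"unknown profile model {self.model!r}")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.model == "mono_exponential" and not self.ke_per_hr > 0:
            raise ValueError("ke must be > 0")
        if self.model == "bi_exponential" and not (self.alpha_per_hr > 0 and self.beta_per_hr > 0):
            raise ValueError("rate constants must be > 0")
        if self.noise_model not in ("lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        object.__setattr__(self, "grid_hr", np.asarray(self.grid_hr, dtype=float))


def _clean_concentrations(spec: SyntheticProfileSpec) -> np.ndarray:
    t = spec.grid_hr
    if spec.model == "mono_exponential":
        return spec.c0_ng_ml * np.exp(-spec.ke_per_hr * t)
    if spec.model == "bi_exponential":
        return spec.a_ng_ml * np.exp(-spec.alpha_per_hr * t) + spec.b_ng_ml * np.exp(
            -spec.beta_per_hr * t
        )
    if spec.pbpk_model is None or spec.dose is None:
        raise ValueError("from_pbpk requires pbpk_model and dose")
    config = SimulationConfig(
        t_start_hr=float(t[0]), t_end_hr=float(t[-1]), output_grid_hr=t
    )
    result = simulate(spec.pbpk_model, spec.dose, config)
    return result[spec.compartment].concentrations_ng_ml


def generate_profile(spec: SyntheticProfileSpec) -> ConcentrationTimeProfile:
    """Generate one profile; noiseless output is the closed form exactly."""
    conc = _clean_concentrations(spec)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "lognormal":
            sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
            conc = conc * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=conc.size)
        else:
            conc = np.clip(conc * (1.0 + spec.noise_cv * rng.standard_normal(conc.size)), 0.0, None)
    return ConcentrationTimeProfile(
        compartment=spec.compartment if spec.model == "from_pbpk" else "plasma",
        times_hr=spec.grid_hr,
        concentrations_ng_ml=conc,
        individual_id=spec.individual_id,
    )


def recovery_suite(
    n_replicates: int,
    spec: SyntheticProfileSpec,
    true_parameters: Mapping[str, float],
    dose_mg_per_kg: float = 0.1,
) -> pd.DataFrame:
    """Bias/RMSE of the NCA estimators over noisy replicates.

    Each replicate draws a fresh noise realisation (seeds ``spec.seed``,
    ``spec.seed+1``, …), runs :func:`pk_summary` and compares the estimates
    named in ``true_parameters`` (keys among ``ke_per_hr``,
    ``auc_0_inf_ng_hr_ml``, ``cl_ml_min_kg``, ``vd_l_kg``, …) with the truth.

    Returns a DataFrame indexed by parameter with columns ``truth``,
    ``mean_estimate``, ``bias``, ``relative_bias``, ``median_relative_bias``
    and ``rmse``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from dataclasses import replace

    estimates: dict[str, list[float]] = {k: [] for k in true_parameters}
    for i in range(n_replicates):
        profile = generate_profile(replace(spec, seed=spec.seed + i))
        result = pk_summary(profile, dose_mg_per_kg).as_dict()
        for key in true_parameters:
            estimates[key].append(result[key])

    rows = []
    for key, truth in true_parameters.items():
        est = np.asarray(estimates[key], dtype=float)
        rows.append(
            {
                "parameter": key,
                "truth": truth,
                "mean_estimate": est.mean(),
                "bias": est.mean() - truth,
                "relative_bias": (est.mean() - truth) / truth,
                "median_relative_bias": float(np.median(est / truth - 1.0)),
                "rmse": float(np.sqrt(np.mean((est - truth) ** 2))),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def water_compound(name: str = "toy_water", fu_plasma: float = 1.0) -> Compound:
    """A fully unbound, non-partitioning compound (k_organ = f_water)."""
    return Compound(
        name=name,
        molecular_weight_g_mol=100.0,
        logP=0.0,
        pKa=7.0,
        solubility_pH74_mg_ml=1.0,
        fu_plasma=fu_plasma,
    )


def reduced_physiology(
    organs: Mapping[str, tuple[float, float]],
    *,
    body_weight_kg: float = 1.0,
    hematocrit: float = 0.45,
    pool_volume_ml: float = 1.0,
    lung_volume_ml: float = 1.0,
    compositions: Mapping[str, tuple[float, float, float]] | None = None,
    species: str = "toy",
) -> Physiology:
    """Few-organ test physiology: ``organs`` maps name -> (volume_ml, flow_ml_min).

    The lung flow is set to the systemic total automatically so flow
    conservation holds; compositions default to pure water (k_organ = 1).
    """
    comps = dict(compositions or {})
    total_flow = sum(q for _, q in organs.values())
    organ_map = {
        "lung": OrganParameters(
            name="lung",
            volume_ml=lung_volume_ml,
            blood_flow_ml_min=total_flow,
            f_vas=0.1,
            f_water=1.0,
            f_lipid=0.0,
            f_protein=0.0,
        )
    }
    for name, (vol, flow) in organs.items():
        fw, fl, fp = comps.get(name, (1.0, 0.0, 0.0))
        organ_map[name] = OrganParameters(
            name=name,
            volume_ml=vol,
            blood_flow_ml_min=flow,
            f_vas=0.1,
            f_water=fw,
            f_lipid=fl,
            f_protein=fp,
        )
    return Physiology(
        species=species,
        body_weight_kg=body_weight_kg,
        hematocrit=hematocrit,
        organs=organ_map,
        saliva_volume_ml=1e-6,
        arterial_volume_ml=pool_volume_ml,
        venous_volume_ml=pool_volume_ml,
        require_full_organ_set=False,
    )


def one_compartment_inputs(
    vd_l_kg: float,
    cl_ml_min_kg: float,
    *,
    body_weight_kg: float = 1.0,
    flow_multiple: float = 1e4,
    pool_fraction: float = 1e-5,
) -> tuple[PBPKModel, float]:
    """A PBPK reduction that behaves as one well-mixed compartment.

    A single all-water ``body`` organ of volume ``Vd`` holds essentially all
    drug; the blood pools and lung are shrunk to ``pool_fraction`` of it and
    perfused at ``flow_multiple ×`` the target clearance.  A large flow
    multiple keeps the body extraction ratio ``E = CL/Q`` negligible (the
    venous profile is ``(D/V)(1−E)·exp(−(CL/V)(1+E)·t)``), so the default
    reduction matches ``(Dose/Vd)·exp(−(CL/Vd)·t)`` to ~1e-4 relative after
    the sub-second mixing transient.

    Returns ``(model, ke_per_hr)`` with the nominal elimination rate
    constant ``CL/Vd``.
    """
    v_ml = vd_l_kg * 1000.0 * body_weight_kg
    cl_ml_hr = cl_ml_min_kg * 60.0 * body_weight_kg
    hct = 0.45
    q_plasma_ml_hr = flow_multiple * cl_ml_hr
    q_blood_ml_min = q_plasma_ml_hr / 60.0 / (1.0 - hct)
    phys = reduced_physiology(
        {"body": (v_ml, q_blood_ml_min)},
        body_weight_kg=body_weight_kg,
        hematocrit=hct,
        pool_volume_ml=pool_fraction * v_ml,
        lung_volume_ml=pool_fraction * v_ml,
        species="one_compartment_toy",
    )
    clearance = ClearanceSpec(
        mode="calibrated_total", total_plasma_clearance_ml_min_kg=cl_ml_min_kg
    )
    model = build_model(
        phys, water_compound(), clearance, eliminating_organs=("body",)
    )
    ke_per_hr = cl_ml_hr / v_ml
    return model, ke_per_hr
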