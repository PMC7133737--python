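"""Whole-body PBPK model assembly, IV bolus dosing and ODE integration.

Topology
--------
The body is a closed circulatory loop: every systemic organ is perfused in
parallel between an arterial and a venous plasma pool, and the lung bridges
the venous pool back to the arterial pool (venous → lung → arterial).  The
model state is the drug *amount* (ng) in each compartment's plasma-accessible
space; distribution is perfusion-limited by default, i.e. the blood leaving
an organ is in equilibrium with its tissue at the organ's tissue-to-plasma
partition coefficient ``k_organ``:

    dA_organ/dt = Q_p,organ · (C_arterial − A_organ / (V_organ · k_organ))
                  − elimination

with ``Q_p = Q_blood · (1 − hematocrit)`` the organ plasma flow.  A
``permeability_limited`` transport mode replaces the exchange conductance by
the series combination ``(1/Q_p + 1/PS_p)⁻¹`` of flow and the
permeability–surface-area product.

Saliva is a small excretion compartment coupled to the salivary gland by
first-order equilibration (rate ``k_sal``, default 10 hr⁻¹) toward
``k_saliva × C_salivary_gland,plasma``; by default ``k_saliva = fu_plasma``,
i.e. saliva tracks the unbound plasma concentration, which reproduces the
observation that salivary kinetics of lipophilic mediators parallel plasma
kinetics.

Elimination
-----------
In ``calibrated_total`` mode a whole-body plasma clearance CL (ml/min/kg,
referenced to venous plasma) is split over the eliminating organs (liver and
kidney by default) in proportion to their blood flows, and each organ's
intrinsic clearance is back-calculated through the well-stirred extraction
relation ``CL_organ = Q_p·CL_int/(Q_p + CL_int)`` so that the venous-plasma
AUC after an IV bolus equals dose/CL *exactly* for the assembled multi-organ
system.  In ``enzymatic`` mode each organ expressing eicosanoid
oxidoreductase degrades drug at the Michaelis–Menten rate driven by its
unbound outflow concentration.

An extra state accumulates eliminated mass, so the full right-hand side sums
to zero and total mass (body + saliva + eliminated) is conserved to solver
tolerance at every output time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .compound import (
    ClearanceSpec,
    Compound,
    PartitionInputs,
    lipid_water_partition,
    organ_partition_coefficient,
    protein_water_partition,
)
from .physiology import Physiology

__all__ = [
    "DoseEvent",
    "SimulationConfig",
    "PBPKModel",
    "ConcentrationTimeProfile",
    "SimulationResult",
    "IntegrationError",
    "UnsupportedRouteError",
    "ModelConfigurationError",
    "build_model",
    "apply_dose",
    "simulate",
    "default_output_grid",
    "quadrature_grid",
]

#: Default saliva/salivary-gland equilibration rate (1/hr): fast enough that
#: saliva tracks plasma with a lag of a few minutes.
DEFAULT_K_SAL_PER_HR = 10.0

#: Calibrated clearance is split over these organs in proportion to blood
#: flow.  Lung is included because eicosanoid oxidoreductase
#: (15-prostaglandin dehydrogenase) is classically pulmonary — the lung is a
#: major single-pass inactivation site for eicosanoids — and because hepatic
#: plus renal plasma flow alone cannot deliver the reported human total
#: plasma clearance of AT-RvD1.
DEFAULT_ELIMINATING_ORGANS = ("liver", "kidney", "lung")

_NG_PER_MG = 1.0e6


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the failing time."""

    def __init__(self, message: str, t_fail_hr: float | None = None):
        super().__init__(message)
        self.t_fail_hr = t_fail_hr


class UnsupportedRouteError(ValueError):
    """Only intravenous bolus dosing is supported."""


class ModelConfigurationError(ValueError):
    """Inconsistent model configuration (missing organ data, infeasible CL)."""


@dataclass(frozen=True)
class DoseEvent:
    """A single IV bolus: ``amount_mg_per_kg`` placed in the venous pool."""

    amount_mg_per_kg: float
    route: str = "iv_bolus"
    time_hr: float = 0.0

    def __post_init__(self) -> None:
        if self.route != "iv_bolus":
            raise UnsupportedRouteError(f"unsupported route {self.route!r}; only iv_bolus")
        if not self.amount_mg_per_kg > 0:
            raise ValueError("dose must be > 0 mg/kg")
        if self.time_hr < 0:
            raise ValueError("dose time must be >= 0")


@dataclass
class SimulationConfig:
    """Integration window, reporting grid and solver tolerances.

    The default reporting grid runs from 0 to 24 hr in 0.05-hr (3-min)
    steps — the grid on which Tmax is resolved.  ``output_grid_hr`` overrides
    it with any strictly increasing array (e.g. :func:`quadrature_grid` for
    accurate AUC work).
    """

    t_start_hr: float = 0.0
    t_end_hr: float = 24.0
    grid_step_hr: float = 0.05
    output_grid_hr: np.ndarray | None = None
    rtol: float = 1e-9
    atol_ng: float | None = None
    method: str = "LSODA"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.t_start_hr < self.t_end_hr:
            raise ValueError("t_start must be < t_end")
        if not self.rtol > 0:
            raise ValueError("rtol must be > 0")
        if self.atol_ng is not None and not self.atol_ng > 0:
            raise ValueError("atol must be > 0")
        if self.output_grid_hr is not None:
            grid = np.asarray(self.output_grid_hr, dtype=float)
            if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
                raise ValueError("output grid must be strictly increasing, length >= 2")
            self.output_grid_hr = grid

    def grid(self) -> np.ndarray:
        if self.output_grid_hr is not None:
            return self.output_grid_hr
        return default_output_grid(self.t_start_hr, self.t_end_hr, self.grid_step_hr)


def default_output_grid(t_start_hr: float, t_end_hr: float, step_hr: float = 0.05) -> np.ndarray:
    """Uniform reporting grid including both endpoints."""
    n = int(round((t_end_hr - t_start_hr) / step_hr))
    return t_start_hr + step_hr * np.arange(n + 1)


def quadrature_grid(
    t_end_hr: float,
    *,
    t_first_hr: float = 1e-5,
    n_early: int = 200,
    mid_end_hr: float = 24.0,
    mid_step_hr: float = 0.05,
    late_step_hr: float = 1.0,
) -> np.ndarray:
    """Composite grid for accurate NCA quadrature after an IV bolus.

    Geometric spacing from ``t_first`` to the first uniform point resolves
    the sub-minute venous mixing transient (whose area would otherwise be
    badly overestimated on a 3-min grid), a 0.05-hr uniform segment covers
    the distribution phase, and a coarser uniform segment extends through
    the terminal phase.
    """
    parts = [np.array([0.0]), np.geomspace(t_first_hr, mid_step_hr, n_early)]
    if t_end_hr > mid_step_hr:
        upper = min(mid_end_hr, t_end_hr)
        parts.append(default_output_grid(mid_step_hr, upper, mid_step_hr)[1:])
    if t_end_hr > mid_end_hr:
        parts.append(default_output_grid(mid_end_hr, t_end_hr, late_step_hr)[1:])
    grid = np.concatenate(parts)
    return np.unique(grid)


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """Sampled concentration vs time for one compartment of one individual."""

    compartment: str
    times_hr: np.ndarray
    concentrations_ng_ml: np.ndarray
    individual_id: str = "reference"
    units: Mapping[str, str] = field(
        default_factory=lambda: {"time": "hr", "concentration": "ng/ml"}
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.times_hr, dtype=float)
        c = np.asarray(self.concentrations_ng_ml, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be 1-D arrays of equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times_hr", t)
        object.__setattr__(self, "concentrations_ng_ml", c)

    def __len__(self) -> int:
        return self.times_hr.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "compartment": self.compartment,
                "time_hr": self.times_hr,
                "conc_ng_per_ml": self.concentrations_ng_ml,
            }
        )


@dataclass(frozen=True)
class PBPKModel:
    """Assembled compartment graph and rate parameters.

    ``k_organ`` holds the tissue-to-plasma partition coefficient of every
    organ; ``intrinsic_clearance_ml_hr`` the linearized intrinsic clearance
    acting on each eliminating organ's outflow plasma concentration
    (calibrated mode); ``exchange_conductance_ml_hr`` the plasma-side
    exchange conductance per systemic organ (equal to the organ plasma flow
    for perfusion-limited organs).
    """

    physiology: Physiology
    compound: Compound
    clearance: ClearanceSpec | None
    k_organ: Mapping[str, float]
    intrinsic_clearance_ml_hr: Mapping[str, float]
    exchange_conductance_ml_hr: Mapping[str, float]
    transport_mode: Mapping[str, str]
    enzymatic_organs: Mapping[str, float]  # organ -> EOR abundance (enzymatic mode)
    k_sal_per_hr: float = DEFAULT_K_SAL_PER_HR
    k_saliva: float | None = None
    fu_applies_to_whole_sum: bool = False

    @property
    def has_saliva(self) -> bool:
        return "salivary_gland" in self.physiology.organs

    @property
    def state_names(self) -> tuple[str, ...]:
        names = ["venous", "arterial", "lung", *self.physiology.systemic_organs]
        if self.has_saliva:
            names.append("saliva")
        names.append("eliminated")
        return tuple(names)

    @property
    def total_plasma_clearance_ml_hr(self) -> float:
        """Whole-body venous-plasma clearance implied by the intrinsic CLs.

        Lung clearance acts on the venous outflow directly; the systemic
        organs' contributions are attenuated by the lung transmission factor
        ``g = 1 − E_lung`` because they see the post-lung arterial exposure.
        """
        g = 1.0
        total = 0.0
        cl_int_lung = self.intrinsic_clearance_ml_hr.get("lung", 0.0)
        if cl_int_lung > 0:
            q_lung = self.exchange_conductance_ml_hr["lung"]
            e_lung = cl_int_lung / (q_lung + cl_int_lung)
            total += q_lung * e_lung
            g = 1.0 - e_lung
        for organ, cl_int in self.intrinsic_clearance_ml_hr.items():
            if organ == "lung":
                continue
            q = self.exchange_conductance_ml_hr[organ]
            total += g * q * cl_int / (q + cl_int)
        return total


def build_model(
    physiology: Physiology,
    compound: Compound,
    clearance: ClearanceSpec | None,
    *,
    eliminating_organs: tuple[str, ...] = DEFAULT_ELIMINATING_ORGANS,
    k_sal_per_hr: float = DEFAULT_K_SAL_PER_HR,
    k_saliva: float | None = None,
    k_lipid: float | None = None,
    k_protein: float | None = None,
    permeability_ps_ml_min: Mapping[str, float] | None = None,
    fu_applies_to_whole_sum: bool = False,
) -> PBPKModel:
    """Assemble a :class:`PBPKModel` from physiology, compound and clearance.

    Partition coefficients are computed per organ from its composition;
    ``k_lipid``/``k_protein`` default to :func:`lipid_water_partition` and
    :func:`protein_water_partition` of the compound but may be overridden.
    ``clearance=None`` builds a closed (zero-elimination) system.

    Raises
    ------
    ModelConfigurationError
        If an organ lacks composition data, no eliminating organ is present,
        or the requested calibrated clearance exceeds what the eliminating
        organs' plasma flows can deliver.
    """
    kl = lipid_water_partition(compound.logP) if k_lipid is None else k_lipid
    kp = protein_water_partition(compound.fu_plasma) if k_protein is None else k_protein

    k_organ: dict[str, float] = {}
    for name, organ in physiology.organs.items():
        try:
            inputs = PartitionInputs(
                f_water=organ.f_water,
                f_lipid=organ.f_lipid,
                f_protein=organ.f_protein,
                k_lipid=kl,
                k_protein=kp,
                fu_plasma=compound.fu_plasma,
            )
        except ValueError as exc:
            raise ModelConfigurationError(f"organ {name!r}: {exc}") from exc
        k = organ_partition_coefficient(inputs, fu_applies_to_whole_sum=fu_applies_to_whole_sum)
        if not k > 0:
            raise ModelConfigurationError(f"organ {name!r} has non-positive k_organ = {k}")
        k_organ[name] = k

    one_minus_hct = 1.0 - physiology.hematocrit
    conductance: dict[str, float] = {}
    transport: dict[str, str] = {}
    ps_map = dict(permeability_ps_ml_min or {})
    for name, organ in physiology.organs.items():
        q_plasma = organ.blood_flow_ml_min * 60.0 * one_minus_hct  # ml/hr
        if name in ps_map:
            ps = ps_map[name] * 60.0 * one_minus_hct
            conductance[name] = 1.0 / (1.0 / q_plasma + 1.0 / ps)
            transport[name] = "permeability_limited"
        else:
            conductance[name] = q_plasma
            transport[name] = "perfusion_limited"

    intrinsic: dict[str, float] = {}
    enzymatic: dict[str, float] = {}
    if clearance is not None and clearance.mode == "calibrated_total":
        present = [o for o in eliminating_organs if o in physiology.organs]
        if not present:
            raise ModelConfigurationError(
                f"none of the eliminating organs {eliminating_organs} is present"
            )
        cl_total_ml_hr = (
            clearance.total_plasma_clearance_ml_min_kg * 60.0 * physiology.body_weight_kg
        )
        flow_sum = sum(physiology.organs[o].blood_flow_ml_min for o in present)
        shares = {
            o: physiology.organs[o].blood_flow_ml_min / flow_sum for o in present
        }
        # Lung elimination extracts drug before the arterial pool, so the
        # systemic organs see only a fraction g of the venous AUC; their
        # effective clearances must be scaled by 1/g for the whole-body
        # venous-plasma clearance to equal the calibrated target exactly.
        g = 1.0
        if "lung" in present:
            cl_lung = cl_total_ml_hr * shares["lung"]
            q_lung = conductance["lung"]
            if cl_lung >= q_lung:
                raise ModelConfigurationError(
                    f"calibrated clearance share {cl_lung:.3g} ml/hr for 'lung' "
                    f"exceeds its plasma conductance {q_lung:.3g} ml/hr"
                )
            intrinsic["lung"] = q_lung * cl_lung / (q_lung - cl_lung)
            g = 1.0 - cl_lung / q_lung
        for organ in present:
            if organ == "lung":
                continue
            cl_part = cl_total_ml_hr * shares[organ] / g
            q = conductance[organ]
            if cl_part >= q:
                raise ModelConfigurationError(
                    f"calibrated clearance share {cl_part:.3g} ml/hr for {organ!r} "
                    f"exceeds its plasma conductance {q:.3g} ml/hr"
                )
            # Invert the well-stirred extraction so that the whole-body
            # venous-plasma clearance equals the calibrated target exactly.
            intrinsic[organ] = q * cl_part / (q - cl_part)
    elif clearance is not None and clearance.mode == "enzymatic":
        enzymatic = {
            name: organ.eor_abundance
            for name, organ in physiology.organs.items()
            if organ.eor_abundance > 0
        }
        if not enzymatic:
            raise ModelConfigurationError(
                "enzymatic mode requires at least one organ with eor_abundance > 0"
            )

    return PBPKModel(
        physiology=physiology,
        compound=compound,
        clearance=clearance,
        k_organ=k_organ,
        intrinsic_clearance_ml_hr=intrinsic,
        exchange_conductance_ml_hr=conductance,
        transport_mode=transport,
        enzymatic_organs=enzymatic,
        k_sal_per_hr=k_sal_per_hr,
        k_saliva=k_saliva,
        fu_applies_to_whole_sum=fu_applies_to_whole_sum,
    )


def apply_dose(
    model: PBPKModel, dose: DoseEvent, body_weight_kg: float | None = None
) -> np.ndarray:
    """Initial amount vector (ng per state) for an IV bolus.

    The full dose (``amount_mg_per_kg × body_weight``) is placed in the
    venous pool; all other compartments start at zero.
    """
    bw = model.physiology.body_weight_kg if body_weight_kg is None else body_weight_kg
    if not bw > 0:
        raise ValueError("body weight must be > 0")
    y0 = np.zeros(len(model.state_names))
    y0[0] = dose.amount_mg_per_kg * _NG_PER_MG * bw
    return y0


def _system_matrix(model: PBPKModel) -> np.ndarray:
    """Constant rate matrix M with dA/dt = M·A (linear part of the system).

    Columns sum to zero by construction (mass moves between states, never
    disappears), which is what makes the conservation invariant hold.
    """
    phys = model.physiology
    names = model.state_names
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    M = np.zeros((n, n))

    one_minus_hct = 1.0 - phys.hematocrit
    v_ven = phys.venous_volume_ml * one_minus_hct
    v_art = phys.arterial_volume_ml * one_minus_hct
    q_lung = model.exchange_conductance_ml_hr["lung"]
    lung = phys.organs["lung"]
    inv_vk_lung = 1.0 / (lung.volume_ml * model.k_organ["lung"])

    i_ven, i_art, i_lung = idx["venous"], idx["arterial"], idx["lung"]
    i_elim = idx["eliminated"]

    # venous -> lung -> arterial
    M[i_ven, i_ven] -= q_lung / v_ven
    M[i_lung, i_ven] += q_lung / v_ven
    M[i_lung, i_lung] -= q_lung * inv_vk_lung
    M[i_art, i_lung] += q_lung * inv_vk_lung
    cl_int_lung = model.intrinsic_clearance_ml_hr.get("lung", 0.0)
    if cl_int_lung > 0:
        M[i_lung, i_lung] -= cl_int_lung * inv_vk_lung
        M[i_elim, i_lung] += cl_int_lung * inv_vk_lung

    for organ in phys.systemic_organs:
        o = phys.organs[organ]
        i_o = idx[organ]
        x = model.exchange_conductance_ml_hr[organ]
        inv_vk = 1.0 / (o.volume_ml * model.k_organ[organ])
        # arterial -> organ
        M[i_art, i_art] -= x / v_art
        M[i_o, i_art] += x / v_art
        # organ -> venous
        M[i_o, i_o] -= x * inv_vk
        M[i_ven, i_o] += x * inv_vk
        # linear (calibrated) elimination on the organ's outflow concentration
        cl_int = model.intrinsic_clearance_ml_hr.get(organ, 0.0)
        if cl_int > 0:
            M[i_o, i_o] -= cl_int * inv_vk
            M[i_elim, i_o] += cl_int * inv_vk

    if model.has_saliva:
        i_sal = idx["saliva"]
        i_sg = idx["salivary_gland"]
        sg = phys.organs["salivary_gland"]
        k_saliva = model.compound.fu_plasma if model.k_saliva is None else model.k_saliva
        a = (
            model.k_sal_per_hr
            * k_saliva
            * phys.saliva_volume_ml
            / (sg.volume_ml * model.k_organ["salivary_gland"])
        )
        M[i_sal, i_sg] += a
        M[i_sg, i_sg] -= a
        M[i_sal, i_sal] -= model.k_sal_per_hr
        M[i_sg, i_sal] += model.k_sal_per_hr
    return M


@dataclass
class SimulationResult:
    """Amounts, concentrations and solver metadata from one simulation."""

    model: PBPKModel
    dose: DoseEvent
    times_hr: np.ndarray
    amounts_ng: np.ndarray  # (n_states, n_times)
    dose_ng: float
    profiles: Mapping[str, ConcentrationTimeProfile]
    solver_stats: Mapping[str, float]
    individual_id: str = "reference"

    def __getitem__(self, compartment: str) -> ConcentrationTimeProfile:
        return self.profiles[compartment]

    @property
    def eliminated_ng(self) -> np.ndarray:
        return self.amounts_ng[-1]

    def mass_balance_rel_error(self) -> float:
        """max |amount in system + eliminated − dose| / dose over the grid."""
        after = self.times_hr >= self.dose.time_hr
        total = self.amounts_ng[:, after].sum(axis=0)
        return float(np.max(np.abs(total - self.dose_ng)) / self.dose_ng)

    def to_dataframe(self):
        import pandas as pd

        return pd.concat([p.to_frame() for p in self.profiles.values()], ignore_index=True)


def simulate(
    model: PBPKModel,
    dose: DoseEvent,
    config: SimulationConfig | None = None,
    *,
    individual_id: str = "reference",
) -> SimulationResult:
    """Integrate the model after an IV bolus and sample the reporting grid.

    Returns a :class:`SimulationResult` whose ``profiles`` map compartment
    names (``plasma`` = venous plasma, ``arterial_plasma``, every organ as
    tissue concentration, ``saliva``) to concentration–time profiles in
    ng/ml.  Grid points before the dose time report zero.
    """
    config = config or SimulationConfig()
    grid = config.grid()
    if dose.time_hr < config.t_start_hr or dose.time_hr >= config.t_end_hr:
        raise ValueError("dose time must lie within [t_start, t_end)")

    names = model.state_names
    y0 = apply_dose(model, dose)
    dose_ng = float(y0[0])
    atol = config.atol_ng if config.atol_ng is not None else max(dose_ng * 1e-13, 1e-15)

    M = _system_matrix(model)
    phys = model.physiology
    idx = {n: i for i, n in enumerate(names)}

    if model.enzymatic_organs:
        vmax_hr = model.clearance.vmax_ng_min * 60.0
        km = model.clearance.km_ng_ml
        fu = model.compound.fu_plasma
        enz = [
            (idx[o], ab, 1.0 / (phys.organs[o].volume_ml * model.k_organ[o]))
            for o, ab in model.enzymatic_organs.items()
        ]
        i_elim = idx["eliminated"]

        def rhs(t, y):
            dy = M @ y
            for i_o, ab, inv_vk in enz:
                cu = fu * max(y[i_o], 0.0) * inv_vk
                r = ab * vmax_hr * cu / (km + cu)
                dy[i_o] -= r
                dy[i_elim] += r
            return dy

        def jac(t, y):
            J = M.copy()
            for i_o, ab, inv_vk in enz:
                cu = fu * max(y[i_o], 0.0) * inv_vk
                dr = ab * vmax_hr * km / (km + cu) ** 2 * fu * inv_vk
                J[i_o, i_o] -= dr
                J[i_elim, i_o] += dr
            return J

    else:

        def rhs(t, y):
            return M @ y

        def jac(t, y):
            return M

    t_eval = grid[grid >= dose.time_hr]
    span = (dose.time_hr, max(config.t_end_hr, grid[-1]))
    sol = solve_ivp(
        rhs,
        span,
        y0,
        method=config.method,
        t_eval=t_eval,
        rtol=config.rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else float(dose.time_hr)
        raise IntegrationError(f"ODE integration failed: {sol.message}", t_fail_hr=t_fail)

    amounts = np.zeros((len(names), grid.size))
    amounts[:, grid >= dose.time_hr] = sol.y
    # Solver tolerances can leave tiny negative amounts; clip them but flag
    # anything beyond numerical noise.
    floor = -max(atol * 1e3, dose_ng * 1e-9)
    if amounts.min() < floor:
        raise IntegrationError(
            f"negative state amount {amounts.min():.3g} ng beyond numerical noise"
        )
    amounts = np.clip(amounts, 0.0, None)

    one_minus_hct = 1.0 - phys.hematocrit
    profiles: dict[str, ConcentrationTimeProfile] = {}

    def _add(name: str, conc: np.ndarray) -> None:
        profiles[name] = ConcentrationTimeProfile(
            compartment=name,
            times_hr=grid,
            concentrations_ng_ml=conc,
            individual_id=individual_id,
        )

    _add("plasma", amounts[idx["venous"]] / (phys.venous_volume_ml * one_minus_hct))
    _add("arterial_plasma", amounts[idx["arterial"]] / (phys.arterial_volume_ml * one_minus_hct))
    for organ in ("lung", *phys.systemic_organs):
        _add(organ, amounts[idx[organ]] / phys.organs[organ].volume_ml)
    if model.has_saliva:
        _add("saliva", amounts[idx["saliva"]] / phys.saliva_volume_ml)

    stats = {
        "n_rhs_evaluations": int(sol.nfev),
        "n_jacobian_evaluations": int(getattr(sol, "njev", 0) or 0),
        "n_accepted_steps": int(sol.t.size),
        "method": config.method,
        "rtol": config.rtol,
        "atol_ng": atol,
    }
    return SimulationResult(
        model=model,
        dose=dose,
        times_hr=grid,
        amounts_ng=amounts,
        dose_ng=dose_ng,
        profiles=profiles,
        solver_stats=stats,
        individual_id=individual_id,
    )
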