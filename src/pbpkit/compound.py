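"""Compound parameterization, tissue partitioning and enzymatic clearance.

The distribution model follows the classical composition-based rule: an
organ's equilibrium tissue-to-plasma partition coefficient is

    K_organ = F_water + K_lipid · F_lipid + K_protein · F_protein · fu_plasma

where ``F_x`` are the organ's water/lipid/protein volume fractions,
``K_lipid`` the lipid/water partition coefficient, ``K_protein`` the
protein/water partition coefficient and ``fu_plasma`` the free fraction in
plasma.  As printed, the free fraction multiplies only the protein term; a
switch (``fu_applies_to_whole_sum``) exposes the alternative reading in which
it scales the entire sum.

``K_lipid`` defaults to the octanol/water estimate ``10**logP`` (the minimal
reading of "derived from the physicochemical properties") and ``K_protein``
to ``(1/fu − 1) / F_protein_plasma`` so that the plasma compartment's own
protein binding is self-consistent with the supplied free fraction.  Both
rules are package conventions and are config-overridable.

Elimination is described by a :class:`ClearanceSpec` in one of two modes:

``calibrated_total``
    A single total plasma clearance (ml/min/kg) distributed over the
    eliminating organs; the mechanistic details are absorbed into organ
    intrinsic clearances at model build time.
``enzymatic``
    Michaelis–Menten degradation by eicosanoid oxidoreductase (EOR, i.e.
    15-prostaglandin dehydrogenase), scaled by each organ's relative
    enzyme abundance and driven by the unbound concentration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "Compound",
    "ClearanceSpec",
    "PartitionInputs",
    "ClearanceModeError",
    "F_PROTEIN_PLASMA",
    "endothelial_surface_area",
    "lipid_water_partition",
    "protein_water_partition",
    "organ_partition_coefficient",
    "enzymatic_rate",
    "get_compound",
]

#: Protein volume fraction of plasma (dimensionless), used to make the
#: protein/water partition coefficient self-consistent with fu_plasma.
F_PROTEIN_PLASMA = 0.06


class ClearanceModeError(ValueError):
    """Operation invoked with the wrong clearance mode."""


@dataclass(frozen=True)
class Compound:
    """Physicochemical and binding parameters of a drug."""

    name: str
    molecular_weight_g_mol: float
    logP: float
    pKa: float
    solubility_pH74_mg_ml: float
    fu_plasma: float
    binding_protein: str = "albumin"
    assumed_parameters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.molecular_weight_g_mol > 0:
            raise ValueError("molecular weight must be > 0")
        if not 0.0 < self.fu_plasma <= 1.0:
            raise ValueError(f"fu_plasma must be in (0, 1], got {self.fu_plasma}")
        if not self.solubility_pH74_mg_ml > 0:
            raise ValueError("solubility must be > 0")
        if not math.isfinite(self.logP):
            raise ValueError("logP must be finite")


@dataclass(frozen=True)
class ClearanceSpec:
    """Elimination specification: calibrated total or enzymatic."""

    mode: str
    total_plasma_clearance_ml_min_kg: float | None = None
    vmax_ng_min: float | None = None
    km_ng_ml: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "calibrated_total":
            if self.total_plasma_clearance_ml_min_kg is None or not (
                self.total_plasma_clearance_ml_min_kg > 0
            ):
                raise ValueError("calibrated_total mode requires total_plasma_clearance > 0")
        elif self.mode == "enzymatic":
            if self.vmax_ng_min is None or not self.vmax_ng_min > 0:
                raise ValueError("enzymatic mode requires vmax > 0")
            if self.km_ng_ml is None or not self.km_ng_ml > 0:
                raise ValueError("enzymatic mode requires km > 0")
        else:
            raise ValueError(f"unknown clearance mode {self.mode!r}")


@dataclass(frozen=True)
class PartitionInputs:
    """Inputs of the composition-based partition-coefficient rule."""

    f_water: float
    f_lipid: float
    f_protein: float
    k_lipid: float
    k_protein: float
    fu_plasma: float

    def __post_init__(self) -> None:
        for label in ("f_water", "f_lipid", "f_protein", "k_lipid", "k_protein", "fu_plasma"):
            if getattr(self, label) < 0:
                raise ValueError(f"{label} must be >= 0")
        if self.fu_plasma > 1.0:
            raise ValueError("fu_plasma must be <= 1")


def endothelial_surface_area(k: float, f_vas: float, v_organ_ml: float) -> float:
    """Capillary endothelial surface area by the organ-vascularization rule.

    ``SA = k · f_vas · V_organ`` with ``k`` a proportionality constant
    (per ml, in whatever area unit ``k`` carries), ``f_vas`` the organ's
    vascular space fraction and ``V_organ`` its volume in ml.  Needed only
    for permeability-limited transport.
    """
    if k < 0 or f_vas < 0 or v_organ_ml < 0:
        raise ValueError("surface-area inputs must be non-negative")
    return k * f_vas * v_organ_ml


def lipid_water_partition(logP: float) -> float:
    """Lipid/water partition coefficient, ``10**logP`` (octanol/water)."""
    if not math.isfinite(logP):
        raise ValueError("logP must be finite")
    return 10.0**logP


def protein_water_partition(fu_plasma: float, f_protein_plasma: float = F_PROTEIN_PLASMA) -> float:
    """Protein/water partition coefficient consistent with plasma binding.

    Solving the plasma compartment's own binding balance
    ``1/fu = 1 + K_protein · F_protein_plasma`` for ``K_protein`` gives
    ``(1/fu − 1) / F_protein_plasma``: a fully unbound drug (fu = 1) has no
    protein affinity, a tightly bound one a large coefficient.
    """
    if not 0.0 < fu_plasma <= 1.0:
        raise ValueError(f"fu_plasma must be in (0, 1], got {fu_plasma}")
    if not 0.0 < f_protein_plasma < 1.0:
        raise ValueError("f_protein_plasma must be in (0, 1)")
    return (1.0 / fu_plasma - 1.0) / f_protein_plasma


def organ_partition_coefficient(
    inputs: PartitionInputs, *, fu_applies_to_whole_sum: bool = False
) -> float:
    """Tissue-to-plasma partition coefficient of one organ.

    By default the plasma free fraction scales only the protein term (the
    rule as printed); ``fu_applies_to_whole_sum=True`` applies it to the
    whole composition sum instead.
    """
    core = (
        inputs.f_water
        + inputs.k_lipid * inputs.f_lipid
        + inputs.k_protein * inputs.f_protein * inputs.fu_plasma
    )
    if fu_applies_to_whole_sum:
        # Alternative precedence: fu multiplies the lipid+protein binding sum.
        core = inputs.fu_plasma * (
            inputs.f_water + inputs.k_lipid * inputs.f_lipid + inputs.k_protein * inputs.f_protein
        )
    return core


def enzymatic_rate(
    clearance: ClearanceSpec, c_unbound_ng_ml: float, abundance: float = 1.0
) -> float:
    """Michaelis–Menten elimination rate (ng/min) at one organ.

    ``abundance · Vmax · Cu / (Km + Cu)`` — saturable in the unbound
    concentration, bounded above by ``abundance · Vmax`` and reducing to the
    linear intrinsic clearance ``abundance · (Vmax/Km) · Cu`` for Cu ≪ Km.
    """
    if clearance.mode != "enzymatic":
        raise ClearanceModeError(
            f"enzymatic_rate requires enzymatic mode, got {clearance.mode!r}"
        )
    if c_unbound_ng_ml < 0:
        raise ValueError("unbound concentration must be >= 0")
    if abundance < 0:
        raise ValueError("abundance must be >= 0")
    return abundance * clearance.vmax_ng_min * c_unbound_ng_ml / (
        clearance.km_ng_ml + c_unbound_ng_ml
    )


def get_compound(name: str = "at_rvd1", *, fu_plasma: float | None = None) -> Compound:
    """Load a shipped compound fixture.

    ``fu_plasma`` is a required input for AT-RvD1 because no measured plasma
    free fraction exists; passing ``None`` when the fixture carries no value
    raises.  Supplying it here flags the value as assumed in the compound's
    metadata.
    """
    path = resources.files("pbpkit.data").joinpath(f"{name}.json")
    try:
        with path.open("r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except FileNotFoundError as exc:
        raise KeyError(f"no shipped compound fixture named {name!r}") from exc
    fu = payload.get("fu_plasma")
    assumed = list(payload.get("assumed_parameters", ()))
    if fu_plasma is not None:
        fu = fu_plasma
        assumed.append(f"fu_plasma={fu_plasma}: user-supplied, no measured value exists")
    if fu is None:
        raise ValueError(
            f"compound {name!r} has no measured fu_plasma; it must be supplied "
            "explicitly (shipped example configs use 0.05, flagged as assumed)"
        )
    return Compound(
        name=payload["name"],
        molecular_weight_g_mol=payload["molecular_weight_g_mol"],
        logP=payload["logP"],
        pKa=payload["pKa"],
        solubility_pH74_mg_ml=payload["solubility_pH74_mg_ml"],
        fu_plasma=fu,
        binding_protein=payload.get("binding_protein", "albumin"),
        assumed_parameters=tuple(assumed),
    )
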