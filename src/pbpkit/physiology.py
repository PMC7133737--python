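"""Species physiologies: organ volumes, blood flows, and allometric scaling.

A :class:`Physiology` is the anatomical half of a whole-body PBPK model: a
collection of perfused organs (each with a volume, a blood flow, a vascular
space fraction and a water/lipid/protein composition), the arterial and venous
blood pools that connect them, the hematocrit that converts blood flow to
plasma flow, and a saliva volume for the salivary excretion compartment.

Two reference physiologies ship with the package as JSON fixtures:

``mouse_nod_shiltj``
    A 27.5 g NOD/ShiLtJ mouse (the Sjögren's-syndrome-like strain).
``human_adult``
    An 80.35 kg adult (BMI 25.22 kg/m²).

Only six organ volumes/flows, hematocrit, body weight and saliva volume are
published for these references; every other value is a documented package
default and is listed in the fixture's ``assumed_parameters`` metadata.  Any
value can be overridden through :func:`get_species_physiology`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "OrganParameters",
    "Physiology",
    "PhysiologyError",
    "UnsupportedSpeciesError",
    "REQUIRED_ORGANS",
    "VOLUME_ALLOMETRIC_EXPONENT",
    "FLOW_ALLOMETRIC_EXPONENT",
    "get_species_physiology",
    "scale_physiology",
]

#: Organs every full-body physiology must provide.  ``lung`` bridges the
#: venous and arterial pools; all others are perfused in parallel.
REQUIRED_ORGANS = frozenset(
    {
        "lung",
        "heart",
        "brain",
        "kidney",
        "liver",
        "spleen",
        "gut",
        "muscle",
        "skin",
        "adipose",
        "bone",
        "gonads",
        "pancreas",
        "salivary_gland",
        "rest_of_body",
    }
)

#: Interspecies/intraspecies allometric exponents: organ volumes scale
#: linearly with body weight, flows (and clearances) with the 3/4 power.
VOLUME_ALLOMETRIC_EXPONENT = 1.0
FLOW_ALLOMETRIC_EXPONENT = 0.75

_FLOW_CONSERVATION_RTOL = 1e-9

_SPECIES_ALIASES = {
    "mouse": "mouse_nod_shiltj",
    "mouse_nod_shiltj": "mouse_nod_shiltj",
    "nod_shiltj": "mouse_nod_shiltj",
    "human": "human_adult",
    "human_adult": "human_adult",
}


class PhysiologyError(ValueError):
    """An anatomically or physiologically inconsistent parameter set."""


class UnsupportedSpeciesError(KeyError):
    """Requested species has no shipped reference physiology."""


@dataclass(frozen=True)
class OrganParameters:
    """Anatomical/physiological parameters of a single perfused organ.

    Parameters
    ----------
    volume_ml : float
        Total organ volume (ml), strictly positive.
    blood_flow_ml_min : float
        Organ blood flow (ml/min), non-negative.  For ``lung`` this is the
        cardiac output.
    f_vas : float
        Fraction of organ volume that is vascular space, in [0, 1].
    f_water, f_lipid, f_protein : float
        Volume fractions of tissue water, lipid and protein.  Their sum may
        not exceed 1; the remainder is other constituents (e.g. minerals).
    eor_abundance : float
        Relative expression of eicosanoid oxidoreductase (the enzyme that
        degrades resolvins), dimensionless and non-negative.  Only used by
        the enzymatic clearance mode.
    """

    name: str
    volume_ml: float
    blood_flow_ml_min: float
    f_vas: float
    f_water: float
    f_lipid: float
    f_protein: float
    eor_abundance: float = 0.0

    def __post_init__(self) -> None:
        if not self.volume_ml > 0:
            raise PhysiologyError(f"{self.name}: volume must be > 0, got {self.volume_ml}")
        if self.blood_flow_ml_min < 0:
            raise PhysiologyError(f"{self.name}: blood flow must be >= 0")
        if not 0.0 <= self.f_vas <= 1.0:
            raise PhysiologyError(f"{self.name}: f_vas must be in [0, 1], got {self.f_vas}")
        for label in ("f_water", "f_lipid", "f_protein"):
            if getattr(self, label) < 0:
                raise PhysiologyError(f"{self.name}: {label} must be >= 0")
        if self.f_water + self.f_lipid + self.f_protein > 1.0 + 1e-12:
            raise PhysiologyError(
                f"{self.name}: composition fractions sum to "
                f"{self.f_water + self.f_lipid + self.f_protein:.4f} > 1"
            )
        if self.eor_abundance < 0:
            raise PhysiologyError(f"{self.name}: eor_abundance must be >= 0")


@dataclass(frozen=True)
class Physiology:
    """A species' body-level and per-organ physiological parameter set.

    The flow-conservation invariant is enforced at construction: lung blood
    flow (cardiac output) must equal the summed blood flows of all systemic
    organs to within 1e-9 relative, because every systemic organ drains into
    the venous pool that feeds the lung.

    ``require_full_organ_set=False`` permits reduced topologies (toy models
    used for closed-form cross-checks); the flow invariant still applies.
    """

    species: str
    body_weight_kg: float
    hematocrit: float
    organs: Mapping[str, OrganParameters]
    saliva_volume_ml: float
    arterial_volume_ml: float
    venous_volume_ml: float
    bmi_kg_m2: float | None = None
    assumed_parameters: tuple[str, ...] = ()
    require_full_organ_set: bool = True

    def __post_init__(self) -> None:
        if not self.body_weight_kg > 0:
            raise PhysiologyError("body weight must be > 0")
        if not 0.0 < self.hematocrit < 1.0:
            raise PhysiologyError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        for label in ("saliva_volume_ml", "arterial_volume_ml", "venous_volume_ml"):
            if not getattr(self, label) > 0:
                raise PhysiologyError(f"{label} must be > 0")
        object.__setattr__(self, "organs", MappingProxyType(dict(self.organs)))
        if self.require_full_organ_set:
            missing = REQUIRED_ORGANS - set(self.organs)
            if missing:
                raise PhysiologyError(f"missing required organs: {sorted(missing)}")
        if "lung" not in self.organs:
            raise PhysiologyError("a 'lung' organ bridging the blood pools is required")
        lung_flow = self.organs["lung"].blood_flow_ml_min
        systemic = sum(
            o.blood_flow_ml_min for n, o in self.organs.items() if n != "lung"
        )
        if not math.isclose(lung_flow, systemic, rel_tol=_FLOW_CONSERVATION_RTOL):
            raise PhysiologyError(
                "flow conservation violated: lung (cardiac output) "
                f"{lung_flow} ml/min != sum of systemic flows {systemic} ml/min"
            )

    @property
    def cardiac_output_ml_min(self) -> float:
        return self.organs["lung"].blood_flow_ml_min

    @property
    def systemic_organs(self) -> tuple[str, ...]:
        """Organ names perfused in parallel between the blood pools."""
        return tuple(sorted(n for n in self.organs if n != "lung"))

    def plasma_flow_ml_min(self, organ: str) -> float:
        """Organ plasma flow: blood flow × (1 − hematocrit)."""
        return self.organs[organ].blood_flow_ml_min * (1.0 - self.hematocrit)

    def to_dict(self) -> dict:
        """JSON-compatible serialization (round-trips through fixtures)."""
        return {
            "species": self.species,
            "body_weight_kg": self.body_weight_kg,
            "bmi_kg_m2": self.bmi_kg_m2,
            "hematocrit": self.hematocrit,
            "saliva_volume_ml": self.saliva_volume_ml,
            "arterial_volume_ml": self.arterial_volume_ml,
            "venous_volume_ml": self.venous_volume_ml,
            "organs": {
                n: {
                    "volume_ml": o.volume_ml,
                    "blood_flow_ml_min": o.blood_flow_ml_min,
                    "f_vas": o.f_vas,
                    "f_water": o.f_water,
                    "f_lipid": o.f_lipid,
                    "f_protein": o.f_protein,
                    "eor_abundance": o.eor_abundance,
                }
                for n, o in self.organs.items()
            },
            "assumed_parameters": list(self.assumed_parameters),
        }


def _load_fixture(name: str) -> dict:
    path = resources.files("pbpkit.data").joinpath(f"{name}.json")
    with path.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def _deep_update(base: dict, overrides: Mapping) -> dict:
    out = dict(base)
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def physiology_from_dict(payload: Mapping, *, require_full_organ_set: bool = True) -> Physiology:
    """Build a :class:`Physiology` from a JSON-compatible mapping."""
    organs = {
        name: OrganParameters(name=name, **params)
        for name, params in payload["organs"].items()
    }
    return Physiology(
        species=payload["species"],
        body_weight_kg=payload["body_weight_kg"],
        bmi_kg_m2=payload.get("bmi_kg_m2"),
        hematocrit=payload["hematocrit"],
        organs=organs,
        saliva_volume_ml=payload["saliva_volume_ml"],
        arterial_volume_ml=payload["arterial_volume_ml"],
        venous_volume_ml=payload["venous_volume_ml"],
        assumed_parameters=tuple(payload.get("assumed_parameters", ())),
        require_full_organ_set=require_full_organ_set,
    )


def get_species_physiology(species: str, overrides: Mapping | None = None) -> Physiology:
    """Return the reference physiology for ``species``.

    Parameters
    ----------
    species : str
        ``"mouse"``/``"mouse_nod_shiltj"`` or ``"human"``/``"human_adult"``.
    overrides : mapping, optional
        Nested partial override of fixture values, e.g.
        ``{"hematocrit": 0.40, "organs": {"liver": {"volume_ml": 2.0}}}``.

    Raises
    ------
    UnsupportedSpeciesError
        If ``species`` is not one of the shipped references.
    """
    key = str(species).strip().lower().replace("-", "_").replace("/", "_")
    if key not in _SPECIES_ALIASES:
        raise UnsupportedSpeciesError(
            f"unsupported species {species!r}; expected one of "
            f"{sorted(set(_SPECIES_ALIASES))}"
        )
    payload = _load_fixture(_SPECIES_ALIASES[key])
    payload.pop("description", None)
    if overrides:
        payload = _deep_update(payload, overrides)
    return physiology_from_dict(payload)


def scale_physiology(
    base: Physiology,
    body_weight_kg: float,
    age_yr: float | None = None,
    sex: str | None = None,
) -> Physiology:
    """Allometrically rescale a physiology to a new body weight.

    Volumes (organs, blood pools, saliva) scale as ``(BW/BW_ref)^1`` and
    blood flows as ``(BW/BW_ref)^0.75``, where ``BW_ref`` is the body weight
    of ``base``.  Hematocrit and tissue compositions are unchanged, so the
    flow-conservation invariant is preserved exactly.  ``age_yr`` and ``sex``
    are accepted for bookkeeping only: organ-level age ontogeny is not
    modelled (age-driven covariates enter through the population module's
    weight-by-age mapping and clearance scaling instead).
    """
    if not body_weight_kg > 0:
        raise PhysiologyError(f"body weight must be > 0, got {body_weight_kg}")
    r = body_weight_kg / base.body_weight_kg
    rv = r**VOLUME_ALLOMETRIC_EXPONENT
    rq = r**FLOW_ALLOMETRIC_EXPONENT
    organs = {
        n: replace(o, volume_ml=o.volume_ml * rv, blood_flow_ml_min=o.blood_flow_ml_min * rq)
        for n, o in base.organs.items()
    }
    return replace(
        base,
        body_weight_kg=body_weight_kg,
        organs=organs,
        saliva_volume_ml=base.saliva_volume_ml * rv,
        arterial_volume_ml=base.arterial_volume_ml * rv,
        venous_volume_ml=base.venous_volume_ml * rv,
    )
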