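"""Species ocular physiologies.

The ocular disposition model uses a fixed compartment topology: the
pre-corneal tear film exchanges with the cornea (epithelium, then stroma)
and the conjunctiva; the anterior route continues into the aqueous humor and
iris–ciliary body, the conjunctival/scleral route into choroid, retina and
vitreous humor.  A physiology object carries the species-specific volumes,
exchange areas, tear dynamics and body weight for that topology.

Tear-film constants (tear volume, pre-cornea maximum volume, drainage rate)
follow the besifloxacin case study: the pre-corneal compartment can hold the
baseline tear volume plus a standard 30 µL instilled drop, and drains back
to baseline at 0.1 min⁻¹ (a value already adjusted for the product's
viscosity).  Tissue volumes and exchange areas are not part of that
parameterization; the built-in tables below are documented defaults drawn
from standard ocular-anatomy literature and can be overridden field by field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "OCULAR_COMPARTMENTS",
    "TOPOLOGY_EDGES",
    "EDGE_PERMEABILITY_TISSUE",
    "SPECIES",
    "OcularPhysiology",
    "builtin_physiology",
    "validate_physiology",
]

#: ocular tissue compartments (pre-cornea excluded: it has time-varying volume)
OCULAR_COMPARTMENTS = (
    "cornea_epithelium",
    "cornea_stroma",
    "conjunctiva",
    "aqueous_humor",
    "iris_ciliary_body",
    "sclera",
    "choroid",
    "retina",
    "vitreous_humor",
)

#: permitted transfer edges (ordered from the ocular surface inward)
TOPOLOGY_EDGES = (
    ("precornea", "cornea_epithelium"),
    ("cornea_epithelium", "cornea_stroma"),
    ("cornea_stroma", "aqueous_humor"),
    ("precornea", "conjunctiva"),
    ("conjunctiva", "sclera"),
    ("sclera", "choroid"),
    ("choroid", "retina"),
    ("retina", "vitreous_humor"),
    ("aqueous_humor", "iris_ciliary_body"),
    ("aqueous_humor", "vitreous_humor"),
)

#: tissue whose permeability governs each edge: the distal (second) member of
#: the ordered pair.  No tissue partition coefficients are applied.
EDGE_PERMEABILITY_TISSUE = {edge: edge[1] for edge in TOPOLOGY_EDGES}

SPECIES = ("NZ_rabbit", "DB_rabbit", "human")

#: standard instilled-drop allowance added to the baseline tear volume to get
#: the pre-cornea maximum volume (µL)
DROP_ALLOWANCE_UL = 30.0


@dataclass(frozen=True)
class OcularPhysiology:
    """Species-specific anatomy and tear dynamics.

    Parameters
    ----------
    species_label
        One of ``NZ_rabbit``, ``DB_rabbit``, ``human``.
    tear_volume
        Baseline pre-corneal fluid volume, µL.
    precornea_max_volume
        Maximum fluid the cul-de-sac holds right after a drop, µL.  Equals
        ``tear_volume + 30``; any excess instilled volume spills over.
    drainage_rate
        First-order nasolacrimal drainage rate of excess pre-corneal volume,
        min⁻¹.
    tear_turnover_rate
        Baseline tear production/drainage flow at physiological volume,
        µL/min; removes dissolved drug even once the volume has returned to
        baseline.
    aqueous_turnover_rate
        Aqueous humor production/outflow, µL/min; carries drug from the
        aqueous humor into the systemic circulation.
    compartment_volumes
        Tissue volumes, mL, keyed by :data:`OCULAR_COMPARTMENTS`.
    exchange_areas
        Exchange surface areas, cm², keyed by :data:`TOPOLOGY_EDGES`.
    body_weight
        kg; used only to convert the per-kg central volume of distribution
        to an absolute volume.
    """

    species_label: str
    tear_volume: float
    precornea_max_volume: float
    drainage_rate: float
    tear_turnover_rate: float
    aqueous_turnover_rate: float
    compartment_volumes: dict[str, float] = field(default_factory=dict)
    exchange_areas: dict[tuple[str, str], float] = field(default_factory=dict)
    body_weight: float = 1.0

    def with_overrides(self, **kwargs) -> "OcularPhysiology":
        """Return a copy with the given fields replaced."""
        merged = {}
        for key, value in kwargs.items():
            if key == "compartment_volumes":
                merged[key] = {**self.compartment_volumes, **value}
            elif key == "exchange_areas":
                current = dict(self.exchange_areas)
                current.update({tuple(k): v for k, v in value.items()})
                merged[key] = current
            else:
                merged[key] = value
        return replace(self, **merged)


# Default tissue volumes (mL).  Not drug-specific; literature-typical values
# for an adult animal/human eye.  Overridable via OcularPhysiology overrides.
_RABBIT_VOLUMES = {
    "cornea_epithelium": 0.010,
    "cornea_stroma": 0.28,
    "conjunctiva": 0.32,
    "aqueous_humor": 0.30,
    "iris_ciliary_body": 0.06,
    "sclera": 0.18,
    "choroid": 0.05,
    "retina": 0.05,
    "vitreous_humor": 1.50,
}
_HUMAN_VOLUMES = {
    "cornea_epithelium": 0.015,
    "cornea_stroma": 0.20,
    "conjunctiva": 0.40,
    "aqueous_humor": 0.25,
    "iris_ciliary_body": 0.10,
    "sclera": 0.55,
    "choroid": 0.20,
    "retina": 0.15,
    "vitreous_humor": 4.00,
}

# Default exchange areas (cm²); rabbit cornea ≈ 1.5 cm², human ≈ 1.0 cm²,
# conjunctival sac several-fold larger than the cornea in both species.
_RABBIT_AREAS = {
    ("precornea", "cornea_epithelium"): 1.5,
    ("cornea_epithelium", "cornea_stroma"): 1.5,
    ("cornea_stroma", "aqueous_humor"): 1.5,
    ("precornea", "conjunctiva"): 7.0,
    ("conjunctiva", "sclera"): 7.0,
    ("sclera", "choroid"): 5.0,
    ("choroid", "retina"): 4.5,
    ("retina", "vitreous_humor"): 4.5,
    ("aqueous_humor", "iris_ciliary_body"): 1.0,
    ("aqueous_humor", "vitreous_humor"): 0.8,
}
_HUMAN_AREAS = {
    ("precornea", "cornea_epithelium"): 1.0,
    ("cornea_epithelium", "cornea_stroma"): 1.0,
    ("cornea_stroma", "aqueous_humor"): 1.0,
    ("precornea", "conjunctiva"): 16.0,
    ("conjunctiva", "sclera"): 16.0,
    ("sclera", "choroid"): 11.0,
    ("choroid", "retina"): 10.0,
    ("retina", "vitreous_humor"): 10.0,
    ("aqueous_humor", "iris_ciliary_body"): 1.2,
    ("aqueous_humor", "vitreous_humor"): 1.0,
}


def builtin_physiology(species_label: str) -> OcularPhysiology:
    """Return the built-in physiology for a supported species.

    NZ (New Zealand white, albino) and DB (Dutch Belted, pigmented) rabbits
    share every field except the label: the only strain difference the full
    model would distinguish is melanin binding, which is not modeled here.
    """
    if species_label in ("NZ_rabbit", "DB_rabbit"):
        return OcularPhysiology(
            species_label=species_label,
            tear_volume=5.0,
            precornea_max_volume=35.0,
            drainage_rate=0.1,
            tear_turnover_rate=0.66,
            aqueous_turnover_rate=3.0,
            compartment_volumes=dict(_RABBIT_VOLUMES),
            exchange_areas=dict(_RABBIT_AREAS),
            body_weight=2.5,
        )
    if species_label == "human":
        return OcularPhysiology(
            species_label="human",
            tear_volume=7.0,
            precornea_max_volume=37.0,
            drainage_rate=0.1,
            tear_turnover_rate=1.2,
            aqueous_turnover_rate=2.5,
            compartment_volumes=dict(_HUMAN_VOLUMES),
            exchange_areas=dict(_HUMAN_AREAS),
            body_weight=70.0,
        )
    raise ValueError(
        f"unknown species {species_label!r}; supported species: {', '.join(SPECIES)}"
    )


def validate_physiology(p: OcularPhysiology) -> list[str]:
    """Check all physiology invariants; return human-readable violations.

    Returns an empty list iff the object is valid.  Violations are returned,
    never raised, so callers can aggregate them into one report.
    """
    violations: list[str] = []
    for name in (
        "tear_volume",
        "precornea_max_volume",
        "drainage_rate",
        "tear_turnover_rate",
        "aqueous_turnover_rate",
        "body_weight",
    ):
        value = getattr(p, name)
        if not value > 0:
            violations.append(f"{name} must be strictly positive, got {value}")

    expected = p.tear_volume + DROP_ALLOWANCE_UL
    if abs(p.precornea_max_volume - expected) > 1e-9:
        violations.append(
            "precornea_max_volume must equal tear_volume + 30 µL "
            f"(expected {expected} µL, got {p.precornea_max_volume} µL)"
        )

    missing = set(OCULAR_COMPARTMENTS) - set(p.compartment_volumes)
    extra = set(p.compartment_volumes) - set(OCULAR_COMPARTMENTS)
    if missing:
        violations.append(f"compartment_volumes missing: {sorted(missing)}")
    if extra:
        violations.append(f"compartment_volumes has unknown entries: {sorted(extra)}")
    for name, vol in p.compartment_volumes.items():
        if not vol > 0:
            violations.append(f"compartment volume {name} must be positive, got {vol}")

    edge_set = set(TOPOLOGY_EDGES)
    have = {tuple(k) for k in p.exchange_areas}
    if edge_set - have:
        violations.append(f"exchange_areas missing edges: {sorted(edge_set - have)}")
    if have - edge_set:
        violations.append(f"exchange_areas has unknown edges: {sorted(have - edge_set)}")
    for edge, area in p.exchange_areas.items():
        if not area > 0:
            violations.append(f"exchange area {edge} must be positive, got {area}")

    return violations
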