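"""Dosage-form mathematics.

Three pieces of formulation science live here:

* dissolved-fraction arithmetic — how much of a suspension's label strength
  is actually in solution at instillation (``min(1, solubility/strength)``);
* Weibull controlled release — the empirical cumulative-release function
  ``F(t) = Max · (1 − exp(−t^b / A))`` used to describe drug held by a
  mucoadhesive polymer vehicle and released over time.  ``Max`` is the
  asymptotic percent released (the remainder is never released and is booked
  as a lumped loss), ``A`` the time scale in h^b, ``b`` the shape;
* shrinking-sphere particle dissolution — a Nernst–Brunner rate for a
  monodisperse particle population, with diffusion-layer thickness equal to
  the particle radius capped at 30 µm.

Amounts are µg, volumes mL, time h; permeabilities and diffusion constants
are accepted in their conventional cm/s and cm²/s and converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .units import G_PER_ML_TO_UG_PER_ML, UM_TO_CM

__all__ = [
    "DrugParameters",
    "WeibullParams",
    "FormulationSpec",
    "besifloxacin",
    "besivance_suspension",
    "besivance_mixed_cr",
    "derive_dissolved_fraction",
    "weibull_fraction_released",
    "weibull_release_rate",
    "dissolution_rate",
    "split_dose",
]

#: diffusion-layer thickness cap for particle dissolution, µm
DIFFUSION_LAYER_CAP_UM = 30.0


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical, permeability and systemic-disposition constants.

    Units: ``water_solubility`` mg/mL; ``intestinal_permeability`` and every
    ``tissue_permeabilities`` entry cm/s; ``systemic_absorption_rates`` s⁻¹;
    ``Vc`` L/kg; ``CL`` L/h (absolute, for the reference body weight);
    ``diffusion_coefficient`` cm²/s; ``true_density`` g/mL.
    """

    name: str
    molecular_weight: float
    logP: float
    pka_list: tuple[tuple[float, str], ...]
    fu_plasma: float
    fu_melanin: float
    blood_to_plasma_ratio: float
    water_solubility: float
    intestinal_permeability: float
    Vc: float
    CL: float
    tissue_permeabilities: dict[str, float] = field(default_factory=dict)
    systemic_absorption_rates: dict[str, float] = field(default_factory=dict)
    diffusion_coefficient: float = 8e-6
    true_density: float = 1.3

    def with_overrides(self, **kwargs) -> "DrugParameters":
        merged = {}
        for key, value in kwargs.items():
            if key in ("tissue_permeabilities", "systemic_absorption_rates"):
                merged[key] = {**getattr(self, key), **value}
            else:
                merged[key] = value
        return replace(self, **merged)

    def validate(self) -> list[str]:
        violations = []
        for name in (
            "molecular_weight",
            "water_solubility",
            "intestinal_permeability",
            "Vc",
            "CL",
            "diffusion_coefficient",
            "true_density",
        ):
            if not getattr(self, name) > 0:
                violations.append(f"{name} must be strictly positive")
        for frac_name in ("fu_plasma", "fu_melanin"):
            frac = getattr(self, frac_name)
            if not (0 < frac <= 1):
                violations.append(f"{frac_name} must be in (0, 1], got {frac}")
        for tissue, perm in self.tissue_permeabilities.items():
            if not perm > 0:
                violations.append(f"permeability for {tissue} must be positive")
        for tissue, rate in self.systemic_absorption_rates.items():
            if not rate > 0:
                violations.append(f"systemic absorption rate for {tissue} must be positive")
        return violations


@dataclass(frozen=True)
class WeibullParams:
    """Cumulative-release function F(t) = max_released · (1 − exp(−t^shape / time_scale)).

    ``max_released`` is a percent in (0, 100]; ``time_scale`` has units
    h^shape; ``shape`` is dimensionless.
    """

    max_released: float
    time_scale: float
    shape: float

    def validate(self) -> list[str]:
        violations = []
        if not (0 < self.max_released <= 100):
            violations.append(f"max_released must be in (0, 100], got {self.max_released}")
        if not self.time_scale > 0:
            violations.append(f"time_scale must be positive, got {self.time_scale}")
        if not self.shape > 0:
            violations.append(f"shape must be positive, got {self.shape}")
        return violations


@dataclass(frozen=True)
class FormulationSpec:
    """A topical ophthalmic dosage form.

    ``dosage_mode`` selects how the undissolved fraction of a dose is
    represented: ``suspension`` instills it as solid particles that dissolve
    in the tear film (and are washed out with it), ``mixed_solution_cr``
    instills it as a controlled-release depot emptied by the Weibull
    function (the depot itself is not subject to tear drainage).
    """

    strength: float  # mg/mL label concentration
    drop_volume: float = 50.0  # µL
    particle_diameter: float = 3.0  # µm, monodisperse
    dissolved_fraction: float = 1.0
    dosage_mode: str = "suspension"
    weibull: WeibullParams | None = None

    def validate(self) -> list[str]:
        violations = []
        if not self.strength > 0:
            violations.append("strength must be positive")
        if not self.drop_volume > 0:
            violations.append("drop_volume must be positive")
        if not self.particle_diameter > 0:
            violations.append("particle_diameter must be positive")
        if not (0 <= self.dissolved_fraction <= 1):
            violations.append("dissolved_fraction must be in [0, 1]")
        if self.dosage_mode not in ("suspension", "mixed_solution_cr"):
            violations.append(f"unknown dosage_mode {self.dosage_mode!r}")
        if self.dosage_mode == "mixed_solution_cr":
            if self.weibull is None:
                violations.append("mixed_solution_cr mode requires weibull parameters")
            else:
                violations.extend(self.weibull.validate())
        return violations


def besifloxacin() -> DrugParameters:
    """Besifloxacin (Besivance 0.6% case study) parameter set.

    Permeabilities for cornea epithelium and conjunctiva and the
    iris–ciliary-body systemic absorption rate were fitted to rabbit ocular
    data; the remaining permeabilities are QSAR-derived defaults.  Systemic
    disposition is a one-compartment model (Vc 1.62 L/kg, CL 15.42 L/h for a
    2.5 kg rabbit).
    """
    return DrugParameters(
        name="besifloxacin",
        molecular_weight=393.85,
        logP=0.26,
        pka_list=((1.8, "base"), (6.0, "acid"), (9.9, "base")),
        fu_plasma=0.415,
        fu_melanin=1.0,
        blood_to_plasma_ratio=1.33,
        water_solubility=1.0,  # mg/mL, hydrochloride salt
        intestinal_permeability=0.39e-4,  # cm/s
        Vc=1.62,
        CL=15.42,
        tissue_permeabilities={  # cm/s
            "cornea_epithelium": 1.0e-7,
            "cornea_stroma": 1.86e-5,
            "conjunctiva": 1.4e-7,
            "aqueous_humor": 8.51e-6,
            "iris_ciliary_body": 7.74e-4,
            "sclera": 1.02e-5,
            "choroid": 1.84e-4,
            "retina": 1.73e-5,
            "vitreous_humor": 6.7e-6,
        },
        systemic_absorption_rates={  # s⁻¹
            "conjunctiva": 3.81e-4,
            "iris_ciliary_body": 5.0e-3,
            "choroid": 2.75e-4,
            "retina": 1.2e-3,
        },
    )


BESIVANCE_WEIBULL = WeibullParams(max_released=25.47, time_scale=11.93, shape=0.88)


def besivance_suspension(drug: DrugParameters | None = None) -> FormulationSpec:
    """Besivance 0.6% as a plain suspension (particles dissolve in tears)."""
    drug = drug or besifloxacin()
    strength = 6.0
    return FormulationSpec(
        strength=strength,
        drop_volume=50.0,
        particle_diameter=3.0,
        dissolved_fraction=derive_dissolved_fraction(drug.water_solubility, strength),
        dosage_mode="suspension",
    )


def besivance_mixed_cr(drug: DrugParameters | None = None) -> FormulationSpec:
    """Besivance 0.6% as mixed solution + controlled release.

    16.7% of each dose is instilled as solution, the remaining 83.3% as a
    CR depot released per the fitted Weibull function.
    """
    drug = drug or besifloxacin()
    strength = 6.0
    return FormulationSpec(
        strength=strength,
        drop_volume=50.0,
        particle_diameter=3.0,
        dissolved_fraction=derive_dissolved_fraction(drug.water_solubility, strength),
        dosage_mode="mixed_solution_cr",
        weibull=BESIVANCE_WEIBULL,
    )


def derive_dissolved_fraction(solubility: float, strength: float) -> float:
    """Fraction of a suspension's dose in solution at instillation.

    ``min(1, solubility / strength)`` with both in mg/mL: a 6 mg/mL
    suspension of a drug with 1 mg/mL water solubility is 16.7% dissolved.
    """
    if not solubility > 0:
        raise ValueError(f"solubility must be positive, got {solubility}")
    if not strength > 0:
        raise ValueError(f"strength must be positive, got {strength}")
    return min(1.0, solubility / strength)


def weibull_fraction_released(t, max_released: float, time_scale: float, shape: float):
    """Cumulative percent released at time ``t`` (h): Max·(1 − exp(−t^b/A)).

    Vectorized over ``t``; returns a float for scalar input.  Monotone
    non-decreasing, F(0) = 0, asymptote ``max_released``.
    """
    params = WeibullParams(max_released, time_scale, shape)
    bad = params.validate()
    if bad:
        raise ValueError("; ".join(bad))
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("release time must be non-negative")
    out = max_released * (-np.expm1(-(t_arr ** shape) / time_scale))
    return float(out) if np.isscalar(t) else out


def weibull_release_rate(t, max_released: float, time_scale: float, shape: float):
    """dF/dt in percent/h.  For shape < 1 the rate diverges at t = 0; callers
    integrating through a dose time should clamp t away from zero."""
    t_arr = np.asarray(t, dtype=float)
    out = (
        max_released
        * (shape * t_arr ** (shape - 1.0) / time_scale)
        * np.exp(-(t_arr ** shape) / time_scale)
    )
    return float(out) if np.isscalar(t) else out


def dissolution_rate(
    mass_undissolved: float,
    radius: float,
    dissolved_conc: float,
    solubility: float,
    D: float,
    density: float,
    fluid_volume: float,
) -> tuple[float, float]:
    """Shrinking-sphere dissolution rate for a monodisperse population.

    Parameters are in reporting units: mass µg, radius µm, concentrations
    µg/mL, D cm²/s, density g/mL, fluid volume mL.  Returns
    ``(dM/dt, dr/dt)`` in µg/h and µm/h, where M is the undissolved mass
    (so dM/dt ≤ 0 under dissolution).

    The rate is Nernst–Brunner with diffusion-layer thickness
    h = min(radius, 30 µm):

        dM/dt = −3·D·M·(Cs − C) / (ρ·h·r)
        dr/dt = −D·(Cs − C) / (ρ·h)

    Both vanish at saturation (C = Cs); under supersaturation the signs flip
    (precipitation onto the existing particles).
    """
    if not fluid_volume > 0:
        raise ValueError("fluid_volume must be positive")
    if mass_undissolved < 0:
        raise ValueError("mass_undissolved must be non-negative")
    if radius <= 0:
        if mass_undissolved > 0:
            raise ValueError("radius must be positive when undissolved mass remains")
        return 0.0, 0.0
    if mass_undissolved == 0:
        return 0.0, 0.0

    D_h = D * 3600.0  # cm²/h
    rho = density * G_PER_ML_TO_UG_PER_ML  # µg/mL
    r_cm = radius * UM_TO_CM
    h_cm = min(radius, DIFFUSION_LAYER_CAP_UM) * UM_TO_CM
    gradient = solubility - dissolved_conc  # µg/mL

    dM_dt = -3.0 * D_h * mass_undissolved * gradient / (rho * h_cm * r_cm)
    dr_dt_cm = -D_h * gradient / (rho * h_cm)
    return dM_dt, dr_dt_cm / UM_TO_CM


def split_dose(total_dose: float, spec: FormulationSpec) -> tuple[float, float, float]:
    """Partition a dose (µg) into (solution, CR depot, solid) amounts.

    The dissolved fraction is instilled as solution in both modes; the
    remainder goes to the CR depot in ``mixed_solution_cr`` mode and to
    suspended solid in ``suspension`` mode.  The parts sum to the input
    exactly.
    """
    if total_dose < 0:
        raise ValueError("total_dose must be non-negative")
    f = spec.dissolved_fraction
    solution = f * total_dose
    remainder = total_dose - solution
    if spec.dosage_mode == "mixed_solution_cr":
        return solution, remainder, 0.0
    return solution, 0.0, remainder
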