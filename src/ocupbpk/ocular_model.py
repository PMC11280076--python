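"""Ocular disposition ODE system.

Assembles and integrates the full model for a topical ophthalmic dose:

* pre-corneal tear film with time-varying volume: an instilled drop raises
  the volume (capped at the species pre-cornea maximum; the excess spills
  and carries its share of drug), after which nasolacrimal drainage returns
  the volume to baseline at a first-order rate, washing out dissolved and
  suspended drug alike; baseline tear turnover keeps removing dissolved
  drug at physiological volume;
* suspended-particle dissolution (shrinking sphere) and/or a
  controlled-release depot emptied by a Weibull function — each dose event
  spawns its own depot with its own release clock;
* passive permeation across the fixed tissue topology (permeability × area
  × concentration difference), first-order systemic absorption from the
  vascularized tissues, aqueous humor turnover outflow;
* a nasolacrimal/GI depot fed by drainage, absorbed into a one-compartment
  systemic model with linear clearance.

Internal units: amounts µg, volumes mL, time h.  Mass balance (dose =
compartments + sinks, including the never-released CR remainder still in
the depot) is checked at every output point and violations above tolerance
are a hard error.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .formulation import (
    DrugParameters,
    FormulationSpec,
    dissolution_rate,
    split_dose,
    weibull_release_rate,
)
from .physiology import (
    EDGE_PERMEABILITY_TISSUE,
    OCULAR_COMPARTMENTS,
    TOPOLOGY_EDGES,
    OcularPhysiology,
    validate_physiology,
)
from .units import (
    CM_PER_S_TO_CM_PER_H,
    MG_PER_ML_TO_UG_PER_ML,
    PER_MIN_TO_PER_H,
    PER_S_TO_PER_H,
    UL_TO_ML,
)

__all__ = [
    "DoseEvent",
    "ModelState",
    "SolverSettings",
    "SimulationResult",
    "apply_dose_event",
    "initial_state",
    "simulate",
]

SINK_NAMES = ("drainage_loss", "spillage_loss", "systemic_cleared", "gi_unabsorbed")

# state vector layout
_IV, _IDISS, _ISOLID, _IRAD, _ICR = 0, 1, 2, 3, 4
_ITISSUE0 = 5
_IGI = _ITISSUE0 + len(OCULAR_COMPARTMENTS)  # 14
_ISYS = _IGI + 1
_IDRAIN = _ISYS + 1
_ICLEAR = _IDRAIN + 1
_IGIUN = _ICLEAR + 1
_ICUMCR = _IGIUN + 1
_NSTATES = _ICUMCR + 1

#: clamp for the Weibull release clock; for shape < 1 the release rate
#: diverges at the dose instant, so the clock never evaluates below this (h)
_RELEASE_CLOCK_EPS = 1e-9
_SOLID_EPS = 1e-9  # µg; below this, dissolution rates are frozen
_RADIUS_EPS = 0.01  # µm; below this, remaining solid dissolves first-order
_FAST_DISSOLUTION = 1e4  # h⁻¹; rate constant for the near-exhausted regime


@dataclass(frozen=True)
class DoseEvent:
    """One instilled drop: ``volume`` µL of a ``strength`` mg/mL product at
    ``time`` h after simulation start."""

    time: float
    volume: float
    strength: float
    formulation: FormulationSpec

    @property
    def dose(self) -> float:
        """Total drug amount in the drop, µg."""
        return self.volume * self.strength  # µL · mg/mL = µg

    def validate(self) -> list[str]:
        violations = []
        if self.time < 0:
            violations.append("dose time must be non-negative")
        if not self.volume > 0:
            violations.append("dose volume must be positive")
        if not self.strength > 0:
            violations.append("dose strength must be positive")
        violations.extend(self.formulation.validate())
        return violations


@dataclass
class ModelState:
    """Snapshot of the full model state.

    ``amounts`` is keyed by compartment (pre-corneal dissolved/solid, CR
    depot, the nine ocular tissues, the nasolacrimal/GI depot, systemic);
    ``sinks`` accumulate eliminated drug.  ``cr_depots`` records, per dose
    event, the depot's release clock origin (h) and initial amount (µg) —
    release follows each depot's own Weibull clock.
    """

    precornea_volume: float  # µL
    amounts: dict[str, float]
    particle_radius: float  # µm
    cumulative_released_cr: float = 0.0
    sinks: dict[str, float] = field(default_factory=lambda: {s: 0.0 for s in SINK_NAMES})
    cr_depots: list[tuple[float, float]] = field(default_factory=list)

    def total_drug(self) -> float:
        return sum(self.amounts.values()) + sum(self.sinks.values())


def initial_state(physiology: OcularPhysiology, formulation: FormulationSpec) -> ModelState:
    """Drug-free state at baseline tear volume."""
    amounts = {"precornea_dissolved": 0.0, "precornea_solid": 0.0, "cr_depot": 0.0}
    amounts.update({c: 0.0 for c in OCULAR_COMPARTMENTS})
    amounts.update({"nasolacrimal_gi_depot": 0.0, "systemic": 0.0})
    return ModelState(
        precornea_volume=physiology.tear_volume,
        amounts=amounts,
        particle_radius=formulation.particle_diameter / 2.0,
    )


def apply_dose_event(
    state: ModelState, event: DoseEvent, physiology: OcularPhysiology
) -> ModelState:
    """Instill a drop, with overflow spillage.

    The pre-corneal volume rises to at most the species maximum; the
    retained fraction φ = (new volume − old volume) / drop volume scales the
    instilled solution, solid and CR amounts, and (1 − φ) of the dose is
    booked to the spillage sink.  Newly instilled particles are pooled with
    any remaining solid at the formulation's nominal radius (monodisperse
    single-radius state).
    """
    v_old = state.precornea_volume
    v_new = min(v_old + event.volume, physiology.precornea_max_volume)
    phi = (v_new - v_old) / event.volume
    solution, cr, solid = split_dose(event.dose, event.formulation)

    amounts = dict(state.amounts)
    amounts["precornea_dissolved"] += phi * solution
    amounts["precornea_solid"] += phi * solid
    amounts["cr_depot"] += phi * cr
    sinks = dict(state.sinks)
    sinks["spillage_loss"] += (1.0 - phi) * event.dose

    cr_depots = list(state.cr_depots)
    if phi * cr > 0:
        cr_depots.append((event.time, phi * cr))

    radius = state.particle_radius
    if phi * solid > 0:
        radius = event.formulation.particle_diameter / 2.0

    return ModelState(
        precornea_volume=v_new,
        amounts=amounts,
        particle_radius=radius,
        cumulative_released_cr=state.cumulative_released_cr,
        sinks=sinks,
        cr_depots=cr_depots,
    )


@dataclass(frozen=True)
class SolverSettings:
    """Integrator and model-plumbing options.

    ``gi_ka`` (h⁻¹) and ``gi_fabs`` parameterize the simplified first-order
    absorption of drained drug from the nasolacrimal/GI depot; with
    ``route_drainage_to_gi`` False, drained drug is booked directly to the
    ``drainage_loss`` sink instead (useful for isolation studies).
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12
    mass_balance_tol: float = 1e-6
    grid_points: int = 481
    route_drainage_to_gi: bool = True
    gi_ka: float = 0.5
    gi_fabs: float = 0.7


@dataclass
class SimulationResult:
    """Time grid plus trajectories for every compartment and sink.

    ``amounts`` are µg; ``concentrations`` µg/mL (tears use the time-varying
    pre-corneal volume; ``cornea`` is the epithelium+stroma pool; ``plasma``
    is systemic amount over the central volume of distribution).
    """

    time: np.ndarray
    precornea_volume: np.ndarray  # µL
    amounts: dict[str, np.ndarray]
    concentrations: dict[str, np.ndarray]
    sinks: dict[str, np.ndarray]
    dose_administered: np.ndarray  # cumulative µg at each output time
    metadata: dict

    def mass_balance_error(self) -> np.ndarray:
        """|dose − (amounts + sinks)| / dose at each output time (0 where
        no dose has been given yet)."""
        total = sum(self.amounts.values()) + sum(self.sinks.values())
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(self.dose_administered - total) / self.dose_administered
        return np.where(self.dose_administered > 0, rel, 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, compartment, amount, concentration) table."""
        rows = []
        for name, amount in self.amounts.items():
            conc = self.concentrations.get(name)
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.time,
                        "compartment": name,
                        "amount": amount,
                        "concentration": conc if conc is not None else np.nan,
                    }
                )
            )
        for name in ("tears", "cornea", "plasma"):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.time,
                        "compartment": name,
                        "amount": np.nan,
                        "concentration": self.concentrations[name],
                    }
                )
            )
        for name, sink in self.sinks.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.time,
                        "compartment": f"sink:{name}",
                        "amount": sink,
                        "concentration": np.nan,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


class _CompiledModel:
    """Parameters pre-converted to internal units for the RHS."""

    def __init__(
        self,
        drug: DrugParameters,
        physiology: OcularPhysiology,
        settings: SolverSettings,
    ):
        self.kd = physiology.drainage_rate * PER_MIN_TO_PER_H  # h⁻¹
        self.v_tear = physiology.tear_volume * UL_TO_ML  # mL
        self.q_tear = physiology.tear_turnover_rate * PER_MIN_TO_PER_H * UL_TO_ML  # mL/h
        self.q_ah = physiology.aqueous_turnover_rate * PER_MIN_TO_PER_H * UL_TO_ML  # mL/h
        self.volumes = np.array(
            [physiology.compartment_volumes[c] for c in OCULAR_COMPARTMENTS]
        )
        self.tissue_index = {c: i for i, c in enumerate(OCULAR_COMPARTMENTS)}
        # per-edge permeability·area in mL/h (cm/h · cm² = cm³/h)
        self.edge_pa = []
        for edge in TOPOLOGY_EDGES:
            perm_tissue = EDGE_PERMEABILITY_TISSUE[edge]
            pa = (
                drug.tissue_permeabilities[perm_tissue]
                * CM_PER_S_TO_CM_PER_H
                * physiology.exchange_areas[edge]
            )
            self.edge_pa.append((edge, pa))
        self.sar = {
            t: r * PER_S_TO_PER_H for t, r in drug.systemic_absorption_rates.items()
        }  # h⁻¹
        self.vd_ml = drug.Vc * physiology.body_weight * 1e3  # mL
        self.kel = drug.CL / (drug.Vc * physiology.body_weight)  # h⁻¹
        self.D = drug.diffusion_coefficient  # cm²/s (converted in dissolution_rate)
        self.density = drug.true_density
        self.cs = drug.water_solubility * MG_PER_ML_TO_UG_PER_ML  # µg/mL
        self.ka = settings.gi_ka
        self.fabs = settings.gi_fabs
        self.route_to_gi = settings.route_drainage_to_gi

    def rhs(self, t: float, y: np.ndarray, depots: list[tuple[float, float]], weibull):
        dy = np.zeros(_NSTATES)
        V = y[_IV]
        diss = y[_IDISS]
        solid = max(y[_ISOLID], 0.0)
        radius = y[_IRAD]

        # tear-film volume dynamics and washout of excess fluid
        excess = max(V - self.v_tear, 0.0)
        dy[_IV] = -self.kd * excess
        washout_frac = self.kd * excess / V if V > 0 else 0.0
        turnover_frac = self.q_tear / V if V > 0 else 0.0
        diss_washout = washout_frac * diss
        solid_washout = washout_frac * solid
        diss_turnover = turnover_frac * diss

        # particle dissolution (shrinking sphere)
        c_pre = diss / V if V > 0 else 0.0
        if solid > _SOLID_EPS and radius > _RADIUS_EPS:
            dM, dr = dissolution_rate(
                solid, radius, c_pre, self.cs, self.D, self.density, V
            )
        elif solid > _SOLID_EPS:
            # shrinking-sphere rate diverges as r → 0; dissolve the residual
            # mass with a fast first-order rate instead (mass-conserving)
            dM, dr = -_FAST_DISSOLUTION * solid * max(self.cs - c_pre, 0.0) / self.cs, 0.0
        else:
            dM, dr = 0.0, 0.0
        dy[_IRAD] = dr

        # controlled release: superposed Weibull depots, each on its own clock
        release = 0.0
        if depots and weibull is not None:
            for t0, amount0 in depots:
                tau = max(t - t0, _RELEASE_CLOCK_EPS)
                release += (
                    amount0
                    * weibull_release_rate(
                        tau, weibull.max_released, weibull.time_scale, weibull.shape
                    )
                    / 100.0
                )
        dy[_ICR] = -release
        dy[_ICUMCR] = release

        dy[_IDISS] = -dM + release - diss_washout - diss_turnover
        dy[_ISOLID] = dM - solid_washout

        # passive permeation over the fixed topology
        conc = y[_ITISSUE0 : _ITISSUE0 + len(OCULAR_COMPARTMENTS)] / self.volumes
        for (src, dst), pa in self.edge_pa:
            ci = c_pre if src == "precornea" else conc[self.tissue_index[src]]
            cj = conc[self.tissue_index[dst]]
            flux = pa * (ci - cj)  # µg/h, positive src→dst
            if src == "precornea":
                dy[_IDISS] -= flux
            else:
                dy[_ITISSUE0 + self.tissue_index[src]] -= flux
            dy[_ITISSUE0 + self.tissue_index[dst]] += flux

        # systemic absorption from vascularized tissues
        systemic_in = 0.0
        for tissue, rate in self.sar.items():
            i = _ITISSUE0 + self.tissue_index[tissue]
            loss = rate * y[i]
            dy[i] -= loss
            systemic_in += loss
        # aqueous humor turnover outflow
        ah = self.tissue_index["aqueous_humor"]
        ah_out = self.q_ah * conc[ah]
        dy[_ITISSUE0 + ah] -= ah_out
        systemic_in += ah_out

        # nasolacrimal/GI depot and one-compartment systemic disposition
        drained = diss_washout + solid_washout + diss_turnover
        if self.route_to_gi:
            gi_out = self.ka * y[_IGI]
            dy[_IGI] = drained - gi_out
            systemic_in += self.fabs * gi_out
            dy[_IGIUN] = (1.0 - self.fabs) * gi_out
        else:
            dy[_IDRAIN] = drained

        cleared = self.kel * y[_ISYS]
        dy[_ISYS] = systemic_in - cleared
        dy[_ICLEAR] = cleared
        return dy


def _state_to_vector(state: ModelState) -> np.ndarray:
    y = np.zeros(_NSTATES)
    y[_IV] = state.precornea_volume * UL_TO_ML
    y[_IDISS] = state.amounts["precornea_dissolved"]
    y[_ISOLID] = state.amounts["precornea_solid"]
    y[_IRAD] = state.particle_radius
    y[_ICR] = state.amounts["cr_depot"]
    for i, c in enumerate(OCULAR_COMPARTMENTS):
        y[_ITISSUE0 + i] = state.amounts[c]
    y[_IGI] = state.amounts["nasolacrimal_gi_depot"]
    y[_ISYS] = state.amounts["systemic"]
    y[_IDRAIN] = state.sinks["drainage_loss"]
    y[_ICLEAR] = state.sinks["systemic_cleared"]
    y[_IGIUN] = state.sinks["gi_unabsorbed"]
    y[_ICUMCR] = state.cumulative_released_cr
    return y


def _vector_to_state(y: np.ndarray, spillage: float, depots) -> ModelState:
    amounts = {
        "precornea_dissolved": y[_IDISS],
        "precornea_solid": y[_ISOLID],
        "cr_depot": y[_ICR],
    }
    for i, c in enumerate(OCULAR_COMPARTMENTS):
        amounts[c] = y[_ITISSUE0 + i]
    amounts["nasolacrimal_gi_depot"] = y[_IGI]
    amounts["systemic"] = y[_ISYS]
    return ModelState(
        precornea_volume=y[_IV] / UL_TO_ML,
        amounts=amounts,
        particle_radius=y[_IRAD],
        cumulative_released_cr=y[_ICUMCR],
        sinks={
            "drainage_loss": y[_IDRAIN],
            "spillage_loss": spillage,
            "systemic_cleared": y[_ICLEAR],
            "gi_unabsorbed": y[_IGIUN],
        },
        cr_depots=list(depots),
    )


def _config_checksum(*objects) -> str:
    text = "|".join(repr(o) for o in objects)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def simulate(
    drug: DrugParameters,
    formulation: FormulationSpec,
    physiology: OcularPhysiology,
    protocol: list[DoseEvent],
    t_end: float,
    settings: SolverSettings | None = None,
    grid: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the full model over ``[0, t_end]`` h.

    Integration restarts at every dose event (the instillation itself is an
    instantaneous state update).  Output is evaluated on ``grid`` (default:
    ``grid_points`` evenly spaced times) plus the dose times; at a dose time
    the reported state is post-dose.  A mass-balance violation beyond
    ``settings.mass_balance_tol`` raises ``RuntimeError``.
    """
    settings = settings or SolverSettings()
    problems = []
    problems += [f"drug: {v}" for v in drug.validate()]
    problems += [f"formulation: {v}" for v in formulation.validate()]
    problems += [f"physiology: {v}" for v in validate_physiology(physiology)]
    if not protocol:
        problems.append("protocol must contain at least one dose event")
    for i, ev in enumerate(protocol):
        problems += [f"dose[{i}]: {v}" for v in ev.validate()]
    if protocol and t_end <= max(ev.time for ev in protocol):
        problems.append("t_end must lie beyond the last dose time")
    if problems:
        raise ValueError("invalid simulation inputs:\n  " + "\n  ".join(problems))

    events = sorted(protocol, key=lambda e: e.time)
    if grid is None:
        grid = np.linspace(0.0, t_end, settings.grid_points)
    grid = np.unique(
        np.concatenate(
            [np.asarray(grid, float), [0.0, t_end], [ev.time for ev in events]]
        )
    )
    if grid[0] < 0 or grid[-1] > t_end:
        raise ValueError("output grid must lie within [0, t_end]")

    model = _CompiledModel(drug, physiology, settings)
    state = initial_state(physiology, formulation)
    weibull = formulation.weibull

    # integration breakpoints: 0, dose times, t_end
    breaks = sorted({0.0, t_end, *(ev.time for ev in events)})
    by_time: dict[float, list[DoseEvent]] = {}
    for ev in events:
        by_time.setdefault(ev.time, []).append(ev)

    times_out: list[float] = []
    states_out: list[np.ndarray] = []
    spill_out: list[float] = []
    y = _state_to_vector(state)
    spillage = 0.0
    depots: list[tuple[float, float]] = []

    for k, t0 in enumerate(breaks):
        if t0 in by_time:
            st = _vector_to_state(y, spillage, depots)
            for ev in by_time[t0]:
                st = apply_dose_event(st, ev, physiology)
            spillage = st.sinks["spillage_loss"]
            depots = st.cr_depots
            y = _state_to_vector(st)
        if t0 in grid:
            times_out.append(t0)
            states_out.append(y.copy())
            spill_out.append(spillage)
        if k == len(breaks) - 1:
            break
        t1 = breaks[k + 1]
        seg_eval = grid[(grid > t0) & (grid < t1)]
        sol = solve_ivp(
            model.rhs,
            (t0, t1),
            y,
            method=settings.method,
            rtol=settings.rtol,
            atol=settings.atol,
            t_eval=np.concatenate([seg_eval, [t1]]),
            args=(depots, weibull),
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed on [{t0}, {t1}] h: {sol.message} "
                f"(drug={drug.name}, species={physiology.species_label})"
            )
        for ti, yi in zip(sol.t[:-1], sol.y.T[:-1]):
            times_out.append(ti)
            states_out.append(yi.copy())
            spill_out.append(spillage)
        y = sol.y[:, -1].copy()

    t_arr = np.array(times_out)
    Y = np.array(states_out).T
    spill_arr = np.array(spill_out)

    amounts = {
        "precornea_dissolved": Y[_IDISS],
        "precornea_solid": Y[_ISOLID],
        "cr_depot": Y[_ICR],
    }
    for i, c in enumerate(OCULAR_COMPARTMENTS):
        amounts[c] = Y[_ITISSUE0 + i]
    amounts["nasolacrimal_gi_depot"] = Y[_IGI]
    amounts["systemic"] = Y[_ISYS]

    v_ml = Y[_IV]
    concentrations = {"precornea_dissolved": amounts["precornea_dissolved"] / v_ml}
    concentrations["tears"] = concentrations["precornea_dissolved"]
    for c in OCULAR_COMPARTMENTS:
        concentrations[c] = amounts[c] / physiology.compartment_volumes[c]
    cornea_vol = (
        physiology.compartment_volumes["cornea_epithelium"]
        + physiology.compartment_volumes["cornea_stroma"]
    )
    concentrations["cornea"] = (
        amounts["cornea_epithelium"] + amounts["cornea_stroma"]
    ) / cornea_vol
    concentrations["plasma"] = amounts["systemic"] / model.vd_ml

    sinks = {
        "drainage_loss": Y[_IDRAIN],
        "spillage_loss": spill_arr,
        "systemic_cleared": Y[_ICLEAR],
        "gi_unabsorbed": Y[_IGIUN],
    }

    dose_cum = np.array(
        [sum(ev.dose for ev in events if ev.time <= ti) for ti in t_arr]
    )
    metadata = {
        "drug": drug,
        "formulation": formulation,
        "physiology": physiology,
        "protocol": events,
        "settings": settings,
        "t_end": t_end,
        "cumulative_released_cr": Y[_ICUMCR],
        "cr_depots": depots,
        "config_checksum": _config_checksum(drug, formulation, physiology, events, settings),
    }
    result = SimulationResult(
        time=t_arr,
        precornea_volume=v_ml / UL_TO_ML,
        amounts=amounts,
        concentrations=concentrations,
        sinks=sinks,
        dose_administered=dose_cum,
        metadata=metadata,
    )

    worst = result.mass_balance_error().max()
    if worst > settings.mass_balance_tol:
        raise RuntimeError(
            f"mass-balance violation {worst:.3e} exceeds tolerance "
            f"{settings.mass_balance_tol:.1e} (drug={drug.name}, "
            f"species={physiology.species_label})"
        )
    return result
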