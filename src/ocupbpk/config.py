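"""Configuration files and pipeline runners.

One YAML document drives a run.  Sections: ``drug`` (a builtin parameter set
plus optional field overrides), ``formulation`` (a preset or explicit
fields), ``physiology`` (species plus overrides), ``protocol`` (dose events
and horizon), ``solver``, and one mode-specific section (``fit``,
``generate`` or ``validate``).  Numeric fields accept unit suffixes for the
documented units ("50 uL", "0.1 1/min", "24 h"); bare numbers are taken in
the canonical unit of the field.

Every runner writes a machine-readable run log (effective parameters, mass
balance, config checksum, seed) next to its data outputs, sufficient to
reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import formulation as formulation_mod
from .fitting import (
    FitProblem,
    FitResult,
    FreeParameter,
    OptimizerSettings,
    fit,
)
from .formulation import DrugParameters, FormulationSpec, WeibullParams
from .ocular_model import DoseEvent, SimulationResult, SolverSettings, simulate
from .physiology import OcularPhysiology, builtin_physiology, validate_physiology
from .pk_analysis import compute_metrics, fold_error
from .synthetic_data import (
    NoiseModel,
    generate_study,
    read_datasets,
    write_datasets,
)
from .units import parse_quantity

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "build_context",
    "run_simulate",
    "run_fit",
    "run_generate",
    "run_validate",
    "physiology_table",
]

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DrugConfig(_Section):
    builtin: str = "besifloxacin"
    overrides: dict[str, Any] = Field(default_factory=dict)


class WeibullConfig(_Section):
    max_released: float
    time_scale: float
    shape: float


class FormulationConfig(_Section):
    preset: str | None = None  # besivance_suspension | besivance_mixed_cr
    strength: float | str | None = None
    drop_volume: float | str | None = None
    particle_diameter: float | str | None = None
    dissolved_fraction: float | None = None
    dosage_mode: str | None = None
    weibull: WeibullConfig | None = None


class PhysiologyConfig(_Section):
    species: str
    overrides: dict[str, Any] = Field(default_factory=dict)


class DoseConfig(_Section):
    time: float | str = 0.0
    volume: float | str = 50.0
    strength: float | str | None = None  # defaults to the formulation strength


class ProtocolConfig(_Section):
    doses: list[DoseConfig]
    t_end: float | str = 24.0


class SolverConfig(_Section):
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12
    mass_balance_tol: float = 1e-6
    grid_points: int = 481
    route_drainage_to_gi: bool = True
    gi_ka: float = 0.5
    gi_fabs: float = 0.7


class FreeParameterConfig(_Section):
    name: str
    initial: float
    lower: float
    upper: float
    log_scale: bool = False


class FitConfig(_Section):
    free_parameters: list[FreeParameterConfig]
    datasets: list[str]  # paths to tidy dataset files
    objective: str = "log_wls"
    n_starts: int = 5
    xatol: float = 1e-6
    fatol: float = 1e-8
    maxiter: int = 2000


class NoiseConfig(_Section):
    cv: float = 0.3
    n_subjects_per_timepoint: int = 4
    sampling: str = "destructive"


class GenerateConfig(_Section):
    timepoints: list[float | str]
    tissues: list[str]
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    study_code: str = "synthetic"


class ValidateConfig(_Section):
    observed: list[str]  # paths to tidy dataset files
    k_fold: float = 3.0


class RunConfig(_Section):
    mode: str
    seed: int = 0
    study_code: str | None = None
    drug: DrugConfig = Field(default_factory=DrugConfig)
    formulation: FormulationConfig = Field(default_factory=FormulationConfig)
    physiology: PhysiologyConfig
    protocol: ProtocolConfig | None = None
    solver: SolverConfig = Field(default_factory=SolverConfig)
    fit: FitConfig | None = None
    generate: GenerateConfig | None = None
    validate_: ValidateConfig | None = Field(default=None, alias="validate")

    model_config = ConfigDict(extra="forbid", populate_by_name=True)


_MODE_SECTIONS = {
    "simulate": ("protocol",),
    "fit": ("protocol", "fit"),
    "generate": ("protocol", "generate"),
    "validate": ("protocol", "validate_"),
}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        config = RunConfig.model_validate(raw)
    except ValidationError as err:
        lines = [
            f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError(f"{path}: invalid configuration:\n  " + "\n  ".join(lines)) from None
    if config.mode not in _MODE_SECTIONS:
        raise ConfigError(
            f"{path}: unknown mode {config.mode!r}; choose from {sorted(_MODE_SECTIONS)}"
        )
    missing = [
        section.rstrip("_")
        for section in _MODE_SECTIONS[config.mode]
        if getattr(config, section) is None
    ]
    if missing:
        raise ConfigError(
            f"{path}: mode {config.mode!r} requires missing section(s): {', '.join(missing)}"
        )
    return config


_BUILTIN_DRUGS = {"besifloxacin": formulation_mod.besifloxacin}
_FORMULATION_PRESETS = {
    "besivance_suspension": formulation_mod.besivance_suspension,
    "besivance_mixed_cr": formulation_mod.besivance_mixed_cr,
}

# physiology override fields that accept unit suffixes, with their dimension
_PHYS_DIMENSIONS = {
    "tear_volume": "volume",
    "precornea_max_volume": "volume",
    "drainage_rate": "rate",
    "tear_turnover_rate": "flow",
    "aqueous_turnover_rate": "flow",
    "body_weight": "mass",
}


def build_context(
    config: RunConfig,
) -> tuple[DrugParameters, FormulationSpec, OcularPhysiology, list[DoseEvent], float, SolverSettings]:
    """Materialize the model objects a config describes."""
    if config.drug.builtin not in _BUILTIN_DRUGS:
        raise ConfigError(
            f"unknown builtin drug {config.drug.builtin!r}; available: "
            f"{sorted(_BUILTIN_DRUGS)}"
        )
    drug = _BUILTIN_DRUGS[config.drug.builtin]()
    if config.drug.overrides:
        drug = drug.with_overrides(**config.drug.overrides)

    fc = config.formulation
    if fc.preset is not None:
        if fc.preset not in _FORMULATION_PRESETS:
            raise ConfigError(
                f"unknown formulation preset {fc.preset!r}; available: "
                f"{sorted(_FORMULATION_PRESETS)}"
            )
        form = _FORMULATION_PRESETS[fc.preset](drug)
    else:
        if fc.strength is None:
            raise ConfigError("formulation needs either a preset or an explicit strength")
        form = FormulationSpec(strength=parse_quantity(fc.strength, "strength"))
    updates: dict[str, Any] = {}
    if fc.strength is not None:
        updates["strength"] = parse_quantity(fc.strength, "strength")
    if fc.drop_volume is not None:
        updates["drop_volume"] = parse_quantity(fc.drop_volume, "volume")
    if fc.particle_diameter is not None:
        updates["particle_diameter"] = parse_quantity(fc.particle_diameter, "length")
    if fc.dissolved_fraction is not None:
        updates["dissolved_fraction"] = fc.dissolved_fraction
    if fc.dosage_mode is not None:
        updates["dosage_mode"] = fc.dosage_mode
    if fc.weibull is not None:
        updates["weibull"] = WeibullParams(
            fc.weibull.max_released, fc.weibull.time_scale, fc.weibull.shape
        )
    if updates:
        form = dataclasses.replace(form, **updates)

    physiology = builtin_physiology(config.physiology.species)
    if config.physiology.overrides:
        overrides = {}
        for key, value in config.physiology.overrides.items():
            if key in _PHYS_DIMENSIONS:
                overrides[key] = parse_quantity(value, _PHYS_DIMENSIONS[key])
            else:
                overrides[key] = value
        physiology = physiology.with_overrides(**overrides)
    problems = validate_physiology(physiology)
    if problems:
        raise ConfigError("invalid physiology:\n  " + "\n  ".join(problems))

    protocol: list[DoseEvent] = []
    t_end = 24.0
    if config.protocol is not None:
        for dose in config.protocol.doses:
            strength = (
                parse_quantity(dose.strength, "strength")
                if dose.strength is not None
                else form.strength
            )
            protocol.append(
                DoseEvent(
                    time=parse_quantity(dose.time, "time"),
                    volume=parse_quantity(dose.volume, "volume"),
                    strength=strength,
                    formulation=form,
                )
            )
        t_end = parse_quantity(config.protocol.t_end, "time")

    sc = config.solver
    settings = SolverSettings(
        method=sc.method,
        rtol=sc.rtol,
        atol=sc.atol,
        mass_balance_tol=sc.mass_balance_tol,
        grid_points=sc.grid_points,
        route_drainage_to_gi=sc.route_drainage_to_gi,
        gi_ka=sc.gi_ka,
        gi_fabs=sc.gi_fabs,
    )
    return drug, form, physiology, protocol, t_end, settings


def physiology_table(p: OcularPhysiology) -> pd.DataFrame:
    """Full effective physiology as a tidy (field, value, unit) table."""
    rows = [
        ("species_label", p.species_label, ""),
        ("tear_volume", p.tear_volume, "uL"),
        ("precornea_max_volume", p.precornea_max_volume, "uL"),
        ("drainage_rate", p.drainage_rate, "1/min"),
        ("tear_turnover_rate", p.tear_turnover_rate, "uL/min"),
        ("aqueous_turnover_rate", p.aqueous_turnover_rate, "uL/min"),
        ("body_weight", p.body_weight, "kg"),
    ]
    for name, vol in p.compartment_volumes.items():
        rows.append((f"volume.{name}", vol, "mL"))
    for (a, b), area in p.exchange_areas.items():
        rows.append((f"area.{a}->{b}", area, "cm2"))
    return pd.DataFrame(rows, columns=["field", "value", "unit"])


def _echo(obj) -> Any:
    """JSON-serializable echo of dataclass parameter objects."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _echo(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _echo(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_echo(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_runlog(path: Path, mode: str, config: RunConfig, context, extra: dict) -> None:
    drug, form, physiology, protocol, t_end, settings = context
    log = {
        "mode": mode,
        "seed": config.seed,
        "drug": _echo(drug),
        "formulation": _echo(form),
        "physiology": _echo(physiology),
        "protocol": _echo(protocol),
        "t_end": t_end,
        "solver": _echo(settings),
        **extra,
    }
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")


def run_simulate(config: RunConfig, outdir: str | Path) -> SimulationResult:
    """Simulate the configured protocol; write the tidy timecourse and a run
    log with full parameter echo and mass-balance report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    context = build_context(config)
    drug, form, physiology, protocol, t_end, settings = context
    result = simulate(drug, form, physiology, protocol, t_end, settings=settings)
    frame = result.to_frame()
    frame.to_csv(outdir / "timecourse.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    physiology_table(physiology).to_csv(
        outdir / "physiology.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    _write_runlog(
        outdir / "runlog.json",
        "simulate",
        config,
        context,
        {
            "mass_balance_worst": float(result.mass_balance_error().max()),
            "config_checksum": result.metadata["config_checksum"],
            "dose_administered_total": float(result.dose_administered[-1]),
        },
    )
    return result


def run_fit(config: RunConfig, outdir: str | Path) -> FitResult:
    """Fit the configured free parameters to the configured datasets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    context = build_context(config)
    drug, form, physiology, protocol, _t_end, settings = context
    assert config.fit is not None
    datasets = []
    for path in config.fit.datasets:
        datasets.extend(read_datasets(path))
    problem = FitProblem(
        free_parameters=[
            FreeParameter(p.name, p.initial, p.lower, p.upper, p.log_scale)
            for p in config.fit.free_parameters
        ],
        datasets=datasets,
        drug=drug,
        formulation=form,
        physiology=physiology,
        protocol=protocol,
        objective=config.fit.objective,
        solver=settings,
    )
    opt = OptimizerSettings(
        n_starts=config.fit.n_starts,
        xatol=config.fit.xatol,
        fatol=config.fit.fatol,
        maxiter=config.fit.maxiter,
    )
    result = fit(problem, opt, seed=config.seed)
    table = pd.DataFrame(
        {
            "parameter": list(result.estimates),
            "estimate": list(result.estimates.values()),
            "stderr": [result.stderr[k] for k in result.estimates],
        }
    )
    table.to_csv(outdir / "parameters.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    result.residuals.to_csv(
        outdir / "residual_summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    _write_runlog(
        outdir / "runlog.json",
        "fit",
        config,
        context,
        {
            "estimates": result.estimates,
            "stderr": result.stderr,
            "objective_value": result.objective_value,
            "objective_initial": result.objective_initial,
            "converged": result.converged,
            "message": result.message,
            "n_evaluations": result.n_evaluations,
            "starts": result.starts,
        },
    )
    return result


def run_generate(config: RunConfig, outdir: str | Path):
    """Generate a synthetic observed-like study and write it as a tidy table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    context = build_context(config)
    drug, form, physiology, protocol, _t_end, settings = context
    assert config.generate is not None
    gc = config.generate
    noise = NoiseModel(
        cv=gc.noise.cv,
        n_subjects_per_timepoint=gc.noise.n_subjects_per_timepoint,
        sampling=gc.noise.sampling,
        seed=config.seed,
    )
    timepoints = [parse_quantity(t, "time") for t in gc.timepoints]
    datasets = generate_study(
        drug,
        form,
        physiology,
        protocol,
        timepoints,
        gc.tissues,
        noise,
        study_code=gc.study_code,
        settings=settings,
    )
    write_datasets(datasets, outdir / "dataset.tsv")
    _write_runlog(
        outdir / "runlog.json",
        "generate",
        config,
        context,
        {"noise": _echo(noise), "tissues": list(gc.tissues), "timepoints": timepoints},
    )
    return datasets


def run_validate(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Simulate the protocol and compare against observed datasets.

    Writes a per-study/tissue report with PK metrics and fold-error
    summaries; returns it as a DataFrame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    context = build_context(config)
    drug, form, physiology, protocol, t_end, settings = context
    assert config.validate_ is not None
    observed = []
    for path in config.validate_.observed:
        observed.extend(read_datasets(path))
    horizon = max([t_end] + [float(ds.data["time"].max()) for ds in observed])
    grid = np.unique(np.concatenate([ds.data["time"].to_numpy(float) for ds in observed]))
    result = simulate(drug, form, physiology, protocol, horizon, settings=settings, grid=grid)

    rows = []
    for ds in observed:
        t = ds.data["time"].to_numpy(float)
        idx = np.searchsorted(result.time, t)
        sim = result.concentrations[ds.tissue][idx]
        obs = ds.data["mean_conc"].to_numpy(float)
        fe = fold_error(sim, obs)
        sim_metrics = compute_metrics(result, ds.tissue)
        obs_metrics = compute_metrics(ds, ds.tissue)
        rows.append(
            {
                "study": ds.study_code,
                "tissue": ds.tissue,
                "n_points": len(t),
                "fold_error_geomean": fe.geometric_mean,
                "fold_error_max": fe.maximum,
                "within_k_fold": fe.within(config.validate_.k_fold),
                "k_fold": config.validate_.k_fold,
                "sim_cmax": sim_metrics.cmax,
                "obs_cmax": obs_metrics.cmax,
                "sim_auc": sim_metrics.auc_0_t,
                "obs_auc": obs_metrics.auc_0_t,
                "n_excluded_zero_obs": fe.n_excluded_zero_obs,
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "validation.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_runlog(
        outdir / "runlog.json",
        "validate",
        config,
        context,
        {"report": report.to_dict(orient="records")},
    )
    return report
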