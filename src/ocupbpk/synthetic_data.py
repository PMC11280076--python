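"""Observed-like dataset generation.

Ocular PK studies of topical products use sparse destructive sampling: at
each timepoint a separate group of animals is sacrificed and tears, cornea,
conjunctiva, aqueous humor and plasma are assayed, so the reported values
are per-timepoint means, SDs and group sizes.  Inter-animal variability in
these studies is large and right-skewed (SDs often exceed means), so the
generator draws multiplicative lognormal deviates around the model-simulated
true concentration, parameterized so the deviates' mean equals the true
value and their coefficient of variation equals ``cv``.

The same tidy delimited format is used for generated and user-supplied real
data, so the fitting and validation code paths are identical for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formulation import DrugParameters, FormulationSpec
from .ocular_model import DoseEvent, SolverSettings, simulate
from .physiology import OcularPhysiology

__all__ = [
    "OBSERVABLE_TISSUES",
    "ObservedDataset",
    "NoiseModel",
    "sample_noisy_means",
    "generate_study",
    "write_datasets",
    "read_datasets",
]

#: tissues an ocular PK study can report, mapped to model concentration keys
OBSERVABLE_TISSUES = ("tears", "cornea", "conjunctiva", "aqueous_humor", "plasma")


@dataclass
class ObservedDataset:
    """Per-timepoint summary data for one tissue of one study.

    ``data`` columns: ``time`` (h, sorted), ``mean_conc`` (µg/mL or µg/g),
    ``sd`` (same units) and ``n`` (animals per timepoint).  The pseudo-tissue
    ``cr_release`` holds a cumulative-release curve in percent, used to fit
    Weibull release parameters decoupled from the tissue model.
    """

    study_code: str
    species_label: str
    tissue: str
    data: pd.DataFrame

    def validate(self) -> list[str]:
        violations = []
        t = self.data["time"].to_numpy()
        if np.any(t < 0):
            violations.append("times must be non-negative")
        if not np.all(np.diff(t) >= 0):
            violations.append("times must be sorted ascending")
        if np.any(self.data["n"].to_numpy() < 1):
            violations.append("n must be at least 1")
        if np.any(self.data["sd"].to_numpy() < 0):
            violations.append("sd must be non-negative")
        return violations


@dataclass(frozen=True)
class NoiseModel:
    """Lognormal inter-subject noise specification.

    ``cv`` is the coefficient of variation of individual concentrations;
    ``sampling='destructive'`` draws independent subjects at every timepoint,
    ``'serial'`` reuses one multiplicative deviate per subject across all
    timepoints (repeated measurement of the same animals).
    """

    cv: float = 0.3
    n_subjects_per_timepoint: int = 4
    sampling: str = "destructive"
    distribution: str = "lognormal"
    seed: int = 0

    def validate(self) -> list[str]:
        violations = []
        if self.cv < 0:
            violations.append("cv must be non-negative")
        if self.n_subjects_per_timepoint < 1:
            violations.append("n_subjects_per_timepoint must be at least 1")
        if self.sampling not in ("destructive", "serial"):
            violations.append(f"unknown sampling {self.sampling!r}")
        if self.distribution != "lognormal":
            violations.append(f"unsupported distribution {self.distribution!r}")
        return violations


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative deviates with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size))


def sample_noisy_means(
    true_conc: np.ndarray, noise: NoiseModel, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-timepoint (mean, sd) summaries around true concentrations.

    With destructive sampling each timepoint gets ``n`` independent subjects;
    with serial sampling the same ``n`` subject-level deviates apply at every
    timepoint.  Means are unbiased for the true concentration; for n ≥ 2 the
    SD is the sample SD (ddof 1), else 0.
    """
    rng = rng or np.random.default_rng(noise.seed)
    true_conc = np.asarray(true_conc, dtype=float)
    n = noise.n_subjects_per_timepoint
    if noise.sampling == "serial":
        factors = np.tile(_lognormal_factors(rng, noise.cv, n), (len(true_conc), 1))
    else:
        factors = _lognormal_factors(rng, noise.cv, (len(true_conc), n))
    draws = true_conc[:, None] * factors
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1) if n > 1 else np.zeros_like(means)
    return means, sds


def generate_study(
    drug: DrugParameters,
    formulation: FormulationSpec,
    physiology: OcularPhysiology,
    protocol: list[DoseEvent],
    timepoints,
    tissues,
    noise: NoiseModel,
    study_code: str = "synthetic",
    settings: SolverSettings | None = None,
) -> list[ObservedDataset]:
    """Simulate true profiles and emit one noisy summary dataset per tissue.

    Fully determined by ``noise.seed``; with ``cv = 0`` the reported means
    equal the simulated true concentrations exactly.
    """
    bad = noise.validate()
    if bad:
        raise ValueError("; ".join(bad))
    timepoints = np.asarray(sorted(timepoints), dtype=float)
    unknown = set(tissues) - set(OBSERVABLE_TISSUES)
    if unknown:
        raise ValueError(f"unknown tissues {sorted(unknown)}; choose from {OBSERVABLE_TISSUES}")
    t_end = float(timepoints[-1])
    last_dose = max(ev.time for ev in protocol)
    if t_end <= last_dose:
        raise ValueError("timepoints must extend beyond the last dose")
    result = simulate(
        drug, formulation, physiology, protocol, t_end, settings=settings, grid=timepoints
    )
    idx = np.searchsorted(result.time, timepoints)
    rng = np.random.default_rng(noise.seed)
    datasets = []
    for tissue in tissues:
        true = result.concentrations[tissue][idx]
        means, sds = sample_noisy_means(true, noise, rng)
        datasets.append(
            ObservedDataset(
                study_code=study_code,
                species_label=physiology.species_label,
                tissue=tissue,
                data=pd.DataFrame(
                    {
                        "time": timepoints,
                        "mean_conc": means,
                        "sd": sds,
                        "n": noise.n_subjects_per_timepoint,
                    }
                ),
            )
        )
    return datasets


def write_datasets(datasets: list[ObservedDataset], path: str | Path) -> None:
    """Write datasets as one tidy tab-separated table.

    Columns: study, species, tissue, time, mean_conc, sd, n.
    """
    frames = []
    for ds in datasets:
        frame = ds.data.copy()
        frame.insert(0, "tissue", ds.tissue)
        frame.insert(0, "species", ds.species_label)
        frame.insert(0, "study", ds.study_code)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_datasets(path: str | Path) -> list[ObservedDataset]:
    """Read a tidy table written by :func:`write_datasets` (or hand-prepared
    real data in the same format) back into per-tissue datasets."""
    table = pd.read_csv(path, sep="\t")
    required = {"study", "species", "tissue", "time", "mean_conc", "sd", "n"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"dataset file {path} is missing columns: {sorted(missing)}")
    datasets = []
    for (study, species, tissue), group in table.groupby(
        ["study", "species", "tissue"], sort=False
    ):
        datasets.append(
            ObservedDataset(
                study_code=study,
                species_label=species,
                tissue=tissue,
                data=group[["time", "mean_conc", "sd", "n"]]
                .sort_values("time")
                .reset_index(drop=True),
            )
        )
    return datasets
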