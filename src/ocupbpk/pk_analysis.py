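"""Summary PK metrics and model–observation comparison.

Cmax/Tmax are taken from the sampled grid, AUC by the linear trapezoid on
that grid (the convention in ocular PK reporting, where profiles are sparse
and destructive).  Optional AUC to infinity extrapolates with the terminal
log-linear slope.  Model adequacy is summarized by fold errors —
``max(sim/obs, obs/sim)`` per matched point — with the customary
"within k-fold" predicate (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ocular_model import SimulationResult
from .synthetic_data import ObservedDataset

__all__ = ["PKMetrics", "FoldErrorSummary", "compute_metrics", "fold_error"]


@dataclass(frozen=True)
class PKMetrics:
    tissue: str
    cmax: float  # µg/mL
    tmax: float  # h
    auc_0_t: float  # µg·h/mL
    auc_0_inf: float | None = None


@dataclass(frozen=True)
class FoldErrorSummary:
    per_point: np.ndarray
    geometric_mean: float
    maximum: float
    n_excluded_zero_obs: int

    def within(self, k: float) -> bool:
        """True if every matched point is within k-fold (inclusive)."""
        return bool(np.all(self.per_point <= k))


def _profile(source, tissue: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(source, SimulationResult):
        if tissue not in source.concentrations:
            raise KeyError(f"no concentration trajectory for tissue {tissue!r}")
        return source.time, source.concentrations[tissue]
    if isinstance(source, ObservedDataset):
        return (
            source.data["time"].to_numpy(float),
            source.data["mean_conc"].to_numpy(float),
        )
    raise TypeError(f"cannot extract a profile from {type(source).__name__}")


def compute_metrics(
    source: SimulationResult | ObservedDataset,
    tissue: str,
    extrapolate: bool = False,
) -> PKMetrics:
    """Cmax, Tmax and trapezoidal AUC for one tissue profile.

    ``extrapolate=True`` adds AUC(0→∞) using the slope of a log-linear
    regression through the last three positive concentrations; it is left
    ``None`` when the terminal phase is not declining.
    """
    t, c = _profile(source, tissue)
    if len(t) < 2:
        raise ValueError("at least two timepoints are required")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")

    i_max = int(np.argmax(c))
    auc = float(np.trapezoid(c, t))
    auc_inf = None
    if extrapolate:
        pos = c > 0
        if pos[-3:].all() and len(t) >= 3:
            slope = np.polyfit(t[-3:], np.log(c[-3:]), 1)[0]
            if slope < 0:
                auc_inf = auc + float(c[-1] / -slope)
    return PKMetrics(
        tissue=tissue,
        cmax=float(c[i_max]),
        tmax=float(t[i_max]),
        auc_0_t=auc,
        auc_0_inf=auc_inf,
    )


def fold_error(simulated, observed) -> FoldErrorSummary:
    """Per-point and summary fold errors between matched profiles.

    Accepts two equal-length concentration arrays, or two ``PKMetrics``
    (compared on Cmax and AUC).  Points with zero observed value are
    excluded and counted; the summary is the geometric mean and maximum of
    the per-point fold errors.  Symmetric in its arguments.
    """
    if isinstance(simulated, PKMetrics) and isinstance(observed, PKMetrics):
        sim = np.array([simulated.cmax, simulated.auc_0_t])
        obs = np.array([observed.cmax, observed.auc_0_t])
    else:
        sim = np.asarray(simulated, dtype=float)
        obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("simulated and observed must be matched (same shape)")

    nonzero = (obs != 0) & (sim != 0)
    n_excluded = int(np.sum(~nonzero))
    ratio = sim[nonzero] / obs[nonzero]
    per_point = np.maximum(ratio, 1.0 / ratio)
    if per_point.size == 0:
        return FoldErrorSummary(per_point, float("nan"), float("nan"), n_excluded)
    return FoldErrorSummary(
        per_point=per_point,
        geometric_mean=float(np.exp(np.mean(np.log(per_point)))),
        maximum=float(per_point.max()),
        n_excluded_zero_obs=n_excluded,
    )
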