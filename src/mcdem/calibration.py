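"""R^2 curve agreement and iterative calibration of contact parameters.

Agreement between a reference compression profile and a simulated one is
quantified by the coefficient of determination

    R^2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2,

with y the reference stress at each reference strain and yhat the
simulated stress linearly interpolated onto the reference strain grid
(loading leg only by default).  Calibration is a budgeted iterative
search over the free contact parameters -- a coarse grid followed by
golden-section refinement when a single parameter (typically the
multi-contact prefactor beta) is free -- terminated as soon as R^2
exceeds the 0.95 threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .contact_laws import ContactModelParams
from .core import StressStrainCurve

__all__ = [
    "ReferenceCurve",
    "CalibrationResult",
    "r_squared",
    "calibrate",
]

R2_THRESHOLD = 0.95


@dataclass
class ReferenceCurve:
    """Target stress-strain profile for calibration.

    ``provenance`` records whether the curve was digitised from
    experiment or generated synthetically by the simulator itself.
    """

    strain: np.ndarray
    stress: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must have equal length")
        if self.provenance not in ("experimental-digitized", "synthetic"):
            raise ValueError("provenance must be 'experimental-digitized' or 'synthetic'")


@dataclass
class CalibrationResult:
    best_params: ContactModelParams
    r2: float
    n_iterations: int
    history: list[tuple[ContactModelParams, float]]
    converged: bool


def r_squared(
    reference: ReferenceCurve,
    simulated: StressStrainCurve,
    loading_only: bool = True,
) -> float:
    """Coefficient of determination of a simulated curve vs a reference.

    The simulated stress is linearly interpolated onto the reference
    strain grid; reference points outside the simulated strain range are
    dropped with a warning.  Needs >= 3 usable points and a
    non-constant reference.
    """
    sim = simulated.loading_leg() if loading_only else simulated
    order = np.argsort(sim.strain, kind="stable")
    s_strain = sim.strain[order]
    s_stress = sim.axial_stress[order]
    mask = (reference.strain >= s_strain[0]) & (reference.strain <= s_strain[-1])
    if not np.all(mask):
        warnings.warn(
            f"{int(np.sum(~mask))} reference points outside the simulated "
            "strain range were dropped",
            stacklevel=2,
        )
    y = reference.stress[mask]
    x = reference.strain[mask]
    if y.size < 3:
        raise ValueError("need at least 3 overlapping points for R^2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference has zero variance; R^2 undefined")
    yhat = np.interp(x, s_strain, s_stress)
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


class _Budget(Exception):
    pass


class _Converged(Exception):
    pass


def calibrate(
    free_params: Mapping[str, tuple[float, float]],
    fixed: ContactModelParams,
    reference: ReferenceCurve,
    sim_runner: Callable[[ContactModelParams], StressStrainCurve],
    budget: int = 20,
    seed: int = 0,
    r2_threshold: float = R2_THRESHOLD,
    grid_points: int = 5,
) -> CalibrationResult:
    """Iterative parameter search terminated at R^2 > ``r2_threshold``.

    ``free_params`` maps ContactModelParams field names (e.g. ``beta``)
    to (low, high) bounds; remaining fields are taken from ``fixed``.
    Strategy: a coarse grid over the free parameters (evaluated in a
    seed-shuffled order so ties break reproducibly), then, for a single
    free parameter, golden-section refinement between the grid
    neighbours of the best point.  Evaluation stops as soon as the
    threshold is crossed or the budget is spent; a sub-threshold best is
    returned flagged ``converged=False`` rather than raised.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not free_params:
        raise ValueError("at least one free parameter is required")
    names = list(free_params)

    history: list[tuple[ContactModelParams, float]] = []
    state = {"evals": 0}

    def evaluate(values: Sequence[float]) -> float:
        if state["evals"] >= budget:
            raise _Budget
        params = replace(fixed, **dict(zip(names, values)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = r_squared(reference, sim_runner(params))
        state["evals"] += 1
        history.append((params, r2))
        if r2 > r2_threshold:
            raise _Converged
        return r2

    axes = []
    for name in names:
        lo, hi = free_params[name]
        if not hi > lo:
            raise ValueError(f"empty bounds for {name}")
        if lo > 0 and hi / lo > 30.0:
            axes.append(np.geomspace(lo, hi, grid_points))
        else:
            axes.append(np.linspace(lo, hi, grid_points))
    mesh = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
    rng = np.random.default_rng(seed)
    mesh = mesh[rng.permutation(mesh.shape[0])]

    converged = False
    try:
        for row in mesh:
            evaluate(row)
        if len(names) == 1:
            # golden-section refinement between the grid neighbours of the best
            grid = np.sort(np.unique([h[0].__getattribute__(names[0]) for h in history]))
            best_val = max(history, key=lambda h: h[1])[0].__getattribute__(names[0])
            k = int(np.searchsorted(grid, best_val))
            lo = grid[max(k - 1, 0)]
            hi = grid[min(k + 1, grid.size - 1)]
            invphi = (math.sqrt(5.0) - 1.0) / 2.0
            a, b = lo, hi
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
            fc = evaluate([c])
            fd = evaluate([d])
            while b - a > 1e-3 * max(hi - lo, 1e-30):
                if fc >= fd:
                    b, d, fd = d, c, fc
                    c = b - invphi * (b - a)
                    fc = evaluate([c])
                else:
                    a, c, fc = c, d, fd
                    d = a + invphi * (b - a)
                    fd = evaluate([d])
    except _Budget:
        pass
    except _Converged:
        converged = True

    best_params, best_r2 = max(history, key=lambda h: h[1])
    return CalibrationResult(
        best_params=best_params,
        r2=best_r2,
        n_iterations=state["evals"],
        history=history,
        converged=converged or best_r2 > r2_threshold,
    )
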