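"""Deterministic rigs and synthetic reference curves for testing/calibration.

The two-particle rig drives a contact law along a scripted overlap path
without any time integration, which makes force-displacement loops
(loading / unloading / reloading / adhesion) exactly reproducible; the
synthetic reference generator runs the full simulator at known
parameters to stand in for experimentally digitised compression
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ReferenceCurve
from .contact_laws import (
    ContactModelParams,
    ContactState,
    effective_properties,
    hertz_normal_force,
    hysteretic_normal_force,
    multicontact_normal_force,
)
from .core import LoadingProtocol, SimulationConfig, run_uniaxial
from .materials import MaterialParams, PSDFit, PSDSpec, fit_psd
from .packing import generate_packing

__all__ = ["ScriptedPath", "make_two_particle_rig", "make_synthetic_reference"]


@dataclass(frozen=True)
class ScriptedPath:
    """Piecewise-linear overlap program delta(t), starting at zero overlap."""

    times: np.ndarray
    overlaps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.overlaps, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "overlaps", d)
        if t.shape != d.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("times/overlaps must be equal-length 1-d arrays (>= 2 points)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if d[0] != 0.0:
            raise ValueError("path must start at zero overlap")
        if np.any(d < 0):
            raise ValueError("overlaps must be >= 0")

    @classmethod
    def from_waypoints(cls, waypoints, n_per_segment: int = 50) -> "ScriptedPath":
        """Densify (time, overlap) waypoints into a sampled path."""
        wp = np.asarray(waypoints, dtype=float)
        ts = [np.array([wp[0, 0]])]
        ds = [np.array([wp[0, 1]])]
        for (t0, d0), (t1, d1) in zip(wp[:-1], wp[1:]):
            s = np.linspace(0.0, 1.0, n_per_segment + 1)[1:]
            ts.append(t0 + s * (t1 - t0))
            ds.append(d0 + s * (d1 - d0))
        return cls(np.concatenate(ts), np.concatenate(ds))


def make_two_particle_rig(
    material: MaterialParams,
    radius: float,
    path: ScriptedPath,
    params: ContactModelParams | None = None,
    law: str = "hysteretic",
    contact_area_pressure=None,
) -> pd.DataFrame:
    """Evaluate a normal contact law along a scripted overlap path.

    Integration-free: the overlap sequence is imposed, the law is
    evaluated exactly, and the per-step branch is recorded.  ``law`` is
    one of ``hertz``, ``hysteretic``, ``multicontact``; the latter needs
    ``contact_area_pressure(overlap) -> (A, P)``.
    Returns a frame with columns time, overlap, force, branch.
    """
    params = params or ContactModelParams()
    pair = effective_properties(material, radius, material, radius, params)
    state = ContactState()
    forces = np.empty(path.times.size)
    branches = []
    for k, dn in enumerate(path.overlaps):
        if law == "hertz":
            forces[k] = hertz_normal_force(dn, 0.0, pair)
            branches.append("loading" if dn > 0 else "broken")
            continue
        if law == "multicontact":
            area, pres = contact_area_pressure(dn) if contact_area_pressure else (0.0, 0.0)
            forces[k], state = multicontact_normal_force(state, dn, pair, params, area, pres)
        elif law == "hysteretic":
            forces[k], state = hysteretic_normal_force(state, dn, pair, params)
        else:
            raise ValueError(f"unknown law {law!r}")
        branches.append(state.branch)
    return pd.DataFrame(
        {"time": path.times, "overlap": path.overlaps, "force": forces, "branch": branches}
    )


def make_synthetic_reference(
    base_params: ContactModelParams,
    beta_true: float,
    protocol: LoadingProtocol,
    seed: int,
    *,
    material: MaterialParams | None = None,
    psd: PSDSpec | PSDFit | None = None,
    box=(0.45e-3, 0.45e-3, 0.45e-3),
    target_fraction: float = 0.59,
    config: SimulationConfig | None = None,
    noise_sd: float = 0.0,
) -> ReferenceCurve:
    """Simulated compression profile with known generating parameters.

    Stands in for digitised experimental curves in calibration tests.
    Defaults to a half-scale coarse-MCC system in a (0.45 mm)^3 box.
    Optional multiplicative Gaussian noise of standard deviation
    ``noise_sd`` is applied to the stress.  Tagged ``synthetic``.
    """
    from dataclasses import replace

    from .materials import MCC_A, MCC_A_PSD

    material = material or MCC_A
    if psd is None:
        psd = fit_psd(MCC_A_PSD.x10 / 2, MCC_A_PSD.x50 / 2, MCC_A_PSD.x90 / 2)
    params = replace(base_params, beta=beta_true)
    packing = generate_packing(np.asarray(box, dtype=float), psd, target_fraction,
                               material, seed=seed)
    result = run_uniaxial(packing, params, protocol, config)
    leg = result.curve.loading_leg()
    stress = leg.axial_stress.copy()
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed + 1)
        stress = stress * (1.0 + noise_sd * rng.standard_normal(stress.size))
    return ReferenceCurve(strain=leg.strain.copy(), stress=stress, provenance="synthetic")
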