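"""Time integration, neighbour search and the uniaxial compaction protocol.

The integrator is velocity-Verlet for translations with an explicit
Euler update for angular velocities (spheres need no orientation state
beyond the rolling torque).  Quasi-static loading is enforced by
Cundall-style local (force-proportional, hence size- and
rate-intensive) background damping on top of the restitution-matched
contact dashpots; the kinetic/elastic energy ratio is logged with every
curve sample so quasi-staticity can be audited after the fact.

Compaction is strain-driven: the top plate moves down at constant speed
until the target engineering strain (referenced to the post-relaxation
bed height) or an optional stress stop is reached, then optionally
reverses at the same speed until the plate unloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .contact_laws import ContactModelParams, effective_properties
from .materials import MaterialParams, STEEL_WALL
from .packing import Packing, packing_fraction

__all__ = [
    "SimulationConfig",
    "LoadingProtocol",
    "StressStrainCurve",
    "CompactionResult",
    "Simulation",
    "SimulationUnstableError",
    "critical_time_step",
    "run_uniaxial",
    "relative_density",
]


class SimulationUnstableError(RuntimeError):
    """Raised when the integration produces non-finite state or runaway overlaps."""


@dataclass(frozen=True)
class LoadingProtocol:
    """Displacement-controlled uniaxial loading along z.

    ``max_strain`` is the engineering strain target; ``max_stress`` (Pa)
    is an optional stop condition on the measured plate stress.  The
    plate speed follows either from ``plate_speed`` (m/s) or from a step
    budget ``n_steps`` for the loading leg (speed = displacement /
    (n_steps * dt)); more steps means closer to the quasi-static limit.
    """

    max_strain: float
    max_stress: float | None = None
    plate_speed: float | None = None
    n_steps: int | None = None
    decompress: bool = True
    axis: str = "z"

    def __post_init__(self) -> None:
        if not 0.0 < self.max_strain < 1.0:
            raise ValueError("max_strain must lie in (0, 1)")
        if self.axis != "z":
            raise ValueError("only z-axis loading is supported")


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical knobs of the DEM engine.

    ``time_step`` overrides the automatic Rayleigh-type estimate, which
    linearises the stiffest contact (the k2 unloading branch of the
    smallest particle) at an overlap of ``dt_overlap_fraction`` of the
    smallest radius and applies ``dt_safety``.  ``local_damping`` is the
    Cundall force-proportional damping coefficient (dimensionless,
    default 0.2); ``viscous_damping`` adds an optional mass-proportional
    drag c*dt (used by fixtures, off by default because it is not
    size-intensive).  ``mass_scaling`` multiplies all dynamic masses
    (the time step grows with its square root).  Gravity is off by
    default: a sub-millimetre RVE loaded to tens of MPa is insensitive
    to it.
    """

    time_step: float | None = None
    dt_safety: float = 0.2
    dt_overlap_fraction: float = 0.5
    viscous_damping: float = 0.0
    local_damping: float = 0.2
    contact_damping: bool = True
    gravity: float = 0.0
    mass_scaling: float = 1.0
    snapshot_interval: int = 200
    skin_fraction: float = 0.5
    max_overlap_fraction: float = 4.0
    seed: int = 0


@dataclass
class StressStrainCurve:
    """Axial engineering strain vs axial stress, plus audit channels."""

    strain: np.ndarray
    axial_stress: np.ndarray
    relative_density: np.ndarray
    kinetic_energy: np.ndarray | None = None
    elastic_energy: np.ndarray | None = None
    n_contacts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.axial_stress = np.asarray(self.axial_stress, dtype=float)
        self.relative_density = np.asarray(self.relative_density, dtype=float)
        if self.strain.shape != self.axial_stress.shape or (
            self.strain.shape != self.relative_density.shape
        ):
            raise ValueError("curve arrays must have equal length")

    def loading_leg(self) -> "StressStrainCurve":
        """Portion up to the maximum strain (compression leg)."""
        k = int(np.argmax(self.strain)) + 1
        return StressStrainCurve(
            self.strain[:k],
            self.axial_stress[:k],
            self.relative_density[:k],
            None if self.kinetic_energy is None else self.kinetic_energy[:k],
            None if self.elastic_energy is None else self.elastic_energy[:k],
            None if self.n_contacts is None else self.n_contacts[:k],
        )

    def stress_at(self, strain: float) -> float:
        """Loading-leg stress interpolated at a given strain."""
        leg = self.loading_leg()
        return float(np.interp(strain, leg.strain, leg.axial_stress))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "strain": self.strain,
            "stress_Pa": self.axial_stress,
            "relative_density": self.relative_density,
        }
        if self.kinetic_energy is not None:
            data["kinetic_energy"] = self.kinetic_energy
        if self.elastic_energy is not None:
            data["elastic_energy"] = self.elastic_energy
        if self.n_contacts is not None:
            data["n_contacts"] = self.n_contacts
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StressStrainCurve":
        df = pd.read_csv(path)
        return cls(
            strain=df["strain"].to_numpy(),
            axial_stress=df["stress_Pa"].to_numpy(),
            relative_density=df.get(
                "relative_density", pd.Series(np.zeros(len(df)))
            ).to_numpy(),
            kinetic_energy=df["kinetic_energy"].to_numpy() if "kinetic_energy" in df else None,
            elastic_energy=df["elastic_energy"].to_numpy() if "elastic_energy" in df else None,
            n_contacts=df["n_contacts"].to_numpy() if "n_contacts" in df else None,
        )


@dataclass
class CompactionResult:
    """Output of :func:`run_uniaxial`."""

    curve: StressStrainCurve
    packing: Packing
    contact_history: dict
    diagnostics: dict


def critical_time_step(
    packing: Packing,
    material: MaterialParams | None = None,
    params: ContactModelParams | None = None,
    overlap_fraction: float = 0.01,
    safety: float = 0.2,
    mass_scaling: float = 1.0,
) -> float:
    """Rayleigh-type stable time step estimate.

    Uses the smallest particle mass against the stiffest linearised
    contact: the unloading branch k2 (worst case) of a contact with the
    wall, linearised at ``overlap_fraction`` of the smallest radius,
    k_lin = 1.5 * k2 * sqrt(delta_ref); dt = safety * sqrt(m_min/k_lin).
    """
    if packing.n == 0:
        raise ValueError("empty packing has no time step")
    material = material or packing.material
    params = params or ContactModelParams(k2_over_k1=1.0, kc_over_k1=0.0)
    r_min = float(packing.radii.min())
    m_min = mass_scaling * material.density * 4.0 / 3.0 * math.pi * r_min**3
    pair_pw = effective_properties(material, r_min, STEEL_WALL)
    pair_pp = effective_properties(material, r_min, material, r_min)
    e43 = (4.0 / 3.0) * max(pair_pw.effective_young, pair_pp.effective_young)
    k1 = e43 * math.sqrt(r_min)
    k_lin = 1.5 * params.k2_over_k1 * k1 * math.sqrt(overlap_fraction * r_min)
    return safety * math.sqrt(m_min / k_lin)


class Simulation:
    """Mutable DEM state for one packing plus force/integration machinery.

    Not a public construction path for most users -- `run_uniaxial` and
    `generate_packing` drive it -- but exposed for rigs and tests.
    """

    def __init__(
        self,
        packing: Packing,
        contact_params: ContactModelParams,
        config: SimulationConfig | None = None,
        material: MaterialParams | None = None,
    ):
        self.config = config or SimulationConfig()
        self.params = contact_params
        self.material = material or packing.material
        self.box = packing.box.copy()
        self.plate_bottom = float(packing.plate_bottom)
        self.plate_top = float(packing.plate_top)
        self.plate_velocity = 0.0

        self.positions = packing.positions.copy()
        self.velocities = packing.velocities.copy()
        self.ang_velocities = packing.ang_velocities.copy()

        mat = self.material
        pp = effective_properties(mat, 1.0, mat, 1.0)
        pw = effective_properties(mat, 1.0, STEEL_WALL)
        self._e43_pp = (4.0 / 3.0) * pp.effective_young
        self._g_pp = pp.effective_shear
        self._e43_pw = (4.0 / 3.0) * pw.effective_young
        self._g_pw = pw.effective_shear
        self._zeta_pp = _restitution_to_zeta(mat.restitution_pp)
        self._zeta_pw = _restitution_to_zeta(mat.restitution_pw)

        n = packing.n
        self._forces = np.zeros((n, 3))
        self._torques = np.zeros((n, 3))
        self._accel = np.zeros((n, 3))
        self.stress = np.zeros((n, 6))
        self._trace_prev = np.zeros(n)
        self.wall_dmax = np.zeros((n, 2))
        self.wall_tspr = np.zeros((n, 2, 3))
        self._pair_keys = np.empty(0, np.int64)
        self._pairs_i = np.empty(0, np.int64)
        self._pairs_j = np.empty(0, np.int64)
        self._dmax = np.empty(0)
        self._tspr = np.empty((0, 3))
        self._disp = np.zeros((n, 3))
        self._pair_cap = max(64, 40 * n)
        self.time = 0.0
        self.n_steps_done = 0

        self.set_radii(packing.radii.copy())

    # -- geometry/state helpers -------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.radii.size)

    @property
    def gap(self) -> float:
        return self.plate_top - self.plate_bottom

    def set_radii(self, radii: np.ndarray) -> None:
        """Replace radii (packing growth); masses, dt and lists follow."""
        self.radii = np.asarray(radii, dtype=float)
        vol = 4.0 / 3.0 * np.pi * self.radii**3
        self.masses = self.config.mass_scaling * self.material.density * vol
        self.inertia = 0.4 * self.masses * self.radii**2
        with np.errstate(divide="ignore"):
            self.inv_vol = 1.0 / vol
        if self.n == 0:
            self._skin = 0.0
            self._cell = 1.0
            self.dt = self.config.time_step or 1e-8
            return
        self._skin = self.config.skin_fraction * float(self.radii.min())
        self._cell = 2.0 * float(self.radii.max()) + self._skin
        if self.config.time_step is not None:
            self.dt = self.config.time_step
        else:
            r_min = float(self.radii.min())
            m_min = float(self.masses.min())
            e43 = max(self._e43_pp, self._e43_pw)
            k_lin = (
                1.5
                * self.params.k2_over_k1
                * e43
                * math.sqrt(r_min)
                * math.sqrt(self.config.dt_overlap_fraction * r_min)
            )
            self.dt = self.config.dt_safety * math.sqrt(m_min / k_lin)
        self._rebuild()

    def reset_velocities(self) -> None:
        self.velocities[:] = 0.0
        self.ang_velocities[:] = 0.0
        self._accel[:] = 0.0

    def kinetic_energy(self) -> float:
        ke_t = 0.5 * float(np.sum(self.masses * np.sum(self.velocities**2, axis=1)))
        ke_r = 0.5 * float(np.sum(self.inertia * np.sum(self.ang_velocities**2, axis=1)))
        return ke_t + ke_r

    def contact_state(self) -> dict:
        """Snapshot of the per-pair history (for persistence/inspection)."""
        return {
            "pairs": np.stack([self._pairs_i, self._pairs_j], axis=1).copy(),
            "max_overlap": self._dmax.copy(),
            "tangential_spring": self._tspr.copy(),
            "wall_max_overlap": self.wall_dmax.copy(),
            "wall_tangential_spring": self.wall_tspr.copy(),
        }

    def as_packing(self) -> Packing:
        return Packing(
            box=self.box.copy(),
            radii=self.radii.copy(),
            positions=self.positions.copy(),
            material=self.material,
            plate_bottom=self.plate_bottom,
            plate_top=self.plate_top,
            velocities=self.velocities.copy(),
            ang_velocities=self.ang_velocities.copy(),
        )

    # -- neighbour list ---------------------------------------------------------

    def _rebuild(self) -> None:
        n = self.n
        while True:
            out_i = np.empty(self._pair_cap, np.int64)
            out_j = np.empty(self._pair_cap, np.int64)
            cnt = _kernels.build_pairs(
                self.positions,
                self.radii,
                float(self.box[0]),
                float(self.box[1]),
                self.plate_bottom,
                self.plate_top,
                self._cell,
                self._skin,
                out_i,
                out_j,
            )
            if cnt >= 0:
                break
            self._pair_cap *= 2
        new_i = out_i[:cnt]
        new_j = out_j[:cnt]
        new_keys = new_i * n + new_j
        order = np.argsort(new_keys, kind="stable")
        new_keys = new_keys[order]
        new_i = new_i[order]
        new_j = new_j[order]
        new_dmax = np.zeros(cnt)
        new_tspr = np.zeros((cnt, 3))
        if self._pair_keys.size:
            idx = np.searchsorted(self._pair_keys, new_keys)
            idx[idx >= self._pair_keys.size] = 0
            hit = self._pair_keys[idx] == new_keys
            new_dmax[hit] = self._dmax[idx[hit]]
            new_tspr[hit] = self._tspr[idx[hit]]
        self._pair_keys = new_keys
        self._pairs_i = np.ascontiguousarray(new_i)
        self._pairs_j = np.ascontiguousarray(new_j)
        self._dmax = new_dmax
        self._tspr = new_tspr
        self._disp[:] = 0.0

    # -- integration ------------------------------------------------------------

    def advance(self, n_steps: int) -> dict:
        """Velocity-Verlet integration of ``n_steps`` steps.

        Returns chunk diagnostics: plate forces averaged over the chunk,
        final kinetic/elastic energies, contact count, overlap measures.
        """
        dt = self.dt
        half_dt2 = 0.5 * dt * dt
        half_dt = 0.5 * dt
        skin_half2 = (0.5 * self._skin) ** 2
        Lx = float(self.box[0])
        Ly = float(self.box[1])
        top_sum = 0.0
        bot_sum = 0.0
        ee = 0.0
        ncon = 0
        max_ofrac = 0.0
        sum_ov = 0.0
        p = self.params
        cfg = self.config

        if self.n == 0:
            self.plate_top += self.plate_velocity * dt * n_steps
            self.time += dt * n_steps
            self.n_steps_done += n_steps
            return {
                "top_force": 0.0,
                "bottom_force": 0.0,
                "elastic_energy": 0.0,
                "kinetic_energy": 0.0,
                "n_contacts": 0,
                "max_overlap_fraction": 0.0,
                "mean_overlap": 0.0,
            }

        for _ in range(n_steps):
            step_disp = self.velocities * dt + self._accel * half_dt2
            self.positions += step_disp
            self._disp += step_disp
            self.positions[:, 0] %= Lx
            self.positions[:, 1] %= Ly
            self.plate_top += self.plate_velocity * dt

            if np.max(np.einsum("ij,ij->i", self._disp, self._disp)) > skin_half2:
                self._rebuild()

            v_half = self.velocities + half_dt * self._accel
            self._forces[:] = 0.0
            self._torques[:] = 0.0
            self.stress[:] = 0.0
            ee, top_fz, bot_fz, ncon, mof, sum_ov = _kernels.compute_forces(
                self.positions,
                v_half,
                self.ang_velocities,
                self.radii,
                self.masses,
                self.inv_vol,
                self._pairs_i,
                self._pairs_j,
                self._dmax,
                self._tspr,
                self.wall_dmax,
                self.wall_tspr,
                self._trace_prev,
                Lx,
                Ly,
                self.plate_bottom,
                self.plate_top,
                self.plate_velocity,
                self._e43_pp,
                self._g_pp,
                self._zeta_pp,
                self.material.sliding_friction_pp,
                self.material.rolling_friction_pp,
                self._e43_pw,
                self._g_pw,
                self._zeta_pw,
                self.material.sliding_friction_pw,
                self.material.rolling_friction_pw,
                p.k2_over_k1,
                p.kc_over_k1,
                p.plasticity_depth,
                p.beta,
                p.pull_off_force,
                self.material.poisson_ratio,
                dt,
                cfg.viscous_damping,
                cfg.local_damping,
                cfg.gravity,
                cfg.contact_damping,
                self._forces,
                self._torques,
                self.stress,
            )
            self._accel = self._forces / self.masses[:, None]
            self.velocities = v_half + half_dt * self._accel
            self.ang_velocities += dt * self._torques / self.inertia[:, None]
            np.add(
                np.add(self.stress[:, 0], self.stress[:, 1]),
                self.stress[:, 2],
                out=self._trace_prev,
            )
            top_sum += top_fz
            bot_sum += bot_fz
            if mof > max_ofrac:
                max_ofrac = mof
            self.time += dt
            self.n_steps_done += 1

        if not math.isfinite(top_sum + bot_sum) or not np.all(
            np.isfinite(self.positions)
        ):
            raise SimulationUnstableError("non-finite state encountered")
        if max_ofrac > self.config.max_overlap_fraction:
            raise SimulationUnstableError(
                f"overlap reached {max_ofrac:.3f} of the smaller radius "
                f"(limit {self.config.max_overlap_fraction})"
            )
        return {
            "top_force": top_sum / max(n_steps, 1),
            "bottom_force": bot_sum / max(n_steps, 1),
            "elastic_energy": ee,
            "kinetic_energy": self.kinetic_energy(),
            "n_contacts": int(ncon),
            "max_overlap_fraction": max_ofrac,
            "mean_overlap": (sum_ov / ncon) if ncon else 0.0,
        }


def _restitution_to_zeta(e: float) -> float:
    """Damping ratio reproducing restitution e for a Hertzian contact."""
    if e >= 1.0:
        return 0.0
    ln_e = math.log(e)
    return -ln_e / math.sqrt(ln_e * ln_e + math.pi**2)


def relative_density(strain: float, packing: Packing) -> float:
    """Relative density at an engineering strain, from the initial fraction.

    phi(strain) = phi0 / (1 - strain): solid volume conserved while the
    bed height shrinks (rigid-particle bound; overlap volume is not
    corrected).
    """
    return packing_fraction(packing) / (1.0 - strain)


def run_uniaxial(
    packing: Packing,
    contact_params: ContactModelParams,
    protocol: LoadingProtocol,
    config: SimulationConfig | None = None,
    material: MaterialParams | None = None,
) -> CompactionResult:
    """Strain-driven uniaxial compaction (and optional decompression).

    The top plate moves down at constant speed; axial stress is the
    chunk-averaged top-plate normal force divided by the lateral area,
    engineering strain is the plate displacement over the initial gap.
    The curve is sampled every ``config.snapshot_interval`` steps.
    """
    config = config or SimulationConfig()
    sim = Simulation(packing, contact_params, config, material=material)
    gap0 = sim.gap
    if gap0 <= 0:
        raise ValueError("plate gap must be positive")
    area = float(sim.box[0] * sim.box[1])
    solid_vol = float(np.sum(4.0 / 3.0 * np.pi * sim.radii**3))
    phi0 = solid_vol / (area * gap0)

    target_disp = protocol.max_strain * gap0
    if protocol.plate_speed is not None:
        speed = float(protocol.plate_speed)
    else:
        n_steps = protocol.n_steps or 60000
        speed = target_disp / (n_steps * sim.dt)
    sim.plate_velocity = -speed

    interval = config.snapshot_interval
    rec: dict[str, list] = {k: [] for k in
                            ("strain", "stress", "rd", "ke", "ee", "nc")}

    def sample(diag: dict) -> tuple[float, float]:
        strain = (gap0 - sim.gap) / gap0
        stress_val = diag["top_force"] / area
        rec["strain"].append(strain)
        rec["stress"].append(stress_val)
        rec["rd"].append(solid_vol / (area * sim.gap))
        rec["ke"].append(diag["kinetic_energy"])
        rec["ee"].append(diag["elastic_energy"])
        rec["nc"].append(diag["n_contacts"])
        return strain, stress_val

    max_chunks = int(2e7 / max(interval, 1))
    peak_stress = 0.0
    for _ in range(max_chunks):
        # do not overshoot the strain target within a chunk
        steps_left = int(math.ceil((target_disp - (gap0 - sim.gap)) / (speed * sim.dt)))
        diag = sim.advance(min(interval, max(steps_left, 1)))
        strain, stress_val = sample(diag)
        peak_stress = max(peak_stress, stress_val)
        if strain >= protocol.max_strain - 1e-12:
            break
        if protocol.max_stress is not None and stress_val >= protocol.max_stress:
            break

    if protocol.decompress:
        sim.plate_velocity = +speed
        for _ in range(max_chunks):
            diag = sim.advance(interval)
            strain, stress_val = sample(diag)
            if stress_val <= max(1e-3 * peak_stress, 0.0) or sim.gap >= gap0:
                break
    sim.plate_velocity = 0.0

    curve = StressStrainCurve(
        strain=np.array(rec["strain"]),
        axial_stress=np.array(rec["stress"]),
        relative_density=np.array(rec["rd"]),
        kinetic_energy=np.array(rec["ke"]),
        elastic_energy=np.array(rec["ee"]),
        n_contacts=np.array(rec["nc"], dtype=int),
    )
    ke = curve.kinetic_energy
    ee = curve.elastic_energy
    mask = (ee > 0) & (curve.axial_stress > 0.01 * max(peak_stress, 1e-30))
    ratio = float(np.max(ke[mask] / ee[mask])) if np.any(mask) else math.inf
    diagnostics = {
        "plate_speed": speed,
        "time_step": sim.dt,
        "mass_scaling": config.mass_scaling,
        "n_steps": sim.n_steps_done,
        "initial_fraction": phi0,
        "peak_stress": peak_stress,
        "max_ke_over_ee": ratio,
    }
    return CompactionResult(
        curve=curve,
        packing=sim.as_packing(),
        contact_history=sim.contact_state(),
        diagnostics=diagnostics,
    )
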