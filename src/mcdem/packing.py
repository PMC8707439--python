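"""Particle packings and the growth-based packing generator.

The representative volume element (RVE) is a laterally periodic box with
rigid top/bottom plates.  Packings are generated by seeding particles at
reduced radii at random positions, inflating all radii by a common
factor in stages while relaxing overlaps with frictionless, strongly
damped dynamics, and terminating growth when the target solid fraction
is reached, followed by a final relaxation to a quasi-stress-free state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .materials import MaterialParams, PSDFit, PSDSpec, _as_fit, sample_radii

__all__ = [
    "Particle",
    "Packing",
    "PackingGenerationError",
    "packing_fraction",
    "generate_packing",
    "save_snapshot",
    "load_snapshot",
]


def _seed_positions(
    rng: np.random.Generator, radii: np.ndarray, box: np.ndarray, max_tries: int = 80
) -> np.ndarray:
    """Random sequential placement, largest first, rejecting overlaps.

    At the reduced seeding fraction (<~0.15) rejection succeeds easily;
    if a particle exhausts its tries the least-overlapping candidate is
    accepted (relaxation dynamics removes the residual).
    """
    n = radii.size
    order = np.argsort(radii)[::-1]
    pos = np.zeros((n, 3))
    placed: list[int] = []
    lx, ly, lz = box
    for i in order:
        r = radii[i]
        best = None
        best_pen = np.inf
        for _ in range(max_tries):
            cand = np.array(
                [rng.uniform(0, lx), rng.uniform(0, ly), rng.uniform(r, lz - r)]
            )
            if placed:
                d = pos[placed] - cand
                d[:, 0] -= lx * np.round(d[:, 0] / lx)
                d[:, 1] -= ly * np.round(d[:, 1] / ly)
                gap = np.sqrt(np.einsum("ij,ij->i", d, d)) - (radii[placed] + r)
                pen = -float(gap.min())
            else:
                pen = -1.0
            if pen <= 0.0:
                best = cand
                break
            if pen < best_pen:
                best_pen = pen
                best = cand
        pos[i] = best
        placed.append(i)
    return pos


class PackingGenerationError(RuntimeError):
    """Growth/relaxation failed; carries the achieved solid fraction."""

    def __init__(self, message: str, achieved_fraction: float):
        super().__init__(f"{message} (achieved fraction {achieved_fraction:.4f})")
        self.achieved_fraction = achieved_fraction


@dataclass(frozen=True)
class Particle:
    """One spherical particle; mass and inertia follow from radius and density."""

    id: int
    radius: float
    position: np.ndarray
    velocity: np.ndarray
    angular_velocity: np.ndarray
    mass: float
    moment_of_inertia: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class Packing:
    """Particles in a laterally periodic box with top/bottom plates.

    ``box`` holds (Lx, Ly, Lz); plates are horizontal at
    ``plate_bottom``/``plate_top``.  Particle centres obey the periodic
    wrap in x and y and sit between the plates.
    """

    box: np.ndarray
    radii: np.ndarray
    positions: np.ndarray
    material: MaterialParams
    plate_bottom: float = 0.0
    plate_top: float | None = None
    velocities: np.ndarray | None = None
    ang_velocities: np.ndarray | None = None
    periodic_xy: tuple[bool, bool] = (True, True)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.plate_top is None:
            self.plate_top = float(self.box[2])
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        if self.ang_velocities is None:
            self.ang_velocities = np.zeros_like(self.positions)

    @property
    def n(self) -> int:
        return int(self.radii.size)

    @property
    def masses(self) -> np.ndarray:
        return self.material.density * 4.0 / 3.0 * np.pi * self.radii**3

    @property
    def solid_volume(self) -> float:
        return float(np.sum(4.0 / 3.0 * np.pi * self.radii**3))

    def particles(self) -> Iterator[Particle]:
        m = self.masses
        for i in range(self.n):
            yield Particle(
                id=i,
                radius=float(self.radii[i]),
                position=self.positions[i].copy(),
                velocity=self.velocities[i].copy(),
                angular_velocity=self.ang_velocities[i].copy(),
                mass=float(m[i]),
                moment_of_inertia=float(0.4 * m[i] * self.radii[i] ** 2),
            )

    def copy(self) -> "Packing":
        return Packing(
            box=self.box.copy(),
            radii=self.radii.copy(),
            positions=self.positions.copy(),
            material=self.material,
            plate_bottom=self.plate_bottom,
            plate_top=self.plate_top,
            velocities=self.velocities.copy(),
            ang_velocities=self.ang_velocities.copy(),
            periodic_xy=self.periodic_xy,
        )


def packing_fraction(p: Packing) -> float:
    """Solid fraction: total sphere volume over Lx * Ly * plate gap.

    Overlap volumes are not subtracted (relaxed packings have mean
    overlaps below 1e-3 of a radius, the standard DEM convention).
    """
    gap = p.plate_top - p.plate_bottom
    if gap <= 0:
        raise ValueError("plate gap must be positive")
    return p.solid_volume / (p.box[0] * p.box[1] * gap)


def generate_packing(
    box,
    psd: PSDSpec | PSDFit,
    target_fraction: float,
    material: MaterialParams,
    seed: int,
    *,
    initial_fraction: float = 0.15,
    growth_stages: int = 35,
    relax_steps: int = 24,
    max_relax_steps: int = 4000,
    overlap_tol: float = 1e-3,
    return_history: bool = False,
):
    """Grow a random packing to ``target_fraction`` inside ``box``.

    Radii are sampled from the PSD with a volume stop rule (then scaled
    by one common factor, typically <1% in radius, so the final solid
    fraction is exact); samples are clipped to
    [x10/2, min(1.2*x90, 0.45*box_edge)] to bound contact stiffness and
    respect the periodic minimum-image convention.  After seeding,
    radii are inflated in multiplicative stages with interleaved
    overlap-relaxation sweeps (friction plays no role in the overdamped
    limit these sweeps represent), then relaxed to a quasi-stress-free
    state.  Deterministic for a fixed seed.  Raises
    :class:`PackingGenerationError` if the final relaxation cannot reach
    a mean overlap below ``overlap_tol`` of the mean radius.
    """
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be a positive 3-vector (Lx, Ly, Lz)")
    if not 0.0 < target_fraction < 0.64:
        raise ValueError(
            "target_fraction must lie in (0, 0.64); higher values exceed "
            "random close packing for spheres"
        )
    fit = _as_fit(psd)
    if isinstance(psd, PSDSpec):
        default_lower, default_upper = psd.x10 / 2.0, 1.2 * psd.x90
    else:
        default_lower = float(fit.quantile(0.1)) / 2.0
        default_upper = 1.2 * float(fit.quantile(0.9))
    lower = fit.lower_cut if fit.lower_cut is not None else default_lower
    upper = fit.upper_cut if fit.upper_cut is not None else default_upper
    upper = min(upper, 0.45 * float(np.min(box)))
    if fit.log_sd == 0.0:
        lower = min(lower, fit.median)
        if fit.median > 0.5 * float(np.min(box)):
            raise ValueError("monodisperse particle diameter exceeds half the box edge")
        upper = max(upper, fit.median)
    if upper <= lower:
        raise ValueError("PSD truncation window is empty; box too small for this PSD")
    fit = replace(fit, lower_cut=lower, upper_cut=upper)

    rng = np.random.default_rng(seed)
    target_volume = target_fraction * float(np.prod(box))
    radii = sample_radii(fit, rng, target_volume=target_volume)
    if 2.0 * radii.max() > 0.5 * min(box[0], box[1]):
        raise ValueError("largest sampled diameter exceeds half the lateral box edge")

    # non-overlapping random seeding at reduced radii; plates flush with box faces
    s0 = min((min(initial_fraction, 0.8 * target_fraction) / target_fraction) ** (1.0 / 3.0), 0.95)
    pos = _seed_positions(rng, s0 * radii, box)

    relaxer = _OverlapRelaxer(pos, box)
    history = [target_fraction * s0**3]
    for s in np.geomspace(s0, 1.0, growth_stages + 1)[1:]:
        relaxer.sweep(s * radii, relax_steps)
        history.append(target_fraction * s**3)

    # final relaxation to a quasi-stress-free state
    mean_radius = float(radii.mean())
    mean_overlap = relaxer.relax_to(
        radii, overlap_tol * mean_radius, max_relax_steps
    )
    if mean_overlap >= overlap_tol * mean_radius:
        raise PackingGenerationError(
            f"relaxation did not reach overlap tolerance {overlap_tol:g} "
            f"within {max_relax_steps} sweeps",
            achieved_fraction=target_fraction,
        )

    out = Packing(
        box=box,
        radii=radii,
        positions=pos,
        material=material,
        plate_bottom=0.0,
        plate_top=float(box[2]),
    )
    if return_history:
        return out, history
    return out


class _OverlapRelaxer:
    """Gauss-Seidel overlap projection with a periodically rebuilt pair list."""

    REBUILD_EVERY = 8

    def __init__(self, pos: np.ndarray, box: np.ndarray, relax: float = 1.2):
        from . import _kernels

        self._k = _kernels
        self.pos = pos
        self.box = box
        self.relax = relax
        self._cap = max(64, 40 * pos.shape[0])

    def _pairs(self, radii: np.ndarray, skin: float):
        cell = 2.0 * float(radii.max()) + skin
        while True:
            out_i = np.empty(self._cap, np.int64)
            out_j = np.empty(self._cap, np.int64)
            cnt = self._k.build_pairs(
                self.pos,
                radii,
                float(self.box[0]),
                float(self.box[1]),
                0.0,
                float(self.box[2]),
                cell,
                skin,
                out_i,
                out_j,
            )
            if cnt >= 0:
                return out_i[:cnt], out_j[:cnt]
            self._cap *= 2

    def sweep(self, radii: np.ndarray, n_sweeps: int) -> tuple[float, int]:
        """Run ``n_sweeps`` projection sweeps at the given radii."""
        skin = 0.3 * float(radii.min())
        sum_ov, ncon = 0.0, 0
        for k in range(n_sweeps):
            if k % self.REBUILD_EVERY == 0:
                pi, pj = self._pairs(radii, skin)
            sum_ov, ncon, _ = self._k.project_overlaps(
                self.pos,
                radii,
                float(self.box[0]),
                float(self.box[1]),
                0.0,
                float(self.box[2]),
                pi,
                pj,
                self.relax,
            )
        return sum_ov, ncon

    def relax_to(self, radii: np.ndarray, tol_abs: float, max_sweeps: int) -> float:
        """Sweep until the mean overlap drops below ``tol_abs`` metres.

        The over-relaxation factor cycles through a short deterministic
        schedule so near-crystalline configurations cannot trap the
        Gauss-Seidel iteration in a limit cycle.
        """
        skin = 0.3 * float(radii.min())
        schedule = (self.relax, 0.85, 1.45)
        for k in range(max_sweeps):
            if k % self.REBUILD_EVERY == 0:
                pi, pj = self._pairs(radii, skin)
            sum_ov, ncon, _ = self._k.project_overlaps(
                self.pos,
                radii,
                float(self.box[0]),
                float(self.box[1]),
                0.0,
                float(self.box[2]),
                pi,
                pj,
                schedule[(k // 600) % 3],
            )
            if ncon == 0 or sum_ov / ncon < tol_abs:
                # measure after the final moves
                pi, pj = self._pairs(radii, skin)
                sum_ov, ncon, _ = self._k.project_overlaps(
                    self.pos, radii, float(self.box[0]), float(self.box[1]),
                    0.0, float(self.box[2]), pi, pj, 0.0,
                )
                if ncon == 0 or sum_ov / ncon < tol_abs:
                    return 0.0 if ncon == 0 else sum_ov / ncon
        return math.inf


# --- columnar text snapshots (round-trip lossless at full float precision) ---


def save_snapshot(packing: Packing, path: str | Path) -> None:
    """Write a packing as columnar text: id radius x y z (+ box/plate header)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# mcdem packing snapshot\n")
        fh.write("# box %.17g %.17g %.17g\n" % tuple(packing.box))
        fh.write("# plates %.17g %.17g\n" % (packing.plate_bottom, packing.plate_top))
        fh.write(f"# material {packing.material.name or 'unnamed'}\n")
        fh.write("# columns id radius x y z\n")
        for i in range(packing.n):
            fh.write(
                "%d %.17g %.17g %.17g %.17g\n"
                % (i, packing.radii[i], *packing.positions[i])
            )


def load_snapshot(path: str | Path, material: MaterialParams) -> Packing:
    """Read a snapshot written by :func:`save_snapshot`."""
    path = Path(path)
    box = plates = None
    rows = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("# box"):
                box = np.array([float(v) for v in line.split()[2:5]])
            elif line.startswith("# plates"):
                plates = [float(v) for v in line.split()[2:4]]
            elif line.startswith("#") or not line.strip():
                continue
            else:
                rows.append([float(v) for v in line.split()])
    if box is None or plates is None:
        raise ValueError(f"{path} is not a valid packing snapshot")
    data = np.asarray(rows)
    order = np.argsort(data[:, 0])
    data = data[order]
    return Packing(
        box=box,
        radii=data[:, 1].copy(),
        positions=data[:, 2:5].copy(),
        material=material,
        plate_bottom=plates[0],
        plate_top=plates[1],
    )
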