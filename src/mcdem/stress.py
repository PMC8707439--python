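"""Per-particle average stress tensors and the multi-contact pair pressure.

The estimator is the standard Love-Weber dyadic sum over the contacts of
a particle, sigma_i = -(1/V_i) sum_c sym(l_c (x) F_c), with l_c the
vector from the particle centre to the contact point and F_c the total
force exerted *on* the particle at that contact.  The leading minus sign
makes compressive states positive, so that under compaction the pair
pressure P_ij is positive and the multi-contact correction
beta*nu*A_ij*P_ij is repulsive (stiffening), as required for confined
compression.

P_ij = (1/3) (tr sigma_i + tr sigma_j) -- the sum (not the mean) of the
two particle pressures, exactly as the model prints it; any factor-2
convention change is absorbed by the calibrated prefactor beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .contact_laws import PairProperties

__all__ = [
    "ParticleStress",
    "particle_stress",
    "contact_area",
    "pair_pressure",
    "save_stress_dump",
]


@dataclass(frozen=True)
class ParticleStress:
    """Symmetric 3x3 average stress of one particle (Pa), compression positive."""

    tensor: np.ndarray
    particle_volume: float

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3):
            raise ValueError("stress tensor must be 3x3")
        if not np.all(np.isfinite(t)):
            raise ValueError("stress tensor entries must be finite")

    @property
    def trace(self) -> float:
        return float(np.trace(self.tensor))

    @property
    def pressure(self) -> float:
        """Mean (isotropic) stress, tr(sigma)/3."""
        return self.trace / 3.0


def particle_stress(
    particle,
    contacts: Iterable[tuple[Sequence[float], Sequence[float]]],
) -> ParticleStress:
    """Love-Weber stress of one particle from its contact list.

    ``particle`` needs ``radius`` (a :class:`~mcdem.packing.Particle`
    works); ``contacts`` yields ``(branch_vector, force)`` pairs, both
    3-vectors in the same frame: the branch vector points from the
    particle centre to the contact point, the force is the total force
    acting on the particle there.
    """
    radius = float(particle.radius)
    volume = 4.0 / 3.0 * np.pi * radius**3
    if volume <= 0.0:
        raise ValueError("particle volume must be positive")
    sigma = np.zeros((3, 3))
    for branch, force in contacts:
        l = np.asarray(branch, dtype=float)
        f = np.asarray(force, dtype=float)
        dyad = np.outer(l, f)
        sigma -= 0.5 * (dyad + dyad.T)
    sigma /= volume
    return ParticleStress(tensor=sigma, particle_volume=volume)


def contact_area(dn: float, pair: PairProperties) -> float:
    """Hertzian contact area A = pi a^2 with a^2 = R* dn, i.e. A = pi R* dn."""
    if dn <= 0.0:
        return 0.0
    return np.pi * pair.effective_radius * dn


def pair_pressure(s_i: ParticleStress, s_j: ParticleStress) -> float:
    """P_ij = (1/3)(tr sigma_i + tr sigma_j), compression positive."""
    return (s_i.trace + s_j.trace) / 3.0


def save_stress_dump(path, stress6: np.ndarray) -> None:
    """Write per-particle stress as columnar text.

    ``stress6`` is an (n, 6) array in Voigt-like order
    (xx, yy, zz, xy, xz, yz), e.g. ``Simulation.stress``.  Columns:
    id sxx syy szz sxy sxz syz pressure (Pa, compression positive).
    """
    s = np.asarray(stress6, dtype=float)
    if s.ndim != 2 or s.shape[1] != 6:
        raise ValueError("expected an (n, 6) stress array")
    with open(path, "w") as fh:
        fh.write("# columns: id sxx syy szz sxy sxz syz pressure\n")
        for i, row in enumerate(s):
            p = (row[0] + row[1] + row[2]) / 3.0
            fh.write(("%d" + " %.17g" * 7 + "\n") % (i, *row, p))
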