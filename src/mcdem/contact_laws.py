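"""Force-displacement laws for sphere-sphere and sphere-wall contacts.

Two normal laws are provided:

* the non-linear elastic Hertz law, ``F = kn * dn**1.5`` with
  ``kn = (4/3) E* sqrt(R*)``, plus an optional viscous dashpot; and
* a non-linear hysteretic adhesive elastic-plastic law with three
  branches -- virgin loading on ``k1``, unloading/reloading on a
  history-dependent stiffness ``k2*``, and an adhesive branch on ``kc``:

  ::

      F = F0 + k1 dn^{3/2}               if  k2*(dn^{3/2} - d0^{3/2}) >= k1 dn^{3/2}
      F = F0 + k2*(dn^{3/2} - d0^{3/2})  intermediate
      F = F0 - kc dn^{3/2}               if -kc dn^{3/2} >= k2*(dn^{3/2} - d0^{3/2})

  where the plastic (residual) overlap ``d0 = (1 - k1/k2*)^{2/3} dmax``
  depends on the largest overlap ``dmax`` ever reached by the contact,
  and ``k2*`` interpolates linearly in ``dmax`` between ``k1`` at zero
  and ``k2`` beyond the plastic-flow limit
  ``dmax* = k2/(k2 - k1) * phi_f * 2 R*``.

  Setting ``k1 = k2`` (and ``kc = 0``, ``F0 = 0``) collapses the law to
  the elastic Hertz model; ``k2 -> inf`` is the perfectly plastic limit.

The multi-contact variant adds ``beta * nu * A_ij * P_ij`` to every
branch, coupling the pair to the mean pressure of the two particles'
stress tensors (see :mod:`mcdem.stress`).

These scalar/vector functions are the reference implementation; the
vectorised numba kernels in :mod:`mcdem._kernels` are tested against
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import MaterialParams

__all__ = [
    "PairProperties",
    "ContactModelParams",
    "ContactState",
    "effective_properties",
    "hertz_normal_force",
    "plastic_overlap",
    "unloading_stiffness",
    "hysteretic_normal_force",
    "tangential_force",
    "rolling_torque",
    "multicontact_normal_force",
    "MCC_A_CONTACT",
    "MCC_P_CONTACT",
    "HERTZIAN",
]


@dataclass(frozen=True)
class ContactModelParams:
    """Dimensionless knobs of the hysteretic multi-contact law.

    ``k2_over_k1`` >= 1 sets the plastic dissipation (1 = elastic),
    ``kc_over_k1`` >= 0 the adhesion branch, ``plasticity_depth`` (phi_f,
    in (0, 1]) the overlap scale at which the unloading stiffness
    saturates, ``beta`` the multi-contact prefactor (0 disables the
    correction) and ``pull_off_force`` the constant adhesive offset F0
    in newtons (default 0).
    """

    k2_over_k1: float = 120.0
    kc_over_k1: float = 0.5
    plasticity_depth: float = 0.99
    beta: float = 0.0
    pull_off_force: float = 0.0

    def __post_init__(self) -> None:
        if self.k2_over_k1 < 1.0:
            raise ValueError("k2_over_k1 must be >= 1")
        if self.kc_over_k1 < 0.0:
            raise ValueError("kc_over_k1 must be >= 0")
        if not 0.0 < self.plasticity_depth <= 1.0:
            raise ValueError("plasticity_depth must lie in (0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")


#: Calibrated parameter sets for the two MCC grades.
MCC_A_CONTACT = ContactModelParams(beta=1.3)
MCC_P_CONTACT = ContactModelParams(beta=1.5)
#: Pure Hertz-Mindlin limit of the hysteretic law.
HERTZIAN = ContactModelParams(k2_over_k1=1.0, kc_over_k1=0.0, beta=0.0)


@dataclass(frozen=True)
class PairProperties:
    """Pre-combined properties of one contacting pair.

    ``k1`` is the virgin-loading stiffness (4/3) E* sqrt(R*) in
    N m^-3/2; ``k2 = k2_over_k1 * k1`` and ``kc = kc_over_k1 * k1``.
    ``normal_damping``/``tangential_damping`` are plain viscous
    coefficients gamma (N s/m) for the dashpot terms; the simulator
    derives its own restitution-matched dashpots and leaves these at 0
    here.  ``rolling_radius`` defaults to the effective radius R*.
    """

    effective_radius: float
    effective_young: float
    effective_shear: float
    k1: float
    k2: float
    kc: float
    normal_damping: float = 0.0
    tangential_damping: float = 0.0
    sliding_friction: float = 0.0
    rolling_friction: float = 0.0
    rolling_radius: float = 0.0
    poisson_mean: float = 0.0

    def __post_init__(self) -> None:
        if min(self.effective_radius, self.effective_young, self.effective_shear) <= 0:
            raise ValueError("R*, E*, G* must be positive")
        if not self.k2 >= self.k1 > 0:
            raise ValueError("need k2 >= k1 > 0")
        if self.kc < 0:
            raise ValueError("kc must be >= 0")

    @property
    def tangential_stiffness(self) -> float:
        """kt = 8 G* sqrt(R*)."""
        return 8.0 * self.effective_shear * math.sqrt(self.effective_radius)


@dataclass
class ContactState:
    """History carried by one contact between steps.

    ``max_overlap`` is the largest normal overlap the contact has seen
    (non-decreasing while the contact persists); ``tangential_spring``
    is the accumulated Mindlin spring displacement.  Both are reset when
    the contact is lost.
    """

    i: int = 0
    j: int = 1
    normal_overlap: float = 0.0
    max_overlap: float = 0.0
    tangential_spring: np.ndarray = field(default_factory=lambda: np.zeros(3))
    branch: str = "broken"

    def copy(self) -> "ContactState":
        return ContactState(
            self.i,
            self.j,
            self.normal_overlap,
            self.max_overlap,
            self.tangential_spring.copy(),
            self.branch,
        )


def effective_properties(
    mat_i: MaterialParams,
    r_i: float,
    mat_j: MaterialParams,
    r_j: float = math.inf,
    params: ContactModelParams | None = None,
) -> PairProperties:
    """Combine two bodies into pair properties.

    1/E* = (1-nu_i^2)/E_i + (1-nu_j^2)/E_j,
    1/G* = (2-nu_i)/G_i + (2-nu_j)/G_j with G = E/(2(1+nu)), and
    R* = R_i R_j / (R_i + R_j).  A wall is a body of infinite radius
    (R* = R_i); pass the wall material (e.g. ``STEEL_WALL``) as
    ``mat_j``, in which case the particle material's ``_pw`` friction
    and restitution apply.
    """
    if r_i <= 0 or r_j <= 0:
        raise ValueError("radii must be positive")
    inv_E = (1.0 - mat_i.poisson_ratio**2) / mat_i.young_modulus + (
        1.0 - mat_j.poisson_ratio**2
    ) / mat_j.young_modulus
    inv_G = (2.0 - mat_i.poisson_ratio) / mat_i.shear_modulus + (
        2.0 - mat_j.poisson_ratio
    ) / mat_j.shear_modulus
    e_star = 1.0 / inv_E
    g_star = 1.0 / inv_G
    r_star = r_i if math.isinf(r_j) else r_i * r_j / (r_i + r_j)

    wall = mat_i.is_wall or mat_j.is_wall
    part = mat_j if mat_i.is_wall else mat_i
    mu = part.sliding_friction_pw if wall else part.sliding_friction_pp
    mur = part.rolling_friction_pw if wall else part.rolling_friction_pp

    p = params or ContactModelParams(k2_over_k1=1.0, kc_over_k1=0.0)
    k1 = (4.0 / 3.0) * e_star * math.sqrt(r_star)
    return PairProperties(
        effective_radius=r_star,
        effective_young=e_star,
        effective_shear=g_star,
        k1=k1,
        k2=p.k2_over_k1 * k1,
        kc=p.kc_over_k1 * k1,
        sliding_friction=mu,
        rolling_friction=mur,
        rolling_radius=r_star,
        poisson_mean=0.5 * (mat_i.poisson_ratio + mat_j.poisson_ratio),
    )


def hertz_normal_force(dn: float, dn_rate: float, pair: PairProperties) -> float:
    """Elastic Hertz normal force F = kn dn^{3/2} + gamma_n dn_rate.

    Negative overlap means no contact (zero force); the dashpot term is
    clipped so the total force never turns attractive.
    """
    if dn <= 0.0:
        return 0.0
    f = pair.k1 * dn**1.5 + pair.normal_damping * dn_rate
    return max(f, 0.0)


def plastic_overlap(dmax: float, k1: float, k2_star: float) -> float:
    """Residual (plastic) overlap d0 = (1 - k1/k2*)^{2/3} dmax."""
    if k2_star < k1:
        raise ValueError("k2_star must be >= k1")
    return (1.0 - k1 / k2_star) ** (2.0 / 3.0) * dmax


def unloading_stiffness(
    dmax: float, pair: PairProperties, params: ContactModelParams
) -> float:
    """History-dependent unloading stiffness k2*(dmax).

    Interpolates linearly between k1 at dmax = 0 and k2 at the
    plastic-flow limit dmax* = k2/(k2-k1) * phi_f * 2 R*, beyond which
    it saturates at k2.
    """
    if dmax < 0:
        raise ValueError("dmax must be >= 0")
    k1, k2 = pair.k1, pair.k2
    if k2 == k1:
        if params.plasticity_depth <= 0:
            raise ValueError("invalid parameters: k2 == k1 with phi_f <= 0")
        return k1
    dmax_star = k2 / (k2 - k1) * params.plasticity_depth * 2.0 * pair.effective_radius
    if dmax >= dmax_star:
        return k2
    return k1 + (k2 - k1) * dmax / dmax_star


def _hysteretic_branches(dn: float, dmax: float, pair: PairProperties,
                         params: ContactModelParams) -> tuple[float, str]:
    """Elastic part of the hysteretic force (without F0) and branch name."""
    k2s = unloading_stiffness(dmax, pair, params)
    d0 = plastic_overlap(dmax, pair.k1, k2s)
    p15 = dn**1.5
    t_load = pair.k1 * p15
    t_unload = k2s * (p15 - d0**1.5)
    t_adh = -pair.kc * p15
    # the virgin branch wins at equality; the tolerance absorbs round-off
    # in the two algebraically-equal expressions at dn == dmax
    tie = 1e-12 * (abs(t_load) + abs(t_unload))
    if t_unload >= t_load - tie:
        return t_load, "loading"
    if t_adh >= t_unload:
        return t_adh, "adhesive"
    return t_unload, "unload_reload"


def hysteretic_normal_force(
    state: ContactState,
    dn: float,
    pair: PairProperties,
    params: ContactModelParams,
) -> tuple[float, ContactState]:
    """Hysteretic adhesive elastic-plastic normal force.

    Updates ``state.max_overlap`` to max(dmax, dn), recomputes d0 and
    k2* from it, and selects the branch; the force is continuous in dn
    along any load/unload/reload path.  At exact branch equality the
    virgin branch wins.  Contact loss (dn <= 0) resets the history.
    """
    new = state.copy()
    if dn <= 0.0:
        new.normal_overlap = 0.0
        new.max_overlap = 0.0
        new.tangential_spring[:] = 0.0
        new.branch = "broken"
        return 0.0, new
    new.normal_overlap = dn
    new.max_overlap = max(state.max_overlap, dn)
    f_el, branch = _hysteretic_branches(dn, new.max_overlap, pair, params)
    new.branch = branch
    return params.pull_off_force + f_el, new


def multicontact_normal_force(
    state: ContactState,
    dn: float,
    pair: PairProperties,
    params: ContactModelParams,
    contact_area: float,
    pair_pressure: float,
) -> tuple[float, ContactState]:
    """Hysteretic force plus the multi-contact correction beta*nu*A*P.

    ``contact_area`` is the Hertzian contact area A_ij (m^2) and
    ``pair_pressure`` the stress-tensor pressure P_ij (Pa, compression
    positive).  With beta = 0 this is exactly the hysteretic law.
    """
    if contact_area < 0:
        raise ValueError("contact area must be >= 0")
    f, new = hysteretic_normal_force(state, dn, pair, params)
    if new.branch == "broken":
        return f, new
    return f + params.beta * pair.poisson_mean * contact_area * pair_pressure, new


def tangential_force(
    state: ContactState,
    v_t: np.ndarray,
    dt: float,
    fn: float,
    pair: PairProperties,
) -> tuple[np.ndarray, ContactState]:
    """Mindlin-style tangential spring force with a Coulomb cap.

    The spring accumulates the tangential surface velocity,
    ``dt_spring += v_t * dt``; the elastic force magnitude is
    kt |spring|^{3/2} plus a viscous term, capped at mu |Fn| with the
    spring rescaled onto the cap (sliding).  A non-compressive contact
    (fn <= 0) resets the spring and transmits nothing.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = state.copy()
    if fn <= 0.0:
        new.tangential_spring[:] = 0.0
        return np.zeros(3), new
    spring = new.tangential_spring + np.asarray(v_t, dtype=float) * dt
    kt = pair.tangential_stiffness
    mag = float(np.linalg.norm(spring))
    if mag == 0.0:
        new.tangential_spring = spring
        return -pair.tangential_damping * np.asarray(v_t, dtype=float), new
    f_el = kt * mag**1.5
    f_cap = pair.sliding_friction * fn
    sliding = f_el >= f_cap
    if sliding:
        spring = spring * ((f_cap / kt) ** (2.0 / 3.0) / mag)
        force = -f_cap * spring / np.linalg.norm(spring) if f_cap > 0 else np.zeros(3)
    else:
        force = -kt * math.sqrt(mag) * spring - pair.tangential_damping * np.asarray(v_t)
        fmag = float(np.linalg.norm(force))
        if fmag > f_cap > 0:
            force *= f_cap / fmag
    new.tangential_spring = spring
    return force, new


def rolling_torque(
    omega_rel: np.ndarray, fn: float, pair: PairProperties
) -> np.ndarray:
    """Constant directional torque (CDT) rolling resistance.

    tau = -omega_rel/|omega_rel| * mu_r * R_r * |Fn|; zero for zero
    relative rotation (no division by zero) or zero normal force.
    """
    w = np.asarray(omega_rel, dtype=float)
    norm = float(np.linalg.norm(w))
    if norm == 0.0 or fn == 0.0:
        return np.zeros(3)
    return -w / norm * pair.rolling_friction * pair.rolling_radius * abs(fn)
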