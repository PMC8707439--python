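"""Material parameters and particle size distributions.

All quantities are SI (metres, kilograms, pascals).  Particle size
distributions are described by their cumulative *volume* (Q3) quantiles
``x10 < x50 < x90`` (diameters), the form in which laser-diffraction data
for pharmaceutical powders is normally reported.  A two-parameter
volume-weighted log-normal is fitted to the quantiles; radii are sampled
from the corresponding number-weighted distribution so that the volume
statistics of a large sample reproduce the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MaterialParams",
    "PSDSpec",
    "PSDFit",
    "fit_psd",
    "sample_radii",
    "MCC_A",
    "MCC_P",
    "MCC_A_PSD",
    "MCC_P_PSD",
    "STEEL_WALL",
]

#: 90% quantile of the standard normal, used to convert x90/x10 to a log-sd.
Z90 = 1.2815515655446004


class InvalidPSDError(ValueError):
    """Raised when PSD quantiles are not strictly increasing."""


@dataclass(frozen=True)
class MaterialParams:
    """Single-particle and particle-wall DEM input parameters.

    ``young_modulus`` is the calibrated particle Young's modulus (Pa),
    not the crystal value: for plastically deforming excipients it is an
    effective contact-scale stiffness.  Restitution and friction come in
    particle-particle (``_pp``) and particle-wall (``_pw``) flavours.
    """

    young_modulus: float
    poisson_ratio: float
    density: float
    restitution_pp: float
    restitution_pw: float
    sliding_friction_pp: float
    sliding_friction_pw: float
    rolling_friction_pp: float
    rolling_friction_pw: float
    name: str = ""
    is_wall: bool = False

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise ValueError("young_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if not self.density > 0:
            raise ValueError("density must be positive")
        for attr in ("restitution_pp", "restitution_pw"):
            e = getattr(self, attr)
            if not 0.0 < e <= 1.0:
                raise ValueError(f"{attr} must lie in (0, 1]")
        for attr in (
            "sliding_friction_pp",
            "sliding_friction_pw",
            "rolling_friction_pp",
            "rolling_friction_pw",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")

    @property
    def shear_modulus(self) -> float:
        """G = E / (2 (1 + nu))."""
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))

    def frictionless(self) -> "MaterialParams":
        """Copy with all friction coefficients set to zero (packing growth)."""
        return replace(
            self,
            sliding_friction_pp=0.0,
            sliding_friction_pw=0.0,
            rolling_friction_pp=0.0,
            rolling_friction_pw=0.0,
        )


@dataclass(frozen=True)
class PSDSpec:
    """Volume-quantile description of a particle size distribution.

    ``x10``, ``x50``, ``x90`` are Q3 (cumulative volume) diameters in
    metres.  Optional ``lower_cut``/``upper_cut`` truncate sampling.
    """

    x10: float
    x50: float
    x90: float
    lower_cut: float | None = None
    upper_cut: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.x10 < self.x50 < self.x90):
            raise InvalidPSDError(
                f"PSD quantiles must satisfy 0 < x10 < x50 < x90, got "
                f"({self.x10}, {self.x50}, {self.x90})"
            )

    @property
    def span(self) -> float:
        return (self.x90 - self.x10) / self.x50


@dataclass(frozen=True)
class PSDFit:
    """Fitted volume-weighted log-normal: diameter quantile(q) = median * exp(sigma * z_q).

    ``median`` is the volume-weighted median diameter (m); ``log_sd`` the
    shape parameter sigma.  Radii are *sampled* from the number-weighted
    companion LN(ln median - 3 sigma^2, sigma) so that volume-weighting a
    large sample recovers this distribution.
    """

    median: float
    log_sd: float
    lower_cut: float | None = None
    upper_cut: float | None = None

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise InvalidPSDError("median diameter must be positive")
        if self.log_sd < 0:
            raise InvalidPSDError("log_sd must be >= 0")

    def quantile(self, q: float | np.ndarray) -> float | np.ndarray:
        """Volume-weighted diameter quantile of the (untruncated) fit."""
        from scipy.stats import norm

        return self.median * np.exp(self.log_sd * norm.ppf(q))

    @property
    def number_median(self) -> float:
        """Median of the number-weighted diameter distribution."""
        return self.median * math.exp(-3.0 * self.log_sd**2)


def fit_psd(
    x10: float,
    x50: float,
    x90: float,
    lower_cut: float | None = None,
    upper_cut: float | None = None,
) -> PSDFit:
    """Fit a volume-weighted log-normal to the three Q3 quantiles.

    A 2-parameter log-normal cannot match three quantiles exactly; the
    median is pinned at ``x50`` and the shape parameter is the
    least-squares compromise over the two log-symmetric quantile ratios,
    sigma = ln(x90/x10) / (2 z90).  Degenerate equal quantiles yield a
    monodisperse (zero log-sd) distribution.

    Parameters are diameters in metres.
    """
    if x10 == x50 == x90 and x10 > 0:
        return PSDFit(median=float(x50), log_sd=0.0, lower_cut=lower_cut, upper_cut=upper_cut)
    if not (0 < x10 < x50 < x90):
        raise InvalidPSDError(
            f"PSD quantiles must satisfy 0 < x10 < x50 < x90, got ({x10}, {x50}, {x90})"
        )
    log_sd = math.log(x90 / x10) / (2.0 * Z90)
    return PSDFit(median=float(x50), log_sd=log_sd, lower_cut=lower_cut, upper_cut=upper_cut)


def _as_fit(psd: "PSDSpec | PSDFit") -> PSDFit:
    if isinstance(psd, PSDFit):
        return psd
    return fit_psd(psd.x10, psd.x50, psd.x90, psd.lower_cut, psd.upper_cut)


def sample_radii(
    psd: "PSDSpec | PSDFit",
    seed: "int | np.random.Generator",
    n: int | None = None,
    target_volume: float | None = None,
    match_volume: bool = True,
) -> np.ndarray:
    """Sample particle radii (m) from the fitted PSD.

    Exactly one stop rule must be given: a particle count ``n`` or a
    ``target_volume`` (m^3) which the summed sphere volumes should reach.
    Sampling is number-weighted from the companion distribution of the
    volume-weighted fit, so large samples reproduce the Q3 quantiles.
    With ``target_volume`` and ``match_volume=True`` all radii are scaled
    by a single factor (typically <1% in radius) so the total volume hits
    the target exactly.  Deterministic for a fixed integer seed.
    """
    fit = _as_fit(psd)
    if (n is None) == (target_volume is None):
        raise ValueError("give exactly one of n or target_volume")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mu_n = math.log(fit.median) - 3.0 * fit.log_sd**2
    lo = fit.lower_cut
    hi = fit.upper_cut

    def draw(k: int) -> np.ndarray:
        if fit.log_sd == 0.0:
            d = np.full(k, fit.median)
        else:
            d = np.exp(rng.normal(mu_n, fit.log_sd, size=k))
        if lo is not None:
            d = d[d >= lo]
        if hi is not None:
            d = d[d <= hi]
        return d

    if n is not None:
        out = np.empty(0)
        while out.size < n:
            out = np.concatenate([out, draw(max(64, n - out.size + 16))])
        return out[:n] / 2.0

    # target-volume stop rule
    diams = np.empty(0)
    cumvol = 0.0
    while cumvol < target_volume:
        chunk = draw(256)
        if chunk.size == 0:
            continue
        diams = np.concatenate([diams, chunk])
        cumvol = float(np.sum(np.pi / 6.0 * diams**3))
    vols = np.pi / 6.0 * diams**3
    cut = int(np.searchsorted(np.cumsum(vols), target_volume)) + 1
    diams = diams[:cut]
    if match_volume:
        total = float(np.sum(np.pi / 6.0 * diams**3))
        diams = diams * (target_volume / total) ** (1.0 / 3.0)
    return diams / 2.0


# --- Presets: microcrystalline cellulose grades and the die-wall steel ---

#: Avicel PH 200 (coarse MCC grade)
MCC_A = MaterialParams(
    young_modulus=2.58e8,
    poisson_ratio=0.30,
    density=1541.1,
    restitution_pp=0.352,
    restitution_pw=0.352,
    sliding_friction_pp=0.561,
    sliding_friction_pw=0.707,
    rolling_friction_pp=0.3,
    rolling_friction_pw=0.01,
    name="MCC-A",
)

#: Pharmacel 102 (fine MCC grade)
MCC_P = MaterialParams(
    young_modulus=1.34e9,
    poisson_ratio=0.30,
    density=1533.7,
    restitution_pp=0.346,
    restitution_pw=0.346,
    sliding_friction_pp=0.548,
    sliding_friction_pw=0.715,
    rolling_friction_pp=0.3,
    rolling_friction_pw=0.01,
    name="MCC-P",
)

#: Punch/die material seen by particle-wall contacts.
STEEL_WALL = MaterialParams(
    young_modulus=7.62e10,
    poisson_ratio=0.31,
    density=7850.0,
    restitution_pp=0.9,
    restitution_pw=0.9,
    sliding_friction_pp=0.0,
    sliding_friction_pw=0.0,
    rolling_friction_pp=0.0,
    rolling_friction_pw=0.0,
    name="steel-wall",
    is_wall=True,
)

MCC_A_PSD = PSDSpec(x10=82.9e-6, x50=224.6e-6, x90=379.3e-6)
MCC_P_PSD = PSDSpec(x10=28.3e-6, x50=86.5e-6, x90=173.8e-6)
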