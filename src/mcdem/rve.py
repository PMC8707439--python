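"""Representative-volume-element size series and convergence analysis.

A packing is regenerated per box size (same PSD, same target fraction)
and compressed under an identical protocol; curves are compared with the
same R^2 machinery used for calibration.  The smallest box large enough
that its response agrees with the next size at R^2 >= 0.95 is declared
representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import R2_THRESHOLD, ReferenceCurve, r_squared
from .contact_laws import ContactModelParams
from .core import LoadingProtocol, SimulationConfig, StressStrainCurve, run_uniaxial
from .materials import MaterialParams, PSDFit, PSDSpec
from .packing import generate_packing

__all__ = ["RVESeriesResult", "run_rve_series"]


@dataclass
class RVESeriesResult:
    """Per-size curves plus the pairwise R^2 agreement matrix.

    ``pairwise_r2[i, j]`` treats curve i as the reference and scores
    curve j against it (NaN where a member run failed).  The last column
    is the deviation-from-largest-box metric.
    """

    sizes: list[float]
    curves: list[StressStrainCurve | None]
    pairwise_r2: np.ndarray
    failures: list[str | None]

    def representative_size(self, threshold: float = R2_THRESHOLD) -> float | None:
        """Smallest size whose curve matches the next size at >= threshold."""
        for k in range(len(self.sizes) - 1):
            if self.pairwise_r2[k + 1, k] >= threshold:
                return self.sizes[k]
        return None


def _member_seed(seed: int, size: float) -> int:
    # identical (seed, size) pairs must give identical members
    return int((seed * 2654435761 + int(round(size * 1e9))) % (2**31 - 1))


def run_rve_series(
    sizes,
    psd: PSDSpec | PSDFit,
    material: MaterialParams,
    params: ContactModelParams,
    protocol: LoadingProtocol,
    seed: int = 0,
    target_fraction: float = 0.59,
    config: SimulationConfig | None = None,
) -> RVESeriesResult:
    """Compact one regenerated packing per cubic box size.

    ``sizes`` are strictly increasing box edge lengths (m).  Unstable
    members are recorded in ``failures`` and skipped in the matrix
    rather than aborting the series.
    """
    sizes = [float(s) for s in sizes]
    if len(sizes) < 2:
        raise ValueError("need at least 2 sizes")
    if not all(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be non-decreasing")

    curves: list[StressStrainCurve | None] = []
    failures: list[str | None] = []
    for size in sizes:
        try:
            pk = generate_packing(
                (size, size, size),
                psd,
                target_fraction,
                material,
                seed=_member_seed(seed, size),
            )
            res = run_uniaxial(pk, params, protocol, config)
            curves.append(res.curve)
            failures.append(None)
        except Exception as exc:  # member failure -> partial result
            curves.append(None)
            failures.append(f"{type(exc).__name__}: {exc}")

    n = len(sizes)
    mat = np.full((n, n), np.nan)
    for i, ci in enumerate(curves):
        if ci is None:
            continue
        leg = ci.loading_leg()
        ref = ReferenceCurve(leg.strain, leg.axial_stress, provenance="synthetic")
        for j, cj in enumerate(curves):
            if cj is None:
                continue
            if i == j:
                mat[i, j] = 1.0
            else:
                mat[i, j] = r_squared(ref, cj)
    return RVESeriesResult(sizes=sizes, curves=curves, pairwise_r2=mat, failures=failures)
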