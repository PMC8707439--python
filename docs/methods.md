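# Methods

`mcdem` simulates confined uniaxial compression (die compaction) of a
powder at the particle scale with a soft-sphere discrete element method
whose normal contact law is (a) hysteretic, adhesive and elastic-plastic
and (b) coupled to the stress state generated by *all* contacts on the
two touching particles. The second ingredient — the multi-contact
correction — is what distinguishes the model from conventional DEM: at
relative densities above ~0.7 the pores are nearly closed, contacts stop
being independent, and a packing of plastically deforming particles
stiffens geometrically. The package reproduces that regime for two
microcrystalline cellulose (MCC) grades, a coarse one (MCC‑A, Avicel
PH 200‑like) and a fine one (MCC‑P, Pharmacel 102‑like).

## Contact model

Normal direction. Between first touch and the largest overlap ever
reached, a contact loads along the *virgin* branch

    F = F0 + k1 δ^{3/2},       k1 = (4/3) E* sqrt(R*),

i.e. Hertzian in form, with the particle Young's modulus entering
through the usual effective modulus `1/E* = (1−ν_i²)/E_i + (1−ν_j²)/E_j`
and `R* = R_i R_j/(R_i+R_j)`. Unloading and reloading follow a stiffer
branch

    F = F0 + k2*(δ^{3/2} − δ0^{3/2}),

whose stiffness `k2*` interpolates linearly in the contact's maximum
overlap `δ_max` between `k1` (at zero) and `k2` beyond the plastic-flow
limit `δ*_max = k2/(k2−k1) · φ_f · 2R*`; the residual (plastic) overlap
is `δ0 = (1 − k1/k2*)^{2/3} δ_max`. Unloading further enters an adhesive
branch `F = F0 − k_c δ^{3/2}`. Setting `k2 = k1`, `k_c = 0`, `F0 = 0`
recovers the non-linear elastic Hertz–Mindlin model exactly; `k2 → ∞`
is the perfectly plastic limit. The branch boundaries follow from the
force law itself: the unload/adhesive switch sits at
`δ_min = ((k2*−k1)/(k2*+k_c))^{2/3} δ_max` (the intersection of the two
branch expressions — note the *plus* sign in the denominator, which a
brute-force sweep of the branches confirms). At exact branch equality
the virgin branch wins; a 1e‑12 relative tolerance absorbs round-off
between the two algebraically identical expressions at `δ = δ_max`.

Multi-contact coupling. Every particle carries a Love–Weber average
stress tensor, `σ_i = −(1/V_i) Σ_c sym(l_c ⊗ F_c)` (compression
positive), accumulated from all of its contacts including walls. Each
particle–particle normal force is augmented by

    ΔF = β ν A_ij P_ij,   A_ij = π R* δ,   P_ij = (tr σ_i + tr σ_j)/3,

with `ν` the (pair-mean) Poisson ratio and `β` a dimensionless,
material-dependent prefactor (`β = 0` switches the effect off). `P_ij`
is the *sum* of the two particle pressures as the model defines it; any
factor-two convention change is absorbed by the calibrated `β`. The
correction uses the stress of the previous time step (explicit lagging,
O(dt) error) to avoid a force–stress fixed point each step, and is
applied to particle–particle contacts only — walls carry no stress
tensor. Compression-positive sign matters: under compaction `P_ij > 0`
and the correction is repulsive, i.e. the bed stiffens, which is the
experimentally observed direction.

Tangential/rotation. A Mindlin-type spring `F_t = k_t |ξ|^{3/2}` with
`k_t = 8 G* sqrt(R*)` accumulates the tangential surface velocity, is
rotated into the current tangent plane, and is capped by Coulomb
friction `μ|F_n|` (spring rescaled onto the cap when sliding; static and
dynamic friction equal). Rolling resistance is the constant directional
torque `τ = −ω̂_rel μ_r R_r |F_n|` with `R_r = R*` (the model leaves the
rolling radius unspecified; the effective radius is the conventional
choice).

Dissipation. Restitution-matched Hertzian dashpots act in both contact
directions (`γ ∝ ζ sqrt(S m*)`, `ζ` from the coefficient of
restitution); a two-particle impact reproduces the tabulated COR 0.352
to better than 1%. The dashpots are excluded from all analytic-law unit
tests.

## Default parameters

| parameter | symbol | MCC‑A | MCC‑P | units |
|---|---|---|---|---|
| particle Young's modulus | E | 2.58e8 | 1.34e9 | Pa |
| wall Young's modulus | E_w | 7.62e10 | 7.62e10 | Pa |
| Poisson ratio (particle/wall) | ν | 0.30/0.31 | 0.30/0.31 | – |
| density | ρ | 1541.1 | 1533.7 | kg m⁻³ |
| restitution (pp = pw) | e | 0.352 | 0.346 | – |
| sliding friction pp / pw | μ_s | 0.561/0.707 | 0.548/0.715 | – |
| rolling friction pp / pw | μ_r | 0.3/0.01 | 0.3/0.01 | – |
| PSD volume quantiles x10/x50/x90 | – | 82.9/224.6/379.3 | 28.3/86.5/173.8 | µm |
| stiffness ratio | k2/k1 | 120 | 120 | – |
| adhesion ratio | k_c/k1 | 0.5 | 0.5 | – |
| plasticity depth | φ_f | 0.99 | 0.99 | – |
| multi-contact prefactor | β | 1.3 | 1.5 | – |
| pull-off force | F0 | 0 | 0 | N |

`F0` defaults to zero because no value is tabulated for these powders;
it remains a config knob.

## Particle size distribution and packing generation

Laser-diffraction PSDs come as three cumulative-volume (Q3) diameters
`x10 < x50 < x90`. A two-parameter volume-weighted log-normal cannot
match three quantiles; the median is pinned at `x50` and
`σ = ln(x90/x10)/(2 z_{0.9})` is the least-squares compromise of the two
log-ratio constraints. Radii are drawn from the number-weighted
companion distribution `LN(ln x50 − 3σ², σ)` so that volume-weighting a
large sample reproduces the fitted quantiles; because the upper volume
quantiles rest on very few large particles, fidelity checks need ≥10⁵
samples. For packing, draws are clipped to
`[x10/2, min(1.2·x90, 0.45·box edge)]` — the lower cut bounds the time
step, the upper cut keeps the periodic minimum-image convention valid —
and radii are sampled until the summed sphere volume reaches
`φ_target · V_box`, then rescaled by one common factor (<1% in radius)
so the target solid fraction is hit exactly.

The RVE is a cube, periodic in x and y, with rigid plates flush with
the z faces. Particles are seeded at reduced radii by rejection
sampling (largest first), then grown in ~35 multiplicative stages with
interleaved overlap-relaxation sweeps: a Gauss–Seidel projection moves
each overlapping pair apart along its normal by 1.2× the overlap, split
in inverse proportion to particle volume — the overdamped, frictionless
limit of relaxation dynamics. Growth stops at the target fraction
(0.59 by default, matching the poured-bed density of these powders) and
a final sweep phase continues until the mean residual overlap is below
10⁻³ of the mean radius, giving a quasi-stress-free start; the
over-relaxation factor cycles through (1.2, 0.85, 1.45) so
near-crystalline states cannot trap the iteration. Everything is
deterministic in the seed, bit-for-bit. Gravity is off throughout: a
sub-millimetre bed loaded to tens of MPa is insensitive to it.

What the generator does *not* emulate: die filling by pouring,
segregation, aspherical/agglomerated particle shapes, and any initial
stress history. Passing tests therefore validate the mechanics of the
model on idealised sphere packings, not the fidelity of real die
filling. Note also that the three quantiles pin the particle count per
unit volume: a (0.8 mm)³ box at 59% solids holds ≈240 spheres of the
coarse PSD and ≈5000–6400 of the fine one (depending on the truncation
window). Published particle-scale studies of these materials sometimes
quote very different counts for the same box, which implies a different
— unstated — effective size distribution; with the distribution fixed
by the quantiles, the count is not a free parameter.

## Time integration and loading protocol

Velocity-Verlet for translations, explicit Euler for angular velocity
(spheres need no orientation state). The automatic time step is a
Rayleigh-type estimate `dt = 0.2 sqrt(m_min/k_lin)` with the stiffest
linearised contact `k_lin = 1.5 k2 sqrt(δ_ref)` evaluated at
`δ_ref = 0.5 r_min` (the public `critical_time_step` helper defaults to
a 1% linearisation overlap for reporting; the engine uses the deeper,
more conservative reference because compaction overlaps are large).
Neighbour search is a cell list with a skin of half the smallest
radius, rebuilt when any particle has moved half a skin; contact
history (maximum overlap, tangential springs) is carried across
rebuilds by key matching.

Quasi-staticity is enforced by Cundall local damping (force
proportional, coefficient 0.2) rather than a viscous background drag:
a mass-proportional drag contributes a stress that grows with box size
squared at fixed strain rate and wrecks RVE comparability, whereas the
local damping is intensive. With it, compaction curves change by <0.5%
when the plate speed is halved. The kinetic-to-elastic energy ratio is
recorded with every curve sample; in the load-bearing regime (axial
stress above ~10% of peak) slow runs keep it below 10⁻³. During the
initial rearrangement phase the denominator is still near zero and the
ratio is not meaningful.

Loading is strain-driven: the top plate descends at constant speed,
set either directly or through a step budget (`n_steps` for the loading
leg); an optional stress stop and a decompression leg at the same speed
are available. Axial stress is the chunk-averaged top-plate normal
force over the lateral area; engineering strain is referenced to the
post-relaxation bed height. Overlaps beyond the smaller particle radius
are *expected* at relative densities approaching 2 (71% strain from a
59% start); the instability diagnostic therefore triggers only on
overlap ratios above 4, near-coincident centres (<5% of `R_i+R_j`), or
non-finite state.

## Calibration and RVE analysis

Curve agreement uses `R² = 1 − SS_res/SS_tot` with the simulated stress
linearly interpolated onto the reference strain grid, loading leg only
by default. Calibration is a budgeted coarse grid (seed-shuffled order)
over the free parameters followed, for a single free parameter, by
golden-section refinement between the best point's grid neighbours; the
search stops when R² exceeds `r2_threshold` (default 0.95, the
practical criterion for noisy experimental references) or the budget is
spent, and a sub-threshold best is returned flagged rather than raised.
For *noise-free synthetic* references the 0.95 threshold is crossed by
almost any candidate (even `β = 0` scores ≈0.99), so self-consistency
tests derive their threshold from the measured `β = 0` baseline (two
orders of magnitude closer to 1); the refinement then recovers the
generating `β` to a few hundredths. `φ_f` stays fixed at 0.99 during
calibration; only `β` (optionally the stiffness ratios) is searched.

The RVE study regenerates a packing per box size at the same PSD and
fraction, compresses each under an identical protocol, and scores each
curve against every other with the same R² machinery; a size is
declared representative when it matches the next size at R² ≥ 0.95.
Cross-seed scatter of a single size sets the noise floor (R² ≈ 0.97 at
(0.6 mm)³, ≈0.99 at (0.8 mm)³ under the test protocol).

## Problem sizes used by the test and acceptance runs

Unit and property tests run on boxes of 0.22–0.55 mm (tens to a few
hundred particles) with step budgets of 1.5k–20k. The acceptance suite
uses the (0.8 mm)³ coarse-grade RVE (~240 particles) compressed in 60k
steps, a (0.6 mm)³ fine-grade RVE (~2700 particles; the fine PSD puts
~5000+ particles in the 0.8 mm box, which buys no accuracy for an
intensive quantity), the four-size RVE series at 40k steps, and a
half-scale calibration rig (~350 particles, 20k steps per evaluation).
The acceptance script runs the compaction legs at 120k–150k steps.
These sizes sit well inside the speed-insensitive regime established
above.

## Known limitations

* Spheres only; the agglomerate shapes of real MCC granules enter only
  through the calibrated parameters.
* The multi-contact coupling uses the isotropic (trace) part of the
  particle stress; anisotropic coupling is out of scope.
* The Hertzian contact area `A = π R* δ` is the small-overlap limit; at
  the deepest overlaps the geometric cap area is up to twice that, a
  difference absorbed into `β` in practice.
* No die-wall ejection stage, no thermal or rate dependence, no
  breakage or bonding.
* The hysteretic law admits arbitrarily deep overlaps at extreme
  densification (particles effectively interpenetrate); results beyond
  relative density ~2 should be read as model extrapolation.
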