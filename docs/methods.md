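# Methods

## Graded lattice geometry

The Schwarz-Diamond (SWD) surface is represented implicitly,
`F(x,y,z) = cos x·cos y·cos z − sin x·sin y·sin z`, 2π-periodic along each
axis. A lattice with spatially varying unit cell size `cs(X)` (mm) is
obtained by transforming the argument rather than the function: along each
axis the argument gradient is `∂x_i/∂X_i = 1/cs`, applied equally in all
three directions so the surface stays triply periodic, and the absolute
argument is the cumulative line integral

    x_i(X⃗) = 2π ∫₀^{X_i} dX'_i / cs(X⃗),

evaluated per axis with the other coordinates held fixed. Because `cs`
varies in all three coordinates, `x₁` at a point depends on `(X₂, X₃)`
through the integrand — this continuous phase shift is what lets the cell
size change without tearing or stitching the surface. The integral is a
1-D trapezoidal cumulative sum along grid lines from the minimum corner of
the design box (origin configurable); the rule is exact for constant `cs`,
where the map reduces to `x_i = 2πX_i/cs`.

The membrane is the sub-level set `SD = F(x⃗) − c ≤ 0`. The offset `c`
(default 0) shifts the surface for wall-thickness/manufacturing tuning; at
`c = 0` the argument shift `(x,y,z) → (x+π,y+π,z+π)` flips the sign of
`F`, so material and fluid each occupy half the volume (the measured
global porosity on an 8 mm³ block at 0.05 mm voxels is 0.4997). One-sided
thresholding is implemented as printed masks require; a thin-shell option
(`|F| ≤ t`) is left as future work.

The argument field is computed on a node lattice (default spacing
`cs_min/8`) and tri-linearly interpolated to voxel centers; voxelization
can stream in Z-slabs so printer-resolution volumes never need to be held
in memory (chunked and monolithic paths produce identical occupancy, which
is tested). Voxel centers sit at `origin + (i+½)·h`, axis order X, Y, Z.
Surface area uses marching cubes on the SD volume; against a sphere SDF of
radius 5 mm at 0.1 mm voxels the error is 0.013%, and the SWD area density
follows the expected `1/cs` scaling (doubling `cs` halves area/volume to
within 1.3% at 0.05 mm voxels).

## Cell-size fields

Cell sizes live on a regular control-point lattice spanning the design
box. The field between control points is a Gaussian-kernel RBF interpolant
with a constant polynomial tail, solved exactly (ridge 1e-10 on the
diagonal for conditioning): control values are reproduced at the control
points to < 1e-9, constant data is reproduced everywhere, and the
interpolant is infinitely smooth — the property that protects a
blood-contacting lattice from abrupt geometry transitions. The kernel
width defaults to the control spacing. Sampled fields are clamped to
`[cs_min, cs_max]` defensively, and a configurable gradient warning
(default |∇cs| > 0.5 mm/mm) flags distorted geometry rather than failing.

## Porous-medium flow

Device-scale flow through the lattice is modelled with the
Darcy–Forchheimer law `∇p = (ηD + ½ρF|u⃗|)u⃗` and continuity `∇·u⃗ = 0`
(superficial velocity; water at 20 °C by default, η = 1.0e-3 Pa·s,
ρ = 998 kg/m³). A full RANS CFD model is deliberately replaced by this
pure porous-continuity solve — inside the porous block, inertial effects
beyond the Forchheimer term are negligible, and the Darcy regime dominates
at oxygenator flow rates (the solver's flow split is verified to be
independent of flow-rate magnitude in that regime).

Discretization: collocated structured grid, face conductances from the
harmonic mean of cell mobilities `k = 1/(ηD + ½ρF|u|)`, fixed total flux
distributed uniformly over the inlet patch, fixed pressure (0) on outlet
faces through the boundary half-cell. The `|u|` nonlinearity is resolved
by Picard iteration with under-relaxation 0.7; convergence is the maximum
face-flux change between iterates relative to Q (tolerance 1e-8, cap 200
iterations, error carries the residual history). In the Darcy limit the
scheme is exactly a linear resistor network, and it matches an
independent dense network solve to round-off; mass balance between inlet
and outlet holds to < 1e-6 relative on all fixtures.

Hydraulic coefficients vs cell size follow pore-size scaling,
`D(cs) = d0(cs0/cs)²`, `F(cs) = f0(cs0/cs)`, with defaults
`d0 = 1e9 1/m²`, `f0 = 1e4 1/m` at `cs0 = 1.2 mm` — placeholders on the
scale typical of mm-pore lattices, intended to be replaced by calibration:
a measured `(cs, D, F)` table can be supplied and is interpolated
monotonically (PCHIP), with out-of-range requests rejected.

The CT experiment is emulated by passive-scalar transport of the
contrast-agent volume fraction Φ at the interstitial velocity `u/ε`:
first-order upwind finite volumes on the solver's face fluxes, internally
sub-stepped to a CFL number ≤ 0.9 (monotone, hence 0 ≤ Φ ≤ Φ_max always),
frames recorded every 0.5 s. The inlet carries Φ_max = 0.20 during a 2 s
bolus; the injected tracer volume is made exact by weighting each substep
with its overlap of the bolus window. Buoyancy of the contrast agent is
omitted (a passive scalar), consistent with the small effect of density
difference on distribution in this regime.

## Cell-size optimization

The optimizer seeks uniform interstitial velocity
`u_ref = Q/(A·ε̄)` (total flow over structure cross-section times
porosity). Each iteration: solve steady flow for the current field,
sample `|u_superficial|/ε` at every control point, evaluate the objective
`|u − u_ref|`, update

    cs_{i+1} = max(cs_min, cs_i − α(u − u_ref)),

then RBF-smooth the control values into the next field. `u` is taken as
interstitial (not superficial) velocity so it is commensurate with
`u_ref`, which divides by porosity; sampling is per control point (a
neighborhood average is a documented alternative). The optimization rate
defaults to `α = 0.5·cs_init/u_ref` — a velocity error of one `u_ref`
moves the cell size by half its initial value — and is exposed in config.
The loop is fully deterministic, runs at least 50 iterations, and stops
when the largest relative cell-size change falls below 5% (cap 300). No
upper cell-size bound is imposed by default; `cs_max` is available.

On the two-channel fixture (two parallel Darcy channels behind a
high-permeability distribution plenum, initial cell sizes 1.2 and 2.0 mm)
the loop converges to the unique fixed point — equal split, both channels
at `u_ref` to ~1e-8 relative — with monotonically decaying change per
iteration down to the flow-solver tolerance floor (~1e-10), terminating
exactly at iteration 50. On the corner-inlet box the cell size grows with
distance from the inlet, as expected when the upper region is starved.
There, with the placeholder coefficients and a 12×12×6 grid, the unbounded
update inflates the far-corner cells to tens of mm before the 5% rule
binds; this is a coarse-grid artifact of uncalibrated `D(cs)` (real
devices bound the growth physically) and is reported, not hidden by a
`cs_max`.

## Perfusion analytics

Voxel HU values mix linearly across the solid membrane fraction and the
fluid phase. Porosity comes from the static scans,

    ε = (HU_t0 − HU_air)/(HU_water − HU_air),

where the subtracted reference is the co-registered *air-filled scan
field*: both static scans contain the identical `(1−ε)·HU_material`
contribution, so the subtraction cancels the solid voxelwise and the
quotient is exactly ε (a scalar air HU is accepted as a fallback, exact
only in solid-free voxels). Concentration unmixing is two-step — remove
the material contribution and divide by ε to get the fluid-phase HU, then
invert the linear water↔CA mixing:

    Φ = [(HU_t − (1−ε)·HU_material)/ε − HU_water]/(HU_CA − HU_water).

This is the only reading of the concentration formula that satisfies both
limits (pure water → 0, pure contrast agent → 1), and the forward/inverse
round trip through the phantom generator is exact to 1e-10 noise-free,
with recovery error growing linearly in the HU noise SD. ε is clipped to
[0.05, 1] to keep the division well-posed; a frame with > 5% of voxels
outside [−0.1, 1.1] before clipping is rejected as mis-registered.

Volumes are block-averaged to 2 mm voxels before unmixing, since the
linear-mixing assumption needs voxels spanning several lattice cells.
Regions: the cross-section is partitioned into four corner blocks, each
covering 35% of both in-plane extents — B (inlet corner), R, L, T
(farthest from the inlet) — plus the complementary center C, swept
through the depth axis; all fractions are configurable since the physical
region dimensions are a reporting convention. Region curves are arithmetic
means per frame; shares are voxel-count-weighted trapezoidal time
integrals normalized to 1.

The Homogeneity Index of a frame is

    HI = 1 − (1/SD_max)·(1/n) Σᵢ SDᵢ,

with SDᵢ the sample standard deviation (m−1 denominator) of Φ, in percent,
on each of the n voxel planes perpendicular to the main flow direction,
using all analysis-resolution voxels of the plane as evaluation points.
`SD_max` defaults to 10 (concentration %): with homogeneous premixing the
inlet concentration is at most 20%, and the population SD of a variable
bounded in [0, 20] is maximized by equal mass at the extremes, range/2 =
10. HI = 1 for perfectly uniform perfusion; HI is deliberately not clamped
below 0 — values below zero flag SD beyond `SD_max` and remain meaningful
for relative comparison between specimens. The plane axis follows the
geometry: for device-like stacks the default is the vertical axis, while
the corner-inlet fixture measures planes perpendicular to its
inlet→outlet axis, which is its bulk transport direction.

Simulation-vs-measurement agreement uses Spearman rank correlation over
all pooled (region, time) samples, with the tied-rank fraction reported so
callers can confirm it stays below ~1%.

## Synthetic CT phantoms

The phantom generator inverts the analytics' mixing model exactly: air
scan `(1−ε)HU_material + ε·HU_air`, water scan with `HU_water`, transient
frames with fluid HU `Φ·HU_CA + (1−Φ)·HU_water`, plus additive i.i.d.
Gaussian noise (seeded; bitwise reproducible). Default constants
(air −1000, water 0, material 120, CA 2000 HU) are synthetic values on the
scale of polymer prints and iodine contrast, not measurements. The
phantoms therefore exercise the unmixing, resampling and metric code
exactly, but do not model beam hardening, scatter, partial-volume effects
beyond voxel mixing, or spatially correlated scanner noise — passing tests
demonstrate algorithmic correctness, not robustness to real scanner
physics.

## Problem sizes and numerical choices

Desk-scale defaults keep every pipeline comfortably within a single CPU:
flow fixtures use ≤ 12×12×6 cells (the corner-inlet box spans 48×48×24 mm
at 4 mm cells, 0.5 l/min), optimization runs 50–120 iterations in a few
seconds, geometry checks voxelize up to 160³ volumes, and transient runs
cover 30 s of bolus transit at 0.5 s frames. Key tolerances: RBF exactness
1e-9, flow Picard 1e-8, conservation 1e-6 relative, phantom round trip
1e-10. Ties and degenerate inputs fail loudly (duplicate control points,
empty regions, constant rank-correlation input, non-positive cell sizes,
out-of-range coefficient tables).

## Known limitations

- The flow model is porous-continuum only: microscopic flow features,
  shear stresses and gas transfer are out of scope, and the default
  `D(cs)`, `F(cs)` coefficients are uncalibrated placeholders.
- The optimizer uses the local-velocity heuristic update, not adjoint
  sensitivities; it equalizes velocity where the geometry permits and can
  inflate cells without bound in regions the flow cannot reach.
- HI and the region shares are relative metrics — comparable between
  specimens analyzed identically, not absolute perfusion measures.
- Image registration, scanner artifact correction and DICOM ingestion are
  not implemented; inputs are assumed co-registered.
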