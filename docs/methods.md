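# Methods

## Cellular Potts model

### State and energy

The lattice is a rectangular 2D grid; axis 0 is the anterior–posterior (AP)
axis with the anterior at row 0, axis 1 is medio-lateral (ML). Each site is
owned by one cell id (0 = medium); everything outside the grid is a fixed
medium frame (no wraparound), so links crossing the boundary contribute
cell–medium contact energy. The energy is the standard
Glazier–Graner–Hogeweg Hamiltonian: contact energies `J(τ, τ')` summed over
unordered heterolabel neighbour links (Moore 8-neighbourhood by default,
von Neumann selectable), plus quadratic volume and surface constraints per
cell. The surface `S(σ)` is defined as the cell's heterolabel-link count
under the same neighbourhood; the literature offers several conventions and
this one makes the incremental bookkeeping exact.

Directed migration is a non-equilibrium drive added to copy attempts only:
`ΔH_M = µ(τ(source)) · λ_M · (c(source) − c(target))` with `c` affine in
the AP row index. The ramp orientation is an explicit configuration flag
(`anterior_favourable`); with it set, `c` increases toward the anterior so
anterior-directed copies by motile cells are energetically favourable.
Medium has mobility 0, so retraction moves carry no drive.

### Dynamics

A surface site is any site whose neighbourhood contains a differently owned
site. One Monte Carlo step (MCS) snapshots the surface sites in row-major
order and performs one copy attempt per site: a candidate source site is
drawn uniformly from the 24 sites within Chebyshev distance 2 of the target
(off-grid candidates are medium); drawing a site owned by the target's own
cell is a no-op. The Metropolis rule accepts `ΔH < 0` always and `ΔH ≥ 0`
with probability `e^{−ΔH/T}`; `ΔH = 0` is therefore always accepted.

Cells whose volume reaches zero are flagged removed and never reacquire
sites (they own none, so they can never be drawn as a source). Removed
cells retain their now-constant penalty `λ_V V₀² + λ_S S₀²` inside the
total energy. This convention makes the energy change of the killing move
include the `(0 − V₀)²` transition and keeps the local delta identically
equal to a full-Hamiltonian recomputation; a constant offset never affects
the dynamics.

Two implementations share this protocol: a readable pure-Python path that
returns full per-attempt records (used by the unit tests and as the
reference), and a numba-compiled kernel for scenario-scale runs. The kernel
can log every attempt (target, source, ΔH, accepted) so the test suite
replays kernel runs through the Python energy functions and verifies both
the per-attempt energetics (to 1e-9) and the final lattice.

Randomness: the Python path uses a caller-supplied `numpy` Generator; the
kernel seeds numba's internal stream once per run. Each path is bit-
reproducible under a fixed seed; the two paths draw from different streams
and are compared through physics, bookkeeping and replay, not bitwise.

## Tissue scenarios and calibration

### Geometry

The replication ("desk") scale uses a 230 × 100-site grid at 2 µm/site —
the simulated field is 460 µm × 200 µm — with 5 × 5-site cells
(V₀ = 25 sites ≙ 10 µm cell diameter, S₀ = 56 links, the boundary-link
count of an isolated square cell). The initial tissue places a one-cell-row
leading-edge band spanning the full field width at rows 107–112, the
prechordal plate (ppl) as a 2 × 6-cell block behind it, the notochordal
plate (NC) as a 10 × 4-cell column trailing, and lateral plate mesoderm
(lpm) flanking and trailing; new lpm cells (10 every 10 MCS, matched to the
anterior volume flux so the sheet stays connected) ingress at free
positions in the posterior 10 rows. A run stops at the first MCS at which
the lpm's inclusive AP bounding box reaches 400 µm, or at a max-MCS guard
(termination reason is recorded). The grid is 30 rows taller than the stop
span so that threshold termination occurs before the leading edge reaches
the anterior boundary. A "tiny" scale (48 × 30 sites, 3 × 3 cells) runs in
seconds and guard-terminates; it exists for smoke tests and demos.

### Parameters (reduced units)

Calibrated defaults: `λ_V = 5`, `λ_S = 0.05`, `λ_M = 5`, `T = 8`, with
mesodermal mobility `µ = 1` and the contact-energy matrix

|        | M   | LE  | ppl | NC  | lpm |
|--------|-----|-----|-----|-----|-----|
| M      | 0   | 8   | 8   | 8   | 8   |
| LE     | 8   | −4  | 4   | 5.5 | 5.5 |
| ppl    | 8   | 4   | 5.5 | 3   | 5.5 |
| NC     | 8   | 5.5 | 3   | 4   | 5.5 |
| lpm    | 8   | 5.5 | 5.5 | 5.5 | 6   |

(lower J = stronger adhesion). These values were calibrated, in order, to
three explicit conditions — acceptance rate at initialization in the
10–40% band (measured ≈ 11–13%), single-cell volume homeostasis
(time-averaged V within 5% of V₀ over 500 MCS; measured −4.7%, the deficit
being the usual boundary-energy pressure), and anterior drift monotone in µ
— and then to the qualitative scenario phenotypes. They are calibration
choices surfaced in the config, not literature values. The matrix encodes:
a highly cohesive leading edge (its cells essentially never exchange
neighbours), an NC that is moderately cohesive and adheres to the ppl
ahead of it, a baseline ppl that is *not* specially sticky to itself, and
loose lpm.

### Leader scenarios

Presets differ from baseline only in their stated knobs:

* `mobile_leaders` — ppl mobility µ doubled (a 100% increase over every
  other mesodermal type).
* `adhesive_leaders` — ppl–ppl *bond strength* doubled. Because the raw
  contact-energy sign convention is ambiguous, "bond strength" is defined
  as the work of adhesion `γ(τ,τ') = J(τ,M) + J(τ',M) − J(τ,τ')`; doubling
  `γ(ppl,ppl)` (10.5 → 21) maps `J(ppl,ppl)` from 5.5 to −5.
* `mobile_adhesive_leaders` — both.

With these conditions (10 seeds each), the notochord's median AP/ML aspect
ratio is strictly greatest for mobile+adhesive leaders; the leading-edge
front is modally concave for adhesive-only leaders (the slow cohesive ppl
cluster starves the central front of forward supply) and modally convex for
mobile+adhesive leaders (the fast cluster drives the centre forward), and
the non-cohesive scenarios leave the notochord broad (baseline) or
elongated but less consistently condensed (mobile-only).

### Morphometric conventions used by the scenario summary

`tissue_extents` reports inclusive bounding boxes × site size, aspect =
AP/ML. `front_curvature_class` extracts the anterior-most front row per ML
column, drops 20% of columns at each lateral end, fits a quadratic, and
classifies by the sign of the quadratic coefficient with a flat tolerance
of 1e-3 per site². The end-trim exists because the terminal columns of a
one-cell-thick cohesive band are rounded by the band's own surface tension
whichever way the front migrates; without it the quadratic is biased convex
for every scenario.

## Optic flow on spherical geometry

`estimate_flow` is a volumetric Lucas–Kanade estimator: spatio-temporal
gradients (central differences on the frame-pair average) accumulated over
a uniform sliding box (default 20 × 20 × 8 voxels in x, y, z) give a 3 × 3
linear system per voxel; voxels whose structure tensor has condition number
above 1e3 (or a vanishing smallest eigenvalue) are invalidated. A second
warp-refinement pass (resampling the later frame along the current
estimate) keeps displacements up to ~2 voxels/frame inside the
linearisation regime. Velocities are computed on voxels; surface projection
happens afterwards. Tissue masks are caller-supplied.

Sphere geometry: algebraic least-squares sphere fit (the linear system
`|p|² = 2c·p + (R² − |c|²)`; degenerate when the design matrix is rank
deficient). `orient_axes` sets the pole axis to the tangential component of
the tissue's principal elongation axis at the mask centroid direction —
second moments are taken in the tangent plane, since the radial component
encodes only surface curvature — which places the elongation axis in the
meridian plane; an isotropic mask (leading moment ratio < 1.2) is an error.
Angles: `φ` is the polar angle from the pole, `θ ∈ [0, 2π)` the azimuth
from the meridian reference; Mercator latitude is `π/2 − φ`, with an ±85°
latitude cutoff. The spherical basis is orthonormal, so the decomposition
preserves speed exactly.

Kymographs average a chosen component (default `v_φ`) per (φ bin, time bin)
within each tissue's validity mask and report ectoderm minus mesoderm; the
default time bin is 5 min; empty bins are NaN (missing, never zero). The
transverse extension rate per φ band is the difference of mean `v_θ`
between the tissue's high-θ and low-θ edges (the integral of ∂v_θ/∂θ across
the tissue width): positive = broadening perpendicular to the migration
axis.

## FRAP curves

Traces are normalized affinely so the mean pre-bleach level is 1 and the
first post-bleach sample 0. Recovery is fitted as the single exponential
`I(t) = plateau · (1 − e^{−kt})` (immobile fraction expressed through
`plateau < 1`) by bounded least squares, `k ∈ (1e−5, 1) s⁻¹`, initialised
from a log-linearisation of the early points and the tail mean; the
parameter covariance is the Gauss–Newton estimate at the solution. The time
to a recovery fraction `f` of the plateau is the closed form
`−ln(1 − f)/k`; a flag switches the reference to the pre-bleach level, in
which case fractions above the plateau are unreachable and raise. The
period-3 centred moving average (valid-region output) is provided for
trendlines.

## Morphometrics

Circularity is `4πA/P²`. The default perimeter estimator is the Crofton
formula with four directions: on rasterized disks of radius ≥ 15 px it
keeps the circle anchor within 0.01 of the analytic 1.0, while
marching-squares contour length measures ~0.91 and pixel-edge counting
~0.62 on the same masks. The exact pixel-edge boundary-polygon length is
available as `method="pixel_edge"` (exact for axis-aligned rectangles: the
2 × 20 rectangle has polygon perimeter 44 and circularity
`4π·40/44² ≈ 0.260`), and marching-squares as `method="contour"`.

Cluster sizing thresholds an intensity image and labels connected
components with full connectivity by default (8 in 2D, 26 in 3D),
discarding components below a physical minimum size; thresholds are
user-supplied. Wound-gap width is measured at 10 fixed, evenly spaced
columns (per the assay convention) as the largest empty run between
occupied pixels, averaged per frame; the closure speed is the negated
linear-regression slope of mean gap versus time (positive = closing).
Pearson colocalization is the sample correlation of voxel intensities
within an optional mask; constant channels are an error rather than NaN.

## Synthetic data

Every consumer has a generator with recorded ground truth, deterministic
under a fixed seed:

* **Flow movies** — a band-limited Gaussian random field (correlation
  length ≈ 4 voxels, guaranteeing well-conditioned gradient systems)
  sampled backwards along an analytic velocity field (uniform translation,
  rigid rotation, or polar-angle drift with a leading/trailing speed
  contrast), in two channels on disjoint spherical shells with masks. The
  backward displacement uses the local field value, exact for translation
  and first-order otherwise; displacements beyond flow validity trigger a
  warning.
* **FRAP traces** — exact normalized exponential recovery plus Gaussian
  noise at 10 s sampling; the bleach-point anchors stay exact because they
  are set, not measured.
* **Label shapes** — disks, rectangles and ellipses rasterized by the
  centre-inclusion rule with analytic area/perimeter/circularity stored
  alongside; overlaps allowed and recorded for merge tests.
* **Colocalization pairs** — `B = ρA + √(1−ρ²)N` with independent standard
  normal A, N.
* **Simulation configs** — complete runnable documents for any scenario at
  `tiny` or `desk` scale, round-tripping through the config parser.

What the generators do *not* emulate: microscope point-spread functions,
photobleaching and drift, segmentation errors, anisotropic voxels, cell
divisions, or biological variability beyond seeded noise. Passing tests
therefore demonstrate correctness of the estimators on idealised inputs,
not robustness to real acquisition artefacts.

## Problem sizes and limitations

The test suite runs the scenario replication at 230 × 100 sites with 10
seeds per scenario (40 runs, ~1.5–2.5 s each), flow recovery on 64 × 64 × 24
volumes, and 100-trace FRAP ensembles; the whole suite completes in under
two minutes on one CPU.

Known limitations:

* The scenario ranking's weakest margin is mobile-only versus
  mobile+adhesive: fast non-cohesive ppl cells can thread through the
  leading-edge band and drag a notochord streak, so the mobile-only median
  aspect ratio comes close to (though below) the mobile+adhesive one at
  this scale. Larger fields and cell counts separate the two more cleanly
  but cost proportionally more runtime.
* The CPM is 2D; out-of-plane intercalation and epiboly are outside scope.
* The mapping from MCS to developmental time is not modelled; the 400 µm
  stop is recorded as the biological endpoint equivalent without assigning
  a rate.
* The kernel path supports the Moore neighbourhood only; the von Neumann
  option exists on the reference path.
* `fit_sphere` is the algebraic (Kåsa) fit; its small bias under heavy
  noise is acceptable at the noise levels tested (radius error < 0.1 at
  σ = 0.5 on 500 points) and no geometric refinement is applied.
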