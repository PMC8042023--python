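# Methods

## Growth model

The cell is modelled as a spherocylinder whose cylindrical **active zone**
(length `L(t)`) elongates while two polar caps of axial size `c` (the
**inert zone**) stay rigid. Wall insertion in the active zone is
homogeneous along the axis, which fixes the velocity field uniquely: a
landmark at cell-centred axial position `y` moves with `H(t)·y` for
`|y| ≤ L/2`, and rides rigidly with its pole otherwise. Consequences used
throughout (and tested as exact invariants):

- `dL/dt = H(t) L`, so pairwise separations obey `V_Dy = H D_y`
  ("Hubble law") with a common `H` for all pairs at a given time;
- the normalized coordinate `N_y = y/L` is conserved during elongation;
- the pole distance obeys the hinge law `V_Py = H (P_y − c)` for active
  landmarks and `V_Py = 0` in the caps — so the changepoint of the
  `V_Py(P_y0)` fit *is* the inert-zone size;
- lateral coordinates never change (no diameter growth or twist).

`H(t) = H0(1 + β t)` is affine in time; `β = 0` gives pure exponential
growth. The affine form is the simplest law reproducing the observed
increase of the expansion rate as cells elongate; no particular functional
form is implied by the measurements, and both parameters are exposed.

**Division** is an independent, local insertion mode. Once the cell passes
the trigger length, mid-cell insertion displaces every landmark on the
upper/lower half outward by the septal offset `s(t)`, growing linearly in
time from 0 to `c` over the division duration (only the endpoint — a
displacement of one cap size — is constrained by observation; the linear
profile is a package choice). The two half-rods keep elongating
homogeneously by default (two-phase independence); a switch pauses
elongation during septation. At completion the cell splits at mid-cell,
each daughter gains a new inert cap of size `c`, and a landmark's material
coordinate maps across the division exactly by the Bernoulli shift map
`N_y → 2N_y ∓ 0.5`. This identity between the division geometry and the
map is a theorem of the model and is tested with zero tolerance. A landmark
exactly at mid-cell is assigned to a daughter by a seeded fair coin; the
map itself refuses `N_y = 0` unless the coin policy is requested.

## Generator defaults (study conditions)

| parameter | LB | TB | SOC | notes |
| --- | --- | --- | --- | --- |
| inert cap `c` (µm) | 0.27 | 0.22 | 0.37 | measured per growth medium |
| diameter `D` (µm) | 1.06 | 1.02 | 1.11 | TB/SOC measured; LB interpolated between them, as its cap size falls between the TB and SOC values |
| `H0` (1/min) | 0.010 | 0.008 | 0.012 | representative of the observed per-interval expansion rates (~0.01/min), faster in richer medium |
| `β` (1/min²) | 0.005 | 0.004 | 0.005 | gives a ~25% rate increase over 50 min, matching the observed within-movie acceleration |

Common defaults: initial active length 2.0 µm, frame interval 10 min,
7 frames (60 min), division trigger 5.0 µm total length, division duration
20 min, localization noise 0.03 µm where noise is requested (sub-pixel
fitting precision at the rendered photon budget), 52 nm/px rendering with a
0.10 µm PSF sigma. Landmark placement is uniform over the whole cell
(caps included) for inert-zone experiments, or a truncated Gaussian
(σ = 0.4 on `N_y ∈ [−0.5, 0.5]`, rejection-sampled) emulating the
center-biased placement of newly produced motors.

One root seed feeds named substreams (placement, lateral, noise, miss,
coin, shot, bootstrap, initial-law, body-noise), so toggling one stochastic
stage never perturbs another; identical seeds give byte-identical CSVs.

**What the generator does not emulate**: landmark diffusion in the membrane
(anchoring is rigid by construction), helical/twisting insertion, diameter
growth, photobleaching, uneven illumination, camera read noise beyond the
Poisson model, and multi-cell scenes. Passing tests therefore certify the
analysis chain under the stated geometry and noise model, not robustness to
those effects in real data.

## Image analysis

Spots: Gaussian smoothing (σ = 1 px) → local maxima (≥ 5 px apart, robust
MAD-based threshold) → 12×12 px ROI → symmetric 2D Gaussian with constant
offset by bounded nonlinear least squares. Fits are rejected when the
center leaves the ROI, the width leaves [0.5, 4] px, or the amplitude is
below threshold; border-clipped ROIs are excluded by default. Localization
is unbiased on noise-free spots (< 0.01 px) and has RMSE ≈ 0.08 px at peak
SNR ≈ 10.

Geometry: smoothing → 4× bicubic upsampling → Otsu threshold → largest
connected component (an error demands single-cell crops when a second
comparable component exists) → sub-pixel boundary. Poles are the vertex
pair maximizing end-to-end separation among pairs splitting the perimeter
into near-equal arcs (< 20% imbalance); each pole is then refined to the
arc-median of the near-maximal vertices, because quantized cap tips are
flat plateaus whose corners would otherwise tilt the midline. The midline
connects midpoints of the two arc-length-resampled contour halves; a light
smoothing spline (0.5 upsampled px) removes boundary-quantization wiggle
that otherwise inflates the arc length by ~1%. Length is the midline arc
length; diameter is the mean contour-to-contour width over the central 50%.
All geometry lives in upsampled pixel space and is converted to µm once.

Division onset: maximum contour-to-convex-hull depth within the central 20%
of the cell, threshold 0.05 µm on ≥ 2 consecutive frames. Frames up to
10 min before onset are `elongation`, frames from onset are `division`, and
the margin in between is `transition` (excluded from per-phase statistics).

## Kinematics

Linking is greedy nearest-neighbour with a gate of 0.3 µm per 10 min
(scaled by the frame interval), bridging one missed frame; assignment order
is by increasing displacement with deterministic tie-breaks. `V_Py` is the
unweighted OLS slope of `P_y` vs time (weighting by localization
uncertainty is not used; all landmarks share the same noise model).
`P_y0` is the first-sample pole distance.

The changepoint fit profiles `P_yc` on a 1 nm grid spanning the observed
`P_y0` range; at each candidate the hinge slope has a closed form (plateau
fixed at exactly 0, slope clamped non-negative), so the fit is a
deterministic global optimum over the grid with no initialization
sensitivity. The 95% CI is a seeded case-resampling percentile bootstrap
(default 1000 replicates). Degenerate inputs (all-zero velocities, all
points on one side) raise explicit non-identifiability errors.

Pair kinematics uses unsigned separations, the interval-start separation as
abscissa, and excludes any pair with a landmark inside the fitted inert
zone at interval start. `H` is no-intercept least squares of `V_Dy` on
`D_y` per interval. Normalized positions use `L = cell length − 2 P_yc`
with the fitted `P_yc` of the condition, never a hard-coded constant.

## Shift-map analysis

Orbit analysis uses exact `fractions.Fraction` arithmetic, since floating
point destroys the periodicity of rational orbits; population simulations
use floats with deterministic per-particle mapping between generations (no
resampling). Smoothing is quantified as the exact-CDF Kolmogorov–Smirnov
distance to the uniform law on [−0.5, 0.5]; histograms (50 bins) are an
output convenience, not part of the model. Starting points whose
denominator is a power of two eventually hit the undefined point 0 and are
excluded from the periodicity guarantee.

## Problem sizes and numerical tolerances

- Changepoint recovery checks use 100 seeded replicates of 195 (LB) or one
  replicate of 220 (SOC) landmarks at 0.03 µm noise; the bootstrap-coverage
  check uses 200 bootstrap replicates per fit, which is sufficient to
  locate the 95% percentile interval to the precision the check needs.
- The population smoothing simulation uses the full 200,000 particles; the
  analytic pushforward oracle uses a 20,001-point density grid.
- End-to-end imaging checks render 40 single-cell movies of 6 landmarks and
  7 frames each at 52 nm/px.
- Exact model identities (homogeneity, `N_y` conservation, the
  division-map identity) are asserted at machine precision (≤ 1e-12);
  changepoint exactness is asserted at the grid resolution (1 nm), with the
  residual sum of squares bounded by the grid-discretization floor (1e-8).
- The rendered division waist is capped at 80% of the radius so the cell
  remains one connected component until the split frame.

## Known limitations

- The midline diameter estimate is biased low by ~1–2% on rendered
  fixtures (paired-point widths are not exactly perpendicular widths).
- The inert-zone boundary is treated as a purely axial coordinate; the
  radial geometry of a partially active spherical cap is not modelled, in
  line with how the measurement itself is defined.
- The segmentation path handles exactly one cell per field; touching cells
  are rejected with an actionable error rather than parsed.
- `H(t)` grows without bound across many generations under the affine
  default; multi-generation runs beyond a few divisions should set `β = 0`.
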