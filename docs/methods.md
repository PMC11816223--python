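# Methods

## The motion model and its assumptions

The package describes breathing motion at each reference-image voxel as
linear in two respiratory covariates, amplitude A and rate Ȧ = dA/dt:

    X(A, Ȧ) = X₀ + α·A + β·Ȧ

with voxel-specific 3-vector coefficients α (mm per a.u.) and β
(mm per a.u./s). The model assumes (i) motion is a single-valued function of
the surrogate state — tissue returns to the same position whenever (A, Ȧ)
recurs; (ii) linearity over the observed amplitude range; and (iii) the
bellows surrogate, after drift correction, is affinely related to the true
respiratory drive. The rate term gives the model hysteresis: inhalation and
exhalation trajectories at equal amplitude differ by 2·β·|Ȧ|.

### Fitting

Displacements come from deformation vector fields (DVFs) between the
reference scan and each of the other scans, pull-from-reference convention,
mm, world frame. Per voxel and axis, α and β solve a 2-unknown
no-intercept least-squares system in the covariate deltas

    aᵢ = Aᵢ(z′) − A_ref(z),   bᵢ = Ȧᵢ(z′) − Ȧ_ref(z)

where z is the voxel's slice, z′ = z + dz/voxel_z its DIR-deformed slice
position, and the 2×2 normal equations are solved in closed form over the
whole grid at once. Design choices the problem leaves open, fixed here:

- **Reference state per voxel.** The reference scan's slices carry their own
  (A, Ȧ) tags; deltas are taken from the tag of each voxel's slice. This
  makes prediction at the reference state return an exactly zero field, and
  the reference scan's implicit zero-displacement observation drops out of
  the normal equations (zero covariates).
- **Target tag lookup at the deformed slice.** A tissue element imaged in
  scan i was imaged in the slice it had moved to, so the covariate reads the
  target scan's tag at z′, interpolated linearly over slice index (clamped
  at the volume ends). The simulator's analytic ground-truth fields use the
  same rule, solved by fixed-point iteration on the z component (the
  within-scan amplitude change per slice keeps the map contractive); this
  consistency is what makes noiseless parameter recovery exact to machine
  precision rather than merely accurate.
- **Rank deficiency never raises.** If the amplitude deltas carry no
  information (Σa² below 1e-10 a.u.²) α is set to zero and flagged while β
  is still estimated, and symmetrically; collinear designs zero and flag
  both. Voxels with zero observed displacement get α = β = 0 automatically.
- Fitting covers every grid voxel, inside the lungs or not; residual
  *statistics* are restricted to the lung mask (below).

## Surrogate processing

- **Drift.** Bellows pressure drifts linearly as the air warms; the
  corrected amplitude is A(t) = v_raw − (d₀ + d₁·t) with d₁ chosen to
  maximize Pearson correlation between A at the abdominal-surface sample
  times and the measured surface heights (≥ 3 samples required). The
  objective is one-dimensional and smooth, so a 201-point bounded grid
  search followed by bounded scalar refinement suffices; d₀ only recenters
  the signal and is reported, not optimized. Constant surface heights make
  the correlation undefined and raise.
- **Rate.** Ȧ is a Savitzky–Golay first derivative, polynomial order 3,
  default window 0.5 s. The window is the one deliberate departure from an
  earlier 1.0 s draft default: on a 4 s-period sinusoid the wider window
  biases the derivative peak by ~2.7 %, the 0.5 s window by < 0.2 %, and
  breath features at clinical rates are well resolved at 0.5 s.
- **Trimming.** Amplitude percentiles use the linear-interpolation
  convention throughout the package; samples outside the closed [P5, P95]
  interval are outliers. The 85th percentile is computed and displayed on
  the QA trace panel but plays no role in phase math — its anchors are the
  trace annotation conventions of the clinical report.
- **Breaths.** Exhalation minima segment the trace: local minima separated
  by ≥ 1.5 s with prominence ≥ 0.2·(P95 − P5), which suppresses spurious
  minima inside breath-holds.
- **Representative breath.** Each breath is resampled to a common
  normalized phase axis (101 points), the per-phase median is taken
  (robust to isolated deep breaths), and the curve is rescaled so its
  minimum is P5 and its maximum P95; the peak maps to P95 (a config-level
  choice — P85 would be the conservative alternative; the rescaling target
  is exposed through the percentile anchors). Its rate curve uses the
  median breath period. The eight phase targets take amplitudes
  P5 + f·(P95 − P5) for f ∈ {0, ¼, ½, ¾, 1, ¾, ½, ¼}; rates are read from
  the matching branch (exhalation ≤ 0, inhalation ≥ 0) and the two turning
  points get Ȧ = 0 exactly.

## Session synchronization

Scan on/off windows come from thresholding the binary scanner signal at the
midpoint of its two levels (medians of each side); if any sample deviates
from its level by half the separation or more, the signal is declared too
noisy and the stage raises. Scans whose slice count differs from the session
mode are dropped (a truncated reference is fatal). Foot-first scans are
resampled onto the reference grid by trilinear interpolation; a residual
offset above 1 mm indicates an acquisition programming error and raises.
Slice tags interpolate the surrogate at slice mid-exposure time plus the
session sync offset; the simulator records its offset (zero), and external
sessions take it from the manifest — no blind clock recovery is attempted.

## Reconstruction

Phase images invert the predicted displacement field by fixed-point
iteration with under-relaxation ω = 0.5 (plain iteration can enter a
period-2 cycle where the field gradient approaches one, e.g. where
per-slice reference amplitudes change quickly); the iteration stops when
the maximum composition residual falls below 0.05 mm, capped at 40
iterations, and non-convergence warns with the achieved residual instead of
raising. Displacement fields are extended nearest-neighbor at grid
boundaries during inversion; intensity pull-back fills out-of-field voxels
with air (−1000). Original-scan reconstruction drives the same inversion
with each output slice's own (A, Ȧ), so the assembled volume is consistent
with slice-by-slice helical acquisition. No density rescaling is applied to
reconstructed intensities — volumes change but Hounsfield units are the
reference scan's.

MIP and MEGA-MIP are voxel-wise maximum volumes (not through-plane
projection images), matching their use for ITV contouring.

## The phantom: what it emulates and what it does not

The simulator provides a minimal thorax in Hounsfield-like units (air
−1000, lung −800, soft tissue 40, diaphragm shell 60, vessels 100, spine
700): an elliptical body cylinder, two lung ellipsoids carved by paraboloid
diaphragm domes, bright vessel-like spheres, and a zero-motion spine.
The ground-truth motion field is a smooth scalar weight times fixed
direction vectors: α peaks at 10 mm/a.u. (craniocaudal) near the diaphragm,
decays cranially (Gaussian, scale 0.33 of the z extent), vanishes smoothly
at the body surface, around the spine, and — via a smoothstep taper over
12 % of the z extent — at the craniocaudal volume edges (keeping the motion
map contractive for inversion); β has the same spatial shape scaled to
2 mm/(a.u./s). The gradient of α stays below 0.6 (mm/a.u.) per mm.

Breathing is a chain of raised-cosine breaths with per-breath period
(4 ± 0.4 s) and depth (1 ± 0.1 a.u.) draws, C¹ at breath boundaries; the
raw bellows value adds gain, offset, a 0.005 a.u./s linear drift and
0.01 a.u. white noise. A session is 25 helical passes of 4 s plus 0.8 s
gaps (~2 minutes), alternating head-first/foot-first with a 0.4 mm
foot-first grid offset, slice times at mid-exposure. Abdominal surface
heights are sampled every 2 s as 8 mm/a.u. times the true amplitude plus
0.1 mm noise — they are synthesized from the trace, not extracted from the
images, so the body surface itself does not bulge in the volumes.

Not emulated: projection-domain CT physics, dose-dependent noise (the
140 vs 40 mAs distinction is metadata only), anatomical realism, surrogate
nonlinearity, or DIR error structure — phantom deformation fields are exact
by construction. Passing tests therefore demonstrate the correctness of the
workflow machinery (synchronization, fitting, inversion, reconstruction,
statistics), not robustness to registration failure or image noise; DIR
quality enters only through the adapter interface and the noise-injection
studies, which add independent Gaussian perturbations to the fields.

## Residual diagnostics

The residual of one (voxel, scan) pair is the Euclidean distance between
the model-predicted and DIR-observed positions. Statistics pool over all
non-reference scans and the lung mask: mean, SD (ddof = 1), linear 95th
percentile, a 1 mm-bin histogram expressed as percent of the pooled set,
and coronal/sagittal maximum-intensity projections of the per-voxel maximum
residual over scans rendered on a green-to-red wash. Lung masking is
threshold-based: voxels below −500 inside the largest connected body
component (filled per axial slice, so lungs crossing the cranial border
stay enclosed), morphologically closed, two largest components kept. With
independent Gaussian noise of σ per axis added to the fields, the pooled
mean approaches the 3-D chi mean σ·2·√(2/π) shrunk by the fitted model's
two degrees of freedom per 24 observations, √(22/24) ≈ 0.96 — the measured
value at σ = 0.5 mm lands within a few percent of 0.80 mm.

## Grading and statistics

Human grading (breathing irregularity, image quality, DIR quality,
suitability for treatment planning, each 1–4 best-to-worst) is out of
automation scope; the package defines the data model, CSV ingest, and an
explicitly-labeled proxy that thresholds the residual 95th percentile at
1/2/4 mm. Usability categories 1–7 group into used (1–2), backup (3–4) and
other (5–7); the summary reports counts, rounded percentages and group
means. The clinical source tables count "used" two ways (category-1–2
membership vs. scans used in planning, 118 vs 139 of 169); the summary
reports the group convention and leaves the caller's table to encode
whichever counting it means — the shipped acceptance computation uses the
139/21/9 composition that reproduces the published 82 % / 12 %.

Spearman correlations use average ranks with Fisher-z 95 % intervals
(bootstrap optional); regression is OLS with intercept, 95 % CIs, t-test
p-values, standardized β = B·sd(x)/sd(y) and adjusted R². Synthetic grade
tables come from a Gaussian copula (latent correlation 0.35 by default,
marginals matching the published grade frequencies) with a planted linear
STP score — so rank targets and regression coefficients are directly
controllable for parameter-recovery studies.

## Problem sizes and numerical defaults

Default grid 64 × 64 × 48 voxels at 4 × 4 × 2.5 mm (slice thickness and
pitch are not clinically standardized inputs here; both are configurable).
The test suite uses 32 × 32 × 24 (8-scan sessions) for unit tests and the
full default for the workflow-level checks; coarse-grid image comparisons
use a 4 %-of-range tolerance where the full-resolution equivalent holds
2 %. Field inversion tolerance 0.05 mm; covariate information threshold
1e-10 a.u.²; percentile convention linear everywhere. All simulation
randomness flows from a single integer seed; identical seeds give
bit-identical sessions.

## Known limitations

- The internal DVF convention (pull-from-reference, mm, world frame) must
  be matched by external DIR adapters; only axis-aligned grids are
  supported.
- The motion model is linear and surrogate-driven: deep-inhale
  extrapolation beyond the fitted amplitude range, surrogate nonlinearity,
  and irregular hysteresis beyond the single rate term are outside the
  model class, as in the clinical method.
- The representative-breath construction (median over normalized phase) is
  this package's own definition of an under-specified clinical procedure
  and is documented as such.
- Reconstructed intensities do not reflect density change with lung
  inflation; ventilation-style Hounsfield scaling is explicitly out of
  scope.
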