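# Methods

## Model and detection principle

Two organelles whose membranes approach within tens of nanometres cannot
be resolved as separate objects by 3D STED (~120 nm lateral / ~250 nm
axial FWHM), but the imaging physics leaves a signature: each channel is
(approximately) the indicator of its object convolved with the PSF, so
across the hidden interface channel A's intensity falls while channel
B's rises.  The same opposition holds for local curvature.  We take the
6-neighbour Laplacian of each channel and keep its negative part
(`max(-lap, 0)`), which is supported inside bright structures near their
cores and edges; at an interface the two channels' negative-Laplacian
fields vary in opposite directions, and their Spearman correlation over
a small window is negative.  The response is gated by the raw-intensity
Spearman also being negative, which rejects low-intensity signal riding
on high-intensity signal and makes identical channels (self-overlap)
produce no response at all.

The window is a cube of `(2w+1)^3` voxels with `w = 2` by default (125
samples, spanning ~350 nm at 25 × 25 × 100 nm voxels).  Larger windows
can detect fainter correlations (the minimum observable correlation
falls with sample size) but cost cubically more time and risk averaging
over opposing interaction patterns — e.g. an interface enclosed by two
mitochondria — cancelling the response.  Runtime is O(N·M log M) for N
voxels and window size M, dominated by ranking; the implementation
vectorises whole z-slabs and is chunked so memory stays bounded and
results are bit-identical regardless of chunk size.

A geometric subtlety worth recording: the anti-correlation signature
requires the interface to be *locally planar* at window scale.  For two
spheres of radius comparable to the PSF, the gap widens in every lateral
direction away from the tangent point, both channels' fields co-decay
off-axis, and the window correlation at the tangent midpoint is
dominated by that co-variation (and by concordant all-zero ties of the
clipped Laplacian) rather than by the across-interface opposition.  Real
organelle contacts are locally planar — a mitochondrion is ~1 µm wide,
an ER sheet hugs its surface — and in that regime the mid-gap
correlation is strongly negative across the whole sub-resolution
separation range and vanishes beyond roughly twice the resolution.  The
phantoms are therefore built in the planar regime (1 µm spheres; sheet
contacts), which is the physically meaningful one.

## Statistical confidence

Each window's correlation gets a two-sided p-value from the Fisher
z-transform with the Spearman variance correction,
`z = atanh(rho) * sqrt((n-3)/1.06)`, and the minimum observable
correlation at level α and power 1−β is
`rho_min = tanh((z_{1−α/2} + z_{power}) * sqrt(1.06/(n−3)))`.
Voxels with `p > α` or `|rho| < rho_min` are zeroed.  For the default
window (n = 125), α = 0.05 and power 0.95 give `rho_min ≈ 0.324`; a
simulation oracle (independent Spearman tests on bivariate-normal
samples) brackets this value in the test suite.  As α → 0, `rho_min → 1`
and the retained set empties — at full confidence no information
remains.  The stated default power comes from reading the tunables as
α = 0.05 and β = 0.05; the literal alternative (power = 0.05, a
degenerate setting) remains selectable via `power_literal`.  No
multiple-testing correction is applied across voxels: the confidence map
is a filter, not an inferential claim.

## Artifact filters

* **Bleed-through.**  The axially elongated PSF spills intensity across
  z-planes; spilled intensity is dim relative to true structure.  Voxels
  must have intensity z-score ≥ `z_filter` (default 3) in *both*
  channels, with mean and standard deviation computed over each
  channel's nonzero voxels so the statistic stays meaningful in
  mostly-empty volumes.  Because the z-score is pivotal, the threshold
  transfers across channels and acquisitions.
* **Shadow.**  Low SNR and pixelation can produce a response band
  parallel to a true interface at a few voxels' offset, where one
  channel has no local structure.  The gradient magnitude of the
  Laplacian (third derivative) is compared against a numerical zero
  (1e-8 of the field's 99th percentile — exact floating-point zeros are
  fragile); voxels where exactly one channel's third derivative is zero
  are removed.  Both-zero voxels pass: a third derivative can vanish at
  a valid contact, but only in both channels at once.
* **Vesicle filter.**  So that reported contacts involve whole
  mitochondria rather than fragments or mitochondria-derived vesicles,
  the mitochondria channel is Otsu-thresholded (on the [0,1] rescaled
  channel — the one place the pipeline segments anything, needed only
  for per-component statistics), 26-connected components are labelled,
  and a contact survives only if some component with `ln(size) ≥ 9` and
  mean rescaled intensity ≥ 0.2 lies within a 1-voxel (26-neighbourhood)
  dilation of it.  Contacts touching no component at all are removed.
  The size threshold is applied as ≥, and adjacency radius 1 voxel is
  the package's choice (contacts are reconstructed at the organelle
  boundary).

Filter order is fixed — bleed-through, gating, confidence, shadow,
labelling with minimum-size removal, vesicle filter — and every stage is
a pure mask, so retained voxel counts are monotone non-increasing; the
run manifest records and asserts this.

## Quantification

Contacts are 26-connected components of the filtered response;
components of ≤ 2 voxels are below the diffraction limit and dropped.
Per contact we report volume, the geometric mean of the per-voxel
response, and shape features from the eigenvalues λ1 ≥ λ2 ≥ λ3 of the
response-weighted covariance of physical (nm) voxel coordinates, using
the linear/planar/spherical decomposition
anisotropy = (λ1−λ2)/λ1, planarity = (λ2−λ3)/λ1, sphericity = λ3/λ1,
chosen for its sum-to-one property and testability (the source work
names the features without printing formulas).  Height is the physical
axial extent `(max z − min z + 1) × spacing_z` in nm, matching the
intuition of contacts extending over several z-slices; `2·sqrt(λ1)` is
available behind a flag.

Because contact sizes are strongly long-tailed, we additionally tile the
volume with non-overlapping cubes of `5k × 5k` lateral by `k` axial
voxels (k = 5 → 25 × 25 × 5, a physical cube under the 4:1 anisotropy;
partial edge tiles included) and record, per cube containing
mitochondria surface: surface voxels (boundary of kept components),
covered surface voxels (within the 1-voxel adjacency radius of a
contact), their ratio, and the number of distinct contact components
adjacent to the cube's surface (a contact spanning two cubes counts in
each — a density estimate).  The per-cell value is the unweighted mean
over surface-containing cubes.  The 95th volume quantile (linear
interpolation between order statistics) defines large contacts, plus a
count above a fixed 500-voxel cutoff.

Group comparisons use the two-sided Mann–Whitney test on per-cell
aggregates only (pooling contacts across cells would break independence),
with no outlier removal and no multiple-testing correction.

## Synthetic phantoms

All test data is generated: imaging is modelled as an anisotropic
Gaussian PSF (FWHM 250/120/120 nm in z/y/x, converted to voxels through
the 100/25/25 nm spacing), applied to solid geometry, with optional
Poisson noise and Gaussian noise.  Phantom noise is smoothed over 1
voxel before addition: the pipeline's intended input is deconvolved
data, whose residual noise is weak and spatially correlated — white
voxel noise at the same amplitude would be unrealistically hostile to a
curvature statistic (the documented low-SNR failure mode, reproducible
via `add_noise`, which adds unsmoothed noise).

* **Two-sphere phantom** — one 1 µm sphere per channel, separated along
  x by a controllable edge-to-edge gap; the sweep from 0 nm to the
  120 nm resolution limit probes the sub-resolution regime, and 240 nm
  (2× resolution) probes emptiness.  Noise-free by default.
* **Cell phantom** — per channel: ER sheets (designated contacts at a
  25 nm gap against mitochondria flanks, locally planar), background ER
  tubes far from everything, and a decoy tube; mitochondria as
  ellipsoids (~15,000-voxel components, above the ln-size-9 threshold)
  rendered as *membrane shells* (~2 lateral / 1 axial voxel thick),
  emulating outer-membrane labelling — this puts peak mitochondrial
  intensity at the surface where contacts form, as TOM20-style markers
  do; five vesicles (≈15 voxels, intensity 0.1) strung along the decoy
  tube, below both vesicle-filter thresholds.  The standard conditions
  (`cell_phantom_spec()`) use a 48 × 160 × 192 volume, two mitochondria,
  two designated contacts, correlated noise σ = 0.01.

Ground truth is geometric: interface voxels are outside both solids,
within one lateral voxel of the equidistant mid-gap surface, where the
local gap is within a voxel of the nominal separation (+3 lateral-voxel
allowance absorbing grid quantization and diagonal adjacency).  For the
two-sphere phantom the contact mask is defined empty beyond the system
resolution — there is no contact to reconstruct — while the geometric
mid-gap region stays available for diagnostics.  Since no physical
voxel-level truth exists for a sub-resolution interface, the tolerances
used when scoring detection against this truth are package-level
choices: recall/precision are computed with a 2-voxel (index-space)
tolerance, the window half-width, because a windowed statistic cannot
localize an interface more sharply than its own window (axially this is
also about one PSF FWHM).

## Problem sizes and numerical choices

The shipped study conditions are desk-scale: the sweep runs six
separations on 28 × 96 × 184 volumes and the cell phantom is
48 × 160 × 192 (≈1.5 M voxels), sizes at which every pipeline property
is measurable while a full suite run stays in minutes.  Zero-variance
windows (constant background) are defined as correlation 0, never NaN —
background must not respond.  Average ranks handle ties.  The w-voxel
outer shell of the response is zeroed rather than trusting replicate
padding.  Eigenvalues are clipped at 0 before the shape decomposition;
single-point contacts (unreachable under the size filter) would be
defined spherical.  The Laplacian uses voxel units — the correlation
compares the two channels voxel-wise with identical stencils, so a
common image-space stencil is consistent; a physical-units mode exists
behind `physical_units`.  The 6-neighbour stencil was chosen over
18/26-neighbour variants and is pinned by the impulse-response test.

## Validation strategy, and what it does not show

Unit oracles are independent re-computations: triple-loop finite
differences, per-window rank-then-Pearson, an arbitrary-precision normal
CDF evaluation, order-statistics quantiles, exact Mann–Whitney
enumeration, and a power simulation.  End-to-end checks use the
geometric ground truth: the sweep sign property, exact recovery of
designated contacts with vesicle decoys excluded, confidence and stage
monotonicity, determinism under fixed seeds, and coverage-ratio
stability across cube sizes k = 3..7 — the latter measured on a
uniformly coated mitochondria surface with a known coated fraction,
because the mean-over-cubes statistic is only scale-stable when coverage
is statistically uniform; a handful of isolated patches makes any
local-density mean intrinsically tiling-sensitive.

The phantoms idealise real data: no labelling-density variation, no
depletion-beam or vectorial PSF effects, no registration error, simple
convex geometry, and noise far tamer than raw acquisitions.  Passing
tests therefore demonstrate correctness of the statistic and pipeline
logic under the stated imaging model, not performance on degraded real
acquisitions.  Known failure modes carried over from that model:
misregistered channels induce false responses (registration is a
precondition, not a feature); very low SNR breaks differential analysis;
intensity transforms that relocate image curvature (e.g. cubing a
low-contrast channel) can move the negative-Laplacian support and with
it the detected voxel set, even though the intensity-rank field is
exactly invariant under any strictly increasing transform; proximate
contacts are reported as one component.
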