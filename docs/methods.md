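# Methods

`gridmech` quantifies the physical microenvironment that micropatterned
holey-carbon EM grids present to cultured cells, and the geometry of the
junctional structures imaged on them. Every analysis runs against seeded
synthetic data, so the package is testable end to end with no external
datasets. This note records the models, the parameter choices, and what
the synthetic generators do and do not emulate.

## Film stiffness from AFM force curves

**Model.** During an approach onto a suspended carbon film, the
cantilever (stiffness `k_c`, N/m) and the film (effective stiffness
`k_f`) act as springs in series. Past the contact point, a piezo
extension `z` splits as

    d_c = z·k_f/(k_c + k_f),   δ_f = z·k_c/(k_c + k_f),

so `d_c + δ_f = z` and `k_c·d_c = k_f·δ_f` hold sample-wise. The film is
assumed linear-elastic over the ~100 nm ramp; loading-rate independence
of the recovered `k_f` is the testable signature of that assumption, and
none of the estimators uses the rate tag.

**Pipeline.** (1) Optical lever sensitivity `S` (nm/V) is the OLS slope
of piezo against photodiode signal in the contact region of a
rigid-substrate (glass) scan. (2) Photodiode volts convert to deflection
as `d = S·V`. (3) Contact is the first sample exceeding the baseline
mean + 3 sd for 5 consecutive samples, with the baseline estimated on
the leading 15% of the record. (4) Film deformation and force are
`δ_f = (z − z_contact) − (d − d_baseline)` and `F = k_c·(d − d_baseline)`.
(5) `k_f` is the total-least-squares (orthogonal regression) slope of
the (δ_f, F) scatter — the first principal axis of the centered data,
from an SVD. TLS is scale dependent, so the fit is always performed in
(nm, nN); the slope is then a stiffness in N/m with no unit conversion.

Numerical conventions: fits with fewer than 20 post-contact samples are
rejected; non-positive slopes are flagged invalid and excluded from
summaries with a logged reason; zeroing δ_f at the detected contact
sample can leave a constant offset below one piezo step, which cancels
exactly in the slope. A ~95% slope CI comes from a 200-resample pair
bootstrap (internally seeded, deterministic).

**Rate comparison.** Per-rate groups are compared with a two-tailed
Student's t test assuming equal variance. Two spread-free identical
groups are reported as t = 0, p = 1 rather than NaN.

**Noise spectrum.** The measured channel is linearly detrended and fed
to a Welch periodogram (segment length ≈ fs/4). Peaks are local maxima
above 10× the median power at ≥20 Hz; the low-frequency cutoff exists
because the ramp's contact kink leaks into the lowest bins on every
curve. Segment averaging keeps the white-noise tail far below the 10×
threshold (a raw periodogram bin exceeds it about once per 10³ bins).

## Hydrogel-equivalent modulus

A vertical point load of adhesion radius `α` on an elastic half-space of
modulus `E` and Poisson ratio `ν` behaves as a spring

    k = π·α·E / ((1 − ν)(1 + ν)).

The module inverts this to express a measured `k_f` as the modulus of a
homogeneous gel, with `ν = 0.48` and `α = 1 µm` as literature-derived
configuration defaults, never hard-coded. Because `E` is linear in `k`,
the standard deviation propagates by exact scaling —
`sd_E = sd_k·(1−ν)(1+ν)/(πα)` — with no linearization error and no need
for Monte Carlo. Internals are SI (Pa, m); `*_kpa_um` helpers take the
kPa/µm units practitioners quote. In-plane traction and finite-thickness
plate bending are out of scope; the equivalence is for axial loading
only, and the reported interval is mean ± 1 sd.

Note on printed precision: forward-evaluating the relation at the
rounded inputs (207 kPa) gives 0.84500 N/m; the unrounded measured mean
(0.85 N/m) maps back to 208.2 kPa. The package reports its own computed
values and does not force agreement between rounded chains.

## Pattern topography

Maps are first leveled by subtracting a least-squares plane fitted on a
reference region (first-order only; bow correction is out of scope).
Plateau steps are differences of region medians, with a robust spread
(1.4826×MAD per region, combined in quadrature) — medians because edge
pixels straddling a step otherwise bias a mean. The pattern boundary is
traced by marching squares at the 0.5 level of the region mask (sub-pixel
crossing interpolation); the region must be simply connected.
Irregularity is summarized as the RMS normal distance of the trace from
the best-fit ideal square (center, side, orientation fitted by
least squares from multiple orientation starts, since the residual is
90°-periodic) plus the excess perimeter relative to that square. Both
metrics are rigid-motion invariant.

## Tilt-accessibility planning

Grid bars are modeled as opaque rectangular walls of height `h`: a film
point stays beam-visible through ±θ only beyond
`clearance = h·tan θ·|cos φ|` of a bar, where φ is the bar's angle to
the tilt axis (a bar parallel to the projected tilt direction casts no
shadow). With `h = 11.3 µm`, θ = 66° and φ = 45° the clearance is
17.95 µm, matching the empirically measured 18 µm limit; bar height and
the rim parameters (inner radius 1300 µm, wall height 220 µm) are
calibrated to reproduce the observed clearance and the patternable
central 10×10 block, and are labeled calibrated, not measured. The
usable region of a ~90 µm mesh opening insets by max(clearance, safety);
the 20 µm safety default leaves a 50×50 µm region, which is why
66.5 µm patterns trigger a warning rather than an error — pattern
centers, not corners, are what the visibility limit constrains, and the
planner reports both readings without enforcing one.

Yield arithmetic: with `n` patterns, success range `[s_lo, s_hi]` and
contact fraction `c`, candidate bounds are `⌊n·s·c⌋` at the two ends
(floor = conservative count of whole candidates) and the expected value
keeps the midpoint product unrounded. Defaults (n=100, 27–70%,
33.4 ± 7.3%) give 9–23 candidates per grid. The lamella junction rate is
a rounded percentage, undefined (error) for zero interpretable lamellae.

## Punctum morphometrics

The inter-membrane distance is the mean ± sd of nearest-neighbor point
distances between the two segmented surfaces, pooled symmetrically
(A→B and B→A) so neither surface's sampling dominates. Distances are
point-to-nearest-point, not point-to-fitted-surface — adequate at the
generator's densities, and documented as a limitation for sparse real
segmentations. Rods are classified clustered vs individual by a width
threshold, default 1.5× the single-rod diameter (6.75 nm for 4.5 nm
rods), configurable because no explicit cutoff is established; counts
are conserved at every threshold, and the clustered:individual ratio is
flagged undefined when no individual rods exist.

## Synthetic generators: what they emulate, and what they do not

All generators are deterministic under a fixed seed.

* **Force curves**: series-spring mechanics with Gaussian photodiode
  noise plus mains-harmonic sinusoids (defaults 60 Hz at 0.2 nm and
  300 Hz at 0.1 nm, random phase) on the deflection channel. Sampling
  rate defaults to 2 kHz — unstated in the source protocols, chosen to
  resolve the 300 Hz harmonic with Nyquist margin — and configs that
  alias a periodic component are refused. The leading 20% of the ramp is
  pre-contact baseline. Not emulated: adhesion/snap-in, hysteresis,
  retract segments, thermal drift, tip shape.
* **Topography**: passivation plateau at 2.0 nm, ECM square at 0.5 nm,
  ablated square at 0, i.i.d. pixel roughness. Edge wander is a
  periodic, Gaussian-correlated process along the square's perimeter
  (default correlation length 250 nm) applied along the max-norm radial
  direction, which keeps the boundary simple and makes its normal
  deviation from the ideal edge equal the wander value exactly — so the
  configured wander sd is the ground truth the RMS metric must recover.
  Defaults: 512 px at 25 nm/px, 5 µm squares, wander sd 50 nm when
  enabled. Not emulated: AFM tip convolution, scanner bow, feedback
  artifacts.
* **Occupancy**: independent Bernoulli draws for usable and (conditional
  on usable) contact-bearing patterns. No spatial correlation between
  neighboring patterns.
* **Junction geometry**: two membrane patches on a shared lateral grid
  (300 nm patch, 10 nm spacing) at gap 15.4 nm. Roughness is a laterally
  correlated undulation field per surface (correlation length 40 nm),
  normalized to the configured pointwise sd — membranes are smooth at
  the point-spacing scale, and uncorrelated per-point noise would bias
  the nearest-neighbor gap downward by ~0.5 nm purely through point-cloud
  discretization. Rod split is deterministic,
  `round(clustered_fraction·n_rods)` (13 of 23 by default); clustered
  widths are uniform on [6.75, 20.4] nm, individual rods are 4.5 nm.
  Not emulated: membrane curvature at the punctum, segmentation noise,
  missing-wedge anisotropy.

Passing the recovery tests therefore demonstrates that the estimators
are unbiased under these idealized conditions at realistic noise levels;
it does not certify performance against segmentation errors, drift, or
instrument artifacts absent from the generators.

## Problem sizes in the test and acceptance runs

Round-trip stiffness checks use 20 curves per rate for the median and
100 replicate experiments of 6 curves per rate (the measured design) for
the rate comparison; topography recovery uses 20 seeded 512² maps;
punctum recovery uses 20 seeded segmentations of ~1000 points per
surface. The full suite runs in well under a minute on one CPU.

## Known limitations

* TLS assumes isotropic errors in (δ_f, F); photodiode noise actually
  enters both coordinates anticorrelated, producing a small (≈0.1–0.2%)
  attenuation at the default noise levels — far inside the 5% recovery
  band but visible as the 0.848 medians in the logs.
* The equal-variance t test compares measurement-noise-limited group
  means when curves share one true `k_f`; with many curves per group it
  becomes sensitive to sub-1e-3 estimator bias differences between
  rates. The replicate design at n=6 per rate matches the power
  structure of the physical experiment.
* The shadow model treats bars and rim as opaque walls; partial electron
  transparency of gold and clip-ring geometry are ignored.
* Boundary tracing requires a simply connected pattern region; real
  segmentations with holes must be cleaned upstream.
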