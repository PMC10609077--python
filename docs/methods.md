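# Methods

## Motion model

A phantom frame's motion has two components, applied in a fixed order:
the **global drift** first (every pixel of the content translated by the
frame's shift), then the **doming deformation** (the radial
barrel/pincushion transform applied to the shifted frame).

Global drift is either:

* the parametric trajectory x(t) = a₁t + a₂t² + cos(t)/10,
  y(t) = b₁t + b₂t² + sin(t²)/5, evaluated at integer frame index
  t = 0 … n−1 with trigonometric arguments in radians. The defaults
  (a₁ = −0.039, a₂ = 0.002, b₁ = −0.02, b₂ = 0.002) combine a linear drift
  rate, a mild quadratic bend, and sub-pixel wobble, emulating drift
  commonly seen in cryo-EM exposures; or
* a fixed step: frame 0 at rest, equal increments along a constant unit
  direction, the final frame displaced by exactly `total_shift` pixels.
  The direction defaults to the 45° diagonal and is a parameter.

Doming uses r_out = r_in (1 + k₁ r_in² + k₂ r_in⁴) on **per-axis
normalized coordinates**: each axis is mapped linearly to [−1, 1] about the
geometric frame centre with the (N−1)/2 pixel-centre convention, so frame
corners reach radius √2 and anisotropic detectors deform consistently per
axis. (Normalizing by the half-diagonal instead would also be compatible
with a [−1, 1] convention; the choice is tagged `per-axis` in the
ground-truth sidecar so downstream consumers are never ambiguous.) The
coefficients grow linearly from k₁ = k₂ = 0.01 at frame 0 to 0.015 at the
last frame, making the deformation more prominent late in the exposure. At
these magnitudes the transform is strictly increasing in r — no fold-over.

The per-frame **displacement field** is the output→source map used for
warping (inverse mapping avoids scattering artifacts): for an output pixel
at normalized radius r, the source sample sits at radius
r (1 + k₁r² + k₂r⁴), converted back to pixel coordinates, minus the frame's
global shift. Zero motion yields the identity map exactly.

## Phantom synthesis

The content image is built once per movie — ice plus signal — and warped
per frame, so frames are deterministic and differ only by motion:

* **Signal**: a grid (lines every 150 px, 5 px wide, starting at pixel
  indices ≡ 0 mod step), a centred disc, or a centred cross. The signal
  adds +1 mean electron on top of the background so Poisson means stay in a
  realistic [0, 3] range; the amplitude is configurable.
* **Ice**: an i.i.d. N(0, 1) field, low-pass filtered, then linearly
  rescaled so its observed minimum and maximum are exactly 0 and 2. The
  default filter is a Gaussian whose amplitude falls to 1% at the cutoff
  frequency (pixel_size / lowpass_resolution cycles/px, default cutoff 3 Å
  at 1 Å pixels), so out-of-band power is ≤ 10⁻⁴ of in-band power — the
  field genuinely carries no content finer than the stated resolution. A
  raised-cosine roll-off (flat to half the cutoff, zero at the cutoff) is
  available as an alternative. A half-maximum-at-cutoff Gaussian was
  rejected because it leaves ~25% power at the band edge, contradicting
  the point of declaring a resolution limit for the ice.
* **Warping**: bicubic interpolation; samples falling outside the content
  are filled with the content mean, avoiding synthetic edges that would
  bias alignment. Interpolation overshoot can produce slightly negative
  means; these are clipped to zero before Poisson sampling (counted in the
  log).
* **Dose**: each deterministic pixel value is the mean of an independent
  Poisson draw. All randomness flows through `numpy.random.default_rng`
  seeded from the movie spec, so identical specs give bit-identical movies.
* **Gain/dark**: all-ones and all-zeros images at movie size, making the
  correction `(raw − dark) · gain` a verifiable no-op on phantom data.

What the generator does *not* emulate: contrast transfer, detector MTF,
realistic macromolecule projections, per-particle Brownian motion, or
dose-dependent radiation damage. Tests passing on phantoms therefore
demonstrate correctness of the geometry, statistics, and bookkeeping of an
aligner — not its performance on real specimen contrast.

## MRC I/O

Movies are stored as MRC2014: 1024-byte header, little-endian with machine
stamp, no extended header on write (the reader skips one if present), data
in z-slices. Modes 0 (int8), 1 (int16), 2 (float32, default), 6 (uint16)
are supported; integer modes reject out-of-range values instead of
wrapping. The file-size model is `1024 + nx·ny·nz·bytes_per_pixel`;
"GB" in reports means GiB (2³⁰). Gain is multiplicative after dark
subtraction — the common camera convention.

## Reference aligner

The aligner is deliberately a transparent method of the cross-correlation
family, not a re-implementation of any production tool.

* **Pairwise shifts**: FFT cross-correlation of mean-subtracted frames;
  the correlation surface is low-pass filtered (Gaussian, 4 px wavelength
  by default) to suppress shot noise; the integer peak is searched within
  ±max_shift (ties break toward the smaller displacement) and refined by a
  1-D parabola per axis over the 3×3 neighbourhood, clamped to ±0.5 px.
* **Global consensus**: all C(n, 2) pairs are measured and the
  overdetermined system s_ij = x_j − x_i solved by least squares, then
  re-referenced to the reference frame (default: middle frame, minimizing
  worst-case temporal extrapolation). Measurements are *flagged* when the
  peak saturates the search bound or disagrees with the consensus by more
  than 5 px; flagged measurements are excluded and the system re-solved.
  Alignment **fails** when more than half of all measurements — or more
  than half of any single frame's measurements — are flagged: the global
  test alone cannot trip for realistic drift geometries (at most ~⅓ of
  pairs can exceed the bound for a linear drift), while a frame that loses
  most of its own measurements genuinely cannot be placed. This reproduces
  the qualitative behaviour of production aligners whose expected-shift
  bound is set too small for the actual drift.
* **Local motion**: frames are shifted back by the global estimate, the
  frame is divided into the patch grid (auto: 5×5 below 5000 px width,
  7×5 above), and each patch's per-frame residual shift is measured
  against the patch's temporal mean (chosen over all-pairs per patch for
  tractability; a documented deviation from any specific published
  aligner). Patches may overlap: the patch side is
  max(min(dims)//grid, 128) px, and the grid is inset from the frame
  border by the observed drift plus 2 px, keeping the drift fill band out
  of the measurements. A tensor-product cubic B-spline over (x, y, t) —
  grid+3 coefficients per spatial axis, n/2 interior temporal knots — is
  least-squares fitted to all patch shifts (fit tolerance 0.1 px at the
  patch centres).
* **Micrograph synthesis**: each frame is warped by the inverse of its
  estimated motion (global + spline local) with cubic-B-spline (default),
  linear, or Fourier-phase-ramp interpolation, then combined as the
  average (default) or the sum; the two conventions differ exactly by the
  frame count. Linear interpolation attenuates power near Nyquist more
  than cubic B-spline — the ordering the package's damping comparison
  asserts.

## Quality metrics

* **Windows**: 512×512 crops at the top-left corner, centre
  (⌊(H−512)/2⌋, ⌊(W−512)/2⌋) and bottom-right corner; the centre window is
  additionally normalized to mean 0 / sd 1.
* **CV**: computed on raw values after discarding values outside
  [Q₁₀ − 1.5·IQR₈₀, Q₉₀ + 1.5·IQR₈₀], IQR₈₀ = Q₉₀ − Q₁₀ (the 1.5 fence is
  configurable); CV = 100·sd/mean.
* **Radial PSD**: |FFT|² azimuthally averaged into ⌊min(dims)/2⌋ bins by
  integer-rounded radial frequency (bin i ↔ i/min(dims) cycles/px);
  corner frequencies beyond the last bin are excluded from the profile but
  retained in the total (Parseval-checked) energy. No apodization by
  default.
* **Resolution limit**: the resolution (Å) of the first bin whose power
  drops below 1/100 of the origin; Nyquist (2·pixel_size) if none does.
  The origin reference is true DC by default; a `first-band` option uses
  the first non-DC bin instead, the practical choice for untapered
  micrographs whose mean offset concentrates arbitrary power at exact DC.
* **Shift RMSE**: both trajectories are re-referenced to the estimator's
  reference frame (the gauge cancels), then the RMS of per-frame Euclidean
  errors is taken over all frames including the reference.

## Statistical harness

One-way ANOVA (scipy `f_oneway`) on a per-(program, movie) metric table;
if significant at α (default 0.05), paired t-tests for every program pair,
paired by movie — the design must be balanced. Both the uncorrected
decision (the protocol's own) and a Bonferroni-adjusted one are reported.
Zero-variance difference pairs are degenerate: all-zero differences give
p = 1; a constant non-zero difference is flagged and treated as
significant. Pixel-distribution comparisons use the two-sample KS test
after per-image standardisation (mean 0 / sd 1, so output conventions
cannot drive the test; an un-normalized mode exists for raw comparisons).
Standardised values are quantized at 10⁻⁶ sd before testing: micrographs of
count data carry heavy ties, and float rounding would otherwise split
those atoms between scale-equivalent inputs, inflating the statistic by
the atom mass. Megapixel images are over-powered for KS, so pixels are
subsampled (default 10⁵, seeded; two generators with one seed so equal-size
images are sampled at identical positions).

## Problem sizes and calibration checks

The package's own test battery runs at desk scale: 512×512×10 movies
(640×640 for the expected-shift-bound failure/recovery demonstration,
where max_shift = 150 must stay below min(dims)/4), 10 seeded replicates
for the doming corner-vs-centre signature, 200 replicates for the Poisson
convergence check on 64×64 frames, and 1000 null simulations (3 groups,
n = 10) for the ANOVA type-I calibration. These sizes give comfortable
statistical margins for every asserted contrast while keeping the whole
battery to well under a minute per component.

## Known limitations

* The simulator's doming is a pure radial polynomial; real doming includes
  astigmatic and non-centred components.
* The aligner's all-pairs global solver is O(n²) in frames — fine for
  10–70-frame movies, deliberately simple rather than fast.
* The grid signal is periodic (150 px), so pairwise shifts approaching the
  grid period are ambiguous for noiseless grid movies; the consistency
  pass rejects aliased measurements but cannot recover them.
* The Fourier interpolation path applies the exact phase ramp for the
  global shift only; a local field, if present, is applied on top with
  cubic interpolation.
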