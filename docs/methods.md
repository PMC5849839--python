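# Methods

## Model

The package predicts electron cutout output factors under two assumptions:

1. **Radial isotropy** — the output contribution of an open beamlet depends
   only on its distance from the calculation point, so the per-pixel
   contribution kernel is circularly symmetric.
2. **Shift invariance** — the contribution pattern does not change as the
   calculation point moves across the cutout plane, so the total output is a
   convolution of the kernel with the binary aperture.

Both assumptions ignore the angular dependence of scatter at off-axis
points and near cutout edges; this is the method's main physical
approximation and the reason predictions degrade for highly irregular
shapes (hence the P2A caution flag).

### Curve representation

Measured circular-field output factors OF(r_i) are interpolated by a
shape-preserving monotone piecewise cubic (PCHIP) through the samples plus
the pinned origin (0, 0); piecewise-linear interpolation is available as an
option. Above the largest measured radius the curve is extrapolated as a
constant, because measured circular-field curves level off by r ≈ 4 cm.

Two conventions are deliberate choices rather than measured facts:

* **OF(0) = 0.** A fully blocked field delivers no output, and this pin
  makes the annular decomposition telescope exactly (see below). The
  behavior of OF below the smallest measured radius (1 cm) is therefore the
  interpolant's, not a measurement.
* **Constant extrapolation** beyond r_max, consistent with the observed
  plateau; it makes all annular differences vanish there, so the kernel
  support can default to the largest measured radius.

### Kernel construction

With annulus width Δr (default: the 1 mm pixel pitch) the annular output
factor is AOF_k = OF((k+1)Δr) − OF(kΔr). Each pixel is assigned to the
annulus containing its center distance, with half-open bins
[kΔr, (k+1)Δr); every pixel of annulus k receives AOF_k / N_k, where N_k is
the number of kernel pixels in annulus k. Pixel-center binning (rather than
area-overlap weighting) makes N_k well defined and yields the exact
telescoping identity

    Σ_{pixels with annulus index < K} OK = OF(K·Δr),

for every K, independent of resolution — circular fields are reproduced by
construction, and this identity is the backbone of the test suite.

Negative AOF values can arise from measurement noise. By default they are
kept (clipping would break telescoping) and the kernel is flagged; clipping
or a hard error are options. Differences below 1e−12 are attributed to
interpolation round-off and not flagged.

### Convolution

Two engines compute COF = OK ∗ f over the padded aperture grid with zero
(blocked) boundary:

* `direct` (default): accumulation of weighted whole-array shifts, one per
  non-zero kernel pixel, in a fixed order. Each output value is the same
  sum of the same numbers regardless of where the aperture sits on the
  grid, so whole-pixel translations of the mask translate the map
  *bit-identically* — the discrete counterpart of the shift-invariance
  assumption, and cheap enough (≈0.4 s for a 6 cm kernel on a 20 cm grid)
  for routine use.
* `fft` (`scipy.signal.fftconvolve`): for large grids or batch work; agrees
  with the direct sum to ~1e−14 absolute. Round-off negatives (~−1e−17)
  are clamped to zero when the kernel is non-negative.

The mask must carry at least a kernel half-width of zero padding so that no
open pixel's neighborhood is truncated; `compute_cof_map` enforces this and
names the required padding in its error.

### Rasterization

A pixel is open iff its center lies inside the polygon. Pixel centers sit on
integer multiples of the pitch in the cutout plane (so whole-pixel polygon
translations translate the mask identically), and centers exactly on an
edge are resolved half-open — left/bottom edges included — implemented as an
infinitesimal (+x, +y) nudge of the test points. The aperture is *not*
magnified for extended SSD: kernels are built per-SSD from fixed-size
physical cutouts, so beam divergence is absorbed in the per-SSD curves.

### Inverse-square SSD extension

For radii ≥ 4 cm (configurable), where the effective SSD no longer varies
appreciably with field size, extended-SSD output factors are derived as
OF_ext(r) = OF₀(r) / F with F = ((SSD_eff + d_max + SSD_ext − SSD₀) /
(SSD_eff + d_max))². Smaller radii must be measured directly and merged
(`merge_curves`). The effective SSD is user input from commissioning data,
not estimated. The percentage difference used to compare two predictions is
symmetric, with the arithmetic mean in the denominator:
100·|a − b| / (½(a + b)).

### Gamma analysis

Per reference point, γ is minimized over a search disk of radius 3×DTA,
sampling the evaluated distribution on a 3× bilinearly upsampled grid; dose
differences are normalized globally at the reference maximum (local
normalization is an option). The passing rate counts points with
γ ≤ 1 (with 1e−9 slack for criterion-boundary round-off) among points at or
above a 10% low-dose threshold; reference points whose full search window
leaves the evaluated extent are excluded from the denominator and counted
separately. Search radius, upsampling factor and threshold are parameters;
the defaults are bounded, reproducible, standard practice.

## Synthetic data

The generators emulate the *structure* of commissioning data, not any
particular linac:

* **Curves**: OF(r) = plateau·(1 − exp(−(r/λ)^p)) sampled at 1–6 cm in 1 cm
  steps, optional truncated Gaussian noise. Presets "6E-like"
  (plateau 1.0, λ = 1.6 cm, p = 2.0), "9E-like" (0.9, 1.2, 1.8) and
  "15E-like" (0.8, 0.9, 1.6) reproduce the qualitative energy trend:
  asymptotes near 1 / 0.9 / 0.8, plateau reached by ~4 cm, kernel output
  concentrated at the center for high energy and spread towards the edge
  for low energy. Any monotone plateauing family would serve; the tests
  depend on the shape properties, not the formula.
* **Cutouts**: circles (regular n-gons), rectangles, and irregular outlines
  r(θ) = R(1 + a·Σ_k c_k sin(kθ + φ_k)) with seeded coefficients normalized
  so the perturbation stays within ±a; for a < 0.5 the outline is
  star-shaped and hence simple.
* **Film**: a computed COF map resampled with a rigid sub-pixel shift plus
  seeded Gaussian noise (percent of map maximum), emulating a registered
  film scan.

What passing tests on these fixtures show: the algorithmic identities
(telescoping, shift invariance, circular-field recovery, gamma closed
forms) hold exactly or to stated tolerance. What they do not show: accuracy
against real chamber or film measurements, which depends on how well the
isotropy/shift-invariance assumptions hold for a physical beam.

## Numerical choices

* Annulus binning adds 1e−9·Δr to the distance/width quotient before
  flooring so Pythagorean-exact boundary distances (e.g. offset (3,4) at
  d = 5) land in their correct outer half-open bin.
* Disk-recovery through rasterized polygon circles is accurate to ≲0.4%
  (128-gon, 1 mm pixels); the annulus-binned disk itself recovers OF
  exactly.
* Gamma for identical fields is zero only up to interpolation round-off
  (~1e−14) because the sub-pixel resampling evaluates the grid through an
  interpolator; uncorrelated film noise is largely *absorbed* by the
  sub-pixel DTA search (some nearby sample usually matches), so noise
  degrades mean γ long before it lowers the passing rate — systematic
  offsets beyond the dose criterion do fail.
* Map point queries default to nearest-pixel (chamber positioning is ~1 mm);
  bilinear is optional. Maximum ties break at the smallest row-major index,
  and all pixels within 0.1% of the maximum are reported as a plateau set.
* P2A classification is inclusive at the cutoff (P2A = 30 → "reliable").

## Problem sizes

Default study sizes keep the full suite and the acceptance script fast:
6 cm kernels (119×119 px at 1 mm), apertures of 2–6 cm with full kernel
padding, gamma grids of ~50–200 px per side, 100-curve/20-pair/1000-polygon
property sweeps. All scale linearly if larger fields are needed.

## Known limitations

* Single simple polygons only; multi-hole apertures are rejected.
* No applicator-size dependence beyond a label (one cone per curve set), no
  depth dependence (d_max plane only), no absolute dose or MU computation.
* No estimation of effective SSD from measurements.
* Accuracy claims for highly irregular shapes (P2A > 30) are explicitly out
  of warranty — that is what the caution flag means.
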