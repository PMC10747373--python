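# Methods

## The selection rule

Given a thin-detector image `T` (sharp, noisy) and a thick-detector
image `K` (blurry, clean) of the same scene, the package denoises `T`
with non-local means at each h on a fixed grid and traces

* `EPI(h)` — edge preservation of `NLM(T, h)` against `T` itself,
  over an edge-bearing ROI;
* `SNRn(h)` — `SNR(NLM(T, h)) / SNR(K)` over a homogeneous ROI,
  which puts the noise measure on the same 0…~1 scale as the EPI.

`EPI` starts at ~1 and falls with h (smoothing erodes the Laplacian
response that the index correlates); `SNRn` starts at
`SNR(T)/SNR(K) < 1` and rises. The selected h\* is the first grid
interval where the curves cross, refined by linear interpolation of
`d(h) = EPI − SNRn` to zero — in log₁₀ h on the default log grid, in h
on a linear grid. An exact tie at a grid point selects that point;
when the curves never cross the result carries a `no_crossing` status
rather than an exception, and `apply()` refuses to run. When several
crossings exist the first (lowest h) is taken: it favours sharpness,
which is the quantity the framework exists to protect.

Grid default: 100 log-spaced steps over [10⁻³, 10⁻¹]. The range spans
two decades, so log spacing gives uniform relative resolution;
linear spacing is available by configuration.

## Non-local means

`NL(i) = Σⱼ w(i,j) I(j)` with `w(i,j) ∝ exp(−d(i,j)/2h²)` and
`Σⱼ w(i,j) = 1`, where `d(i,j)` is the unweighted mean squared
difference between the square patches centred on i and j, and j runs
over a square search window around i. Defaults: 3×3 patches inside 5×5
windows — the centred odd-sized equivalents of the nominal 2×2
patch/window sizes, which cannot be centred on a pixel. Patches and
windows that overhang the image use reflective padding, so the weights
sum to one everywhere and the output at each pixel stays inside the
range of its search window (convexity). The self-weight is kept as
computed (exp(0) = 1 before normalization).

Intensities are normalized to [0, 1] before weighting and restored
afterwards, so h is dimensionless and the grid above is meaningful for
16-bit inputs. Normalization uses the image's declared native range
(e.g. 0…65535 for a 16-bit detector, attached by the simulator and the
TIFF reader) and falls back to the image's own min/max when no range
is declared. Normalizing by the native range — rather than per-image
min/max — is what makes h transferable: the h\* derived on an edge
scene can then be applied to flat-field frames of the same detector
(whose own min/max would be just the noise excursion) and to any later
acquisition, which is the entire point of pre-computing the parameter.

Two evaluation paths share one contract: a vectorized path (one
shifted-difference pass per window offset, patch distances via a
uniform filter) used everywhere, and a brute-force path that
enumerates every pixel pair and exists as the independent oracle in
the tests (agreement to 10⁻¹⁰ is asserted, including under randomized
patch/window geometry).

## Quality metrics

**EPI.** Both images are filtered with the 3×3 four-neighbour
Laplacian ([[0,1,0],[1,−4,1],[0,1,0]], reflective boundaries) over
their full extent; the responses are then restricted to the ROI,
mean-subtracted, and correlated: `EPI = Γ(a,b)/√(Γ(a,a)Γ(b,b))` with
`Γ(a,b) = Σ ab`. Filtering before ROI extraction avoids ROI-edge
artefacts. The index is symmetric, affine-invariant, 1 for identical
images and −1 for a sign-inverted edge field. A constant Laplacian
response inside the ROI makes the ratio undefined and is rejected
distinctly from a shape mismatch.

**ROI SNR.** Mean divided by the population (divisor N) standard
deviation over the ROI. Population vs sample is numerically immaterial
for realistic ROI sizes but is fixed so that exactness tests are
well-defined. A zero-spread ROI is rejected as "homogeneous".

**No-reference score.** BRISQUE-style scoring is an adapter only: an
installed backend (or an injected callable) is delegated to unchanged;
without one a capability error names the optional dependency group.
The score's internals are out of scope here.

## NNPS

From M flat-field frames: subtract the ensemble-average frame S, tile
each difference into square ROIs (size 128 by default, 50% overlap),
average `|FFT|²` over all ROIs and frames, scale by
`Δx·Δy/(Nx·Ny)` and divide by the squared grand mean of S. Units mm².
For white noise of variance σ² on mean μ this gives a flat spectrum at
`σ²Δ²/μ²` times `(1 − 1/M)` — the variance absorbed by subtracting the
ensemble mean. No `M/(M−1)` correction is applied: the estimator then
satisfies Parseval's identity against the directly measured variance
of `I − S`, which is the self-consistency the tests check, and the
small bias (6% at M = 16) vanishes as frames are added. No polynomial
detrending is applied; simulated flats have no heel effect.

1-D reductions: the axial curves average 7 lines (configurable) on
each side of — and excluding — the zero-frequency axes, folded over
±f; the radial curve bins off-axis values by √(f_u² + f_v²) with bin
width equal to the frequency sampling interval. The DC bin and both
zero-frequency axes are excluded from every 1-D average, since DC
holds residual mean rather than noise power. Curves run up to Nyquist
= 1/(2·pitch).

Defaults (ROI 128 on a 512 × 1024 frame, overlap 0.5, band half-width
7) follow standard detector-characterization practice scaled to the
simulated image size.

## Slanted-edge MTF

A roughly vertical edge tilted 1–3° staggers its sub-pixel phase
across rows. Per row, the edge position is the centroid of the
absolute row derivative, localized to ±10 px around the derivative
peak with a 2×MAD noise floor subtracted — without the localization
the noise floor drags the plain centroid toward the ROI centre and
biases the angle low on noisy inputs. Rows whose derivative maximum
does not exceed 5× the row MAD are dropped; fewer than 10 usable rows
is a rejection. A least-squares line through (row, position) gives the
tilt.

Pixels are projected onto the edge normal and binned at pitch/4 (or
pitch/8) into an oversampled ESF; isolated empty bins are filled by
linear interpolation, more than 10% empty is a rejection (the tilt is
too small for the oversampling). Central differences give the LSF, a
Hann window centred on the LSF peak suppresses tail noise, and |FFT|
normalized at DC gives the MTF. Two known signatures of the estimator
itself are divided out — the boxcar aperture of the binning,
`sinc(f·Δb)`, and the central-difference response, `sinc(2f·Δb)` —
which is what brings the estimator within 2% of the analytic
pixel-aperture MTF of an exactly rendered noiseless edge. f10 is found
by linear interpolation between the bracketing samples; a curve that
never falls below 0.10 before Nyquist reports f10 = Nyquist with an
explicit flag.

## The simulator

The detector chain is operational, not physical: noiseless scene →
Gaussian PSF (σ in mm, reflective boundaries) → gain scaling → Poisson
sampling per pixel → additive Gaussian read noise → clip to the
quantizer range and round. Same seed, same output, bit for bit.
Scintillator thickness is represented purely as a blur/noise operating
point; no light transport, energy-dependent absorption, optical
cross-talk, or lag is modelled. Consequences worth knowing: the noise
is white (the PSF blurs the scene, not the quanta), so simulated NNPS
curves are flat apart from the signal term, whereas real scintillator
NNPS falls with frequency; and the flat-field has no gain map, heel
effect, or structured noise. Passing tests therefore demonstrate the
estimators and the selection logic, not radiographic realism.

Scenes: uniform flats; square-wave bar groups (rejected at or above
Nyquist); and a tilted two-level step rendered with exact per-pixel
area fractions (piecewise-linear clipped integration, cross-checked
against polygon clipping), which makes the rendered edge an analytic
MTF reference.

Presets (package defaults, chosen as a usable emulation of the
thin/thick trade-off, not measurements of any physical screen):

| preset | PSF σ (mm) | gain | read noise (counts) |
|--------|-----------|------|---------------------|
| thin   | 0.050     | 40   | 280                 |
| thick  | 0.100     | 80   | 60                  |

with pitch 0.048 mm, 16-bit output, and a default fluence of 750
(thin mean ≈ 30 000 counts, thick ≈ 60 000). These values were set by
two analytic requirements: the thin detector's total noise is ~0.5% of
full scale, which places the NLM weight transition — and hence the
EPI/SNR crossing — in the interior of the standard h grid rather than
at its edge; and both PSFs are wide enough that the 10%-MTF
frequencies (≈ 6.7 and ≈ 3.4 lp/mm) fall strictly below the 10.4 lp/mm
Nyquist frequency, so resolution orderings are measurable. The thin
preset's noise is dominated by the additive term; it stands in for all
non-quantum noise of an under-exposed thin screen.

The standard simulated study (`simulate_edge_pair`) images one tilted
edge (2.8°, contrast 0.75) with both presets under independent noise,
and lays out the sweep ROIs: an edge-straddling EPI ROI, a disjoint
homogeneous SNR ROI on the bright side, and an MTF ROI.

## Problem sizes and numerical notes

* Default study geometry for tests is 256 × 256 with a 25-step sweep;
  `scripts/acceptance.py` runs the full 100-step sweep at 512 × 1024
  and uses 8-frame 256 × 256 stacks (ROI 64) for the NNPS ensembles.
  These are the package's standard fixtures; all orderings they check
  are scale-free.
* The sweep caches only the normalization denominator `SNR(K)`; each
  step is an independent full-image denoise.
* Monte-Carlo tolerances in the tests follow the estimators' known
  sampling behaviour (e.g. white-noise NNPS within 10%, Parseval
  within 5%, frame-doubling variance halving within 30%); RNG seeds
  are fixed so the suite is deterministic.
* At large h the NLM output saturates toward the window mean and its
  residual std can wiggle at the 10⁻⁴ relative level; monotone-
  smoothing checks allow that much slack.
* Degenerate inputs are first-class contract cases: noiseless flats
  (zero-std SNR ROI), constant Laplacian ROIs, edges aligned exactly
  with the pixel grid (allowed in rendering; too little tilt is
  rejected by the MTF estimator via the empty-bin rule), and sweeps
  with no crossing.

## Known limitations

* f10 differences between the thin input and its h\*-restored version
  are small (the crossing deliberately picks an h that barely touches
  edges); at large image sizes the two values can sit within the MTF
  estimator's own noise of each other.
* The no-reference (BRISQUE) hook requires an external backend; none
  is bundled.
* The simulator's noise is spatially white; colored-noise NNPS shapes
  appear only in tests that blur the noise explicitly.
* Only single-frame, single-domain NLM is implemented; multi-scale
  variants and joint patch/window optimization are out of scope.
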