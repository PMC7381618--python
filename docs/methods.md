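# Methods

## Geometric surface-area model

The model treats a muscle fibre as a perfect cylinder and the T-tubule
system as a set of elliptical tubes, one plane per sarcomere. Its inputs and
defaults:

| parameter | meaning | default | units |
|---|---|---|---|
| `length_L` | fibre length | — | µm |
| `diameter_D` / `cross_section_C` | fibre diameter or cross-section (one derives the other via *C* = π(*D*/2)²) | — | µm / µm² |
| `d1`, `d2` | tubule ellipse axes | 59.24, 96.47 | nm |
| `sarcomere_s` | sarcomere length = tubule spacing | 1.9 | µm |
| `myo_slope`, `myo_intercept` | myofibril area vs fibre area | 0.95, −13.55 | —, µm² |
| `furrow_slope`, `furrow_intercept` | furrow length per Z-line vs myofibril area | 1.26, 6.06 | µm⁻¹·µm², µm |
| `somite_poly` | somite width vs days post fertilisation (cubic) | 0.2, −2.6, 17, 65 | µm |

The implementation composes the unsimplified chain
perimeter × (L/s) × (1.26·(0.95·C − 13.55) + 6.06) and is verified in tests
to agree with the algebraically factored diameter and area forms to 1e−9
relative. Units are fixed by contract — `d1`/`d2` in nm, lengths in µm — and
the single nm→µm conversion lives inside the perimeter function.

**Domain of validity.** The myofibril regression goes non-positive for fibre
cross-sections below ≈ 14.26 µm²; the model raises a domain error there
rather than clamping, so invalid extrapolation is loud. The Z-line count
L/s is real-valued, matching the model's symbolic use of it (no flooring, no
terminal-Z-line correction).

**Intercepts.** The sizes at which SA_TT = SA_SL come from closed forms
derived by equating the two area expressions: for fixed *D*,
L = (πD²/2)/(g(D) − πD) with g(D) = d(SA_TT)/dL; for fixed *L*, the equality
is a quadratic in *D* whose unique positive root is returned (smaller root
with a warning if both were positive, not observed with defaults). All
constants are carried unrounded, so the two areas agree to better than 1e−10
relative at the returned point; rounded-constant versions of the same
formulae agree with ours to about 1e−4 in *L*. Non-positive solutions are
reported as a no-intercept value, not an error: short or thin fibres whose
tubule system can never catch the sarcolemma are a meaningful regime.
Non-default ellipse or allometry coefficients flow through the same algebra,
which remains closed-form; no numeric root-finding is needed.

**Stage presets.** The four shipped presets (48 hpf: L = 90.23 µm,
C = 192.04 µm²; 5 dpf: 107.77/290.42; 10 dpf: 158.83/560.86; adult:
580/1256.64) are canonical as printed. The somite-width cubic is provided
for completeness but is not used to regenerate them: its published
coefficients are rounded and reproduce the preset lengths only approximately
(110.0 vs 107.77 at 5 dpf, 175.0 vs 158.83 at 10 dpf). Growth rates divide
the change in total membrane (TT + SL) by the elapsed time between stages:
4320 min for 48 hpf→5 dpf and 7200 min for 5 dpf→10 dpf. Reported integers
round conventionally; internal comparisons use 0.1% relative tolerance to
absorb rounding in the published inputs.

## Morphometric tracing and fitting

ROIs form a three-level hierarchy with the tracing rules enforced as vector
geometry (shapely): a new fibre is trimmed to abut existing fibres (earlier
ROIs win — order-dependent by design, as in sequential manual tracing);
myofibrils are clipped to their parent fibre and named after it
(`<fibre>-myo<k>`); furrow polylines are clipped to their parent myofibril.
Furrows are genuine polylines and their measurement is arc length, not thin-
polygon area. Coordinates are 0-based pixel corners, origin top-left, so a
w×h-pixel rectangle has area w·h; areas use the shoelace formula ×
pixel-size², orientation-independent. ROIs serialise to transparent JSON
rather than any binary ROI format; an importer builds fibre ROIs from
integer label masks by contour tracing. Byte-identical replication of any
particular tracing tool is not claimed — the rules, not the rasteriser, are
the contract.

Regression is ordinary least squares on a polynomial design with classical
standard errors from the residual variance (spreadsheet-LINEST behaviour),
cross-checked in tests against an independent simple-regression
implementation to 1e−9.

## Image quantification

All measurements run on median-prefiltered data (disc footprint, radius 1 px
by default, replicate padding) to suppress single-pixel spikes; radius 0 is
the bit-exact identity.

* **Amplitude** is peak-to-trough (max − min) of the y-averaged profile over
  a box spanning an array of eight tubules. The published procedure says
  only "amplitude"; max − min is the simplest faithful reading, and a
  per-period mean peak-to-trough would be a drop-in alternative. The
  expressing/wildtype percentage is only defined for boxes from the same
  image (enforced by the API taking a single image).
* **Domain scoring** samples circle ROIs; the default radius is the apparent
  tubule half-width (380 nm / 2 / pixel size, rounded up), configurable,
  chosen to stay within the visible tubule. Enrichment is the ratio of raw
  domain means (no per-marker normalisation before ranking); the
  significance gate is a ≥10% TT-over-IT increase. No multiple-testing
  correction is applied across markers — raw two-tailed Welch p values are
  reported, a documented caveat.
* **Spacing** uses the autocorrelation of the mean-subtracted profile: first
  local maximum at positive lag, refined by a three-point parabola, declared
  significant only when it rises 3× above the autocorrelation noise floor
  (median absolute level beyond the central peak); among near-equal peaks the
  earliest within 80% of the tallest is preferred so the fundamental period
  beats its harmonics. Constant traces return a no-period result.
* **Welch's t** uses the unequal-variance statistic with Welch–Satterthwaite
  degrees of freedom and two-tailed p (scipy's implementation behind the
  package surface).

## Synthetic data

The fluorescence generator renders two cells side by side — expressing left,
wildtype right — mirroring the internal-control design. Tubules are
vertical stripes, Gaussian in x (FWHM = apparent width, 380 nm default,
the standard proxy for a diffraction-limited line), constant in y, at 1.9 µm
spacing on a 0.1 µm pixel; an optional sarcolemma band runs along the top
and bottom edges. The expressing cell's stripe contrast is scaled by the
perturbation factor. The marker channel is piecewise-constant over the
domain masks at `signal_level × enrichment` with the inter-tubule domain as
baseline, so the ratio of noiseless domain means equals the generating
enrichment exactly. Noise is Poisson on the clean image followed by additive
Gaussian read noise (sd 10 counts on a 100/400 background/signal), clipped
at zero; everything is driven by one `numpy` PRNG seed and identical
parameters give bit-identical scenes. Default scene size is 360×110 px —
about eight tubules per cell, matching the eight-tubule measurement box.

The morphometric generator places rectangular fibres in a non-overlapping
row, each wrapping a myofibril rectangle and a serpentine furrow whose
exact areas/lengths realise the allometric relations (plus optional Gaussian
scatter on the myofibril area and furrow length); the recorded truth is an
analytic property of the generated polygons, so extraction must agree with
it to floating-point precision.

What the generators do **not** emulate: optics (no PSF convolution or
z-sectioning), fibre curvature or irregular outlines, heterogeneous
staining, fragmented tubules, and EM texture. Passing recovery tests
therefore demonstrates correctness of the measurement logic under the stated
noise model, not robustness to every property of real micrographs.

## Validation problem sizes

The recovery suites use 200 seeded replicates per statistic (spacing,
enrichment, perturbation, marker ranking, allometry), 12-fibre morphometric
scenes with 5 µm² scatter, and 5000 null replicates at n = 6 per group for
the Welch type-I calibration — sizes chosen to give stable rates while
keeping the full suite fast on a single CPU (≈half a minute).

## Known limitations

* The allometric regressions are empirical for developing zebrafish trunk
  muscle; applying the model to other muscles means refitting them.
* The model ignores tubule tortuosity, longitudinal elements and the
  sarcoplasmic reticulum; it predicts Z-line-associated transverse tubules
  only.
* Ranking determinism under exact enrichment ties relies on name order.
* The ROI trimming is order-dependent by design; re-tracing in a different
  order can change boundaries between abutting fibres.
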