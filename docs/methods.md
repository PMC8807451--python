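# Methods

This note documents the models behind `ctiq`, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Reconstruction emulation

Non-linear CT reconstructions (hybrid/model-based iterative, deep-learning)
are represented purely by their measurable image-domain signature:

* **Sharpness** — an isotropic Gaussian point-spread function of scale
  `blur_sigma` (mm).  Convolution uses periodic boundary handling, which
  preserves the image mean exactly; rendered phantoms are bordered by
  uniform air, so wrapping does not contaminate measurement regions.
* **Noise texture** — a stationary zero-mean Gaussian random field whose
  2D power spectrum is proportional to a radial shape `S(f)` and whose
  pixel SD is calibrated to a target value (in HU).  Synthesis is spectral:
  white noise is filtered with `sqrt(S)` on the FFT frequency grid, the DC
  component is zeroed, and the filter is scaled so the *expected* pixel
  variance equals the target; the sample variance of a 512² field is
  within a few percent of it.

`S(f)` is a two-lobe family, `a·exp(−f²/2s₀²) + b·f·exp(−f²/2s₁²)`
(cycles/mm): a low-frequency lobe plus a band-pass lobe peaking at `s₁`.
The presets (`mbir_like`: low-frequency-heavy, "blotchy"; `dlr_like`:
band-pass at 0.28 cycles/mm, "fine grain"; `hir_like`: mid-band) emulate
the qualitative texture range of clinical reconstruction families.  They
are an emulation of texture classes, not a claim about any vendor's
algorithm; no projection-domain physics (beam hardening, photon
starvation, non-stationarity across the field) is modelled.

**Dose coupling.**  The automatic-exposure-control *noise index* NI is the
target pixel SD at 5 mm slice thickness.  Noise variance scales inversely
with slice thickness, so the thin-slice target is
`SD(t) = NI·sqrt(5/t)` — e.g. NI 35 HU at 0.5 mm gives 110.7 HU, and
doubling NI quadruples the variance.  A reconstruction's `noise_sd`, when
set, overrides this mapping (AEC internals are proprietary; the mapping is
a modelling convention, and deliberately explicit).

## Phantom rendering

Phantoms are a disk or ellipse body (air outside, −1000 HU) with optional
cylindrical inserts.  The QA phantom carries the standard material ladder —
air −1000, polypropylene −105, water 0, acrylic +120, Delrin +340, Teflon
+940 HU — on a 60 mm ring inside a 100 mm water-equivalent disk; the
abdomen phantom is a uniform 33 cm × 22 cm ellipse.  Default rendering is
**area-fraction antialiasing**: pixels crossing a region boundary take the
area-weighted HU mixture, computed by 8×8 sub-pixel quadrature on the
boundary band only (interior/exterior pixels are classified by signed
distance).  A **pixel-centre** mode (value of the region containing the
pixel centre) is retained as the brute-force oracle used in tests.
Geometry that places an insert outside the body, or a body outside the
grid, is rejected.

## TTF estimation

1. **Centre detection** — robust medians estimate the insert and local
   background levels; pixels above half contrast within 1.3× the nominal
   radius are labelled, the connected component nearest the initial guess
   is kept, and its contrast-weighted centroid is refined once.  The
   refinement shift is reported as a diagnostic.  Detection requires at
   least 20 HU of local contrast (configurable).
2. **Radial ESF** — every pixel with distance within ±w of the nominal
   radius contributes (r − R, HU); samples are averaged in bins of 0.1
   pixel (the circular edge supplies dense sub-pixel phases).  Default
   annulus half-width: min(6 mm, 0.6·R).  Multi-slice stacks are pooled at
   the ESF level — noise averaging happens before differentiation, not by
   averaging final TTFs.
3. **LSF** — the ESF is resampled to its uniform bin grid (dropped empty
   bins filled by linear interpolation) and differentiated centrally.
   Savitzky–Golay pre-smoothing is available but **off by default**: it
   biases the TTF downward, and the dense radial binning already averages
   noise.
4. **TTF** — the mean of the outer 10% tails is subtracted as baseline, a
   Hann window tapers the LSF, and the magnitude of the real FFT is
   normalised to 1 at DC (exactly, by construction).  TTF50/TTF10 are the
   linearly interpolated first downward crossings.

Validation uses Gaussian optics: a disk of radius R blurred with a
Gaussian PSF has the exact radial profile
`E(r) = ΔHU · P[χ²₂(nc = (r/σ)²) ≤ (R/σ)²]` — a noncentral-χ² CDF with 2
degrees of freedom — which approaches the planar edge `ΔHU·Φ((R−r)/σ)` for
R ≫ σ, and the closed-form transfer function `exp(−2π²σ²f²)`.  On
noiseless synthetic inserts the estimated TTF tracks the closed form
within 0.03 (absolute modulation) up to 1 cycle/mm, and within 0.08 with
5 HU noise over a 20-slice pool; bin-level ESF agreement with the exact
disk profile is better than 1% of contrast on a well-sampled fixture
(σ = 3 px).  The curvature of a circular edge costs ~σ/(2R) relative to
the planar CDF — visible at 15 mm radius, which is why the exact disk form
is the test oracle.

## NPS estimation

Uniform regions are tiled into 128-pixel ROIs with 50% overlap
(deterministic raster; the overlap-induced covariance between ROIs is
accepted — it lowers the variance of the ensemble mean less than disjoint
tiling of the same area, but costs nothing in bias).  Each ROI is
detrended by least-squares removal of a full second-order 2D polynomial
(orders 0–2 configurable), eliminating shading/cupping so only stochastic
noise remains.  The 2D NPS is the ensemble periodogram
`(Δx·Δy/NxNy)·⟨|DFT|²⟩`; with this normalisation the sum of power times
frequency-bin area equals the mean residual variance *as an exact DFT
identity* (the test tolerance of 1e−6 covers floating-point error only —
the few-percent tolerances elsewhere are sampling noise).  The 1D curve is
the radial average of the 2D NPS over 64 annular bins up to Nyquist, with
the DC sample excluded and reported separately.  The overall noise SD
integrates the **2D** spectrum (not the 1D curve), avoiding the annular
Jacobian; low/high band fractions split the same integral at a cutoff of
0.2 cycles/mm by default — "low-frequency noise" has no canonical numeric
definition, so the cutoff is an explicit knob.

Known estimator behaviour: second-order detrending removes genuine noise
power near DC, so strongly low-frequency textures read a slightly low
overall SD (~2% on the preset); the periodogram of a correlated field is
blurred by the ROI window, so the round-trip correlation between the
estimated radial curve and the generating shape is high (> 0.95 with 64
ROIs) but not 1.

## Clinical cohort generator

The generator emulates the *measurement structure* of a paired two-arm
reading study (n = 36 by default): per patient and arm, six ROI
measurements (liver aggregated over 3 ROIs, upper/lower subcutaneous fat,
psoas, bladder, prostate-or-uterus), seven 5-point reader items scored by
two reviewers, and a dose record.  Defaults follow the study table this
package was built around: liver objective noise 6.4 ± 0.1 vs 9.5 ± 0.1 HU,
CNR liver 5.2 vs 4.2, CNR pelvis 6.8 vs 5.3, rating means from 4.8/3.8
(subjective noise, liver) down to 2.0/3.7 (texture, pelvis), body weight
57.1 ± 11.7 kg, DLP 243.2 ± 106.0 mGy·cm, CTDIvol 4.2 ± 1.6 mGy.

Objective-noise values are Gaussian draws paired across arms at a
configurable correlation (default 0.5; independent-arm draws are used
where a worst-case variance is wanted).  Tissue attenuations are drawn
once per patient.  The liver and pelvic-organ mean HU are **derived** as
`psoas + CNR_draw · fat_sd` (resp. `bladder + CNR_draw · fat_sd`), with
the CNR drawn from its own per-arm mean/SD: this makes the CNR rows exact
generating parameters.  The alternative — drawing all tissues
independently and letting CNR fall out as a ratio — biases the expected
CNR upward by E[1/σ] ≈ (1 + cv²)/μ, about +11% at the default fat-noise
spread, which would confound parameter-recovery validation with a property
of ratio distributions rather than of the estimators.  Ratings are drawn
from per-item/arm probability vectors (defaults: the two-point
distribution on adjacent scores matching the target mean); the second
reviewer repeats the first with probability 0.9 (yielding weighted κ in
the high-0.9s), else redraws.  Everything is reproducible from one seed,
and the draw order is fixed.

What the generator does **not** emulate: non-Gaussian noise marginals,
within-patient spatial correlation between anatomies, reader drift or
item-to-item correlation beyond the shared patient draw, missing data, and
any dependence of ratings on the numeric measurements.  Passing tests
therefore demonstrate estimator and test correctness under the stated
parametric structure, not robustness to real-world reading-study
pathologies.

## Statistical procedures

* Paired and Welch t-tests delegate to scipy; zero-variance differences
  raise a degenerate-input error rather than returning a meaningless
  statistic.
* The Wilcoxon signed-rank test drops zero differences (Pratt handling
  available), mid-ranks ties, and computes the two-sided p **exactly** —
  by dynamic-programming enumeration of all 2ⁿ sign patterns — whenever
  n ≤ 20 nonzero untied differences remain; otherwise a normal
  approximation with tie correction and 0.5 continuity correction is used.
  Exactness is verified against brute-force enumeration in tests.
* Weighted κ uses linear disagreement weights by default (quadratic
  available); the weighting scheme is recorded in the result, since a
  single reported κ cannot distinguish the two.
* The study table reports raw two-sided p-values with no multiplicity
  correction, matching the reporting convention it mirrors; rows with no
  informative differences (identical scores in both arms) report p = 1
  rather than failing.
* Type-I error of the paired-t rows is verified at α = 0.05 within
  binomial error over 1000 simulated null cohorts.

## Problem sizes and determinism

Validation fixtures are sized for desk-scale runs: 512² phantom grids
(0.5 mm spacing for oracle fixtures, 350 mm/512 for protocol-like ones),
20-slice stacks for noisy-TTF checks, 49–64 ROIs per NPS ensemble, 36- to
10 000-patient cohorts, and 1000-cohort null calibrations.  Every random
quantity flows from an explicit integer seed through
`numpy.random.default_rng`; identical inputs and seeds give bit-identical
images, cohorts and reports.

## Limitations

* The reconstruction emulation is image-domain only; it cannot reproduce
  non-stationary noise, streaks, or contrast-dependent resolution of real
  iterative/deep-learning algorithms (TTF here is measured at a single
  task contrast by design).
* The NPS is 2D (in-plane); no 3D/through-plane analysis.
* No detectability-index or lesion-level modelling: outputs stop at
  resolution, noise, CNR, dose and reader-score statistics.
* CSV/JSON report outputs are byte-deterministic; PNG figures are not
  guaranteed byte-stable across matplotlib versions.
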