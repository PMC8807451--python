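# ctiq — task-based CT image-quality analysis

`ctiq` is a Python toolkit for the quantitative comparison of CT
reconstruction algorithms, of the kind routinely done when a department
evaluates a low-dose protocol: iterative and deep-learning reconstructions
are non-linear, so their resolution and noise must be characterised with
task-based phantom metrics, and their clinical impact with paired ROI
measurements and reader scores.  The package covers the whole chain:

* **TTF** — the task-based transfer function, i.e. the modulation transfer
  function measured at a specific task contrast from the circular edge of a
  phantom insert.  Radial profiles across the edge are pooled into an
  oversampled edge-spread function ESF(r); the line-spread function is its
  derivative, LSF = dESF/dr; and

  TTF(f) = |F[LSF](f)| / |F[LSF](0)|,

  summarised by the 50% and 10% crossing frequencies (TTF50, TTF10).
* **NPS** — the noise power spectrum from uniform phantom regions, as an
  ensemble average of detrended-ROI periodograms,

  NPS(u, v) = (Δx·Δy / NxNy) ⟨|DFT(ROI residual)|²⟩,

  normalised so that ∫∫ NPS du dv equals the pixel variance; the overall
  noise SD is the square root of that area, and a configurable cutoff
  (default 0.2 cycles/mm) splits low-frequency ("blotchy texture") from
  high-frequency ("fine grain") noise.
* **Clinical metrics** — objective noise (mean ROI SD across patients),
  contrast-to-noise ratios CNR = (μ₁ − μ₂)/σ_fat for the liver and pelvis,
  effective dose = DLP × k (k = 0.015 mSv·mGy⁻¹·cm⁻¹ for abdomen/pelvis),
  and contrast-material volume/flow arithmetic.
* **Paired statistics** — paired t-tests for noise and CNR, exact/corrected
  Wilcoxon signed-rank tests for 5-point reader scores, Welch's t for
  demographics, and weighted Cohen's κ for inter-reviewer agreement,
  assembled into a study table by the `ArmComparison` model.
* **Synthetic ground truth** — a phantom simulator (QA insert phantom and
  elliptical abdomen phantom, Gaussian reconstruction blur, stationary
  correlated noise with a prescribed spectrum, AEC noise-index dose
  coupling) and a paired-cohort generator, so every estimator can be
  validated end-to-end against known truth without scanner data.

## Worked example

Simulate a QA phantom scan with a "DLR-like" reconstruction (sharp PSF,
high-frequency noise texture), estimate the TTF of its acrylic insert
(+120 HU on water) and the NPS of the noise field, then compare a simulated
36-patient paired cohort:

```python
import numpy as np
from ctiq import (qa_phantom, dlr_like, simulate_scan, synthesize_noise,
                  TaskTransferFunction, NoisePowerSpectrum,
                  default_cohort_spec, generate_cohort, compare_arms)

model = dlr_like(noise_sd=8.0)
img = simulate_scan(qa_phantom(), model, noise_index=35.0, shape=(512, 512),
                    pixel_spacing=350 / 512, n_slices=10, seed=42)
print(TaskTransferFunction(img, approx_center=(-60.0, 0.0),
                           approx_radius=15.0).fit().summary())

field = synthesize_noise(model, (512, 512), 350 / 512, seed=42)
print(NoisePowerSpectrum(field).fit().summary())

records = generate_cohort(default_cohort_spec(n_patients=36, seed=0))
print(compare_arms(records).summary())
```

This prints:

```
Task transfer function
  centre (mm):      (-59.994, +0.009)  [refinement residual 0.0000 mm]
  edge contrast:    120.1 HU (SE 0.18)
  TTF50:            0.659 cycles/mm
  TTF10:            1.336 cycles/mm

Noise power spectrum
  ROIs averaged:      49
  overall noise SD:   8.01 HU
  low-band fraction:  0.107  (f < 0.2 cycles/mm)
  high-band fraction: 0.893

Paired comparison MBIR vs DLR  (n = 36 patients)
------------------------------------------------------------------------
noise_liver                 6.4 ±  0.1      9.5 ±  0.1   P <0.001
noise_upper_fat             7.1 ±  2.3      8.9 ±  1.6   P <0.001
...
cnr_liver                   5.2 ±  0.0      4.2 ±  0.1   P <0.001
subjective_texture_pelvis   2.0 ±  0.0      3.7 ±  0.4   P <0.001
------------------------------------------------------------------------
inter-reviewer weighted kappa: 0.98 (linear weights, 5 categories)
```

The TTF block says the insert edge was found to sub-pixel precision, the
recovered task contrast is the nominal 120 HU, and the reconstruction
resolves 50% modulation at 0.66 cycles/mm.  The NPS block reports the
calibrated 8 HU noise with ~11% of its variance below 0.2 cycles/mm — a
fine-grain texture.  The comparison table mirrors a clinical study report:
per-arm mean ± SD and a raw two-sided p-value per row.

The same operations are available from the shell:

```
ctiq simulate --phantom qa --recon dlr-like --noise-index 35 --seed 42 --out sim/
ctiq ttf --in sim/qa_DLR-like.npy --center-x -60 --center-y 0 --radius 15 --out ttf/
ctiq nps --in sim/qa_DLR-like.npy --roi-size 128 --cutoff 0.2 --out nps/
ctiq cohort --n 36 --seed 0 --out cohort/
ctiq stats --measurements cohort/measurements.csv --ratings cohort/ratings.csv --out report/
```

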