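"""ESF → LSF → TTF chain against closed-form Gaussian-optics oracles."""

import numpy as np
import pytest
from scipy.stats import ncx2, norm

from ctiq.exceptions import DetectionError, GeometryError, NormalizationError
from ctiq.grid import ImageGrid
from ctiq.phantom import (
    InsertSpec,
    PhantomSpec,
    ReconModel,
    apply_recon_blur,
    render_phantom,
    synthesize_noise,
)
from ctiq.ttf import (
    ESFCurve,
    LSFCurve,
    TaskTransferFunction,
    esf_to_lsf,
    estimate_center,
    extract_radial_esf,
    lsf_to_ttf,
    ttf_at_fraction,
)

from conftest import flat_shape


def gaussian_mtf(f, sigma):
    return np.exp(-2 * np.pi**2 * sigma**2 * np.asarray(f) ** 2)


class TestEstimateCenter:
    def test_centered_disk(self, blurred_disk):
        est = estimate_center(blurred_disk, (0.0, 0.0), 15.0)
        assert np.hypot(*est.center) < 0.05 * 0.5  # 0.05 px at 0.5 mm spacing
        assert est.contrast == pytest.approx(120.0, abs=5)

    def test_shifted_disk_recovered(self):
        # shift of (1.3, -0.7) px on a 0.5 mm grid
        spec = PhantomSpec(
            "disk", (100.0, 100.0), 0.0,
            (InsertSpec("a", (0.65, -0.35), 15.0, 120.0),),
        )
        img = render_phantom(spec, (512, 512), 0.5, mode="area")
        blurred = apply_recon_blur(img, ReconModel("g", 0.5, flat_shape))
        est = estimate_center(blurred, (0.0, 0.0), 15.0)
        assert np.hypot(est.center[0] - 0.65, est.center[1] + 0.35) < 0.1 * 0.5

    def test_pure_noise_raises(self):
        model = ReconModel("w", 0.0, flat_shape, noise_sd=10.0)
        noise = synthesize_noise(model, (256, 256), 0.5, seed=4)
        with pytest.raises(DetectionError):
            estimate_center(noise, (0.0, 0.0), 15.0)


class TestRadialESF:
    def test_sharp_disk_is_step(self, sharp_disk):
        esf = extract_radial_esf(sharp_disk, (0.0, 0.0), 15.0, bin_width=0.05)
        inner = esf.value[esf.radial_distance < -1.0]
        outer = esf.value[esf.radial_distance > 1.0]
        assert np.all(inner == 120.0)
        assert np.all(outer == 0.0)

    def test_blurred_disk_matches_closed_form(self):
        # exact closed form for disk * Gaussian: a noncentral-chi^2 CDF in
        # the radius; the planar normal-CDF edge is the large-R limit
        spacing, sigma, R = 0.25, 0.75, 15.0
        spec = PhantomSpec(
            "disk", (60.0, 60.0), 0.0, (InsertSpec("a", (0.0, 0.0), R, 120.0),)
        )
        img = render_phantom(spec, (512, 512), spacing, mode="area")
        blurred = apply_recon_blur(img, ReconModel("g", sigma, flat_shape))
        esf = extract_radial_esf(blurred, (0.0, 0.0), R)
        r = esf.radial_distance + R
        exact = 120.0 * ncx2.cdf((R / sigma) ** 2, 2, (r / sigma) ** 2)
        planar = 120.0 * norm.cdf(-esf.radial_distance / sigma)
        assert np.abs(esf.value - exact).max() < 0.01 * 120.0
        # curvature of the circular edge costs ~sigma/(2R) extra
        assert np.abs(esf.value - planar).max() < 0.02 * 120.0

    def test_contrast_recovery_within_3se(self, acrylic_disk_spec):
        model = ReconModel("g", 0.5, flat_shape, noise_sd=5.0)
        img = render_phantom(acrylic_disk_spec, (512, 512), 0.5, mode="area")
        blurred = apply_recon_blur(img, model)
        noise = synthesize_noise(model, (20, 512, 512), 0.5, seed=8)
        stack = ImageGrid(blurred.pixels[None] + noise.pixels, 0.5)
        res = TaskTransferFunction(stack, (0.0, 0.0), 15.0).fit()
        assert abs(res.contrast - 120.0) < 3 * res.contrast_se + 0.5

    def test_annulus_outside_image_raises(self, sharp_disk):
        with pytest.raises(GeometryError):
            extract_radial_esf(sharp_disk, (120.0, 0.0), 15.0)


class TestESFtoLSF:
    @staticmethod
    def _uniform_esf(values, width=0.05):
        x = (np.arange(len(values)) + 0.5) * width - len(values) * width / 2
        return ESFCurve(x, np.asarray(values, float), np.ones(len(values)), width)

    def test_step_esf_gives_single_impulse(self):
        v = np.where(np.arange(40) < 20, 120.0, 0.0)
        lsf = esf_to_lsf(self._uniform_esf(v))
        area = np.trapezoid(lsf.value, lsf.position)
        assert area == pytest.approx(-120.0, rel=1e-6)  # decreasing edge
        # derivative support is one central-difference stencil wide
        assert np.count_nonzero(np.abs(lsf.value) > 1e-9) <= 3

    def test_normal_cdf_esf_gives_gaussian_lsf(self):
        x = np.linspace(-5, 5, 201)
        esf = ESFCurve(x, 120 * norm.cdf(-x / 0.5), np.ones_like(x), x[1] - x[0])
        lsf = esf_to_lsf(esf)
        pred = -120 * norm.pdf(lsf.position / 0.5) / 0.5
        np.testing.assert_allclose(lsf.value, pred, atol=0.5)
        assert abs(lsf.position[np.argmax(np.abs(lsf.value))]) <= esf.bin_width

    def test_flat_esf_zero_lsf(self):
        lsf = esf_to_lsf(self._uniform_esf(np.full(30, 7.0)))
        np.testing.assert_allclose(lsf.value, 0.0, atol=1e-12)

    def test_too_few_bins(self):
        with pytest.raises(ValueError, match="at least 8"):
            esf_to_lsf(self._uniform_esf(np.arange(5.0)))


class TestLSFtoTTF:
    def test_impulse_lsf_flat_ttf(self):
        pos = np.arange(-6, 6.0001, 0.05)
        v = np.zeros_like(pos)
        v[len(pos) // 2] = 1.0
        ttf = lsf_to_ttf(LSFCurve(pos, v))
        np.testing.assert_allclose(ttf.modulation, 1.0, atol=1e-9)

    def test_gaussian_lsf_closed_form(self):
        pos = np.arange(-6, 6.0001, 0.05)
        sigma = 0.5
        ttf = lsf_to_ttf(LSFCurve(pos, norm.pdf(pos, scale=sigma) * 120))
        sel = ttf.frequency <= 1.5
        np.testing.assert_allclose(
            ttf.modulation[sel], gaussian_mtf(ttf.frequency[sel], sigma), atol=0.015
        )
        assert ttf.modulation[0] == 1.0  # exact DC normalization
        # spot value at 0.3 cycles/mm: exp(-0.444)
        assert ttf.at(0.3) == pytest.approx(np.exp(-0.4441), abs=0.01)

    def test_zero_lsf_raises(self):
        pos = np.arange(-3, 3.0001, 0.05)
        with pytest.raises(NormalizationError):
            lsf_to_ttf(LSFCurve(pos, np.zeros_like(pos)))

    def test_blur_ordering_monotone(self, acrylic_disk_spec):
        f50 = {}
        for sigma in (0.4, 0.8):
            img = render_phantom(acrylic_disk_spec, (512, 512), 0.5, mode="area")
            blurred = apply_recon_blur(img, ReconModel("g", sigma, flat_shape))
            res = TaskTransferFunction(blurred, (0.0, 0.0), 15.0).fit()
            f50[sigma] = res.f50
        df = res.ttf.frequency[1] - res.ttf.frequency[0]
        assert f50[0.4] >= f50[0.8] - df


class TestTTFAtFraction:
    def _gauss_curve(self, sigma, df=0.01, fmax=2.0):
        from ctiq.ttf import TTFCurve

        f = np.arange(0, fmax, df)
        return TTFCurve(f, gaussian_mtf(f, sigma))

    def test_f50_closed_form(self):
        sigma = 0.5
        f50 = ttf_at_fraction(self._gauss_curve(sigma), 0.5)
        assert f50 == pytest.approx(np.sqrt(np.log(2) / (2 * np.pi**2 * sigma**2)), abs=1e-3)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            ttf_at_fraction(self._gauss_curve(0.5), 1.0)

    def test_never_crosses(self):
        with pytest.raises(ValueError, match="never crosses"):
            ttf_at_fraction(self._gauss_curve(0.5, fmax=0.1), 0.5)

    def test_coarse_vs_fine_sampling(self):
        fine = ttf_at_fraction(self._gauss_curve(0.5, df=0.002), 0.5)
        coarse = ttf_at_fraction(self._gauss_curve(0.5, df=0.1), 0.5)
        assert abs(fine - coarse) < 0.1  # within one coarse bin


class TestFullPipeline:
    def test_noisy_stack_matches_oracle(self, blurred_disk):
        # 5 HU white noise, 20 slices pooled at the ESF level
        model = ReconModel("g", 0.5, flat_shape, noise_sd=5.0)
        noise = synthesize_noise(model, (20, 512, 512), 0.5, seed=7)
        stack = ImageGrid(blurred_disk.pixels[None] + noise.pixels, 0.5)
        res = TaskTransferFunction(stack, (0.3, -0.2), 15.0).fit()
        sel = res.ttf.frequency <= 1.0
        err = np.abs(res.ttf.modulation[sel] - gaussian_mtf(res.ttf.frequency[sel], 0.5))
        assert err.max() < 0.08

    def test_summary_mentions_f50(self, blurred_disk):
        res = TaskTransferFunction(blurred_disk, (0.0, 0.0), 15.0).fit()
        assert "TTF50" in res.summary()
        assert res.f10 is not None and res.f10 > res.f50
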