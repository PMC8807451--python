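"""NPS estimator: tiling, detrending, Parseval contract, band metrics."""

import numpy as np
import pytest

from ctiq.exceptions import TooFewROIsError
from ctiq.grid import ImageGrid
from ctiq.nps import (
    NPS2D,
    NoisePowerSpectrum,
    detrend_roi,
    estimate_nps2d,
    noise_summary,
    radial_average,
    tile_rois,
)
from ctiq.phantom import ReconModel, lobe_mixture, synthesize_noise

from conftest import flat_shape


def white_field(shape=(512, 512), sd=10.0, seed=3, spacing=0.5):
    model = ReconModel("w", 0.0, flat_shape, noise_sd=sd)
    return synthesize_noise(model, shape, spacing, seed=seed)


class TestTiling:
    def test_half_overlap_count(self):
        img = np.zeros((512, 512))
        assert len(tile_rois(img, roi_size=128, overlap=0.5)) == 49

    def test_disjoint_count(self):
        img = np.zeros((300, 500))
        rois = tile_rois(img, roi_size=100, overlap=0.0)
        assert len(rois) == (300 // 100) * (500 // 100)

    def test_mask_smaller_than_roi(self):
        img = np.zeros((256, 256))
        mask = np.zeros((256, 256), dtype=bool)
        mask[:64, :64] = True
        with pytest.raises(TooFewROIsError, match="0 ROI"):
            tile_rois(img, mask, roi_size=128)

    def test_rois_respect_mask(self):
        img = np.arange(256 * 256, dtype=float).reshape(256, 256)
        mask = np.zeros_like(img, dtype=bool)
        mask[:, :192] = True
        rois = tile_rois(img, mask, roi_size=64, overlap=0.0)
        assert len(rois) == 4 * 3


class TestDetrend:
    def test_quadratic_surface_removed(self):
        y, x = np.mgrid[0:64, 0:64] / 32.0 - 1
        surface = 5 + 3 * x - 2 * y + 4 * x * y + 6 * x**2 - 1.5 * y**2
        res = detrend_roi(surface)
        np.testing.assert_allclose(res, 0.0, atol=1e-9)
        assert abs(res.mean()) < 1e-9

    def test_noise_sd_preserved(self):
        rng = np.random.default_rng(1)
        y, x = np.mgrid[0:128, 0:128] / 64.0 - 1
        roi = 10 * x**2 - 5 * y + rng.normal(0, 10, (128, 128))
        res = detrend_roi(roi)
        assert res.std() == pytest.approx(10.0, rel=0.02)

    def test_constant_roi(self):
        np.testing.assert_allclose(detrend_roi(np.full((32, 32), 9.0)), 0.0, atol=1e-9)

    def test_too_small(self):
        with pytest.raises(ValueError):
            detrend_roi(np.zeros((8, 8)))


class TestEstimateNPS2D:
    def test_parseval_exact_and_white_flatness(self):
        rois = [detrend_roi(r) for r in tile_rois(white_field().pixels, roi_size=128)]
        nps2 = estimate_nps2d(rois, 0.5)
        var = np.mean([r.var() for r in rois])
        assert abs(nps2.integral() - var) < 1e-6 * var
        assert nps2.integral() == pytest.approx(100.0, rel=0.03)
        # flat spectrum: radial curve flat to within ensemble noise
        curve = radial_average(nps2)
        assert curve.power.std() / curve.power.mean() < 0.2

    def test_all_zero_rois(self):
        nps2 = estimate_nps2d([np.zeros((32, 32))] * 4, 0.5)
        assert np.all(nps2.power == 0.0)

    def test_mixed_sizes_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            estimate_nps2d([np.zeros((32, 32))] * 3 + [np.zeros((64, 64))], 0.5)

    def test_too_few_rois(self):
        with pytest.raises(TooFewROIsError):
            estimate_nps2d([np.zeros((32, 32))] * 3, 0.5)

    def test_round_trip_with_generator(self):
        # 576^2 field -> 64 averaged ROIs; estimated radial curve correlates
        # with the generating shape
        for maker, min_corr in ((lobe_mixture(1.0, 0.06, 0.3, 0.15), 0.95),
                                (lobe_mixture(0.15, 0.06, 1.0, 0.28), 0.95)):
            model = ReconModel("m", 0.0, maker, noise_sd=8.0)
            field = synthesize_noise(model, (576, 576), 0.5, seed=11)
            res = NoisePowerSpectrum(field).fit()
            assert res.nps2d.n_rois == 64
            corr = np.corrcoef(
                maker(res.curve.radial_frequency), res.curve.power
            )[0, 1]
            assert corr > min_corr

    def test_ensemble_cv_scales_inverse_sqrt(self):
        # doubling the ROI count shrinks the per-bin CV by about 1/sqrt(2)
        curves8, curves16 = [], []
        for seed in range(12):
            field = white_field((256, 256), seed=100 + seed)
            rois = [detrend_roi(r) for r in tile_rois(field.pixels, roi_size=64, overlap=0.0)]
            curves8.append(radial_average(estimate_nps2d(rois[:8], 0.5)).power)
            curves16.append(radial_average(estimate_nps2d(rois, 0.5)).power)
        cv8 = (np.std(curves8, axis=0) / np.mean(curves8, axis=0)).mean()
        cv16 = (np.std(curves16, axis=0) / np.mean(curves16, axis=0)).mean()
        assert cv8 / cv16 == pytest.approx(np.sqrt(2), rel=0.30)


class TestRadialAverageAndSummary:
    def test_flat_spectrum_flat_curve(self):
        power = np.ones((64, 64))
        f = np.fft.fftshift(np.fft.fftfreq(64, 0.5))
        nps2 = NPS2D(f, f, power, 0.5, n_rois=4)
        curve = radial_average(nps2)
        np.testing.assert_allclose(curve.power, 1.0, atol=1e-12)

    def test_anisotropic_stripe_between_axis_profiles(self):
        # stripe spectrum varying only with f_y: on every annulus the power
        # ranges between its y-axis value (min) and x-axis value (max), so
        # the radial average must lie between the two axis profiles
        f = np.fft.fftshift(np.fft.fftfreq(64, 0.5))
        FX, FY = np.meshgrid(f, f)
        power = np.exp(-(FY**2) / 0.02)
        nps2 = NPS2D(f, f, power, 0.5, n_rois=4)
        curve = radial_average(nps2)
        ix = np.argsort(np.abs(f))
        prof_x = power[np.abs(f).argmin(), :]  # along x axis (f_y = 0)
        prof_y = power[:, np.abs(f).argmin()]  # along y axis
        for fc, pw in zip(curve.radial_frequency, curve.power):
            lo = np.interp(fc, np.abs(f)[ix], prof_y[ix])
            hi = np.interp(fc, np.abs(f)[ix], prof_x[ix])
            assert lo - 1e-9 <= pw <= hi + 1e-9

    def test_dc_reported_separately(self):
        power = np.ones((64, 64))
        f = np.fft.fftshift(np.fft.fftfreq(64, 0.5))
        power[np.abs(f).argmin(), np.abs(f).argmin()] = 99.0
        nps2 = NPS2D(f, f, power, 0.5, n_rois=4)
        curve = radial_average(nps2)
        assert curve.dc_power == 99.0
        assert curve.power.max() < 2.0

    def test_summary_white_noise(self):
        res = NoisePowerSpectrum(white_field()).fit()
        assert res.noise.overall_sd == pytest.approx(10.0, rel=0.03)
        s = res.noise.low_band_fraction + res.noise.high_band_fraction
        assert s == pytest.approx(1.0, abs=1e-9)

    def test_zero_field_zero_sd(self):
        img = ImageGrid(np.zeros((256, 256)), 0.5)
        res = NoisePowerSpectrum(img).fit()
        assert res.noise.overall_sd == 0.0

    def test_low_pass_has_larger_low_band_fraction(self):
        lp = ReconModel("lp", 0.0, lobe_mixture(1.0, 0.06, 0.0, 1.0), noise_sd=10.0)
        white = ReconModel("w", 0.0, flat_shape, noise_sd=10.0)
        f_lp = NoisePowerSpectrum(synthesize_noise(lp, (512, 512), 0.5, seed=6)).fit()
        f_w = NoisePowerSpectrum(synthesize_noise(white, (512, 512), 0.5, seed=6)).fit()
        assert f_lp.noise.low_band_fraction > f_w.noise.low_band_fraction

    def test_cutoff_validation(self):
        nps2 = NoisePowerSpectrum(white_field((256, 256))).fit().nps2d
        with pytest.raises(ValueError):
            noise_summary(nps2, cutoff=0.0)
        with pytest.raises(ValueError):
            noise_summary(nps2, cutoff=5.0)
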