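"""Phantom rendering, blur and correlated-noise synthesis."""

import numpy as np
import pytest
from scipy.stats import norm

from ctiq.exceptions import GeometryError
from ctiq.grid import ImageGrid
from ctiq.phantom import (
    InsertSpec,
    PhantomSpec,
    ReconModel,
    abdomen_phantom,
    apply_recon_blur,
    lobe_mixture,
    noise_sd_from_index,
    qa_phantom,
    render_phantom,
    simulate_scan,
    synthesize_noise,
)

from conftest import flat_shape


class TestRenderPhantom:
    def test_insert_and_background_values(self, acrylic_disk_spec):
        img = render_phantom(acrylic_disk_spec, (256, 256), 1.0, mode="center")
        X, Y = img.coords()
        center = np.hypot(X, Y) < 5.0
        background = (np.hypot(X, Y) > 30.0) & (np.hypot(X, Y) < 80.0)
        assert np.all(img.pixels[center] == 120.0)
        assert np.all(img.pixels[background] == 0.0)

    def test_zero_inserts_uniform_body(self):
        spec = PhantomSpec("disk", (50.0, 50.0), 0.0)
        img = render_phantom(spec, (128, 128), 1.0, mode="center")
        X, Y = img.coords()
        body = np.hypot(X, Y) <= 50.0
        assert np.all(img.pixels[body] == 0.0)
        assert np.all(img.pixels[~body] == -1000.0)

    def test_pixel_center_count_matches_brute_force(self):
        # 5 mm disk insert on a 0.5 mm grid: pixels at full insert HU must
        # be exactly those whose centres fall inside the disk
        spec = PhantomSpec(
            "disk", (40.0, 40.0), 0.0, (InsertSpec("a", (3.3, -2.7), 5.0, 120.0),)
        )
        img = render_phantom(spec, (200, 200), 0.5, mode="center")
        X, Y = img.coords()
        brute = int(np.sum(np.hypot(X - 3.3, Y + 2.7) <= 5.0))
        assert int(np.sum(img.pixels >= 120.0)) == brute

    def test_area_mode_total_coverage_matches_disk_area(self):
        spec = PhantomSpec(
            "disk", (40.0, 40.0), 0.0, (InsertSpec("a", (0.0, 0.0), 5.0, 120.0),)
        )
        img = render_phantom(spec, (200, 200), 0.5, mode="area")
        # positive pixels belong to the insert (body is 0 HU, air negative)
        pos = img.pixels[img.pixels > 0]
        covered_area = pos.sum() / 120.0 * 0.5**2  # HU-weighted pixel area
        assert covered_area == pytest.approx(np.pi * 25.0, rel=1e-3)

    def test_insert_outside_body_rejected(self):
        with pytest.raises(GeometryError):
            PhantomSpec(
                "disk", (50.0, 50.0), 0.0, (InsertSpec("a", (48.0, 0.0), 5.0, 120.0),)
            )

    def test_grid_must_cover_phantom(self):
        with pytest.raises(GeometryError):
            render_phantom(abdomen_phantom(), (128, 128), 0.5)

    def test_factories(self):
        qa = qa_phantom()
        assert {i.label for i in qa.inserts} == {
            "air", "polypropylene", "water", "acrylic", "delrin", "teflon",
        }
        assert {i.hu_value for i in qa.inserts} == {-1000, -105, 0, 120, 340, 940}
        ab = abdomen_phantom()
        assert ab.semi_axes == (165.0, 110.0) and ab.inserts == ()


class TestReconBlur:
    def test_zero_sigma_identity(self, sharp_disk):
        out = apply_recon_blur(sharp_disk, ReconModel("id", 0.0, flat_shape))
        np.testing.assert_array_equal(out.pixels, sharp_disk.pixels)

    def test_uniform_image_unchanged(self):
        img = ImageGrid(np.full((64, 64), 40.0), 0.5)
        out = apply_recon_blur(img, ReconModel("g", 1.0, flat_shape))
        np.testing.assert_allclose(out.pixels, 40.0, atol=1e-9)

    def test_mean_preserved_periodic_field(self):
        # wrap boundaries make blur an exact mean-preserving convolution
        rng = np.random.default_rng(0)
        img = ImageGrid(rng.normal(50, 10, (128, 128)), 0.5)
        out = apply_recon_blur(img, ReconModel("g", 1.0, flat_shape))
        assert abs(out.pixels.mean() - img.pixels.mean()) < 1e-6 * abs(img.pixels.mean())

    def test_gaussian_edge_response_closed_form(self):
        # half-plane step of 120 HU blurred with sigma: profile equals the
        # scaled normal CDF (e.g. 120*Phi(1) at 0.5 mm inside the edge)
        spacing, sigma = 0.1, 0.5
        grid = ImageGrid(np.zeros((64, 256)), spacing)
        X, _ = grid.coords()
        step = grid.with_pixels(np.where(X < 0, 120.0, 0.0))
        out = apply_recon_blur(step, ReconModel("g", sigma, flat_shape))
        x = grid.x_coords()
        interior = (np.abs(x) < 8.0)
        # edge midpoint sits half a pixel left of the first dark column
        edge = x[np.where(x >= 0)[0][0]] - spacing / 2
        pred = 120.0 * norm.cdf((edge - x[interior]) / sigma)
        np.testing.assert_allclose(out.pixels[32, interior], pred, atol=0.6)
        at_half_mm = np.interp(edge - 0.5, x[interior], out.pixels[32, interior])
        assert at_half_mm == pytest.approx(120.0 * norm.cdf(1.0), abs=0.6)


class TestSynthesizeNoise:
    def test_zero_sd_gives_zero_field(self):
        model = ReconModel("z", 0.0, flat_shape, noise_sd=0.0)
        out = synthesize_noise(model, (64, 64), 0.5, seed=1)
        assert np.all(out.pixels == 0)

    def test_flat_shape_sample_sd(self):
        model = ReconModel("w", 0.0, flat_shape, noise_sd=10.0)
        out = synthesize_noise(model, (512, 512), 0.5, seed=3)
        assert out.pixels.std() == pytest.approx(10.0, rel=0.03)
        assert abs(out.pixels.mean()) < 0.1

    def test_deterministic(self):
        model = ReconModel("w", 0.0, flat_shape, noise_sd=5.0)
        a = synthesize_noise(model, (64, 64), 0.5, seed=42)
        b = synthesize_noise(model, (64, 64), 0.5, seed=42)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        c = synthesize_noise(model, (64, 64), 0.5, seed=43)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_zero_shape_with_positive_sd_rejected(self):
        model = ReconModel("bad", 0.0, lambda f: np.zeros_like(f), noise_sd=5.0)
        with pytest.raises(ValueError, match="identically zero"):
            synthesize_noise(model, (64, 64), 0.5, seed=0)

    def test_low_pass_power_concentrates_below_cutoff(self):
        # spectral mass of a narrow low-pass texture sits below 0.2 cyc/mm
        model = ReconModel("lp", 0.0, lobe_mixture(1.0, 0.05, 0.0, 1.0), noise_sd=8.0)
        out = synthesize_noise(model, (256, 256), 0.5, seed=5)
        F = np.abs(np.fft.fft2(out.pixels)) ** 2
        fr = np.hypot(*np.meshgrid(np.fft.fftfreq(256, 0.5), np.fft.fftfreq(256, 0.5)))
        low = F[fr < 0.2].sum() / F.sum()
        assert low > 0.9


class TestSimulateScan:
    def test_noise_index_mapping(self):
        assert noise_sd_from_index(35.0, 0.5) == pytest.approx(35 * np.sqrt(10))
        assert noise_sd_from_index(35.0, 5.0) == pytest.approx(35.0)
        # doubling the noise index quadruples the target variance
        assert noise_sd_from_index(20.0, 0.5) ** 2 * 4 == pytest.approx(
            noise_sd_from_index(40.0, 0.5) ** 2
        )

    def test_deterministic_and_metadata(self, acrylic_disk_spec):
        model = ReconModel("g", 0.3, flat_shape, noise_sd=10.0)
        a = simulate_scan(acrylic_disk_spec, model, 35.0, (256, 256), 1.0, seed=9)
        b = simulate_scan(acrylic_disk_spec, model, 35.0, (256, 256), 1.0, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.meta["seed"] == 9 and a.meta["noise_sd"] == 10.0

    def test_noise_sd_override_vs_index(self, acrylic_disk_spec):
        # without an explicit override the realized SD follows the index map
        model = ReconModel("w", 0.0, flat_shape)
        img = simulate_scan(
            acrylic_disk_spec, model, 35.0, (512, 512), 0.5, slice_thickness=5.0, seed=2
        )
        X, Y = img.coords()
        bg = (np.hypot(X, Y) > 40) & (np.hypot(X, Y) < 80)
        assert img.pixels[bg].std() == pytest.approx(35.0, rel=0.05)

    def test_multislice_shape(self, acrylic_disk_spec):
        model = ReconModel("w", 0.0, flat_shape, noise_sd=5.0)
        img = simulate_scan(
            acrylic_disk_spec, model, 35.0, (128, 128), 2.0, n_slices=4, seed=1
        )
        assert img.pixels.shape == (4, 128, 128)
        assert not np.array_equal(img.pixels[0], img.pixels[1])
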