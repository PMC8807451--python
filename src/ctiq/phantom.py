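"""Synthetic CT phantoms and reconstruction emulation.

This module renders noiseless phantom HU maps (a QA phantom with cylindrical
contrast inserts, and an elliptical abdomen phantom), and emulates the two
image-domain effects of a CT reconstruction that the estimators in
:mod:`ctiq.ttf` and :mod:`ctiq.nps` measure:

* sharpness, as an isotropic Gaussian point-spread function of scale
  ``blur_sigma`` (mm), and
* noise amount and texture, as a stationary zero-mean Gaussian random field
  whose power spectrum is proportional to a configurable radial shape and
  whose pixel standard deviation is calibrated to a target value in HU.

No projection-domain physics is modelled: iterative and deep-learning
reconstructions enter only through their measurable image-domain signature
(blur scale plus noise texture).  That is exactly the ground truth the
task-transfer-function and noise-power-spectrum estimators need for
end-to-end validation.

Dose is coupled to noise through the automatic-exposure-control *noise
index*: the target pixel SD at 5 mm slice thickness.  Thin-slice variance
scales inversely with slice thickness, so a noise index ``NI`` at thickness
``t`` mm yields a target SD of ``NI * sqrt(5 / t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError
from .grid import ImageGrid

__all__ = [
    "InsertSpec",
    "PhantomSpec",
    "ReconModel",
    "qa_phantom",
    "abdomen_phantom",
    "render_phantom",
    "apply_recon_blur",
    "synthesize_noise",
    "simulate_scan",
    "noise_sd_from_index",
    "lobe_mixture",
    "mbir_like",
    "dlr_like",
    "hir_like",
]

# HU range representable by standard 12-bit CT
_HU_MIN, _HU_MAX = -1024.0, 3071.0


@dataclass(frozen=True)
class InsertSpec:
    """A cylindrical contrast insert: label, centre (mm), radius (mm), HU."""

    label: str
    center_xy: tuple[float, float]
    radius: float
    hu_value: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise GeometryError(f"insert {self.label!r}: radius must be > 0")
        if not (_HU_MIN <= self.hu_value <= _HU_MAX):
            raise ValueError(
                f"insert {self.label!r}: hu_value {self.hu_value} outside "
                f"[{_HU_MIN}, {_HU_MAX}]"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a cylindrical phantom body with optional inserts.

    ``shape`` is ``"disk"`` (equal semi-axes) or ``"ellipse"``.  The body is
    centred at the physical origin; everything outside it is air
    (``outside_hu``, −1000 HU by default).
    """

    shape: str
    semi_axes: tuple[float, float]
    background_hu: float
    inserts: tuple[InsertSpec, ...] = ()
    outside_hu: float = -1000.0

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "ellipse"):
            raise ValueError(f"shape must be 'disk' or 'ellipse', got {self.shape!r}")
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise GeometryError("semi_axes must be > 0")
        if self.shape == "disk" and not math.isclose(a, b):
            raise GeometryError("disk phantom requires equal semi-axes")
        object.__setattr__(self, "inserts", tuple(self.inserts))
        for ins in self.inserts:
            self._check_inside(ins)

    def _check_inside(self, ins: InsertSpec) -> None:
        """Insert circle must lie fully inside the body outline."""
        a, b = self.semi_axes
        cx, cy = ins.center_xy
        theta = np.linspace(0.0, 2 * np.pi, 256, endpoint=False)
        px = cx + ins.radius * np.cos(theta)
        py = cy + ins.radius * np.sin(theta)
        if np.any((px / a) ** 2 + (py / b) ** 2 > 1.0 + 1e-12):
            raise GeometryError(
                f"insert {ins.label!r} (centre {ins.center_xy}, r={ins.radius}) "
                "extends outside the phantom body"
            )


@dataclass(frozen=True)
class ReconModel:
    """Image-domain emulation of one reconstruction algorithm.

    Parameters
    ----------
    label
        Display name, e.g. ``"MBIR-like"`` or ``"DLR-like"``.
    blur_sigma
        Gaussian PSF scale in mm (0 = no blur).
    nps_shape
        Nonnegative function of radial frequency (cycles/mm) giving the
        *relative* noise power spectrum; overall amount is set separately.
    noise_sd
        Target pixel SD in HU at the reference slice thickness, or ``None``
        to derive it from the scan's noise index (see
        :func:`noise_sd_from_index`).
    """

    label: str
    blur_sigma: float
    nps_shape: Callable[[np.ndarray], np.ndarray]
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# noise-texture shape families


def lobe_mixture(
    low_amp: float, low_scale: float, band_amp: float, band_scale: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Two-lobe radial NPS shape: low-frequency lobe plus band-pass lobe.

    ``S(f) = low_amp * exp(-f^2 / (2 low_scale^2))
           + band_amp * f * exp(-f^2 / (2 band_scale^2))``

    with ``f`` in cycles/mm.  The band-pass lobe peaks at ``f = band_scale``.
    Mixing the two reproduces the qualitative range of CT noise textures,
    from low-frequency-heavy ("blotchy") to high-frequency-heavy ("fine
    grain").  Amplitudes are relative; the field is rescaled to a target
    pixel SD at synthesis time.
    """

    if min(low_amp, low_scale, band_amp, band_scale) < 0:
        raise ValueError("lobe_mixture parameters must be nonnegative")

    def shape(f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return low_amp * np.exp(-(f**2) / (2 * low_scale**2)) + band_amp * f * np.exp(
            -(f**2) / (2 * band_scale**2)
        )

    return shape


def mbir_like(noise_sd: float | None = None, blur_sigma: float = 0.45) -> ReconModel:
    """Model-based-iterative-like arm: sharp-ish, low-frequency-heavy noise."""
    return ReconModel(
        label="MBIR-like",
        blur_sigma=blur_sigma,
        nps_shape=lobe_mixture(1.0, 0.06, 0.30, 0.15),
        noise_sd=noise_sd,
    )


def dlr_like(noise_sd: float | None = None, blur_sigma: float = 0.30) -> ReconModel:
    """Deep-learning-like arm: sharper, high-frequency-weighted noise."""
    return ReconModel(
        label="DLR-like",
        blur_sigma=blur_sigma,
        nps_shape=lobe_mixture(0.15, 0.06, 1.0, 0.28),
        noise_sd=noise_sd,
    )


def hir_like(noise_sd: float | None = None, blur_sigma: float = 0.55) -> ReconModel:
    """Hybrid-iterative-like reference arm: mid-band noise texture."""
    return ReconModel(
        label="HIR-like",
        blur_sigma=blur_sigma,
        nps_shape=lobe_mixture(0.35, 0.08, 1.0, 0.22),
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# phantom factories


def qa_phantom(
    body_radius: float = 100.0,
    insert_radius: float = 15.0,
    ring_radius: float = 60.0,
) -> PhantomSpec:
    """QA phantom: water-equivalent disk with six material inserts.

    The inserts span the standard contrast ladder — air (−1000 HU),
    polypropylene (−105), water (0), acrylic (+120), Delrin (+340) and
    Teflon (+940) — arranged on a ring.  The acrylic insert provides the
    low-positive task contrast (soft tissue vs fat) used for TTF work.
    """

    materials = [
        ("air", -1000.0),
        ("polypropylene", -105.0),
        ("water", 0.0),
        ("acrylic", 120.0),
        ("delrin", 340.0),
        ("teflon", 940.0),
    ]
    inserts = []
    for k, (label, hu) in enumerate(materials):
        ang = 2 * np.pi * k / len(materials)
        cx = ring_radius * math.cos(ang)
        cy = ring_radius * math.sin(ang)
        inserts.append(InsertSpec(label, (cx, cy), insert_radius, hu))
    return PhantomSpec(
        shape="disk",
        semi_axes=(body_radius, body_radius),
        background_hu=0.0,
        inserts=tuple(inserts),
    )


def abdomen_phantom(background_hu: float = 50.0) -> PhantomSpec:
    """Elliptical abdomen phantom (33 cm × 22 cm), uniform resin body.

    No inserts: the uniform interior is the measurement region for noise
    power spectrum estimation.
    """

    return PhantomSpec(
        shape="ellipse",
        semi_axes=(165.0, 110.0),
        background_hu=background_hu,
        inserts=(),
    )


# ---------------------------------------------------------------------------
# rendering


def _disk_coverage(
    X: np.ndarray,
    Y: np.ndarray,
    cx: float,
    cy: float,
    r: float,
    spacing: float,
    supersample: int,
) -> np.ndarray:
    """Per-pixel area fraction covered by a disk.

    Pixels well inside/outside are classified by signed distance; only the
    boundary band is refined with an ``supersample`` × ``supersample``
    sub-pixel quadrature, so the cost is proportional to the perimeter.
    """

    d = np.hypot(X - cx, Y - cy) - r
    band = spacing  # > half pixel diagonal
    cov = (d < 0).astype(float)
    edge = np.abs(d) <= band
    if np.any(edge):
        off = (np.arange(supersample) + 0.5) / supersample - 0.5
        ox, oy = np.meshgrid(off * spacing, off * spacing)
        ex = X[edge][:, None] + ox.ravel()[None, :]
        ey = Y[edge][:, None] + oy.ravel()[None, :]
        inside = np.hypot(ex - cx, ey - cy) <= r
        cov[edge] = inside.mean(axis=1)
    return cov


def _ellipse_coverage(
    X: np.ndarray,
    Y: np.ndarray,
    a: float,
    b: float,
    spacing: float,
    supersample: int,
) -> np.ndarray:
    """Per-pixel area fraction covered by an origin-centred ellipse."""

    if math.isclose(a, b):
        return _disk_coverage(X, Y, 0.0, 0.0, a, spacing, supersample)
    rho2 = (X / a) ** 2 + (Y / b) ** 2
    # first-order signed distance from the level set rho^2 = 1
    g = 2 * np.sqrt((X / a**2) ** 2 + (Y / b**2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(g > 0, (rho2 - 1.0) / g, -1.0)
    band = 2 * spacing
    cov = (rho2 < 1.0).astype(float)
    edge = np.abs(d) <= band
    if np.any(edge):
        off = (np.arange(supersample) + 0.5) / supersample - 0.5
        ox, oy = np.meshgrid(off * spacing, off * spacing)
        ex = X[edge][:, None] + ox.ravel()[None, :]
        ey = Y[edge][:, None] + oy.ravel()[None, :]
        inside = (ex / a) ** 2 + (ey / b) ** 2 <= 1.0
        cov[edge] = inside.mean(axis=1)
    return cov


def render_phantom(
    spec: PhantomSpec,
    shape: tuple[int, int] = (512, 512),
    pixel_spacing: float = 35 * 10.0 / 512,
    *,
    slice_thickness: float = 0.5,
    mode: str = "area",
    supersample: int = 8,
) -> ImageGrid:
    """Render a noiseless, blur-free HU map of a phantom.

    Parameters
    ----------
    spec
        Phantom geometry.  The body must fit inside the rendered grid.
    shape
        ``(ny, nx)`` of the output image.
    pixel_spacing
        mm per pixel; the default corresponds to a 35 cm field of view on a
        512 matrix.
    mode
        ``"area"`` (default): boundary pixels take the area-weighted mixture
        of the HU on either side (sub-pixel quadrature), giving clean edges
        for edge-spread-function work.  ``"center"``: each pixel takes the
        HU of the region containing its centre — the simple rule used as a
        brute-force oracle in tests.
    supersample
        Sub-pixel quadrature order per axis in area mode.
    """

    if mode not in ("area", "center"):
        raise ValueError(f"mode must be 'area' or 'center', got {mode!r}")
    grid = ImageGrid(
        pixels=np.zeros(shape),
        pixel_spacing=pixel_spacing,
        slice_thickness=slice_thickness,
    )
    X, Y = grid.coords()
    a, b = spec.semi_axes
    xmin, xmax, ymin, ymax = grid.extent()
    if a > max(abs(xmin), xmax) or b > max(abs(ymin), ymax):
        raise GeometryError("grid does not cover the phantom outline")

    if mode == "center":
        body = ((X / a) ** 2 + (Y / b) ** 2 <= 1.0).astype(float)
    else:
        body = _ellipse_coverage(X, Y, a, b, pixel_spacing, supersample)
    img = spec.outside_hu + body * (spec.background_hu - spec.outside_hu)

    for ins in spec.inserts:
        cx, cy = ins.center_xy
        if mode == "center":
            cov = (np.hypot(X - cx, Y - cy) <= ins.radius).astype(float)
        else:
            cov = _disk_coverage(X, Y, cx, cy, ins.radius, pixel_spacing, supersample)
        img = img + cov * (ins.hu_value - spec.background_hu)

    return grid.with_pixels(img, phantom_mode=mode)


# ---------------------------------------------------------------------------
# reconstruction emulation


def apply_recon_blur(img: ImageGrid, model: ReconModel) -> ImageGrid:
    """Convolve with the reconstruction's isotropic Gaussian PSF (in-plane).

    ``blur_sigma`` is in mm and converted to pixels through the grid
    spacing; a zero sigma returns an identical copy.  Boundaries are
    handled periodically (wrap), which preserves the spatial mean exactly;
    phantom renders are bordered by uniform air, so wrapping introduces no
    artefact where measurements are taken.
    """

    if model.blur_sigma == 0:
        return img.with_pixels(img.pixels.copy(), blur_sigma=0.0)
    sigma_px = model.blur_sigma / img.pixel_spacing
    if img.pixels.ndim == 2:
        out = ndimage.gaussian_filter(img.pixels, sigma_px, mode="wrap")
    else:
        out = np.stack(
            [ndimage.gaussian_filter(s, sigma_px, mode="wrap") for s in img.pixels]
        )
    return img.with_pixels(out, blur_sigma=model.blur_sigma)


def noise_sd_from_index(noise_index: float, slice_thickness: float) -> float:
    """Thin-slice target SD implied by an AEC noise index.

    The noise index is defined as the pixel SD at 5 mm slice thickness;
    averaging over slice thickness scales variance as 1/thickness, so

    ``SD(t) = NI * sqrt(5 / t)``.

    For example a noise index of 35 HU at 0.5 mm thickness targets
    ``35 * sqrt(10) ≈ 110.7`` HU.
    """

    if not noise_index > 0:
        raise ValueError("noise_index must be > 0")
    if not slice_thickness > 0:
        raise ValueError("slice_thickness must be > 0")
    return noise_index * math.sqrt(5.0 / slice_thickness)


def _noise_slice(
    H: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    w = rng.standard_normal(H.shape)
    x = np.fft.ifft2(np.fft.fft2(w) * H).real
    return x * noise_sd


def synthesize_noise(
    model: ReconModel,
    shape: tuple[int, int] | tuple[int, int, int],
    pixel_spacing: float,
    seed: int,
    *,
    noise_sd: float | None = None,
    slice_thickness: float = 0.5,
) -> ImageGrid:
    """Zero-mean stationary Gaussian noise with the model's power spectrum.

    The field is synthesized by spectral filtering of white noise with
    ``sqrt(nps_shape)`` evaluated on the radial frequency grid; the filter
    is scaled so the *expected* pixel variance equals ``noise_sd**2``
    (sample variance converges to it as the grid grows).  The DC component
    is zeroed so every realization has zero mean in expectation and no
    random offset.  Identical seeds give bit-identical fields.
    """

    sd = model.noise_sd if noise_sd is None else noise_sd
    if sd is None:
        raise ValueError("noise_sd not set on model and not passed explicitly")
    if sd < 0:
        raise ValueError("noise_sd must be >= 0")

    if len(shape) == 2:
        nz, (ny, nx) = 1, shape
        squeeze = True
    else:
        nz, ny, nx = shape
        squeeze = False

    if sd == 0:
        pixels = np.zeros((ny, nx) if squeeze else (nz, ny, nx))
        return ImageGrid(pixels, pixel_spacing, slice_thickness, meta={"seed": seed})

    fx = np.fft.fftfreq(nx, d=pixel_spacing)
    fy = np.fft.fftfreq(ny, d=pixel_spacing)
    fr = np.hypot(*np.meshgrid(fx, fy))
    S = np.asarray(model.nps_shape(fr), dtype=float)
    if S.shape != fr.shape:
        raise ValueError("nps_shape must evaluate elementwise on frequency arrays")
    if np.any(~np.isfinite(S)) or np.any(S < 0):
        raise ValueError("nps_shape must be finite and nonnegative")
    H = np.sqrt(S)
    H[0, 0] = 0.0  # zero-mean field: no DC power
    ms = np.mean(H**2)
    if ms == 0:
        raise ValueError("nps_shape is identically zero but noise_sd > 0")
    H = H / math.sqrt(ms)  # unit expected pixel variance before scaling

    rng = np.random.default_rng(seed)
    slices = [_noise_slice(H, sd, rng) for _ in range(nz)]
    pixels = slices[0] if squeeze else np.stack(slices)
    return ImageGrid(
        pixels,
        pixel_spacing,
        slice_thickness,
        meta={"seed": seed, "noise_sd": sd, "recon": model.label},
    )


def simulate_scan(
    spec: PhantomSpec,
    model: ReconModel,
    noise_index: float,
    shape: tuple[int, int] = (512, 512),
    pixel_spacing: float = 35 * 10.0 / 512,
    *,
    slice_thickness: float = 0.5,
    n_slices: int = 1,
    seed: int = 0,
    mode: str = "area",
) -> ImageGrid:
    """Render → blur → add noise: a full emulated phantom acquisition.

    The realized noise SD is ``model.noise_sd`` when set, otherwise it is
    mapped from the AEC noise index via :func:`noise_sd_from_index`, so the
    target variance scales with ``noise_index**2``.  With ``n_slices > 1``
    the same noiseless section is repeated with independent noise per
    slice.  The same inputs and seed reproduce the image bit for bit.
    """

    sd = model.noise_sd
    if sd is None:
        sd = noise_sd_from_index(noise_index, slice_thickness)
    clean = render_phantom(
        spec, shape, pixel_spacing, slice_thickness=slice_thickness, mode=mode
    )
    blurred = apply_recon_blur(clean, model)
    noise = synthesize_noise(
        model,
        (n_slices, *shape),
        pixel_spacing,
        seed,
        noise_sd=sd,
        slice_thickness=slice_thickness,
    )
    pixels = blurred.pixels[None, :, :] + noise.pixels
    if n_slices == 1:
        pixels = pixels[0]
    return blurred.with_pixels(
        pixels,
        seed=seed,
        noise_index=noise_index,
        noise_sd=sd,
        recon=model.label,
    )
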