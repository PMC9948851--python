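"""Synthetic CT scans of a DDC module, with ground truth, and a simulated observer.

The forward model is deliberately simple but fully controlled:

* the noiseless HU map is the epoxy base (default 60 HU) plus each rod's
  rendered contrast, rasterised with sub-pixel supersampling so edge pixels
  carry partial-volume fractions; the PMMA body around the barrel renders at
  120 HU;
* contrast-agent (iodine) rods are scaled by a configurable per-kV response
  f(kV) with f(120 kV) = 1, because iodine contrast rises towards lower tube
  voltages; native (sucrose) rods are energy-independent;
* an optional Gaussian PSF models in-plane blur;
* image noise is stationary white Gaussian with a standard deviation that
  follows the usual dose law  sigma = sigma_ref * sqrt(CTDIvol_ref / CTDIvol).

The simulated observer detects each rod independently with probability
logistic((d - threshold) / width) where d = dHU * s / sigma is a
Rose-criterion-style detectability index (contrast times diameter over noise).
It is a testing device for the evaluation pipeline, not a model of human
performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .ddc import ClickRecord, ObserverSession
from .errors import GeometryError
from .phantom import ModuleLayout
from .transform import RigidTransform

__all__ = [
    "SUPPORTED_KV",
    "DEFAULT_KV_RESPONSE",
    "AcquisitionSettings",
    "CTVolume",
    "GroundTruth",
    "PsychometricParams",
    "rendered_contrasts",
    "render_slice",
    "simulate_volume",
    "simulate_observer",
]

SUPPORTED_KV = (80, 100, 120, 140)

#: Default relative contrast response of the iodine rods per tube voltage.
#: Placeholder values with the right qualitative shape (iodine contrast
#: falls with increasing kV); override per scanner via configuration.
DEFAULT_KV_RESPONSE: Mapping[int, float] = {80: 1.30, 100: 1.15, 120: 1.00, 140: 0.90}

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # FWHM = 2 sqrt(2 ln 2) sigma


@dataclass(frozen=True)
class AcquisitionSettings:
    """Scan and reconstruction parameters of one simulated acquisition."""

    kv: int = 120
    ctdi_vol_mgy: float = 9.0
    pixel_spacing_mm: float = 0.5
    slice_thickness_mm: float = 2.0
    n_slices: int = 5
    n_pixels: int = 192
    psf_fwhm_mm: float = 0.8
    noise_sigma_ref_hu: float = 10.0
    ctdi_ref_mgy: float = 10.0
    kernel_label: str = "I30f"
    scan_date: str = "2022-01-01"

    def __post_init__(self) -> None:
        if self.kv not in SUPPORTED_KV:
            raise ValueError(f"kv must be one of {SUPPORTED_KV}, got {self.kv}")
        for name in ("ctdi_vol_mgy", "pixel_spacing_mm", "slice_thickness_mm",
                     "ctdi_ref_mgy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_slices < 1 or self.n_pixels < 8:
            raise ValueError("n_slices must be >= 1 and n_pixels >= 8")
        if self.psf_fwhm_mm < 0 or self.noise_sigma_ref_hu < 0:
            raise ValueError("psf_fwhm_mm and noise_sigma_ref_hu must be >= 0")

    @property
    def noise_sigma_hu(self) -> float:
        """Noise SD at this dose: sigma_ref * sqrt(ctdi_ref / ctdi_vol)."""
        return self.noise_sigma_ref_hu * np.sqrt(self.ctdi_ref_mgy / self.ctdi_vol_mgy)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSettings":
        return cls(**d)


@dataclass
class CTVolume:
    """A HU voxel stack (slices x rows x cols) with spacing and settings."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]  # (slice, row, col)
    settings: AcquisitionSettings

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be (slices, rows, cols)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class GroundTruth:
    """Per-rod truth for a simulated volume.

    ``rod_masks`` are interior pixel masks (full in-plane coverage, one 2-D
    mask per rod, identical on every slice since rods run axially);
    ``rendered_contrast_hu`` is the kV-scaled contrast actually rendered.
    """

    layout: ModuleLayout
    transform: RigidTransform
    rod_masks: list[np.ndarray]
    rendered_contrast_hu: np.ndarray
    background_mask: np.ndarray
    base_hu: float

    def __post_init__(self) -> None:
        stack = np.array([m.astype(int) for m in self.rod_masks])
        if stack.sum(axis=0).max() > 1:
            raise ValueError("rod masks must be pairwise disjoint")
        if np.any(stack.sum(axis=0).astype(bool) & self.background_mask):
            raise ValueError("rod masks must be disjoint from the background mask")


@dataclass(frozen=True)
class PsychometricParams:
    """Logistic detection model on the index d = dHU * s / sigma.

    ``threshold`` is the index value at 50 % detection probability and
    ``width`` the logistic scale.  Defaults give difference-detail curves of
    realistic magnitude for an abdominal scan at ~10 HU noise (9 mm rods
    detected near 48 HU, 3 mm rods mostly missed below 80 HU).
    """

    threshold: float = 25.0
    width: float = 5.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")

    def detection_probability(self, contrast_hu, diameter_mm, noise_sigma_hu):
        d = np.asarray(contrast_hu, dtype=float) * np.asarray(diameter_mm, dtype=float)
        d = d / float(noise_sigma_hu)
        z = (d - self.threshold) / self.width
        return 1.0 / (1.0 + np.exp(-z))


def rendered_contrasts(
    layout: ModuleLayout, kv: int, kv_response: Mapping[int, float] | None = None
) -> np.ndarray:
    """Per-rod rendered contrast: target dHU scaled by f(kV) for iodine rods."""
    resp = DEFAULT_KV_RESPONSE if kv_response is None else kv_response
    out = np.empty(len(layout.rods))
    for j, rod in enumerate(layout.rods):
        f = resp[kv] if rod.spec.module_type == "contrast_agent" else 1.0
        out[j] = f * rod.spec.target_contrast_hu
    return out


def _block_mean(a: np.ndarray, s: int) -> np.ndarray:
    n0, n1 = a.shape[0] // s, a.shape[1] // s
    return a.reshape(n0, s, n1, s).mean(axis=(1, 3))


def render_slice(
    layout: ModuleLayout,
    transform: RigidTransform,
    n_pixels: int,
    contrasts_hu: Sequence[float],
    base_hu: float = 60.0,
    body_hu: float = 120.0,
    supersample: int = 4,
    return_masks: bool = False,
):
    """Rasterise one noiseless module slice.

    Pixel values are area-weighted through ``supersample``^2 sub-pixel
    samples, so edge pixels carry partial-volume fractions.  With
    ``return_masks`` the per-rod interior masks (pixels at full coverage) and
    the pre-erosion background mask are returned as well.
    """
    s = int(supersample)
    if s < 1:
        raise ValueError("supersample must be >= 1")
    n = int(n_pixels)
    barrel_r = layout.barrel_diameter_mm / 2.0

    off = (np.arange(s) + 0.5) / s - 0.5
    rows = (np.arange(n)[:, None] + off[None, :]).ravel()
    cols = (np.arange(n)[:, None] + off[None, :]).ravel()
    x, y = transform.pixel_to_module(rows[:, None], cols[None, :])

    img = np.full((n, n), float(body_hu))
    barrel_cov = _block_mean(x * x + y * y <= barrel_r * barrel_r, s)
    img += (base_hu - body_hu) * barrel_cov

    masks: list[np.ndarray] = []
    for rod, c in zip(layout.rods, contrasts_hu):
        r = rod.spec.radius_mm
        inside = (x - rod.x_mm) ** 2 + (y - rod.y_mm) ** 2 <= r * r
        cov = _block_mean(inside, s)
        img += float(c) * cov
        if return_masks:
            masks.append(cov >= 1.0 - 1e-12)

    if not return_masks:
        return img

    xc, yc = transform.pixel_to_module(
        np.arange(n, dtype=float)[:, None], np.arange(n, dtype=float)[None, :])
    bg = xc * xc + yc * yc <= (barrel_r - 2.0) ** 2
    for rod in layout.rods:
        r = rod.spec.radius_mm + 2.0
        bg &= (xc - rod.x_mm) ** 2 + (yc - rod.y_mm) ** 2 > r * r
    return img, masks, bg


def _check_in_field(layout: ModuleLayout, transform: RigidTransform, n: int) -> None:
    for rod in layout.rods:
        row, col = transform.module_to_pixel(rod.x_mm, rod.y_mm)
        r_px = rod.spec.radius_mm / transform.pixel_spacing_mm
        if (row - r_px < 0 or row + r_px > n - 1
                or col - r_px < 0 or col + r_px > n - 1):
            raise GeometryError(
                f"rod at ({rod.x_mm:.1f}, {rod.y_mm:.1f}) mm falls outside the "
                f"{n}x{n} px field of view")


def simulate_volume(
    layout: ModuleLayout,
    settings: AcquisitionSettings,
    seed: int,
    rotation_deg: float = 0.0,
    shift_mm: tuple[float, float] = (0.0, 0.0),
    base_hu: float = 60.0,
    body_hu: float = 120.0,
    kv_response: Mapping[int, float] | None = None,
    supersample: int = 4,
) -> tuple[CTVolume, GroundTruth]:
    """Simulate a CT volume of one module plus its ground truth.

    The module is placed at the image centre, rotated by ``rotation_deg`` and
    shifted by ``shift_mm`` (module-plane mm).  Identical arguments and seed
    give a bit-identical volume.
    """
    n = settings.n_pixels
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    transform = RigidTransform(rotation_deg, tuple(shift_mm),
                               settings.pixel_spacing_mm, center)
    _check_in_field(layout, transform, n)

    contrasts = rendered_contrasts(layout, settings.kv, kv_response)
    clean, masks, bg = render_slice(
        layout, transform, n, contrasts, base_hu=base_hu, body_hu=body_hu,
        supersample=supersample, return_masks=True)

    if settings.psf_fwhm_mm > 0:
        sigma_px = settings.psf_fwhm_mm * _FWHM_TO_SIGMA / settings.pixel_spacing_mm
        clean = gaussian_filter(clean, sigma_px, mode="nearest")

    voxels = np.repeat(clean[None, :, :], settings.n_slices, axis=0)
    sigma = settings.noise_sigma_hu
    if sigma > 0:
        rng = np.random.default_rng(seed)
        voxels = voxels + rng.normal(0.0, sigma, size=voxels.shape)

    volume = CTVolume(
        voxels=voxels,
        spacing_mm=(settings.slice_thickness_mm, settings.pixel_spacing_mm,
                    settings.pixel_spacing_mm),
        settings=settings,
    )
    truth = GroundTruth(
        layout=layout,
        transform=transform,
        rod_masks=masks,
        rendered_contrast_hu=contrasts,
        background_mask=bg,
        base_hu=base_hu,
    )
    return volume, truth


def simulate_observer(
    truth: GroundTruth,
    noise_sigma_hu: float,
    params: PsychometricParams,
    seed: int,
    observer_id: str = "sim",
    false_click_rate: float = 0.0,
    slice_index: int = 0,
) -> ObserverSession:
    """Generate one click session from a psychometric simulated observer.

    Each rod is clicked (at its centre) independently with the logistic
    probability of :class:`PsychometricParams`; ``false_click_rate`` is the
    expected number of spurious background clicks per session (Poisson,
    uniform over the barrel).
    """
    if noise_sigma_hu <= 0:
        raise ValueError("noise_sigma_hu must be positive")
    rng = np.random.default_rng(seed)
    layout = truth.layout
    clicks: list[ClickRecord] = []
    for rod, c in zip(layout.rods, truth.rendered_contrast_hu):
        p = params.detection_probability(c, rod.spec.diameter_mm, noise_sigma_hu)
        if rng.random() < p:
            row, col = truth.transform.module_to_pixel(rod.x_mm, rod.y_mm)
            clicks.append(ClickRecord(x_px=float(col), y_px=float(row),
                                      slice_index=slice_index))
    n_false = int(rng.poisson(false_click_rate)) if false_click_rate > 0 else 0
    barrel_r = layout.barrel_diameter_mm / 2.0 - 2.0
    for _ in range(n_false):
        rho = barrel_r * np.sqrt(rng.random())
        phi = 2 * np.pi * rng.random()
        row, col = truth.transform.module_to_pixel(rho * np.cos(phi),
                                                   rho * np.sin(phi))
        clicks.append(ClickRecord(x_px=float(col), y_px=float(row),
                                  slice_index=slice_index))
    return ObserverSession(observer_id=observer_id, clicks=clicks,
                           meta={"window_ww": 400, "window_wc": 60,
                                 "module_id": layout.module_id})
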