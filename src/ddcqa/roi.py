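"""ROI extraction and contrast verification for DDC module scans.

The measurement chain mirrors an automated phantom-QA workflow: register the
known rod layout to the image (rotation grid search maximising normalised
cross-correlation, plus integer translation via FFT cross-correlation),
build per-rod and background pixel masks, peel off each ROI's periphery with
a 5-pixel-diameter disc erosion so template inaccuracies and edge
partial-volume pixels do not bias the statistics, and reduce the remaining
pixels to per-slice and aggregate summaries.

Verification analytics operate on tables of measured contrasts:
per-diameter linearity of measured vs target contrast, long-term drift, and
the energy (tube-voltage) response that separates iodine from sucrose rods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .ddc import DDCCurve  # noqa: F401  (re-exported pipeline type)
from .errors import InsufficientDataError, RegistrationError
from .phantom import ModuleLayout
from .simulate import CTVolume, render_slice, rendered_contrasts
from .transform import RigidTransform

__all__ = [
    "ROIStats",
    "ContrastMeasurement",
    "RegressionResult",
    "disc_footprint",
    "erode_roi",
    "register_template",
    "build_rod_masks",
    "build_background_mask",
    "rod_statistics",
    "measure_contrasts",
    "fit_linearity",
    "drift_summary",
    "energy_response",
]


@dataclass
class ROIStats:
    """Summary statistics of one ROI, per slice and pooled across slices."""

    label: str
    n_pixels: int
    mean: float
    sd: float
    min: float
    max: float
    median: float
    per_slice: pd.DataFrame | None = None
    unmeasurable: bool = False


@dataclass(frozen=True)
class ContrastMeasurement:
    """Measured contrast of one rod: rod mean minus background mean (HU)."""

    diameter_mm: float
    target_contrast_hu: float
    module_type: str
    measured_contrast_hu: float
    kv: int | None = None
    ctdi_vol_mgy: float | None = None
    date: str | None = None
    kernel_label: str | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


# -- morphology ------------------------------------------------------------

def disc_footprint(diameter_px: int) -> np.ndarray:
    """Disc structuring element: offsets whose centre lies within d/2."""
    if diameter_px < 1:
        raise ValueError("diameter_px must be >= 1")
    r = diameter_px / 2.0
    k = int(np.floor(r))
    yy, xx = np.mgrid[-k:k + 1, -k:k + 1]
    return (yy * yy + xx * xx) <= r * r + 1e-12


def erode_roi(mask: np.ndarray, disc_diameter_px: int = 5) -> np.ndarray:
    """Morphological erosion by a disc; an empty result is legal and must be
    flagged downstream, not silently used."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must be non-empty")
    return ndimage.binary_erosion(mask, structure=disc_footprint(disc_diameter_px),
                                  border_value=0)


# -- registration ----------------------------------------------------------

def _ncc_shift(image: np.ndarray, template: np.ndarray,
               max_shift_px: int) -> tuple[float, tuple[int, int]]:
    """Best integer shift of template (within +-max_shift) and its NCC score."""
    a = image - image.mean()
    b = template - template.mean()
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    cc = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    shifts = np.fft.fftfreq(a.shape[0], 1 / a.shape[0]).astype(int)
    keep = np.abs(shifts) <= max_shift_px
    sub = cc[np.ix_(keep, keep)]
    ij = np.unravel_index(np.argmax(sub), sub.shape)
    dr = int(shifts[keep][ij[0]])
    dc = int(shifts[keep][ij[1]])
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    score = float(sub[ij] / denom) if denom > 0 else 0.0
    return score, (dr, dc)


def register_template(
    volume: CTVolume,
    layout: ModuleLayout,
    rotation_step_deg: float = 0.5,
    coarse_step_deg: float = 2.0,
    rotation_range_deg: tuple[float, float] = (-180.0, 180.0),
    max_shift_mm: float = 10.0,
    corr_floor: float = 0.2,
    base_hu: float = 60.0,
    body_hu: float = 120.0,
) -> RigidTransform:
    """Recover the module's rigid pose from the image.

    A noiseless template of the layout is rendered over a coarse rotation
    grid, then a fine grid (``rotation_step_deg``) around the best coarse
    angle, scoring each angle by the normalised cross-correlation at the best
    integer translation; a parabolic sub-step refinement interpolates the
    final angle.  Raises :class:`RegistrationError` when the best correlation
    stays below ``corr_floor`` (e.g. pure-noise input).
    """
    n = volume.voxels.shape[1]
    if volume.voxels.shape[2] != n:
        raise ValueError("registration expects square slices")
    spacing = volume.spacing_mm[1]
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    image = volume.voxels.mean(axis=0)
    contrasts = rendered_contrasts(layout, volume.settings.kv)
    max_shift_px = max(1, int(round(max_shift_mm / spacing)))

    def score_angle(theta: float) -> tuple[float, tuple[int, int]]:
        tf = RigidTransform(theta, (0.0, 0.0), spacing, center)
        tmpl = render_slice(layout, tf, n, contrasts, base_hu=base_hu,
                            body_hu=body_hu, supersample=1)
        return _ncc_shift(image, tmpl, max_shift_px)

    lo, hi = rotation_range_deg
    coarse = np.arange(lo, hi, coarse_step_deg)
    coarse_scores = [score_angle(t)[0] for t in coarse]
    best_coarse = coarse[int(np.argmax(coarse_scores))]

    fine = np.arange(best_coarse - coarse_step_deg,
                     best_coarse + coarse_step_deg + 1e-9, rotation_step_deg)
    fine_results = [score_angle(t) for t in fine]
    fine_scores = np.array([s for s, _ in fine_results])
    j = int(np.argmax(fine_scores))
    best_score, (dr, dc) = fine_results[j]
    if best_score < corr_floor:
        raise RegistrationError(
            f"best correlation {best_score:.3f} below floor {corr_floor}")

    # parabolic sub-step refinement of the rotation angle
    theta = float(fine[j])
    if 0 < j < len(fine) - 1:
        y0, y1, y2 = fine_scores[j - 1], fine_scores[j], fine_scores[j + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            theta += 0.5 * rotation_step_deg * (y0 - y2) / denom

    # peak at (dr, dc): template must move dr rows down / dc cols right;
    # in module-plane mm that is x += dc*spacing, y -= dr*spacing
    shift = (dc * spacing, -dr * spacing)
    return RigidTransform(theta, shift, spacing, center)


# -- masks and statistics --------------------------------------------------

def build_rod_masks(layout: ModuleLayout, transform: RigidTransform,
                    shape: tuple[int, int]) -> list[np.ndarray]:
    """Per-rod masks: pixels whose centre lies inside the rod footprint."""
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    x, y = transform.pixel_to_module(rows, cols)
    masks = []
    for rod in layout.rods:
        r = rod.spec.radius_mm
        masks.append((x - rod.x_mm) ** 2 + (y - rod.y_mm) ** 2 <= r * r)
    return masks


def build_background_mask(layout: ModuleLayout, transform: RigidTransform,
                          shape: tuple[int, int], rod_dilation_mm: float = 2.0,
                          barrel_margin_mm: float = 2.0) -> np.ndarray:
    """Background (epoxy) mask: barrel interior minus dilated rod footprints.

    The precise background region is a package convention: all pixels at
    least ``barrel_margin_mm`` inside the barrel and ``rod_dilation_mm``
    clear of every rod footprint, eroded downstream like any other ROI.
    """
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    x, y = transform.pixel_to_module(rows, cols)
    barrel_r = layout.barrel_diameter_mm / 2.0 - barrel_margin_mm
    bg = x * x + y * y <= barrel_r * barrel_r
    for rod in layout.rods:
        r = rod.spec.radius_mm + rod_dilation_mm
        bg &= (x - rod.x_mm) ** 2 + (y - rod.y_mm) ** 2 > r * r
    return bg


def _select_slices(n_slices: int, slices: list[int] | None) -> list[int]:
    if slices is not None:
        if not slices:
            raise ValueError("at least one slice must be selected")
        return list(slices)
    # default: drop one slice at each end (module-edge partial volume)
    if n_slices >= 3:
        return list(range(1, n_slices - 1))
    return list(range(n_slices))


def _stats_for_mask(voxels: np.ndarray, mask: np.ndarray, label: str,
                    slices: list[int]) -> ROIStats:
    if not mask.any():
        return ROIStats(label=label, n_pixels=0, mean=np.nan, sd=np.nan,
                        min=np.nan, max=np.nan, median=np.nan,
                        unmeasurable=True)
    rows = []
    pooled = []
    for k in slices:
        vals = voxels[k][mask]
        pooled.append(vals)
        rows.append({"slice": k, "n_pixels": vals.size,
                     "mean": vals.mean(), "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                     "min": vals.min(), "max": vals.max(),
                     "median": np.median(vals)})
    allv = np.concatenate(pooled)
    return ROIStats(
        label=label, n_pixels=int(allv.size), mean=float(allv.mean()),
        sd=float(allv.std(ddof=1)) if allv.size > 1 else 0.0,
        min=float(allv.min()), max=float(allv.max()),
        median=float(np.median(allv)), per_slice=pd.DataFrame(rows))


def rod_statistics(
    volume: CTVolume,
    layout: ModuleLayout,
    transform: RigidTransform,
    slices: list[int] | None = None,
    erosion_diameter_px: int = 5,
    rod_dilation_mm: float = 2.0,
) -> tuple[list[ROIStats], ROIStats]:
    """Eroded-ROI statistics for every rod and for the epoxy background.

    An ROI whose eroded mask is empty is returned with ``unmeasurable=True``
    rather than raising, so one thin rod cannot abort a whole verification
    run.
    """
    shape = volume.voxels.shape[1:]
    sel = _select_slices(volume.n_slices, slices)
    rod_masks = build_rod_masks(layout, transform, shape)
    bg_mask = build_background_mask(layout, transform, shape,
                                    rod_dilation_mm=rod_dilation_mm)
    per_rod = []
    for rod, mask in zip(layout.rods, rod_masks):
        label = f"{rod.spec.diameter_mm:g}mm_{rod.spec.target_contrast_hu:g}HU"
        eroded = (erode_roi(mask, erosion_diameter_px)
                  if mask.any() else np.zeros(shape, bool))
        per_rod.append(_stats_for_mask(volume.voxels, eroded, label, sel))
    bg_eroded = erode_roi(bg_mask, erosion_diameter_px)
    bg_stats = _stats_for_mask(volume.voxels, bg_eroded, "background", sel)
    return per_rod, bg_stats


def measure_contrasts(
    layout: ModuleLayout,
    rod_stats: list[ROIStats],
    bg_stats: ROIStats,
    settings=None,
) -> list[ContrastMeasurement]:
    """Rod-minus-background contrasts; unmeasurable rods yield NaN."""
    out = []
    for rod, st in zip(layout.rods, rod_stats):
        measured = (np.nan if st.unmeasurable or bg_stats.unmeasurable
                    else st.mean - bg_stats.mean)
        out.append(ContrastMeasurement(
            diameter_mm=rod.spec.diameter_mm,
            target_contrast_hu=rod.spec.target_contrast_hu,
            module_type=rod.spec.module_type,
            measured_contrast_hu=float(measured),
            kv=getattr(settings, "kv", None),
            ctdi_vol_mgy=getattr(settings, "ctdi_vol_mgy", None),
            date=getattr(settings, "scan_date", None),
            kernel_label=getattr(settings, "kernel_label", None),
        ))
    return out


def measurements_to_frame(measurements: list[ContrastMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in measurements])


# -- verification analytics ------------------------------------------------

def fit_linearity(measurements: pd.DataFrame) -> dict[float, RegressionResult]:
    """Per-diameter OLS of measured on target contrast.

    An ideal module yields slope 1, intercept 0 for every diameter; small
    diameters in a real module fall below that line.
    """
    out = {}
    for diameter, grp in measurements.groupby("diameter_mm"):
        if grp["target_contrast_hu"].nunique() < 2:
            raise InsufficientDataError(
                f"diameter {diameter} mm has < 2 distinct target contrasts")
        res = stats.linregress(grp["target_contrast_hu"],
                               grp["measured_contrast_hu"])
        out[float(diameter)] = RegressionResult(
            slope=float(res.slope), intercept=float(res.intercept),
            r_squared=float(res.rvalue ** 2), n=len(grp))
    return out


def drift_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Stability over time per contrast series.

    Expects columns target_contrast_hu, date, measured_contrast_hu; returns
    per-date mean/sd plus, per series, the grand mean of the per-date means
    and their standard deviation (the dashed/dotted reference lines of a
    drift chart).
    """
    if measurements["date"].nunique() < 2:
        raise InsufficientDataError("drift summary needs >= 2 dates")
    per_date = (measurements
                .groupby(["target_contrast_hu", "date"])["measured_contrast_hu"]
                .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
                .reset_index())
    grand = (per_date.groupby("target_contrast_hu")["mean"]
             .agg(grand_mean="mean",
                  sd_of_means=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
             .reset_index())
    return per_date.merge(grand, on="target_contrast_hu")


def energy_response(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-(module type, kV) regression of measured vs target contrast.

    Native (sucrose) rods give equal slopes at every tube voltage; iodine
    rod slopes order with the kV contrast response.
    """
    if measurements["kv"].nunique() < 2:
        raise InsufficientDataError("energy response needs >= 2 kV levels")
    rows = []
    for (mt, kv), grp in measurements.groupby(["module_type", "kv"]):
        res = stats.linregress(grp["target_contrast_hu"],
                               grp["measured_contrast_hu"])
        rows.append({"module_type": mt, "kv": int(kv),
                     "slope": float(res.slope),
                     "intercept": float(res.intercept),
                     "r_squared": float(res.rvalue ** 2), "n": len(grp)})
    return pd.DataFrame(rows).sort_values(["module_type", "kv"]).reset_index(drop=True)
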