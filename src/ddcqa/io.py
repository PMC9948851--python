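"""File formats: DICOM series, simulator archives, curve tables, display export.

Stored CT pixel values round-trip to HU through the standard DICOM rescale
(HU = slope * stored + intercept).  Simulator output can also be archived
losslessly as an ``.npz`` + JSON pair, which preserves the float HU map and
the ground truth exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .ddc import DDCCurve, curves_to_frame, frame_to_curves
from .errors import FormatError
from .phantom import ModuleLayout
from .simulate import SUPPORTED_KV, AcquisitionSettings, CTVolume, GroundTruth
from .transform import RigidTransform

__all__ = [
    "read_ct",
    "write_dicom_series",
    "save_volume_archive",
    "export_display",
    "read_curves_csv",
    "write_curves_csv",
    "save_ground_truth",
    "load_ground_truth",
    "RunConfig",
]

_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"


def write_dicom_series(
    volume: CTVolume,
    directory,
    slope: float = 1.0,
    intercept: float = -1024.0,
) -> list[Path]:
    """Write a CT volume as one DICOM file per slice.

    Stored values are int16 with the given rescale, so integer-valued HU
    round-trip exactly; fractional HU are quantised to ``slope``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    st = volume.settings
    paths = []
    for i in range(volume.n_slices):
        stored = np.round((volume.voxels[i] - intercept) / slope)
        if stored.min() < -32768 or stored.max() > 32767:
            raise FormatError("HU values out of int16 stored range")
        ds = Dataset()
        ds.SOPClassUID = _CT_SOP_CLASS
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "DDC^Phantom"
        ds.PatientID = "DDCQA"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i * st.slice_thickness_mm)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [st.pixel_spacing_mm, st.pixel_spacing_mm]
        ds.SliceThickness = st.slice_thickness_mm
        ds.KVP = st.kv
        ds.ConvolutionKernel = st.kernel_label
        ds.AcquisitionDate = st.scan_date.replace("-", "")
        ds.Rows, ds.Columns = volume.voxels.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.RescaleType = "HU"
        ds.PixelData = stored.astype("<i2").tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def _settings_from_dicom(ds: Dataset, n_slices: int) -> AcquisitionSettings:
    kv = int(getattr(ds, "KVP", 120) or 120)
    if kv not in SUPPORTED_KV:
        kv = 120
    spacing = getattr(ds, "PixelSpacing", [0.5, 0.5])
    date = str(getattr(ds, "AcquisitionDate", "") or "20220101")
    return AcquisitionSettings(
        kv=kv,
        pixel_spacing_mm=float(spacing[0]),
        slice_thickness_mm=float(getattr(ds, "SliceThickness", 2.0) or 2.0),
        n_slices=n_slices,
        n_pixels=int(ds.Rows),
        kernel_label=str(getattr(ds, "ConvolutionKernel", "") or "unknown"),
        scan_date=f"{date[:4]}-{date[4:6]}-{date[6:8]}",
    )


def read_ct(path) -> CTVolume:
    """Read a CT volume from a DICOM series directory or a simulator archive.

    DICOM slices are sorted by z position (instance number as fallback) and
    converted to HU via the rescale tags; a directory mixing several series
    or lacking rescale tags is rejected.
    """
    path = Path(path)
    if (path / "volume.npz").exists():
        return _load_volume_archive(path)
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".dcm", ".ima") or p.suffix == "")
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"no DICOM slices found in {path}")
    uids = sorted({str(ds.SeriesInstanceUID) for ds in datasets})
    if len(uids) > 1:
        raise FormatError(
            "directory contains multiple series: " + ", ".join(uids))
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise FormatError("missing RescaleSlope/RescaleIntercept tags")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(ds.InstanceNumber)

    datasets.sort(key=sort_key)
    slices = [float(ds.RescaleSlope) * ds.pixel_array.astype(float)
              + float(ds.RescaleIntercept) for ds in datasets]
    voxels = np.stack(slices)
    st = _settings_from_dicom(datasets[0], len(datasets))
    return CTVolume(voxels=voxels,
                    spacing_mm=(st.slice_thickness_mm, st.pixel_spacing_mm,
                                st.pixel_spacing_mm),
                    settings=st)


def save_volume_archive(volume: CTVolume, directory) -> None:
    """Lossless simulator archive: float HU in .npz plus JSON settings."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(directory / "volume.npz", voxels=volume.voxels)
    with open(directory / "volume.json", "w") as fh:
        json.dump({"spacing_mm": list(volume.spacing_mm),
                   "settings": volume.settings.to_dict()}, fh, indent=2)


def _load_volume_archive(directory: Path) -> CTVolume:
    with open(directory / "volume.json") as fh:
        meta = json.load(fh)
    voxels = np.load(directory / "volume.npz")["voxels"]
    return CTVolume(voxels=voxels, spacing_mm=tuple(meta["spacing_mm"]),
                    settings=AcquisitionSettings.from_dict(meta["settings"]))


def export_display(
    volume: CTVolume, directory, ww: float = 400.0, wc: float = 60.0
) -> list[Path]:
    """Window a volume to 8-bit PNGs: [wc - ww/2, wc + ww/2] -> [0, 255].

    Half-integers round up (HU exactly at the window centre maps to 128 for
    the abdominal ww 400 / wc 60 window).
    """
    if ww <= 0:
        raise ValueError("window width must be positive")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo = wc - ww / 2.0
    paths = []
    for i in range(volume.n_slices):
        scaled = (volume.voxels[i] - lo) / ww * 255.0
        img = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
        p = directory / f"display_{i:04d}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths


def read_curves_csv(path) -> list[DDCCurve]:
    return frame_to_curves(pd.read_csv(path))


def write_curves_csv(curves: list[DDCCurve], path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def save_ground_truth(truth: GroundTruth, directory,
                      write_mask_images: bool = False) -> None:
    """Ground truth to JSON (+ optional PNG masks for visual inspection)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.layout.save(directory / "layout.json")
    doc = {
        "transform": truth.transform.to_dict(),
        "base_hu": truth.base_hu,
        "rendered_contrast_hu": [float(c) for c in truth.rendered_contrast_hu],
        "rod_masks": [np.flatnonzero(m.ravel()).tolist() for m in truth.rod_masks],
        "background_mask": np.flatnonzero(truth.background_mask.ravel()).tolist(),
        "shape": list(truth.background_mask.shape),
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(doc, fh)
    if write_mask_images:
        for j, m in enumerate(truth.rod_masks):
            iio.imwrite(directory / f"mask_rod_{j:02d}.png",
                        (m * np.uint8(255)))
        iio.imwrite(directory / "mask_background.png",
                    (truth.background_mask * np.uint8(255)))


def load_ground_truth(directory) -> GroundTruth:
    directory = Path(directory)
    layout = ModuleLayout.load(directory / "layout.json")
    with open(directory / "truth.json") as fh:
        doc = json.load(fh)
    shape = tuple(doc["shape"])

    def unflatten(idx):
        m = np.zeros(shape[0] * shape[1], dtype=bool)
        m[idx] = True
        return m.reshape(shape)

    return GroundTruth(
        layout=layout,
        transform=RigidTransform.from_dict(doc["transform"]),
        rod_masks=[unflatten(i) for i in doc["rod_masks"]],
        rendered_contrast_hu=np.asarray(doc["rendered_contrast_hu"]),
        background_mask=unflatten(doc["background_mask"]),
        base_hu=float(doc["base_hu"]),
    )


@dataclass
class RunConfig:
    """Flat, schema-checked run configuration (YAML)."""

    seed: int = 0
    layout: dict = dc_field(default_factory=dict)
    acquisition: dict = dc_field(default_factory=dict)
    analysis: dict = dc_field(default_factory=dict)
    psychometric: dict = dc_field(default_factory=dict)
    fit: dict = dc_field(default_factory=dict)
    bootstrap: dict = dc_field(default_factory=dict)
    outputs: dict = dc_field(default_factory=dict)

    _SECTION_KEYS = {
        "layout": {"min_gap_mm", "edge_margin_mm", "module_type", "module_id"},
        "acquisition": set(AcquisitionSettings.__dataclass_fields__),
        "analysis": {"erosion_diameter_px", "rod_dilation_mm", "corr_floor",
                     "rotation_step_deg", "coarse_step_deg", "slices"},
        "psychometric": {"threshold", "width", "false_click_rate",
                         "noise_sigma_hu"},
        "fit": {"observer_model", "tolerance_mm"},
        "bootstrap": {"k", "m"},
        "outputs": {"directory", "write_dicom", "write_display"},
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = set(cls._SECTION_KEYS) | {"seed"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for section, keys in cls._SECTION_KEYS.items():
            extra = set(doc.get(section, {}) or {}) - keys
            if extra:
                raise ValueError(
                    f"unknown keys in [{section}]: {sorted(extra)}")
        return cls(**doc)

    def acquisition_settings(self) -> AcquisitionSettings:
        return AcquisitionSettings(**self.acquisition)
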