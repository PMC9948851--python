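"""Rigid in-plane transform between module-local mm and image pixel coordinates.

Module-local coordinates have their origin at the barrel centre, x to the
right and y up.  Pixel coordinates are 0-based (row, col) with pixel centres
at integer positions; rows increase downwards, so the y axis flips sign.
The transform rotates by ``rotation_deg`` (counter-clockwise in module
coordinates), then shifts by ``shift_mm`` and scales by the pixel spacing
about ``center_px``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, radians, sin

import numpy as np

__all__ = ["RigidTransform"]


@dataclass(frozen=True)
class RigidTransform:
    rotation_deg: float
    shift_mm: tuple[float, float]
    pixel_spacing_mm: float
    center_px: tuple[float, float]  # (row, col) of the module origin at zero shift

    def module_to_pixel(self, x_mm, y_mm):
        """Map module-local mm to (row, col) pixel coordinates."""
        th = radians(self.rotation_deg)
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        xr = x * cos(th) - y * sin(th) + self.shift_mm[0]
        yr = x * sin(th) + y * cos(th) + self.shift_mm[1]
        col = self.center_px[1] + xr / self.pixel_spacing_mm
        row = self.center_px[0] - yr / self.pixel_spacing_mm
        return row, col

    def pixel_to_module(self, row, col):
        """Inverse of :meth:`module_to_pixel`."""
        th = radians(self.rotation_deg)
        xr = (np.asarray(col, dtype=float) - self.center_px[1]) * self.pixel_spacing_mm
        yr = (self.center_px[0] - np.asarray(row, dtype=float)) * self.pixel_spacing_mm
        xr = xr - self.shift_mm[0]
        yr = yr - self.shift_mm[1]
        x = xr * cos(th) + yr * sin(th)
        y = -xr * sin(th) + yr * cos(th)
        return x, y

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg,
            "shift_mm": list(self.shift_mm),
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "center_px": list(self.center_px),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation_deg=float(d["rotation_deg"]),
            shift_mm=tuple(d["shift_mm"]),
            pixel_spacing_mm=float(d["pixel_spacing_mm"]),
            center_px=tuple(d["center_px"]),
        )
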