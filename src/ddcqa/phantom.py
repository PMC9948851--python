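"""Geometric and material model of the body phantom and its DDC modules.

A DDC (difference-detail-curve) module is an 80 mm epoxy cylinder holding 30
cylindrical contrast rods: every combination of six diameters (3-9 mm) and
five target contrasts (16-80 HU above the epoxy base).  Rod positions are
randomised so observers cannot infer unseen rods from a regular pattern.
Two module types exist: one doped with an iodine contrast agent (NaI
solution) and one "native" module doped with sucrose.

The module plugs into an elliptical PMMA body phantom available in five
cross-sections; body size is summarised by the AAPM effective diameter
sqrt(AP * LAT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from math import sqrt
from typing import Literal

import numpy as np
import pandas as pd

from .errors import PlacementError

__all__ = [
    "DIAMETERS_MM",
    "TARGET_CONTRASTS_HU",
    "BODY_SLICE_SIZES_CM",
    "ModuleType",
    "RodSpec",
    "RodPlacement",
    "ModuleLayout",
    "MaterialsTable",
    "BodyPhantom",
    "generate_layout",
    "lookup_mixture",
    "effective_diameter",
    "effective_diameter_label",
]

#: Rod diameters present in every module (mm).
DIAMETERS_MM: tuple[int, ...] = (3, 4, 5, 6, 8, 9)

#: Nominal rod contrasts above the epoxy base (HU).
TARGET_CONTRASTS_HU: tuple[int, ...] = (16, 32, 48, 64, 80)

#: Elliptical body slice sizes (AP, LAT) in cm.
BODY_SLICE_SIZES_CM: tuple[tuple[int, int], ...] = (
    (16, 22), (20, 24), (24, 32), (28, 34), (30, 34))

ModuleType = Literal["contrast_agent", "native"]
_MODULE_TYPES = ("contrast_agent", "native")

BARREL_DIAMETER_MM = 80.0
MODULE_DEPTH_MM = 40.0


@dataclass(frozen=True)
class RodSpec:
    """One cylindrical contrast rod: diameter (mm) and nominal contrast (HU)."""

    diameter_mm: float
    target_contrast_hu: float
    module_type: ModuleType = "contrast_agent"

    def __post_init__(self) -> None:
        if self.diameter_mm not in DIAMETERS_MM:
            raise ValueError(
                f"diameter must be one of {DIAMETERS_MM} mm, got {self.diameter_mm}")
        if self.target_contrast_hu not in TARGET_CONTRASTS_HU:
            raise ValueError(
                f"target contrast must be one of {TARGET_CONTRASTS_HU} HU, "
                f"got {self.target_contrast_hu}")
        if self.module_type not in _MODULE_TYPES:
            raise ValueError(f"unknown module type {self.module_type!r}")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class RodPlacement:
    """A rod together with its centre in module-local mm (origin at barrel
    centre, x right, y up)."""

    spec: RodSpec
    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class ModuleLayout:
    """Full geometric description of one DDC module.

    The eight fiducial angles locate the triangular cutouts milled into the
    barrel for automatic identification; the barcode is the module's unique
    id.  Both are carried as metadata: registration in this package keys on
    the (unique, randomised) rod pattern itself.
    """

    module_id: str
    rods: tuple[RodPlacement, ...]
    barrel_diameter_mm: float = BARREL_DIAMETER_MM
    depth_mm: float = MODULE_DEPTH_MM
    fiducial_angles_deg: tuple[float, ...] = tuple(45.0 * i for i in range(8))
    barcode: int = 0
    rng_seed: int | None = None
    min_gap_mm: float = 1.0
    edge_margin_mm: float = 3.0

    @property
    def module_type(self) -> ModuleType:
        return self.rods[0].spec.module_type

    def validate(self) -> None:
        """Raise ``PlacementError`` if any layout invariant is violated."""
        if len(self.rods) != 30:
            raise PlacementError(f"expected 30 rods, found {len(self.rods)}")
        combos = {(r.spec.diameter_mm, r.spec.target_contrast_hu) for r in self.rods}
        if len(combos) != 30:
            raise PlacementError("duplicate (diameter, contrast) combination")
        radius = self.barrel_diameter_mm / 2.0
        for r in self.rods:
            d = sqrt(r.x_mm ** 2 + r.y_mm ** 2)
            if d + r.spec.radius_mm > radius - self.edge_margin_mm + 1e-9:
                raise PlacementError(
                    f"rod {r.spec.diameter_mm} mm / {r.spec.target_contrast_hu} HU "
                    f"violates the edge margin")
        for i, a in enumerate(self.rods):
            for b in self.rods[i + 1:]:
                dist = sqrt((a.x_mm - b.x_mm) ** 2 + (a.y_mm - b.y_mm) ** 2)
                if dist < a.spec.radius_mm + b.spec.radius_mm + self.min_gap_mm - 1e-9:
                    raise PlacementError("rod footprints overlap or violate min_gap")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["rods"] = [
            {"diameter_mm": r.spec.diameter_mm,
             "target_contrast_hu": r.spec.target_contrast_hu,
             "module_type": r.spec.module_type,
             "x_mm": r.x_mm, "y_mm": r.y_mm}
            for r in self.rods
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleLayout":
        rods = tuple(
            RodPlacement(
                RodSpec(r["diameter_mm"], r["target_contrast_hu"], r["module_type"]),
                r["x_mm"], r["y_mm"])
            for r in d["rods"]
        )
        kwargs = {k: v for k, v in d.items() if k != "rods"}
        kwargs["fiducial_angles_deg"] = tuple(kwargs.get("fiducial_angles_deg", ()))
        return cls(rods=rods, **kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ModuleLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def generate_layout(
    seed: int,
    min_gap_mm: float = 1.0,
    edge_margin_mm: float = 3.0,
    module_type: ModuleType = "contrast_agent",
    module_id: str | None = None,
    max_attempts: int = 100_000,
) -> ModuleLayout:
    """Generate a randomised 30-rod module layout by rejection sampling.

    Rods are placed largest-first, each centre drawn uniformly over the
    admissible disc until it clears every previously placed rod by
    ``min_gap_mm`` and stays ``edge_margin_mm`` inside the barrel.  The same
    seed always yields the same layout.

    Raises
    ------
    PlacementError
        If a rod cannot be placed within ``max_attempts`` draws.
    """
    if min_gap_mm < 0 or edge_margin_mm < 0:
        raise ValueError("min_gap_mm and edge_margin_mm must be >= 0")
    rng = np.random.default_rng(seed)
    barrel_radius = BARREL_DIAMETER_MM / 2.0
    specs = sorted(
        (RodSpec(d, c, module_type) for d in DIAMETERS_MM for c in TARGET_CONTRASTS_HU),
        key=lambda s: (-s.diameter_mm, s.target_contrast_hu),
    )
    placed: list[RodPlacement] = []
    for spec in specs:
        rmax = barrel_radius - edge_margin_mm - spec.radius_mm
        if rmax <= 0:
            raise PlacementError(
                f"edge margin leaves no room for a {spec.diameter_mm} mm rod")
        for attempt in range(max_attempts):
            rho = rmax * sqrt(rng.random())
            phi = 2.0 * np.pi * rng.random()
            x, y = rho * np.cos(phi), rho * np.sin(phi)
            ok = all(
                (x - p.x_mm) ** 2 + (y - p.y_mm) ** 2
                >= (spec.radius_mm + p.spec.radius_mm + min_gap_mm) ** 2
                for p in placed
            )
            if ok:
                placed.append(RodPlacement(spec, float(x), float(y)))
                break
        else:
            raise PlacementError(
                f"could not place {spec.diameter_mm} mm / "
                f"{spec.target_contrast_hu} HU rod after {max_attempts} attempts: "
                f"min_gap={min_gap_mm} mm, edge_margin={edge_margin_mm} mm")
    barcode = int(rng.integers(0, 2**31 - 1))
    layout = ModuleLayout(
        module_id=module_id or f"{module_type}-{seed}",
        rods=tuple(placed),
        barcode=barcode,
        rng_seed=int(seed),
        min_gap_mm=float(min_gap_mm),
        edge_margin_mm=float(edge_margin_mm),
    )
    layout.validate()
    return layout


class MaterialsTable:
    """Epoxy mixture recipes per (module type, target contrast).

    Each row gives the weight percentage of Translux D150 resin and of the
    additive (a 1:1 NaI/water solution for the contrast-agent module,
    sucrose for the native module).  Fractions in a row sum to 100 %.
    """

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            with resources.files("ddcqa.data").joinpath("materials.csv").open() as fh:
                frame = pd.read_csv(fh)
        self.frame = frame
        self._check()

    def _check(self) -> None:
        total = self.frame["resin_pct"] + self.frame["additive_pct"]
        if not np.allclose(total, 100.0, atol=0.01):
            raise ValueError("mixture fractions must sum to 100 %")
        for mt, grp in self.frame.groupby("module_type"):
            g = grp.sort_values("target_contrast_hu")
            if not g["additive_pct"].is_monotonic_increasing or \
                    g["additive_pct"].duplicated().any():
                raise ValueError(
                    f"additive fraction must increase strictly with contrast ({mt})")

    def lookup(self, target_contrast_hu: float, module_type: ModuleType) -> dict:
        sel = self.frame[
            (self.frame["module_type"] == module_type)
            & (self.frame["target_contrast_hu"] == target_contrast_hu)
        ]
        if len(sel) != 1:
            raise ValueError(
                f"no mixture for target {target_contrast_hu} HU in module "
                f"type {module_type!r}")
        row = sel.iloc[0]
        return {
            "resin_pct": float(row["resin_pct"]),
            "additive": str(row["additive"]),
            "additive_pct": float(row["additive_pct"]),
        }


_DEFAULT_TABLE: MaterialsTable | None = None


def lookup_mixture(target_contrast_hu: float, module_type: ModuleType) -> dict:
    """Weight fractions for one rod recipe (see :class:`MaterialsTable`)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = MaterialsTable()
    return _DEFAULT_TABLE.lookup(target_contrast_hu, module_type)


def effective_diameter(ap_cm: float, lat_cm: float) -> float:
    """AAPM effective diameter sqrt(AP * LAT) of an elliptical cross-section, cm."""
    if ap_cm <= 0 or lat_cm <= 0:
        raise ValueError("AP and LAT must be positive")
    return sqrt(ap_cm * lat_cm)


def effective_diameter_label(
    ap_cm: float, lat_cm: float, overrides: dict[tuple[float, float], str] | None = None
) -> str:
    """Nearest-cm label for an effective diameter, e.g. ``"32 cm"``.

    ``overrides`` maps (AP, LAT) to a custom label for sites that round
    differently (a 24 x 32 cm body, sqrt = 27.7 cm, is conventionally
    labelled "27 cm").
    """
    if overrides and (ap_cm, lat_cm) in overrides:
        return overrides[(ap_cm, lat_cm)]
    return f"{round(effective_diameter(ap_cm, lat_cm))} cm"


@dataclass(frozen=True)
class BodyPhantom:
    """Stack of elliptical PMMA slices with two 80 mm module slots."""

    ap_cm: float
    lat_cm: float
    n_slices: int = 3
    module_slot_offsets_cm: tuple[tuple[float, float], ...] = ((-6.0, 0.0), (6.0, 0.0))
    label_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.ap_cm, self.lat_cm) not in BODY_SLICE_SIZES_CM:
            raise ValueError(
                f"slice size ({self.ap_cm}, {self.lat_cm}) cm not in "
                f"{BODY_SLICE_SIZES_CM}")

    @property
    def effective_diameter_cm(self) -> float:
        return effective_diameter(self.ap_cm, self.lat_cm)

    @property
    def label(self) -> str:
        over = {tuple(k) if not isinstance(k, tuple) else k: v
                for k, v in self.label_overrides.items()}
        return effective_diameter_label(self.ap_cm, self.lat_cm, over)
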