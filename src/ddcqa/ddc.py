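"""Click-session evaluation and the difference-detail-curve (DDC) model.

A click session records which low-contrast rods an observer marked in a CT
scan of a DDC module.  Matching clicks to the known rod layout yields, for
each rod diameter s, the minimal nominal contrast still detected,
Delta_min(s) -- one DDC per session.  Psychophysics (Weber/Fechner-type
laws) motivates a log-linear model for its expectation:

    E[Delta_min(s)] = alpha + beta * ln s                         (pooled)

and, with several observers i, observer-bias terms constrained to average
zero:

    E[Delta_min(s)] = (alpha + alpha_i') + (beta + beta_i') * ln s,
    sum_i alpha_i' = sum_i beta_i' = 0.

Because the parametrisation (alpha + alpha_i', beta + beta_i') is a
bijection onto per-observer lines under the sum-to-zero constraint, the
constrained least-squares solution equals independent per-observer OLS fits
recombined by averaging -- which is how :func:`fit_observer_bias` computes
it.  Tests verify this equivalence against a generic effects-coded solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .phantom import DIAMETERS_MM, ModuleLayout
from .transform import RigidTransform

__all__ = [
    "MISSING",
    "ClickRecord",
    "ObserverSession",
    "DDCCurve",
    "DDCFit",
    "match_clicks",
    "extract_ddc",
    "fit_pooled",
    "fit_observer_bias",
    "predict",
    "curves_to_frame",
    "frame_to_curves",
    "load_reference_curves",
]

#: Sentinel for a diameter at which no rod was detected (printed as "-").
MISSING = None


@dataclass(frozen=True)
class ClickRecord:
    """One observer click in image pixel coordinates (x = col, y = row)."""

    x_px: float
    y_px: float
    slice_index: int = 0
    timestamp: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_px) and np.isfinite(self.y_px)):
            raise ValueError("click position must be finite")


@dataclass
class ObserverSession:
    """All clicks of one observer on one scan.

    ``meta`` carries display and provenance information (the evaluation
    window is fixed at ww 400 / wc 60 for abdominal scans).
    """

    observer_id: str
    clicks: list[ClickRecord]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.observer_id:
            raise ValueError("observer_id must be non-empty")

    def to_dict(self) -> dict:
        return {
            "observer_id": self.observer_id,
            "clicks": [
                {"x_px": c.x_px, "y_px": c.y_px, "slice_index": c.slice_index,
                 "timestamp": c.timestamp}
                for c in self.clicks
            ],
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverSession":
        clicks = [ClickRecord(**c) for c in d["clicks"]]
        return cls(observer_id=d["observer_id"], clicks=clicks,
                   meta=d.get("meta", {}))


@dataclass
class DDCCurve:
    """One difference-detail curve: diameter (mm) -> minimal detected contrast (HU).

    ``points`` maps every module diameter to a nominal contrast from the
    module's contrast set, or to :data:`MISSING` when the observer saw no rod
    of that size.
    """

    observer_id: str
    points: dict[float, float | None]
    module_type: str = "contrast_agent"
    kv: int | None = None
    ctdi_vol_mgy: float | None = None
    scan_id: str | None = None
    date: str | None = None

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """(diameters, contrasts) of the non-missing points."""
        items = [(s, v) for s, v in sorted(self.points.items()) if v is not None]
        if not items:
            return np.empty(0), np.empty(0)
        s, v = zip(*items)
        return np.asarray(s, dtype=float), np.asarray(v, dtype=float)


@dataclass
class DDCFit:
    """Fitted log-linear DDC model (natural logarithm of the diameter).

    ``alpha_i`` / ``beta_i`` are per-observer offsets summing to zero; both
    are empty for a pooled fit.
    """

    alpha: float
    beta: float
    alpha_i: dict[str, float] = field(default_factory=dict)
    beta_i: dict[str, float] = field(default_factory=dict)
    n_points: int = 0
    r_squared: float = float("nan")
    residuals: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "alpha_i": dict(self.alpha_i),
            "beta_i": dict(self.beta_i),
            "n_points": self.n_points,
            "r_squared": self.r_squared,
        }


def match_clicks(
    session: ObserverSession,
    layout: ModuleLayout,
    transform: RigidTransform,
    tolerance_mm: float = 1.0,
) -> tuple[set[int], list[ClickRecord]]:
    """Assign clicks to rods; unassigned clicks are false clicks.

    A click belongs to the rod whose footprint, dilated by ``tolerance_mm``,
    contains it; among several candidates the nearest centre wins.  Repeated
    clicks on one rod count once.  Returns (indices of detected rods in
    ``layout.rods``, false clicks).
    """
    centers = np.array([(r.x_mm, r.y_mm) for r in layout.rods])
    radii = np.array([r.spec.radius_mm for r in layout.rods])
    detected: set[int] = set()
    false_clicks: list[ClickRecord] = []
    for click in session.clicks:
        x, y = transform.pixel_to_module(click.y_px, click.x_px)
        dist = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
        inside = dist <= radii + tolerance_mm
        if inside.any():
            candidates = np.flatnonzero(inside)
            detected.add(int(candidates[np.argmin(dist[candidates])]))
        else:
            false_clicks.append(click)
    return detected, false_clicks


def extract_ddc(
    detected: set[int],
    layout: ModuleLayout,
    observer_id: str,
    **meta,
) -> DDCCurve:
    """Minimal detected nominal contrast per diameter; MISSING where none.

    False clicks never enter: only indices of actual rods contribute.
    """
    points: dict[float, float | None] = {float(d): MISSING for d in DIAMETERS_MM}
    for idx in detected:
        spec = layout.rods[idx].spec
        s = float(spec.diameter_mm)
        current = points[s]
        if current is None or spec.target_contrast_hu < current:
            points[s] = float(spec.target_contrast_hu)
    return DDCCurve(observer_id=observer_id, points=points,
                    module_type=layout.module_type, **meta)


def _pooled_xy(curves: list[DDCCurve]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for c in curves:
        s, v = c.observed()
        xs.append(np.log(s))
        ys.append(v)
    if not xs:
        return np.empty(0), np.empty(0)
    return np.concatenate(xs), np.concatenate(ys)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares intercept and slope of y on x."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_pooled(curves: list[DDCCurve]) -> DDCFit:
    """OLS of Delta_min on ln s over all non-missing points of all curves."""
    x, y = _pooled_xy(curves)
    if np.unique(x).size < 2:
        raise InsufficientDataError(
            "pooled fit needs points at >= 2 distinct diameters")
    a, b = _ols_line(x, y)
    fitted = a + b * x
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
    return DDCFit(alpha=a, beta=b, n_points=x.size, r_squared=r2, residuals=resid)


def fit_observer_bias(curves: list[DDCCurve]) -> DDCFit:
    """Constrained least squares of the observer-bias model.

    Repeated curves from one observer are pooled (they share that observer's
    offsets).  Each observer line is fitted by OLS; the shared alpha / beta
    are the means of the per-observer intercepts / slopes and the offsets the
    differences, which solves the sum-to-zero constrained problem exactly.
    """
    by_obs: dict[str, list[DDCCurve]] = {}
    for c in curves:
        by_obs.setdefault(c.observer_id, []).append(c)
    if len(by_obs) < 2:
        raise InsufficientDataError("observer-bias fit needs >= 2 observers")

    intercepts: dict[str, float] = {}
    slopes: dict[str, float] = {}
    xs_all, ys_all, obs_all = [], [], []
    for obs_id, obs_curves in by_obs.items():
        x, y = _pooled_xy(obs_curves)
        if np.unique(x).size < 2:
            raise InsufficientDataError(
                f"observer {obs_id!r} has points at < 2 distinct diameters; "
                f"the slope is inestimable")
        intercepts[obs_id], slopes[obs_id] = _ols_line(x, y)
        xs_all.append(x)
        ys_all.append(y)
        obs_all.extend([obs_id] * x.size)

    alpha = float(np.mean(list(intercepts.values())))
    beta = float(np.mean(list(slopes.values())))
    alpha_i = {k: v - alpha for k, v in intercepts.items()}
    beta_i = {k: v - beta for k, v in slopes.items()}

    x = np.concatenate(xs_all)
    y = np.concatenate(ys_all)
    fitted = np.array([
        intercepts[o] + slopes[o] * xi for o, xi in zip(obs_all, x)])
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
    return DDCFit(alpha=alpha, beta=beta, alpha_i=alpha_i, beta_i=beta_i,
                  n_points=x.size, r_squared=r2, residuals=resid)


def predict(fit: DDCFit, s_mm: float, observer_id: str | None = None) -> float:
    """Expected Delta_min at diameter ``s_mm`` (observer offsets if given)."""
    if s_mm <= 0:
        raise ValueError("diameter must be positive")
    a, b = fit.alpha, fit.beta
    if observer_id is not None:
        a += fit.alpha_i[observer_id]
        b += fit.beta_i[observer_id]
    return a + b * float(np.log(s_mm))


# -- tabular interchange ---------------------------------------------------

_CURVE_COLUMNS = ["observer_id", "diameter_mm", "delta_min_hu", "module_type",
                  "kv", "ctdi_vol_mgy", "scan_id", "date"]


def curves_to_frame(curves: list[DDCCurve]) -> pd.DataFrame:
    """Long-format table, one row per (curve, diameter); missing stays NaN."""
    rows = []
    for c in curves:
        for s, v in sorted(c.points.items()):
            rows.append({
                "observer_id": c.observer_id,
                "diameter_mm": s,
                "delta_min_hu": np.nan if v is None else v,
                "module_type": c.module_type,
                "kv": c.kv,
                "ctdi_vol_mgy": c.ctdi_vol_mgy,
                "scan_id": c.scan_id,
                "date": c.date,
            })
    return pd.DataFrame(rows, columns=_CURVE_COLUMNS)


def frame_to_curves(frame: pd.DataFrame) -> list[DDCCurve]:
    """Inverse of :func:`curves_to_frame`; one curve per (observer, scan)."""
    curves = []
    keys = ["observer_id", "scan_id"]
    for (obs, scan), grp in frame.groupby(keys, dropna=False, sort=False):
        points = {
            float(r.diameter_mm):
                (MISSING if pd.isna(r.delta_min_hu) else float(r.delta_min_hu))
            for r in grp.itertuples()
        }
        first = grp.iloc[0]
        curves.append(DDCCurve(
            observer_id=str(obs),
            points=points,
            module_type=str(first.get("module_type", "contrast_agent")),
            kv=None if pd.isna(first.get("kv")) else int(first["kv"]),
            ctdi_vol_mgy=(None if pd.isna(first.get("ctdi_vol_mgy"))
                          else float(first["ctdi_vol_mgy"])),
            scan_id=None if pd.isna(scan) else str(scan),
            date=None if pd.isna(first.get("date")) else str(first["date"]),
        ))
    return curves


def load_reference_curves() -> list[DDCCurve]:
    """Bundled five-observer reference DDC set (120 kV, 9 mGy abdominal scan)."""
    with resources.files("ddcqa.data").joinpath("reference_curves.csv").open() as fh:
        return frame_to_curves(pd.read_csv(fh))
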