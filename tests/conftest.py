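"""Shared fixtures and independent oracles for the test suite.

The oracles here intentionally re-derive results by brute force or via a
generic solver so the package code paths are checked against independent
routes: exhaustive erosion, exhaustive click matching, normal-equation OLS,
and an effects-coded constrained least-squares solve.
"""

from __future__ import annotations

import numpy as np
import pytest

from ddcqa import AcquisitionSettings, generate_layout, simulate_volume
from ddcqa.ddc import DDCCurve

DIAMETERS = (3.0, 4.0, 5.0, 6.0, 8.0, 9.0)


@pytest.fixture(scope="session")
def layout():
    return generate_layout(1)


@pytest.fixture(scope="session")
def clean_sim(layout):
    """Noise-free, PSF-free simulation: the exact-recovery reference case."""
    settings = AcquisitionSettings(noise_sigma_ref_hu=0.0, psf_fwhm_mm=0.0,
                                   n_slices=3)
    volume, truth = simulate_volume(layout, settings, seed=0)
    return volume, truth


# -- oracles ---------------------------------------------------------------

def erosion_oracle(mask: np.ndarray, disc_diameter_px: int) -> np.ndarray:
    """Exhaustive erosion: keep a pixel iff every offset within d/2 is set."""
    r = disc_diameter_px / 2.0
    k = int(np.floor(r))
    offsets = [(dy, dx) for dy in range(-k, k + 1) for dx in range(-k, k + 1)
               if dy * dy + dx * dx <= r * r + 1e-12]
    out = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            ok = True
            for dy, dx in offsets:
                y, x = i + dy, j + dx
                if not (0 <= y < h and 0 <= x < w and mask[y, x]):
                    ok = False
                    break
            out[i, j] = ok
    return out


def constrained_ls_oracle(points):
    """Generic sum-to-zero constrained LS via effects coding.

    ``points`` is a list of (observer_id, x, y).  Parameters are
    (alpha, beta, alpha'_1..alpha'_{p-1}, beta'_1..beta'_{p-1}); the last
    observer's offsets are the negative sums, which encodes the constraint
    exactly in the design matrix.
    """
    obs = sorted({o for o, _, _ in points})
    p = len(obs)
    index = {o: i for i, o in enumerate(obs)}
    rows, ys = [], []
    for o, x, y in points:
        i = index[o]
        row = np.zeros(2 + 2 * (p - 1))
        row[0] = 1.0
        row[1] = x
        if i < p - 1:
            row[2 + i] = 1.0
            row[2 + (p - 1) + i] = x
        else:
            row[2:2 + (p - 1)] = -1.0
            row[2 + (p - 1):] = -x
        rows.append(row)
        ys.append(y)
    coef, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(ys), rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    ai = list(coef[2:2 + (p - 1)])
    bi = list(coef[2 + (p - 1):])
    ai.append(-sum(ai))
    bi.append(-sum(bi))
    return alpha, beta, dict(zip(obs, ai)), dict(zip(obs, bi))


def curve_points(curves):
    """Flatten curves to (observer_id, ln s, y) triples, skipping missing."""
    out = []
    for c in curves:
        s, v = c.observed()
        for si, vi in zip(s, v):
            out.append((c.observer_id, float(np.log(si)), float(vi)))
    return out


def random_curve_dataset(rng: np.random.Generator, n_obs: int | None = None):
    """Random multi-observer DDC sets with unbalanced missingness patterns,
    including occasional repeated curves from one observer."""
    p = int(n_obs or rng.integers(3, 7))
    curves = []
    for i in range(p):
        a = rng.uniform(60.0, 140.0)
        b = rng.uniform(-45.0, -10.0)

        def one_curve(scan_id):
            keep = rng.random(6) > 0.25
            while np.unique(np.array(DIAMETERS)[keep]).size < 2:
                keep = rng.random(6) > 0.25
            points = {
                s: (float(a + b * np.log(s) + rng.normal(0.0, 6.0)) if k else None)
                for s, k in zip(DIAMETERS, keep)
            }
            return DDCCurve(observer_id=f"obs{i}", points=points, scan_id=scan_id)

        curves.append(one_curve("scan0"))
        if rng.random() < 0.3:  # repeated measure by the same observer
            curves.append(one_curve("scan1"))
    return curves
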