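"""Bootstrap standard errors of DDC fit parameters.

From n available difference-detail curves, m resamples of size k are drawn
uniformly with replacement; each resample is fitted with the pooled
log-linear model and the standard deviation of the m parameter estimates
(with the 1/(m-1) divisor)

    se(theta) = sqrt( 1/(m-1) * sum_j (theta_kj - mean_j theta_kj)^2 )

estimates the standard error of alpha and beta at observer-panel size k.
Shrinking k mimics sites with fewer observers: the standard error grows as
k drops, quantifying how many observers a protocol comparison needs.

Resamples are fitted with the pooled model (not the observer-bias model),
which is undefined when a draw omits or duplicates observers.  Draws whose
pooled points span fewer than two distinct diameters cannot support a line
fit; they are redrawn and counted.

Each of the m fits is a 2-parameter OLS whose normal equations depend only
on additive per-curve sufficient statistics (n, sum x, sum y, sum x^2,
sum xy with x = ln s), so the whole bootstrap is vectorised over draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ddc import DDCCurve
from .errors import DegenerateResampleError

__all__ = ["BootstrapResult", "bootstrap_se"]


@dataclass
class BootstrapResult:
    k: int
    n: int
    m: int
    seed: int
    se_alpha: float
    se_beta: float
    mean_alpha: float
    mean_beta: float
    n_degenerate: int = 0
    alpha_draws: np.ndarray | None = None
    beta_draws: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "k": self.k, "n": self.n, "m": self.m, "seed": self.seed,
            "se_alpha": self.se_alpha, "se_beta": self.se_beta,
            "mean_alpha": self.mean_alpha, "mean_beta": self.mean_beta,
            "n_degenerate": self.n_degenerate,
        }


def _curve_stats(curves: list[DDCCurve]) -> tuple[np.ndarray, np.ndarray]:
    """Per-curve OLS sufficient statistics and diameter bitmasks."""
    stats = np.zeros((len(curves), 5))
    masks = np.zeros(len(curves), dtype=np.int64)
    for i, c in enumerate(curves):
        s, v = c.observed()
        if s.size == 0:
            continue
        x = np.log(s)
        stats[i] = (s.size, x.sum(), v.sum(), (x * x).sum(), (x * v).sum())
        for d in np.unique(s):
            masks[i] |= 1 << int(round(d))
    return stats, masks


def _popcount_ge2(m: np.ndarray) -> np.ndarray:
    return (m & (m - 1)) != 0  # at least two bits set


def bootstrap_se(
    curves: list[DDCCurve],
    k: int,
    m: int,
    seed: int,
    max_redraw_rounds: int = 100,
    keep_draws: bool = False,
) -> BootstrapResult:
    """Bootstrap standard errors of (alpha, beta) at resample size ``k``.

    Fixed ``seed`` gives bit-reproducible results.  Raises
    :class:`DegenerateResampleError` when more than half of the initial draws
    cannot support a fit.
    """
    n = len(curves)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n = {n}, got {k}")
    if m < 2:
        raise ValueError("m must be >= 2")
    stats, dmasks = _curve_stats(curves)
    rng = np.random.default_rng(seed)

    draws = rng.integers(0, n, size=(m, k))
    union = np.bitwise_or.reduce(dmasks[draws], axis=1)
    bad = ~_popcount_ge2(union)
    n_degenerate = int(bad.sum())
    if n_degenerate > m // 2:
        raise DegenerateResampleError(
            f"{n_degenerate} of {m} draws span < 2 distinct diameters")
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_redraw_rounds:
            raise DegenerateResampleError(
                "could not complete redraws of degenerate resamples")
        idx = np.flatnonzero(bad)
        draws[idx] = rng.integers(0, n, size=(idx.size, k))
        union = np.bitwise_or.reduce(dmasks[draws[idx]], axis=1)
        still_bad = ~_popcount_ge2(union)
        n_degenerate += int(still_bad.sum())
        bad[idx] = still_bad

    agg = stats[draws].sum(axis=1)  # (m, 5): n, Sx, Sy, Sxx, Sxy
    npts, sx, sy, sxx, sxy = agg.T
    denom = npts * sxx - sx * sx
    beta = (npts * sxy - sx * sy) / denom
    alpha = (sy - beta * sx) / npts

    result = BootstrapResult(
        k=k, n=n, m=m, seed=int(seed),
        se_alpha=float(np.std(alpha, ddof=1)),
        se_beta=float(np.std(beta, ddof=1)),
        mean_alpha=float(alpha.mean()),
        mean_beta=float(beta.mean()),
        n_degenerate=n_degenerate,
        alpha_draws=alpha if keep_draws else None,
        beta_draws=beta if keep_draws else None,
    )
    return result
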