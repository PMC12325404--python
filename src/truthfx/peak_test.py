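"""Quadratic-regression bootstrap midpoint test and its Monte-Carlo power study.

The constant-fluency model predicts that the per-statement truth effect
R - N, plotted against perceived truth (R + N) / 2, forms an inverted U
peaking exactly at .50.  The test fits a quadratic by ordinary least
squares, locates the vertex -b1 / (2 b2), and builds a percentile
confidence interval for the vertex by resampling statements with
replacement; the midpoint hypothesis is rejected when .50 falls outside
the interval.

The power study repeats the test on datasets simulated from each of the
four fluency variants and reports rejection rates.  The bootstrap path is
fully vectorized: resample sums of x-powers are obtained from resample
count matrices and the 3x3 normal equations are solved in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_LINK, LinkSpec, ModelVariant
from .simulate import simulate_item_counts

__all__ = [
    "NoInteriorPeakError",
    "PeakTestResult",
    "PowerResult",
    "quadratic_fit",
    "peak_location",
    "bootstrap_peak_ci",
    "power_study",
]


class NoInteriorPeakError(ValueError):
    """Raised when the fitted quadratic opens upward (b2 >= 0): no interior maximum."""


@dataclass(frozen=True)
class PeakTestResult:
    b0: float
    b1: float
    b2: float
    peak: float
    ci_lo: float
    ci_hi: float
    level: float
    midpoint: float
    reject: bool
    n_bootstrap: int
    n_degenerate: int
    unreliable: bool

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.b0, self.b1, self.b2)


@dataclass(frozen=True)
class PowerResult:
    variant: ModelVariant
    m: float
    n_datasets: int
    n_rejections: int
    rejection_rate: float
    n_statements: int
    n_judgments: int
    n_bootstrap: int
    x_mode: str


def _extract_xy(items, x_mode: str) -> tuple[np.ndarray, np.ndarray]:
    if x_mode not in ("mean_RN", "new_only"):
        raise ValueError(f"x_mode must be 'mean_RN' or 'new_only', got {x_mode!r}")
    if isinstance(items, pd.DataFrame):
        x = items["perceived_truth_mean" if x_mode == "mean_RN" else "prop_new"].to_numpy(float)
        y = items["truth_effect"].to_numpy(float)
    else:
        x, y = (np.asarray(a, dtype=float) for a in items)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 items with defined proportions")
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient design: all x values are equal")
    return x, y


def quadratic_fit(items, x_mode: str = "mean_RN") -> tuple[float, float, float]:
    """OLS fit of the truth effect on perceived truth and its square.

    ``x_mode='mean_RN'`` uses (R + N) / 2 (the original operationalization);
    ``'new_only'`` uses the new-statement proportion N.
    Returns (b0, b1, b2).
    """
    x, y = _extract_xy(items, x_mode)
    X = np.column_stack([np.ones_like(x), x, x * x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return tuple(float(b) for b in beta)


def peak_location(coefficients) -> float:
    """Vertex of the fitted quadratic, -b1 / (2 b2); requires b2 < 0."""
    _, b1, b2 = coefficients
    if b2 >= 0:
        raise NoInteriorPeakError(f"b2 = {b2} >= 0: the quadratic has no interior maximum")
    return -b1 / (2.0 * b2)


def _bootstrap_peaks(x: np.ndarray, y: np.ndarray, n_bootstrap: int, rng: np.random.Generator):
    """Vertex of the quadratic refit on each statement-level resample.

    Returns (peaks, valid_mask); resamples whose quadratic opens upward (or
    whose normal equations are numerically singular) are marked invalid.
    """
    n = x.size
    # per-item moment vector: resampled normal equations need only sums of
    # x^0..x^4, y, xy, x^2 y over the resample
    M = np.column_stack([np.ones(n), x, x**2, x**3, x**4, y, x * y, x * x * y])
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    rows = np.repeat(np.arange(n_bootstrap), n)
    counts = np.bincount(rows * n + idx.ravel(), minlength=n_bootstrap * n).reshape(n_bootstrap, n)
    S = counts @ M  # (B, 8): S0..S4, T0, T1, T2
    A = np.empty((n_bootstrap, 3, 3))
    A[:, 0, 0] = S[:, 0]
    A[:, 0, 1] = A[:, 1, 0] = S[:, 1]
    A[:, 0, 2] = A[:, 2, 0] = A[:, 1, 1] = S[:, 2]
    A[:, 1, 2] = A[:, 2, 1] = S[:, 3]
    A[:, 2, 2] = S[:, 4]
    t = S[:, 5:8]
    det = np.linalg.det(A)
    scale = np.abs(A).max(axis=(1, 2)) ** 3
    solvable = np.abs(det) > 1e-12 * np.maximum(scale, 1.0)
    beta = np.full((n_bootstrap, 3), np.nan)
    if solvable.any():
        beta[solvable] = np.linalg.solve(A[solvable], t[solvable, :, None])[..., 0]
    valid = solvable & (beta[:, 2] < 0)
    peaks = np.full(n_bootstrap, np.nan)
    peaks[valid] = -beta[valid, 1] / (2.0 * beta[valid, 2])
    return peaks, valid


def bootstrap_peak_ci(
    items,
    x_mode: str = "mean_RN",
    n_bootstrap: int = 5000,
    level: float = 0.95,
    rng=None,
    midpoint: float = 0.5,
) -> PeakTestResult:
    """Percentile bootstrap CI for the quadratic vertex; reject iff the
    midpoint lies outside the interval.

    Statements are resampled with replacement.  Resamples without an
    interior peak (b2 >= 0) are excluded from the percentile computation and
    counted; if they exceed half of all resamples the result is flagged
    unreliable.
    """
    rng = np.random.default_rng(rng)
    x, y = _extract_xy(items, x_mode)
    b0, b1, b2 = quadratic_fit(items, x_mode)
    peak = -b1 / (2.0 * b2) if b2 < 0 else np.nan
    peaks, valid = _bootstrap_peaks(x, y, n_bootstrap, rng)
    n_degenerate = int(n_bootstrap - valid.sum())
    unreliable = n_degenerate > n_bootstrap // 2
    alpha = 1.0 - level
    if valid.any():
        lo, hi = np.quantile(peaks[valid], [alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        lo = hi = np.nan
    reject = bool(valid.any() and not (lo <= midpoint <= hi))
    return PeakTestResult(
        b0=b0, b1=b1, b2=b2, peak=float(peak), ci_lo=float(lo), ci_hi=float(hi),
        level=level, midpoint=midpoint, reject=reject, n_bootstrap=n_bootstrap,
        n_degenerate=n_degenerate, unreliable=unreliable,
    )


def power_study(
    variant,
    m: float,
    n_datasets: int = 1000,
    n_statements: int = 80,
    n_judgments: int = 250,
    n_bootstrap: int = 5000,
    level: float = 0.95,
    x_mode: str = "mean_RN",
    link: LinkSpec = DEFAULT_LINK,
    rng=None,
    midpoint: float = 0.5,
) -> PowerResult:
    """Rejection rate of the bootstrap midpoint test under a generating variant.

    Each dataset holds ``n_statements`` on the uniform [-1, 2] plausibility
    grid with ``n_judgments`` binomial judgments per condition (no random
    effects); rejection is counted when the percentile CI excludes the
    midpoint.
    """
    variant = ModelVariant.coerce(variant)
    rng = np.random.default_rng(rng)
    props = simulate_item_counts(
        variant, m, n_statements=n_statements, n_judgments=n_judgments,
        link=link, rng=rng, n_datasets=max(n_datasets, 2),
    )
    prop_new, prop_rep = props[0][:n_datasets], props[1][:n_datasets]
    alpha = 1.0 - level
    n_reject = 0
    for d in range(n_datasets):
        xn, xr = prop_new[d], prop_rep[d]
        y = xr - xn
        x = 0.5 * (xr + xn) if x_mode == "mean_RN" else xn
        peaks, valid = _bootstrap_peaks(x, y, n_bootstrap, rng)
        if not valid.any():
            continue
        lo, hi = np.quantile(peaks[valid], [alpha / 2.0, 1.0 - alpha / 2.0])
        if not (lo <= midpoint <= hi):
            n_reject += 1
    return PowerResult(
        variant=variant, m=float(m), n_datasets=n_datasets, n_rejections=n_reject,
        rejection_rate=n_reject / n_datasets, n_statements=n_statements,
        n_judgments=n_judgments, n_bootstrap=n_bootstrap, x_mode=x_mode,
    )
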