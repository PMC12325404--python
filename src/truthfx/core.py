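"""Deterministic mathematics of the probit-link truth-effect model.

The model assumes each statement carries a latent plausibility ``p`` on a
probit scale.  A "true" judgment occurs when a noisy latent value
``y* ~ Normal(p, sigma)`` exceeds a fixed threshold, so the probability of
judging a *new* statement true is ``Phi((p - threshold) / sigma)``.
Repetition adds a fluency increment ``f(m, p)`` to the latent plausibility;
the four model variants differ only in how ``f`` depends on ``p``:

* M1 — constant: ``f = m``
* M2 — increasing with plausibility: ``f = m * p``
* M3 — decreasing with plausibility: ``f = m * (1 - p)``
* M4 — triangular, peaked at ``p = 0.5``: ``f = 2m * (0.5 - |p - 0.5|)``

The link uses a *non-standard* latent scale (``sigma = 0.5``) and threshold
(``0.5``) rather than the standardized probit convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "LinkSpec",
    "ModelVariant",
    "DEFAULT_LINK",
    "default_grid",
    "prob_true_new",
    "fluency_shift",
    "fluency_shift_grad",
    "prob_true_rep",
    "truth_effect_curve",
    "transform_scale",
]


@dataclass(frozen=True)
class LinkSpec:
    """Latent-threshold link: scale ``sigma`` and cutoff ``threshold``."""

    sigma: float = 0.5
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be a positive finite real, got {self.sigma}")
        if not np.isfinite(self.threshold):
            raise ValueError(f"threshold must be finite, got {self.threshold}")


DEFAULT_LINK = LinkSpec()


class ModelVariant(enum.IntEnum):
    """The four admissible fluency functions linking plausibility to repetition."""

    M1 = 1  # constant shift
    M2 = 2  # proportional to plausibility
    M3 = 3  # proportional to implausibility
    M4 = 4  # triangular, peaked at p = 0.5

    @classmethod
    def coerce(cls, value: "ModelVariant | int | str") -> "ModelVariant":
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        if isinstance(value, str):
            key = value.strip().upper()
            if key.isdigit():
                return cls(int(key))
            return cls[key]
        raise ValueError(f"cannot interpret {value!r} as a model variant")


def default_grid(lo: float = -1.0, hi: float = 2.0, step: float = 0.01) -> np.ndarray:
    """Plausibility grid: -1 (highly implausible) to 2 (highly plausible), step 0.01."""
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


def _check_finite(p: np.ndarray, name: str = "p") -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def prob_true_new(p, link: LinkSpec = DEFAULT_LINK):
    """Probability of judging a new statement true: Phi((p - threshold) / sigma)."""
    arr = _check_finite(p)
    out = ndtr((arr - link.threshold) / link.sigma)
    return float(out) if np.isscalar(p) else out


def fluency_shift(variant, m, p):
    """Repetition-induced fluency increment f(m, p) for a model variant.

    Applied literally for p outside [0, 1]; variants M2–M4 can then yield
    negative shifts.
    """
    variant = ModelVariant.coerce(variant)
    m = float(m)
    if not np.isfinite(m) or m < 0:
        raise ValueError(f"m must be a nonnegative finite real, got {m}")
    arr = _check_finite(p)
    if variant is ModelVariant.M1:
        out = np.full_like(arr, m)
    elif variant is ModelVariant.M2:
        out = m * arr
    elif variant is ModelVariant.M3:
        out = m * (1.0 - arr)
    else:  # M4
        out = 2.0 * m * (0.5 - np.abs(arr - 0.5))
    return float(out) if np.isscalar(p) else out


def fluency_shift_grad(variant, m, p):
    """(df/dm, df/dp) of the fluency function, vectorized over p.

    M4 is non-differentiable at p = 0.5; the subgradient 0 is used there.
    """
    variant = ModelVariant.coerce(variant)
    arr = np.asarray(p, dtype=float)
    if variant is ModelVariant.M1:
        return np.ones_like(arr), np.zeros_like(arr)
    if variant is ModelVariant.M2:
        return arr.copy(), np.full_like(arr, m)
    if variant is ModelVariant.M3:
        return 1.0 - arr, np.full_like(arr, -m)
    dfdm = 2.0 * (0.5 - np.abs(arr - 0.5))
    dfdp = -2.0 * m * np.sign(arr - 0.5)
    return dfdm, dfdp


def prob_true_rep(variant, p, m, link: LinkSpec = DEFAULT_LINK, item_residual=0.0):
    """Probability of judging a repeated statement true.

    Phi((p + f(m, p) + item_residual - threshold) / sigma); reduces to
    :func:`prob_true_new` at m = 0 and zero residual.
    """
    arr = _check_finite(p)
    shift = fluency_shift(variant, m, arr)
    out = ndtr((arr + shift + np.asarray(item_residual) - link.threshold) / link.sigma)
    return float(out) if np.isscalar(p) and np.isscalar(item_residual) else out


def truth_effect_curve(variant, m, p_grid=None, link: LinkSpec = DEFAULT_LINK) -> pd.DataFrame:
    """Exact truth-effect curve over a plausibility grid (no simulation noise).

    Returns one row per grid point with the new/repeated response
    probabilities, the truth effect R - N, and both x-axis
    operationalizations of perceived truth: the new-only probability N and
    the across-condition mean (R + N) / 2.
    """
    grid = default_grid() if p_grid is None else np.atleast_1d(np.asarray(p_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("p_grid must be nonempty")
    theta_new = prob_true_new(grid, link)
    theta_rep = prob_true_rep(variant, grid, m, link)
    return pd.DataFrame(
        {
            "p": grid,
            "theta_new": theta_new,
            "theta_rep": theta_rep,
            "truth_effect": theta_rep - theta_new,
            "perceived_truth_N": theta_new,
            "perceived_truth_mean": 0.5 * (theta_rep + theta_new),
        }
    )


_SCALES = ("probability", "probit", "logit")


def transform_scale(theta, target: str):
    """Map response probabilities onto the probability, probit, or logit scale.

    The probit target applies the standardized normal quantile; the logit
    target the plain log-odds.  Boundary values 0/1 are rejected for the
    non-identity targets.
    """
    if target not in _SCALES:
        raise ValueError(f"target must be one of {_SCALES}, got {target!r}")
    arr = np.asarray(theta, dtype=float)
    if target == "probability":
        out = arr
    else:
        if np.any((arr <= 0.0) | (arr >= 1.0)):
            raise ValueError(f"theta must lie strictly in (0, 1) for target {target!r}")
        out = ndtri(arr) if target == "probit" else np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(theta) else out
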