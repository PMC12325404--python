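"""Generative model for trial-level truth-judgment data.

Two generators live here:

* the full hierarchical process (statement plausibilities, participant
  response bias ``u_j``, item-specific truth-effect residuals ``v_i``,
  within-participant half-repetition with across-participant
  counterbalancing) used for calibration, recovery, and model-selection
  simulations, and
* an aggregated binomial item-level generator used by the peak-test power
  study, where each statement contributes a fixed number of judgments per
  condition and no random effects enter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_LINK, LinkSpec, ModelVariant, fluency_shift, prob_true_new, prob_true_rep

__all__ = [
    "DesignSpec",
    "TruthParams",
    "simulate_latent_judgment",
    "draw_parameters",
    "simulate_trials",
    "simulate_dataset",
    "simulate_item_counts",
    "summarize_items",
]

TRIAL_COLUMNS = ("participant_id", "statement_id", "repeated", "judgment")


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design for simulated truth-judgment studies.

    Defaults emulate the canonical paradigm: 80 statements spanning latent
    plausibility -1..2, every participant judging all statements with half
    repeated, counterbalanced across participants.
    """

    n_statements: int = 80
    n_participants: int = 200
    plausibility_source: str = "grid_uniform"  # or "normal_hierarchical"
    mu_p: float = 0.5
    sigma_p: float = 0.75
    sigma_u: float = 0.0
    sigma_v: float = 0.0
    repetition_scheme: str = "half_within_participant"
    seed: int | None = None
    link: LinkSpec = field(default=DEFAULT_LINK)

    def __post_init__(self) -> None:
        if self.n_statements <= 0 or self.n_participants <= 0:
            raise ValueError("n_statements and n_participants must be positive")
        if self.repetition_scheme == "half_within_participant" and self.n_statements % 2:
            raise ValueError("n_statements must be even for half_within_participant repetition")
        if self.plausibility_source not in ("grid_uniform", "normal_hierarchical"):
            raise ValueError(f"unknown plausibility_source {self.plausibility_source!r}")
        for name in ("sigma_p", "sigma_u", "sigma_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TruthParams:
    """Realized parameters of one simulated study."""

    p: np.ndarray  # per-statement plausibility
    v: np.ndarray  # per-statement truth-effect residual
    u: np.ndarray  # per-participant response bias
    m: float
    variant: ModelVariant
    link: LinkSpec = DEFAULT_LINK

    def __post_init__(self) -> None:
        if len(self.p) != len(self.v):
            raise ValueError("p and v must have one entry per statement")


def simulate_latent_judgment(p, shift, link: LinkSpec = DEFAULT_LINK, rng=None):
    """Single latent-threshold judgment: 1 iff Normal(p + shift, sigma) > threshold."""
    rng = np.random.default_rng(rng)
    y_star = rng.normal(np.asarray(p, dtype=float) + np.asarray(shift, dtype=float), link.sigma)
    out = (y_star > link.threshold).astype(np.int8)
    return int(out) if np.isscalar(p) and np.isscalar(shift) else out


def draw_parameters(design: DesignSpec, variant, m: float, rng=None) -> TruthParams:
    """Draw statement plausibilities and crossed random effects for a design."""
    variant = ModelVariant.coerce(variant)
    rng = np.random.default_rng(design.seed if rng is None else rng)
    if design.plausibility_source == "grid_uniform":
        p = np.linspace(-1.0, 2.0, design.n_statements)
    else:
        p = rng.normal(design.mu_p, design.sigma_p, design.n_statements)
    u = rng.normal(0.0, design.sigma_u, design.n_participants) if design.sigma_u > 0 else np.zeros(design.n_participants)
    v = rng.normal(0.0, design.sigma_v, design.n_statements) if design.sigma_v > 0 else np.zeros(design.n_statements)
    return TruthParams(p=p, v=v, u=u, m=float(m), variant=variant, link=design.link)


def _repetition_masks(n_participants: int, n_statements: int, rng: np.random.Generator) -> np.ndarray:
    """Within-participant half split, counterbalanced in complementary pairs.

    Each statement ends up repeated for n_participants/2 (+-1) participants.
    """
    half = n_statements // 2
    masks = np.zeros((n_participants, n_statements), dtype=np.int8)
    for j in range(0, n_participants, 2):
        perm = rng.permutation(n_statements)
        masks[j, perm[:half]] = 1
        if j + 1 < n_participants:
            masks[j + 1, perm[half:]] = 1
    return masks


def simulate_trials(design: DesignSpec, params: TruthParams, rng=None) -> pd.DataFrame:
    """Simulate a long-format trial table under the hierarchical process.

    A "true" judgment occurs when y* ~ Normal(p_i + R_ij (f_i + v_i) + u_j,
    sigma) exceeds the threshold, i.e., success probability
    Phi((p_i + R_ij (f_i + v_i) + u_j - threshold) / sigma).
    """
    if len(params.p) != design.n_statements or len(params.u) != design.n_participants:
        raise ValueError("params are inconsistent with the design")
    rng = np.random.default_rng(design.seed if rng is None else rng)
    S, P = design.n_statements, design.n_participants
    repeated = _repetition_masks(P, S, rng)  # (P, S)
    f = fluency_shift(params.variant, params.m, params.p)
    mu = params.p[None, :] + repeated * (f + params.v)[None, :] + params.u[:, None]
    y_star = rng.normal(mu, params.link.sigma)
    judgment = (y_star > params.link.threshold).astype(np.int8)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(P), S),
            "statement_id": np.tile(np.arange(S), P),
            "repeated": repeated.ravel(),
            "judgment": judgment.ravel(),
        }
    )


def simulate_dataset(design: DesignSpec, variant, m: float, rng=None) -> tuple[pd.DataFrame, TruthParams]:
    """Convenience wrapper: draw parameters, then simulate the trial table."""
    rng = np.random.default_rng(design.seed if rng is None else rng)
    params = draw_parameters(design, variant, m, rng)
    return simulate_trials(design, params, rng), params


def simulate_item_counts(
    variant,
    m: float,
    n_statements: int = 80,
    n_judgments: int = 250,
    link: LinkSpec = DEFAULT_LINK,
    rng=None,
    n_datasets: int = 1,
) -> pd.DataFrame | np.ndarray:
    """Aggregated binomial generator used by the power study.

    Statements sit on the uniform [-1, 2] plausibility grid; each
    contributes ``n_judgments`` binomial judgments per condition, with no
    item or participant residuals.  With ``n_datasets`` > 1 the per-item
    proportions are returned as arrays of shape (n_datasets, n_statements)
    stacked as (prop_new, prop_rep).
    """
    rng = np.random.default_rng(rng)
    p = np.linspace(-1.0, 2.0, n_statements)
    theta_new = prob_true_new(p, link)
    theta_rep = prob_true_rep(variant, p, m, link)
    size = (n_datasets, n_statements)
    prop_new = rng.binomial(n_judgments, theta_new, size=size) / n_judgments
    prop_rep = rng.binomial(n_judgments, theta_rep, size=size) / n_judgments
    if n_datasets == 1:
        return pd.DataFrame(
            {
                "statement_id": np.arange(n_statements),
                "p": p,
                "prop_new": prop_new[0],
                "prop_rep": prop_rep[0],
                "truth_effect": prop_rep[0] - prop_new[0],
                "perceived_truth_mean": 0.5 * (prop_rep[0] + prop_new[0]),
                "n_new": n_judgments,
                "n_rep": n_judgments,
            }
        )
    return np.stack([prop_new, prop_rep])


def summarize_items(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-statement proportions of "true" responses by condition.

    Returns N (new), R (repeated), the truth effect R - N, and the mean
    (R + N) / 2, with condition counts.  A statement with zero trials in a
    condition carries count 0 and NaN proportions (flagged, not silently
    dropped).
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    grouped = trials.groupby(["statement_id", "repeated"])["judgment"].agg(["sum", "count"])
    wide = grouped.unstack("repeated", fill_value=0)
    n_new = wide[("count", 0)] if ("count", 0) in wide else pd.Series(0, index=wide.index)
    n_rep = wide[("count", 1)] if ("count", 1) in wide else pd.Series(0, index=wide.index)
    s_new = wide[("sum", 0)] if ("sum", 0) in wide else pd.Series(0, index=wide.index)
    s_rep = wide[("sum", 1)] if ("sum", 1) in wide else pd.Series(0, index=wide.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_new = np.where(n_new > 0, s_new / n_new.replace(0, 1), np.nan)
        prop_rep = np.where(n_rep > 0, s_rep / n_rep.replace(0, 1), np.nan)
    out = pd.DataFrame(
        {
            "statement_id": wide.index.to_numpy(),
            "prop_new": prop_new,
            "prop_rep": prop_rep,
            "truth_effect": prop_rep - prop_new,
            "perceived_truth_mean": 0.5 * (prop_rep + prop_new),
            "n_new": n_new.to_numpy(),
            "n_rep": n_rep.to_numpy(),
        }
    ).reset_index(drop=True)
    return out
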