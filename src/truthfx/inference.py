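"""Hierarchical Bayesian estimation of the probit truth-effect models.

The likelihood for a judgment of statement *i* by participant *j* is

    y_ij ~ Bernoulli( Phi( (p_i + R_ij (f(m, p_i) + v_i) + u_j - c) / sigma ) )

with fixed link scale sigma = 0.5 and threshold c = 0.5.  Statement
plausibilities are hierarchical, p_i ~ Normal(mu_p, sigma_p); v_i are
item-specific truth-effect residuals and u_j participant response biases,
both zero-centered normals.  Hyper-priors: mu_p ~ Normal(0.5, 1) (uniform
over the implied baseline response probability), half-Normal(1) scales, and
a positive-truncated normal prior on m whose mean is calibrated per variant
so all four variants imply the same average truth effect.

Sampling uses the in-package chain-batched HMC on an unconstrained,
non-centered parameterization (log transforms for the scales and m, with
Jacobian terms in the target density).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr

from .core import DEFAULT_LINK, LinkSpec, ModelVariant
from .hmc import sample_hmc

__all__ = [
    "MATCHED_M_PRIOR_MEANS",
    "PriorSpec",
    "McmcSettings",
    "PosteriorFit",
    "fit_model",
    "diagnostics",
    "posterior_summary",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

# prior means for m, calibrated so each variant implies the same average
# truth effect (see the calibration module)
MATCHED_M_PRIOR_MEANS = {
    ModelVariant.M1: 0.11,
    ModelVariant.M2: 0.27,
    ModelVariant.M3: 0.19,
    ModelVariant.M4: 0.38,
}


@dataclass(frozen=True)
class PriorSpec:
    """Hyper-priors of the hierarchical model.

    ``m_mean``/``m_sd`` parameterize the positive-truncated normal prior on
    the fluency parameter m; the remaining scales carry half-normal priors.
    """

    mu_p_mean: float = 0.5
    mu_p_sd: float = 1.0
    sigma_p_sd: float = 1.0
    sigma_u_sd: float = 1.0
    sigma_v_sd: float = 1.0
    m_mean: float = 0.11
    m_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("mu_p_sd", "sigma_p_sd", "sigma_u_sd", "sigma_v_sd", "m_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_variant(cls, variant, m_sd: float = 0.1, **overrides) -> "PriorSpec":
        """Variant-specific prior with the calibrated mean for m."""
        variant = ModelVariant.coerce(variant)
        return cls(m_mean=MATCHED_M_PRIOR_MEANS[variant], m_sd=m_sd, **overrides)


@dataclass(frozen=True)
class McmcSettings:
    """MCMC run profile; defaults follow the full-scale analysis profile."""

    chains: int = 8
    warmup: int = 1000
    draws: int = 10000
    seed: int = 0
    target_accept: float = 0.8
    max_leapfrog: int = 32
    max_loglik_draws: int = 1000  # thinning cap for the stored pointwise log-likelihood

    def __post_init__(self) -> None:
        if min(self.chains, self.warmup, self.draws) <= 0:
            raise ValueError("chains, warmup, and draws must be positive")

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "McmcSettings":
        """Scaled-down profile for desk-scale runs and the test suite."""
        return cls(chains=4, warmup=500, draws=1500, seed=seed, **overrides)


def _halfnormal_logpdf(x, sd):
    return np.log(2.0) - _LOG_SQRT_2PI - np.log(sd) - 0.5 * (x / sd) ** 2


def _normal_logpdf(x, mean, sd):
    return -_LOG_SQRT_2PI - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


class ProbitTruthModel:
    """Unconstrained-space log posterior (with Jacobians) and its gradient.

    Parameter vector layout: [mu_p, log sigma_p, log sigma_u, log sigma_v,
    log m, p (S), u (P), z_v (S)].  The plausibilities p and participant
    biases u are parameterized directly (centered): every unit carries on
    the order of a hundred Bernoulli trials, so the likelihood dominates
    and the centered geometry mixes best.  The item residuals v, which are
    only weakly identified, stay non-centered via v = sigma_v z_v.
    """

    def __init__(self, trials: pd.DataFrame | None, variant, priors: PriorSpec,
                 link: LinkSpec = DEFAULT_LINK):
        self.variant = ModelVariant.coerce(variant)
        self.priors = priors
        self.link = link
        if trials is None or len(trials) == 0:
            self.n_trials = 0
            self.statements = np.array([], dtype=object)
            self.participants = np.array([], dtype=object)
        else:
            self.statements, self.item_idx = np.unique(trials["statement_id"], return_inverse=True)
            self.participants, self.part_idx = np.unique(trials["participant_id"], return_inverse=True)
            self.item_idx = self.item_idx.astype(np.int64)
            self.part_idx = self.part_idx.astype(np.int64)
            self.rep = trials["repeated"].to_numpy(np.float64)
            self.y = trials["judgment"].to_numpy(np.float64)
            self.sign = 2.0 * self.y - 1.0
            self.n_trials = len(trials)
        self.n_items = len(self.statements)
        self.n_parts = len(self.participants)
        self.dim = 5 + 2 * self.n_items + self.n_parts
        # truncation constant of the positive-truncated normal prior on m
        self._m_log_z = np.log(ndtr(priors.m_mean / priors.m_sd))

    # ---- parameter packing ------------------------------------------------
    def split(self, q: np.ndarray):
        """Split unconstrained positions (..., dim) into named blocks."""
        S, P = self.n_items, self.n_parts
        mu_p = q[..., 0]
        log_sp, log_su, log_sv, log_m = (q[..., k] for k in range(1, 5))
        p = q[..., 5:5 + S]
        u = q[..., 5 + S:5 + S + P]
        z_v = q[..., 5 + S + P:]
        return mu_p, log_sp, log_su, log_sv, log_m, p, u, z_v

    def constrain(self, q: np.ndarray) -> dict[str, np.ndarray]:
        """Map unconstrained draws to the natural parameterization."""
        mu_p, log_sp, log_su, log_sv, log_m, p, u, z_v = self.split(q)
        sigma_v = np.exp(log_sv)
        return {
            "mu_p": mu_p,
            "sigma_p": np.exp(log_sp),
            "sigma_u": np.exp(log_su),
            "sigma_v": sigma_v,
            "m": np.exp(log_m),
            "p": p,
            "u": u,
            "v": sigma_v[..., None] * z_v,
        }

    def initial_positions(self, n_chains: int, rng: np.random.Generator) -> np.ndarray:
        q = 0.1 * rng.standard_normal((n_chains, self.dim))
        q[:, 0] += self.priors.mu_p_mean
        q[:, 1:4] = np.log(0.3) + 0.1 * rng.standard_normal((n_chains, 3))
        q[:, 4] = np.log(max(self.priors.m_mean, 0.05)) + 0.1 * rng.standard_normal(n_chains)
        q[:, 5:5 + self.n_items] += self.priors.mu_p_mean
        return q

    # ---- densities --------------------------------------------------------
    def logp_and_grad(self, q: np.ndarray):
        """Batched log posterior density and gradient on the unconstrained space.

        Rows with non-finite density (overflowing positions during warmup)
        return -inf and are rejected by the sampler.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp, grad = self._logp_and_grad(q)
        return np.where(np.isfinite(lp), lp, -np.inf), np.nan_to_num(grad)

    def _logp_and_grad(self, q: np.ndarray):
        q = np.atleast_2d(q)
        pr = self.priors
        mu_p, log_sp, log_su, log_sv, log_m, p, u, z_v = self.split(q)
        with np.errstate(over="ignore", invalid="ignore"):
            sigma_p, sigma_u, sigma_v, m = np.exp(log_sp), np.exp(log_su), np.exp(log_sv), np.exp(log_m)

        # hyper-priors (+ Jacobians of the log transforms) and their gradients
        lp = _normal_logpdf(mu_p, pr.mu_p_mean, pr.mu_p_sd)
        lp += _halfnormal_logpdf(sigma_p, pr.sigma_p_sd) + log_sp
        lp += _halfnormal_logpdf(sigma_u, pr.sigma_u_sd) + log_su
        lp += _halfnormal_logpdf(sigma_v, pr.sigma_v_sd) + log_sv
        lp += (_normal_logpdf(m, pr.m_mean, pr.m_sd) - self._m_log_z) + log_m

        grad = np.zeros_like(q)
        grad[:, 0] = -(mu_p - pr.mu_p_mean) / pr.mu_p_sd**2
        grad[:, 1] = -(sigma_p / pr.sigma_p_sd) ** 2 + 1.0
        grad[:, 2] = -(sigma_u / pr.sigma_u_sd) ** 2 + 1.0
        grad[:, 3] = -(sigma_v / pr.sigma_v_sd) ** 2 + 1.0
        grad[:, 4] = -m * (m - pr.m_mean) / pr.m_sd**2 + 1.0

        S, P = self.n_items, self.n_parts
        # random-effect densities: centered p and u, non-centered v
        dp = p - mu_p[:, None]
        lp += -0.5 * np.sum((dp / sigma_p[:, None]) ** 2, axis=-1) \
            - S * _LOG_SQRT_2PI - S * log_sp
        lp += -0.5 * np.sum((u / sigma_u[:, None]) ** 2, axis=-1) \
            - P * _LOG_SQRT_2PI - P * log_su
        lp += -0.5 * np.sum(z_v**2, axis=-1) - z_v.shape[-1] * _LOG_SQRT_2PI
        grad[:, 0] += np.sum(dp, axis=-1) / sigma_p**2
        grad[:, 1] += np.sum((dp / sigma_p[:, None]) ** 2, axis=-1) - S
        grad[:, 2] += np.sum((u / sigma_u[:, None]) ** 2, axis=-1) - P
        grad[:, 5:5 + S] = -dp / sigma_p[:, None] ** 2
        grad[:, 5 + S:5 + S + P] = -u / sigma_u[:, None] ** 2
        grad[:, 5 + S + P:] = -z_v

        if self.n_trials == 0:
            return lp, grad

        with np.errstate(over="ignore", invalid="ignore"):
            v = sigma_v[:, None] * z_v                       # (C, S)
        bad = ~(np.isfinite(p).all(axis=1) & np.isfinite(u).all(axis=1)
                & np.isfinite(v).all(axis=1) & np.isfinite(m))
        if bad.any():
            p, u, v, m = (np.nan_to_num(a) for a in (p, u, v, m))
        p, u, v = np.ascontiguousarray(p), np.ascontiguousarray(u), np.ascontiguousarray(v)

        ll, g_p, g_u, g_v, g_m = _loglik_grad_kernel(
            p, u, v, np.asarray(m, dtype=float), self.item_idx, self.part_idx,
            self.rep, self.sign, int(self.variant), self.link.sigma, self.link.threshold,
        )
        lp = lp + ll
        if bad.any():
            lp[bad] = -np.inf

        grad[:, 3] += sigma_v * np.sum(g_v * z_v, axis=-1)
        grad[:, 4] += m * g_m
        grad[:, 5:5 + S] += g_p
        grad[:, 5 + S:5 + S + P] += g_u
        grad[:, 5 + S + P:] += sigma_v[:, None] * g_v
        return lp, grad

    def logp(self, q: np.ndarray) -> np.ndarray:
        return self.logp_and_grad(q)[0]

    def pointwise_loglik(self, q: np.ndarray) -> np.ndarray:
        """Per-trial Bernoulli-probit log likelihood for draws q (..., dim)."""
        pars = self.constrain(np.atleast_2d(q))
        p_t = pars["p"][..., self.item_idx]
        f_t = fluency_shift_batch(self.variant, pars["m"][..., None], p_t)
        eta = (p_t + self.rep * (f_t + pars["v"][..., self.item_idx])
               + pars["u"][..., self.part_idx] - self.link.threshold) / self.link.sigma
        return self.y * log_ndtr(eta) + (1.0 - self.y) * log_ndtr(-eta)


def fluency_shift_batch(variant, m, p):
    """Fluency shift with broadcastable m (used by the batched likelihood)."""
    mb = _bcast_m(m, p)
    if variant is ModelVariant.M1:
        return mb * np.ones_like(p)
    if variant is ModelVariant.M2:
        return mb * p
    if variant is ModelVariant.M3:
        return mb * (1.0 - p)
    return 2.0 * mb * (0.5 - np.abs(p - 0.5))


def _bcast_m(m, p):
    m = np.asarray(m, dtype=float)
    if m.ndim == 1 and p.ndim == 2:
        return m[:, None]
    return m


def fluency_shift_grad_batch(variant, m, p):
    mb = _bcast_m(m, p)
    if variant is ModelVariant.M1:
        return np.ones_like(p), np.zeros_like(p)
    if variant is ModelVariant.M2:
        return p, mb * np.ones_like(p)
    if variant is ModelVariant.M3:
        return 1.0 - p, -mb * np.ones_like(p)
    return 2.0 * (0.5 - np.abs(p - 0.5)), -2.0 * mb * np.sign(p - 0.5)


_SQRT2 = math.sqrt(2.0)


@numba.njit(cache=True, inline="always")
def _log_ndtr_scalar(x: float) -> float:
    if x > 6.0:
        return math.log1p(-0.5 * math.erfc(x / _SQRT2))
    return math.log(0.5 * math.erfc(-x / _SQRT2))


@numba.njit(cache=True)
def _loglik_grad_kernel(p, u, v, m, item_idx, part_idx, rep, sign, variant, sigma, thr):
    """Fused Bernoulli-probit log likelihood and gradient accumulation.

    One pass over (chain, trial); eta is clamped to +-37 where the normal
    CDF saturates in double precision.
    """
    C, S = p.shape
    P = u.shape[1]
    T = item_idx.shape[0]
    lp = np.zeros(C)
    g_p = np.zeros((C, S))
    g_u = np.zeros((C, P))
    g_v = np.zeros((C, S))
    g_m = np.zeros(C)
    log_sqrt_2pi = 0.5 * math.log(2.0 * math.pi)
    for c in range(C):
        mc = m[c]
        acc = 0.0
        for t in range(T):
            i = item_idx[t]
            j = part_idx[t]
            pi = p[c, i]
            if variant == 1:
                f = mc
                dfdm = 1.0
                dfdp = 0.0
            elif variant == 2:
                f = mc * pi
                dfdm = pi
                dfdp = mc
            elif variant == 3:
                f = mc * (1.0 - pi)
                dfdm = 1.0 - pi
                dfdp = -mc
            else:
                a = 0.5 - abs(pi - 0.5)
                f = 2.0 * mc * a
                dfdm = 2.0 * a
                dfdp = -2.0 * mc if pi > 0.5 else (2.0 * mc if pi < 0.5 else 0.0)
            r = rep[t]
            eta = (pi + r * (f + v[c, i]) + u[c, j] - thr) / sigma
            if eta > 37.0:
                eta = 37.0
            elif eta < -37.0:
                eta = -37.0
            s = sign[t]
            log_cdf = _log_ndtr_scalar(s * eta)
            acc += log_cdf
            ratio = math.exp(-0.5 * eta * eta - log_sqrt_2pi - log_cdf)
            g_eta = s * ratio / sigma
            g_p[c, i] += g_eta * (1.0 + r * dfdp)
            g_u[c, j] += g_eta
            g_v[c, i] += g_eta * r
            g_m[c] += g_eta * r * dfdm
        lp[c] = acc
    return lp, g_p, g_u, g_v, g_m


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one fitted model variant."""

    model: ProbitTruthModel
    settings: McmcSettings
    unconstrained: np.ndarray        # (chains, draws, dim)
    logp_draws: np.ndarray           # (chains, draws)
    accept_rate: np.ndarray
    n_divergent: int
    loglik: np.ndarray | None        # (chains, thin_draws, n_trials) or None
    data_fingerprint: str
    _diag: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def variant(self) -> ModelVariant:
        return self.model.variant

    @property
    def priors(self) -> PriorSpec:
        return self.model.priors

    @property
    def n_trials(self) -> int:
        return self.model.n_trials

    def posterior(self) -> dict[str, np.ndarray]:
        """Constrained draws keyed by parameter name, chain dimension kept."""
        return self.model.constrain(self.unconstrained)

    def flat_posterior(self) -> dict[str, np.ndarray]:
        out = {}
        for k, arr in self.posterior().items():
            out[k] = arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr.ravel()
        return out

    def to_inference_data(self):
        import arviz as az

        post = {k: v for k, v in self.posterior().items() if v.ndim == 2 or v.shape[-1] > 0}
        coords = {"statement": self.model.statements, "participant": self.model.participants}
        dims = {"p": ["statement"], "v": ["statement"], "u": ["participant"]}
        kwargs = {}
        if self.loglik is not None and self.n_trials > 0:
            kwargs["log_likelihood"] = {"y": self.loglik}
        return az.from_dict(posterior=post, coords=coords, dims=dims, **kwargs)

    def diagnostics_table(self) -> pd.DataFrame:
        if self._diag is None:
            self._diag = _compute_diagnostics(self)
        return self._diag

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics_table()["rhat"].max())

    @property
    def converged(self) -> bool:
        return self.max_rhat < 1.02


def _data_fingerprint(trials: pd.DataFrame | None) -> str:
    if trials is None or len(trials) == 0:
        return "prior-only"
    import hashlib

    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(trials.reset_index(drop=True), index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def fit_model(
    trials: pd.DataFrame | None,
    variant,
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
) -> PosteriorFit:
    """Fit one model variant to a trial table by adaptive HMC.

    Passing ``trials=None`` (or an empty table) samples the prior only.
    Non-convergence (any R-hat >= 1.02) is flagged on the returned fit and
    raised as a warning, never silently ignored.
    """
    variant = ModelVariant.coerce(variant)
    if priors is None:
        priors = PriorSpec.for_variant(variant)
    if settings is None:
        settings = McmcSettings()
    model = ProbitTruthModel(trials, variant, priors)
    rng = np.random.default_rng(settings.seed)
    init = model.initial_positions(settings.chains, rng)
    res = sample_hmc(
        model.logp_and_grad,
        init,
        n_warmup=settings.warmup,
        n_draws=settings.draws,
        seed=rng,
        target_accept=settings.target_accept,
        max_leapfrog=settings.max_leapfrog,
    )
    loglik = None
    if model.n_trials > 0:
        thin = max(1, settings.draws // settings.max_loglik_draws)
        sub = res.draws[:, ::thin, :]
        loglik = np.asarray(
            [model.pointwise_loglik(sub[c]) for c in range(settings.chains)], dtype=np.float32
        )
    fit = PosteriorFit(
        model=model,
        settings=settings,
        unconstrained=res.draws,
        logp_draws=res.logp,
        accept_rate=res.accept_rate,
        n_divergent=res.n_divergent,
        loglik=loglik,
        data_fingerprint=_data_fingerprint(trials),
    )
    if not fit.converged:
        warnings.warn(
            f"MCMC for {variant.name} did not converge: max R-hat = {fit.max_rhat:.3f}",
            RuntimeWarning,
            stacklevel=2,
        )
    return fit


def _compute_diagnostics(fit: PosteriorFit) -> pd.DataFrame:
    import arviz as az

    idata = fit.to_inference_data()
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rows = []
    for name in rhat_ds.data_vars:
        r = np.atleast_1d(np.asarray(rhat_ds[name]))
        e = np.atleast_1d(np.asarray(ess_ds[name]))
        if r.size == 1:
            rows.append((str(name), float(r.ravel()[0]), float(e.ravel()[0])))
        else:
            for k, (rk, ek) in enumerate(zip(r.ravel(), e.ravel())):
                rows.append((f"{name}[{k}]", float(rk), float(ek)))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess"]).set_index("parameter")


def diagnostics(fit: PosteriorFit, min_ess: float = 400.0, rhat_threshold: float = 1.02) -> pd.DataFrame:
    """Per-parameter R-hat and ESS with pass/fail flags against thresholds."""
    table = fit.diagnostics_table().copy()
    table["rhat_ok"] = table["rhat"] < rhat_threshold
    table["ess_ok"] = table["ess"] >= min_ess
    table.attrs["converged"] = bool(table["rhat_ok"].all())
    table.attrs["n_divergent"] = fit.n_divergent
    return table


def posterior_summary(fit: PosteriorFit, hdi_prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean, SD, and HDI for the scalar parameters and the realized
    random-effect variances (the posterior of var(u) and var(v))."""
    import arviz as az

    post = fit.posterior()
    rows = {}
    scalars = {k: post[k] for k in ("m", "mu_p", "sigma_p", "sigma_u", "sigma_v")}
    if fit.model.n_parts > 1:
        scalars["var_u"] = post["u"].var(axis=-1)
    if fit.model.n_items > 1:
        scalars["var_v"] = post["v"].var(axis=-1)
    for name, arr in scalars.items():
        flat = arr.ravel()
        sd = float(flat.std())
        if sd == 0.0:
            lo = hi = float(flat[0])
        else:
            lo, hi = (float(x) for x in az.hdi(flat, hdi_prob=hdi_prob))
        rows[name] = {"mean": float(flat.mean()), "sd": sd, "hdi_lo": lo, "hdi_hi": hi}
    return pd.DataFrame(rows).T[["mean", "sd", "hdi_lo", "hdi_hi"]]
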