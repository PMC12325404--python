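"""Marginal likelihoods by bridge sampling, Bayes factors, posterior model
probabilities, and PSIS-LOO predictive comparison.

The bridge estimator iterates the Meng–Wong optimal-bridge fixed point
between the posterior draws (on the unconstrained space, Jacobians
included) and a moment-matched multivariate normal proposal, with half of
the posterior draws reserved for fitting the proposal.  The Monte-Carlo
error follows the standard asymptotic formula with an autocorrelation
correction for the posterior-side term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import ModelVariant
from .inference import PosteriorFit

__all__ = [
    "BridgeResult",
    "LooResult",
    "ComparisonResult",
    "bridge_sampler",
    "log_marginal_likelihood",
    "bayes_factor",
    "log_bayes_factor",
    "posterior_model_probs",
    "loo_elpd",
    "elpd_difference",
    "compare_models",
]


@dataclass(frozen=True)
class BridgeResult:
    logml: float
    mc_error: float
    n_iterations: int
    converged: bool


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, chol: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    d = mean.size

    diff = (x - mean).T
    z = solve_triangular(chol, diff, lower=True)
    logdet = np.sum(np.log(np.diag(chol)))
    return -0.5 * d * np.log(2.0 * np.pi) - logdet - 0.5 * np.sum(z * z, axis=0)


def bridge_sampler(
    draws: np.ndarray,
    logp_fn,
    rng=None,
    n_proposal_draws: int | None = None,
    max_iterations: int = 1000,
    tol: float = 1e-10,
    n_chains: int = 1,
) -> BridgeResult:
    """Estimate the log marginal likelihood from posterior draws.

    Parameters
    ----------
    draws
        Posterior draws on an unconstrained space, shape (n, dim).  The
        first half fits the moment-matched normal proposal; the second half
        enters the bridge.
    logp_fn
        Batched unnormalized log joint density on the same space (log
        likelihood + log prior + log Jacobian), mapping (n, dim) -> (n,).
    n_chains
        Used only for the autocorrelation correction of the error estimate.
    """
    rng = np.random.default_rng(rng)
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    n, d = draws.shape
    if n < 10:
        raise ValueError("bridge sampling needs a nontrivial number of draws")
    half = n // 2
    fit_draws, bridge_draws = draws[:half], draws[half:]
    n1 = bridge_draws.shape[0]
    n2 = n1 if n_proposal_draws is None else int(n_proposal_draws)

    mean = fit_draws.mean(axis=0)
    cov = np.cov(fit_draws, rowvar=False).reshape(d, d)
    cov[np.diag_indices(d)] += 1e-10 * max(1.0, np.trace(cov) / d)
    chol = np.linalg.cholesky(cov)

    proposal = mean + rng.standard_normal((n2, d)) @ chol.T
    l1 = logp_fn(bridge_draws) - _mvn_logpdf(bridge_draws, mean, chol)
    l2 = logp_fn(proposal) - _mvn_logpdf(proposal, mean, chol)
    if not np.all(np.isfinite(l1)):
        raise FloatingPointError("non-finite importance ratios on the posterior draws")
    keep = np.isfinite(l2)
    if not keep.all():  # proposal points in regions of zero posterior mass
        l2 = l2[keep]
        n2 = int(keep.sum())
        if n2 < 10:
            raise FloatingPointError("proposal draws almost never land in the posterior support")

    lstar = np.median(l1)
    s1 = n1 / (n1 + n2)
    s2 = n2 / (n1 + n2)
    e1 = np.exp(l1 - lstar)
    e2 = np.exp(l2 - lstar)

    r = 1.0
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        num = np.mean(e2 / (s1 * e2 + s2 * r))
        den = np.mean(1.0 / (s1 * e1 + s2 * r))
        r_new = num / den
        if not np.isfinite(r_new) or r_new <= 0:
            raise FloatingPointError("bridge fixed-point iteration left the feasible region")
        if abs(r_new - r) / r_new < tol:
            r = r_new
            converged = True
            break
        r = r_new
    logml = float(np.log(r) + lstar)

    # asymptotic relative-MSE formula; rho corrects for posterior autocorrelation
    f1 = e2 / (s1 * e2 + s2 * r)
    f2 = 1.0 / (s1 * e1 + s2 * r)
    rho = _spectral0_ratio(f2, n_chains)
    re2 = f1.var() / (n2 * f1.mean() ** 2) + rho * f2.var() / (n1 * f2.mean() ** 2)
    return BridgeResult(logml=logml, mc_error=float(np.sqrt(max(re2, 0.0))),
                        n_iterations=it, converged=converged)


def _spectral0_ratio(x: np.ndarray, n_chains: int) -> float:
    """Normalized spectral density at frequency zero (initial positive sequence)."""
    n = x.size // max(n_chains, 1)
    if n < 8:
        return 1.0
    rho_sum = 0.0
    xs = x[: n * n_chains].reshape(n_chains, n)
    xc = xs - xs.mean(axis=1, keepdims=True)
    var = np.mean(xc**2)
    if var == 0:
        return 1.0
    for lag in range(1, min(n - 1, 200)):
        acov = np.mean(xc[:, :-lag] * xc[:, lag:])
        rho = acov / var
        if rho <= 0.0:
            break
        rho_sum += rho
    return float(1.0 + 2.0 * rho_sum)


def log_marginal_likelihood(
    fit: PosteriorFit,
    n_proposal_draws: int | None = None,
    rng=None,
    max_iterations: int = 1000,
    tol: float = 1e-10,
) -> BridgeResult:
    """Bridge-sampling log marginal likelihood of a fitted model variant.

    A prior-only fit integrates to one by construction, so its log marginal
    likelihood is exactly zero.
    """
    if fit.n_trials == 0:
        return BridgeResult(logml=0.0, mc_error=0.0, n_iterations=0, converged=True)
    C, N, D = fit.unconstrained.shape
    draws = fit.unconstrained.reshape(C * N, D)
    return bridge_sampler(
        draws, fit.model.logp, rng=rng, n_proposal_draws=n_proposal_draws,
        max_iterations=max_iterations, tol=tol, n_chains=C,
    )


def log_bayes_factor(lml_a: float, lml_b: float) -> float:
    if not (np.isfinite(lml_a) and np.isfinite(lml_b)):
        raise ValueError("log marginal likelihoods must be finite")
    return float(lml_a - lml_b)


def bayes_factor(lml_a: float, lml_b: float) -> float:
    """BF_ab = exp(lml_a - lml_b); use :func:`log_bayes_factor` near overflow."""
    return float(np.exp(log_bayes_factor(lml_a, lml_b)))


def posterior_model_probs(lmls, prior_probs=None) -> np.ndarray:
    """Posterior model probabilities via log-sum-exp normalization."""
    lml = np.asarray(list(lmls.values()) if isinstance(lmls, dict) else lmls, dtype=float)
    k = lml.size
    if prior_probs is None:
        prior = np.full(k, 1.0 / k)
    else:
        prior = np.asarray(prior_probs, dtype=float)
        if prior.shape != lml.shape or np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-8:
            raise ValueError("prior_probs must be a simplex matching the models")
    with np.errstate(divide="ignore"):
        logw = lml + np.log(prior)
    probs = np.exp(logw - logsumexp(logw))
    out = probs / probs.sum()
    if isinstance(lmls, dict):
        return dict(zip(lmls.keys(), out))
    return out


@dataclass(frozen=True)
class LooResult:
    elpd: float
    se: float
    pareto_k: np.ndarray
    n_high_k: int
    pointwise: np.ndarray

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd


def loo_elpd(fit: PosteriorFit, high_k: float = 0.7) -> LooResult:
    """PSIS-smoothed leave-one-out ELPD on the sum-over-observations scale."""
    import warnings as _warnings

    import arviz as az

    if fit.loglik is None:
        raise ValueError("fit carries no pointwise log-likelihood matrix")
    idata = fit.to_inference_data()
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    k = np.asarray(res.pareto_k)
    n_high = int((k > high_k).sum())
    if n_high > 0.05 * k.size:
        _warnings.warn(f"{n_high} observations with Pareto k > {high_k}; "
                       "PSIS-LOO may be unreliable", RuntimeWarning, stacklevel=2)
    return LooResult(
        elpd=float(res.elpd_loo), se=float(res.se), pareto_k=k, n_high_k=n_high,
        pointwise=np.asarray(res.loo_i),
    )


def elpd_difference(a: LooResult, b: LooResult) -> tuple[float, float]:
    """Pairwise ELPD difference (a - b) with its paired standard error."""
    if a.pointwise.shape != b.pointwise.shape:
        raise ValueError("fits were not evaluated on the same observations")
    d = a.pointwise - b.pointwise
    return float(d.sum()), float(np.sqrt(d.size * d.var(ddof=1)))


@dataclass
class ComparisonResult:
    """Model-comparison summary across fitted variants."""

    variants: list[ModelVariant]
    logml: dict[ModelVariant, float]
    mc_error: dict[ModelVariant, float]
    posterior_probs: dict[ModelVariant, float]
    prior_probs: dict[ModelVariant, float]
    log_bf: dict[str, float] = field(default_factory=dict)
    bf: dict[str, float] = field(default_factory=dict)
    elpd: dict[ModelVariant, float] | None = None
    elpd_se: dict[ModelVariant, float] | None = None
    elpd_diff: dict[str, tuple[float, float]] | None = None

    def to_dict(self) -> dict:
        out = {
            "log_marginal_likelihood": {v.name: self.logml[v] for v in self.variants},
            "mc_error": {v.name: self.mc_error[v] for v in self.variants},
            "posterior_model_probs": {v.name: self.posterior_probs[v] for v in self.variants},
            "prior_model_probs": {v.name: self.prior_probs[v] for v in self.variants},
            "log_bayes_factors": self.log_bf,
            "bayes_factors": self.bf,
        }
        if self.elpd is not None:
            out["elpd"] = {v.name: self.elpd[v] for v in self.variants}
            out["elpd_se"] = {v.name: self.elpd_se[v] for v in self.variants}
            out["elpd_diff"] = {k: list(v) for k, v in (self.elpd_diff or {}).items()}
        return out


def compare_models(
    fits: dict | list,
    method: str = "bridge",
    prior_probs=None,
    rng=None,
) -> ComparisonResult:
    """Compare fitted variants by bridge-sampling Bayes factors and/or PSIS-LOO."""
    if method not in ("bridge", "loo", "both"):
        raise ValueError("method must be 'bridge', 'loo', or 'both'")
    fit_list = list(fits.values()) if isinstance(fits, dict) else list(fits)
    variants = [f.variant for f in fit_list]
    if len(set(variants)) != len(variants):
        raise ValueError("duplicate model variants in comparison")
    rng = np.random.default_rng(rng)

    logml, mc_err = {}, {}
    if method in ("bridge", "both"):
        for f in fit_list:
            res = log_marginal_likelihood(f, rng=rng)
            logml[f.variant], mc_err[f.variant] = res.logml, res.mc_error
    else:
        logml = {f.variant: np.nan for f in fit_list}
        mc_err = dict(logml)

    k = len(fit_list)
    prior = np.full(k, 1.0 / k) if prior_probs is None else np.asarray(prior_probs, float)
    if method in ("bridge", "both"):
        probs = posterior_model_probs(np.array([logml[v] for v in variants]), prior)
    else:
        probs = np.full(k, np.nan)
    log_bf, bf = {}, {}
    if method in ("bridge", "both"):
        for i, a in enumerate(variants):
            for b in variants[i + 1:]:
                key = f"BF_{a.value}{b.value}"
                log_bf[key] = log_bayes_factor(logml[a], logml[b])
                bf[key] = float(np.exp(log_bf[key]))

    elpd = elpd_se = elpd_diff = None
    if method in ("loo", "both"):
        loos = {f.variant: loo_elpd(f) for f in fit_list}
        elpd = {v: loos[v].elpd for v in variants}
        elpd_se = {v: loos[v].se for v in variants}
        elpd_diff = {}
        for i, a in enumerate(variants):
            for b in variants[i + 1:]:
                elpd_diff[f"{a.name}-{b.name}"] = elpd_difference(loos[a], loos[b])

    return ComparisonResult(
        variants=variants,
        logml=logml,
        mc_error=mc_err,
        posterior_probs=dict(zip(variants, probs)),
        prior_probs=dict(zip(variants, prior)),
        log_bf=log_bf,
        bf=bf,
        elpd=elpd,
        elpd_se=elpd_se,
        elpd_diff=elpd_diff,
    )
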