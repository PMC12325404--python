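"""Chain-batched adaptive Hamiltonian Monte Carlo.

A generic sampler for differentiable log densities on an unconstrained
parameter space.  All chains advance in lockstep so that a single vectorized
log-density/gradient evaluation serves every chain — the dominant cost for
hierarchical probit likelihoods is elementwise special functions over
trials, which batch essentially for free.

Adaptation follows the standard warmup recipe: dual averaging of the step
size toward a target acceptance rate, with a diagonal mass matrix
re-estimated from accumulated warmup draws at fixed checkpoints (step-size
adaptation restarts after each mass update).  Trajectory lengths are
jittered uniformly up to ``max_leapfrog`` to avoid resonance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HmcResult", "sample_hmc"]


@dataclass
class HmcResult:
    draws: np.ndarray          # (chains, n_draws, dim), unconstrained
    logp: np.ndarray           # (chains, n_draws)
    accept_rate: np.ndarray    # (chains,)
    step_size: np.ndarray      # (chains,)
    n_divergent: int
    mass_diag: np.ndarray      # (dim,)


class _DualAveraging:
    """Nesterov dual averaging of log step size (per chain)."""

    def __init__(self, eps0: np.ndarray, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps_bar = np.zeros_like(eps0)
        self.h_bar = np.zeros_like(eps0)
        self.t = 0

    def update(self, accept_prob: np.ndarray) -> np.ndarray:
        self.t += 1
        eta = 1.0 / (self.t + self.t0)
        self.h_bar = (1.0 - eta) * self.h_bar + eta * (self.target - accept_prob)
        log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1.0 - w) * self.log_eps_bar
        return np.exp(log_eps)

    def final(self) -> np.ndarray:
        return np.exp(self.log_eps_bar)


def sample_hmc(
    logp_and_grad,
    init: np.ndarray,
    n_warmup: int = 500,
    n_draws: int = 1000,
    seed=None,
    target_accept: float = 0.8,
    max_leapfrog: int = 32,
    init_step_size: float = 0.1,
    max_energy_error: float = 1000.0,
) -> HmcResult:
    """Sample with adaptive HMC.

    Parameters
    ----------
    logp_and_grad
        Callable mapping positions of shape (chains, dim) to a tuple of
        log densities (chains,) and gradients (chains, dim).
    init
        Initial positions, shape (chains, dim).
    """
    rng = np.random.default_rng(seed)
    q = np.array(init, dtype=float)
    n_chains, dim = q.shape
    lp, grad = logp_and_grad(q)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite log density at the initial positions")

    mass = np.ones(dim)
    eps = np.full(n_chains, init_step_size)
    da = _DualAveraging(eps, target_accept)
    # mass re-estimation checkpoints inside warmup
    checkpoints = {int(n_warmup * 0.4), int(n_warmup * 0.8)} if n_warmup >= 20 else set()
    warm_buffer: list[np.ndarray] = []

    draws = np.empty((n_chains, n_draws, dim))
    logps = np.empty((n_chains, n_draws))
    n_accept = np.zeros(n_chains)
    n_divergent = 0

    inv_mass = 1.0 / mass
    sqrt_mass = np.sqrt(mass)

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        n_leap = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
        momentum = rng.standard_normal((n_chains, dim)) * sqrt_mass
        with np.errstate(over="ignore", invalid="ignore"):
            h0 = -lp + 0.5 * np.sum(momentum * momentum * inv_mass, axis=1)

            q_new, lp_new, grad_new = q, lp, grad
            pm = momentum + 0.5 * eps[:, None] * grad_new
            for step in range(n_leap):
                q_new = q_new + eps[:, None] * pm * inv_mass
                lp_new, grad_new = logp_and_grad(q_new)
                if step < n_leap - 1:
                    pm = pm + eps[:, None] * grad_new
            pm = pm + 0.5 * eps[:, None] * grad_new

            kinetic = 0.5 * np.sum(pm * pm * inv_mass, axis=1)
            h1 = np.where(np.isfinite(lp_new) & np.isfinite(kinetic), -lp_new + kinetic, np.inf)
            energy_err = h1 - h0
        divergent = ~np.isfinite(energy_err) | (energy_err > max_energy_error)
        accept_prob = np.where(divergent, 0.0, np.exp(np.minimum(0.0, -energy_err)))
        accept = rng.random(n_chains) < accept_prob

        q = np.where(accept[:, None], q_new, q)
        lp = np.where(accept, lp_new, lp)
        grad = np.where(accept[:, None], grad_new, grad)

        if warming:
            eps = np.clip(da.update(accept_prob), 1e-8, 10.0)
            warm_buffer.append(q.copy())
            if it + 1 in checkpoints and len(warm_buffer) >= 10:
                recent = np.asarray(warm_buffer[len(warm_buffer) // 2:])  # (t, chains, dim)
                var = recent.reshape(-1, dim).var(axis=0)
                mass = 1.0 / np.maximum(var, 1e-10)
                inv_mass = 1.0 / mass
                sqrt_mass = np.sqrt(mass)
                da = _DualAveraging(eps, target_accept)
        else:
            if it == n_warmup and n_warmup > 0:
                pass  # step size already frozen below
            idx = it - n_warmup
            draws[:, idx, :] = q
            logps[:, idx] = lp
            n_accept += accept
            n_divergent += int(divergent.sum())

        if it == n_warmup - 1:
            eps = np.clip(da.final(), 1e-8, 10.0)

    return HmcResult(
        draws=draws,
        logp=logps,
        accept_rate=n_accept / max(n_draws, 1),
        step_size=eps,
        n_divergent=n_divergent,
        mass_diag=mass,
    )
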