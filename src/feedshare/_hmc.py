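"""A compact adaptive Hamiltonian Monte Carlo sampler.

Static-trajectory HMC with Stan-style warmup: dual-averaging step-size
adaptation towards a target acceptance statistic, and a diagonal metric
estimated over expanding warmup windows. Trajectory lengths are jittered to
avoid resonances. This is deliberately small: the posterior it targets (a
hierarchical softmax regression with non-centred random effects, ~100
dimensions) is well-conditioned after standardization, so a diagonal metric
and fixed simulation length are sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, dim)
    accept_rate: float
    n_divergent: int
    step_size: float
    inv_mass: np.ndarray


def _leapfrog(
    logp_grad: LogpGrad,
    x: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    x, p = x.copy(), p.copy()
    p = p + 0.5 * eps * grad
    lp = -np.inf
    for step in range(n_steps):
        x += eps * inv_mass * p
        lp, grad = logp_grad(x)
        if not (np.isfinite(lp) and np.all(np.isfinite(grad))):
            return x, p, -np.inf, grad, True
        if step < n_steps - 1:
            p += eps * grad
    p += 0.5 * eps * grad
    return x, p, lp, grad, False


def _find_initial_step(
    logp_grad: LogpGrad, x: np.ndarray, inv_mass: np.ndarray, rng: np.random.Generator
) -> float:
    """Crude bracketing: double/halve eps until the one-step accept prob
    crosses 0.5 (Stan's heuristic)."""
    eps = 0.1
    lp0, grad0 = logp_grad(x)
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0**2)
    _, p1, lp1, _, div = _leapfrog(logp_grad, x, p0, grad0, eps, 1, inv_mass)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2) if not div else -np.inf
    direction = 1 if (h1 - h0) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, lp1, _, div = _leapfrog(logp_grad, x, p0, grad0, eps, 1, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2) if not div else -np.inf
        crossed = (h1 - h0) > np.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            break
    return float(eps)


def _warmup_windows(n_warmup: int) -> list[tuple[int, int]]:
    """(start, end) of metric-adaptation windows within warmup."""
    if n_warmup < 60:
        return []
    init_buffer = max(15, int(0.15 * n_warmup))
    term_buffer = max(10, int(0.10 * n_warmup))
    windows = []
    start, width = init_buffer, 25
    while start + width < n_warmup - term_buffer:
        if start + 3 * width >= n_warmup - term_buffer:
            width = n_warmup - term_buffer - start  # absorb the remainder
        windows.append((start, start + width))
        start += width
        width *= 2
    return windows


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    sim_length: float = 2.5,
    max_steps: int = 64,
) -> ChainResult:
    """Run one HMC chain; returns post-warmup draws."""
    dim = x0.size
    x = x0.astype(float).copy()
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-density")

    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = _warmup_windows(n_warmup)
    window_idx = 0
    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    n_accept = 0.0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        cur_eps = eps if warming else np.exp(log_eps_bar)
        n_steps = int(np.ceil(sim_length / cur_eps * rng.uniform(0.8, 1.2)))
        n_steps = max(1, min(max_steps, n_steps))

        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0**2)
        x1, p1, lp1, grad1, div = _leapfrog(logp_grad, x, p0, grad, cur_eps, n_steps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(lp1) else -np.inf
        delta_h = h1 - h0
        divergent = div or (not np.isfinite(delta_h)) or (-delta_h > _DIVERGENCE_THRESHOLD)
        accept_prob = 0.0 if divergent else min(1.0, float(np.exp(min(delta_h, 0.0))))
        if (not divergent) and rng.uniform() < accept_prob:
            x, lp, grad = x1, lp1, grad1

        if warming:
            # dual averaging (counter restarts with each adaptation window)
            da_count += 1
            m = da_count
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            eta = m**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            # metric adaptation over the current window
            if window_idx < len(windows):
                w_start, w_end = windows[window_idx]
                if w_start <= it < w_end:
                    welford_n += 1
                    delta = x - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (x - welford_mean)
                if it == w_end - 1:
                    if welford_n > 4:
                        var = welford_m2 / (welford_n - 1)
                        # regularize towards unit metric (Stan's shrinkage)
                        n_w = welford_n
                        inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                        inv_mass = np.maximum(inv_mass, 1e-10)
                    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)
                    window_idx += 1
                    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = np.log(eps), 0.0, 0
        else:
            draws[it - n_warmup] = x
            n_accept += accept_prob
            n_divergent += int(divergent)

    return ChainResult(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        n_divergent=n_divergent,
        step_size=float(np.exp(log_eps_bar)),
        inv_mass=inv_mass,
    )
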