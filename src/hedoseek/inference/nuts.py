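"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A compact, dependency-free NUTS implementation (slice variant with
multiplicative tree doubling) sufficient for the hierarchical models in this
package: target densities are smooth, unconstrained, and low-dimensional
(tens to a few hundred parameters).  The warm-up follows the usual three-phase
scheme: an initial step-size phase, expanding variance-estimation windows that
refresh the diagonal mass matrix, and a final step-size phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_MAX_DELTA_H = 1000.0  # divergence threshold on the log joint


@dataclass
class ChainStats:
    divergences: int = 0
    max_treedepth_hits: int = 0
    step_size: float = 0.0
    inv_mass: np.ndarray | None = None
    accept_mean: float = 0.0
    treedepths: list[int] = field(default_factory=list)


def _leapfrog(logp_grad: LogpGrad, x, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_mass * p
    logp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _kinetic(p, inv_mass) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        return 0.5 * float(np.dot(p, inv_mass * p))


def _find_initial_step(logp_grad: LogpGrad, x0, inv_mass, rng) -> float:
    """Heuristic: scale eps by 2x until the one-step accept prob crosses 0.5."""
    with np.errstate(all="ignore"):
        eps = 1.0
        logp0, grad0 = logp_grad(x0)
        p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
        h0 = logp0 - _kinetic(p0, inv_mass)
        _, p1, logp1, _ = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
        for _ in range(100):
            eps *= 2.0**direction
            _, p1, logp1, _ = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass)
            h1 = logp1 - _kinetic(p1, inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            if direction * (h1 - h0) < direction * np.log(0.5):
                break
        return eps


class _Tree:
    """State carried through recursive tree doubling."""

    __slots__ = ("logp_grad", "inv_mass", "eps", "log_u", "h0", "rng",
                 "n_accept", "sum_accept", "diverged")

    def __init__(self, logp_grad, inv_mass, eps, log_u, h0, rng):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.eps = eps
        self.log_u = log_u
        self.h0 = h0
        self.rng = rng
        self.n_accept = 0
        self.sum_accept = 0.0
        self.diverged = False

    def build(self, x, p, grad, direction, depth):
        """Returns (x-, p-, grad-, x+, p+, grad+, x', n', stop)."""
        if depth == 0:
            x1, p1, logp1, grad1 = _leapfrog(
                self.logp_grad, x, p, grad, direction * self.eps, self.inv_mass
            )
            h1 = logp1 - _kinetic(p1, self.inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            n1 = int(self.log_u <= h1)
            stop = (self.log_u - _MAX_DELTA_H) > h1
            if stop:
                self.diverged = True
            self.sum_accept += min(1.0, float(np.exp(min(0.0, h1 - self.h0))))
            self.n_accept += 1
            return x1, p1, grad1, x1, p1, grad1, x1, n1, stop
        xm, pm, gm, xp, pp, gp, xc, nc, stop = self.build(x, p, grad, direction, depth - 1)
        if not stop:
            if direction == -1:
                xm, pm, gm, _, _, _, xc2, nc2, stop2 = self.build(
                    xm, pm, gm, direction, depth - 1
                )
            else:
                _, _, _, xp, pp, gp, xc2, nc2, stop2 = self.build(
                    xp, pp, gp, direction, depth - 1
                )
            if nc2 > 0 and self.rng.random() < nc2 / max(nc + nc2, 1):
                xc = xc2
            nc += nc2
            dx = xp - xm
            uturn = (np.dot(dx, self.inv_mass * pm) < 0) or (
                np.dot(dx, self.inv_mass * pp) < 0
            )
            stop = stop2 or uturn
        return xm, pm, gm, xp, pp, gp, xc, nc, stop


def _nuts_step(logp_grad, x, logp, grad, eps, inv_mass, rng, max_treedepth):
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p0, inv_mass)
    log_u = h0 + np.log(rng.random())
    tree = _Tree(logp_grad, inv_mass, eps, log_u, h0, rng)
    xm = xp = x
    pm = pp = p0
    gm = gp = grad
    x_new, n, depth = x, 1, 0
    while depth < max_treedepth:
        direction = -1 if rng.random() < 0.5 else 1
        if direction == -1:
            xm, pm, gm, _, _, _, xc, nc, stop = tree.build(xm, pm, gm, direction, depth)
        else:
            _, _, _, xp, pp, gp, xc, nc, stop = tree.build(xp, pp, gp, direction, depth)
        if stop:
            break
        if nc > 0 and rng.random() < min(1.0, nc / n):
            x_new = xc
        n += nc
        dx = xp - xm
        if (np.dot(dx, inv_mass * pm) < 0) or (np.dot(dx, inv_mass * pp) < 0):
            break
        depth += 1
    accept_stat = tree.sum_accept / max(tree.n_accept, 1)
    logp_new, grad_new = (logp, grad) if x_new is x else logp_grad(x_new)
    return x_new, logp_new, grad_new, accept_stat, tree.diverged, depth


def _warmup_windows(n_warmup: int) -> list[tuple[int, int, bool]]:
    """(start, end, update_mass) windows covering the warm-up."""
    if n_warmup < 60:
        return [(0, n_warmup, False)]
    init = max(25, int(0.1 * n_warmup))
    term = max(25, int(0.1 * n_warmup))
    windows: list[tuple[int, int, bool]] = [(0, init, False)]
    pos, size = init, 25
    while pos + size < n_warmup - term:
        if pos + 3 * size >= n_warmup - term:
            size = n_warmup - term - pos  # absorb remainder
        windows.append((pos, pos + size, True))
        pos += size
        size *= 2
    windows.append((pos, n_warmup, False))
    return windows


def sample_nuts(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
) -> tuple[np.ndarray, ChainStats]:
    """Run one NUTS chain; returns post-warm-up draws and chain statistics."""
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    # dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    stats = ChainStats()
    windows = _warmup_windows(n_warmup)
    wi = 0
    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    for it in range(n_warmup):
        x, logp, grad, accept, diverged, _ = _nuts_step(
            logp_grad, x, logp, grad, eps, inv_mass, rng, max_treedepth
        )
        da_count += 1
        h_bar = (1 - 1 / (da_count + t0)) * h_bar + (target_accept - accept) / (
            da_count + t0
        )
        log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
        w = da_count ** (-kappa)
        log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
        eps = float(np.exp(log_eps))

        start, end, update_mass = windows[wi]
        if update_mass:
            welford_n += 1
            delta = x - welford_mean
            welford_mean += delta / welford_n
            welford_m2 += delta * (x - welford_mean)
        if it + 1 == end:
            if update_mass and welford_n > 4:
                var = welford_m2 / (welford_n - 1)
                # Stan-style regularization toward unit scale
                inv_mass = var * (welford_n / (welford_n + 5.0)) + 1e-3 * (
                    5.0 / (welford_n + 5.0)
                )
                eps = _find_initial_step(logp_grad, x, inv_mass, rng)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
                welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)
            wi = min(wi + 1, len(windows) - 1)

    eps = float(np.exp(log_eps_bar)) if n_warmup > 0 else eps
    stats.step_size = eps
    stats.inv_mass = inv_mass.copy()

    draws = np.empty((n_draws, dim))
    accepts = np.empty(n_draws)
    for it in range(n_draws):
        x, logp, grad, accept, diverged, depth = _nuts_step(
            logp_grad, x, logp, grad, eps, inv_mass, rng, max_treedepth
        )
        draws[it] = x
        accepts[it] = accept
        stats.divergences += int(diverged)
        stats.max_treedepth_hits += int(depth >= max_treedepth)
        stats.treedepths.append(depth)
    stats.accept_mean = float(accepts.mean()) if n_draws else 0.0
    return draws, stats
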