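"""No-U-Turn sampler with dual-averaging step size and diagonal or dense metric.

A self-contained gradient-based MCMC engine operating on an unconstrained
parameter vector.  The interface is a single function, :func:`sample_nuts`,
taking a ``logp_and_grad(x) -> (float, ndarray)`` callable.  Multinomial
state selection within each doubling and an energy-error divergence
threshold of 1000.  Two metrics are supported:

* diagonal (default): Stan-style three-phase warmup — initial step-size
  window, expanding variance-estimation windows, terminal step-size window;
* dense: a fixed inverse metric (an estimate of the posterior covariance,
  e.g. from the Hessian at the posterior mode) with step-size adaptation
  only.  A dense metric absorbs the strong correlations between a
  participant's learning components that a diagonal metric cannot, which
  shortens trajectories considerably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["sample_nuts", "NutsResult"]

DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_draws, dim), post-warmup
    logp: np.ndarray           # (n_draws,)
    divergences: int
    accept_stat: float
    step_size: float
    inv_mass: np.ndarray
    treedepths: np.ndarray


class _Tree:
    __slots__ = ("z_minus", "r_minus", "z_plus", "r_plus", "z_prop", "logp_prop",
                 "log_w", "sum_accept", "n_leapfrog", "turning", "divergent",
                 "_grad_minus", "_grad_plus")

    def __init__(self, z_minus, r_minus, z_plus, r_plus, z_prop, logp_prop,
                 log_w, sum_accept, n_leapfrog, turning, divergent):
        self.z_minus = z_minus
        self.r_minus = r_minus
        self.z_plus = z_plus
        self.r_plus = r_plus
        self.z_prop = z_prop
        self.logp_prop = logp_prop
        self.log_w = log_w
        self.sum_accept = sum_accept
        self.n_leapfrog = n_leapfrog
        self.turning = turning
        self.divergent = divergent


def sample_nuts(
    logp_and_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    inv_mass0: np.ndarray | None = None,
    dense_inv_mass: np.ndarray | None = None,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws and sampler statistics.

    ``inv_mass0`` seeds the diagonal inverse metric (refined during warmup);
    ``dense_inv_mass`` instead fixes a dense inverse metric for the whole
    run (only the step size is adapted).
    """
    dim = x0.size
    z = np.asarray(x0, dtype=float).copy()
    logp, grad = logp_and_grad(z)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")

    dense = dense_inv_mass is not None
    if dense:
        from scipy.linalg import cholesky, solve_triangular
        sigma = np.asarray(dense_inv_mass, dtype=float)
        chol_sigma = cholesky(sigma, lower=True)

        def sample_momentum():
            xi = rng.standard_normal(dim)
            return solve_triangular(chol_sigma, xi, lower=True, trans="T")

        def velocity(r):
            return sigma @ r

        inv_mass = np.diag(sigma).copy()   # reported only
    else:
        inv_mass = np.ones(dim) if inv_mass0 is None else np.asarray(inv_mass0, dtype=float).copy()

        def sample_momentum():
            return rng.standard_normal(dim) / np.sqrt(inv_mass)

        def velocity(r):
            return inv_mass * r

    def kinetic(r):
        return 0.5 * float(np.dot(r, velocity(r)))

    def uturn(z_plus, z_minus, r_plus, r_minus):
        dz = z_plus - z_minus
        return (np.dot(dz, velocity(r_minus)) < 0) or (np.dot(dz, velocity(r_plus)) < 0)

    def leapfrog(z, r, grad, eps):
        r_half = r + 0.5 * eps * grad
        z_new = z + eps * velocity(r_half)
        logp_new, grad_new = logp_and_grad(z_new)
        r_new = r_half + 0.5 * eps * grad_new
        return z_new, r_new, logp_new, grad_new

    def joint(logp_val, r):
        return logp_val - kinetic(r)

    def find_initial_step(z, logp, grad):
        eps = 1.0
        r = sample_momentum()
        j0 = joint(logp, r)
        z1, r1, lp1, _ = leapfrog(z, r, grad, eps)
        j1 = joint(lp1, r1) if np.isfinite(lp1) else -np.inf
        direction = 1.0 if (j1 - j0) > math.log(0.5) else -1.0
        for _ in range(100):
            eps *= 2.0 ** direction
            z1, r1, lp1, _ = leapfrog(z, r, grad, eps)
            j1 = joint(lp1, r1) if np.isfinite(lp1) else -np.inf
            if direction == 1.0 and (j1 - j0) <= math.log(0.5):
                break
            if direction == -1.0 and (j1 - j0) > math.log(0.5):
                break
        return eps

    def build_tree(z, r, grad, logp_val, direction, depth, eps, j0):
        if depth == 0:
            z1, r1, lp1, g1 = leapfrog(z, r, grad, direction * eps)
            j1 = joint(lp1, r1) if np.isfinite(lp1) else -np.inf
            divergent = (j0 - j1) > DIVERGENCE_THRESHOLD or not np.isfinite(j1)
            log_w = j1 - j0
            accept = min(1.0, math.exp(min(0.0, log_w)))
            tree = _Tree(z1, r1, z1, r1, z1, lp1, log_w, accept, 1, False, divergent)
            tree._grad_minus = g1
            tree._grad_plus = g1
            return tree
        first = build_tree(z, r, grad, logp_val, direction, depth - 1, eps, j0)
        if first.turning or first.divergent:
            return first
        if direction > 0:
            second = build_tree(first.z_plus, first.r_plus, first._grad_plus,
                                first.logp_prop, direction, depth - 1, eps, j0)
        else:
            second = build_tree(first.z_minus, first.r_minus, first._grad_minus,
                                first.logp_prop, direction, depth - 1, eps, j0)
        total_log_w = np.logaddexp(first.log_w, second.log_w)
        if (not second.divergent) and math.log(rng.random() + 1e-300) < second.log_w - total_log_w:
            z_prop, logp_prop = second.z_prop, second.logp_prop
        else:
            z_prop, logp_prop = first.z_prop, first.logp_prop
        if direction > 0:
            z_minus, r_minus, g_minus = first.z_minus, first.r_minus, first._grad_minus
            z_plus, r_plus, g_plus = second.z_plus, second.r_plus, second._grad_plus
        else:
            z_minus, r_minus, g_minus = second.z_minus, second.r_minus, second._grad_minus
            z_plus, r_plus, g_plus = first.z_plus, first.r_plus, first._grad_plus
        turning = second.turning or uturn(z_plus, z_minus, r_plus, r_minus)
        tree = _Tree(z_minus, r_minus, z_plus, r_plus, z_prop, logp_prop, total_log_w,
                     first.sum_accept + second.sum_accept,
                     first.n_leapfrog + second.n_leapfrog,
                     turning, second.divergent)
        tree._grad_minus = g_minus
        tree._grad_plus = g_plus
        return tree

    # --- warmup schedule ---
    if dense:
        init_window, adapt_end = n_warmup, n_warmup  # step-size adaptation only
        window_ends = []
    else:
        init_window = max(1, int(0.15 * n_warmup))
        term_window = max(1, int(0.10 * n_warmup))
        adapt_end = n_warmup - term_window
        window_ends = []
        w = max(10, int(0.08 * n_warmup))
        e = init_window + w
        while e < adapt_end - w:      # last doubling window absorbs the remainder
            window_ends.append(e)
            w *= 2
            e += w
        window_ends.append(adapt_end)

    eps = find_initial_step(z, logp, grad)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)
    next_window = 0

    total = n_warmup + n_draws
    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    treedepths = np.zeros(n_draws, dtype=np.int64)
    divergences = 0
    accept_accum = 0.0

    for it in range(total):
        r0 = sample_momentum()
        j0 = joint(logp, r0)
        z_minus = z_plus = z
        r_minus = r_plus = r0
        g_minus = g_plus = grad
        lp_edge_minus = lp_edge_plus = logp
        z_prop, logp_prop = z, logp
        log_w_total = 0.0
        sum_accept, n_leap = 0.0, 0
        divergent_iter = False
        depth = 0
        while depth < max_treedepth:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            if direction > 0:
                sub = build_tree(z_plus, r_plus, g_plus, lp_edge_plus, direction, depth, eps, j0)
            else:
                sub = build_tree(z_minus, r_minus, g_minus, lp_edge_minus, direction, depth, eps, j0)
            sum_accept += sub.sum_accept
            n_leap += sub.n_leapfrog
            if sub.divergent:
                divergent_iter = True
                break
            if sub.turning:
                break
            # biased progressive sampling: favour the new subtree
            if math.log(rng.random() + 1e-300) < sub.log_w - log_w_total:
                z_prop, logp_prop = sub.z_prop, sub.logp_prop
            log_w_total = np.logaddexp(log_w_total, sub.log_w)
            if direction > 0:
                z_plus, r_plus, g_plus = sub.z_plus, sub.r_plus, sub._grad_plus
                lp_edge_plus = sub.logp_prop
            else:
                z_minus, r_minus, g_minus = sub.z_minus, sub.r_minus, sub._grad_minus
                lp_edge_minus = sub.logp_prop
            depth += 1
            if uturn(z_plus, z_minus, r_plus, r_minus):
                break
        if not np.array_equal(z_prop, z):
            z = z_prop
            logp, grad = logp_and_grad(z)

        accept_stat = sum_accept / max(n_leap, 1)
        if it < n_warmup:
            # dual averaging
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_stat) / (m + t0)
            log_eps = mu - math.sqrt(m) / gamma * h_bar
            w_m = m ** (-kappa)
            log_eps_bar = w_m * log_eps + (1 - w_m) * log_eps_bar
            eps = math.exp(log_eps)
            if init_window <= it < adapt_end:
                welford_n += 1
                delta = z - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (z - welford_mean)
                if next_window < len(window_ends) and it + 1 == window_ends[next_window] and welford_n > 4:
                    var = welford_m2 / (welford_n - 1)
                    # regularize toward unit metric as Stan does
                    var = (welford_n / (welford_n + 5.0)) * var + (5.0 / (welford_n + 5.0)) * 1e-3
                    inv_mass = np.maximum(var, 1e-10)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    next_window += 1
                    eps = find_initial_step(z, logp, grad)
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar = math.log(eps), 0.0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            k = it - n_warmup
            draws[k] = z
            logps[k] = logp
            treedepths[k] = depth
            accept_accum += accept_stat
            if divergent_iter:
                divergences += 1

    return NutsResult(
        draws=draws,
        logp=logps,
        divergences=divergences,
        accept_stat=accept_accum / max(n_draws, 1),
        step_size=eps,
        inv_mass=inv_mass,
        treedepths=treedepths,
    )
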