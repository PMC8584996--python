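"""No-U-Turn Hamiltonian Monte Carlo.

A compact NUTS engine used to sample the hierarchical multinomial-logit
posterior.  Gradients are supplied analytically by the caller.  The
implementation follows the multinomial-sampling formulation with
doubling trajectory expansion, a generalized U-turn criterion under a
diagonal mass matrix, dual-averaging step-size adaptation and mass
estimation from an intermediate warmup window — the standard recipe for
hierarchical posteriors whose group-scale coordinates form funnels that
fixed-length trajectories traverse poorly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DIVERGENCE_GAP = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, dim)
    accept_rate: float
    divergences: int
    step_size: float
    mean_tree_depth: float


class _Tree:
    __slots__ = (
        "x_minus", "p_minus", "grad_minus", "x_plus", "p_plus", "grad_plus",
        "x_prop", "lp_prop", "grad_prop", "log_sum_w", "sum_accept",
        "n_leap", "divergent", "turning",
    )

    def __init__(self, x, p, grad, lp, log_w, accept):
        self.x_minus = self.x_plus = self.x_prop = x
        self.p_minus = self.p_plus = p
        self.grad_minus = self.grad_plus = self.grad_prop = grad
        self.lp_prop = lp
        self.log_sum_w = log_w
        self.sum_accept = accept
        self.n_leap = 1
        self.divergent = False
        self.turning = False


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_mass * p
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _turning(x_minus, p_minus, x_plus, p_plus, inv_mass) -> bool:
    dx = x_plus - x_minus
    return (
        dx @ (inv_mass * p_minus) < 0 or dx @ (inv_mass * p_plus) < 0
    )


def _build_tree(
    logp_grad, x, p, grad, depth, direction, eps, inv_mass, h0, rng
) -> _Tree:
    if depth == 0:
        x1, p1, lp1, grad1 = _leapfrog(
            logp_grad, x, p, grad, direction * eps, inv_mass
        )
        if np.isfinite(lp1):
            h1 = lp1 - 0.5 * np.sum(inv_mass * p1**2)
            dh = h1 - h0
        else:
            dh = -np.inf
        tree = _Tree(
            x1, p1, grad1, lp1,
            log_w=dh if np.isfinite(dh) else -np.inf,
            accept=min(1.0, float(np.exp(min(dh, 0.0)))) if np.isfinite(dh) else 0.0,
        )
        tree.divergent = not np.isfinite(dh) or dh < -_DIVERGENCE_GAP
        return tree

    first = _build_tree(
        logp_grad, x, p, grad, depth - 1, direction, eps, inv_mass, h0, rng
    )
    if first.divergent or first.turning:
        return first
    if direction == 1:
        x0, p0, g0 = first.x_plus, first.p_plus, first.grad_plus
    else:
        x0, p0, g0 = first.x_minus, first.p_minus, first.grad_minus
    second = _build_tree(
        logp_grad, x0, p0, g0, depth - 1, direction, eps, inv_mass, h0, rng
    )
    # merge
    first.n_leap += second.n_leap
    first.sum_accept += second.sum_accept
    if second.divergent or second.turning:
        first.divergent = second.divergent
        first.turning = second.turning
        return first
    total = np.logaddexp(first.log_sum_w, second.log_sum_w)
    if np.log(rng.uniform()) < second.log_sum_w - total:
        first.x_prop = second.x_prop
        first.lp_prop = second.lp_prop
        first.grad_prop = second.grad_prop
    first.log_sum_w = total
    if direction == 1:
        first.x_plus, first.p_plus = second.x_plus, second.p_plus
        first.grad_plus = second.grad_plus
    else:
        first.x_minus, first.p_minus = second.x_minus, second.p_minus
        first.grad_minus = second.grad_minus
    first.turning = _turning(
        first.x_minus, first.p_minus, first.x_plus, first.p_plus, inv_mass
    )
    return first


def _nuts_step(logp_grad, x, lp, grad, eps, inv_mass, rng, max_depth):
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(inv_mass * p0**2)
    tree = _Tree(x, p0, grad, lp, log_w=0.0, accept=1.0)
    tree.n_leap = 0
    tree.sum_accept = 0.0
    depth = 0
    divergent = False
    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            x0, p0_, g0 = tree.x_plus, tree.p_plus, tree.grad_plus
        else:
            x0, p0_, g0 = tree.x_minus, tree.p_minus, tree.grad_minus
        sub = _build_tree(
            logp_grad, x0, p0_, g0, depth, direction, eps, inv_mass, h0, rng
        )
        tree.n_leap += sub.n_leap
        tree.sum_accept += sub.sum_accept
        if sub.divergent:
            divergent = True
            break
        if sub.turning:
            break
        # biased progressive sampling toward the new subtree
        if np.log(rng.uniform()) < sub.log_sum_w - tree.log_sum_w:
            tree.x_prop = sub.x_prop
            tree.lp_prop = sub.lp_prop
            tree.grad_prop = sub.grad_prop
        tree.log_sum_w = np.logaddexp(tree.log_sum_w, sub.log_sum_w)
        if direction == 1:
            tree.x_plus, tree.p_plus = sub.x_plus, sub.p_plus
            tree.grad_plus = sub.grad_plus
        else:
            tree.x_minus, tree.p_minus = sub.x_minus, sub.p_minus
            tree.grad_minus = sub.grad_minus
        if _turning(tree.x_minus, tree.p_minus, tree.x_plus, tree.p_plus,
                    inv_mass):
            depth += 1
            break
        depth += 1
    accept_stat = tree.sum_accept / max(tree.n_leap, 1)
    return tree.x_prop, tree.lp_prop, tree.grad_prop, accept_stat, divergent, depth


def _adaptation_windows(n_warmup: int) -> tuple[int, set[int]]:
    """Expanding slow-adaptation windows (mass-matrix re-estimation points).

    An initial fast phase (15%) adapts only the step size; doubling
    windows starting at 25 iterations re-estimate the diagonal mass,
    with a terminal fast phase (10%) left for final step-size tuning.
    """
    if n_warmup < 120:
        return max(1, n_warmup // 4), {int(0.85 * n_warmup)}
    fast_end = int(0.15 * n_warmup)
    term = int(0.1 * n_warmup)
    ends: set[int] = set()
    pos = fast_end
    w = 25
    while pos + w < n_warmup - term:
        # absorb the remainder if the next doubling would overshoot
        if pos + 3 * w >= n_warmup - term:
            w = n_warmup - term - pos
        pos += w
        ends.add(pos)
        w *= 2
    return fast_end, ends


def _find_initial_step(logp_grad, x, rng, inv_mass) -> float:
    """Heuristic: double/halve eps until the one-step accept prob crosses 0.5."""
    eps = 0.1
    lp0, grad0 = logp_grad(x)
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0**2)

    def h_after(eps):
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p0, grad0, eps, inv_mass)
        return (
            lp1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(lp1) else -np.inf
        )

    direction = 1 if (h_after(eps) - h0) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        crossed = (h_after(eps) - h0) > np.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            break
    return float(max(eps, 1e-7))


def slice_sample_1d(
    logf: Callable[[float], float],
    x0: float,
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
) -> float:
    """Univariate slice sampling with stepping-out and shrinkage."""
    y = logf(x0) - rng.exponential()
    lo = x0 - w * rng.uniform()
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= y:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_depth: int = 10,
    extra_step: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
) -> ChainResult:
    """Run one NUTS chain; returns post-warmup draws and diagnostics.

    ``extra_step`` is an optional Markov-kernel callback applied after
    every NUTS transition (used for interweaved Gibbs-type updates of
    group-scale parameters); it must leave the target invariant.
    """
    dim = x0.size
    x = x0.astype(float).copy()
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    eps = _find_initial_step(logp_grad, x, rng, inv_mass)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    fast_end, window_ends = _adaptation_windows(n_warmup)
    window: list[np.ndarray] = []
    draws = np.empty((n_draws, dim))
    accept_sum, divergences, depth_sum = 0.0, 0, 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        # mild step-size jitter guards against locally varying curvature
        eps_it = eps * (0.5 + rng.uniform())
        x, lp, grad, accept_stat, divergent, depth = _nuts_step(
            logp_grad, x, lp, grad, eps_it, inv_mass, rng, max_depth
        )
        if extra_step is not None:
            x = extra_step(x, rng)
            lp, grad = logp_grad(x)
        if warming:
            adapt_iter += 1
            eta = 1.0 / (adapt_iter + t0)
            h_bar = (1 - eta) * h_bar + eta * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            w = adapt_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it + 1 == fast_end:
                window = []  # discard the initial fast-phase transient
            else:
                window.append(x.copy())
            if it + 1 in window_ends:
                if len(window) >= 10:
                    var = np.var(np.asarray(window), axis=0)
                    n_w = len(window)
                    inv_mass = (
                        (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                    )
                    inv_mass = np.clip(inv_mass, 1e-8, 1e8)
                    eps = _find_initial_step(logp_grad, x, rng, inv_mass)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
                window = []
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            if divergent:
                divergences += 1
            accept_sum += accept_stat
            depth_sum += depth
            draws[it - n_warmup] = x
    return ChainResult(
        draws=draws,
        accept_rate=accept_sum / max(n_draws, 1),
        divergences=divergences,
        step_size=eps,
        mean_tree_depth=depth_sum / max(n_draws, 1),
    )


def sample(
    logp_grad: LogpGrad,
    init: Callable[[np.random.Generator], np.ndarray],
    dim: int,
    chains: int,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.9,
    max_depth: int = 10,
    extra_step=None,
) -> tuple[np.ndarray, dict]:
    """Run several chains; returns draws (chains, n_draws, dim) and stats."""
    ss = np.random.SeedSequence(seed)
    out = np.empty((chains, n_draws, dim))
    stats = {"accept_rate": [], "divergences": 0, "step_size": [],
             "mean_tree_depth": []}
    for c, child in enumerate(ss.spawn(chains)):
        rng = np.random.default_rng(child)
        res = sample_chain(
            logp_grad, init(rng), n_warmup, n_draws, rng,
            target_accept=target_accept, max_depth=max_depth,
            extra_step=extra_step,
        )
        out[c] = res.draws
        stats["accept_rate"].append(res.accept_rate)
        stats["divergences"] += res.divergences
        stats["step_size"].append(res.step_size)
        stats["mean_tree_depth"].append(res.mean_tree_depth)
    return out, stats
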