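"""No-U-Turn Hamiltonian Monte Carlo with warmup adaptation.

A self-contained NUTS implementation for targets that expose
``logp_grad(theta) -> (logp, grad)`` on an unconstrained parameter vector:

* multinomial trajectory sampling over a doubling binary tree with the
  no-U-turn termination criterion evaluated with metric velocities;
* dual-averaging step-size adaptation toward a target acceptance statistic;
* diagonal (Euclidean) metric estimated from warmup draws in doubling
  adaptation windows, Stan-style (initial step-size buffer, growing variance
  windows, terminal step-size buffer);
* divergence detection at an energy error of 1000 nats.

Chains are run sequentially, each with an independent child seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "sample_nuts"]

_MAX_ENERGY_ERROR = 1000.0


@dataclass
class NutsResult:
    """Raw sampler output: draws (chains, draws, dim) plus per-draw statistics."""

    draws: np.ndarray
    diverging: np.ndarray
    tree_depth: np.ndarray
    accept_stat: np.ndarray
    energy: np.ndarray
    step_size: np.ndarray  # per chain, post-warmup
    inv_mass: np.ndarray   # per chain, diagonal

    @property
    def n_divergent(self) -> int:
        return int(self.diverging.sum())

    @property
    def divergence_rate(self) -> float:
        return float(self.diverging.mean())


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman)."""

    def __init__(self, eps0: float, target: float, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75) -> None:
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


class _Welford:
    """Streaming mean/variance for metric adaptation."""

    def __init__(self, dim: int) -> None:
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularise toward unity as Stan does, protecting tiny windows
        w = self.n / (self.n + 5.0)
        return w * var + (1.0 - w) * 1e-3


def _find_reasonable_epsilon(
    logp_grad: Callable, theta: np.ndarray, inv_mass: np.ndarray, rng: np.random.Generator
) -> float:
    eps = 1.0
    logp, grad = logp_grad(theta)
    p = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * float(p * inv_mass @ p)

    def energy_after(eps: float) -> float:
        p1 = p + 0.5 * eps * grad
        theta1 = theta + eps * inv_mass * p1
        logp1, grad1 = logp_grad(theta1)
        p1 = p1 + 0.5 * eps * grad1
        if not np.isfinite(logp1):
            return math.inf
        return -logp1 + 0.5 * float(p1 * inv_mass @ p1)

    diff = h0 - energy_after(eps)
    direction = 1 if diff > math.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0**direction
        diff = h0 - energy_after(eps)
        if (direction == 1 and diff <= math.log(0.5)) or (
            direction == -1 and diff >= math.log(0.5)
        ):
            break
    return eps


class _Tree:
    """One NUTS trajectory tree (per-draw scratch state)."""

    __slots__ = (
        "logp_grad", "inv_mass", "eps", "h0", "rng",
        "sum_accept", "n_leaves", "diverging", "depth_reached",
    )

    def __init__(self, logp_grad, inv_mass, eps, h0, rng):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.eps = eps
        self.h0 = h0
        self.rng = rng
        self.sum_accept = 0.0
        self.n_leaves = 0
        self.diverging = False

    def _leapfrog(self, theta, p, grad, direction):
        eps = direction * self.eps
        p1 = p + 0.5 * eps * grad
        theta1 = theta + eps * self.inv_mass * p1
        logp1, grad1 = self.logp_grad(theta1)
        p1 = p1 + 0.5 * eps * grad1
        return theta1, p1, logp1, grad1

    def build(self, theta, p, grad, depth, direction):
        """Returns (theta-, p-, grad-, theta+, p+, grad+, proposal, logp_prop,
        log_weight, turning)."""
        if depth == 0:
            theta1, p1, logp1, grad1 = self._leapfrog(theta, p, grad, direction)
            if np.isfinite(logp1):
                h = -logp1 + 0.5 * float(p1 * self.inv_mass @ p1)
            else:
                h = math.inf
            energy_error = h - self.h0
            if energy_error > _MAX_ENERGY_ERROR or not math.isfinite(h):
                self.diverging = True
                return theta1, p1, grad1, theta1, p1, grad1, theta1, logp1, -math.inf, True
            self.sum_accept += min(1.0, math.exp(-energy_error))
            self.n_leaves += 1
            return theta1, p1, grad1, theta1, p1, grad1, theta1, logp1, -energy_error, False

        # first half
        out = self.build(theta, p, grad, depth - 1, direction)
        (tm, pm, gm, tp, pp, gp, prop, logp_prop, lw1, stop) = out
        if stop:
            return out
        # second half, grown in the same direction
        if direction == -1:
            out2 = self.build(tm, pm, gm, depth - 1, direction)
            (tm, pm, gm, _, _, _, prop2, logp2, lw2, stop2) = out2
        else:
            out2 = self.build(tp, pp, gp, depth - 1, direction)
            (_, _, _, tp, pp, gp, prop2, logp2, lw2, stop2) = out2
        if stop2:
            return tm, pm, gm, tp, pp, gp, prop, logp_prop, lw1, True
        total = np.logaddexp(lw1, lw2)
        if math.log(self.rng.uniform()) < lw2 - total:
            prop, logp_prop = prop2, logp2
        turning = self._uturn(tm, pm, tp, pp)
        return tm, pm, gm, tp, pp, gp, prop, logp_prop, total, turning

    def _uturn(self, theta_minus, p_minus, theta_plus, p_plus) -> bool:
        dtheta = theta_plus - theta_minus
        return (
            float(dtheta @ (self.inv_mass * p_minus)) < 0.0
            or float(dtheta @ (self.inv_mass * p_plus)) < 0.0
        )


def _nuts_step(logp_grad, theta, logp, grad, eps, inv_mass, rng, max_treedepth):
    p0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * float(p0 * inv_mass @ p0)
    tree = _Tree(logp_grad, inv_mass, eps, h0, rng)

    theta_m = theta_p = theta
    p_m = p_p = p0
    grad_m = grad_p = grad
    prop, logp_prop = theta, logp
    log_w = 0.0
    depth = 0
    for depth in range(1, max_treedepth + 1):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == -1:
            (theta_m, p_m, grad_m, _, _, _, prop2, logp2, lw2, stop) = tree.build(
                theta_m, p_m, grad_m, depth - 1, -1
            )
        else:
            (_, _, _, theta_p, p_p, grad_p, prop2, logp2, lw2, stop) = tree.build(
                theta_p, p_p, grad_p, depth - 1, 1
            )
        if stop:
            break
        # biased progressive sampling: favour the fresh subtree
        if math.log(rng.uniform()) < lw2 - log_w:
            prop, logp_prop = prop2, logp2
        log_w = np.logaddexp(log_w, lw2)
        if tree._uturn(theta_m, p_m, theta_p, p_p):
            break

    accept_stat = tree.sum_accept / max(tree.n_leaves, 1)
    if not np.array_equal(prop, theta):
        _, grad_prop = logp_grad(prop)
    else:
        grad_prop = grad
    return prop, logp_prop, grad_prop, accept_stat, tree.diverging, depth, h0


def _warmup_schedule(tune: int) -> tuple[int, int, list[int]]:
    """(initial stepsize buffer, terminal buffer, metric window ends)."""
    if tune <= 20:
        return tune, 0, []
    init = min(75, int(0.15 * tune))
    term = min(50, int(0.10 * tune))
    windows: list[int] = []
    size = 25
    pos = init
    while pos + size < tune - term:
        # last window absorbs the remainder
        if pos + 2 * size >= tune - term:
            size = (tune - term) - pos
        windows.append(pos + size)
        pos += size
        size *= 2
    if not windows and tune - term > init:
        windows.append(tune - term)
    return init, term, windows


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    initial_points: list[np.ndarray],
    *,
    tune: int = 1000,
    draws: int = 1000,
    seed: int | None = None,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain per initial point and return stacked draws."""
    chains = len(initial_points)
    dim = initial_points[0].size
    seeds = np.random.SeedSequence(seed).spawn(chains)

    all_draws = np.empty((chains, draws, dim))
    diverging = np.zeros((chains, draws), dtype=bool)
    tree_depth = np.zeros((chains, draws), dtype=np.int8)
    accept = np.zeros((chains, draws))
    energy = np.zeros((chains, draws))
    step_sizes = np.zeros(chains)
    inv_masses = np.zeros((chains, dim))

    init_buf, term_buf, windows = _warmup_schedule(tune)

    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        theta = np.array(initial_points[c], dtype=float)
        logp, grad = logp_grad(theta)
        if not np.isfinite(logp):
            raise ValueError(f"initial point of chain {c} has non-finite log density")
        inv_mass = np.ones(dim)
        eps = _find_reasonable_epsilon(logp_grad, theta, inv_mass, rng)
        da = _DualAveraging(eps, target_accept)
        welford = _Welford(dim)
        window_iter = iter(windows)
        next_window = next(window_iter, None)

        for i in range(tune):
            theta, logp, grad, a, div, depth, h = _nuts_step(
                logp_grad, theta, logp, grad, eps, inv_mass, rng, max_treedepth
            )
            eps = da.update(a)
            in_metric_phase = init_buf <= i < tune - term_buf and next_window is not None
            if in_metric_phase:
                welford.update(theta)
                if i + 1 == next_window:
                    inv_mass = welford.variance()
                    welford = _Welford(dim)
                    next_window = next(window_iter, None)
                    # re-tune the step size for the new metric
                    eps = _find_reasonable_epsilon(logp_grad, theta, inv_mass, rng)
                    da = _DualAveraging(eps, target_accept)
        eps = da.adapted if da.count > 0 else eps

        for i in range(draws):
            theta, logp, grad, a, div, depth, h = _nuts_step(
                logp_grad, theta, logp, grad, eps, inv_mass, rng, max_treedepth
            )
            all_draws[c, i] = theta
            diverging[c, i] = div
            tree_depth[c, i] = depth
            accept[c, i] = a
            energy[c, i] = h
        step_sizes[c] = eps
        inv_masses[c] = inv_mass

    return NutsResult(
        draws=all_draws,
        diverging=diverging,
        tree_depth=tree_depth,
        accept_stat=accept,
        energy=energy,
        step_size=step_sizes,
        inv_mass=inv_masses,
    )
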