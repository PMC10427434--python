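"""No-U-Turn sampling on an unconstrained parameter vector.

A compact NUTS implementation (slice variant of Hoffman & Gelman 2014)
sufficient for the multilevel logistic posteriors in this package:
analytic gradients supplied by the caller, dual-averaging step-size
adaptation towards a target acceptance statistic, and one diagonal
mass-matrix update estimated mid-warmup.  Deterministic given the numpy
Generator.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

# energy error beyond which a trajectory is cut and counted as divergent
DELTA_MAX = 1000.0


class _DualAveraging:
    """Nesterov dual averaging of the log step size."""

    def __init__(self, step0: float, target: float,
                 gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.t = 0
        self.h_bar = 0.0
        self.log_step_bar = np.log(step0)
        self.log_step = np.log(step0)

    def update(self, accept_stat: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_step = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        eta = self.t ** (-self.kappa)
        self.log_step_bar = eta * self.log_step + (1 - eta) * self.log_step_bar
        return float(np.exp(self.log_step))

    @property
    def adapted_step(self) -> float:
        return float(np.exp(self.log_step_bar))


class _Nuts:
    """One NUTS transition; holds the state shared by the tree recursion."""

    def __init__(self, logp_grad, step, inv_mass, rng):
        self.logp_grad = logp_grad
        self.step = step
        self.inv_mass = inv_mass
        self.rng = rng
        self.divergent = False
        self.accept_sum = 0.0
        self.accept_n = 0

    def _leapfrog(self, theta, r, grad, direction):
        eps = direction * self.step
        r = r + 0.5 * eps * grad
        theta = theta + eps * self.inv_mass * r
        logp, grad = self.logp_grad(theta)
        r = r + 0.5 * eps * grad
        return theta, r, grad, logp

    def _joint(self, logp, r):
        return logp - 0.5 * float(np.sum(self.inv_mass * r * r))

    def _build(self, theta, r, grad, log_u, direction, depth, joint0):
        if depth == 0:
            theta1, r1, grad1, logp1 = self._leapfrog(theta, r, grad, direction)
            joint = self._joint(logp1, r1) if np.isfinite(logp1) else -np.inf
            n_keep = int(log_u <= joint)
            keep_going = log_u < joint + DELTA_MAX
            if not keep_going:
                self.divergent = True
            self.accept_sum += min(1.0, np.exp(min(joint - joint0, 0.0)))
            self.accept_n += 1
            return (theta1, r1, grad1, theta1, r1, grad1, theta1,
                    n_keep, keep_going)
        (t_m, r_m, g_m, t_p, r_p, g_p, t_prop, n_keep, keep_going) = self._build(
            theta, r, grad, log_u, direction, depth - 1, joint0)
        if keep_going:
            if direction == -1:
                (t_m, r_m, g_m, _, _, _, t_prop2, n2, kg2) = self._build(
                    t_m, r_m, g_m, log_u, direction, depth - 1, joint0)
            else:
                (_, _, _, t_p, r_p, g_p, t_prop2, n2, kg2) = self._build(
                    t_p, r_p, g_p, log_u, direction, depth - 1, joint0)
            if n2 > 0 and self.rng.uniform() < n2 / max(n_keep + n2, 1):
                t_prop = t_prop2
            n_keep += n2
            span = t_p - t_m
            keep_going = (kg2
                          and np.dot(span, self.inv_mass * r_m) >= 0
                          and np.dot(span, self.inv_mass * r_p) >= 0)
        return t_m, r_m, g_m, t_p, r_p, g_p, t_prop, n_keep, keep_going

    def transition(self, theta, logp, grad, max_depth):
        r0 = self.rng.standard_normal(theta.size) / np.sqrt(self.inv_mass)
        joint0 = self._joint(logp, r0)
        log_u = joint0 + np.log(self.rng.uniform())
        t_m = t_p = theta
        r_m = r_p = r0
        g_m = g_p = grad
        proposal, n_keep = theta, 1
        for depth in range(max_depth):
            direction = -1 if self.rng.uniform() < 0.5 else 1
            if direction == -1:
                (t_m, r_m, g_m, _, _, _, t_prop, n2, keep_going) = self._build(
                    t_m, r_m, g_m, log_u, direction, depth, joint0)
            else:
                (_, _, _, t_p, r_p, g_p, t_prop, n2, keep_going) = self._build(
                    t_p, r_p, g_p, log_u, direction, depth, joint0)
            if keep_going and n2 > 0 and self.rng.uniform() < n2 / n_keep:
                proposal = t_prop
            n_keep += n2
            if not keep_going:
                break
            span = t_p - t_m
            if (np.dot(span, self.inv_mass * r_m) < 0
                    or np.dot(span, self.inv_mass * r_p) < 0):
                break
        return proposal


def sample_chain(logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
                 theta0: np.ndarray, *, warmup: int, samples: int,
                 rng: np.random.Generator, target_accept: float = 0.9,
                 max_depth: int = 9, init_step: float = 0.1,
                 ) -> tuple[np.ndarray, dict]:
    """Run one NUTS chain; returns (draws with shape (samples, dim), stats)."""
    dim = theta0.size
    theta = theta0.astype(float).copy()
    inv_mass = np.ones(dim)
    # iterations [w1, w2) of warmup feed the diagonal mass estimate
    w1, w2 = max(1, warmup // 4), max(2, (3 * warmup) // 4)
    window: list[np.ndarray] = []

    da = _DualAveraging(init_step, target_accept)
    step = init_step
    divergences = 0
    accept_stats = []
    draws = np.empty((samples, dim))

    logp, grad = logp_grad(theta)
    for it in range(warmup + samples):
        sampling = it >= warmup
        nuts = _Nuts(logp_grad, step, inv_mass, rng)
        theta_new = nuts.transition(theta, logp, grad, max_depth)
        if theta_new is not theta:
            theta = theta_new
            logp, grad = logp_grad(theta)
        accept_stat = (nuts.accept_sum / nuts.accept_n) if nuts.accept_n else 0.0
        if sampling:
            if nuts.divergent:
                divergences += 1
            accept_stats.append(accept_stat)
            draws[it - warmup] = theta
        else:
            step = da.update(accept_stat)
            if w1 <= it < w2:
                window.append(theta.copy())
            if it == w2 - 1 and len(window) >= 10:
                arr = np.asarray(window)
                var = arr.var(axis=0)
                n = arr.shape[0]
                # regularize towards unit scale (Stan-style shrinkage)
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                inv_mass = np.clip(inv_mass, 1e-8, None)
                da = _DualAveraging(max(da.adapted_step, 1e-4), target_accept)
                step = float(np.exp(da.log_step))
            if it == warmup - 1:
                step = da.adapted_step

    stats = {
        "step_size": float(step),
        "accept_rate": float(np.mean(accept_stats)) if accept_stats else np.nan,
        "divergences": int(divergences),
    }
    return draws, stats
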