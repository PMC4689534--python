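"""Motivational state, average reward, and the cue-evoked TD error.

The actor chooses its press latency stochastically via a softmax over
relative action values, P(tau) proportional to exp(beta * Q(1, tau)) with
Q(1, tau) = a/tau + b + r - rho * (tau + tau_post + tau_I) + const.
Because rho itself depends on the policy, policy and average reward are
solved jointly by damped fixed-point iteration.  Sweeping the reward
utility r (a proxy for motivational state) shows that the average utility
rate rho and the trial-start TD transient rise together while mean latency
falls — a correlation between "phasic" and "tonic" signals that requires
no mechanistic coupling between them.

The trial-start transient delta_cue is the expected value step from the
preparedness state into the new trial, rho * (tau_I + tau_post); with a
zero inter-trial interval the trial-start cue coincides with press
completion and this is the entire mean transient at that event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actor_critic_smdp import TaskSpec

__all__ = [
    "SoftmaxPolicy",
    "MotivationSweep",
    "softmax_policy",
    "solve_policy_rho_fixed_point",
    "sweep_reward_utility",
]


@dataclass(frozen=True)
class SoftmaxPolicy:
    """Probabilities over a latency grid, P(tau) proportional to exp(beta*q)."""

    beta: float
    tau_grid: np.ndarray = field(repr=False)
    probs: np.ndarray = field(repr=False)

    @property
    def mean_latency(self) -> float:
        return float(np.dot(self.probs, self.tau_grid))


def softmax_policy(q: np.ndarray, tau_grid: np.ndarray, beta: float) -> SoftmaxPolicy:
    """Max-shifted softmax over latencies; beta=0 gives the uniform policy."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("q must be finite")
    x = beta * q
    x = x - x.max()
    w = np.exp(x)
    return SoftmaxPolicy(beta=beta, tau_grid=np.asarray(tau_grid, float), probs=w / w.sum())


def _q_values(spec: TaskSpec, tau_grid: np.ndarray, rho: float) -> np.ndarray:
    """Relative action values up to a tau-independent constant."""
    return (
        spec.a / tau_grid + spec.b + spec.r
        - rho * (tau_grid + spec.tau_post + spec.tau_I)
    )


def _policy_rho(spec: TaskSpec, pol: SoftmaxPolicy) -> float:
    u = spec.r + spec.a / pol.tau_grid + spec.b
    cycle = pol.tau_grid + spec.tau_post + spec.tau_I
    return float(np.dot(pol.probs, u) / np.dot(pol.probs, cycle))


def solve_policy_rho_fixed_point(
    spec: TaskSpec,
    beta: float,
    tau_grid: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    rho0: float = 0.0,
    damping: float = 0.5,
) -> tuple[float, SoftmaxPolicy]:
    """Jointly solve the softmax latency policy and its average utility rate.

    Alternates (i) Q from the current rho, (ii) policy from Q, (iii) rho
    from the renewal-reward ratio under the policy, with damped rho updates,
    until |delta rho| < tol.
    """
    if tau_grid is None:
        tau_grid = np.geomspace(0.1, 20.0, 200)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if np.any(tau_grid <= 0):
        raise ValueError("tau_grid must be positive")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    rho = rho0
    history = []
    for _ in range(max_iter):
        pol = softmax_policy(_q_values(spec, tau_grid, rho), tau_grid, beta)
        rho_new = _policy_rho(spec, pol)
        history.append(rho_new)
        step = rho_new - rho
        rho = rho + damping * step
        if abs(step) < tol:
            return rho, pol
    raise RuntimeError(
        f"policy/rho fixed point did not converge in {max_iter} iterations; "
        f"last iterates {history[-5:]}"
    )


@dataclass(frozen=True)
class MotivationSweep:
    """Per-reward-utility records of (rho, delta_cue, mean_latency)."""

    r_values: np.ndarray
    rho: np.ndarray
    delta_cue: np.ndarray
    mean_latency: np.ndarray

    def corr(self, x: str, y: str) -> float | None:
        if self.r_values.size < 2:
            return None
        return float(np.corrcoef(getattr(self, x), getattr(self, y))[0, 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.r_values,
                "rho": self.rho,
                "delta_cue": self.delta_cue,
                "mean_latency": self.mean_latency,
            }
        )


def sweep_reward_utility(
    spec: TaskSpec,
    beta: float,
    r_values: np.ndarray,
    tau_grid: np.ndarray | None = None,
    tol: float = 1e-10,
) -> MotivationSweep:
    """Solve the fixed point for each reward utility and record the trio
    (rho, trial-start TD transient, mean latency)."""
    r_values = np.asarray(r_values, dtype=float)
    if r_values.size == 0:
        raise ValueError("r_values must be non-empty")
    from dataclasses import replace

    rhos, deltas, lats = [], [], []
    for r in r_values:
        s = replace(spec, r=float(r))
        rho, pol = solve_policy_rho_fixed_point(s, beta, tau_grid, tol=tol)
        rhos.append(rho)
        deltas.append(rho * (s.tau_I + s.tau_post))
        lats.append(pol.mean_latency)
    return MotivationSweep(
        r_values=r_values,
        rho=np.array(rhos),
        delta_cue=np.array(deltas),
        mean_latency=np.array(lats),
    )
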