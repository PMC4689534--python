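"""Discounted vigour and the quasi-tonic ramp toward goals.

Under exponential discounting the role that the average reward rate rho
plays in the average-reward account — the opportunity cost of time, and
the putative tonic dopamine level — is taken by the quantity
(1 - gamma) * V^gamma(s_{t+1}).  Because the discounted value function
rises as a goal is approached, this signal *ramps*, peaking at
(1 - gamma) * r at the goal regardless of how long or far the approach
was, scaling linearly with reward size, and tracking goal proximity
(flat when progress stalls, falling when the agent retreats).

Latency choice: a press of latency tau earns Q^gamma(tau) = a/tau +
gamma^tau * v_next (hyperbolic cost of acting quickly against the decay
of the future's worth).  An interior optimal latency tau* exists only
while the cost factor is above the analytic bound a_min = 4/(e^2 ln
gamma); continuing tasks (a fresh trial after an inter-trial interval
tau_I) hasten pressing only when tau_I is short relative to the
discounting horizon -1/ln(gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .signal_kernels import DRFKernel, TimeSeries, convolve_drf

__all__ = [
    "VigourProblem",
    "Trajectory",
    "RampResult",
    "q_gamma",
    "optimal_latency",
    "a_min",
    "delta_tau_star",
    "quasi_tonic_trace",
    "approach_trajectory",
    "discounted_values_markov",
]


@dataclass(frozen=True)
class VigourProblem:
    """A discounted latency-choice problem.

    a : hyperbolic cost factor (utility*s, <= 0); gamma : per-second
    discount in (0, 1); r : reward utility; chain : 'terminating' (the
    post-press value is fixed at 1, reward folded in) or 'continuing'
    (reward r at press completion, then an inter-trial interval tau_I
    before the next opportunity).
    """

    a: float = -1.0
    gamma: float = 0.98
    r: float = 1.0
    chain: str = "terminating"
    tau_I: float = 30.0

    def __post_init__(self):
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.a > 0:
            raise ValueError("cost factor a must be <= 0")
        if self.chain not in ("terminating", "continuing"):
            raise ValueError(f"unknown chain type {self.chain!r}")
        if self.tau_I < 0:
            raise ValueError("tau_I must be >= 0")


def q_gamma(p: VigourProblem, tau, v_next: float = 1.0):
    """Latency value a/tau + gamma^tau * v_next (terminating convention:
    the immediate reward is folded into v_next = 1)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0")
    out = p.a / tau + p.gamma**tau * v_next
    return out if out.ndim else float(out)


def a_min(gamma: float) -> float:
    """Cost bound 4 / (e^2 ln gamma) below which no optimal latency exists."""
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    return 4.0 / (np.e**2 * np.log(gamma))


def _tau_star_terminating(a: float, gamma: float, v_next: float = 1.0) -> float | None:
    """Interior maximiser of a/tau + gamma^tau * v_next, or None.

    The stationarity condition |a| = v_next * tau^2 gamma^tau |ln gamma|
    has roots iff |a| <= max_tau RHS; the smaller root is the local
    maximum.  Found by golden-section search over a log-spaced bracket,
    refined to 1e-4 s (ties broken toward the smaller tau by searching
    the left stationary branch).
    """
    if a == 0.0:
        return None  # value strictly decreasing in tau: no interior maximum
    lng = abs(np.log(gamma))
    tau_hat = 2.0 / lng  # peak of tau^2 gamma^tau
    g_max = v_next * tau_hat**2 * gamma**tau_hat * lng
    if abs(a) > g_max:
        return None
    f = lambda t: -(a / t + gamma**t * v_next)
    res = optimize.minimize_scalar(
        f, bounds=(1e-6, tau_hat), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def optimal_latency(p: VigourProblem, tol: float = 1e-10) -> float | None:
    """Optimal latency tau*, or None when no interior maximum exists.

    Continuing chains solve the value fixed point V = max_tau [a/tau +
    gamma^tau (r + gamma^{tau_I} V)] by damped iteration before reading
    off the maximiser.
    """
    if p.chain == "terminating":
        return _tau_star_terminating(p.a, p.gamma, v_next=1.0)
    V = 0.0
    for _ in range(100_000):
        tau = _tau_star_terminating(p.a, p.gamma, v_next=p.r + p.gamma**p.tau_I * V)
        if tau is None:
            return None
        V_new = p.a / tau + p.gamma**tau * (p.r + p.gamma**p.tau_I * V)
        if abs(V_new - V) < tol:
            return tau
        V = 0.5 * V + 0.5 * V_new
    raise RuntimeError("continuing-chain value iteration did not converge")


def continuing_value(p: VigourProblem, tol: float = 1e-12) -> float:
    """Fixed point V = max_tau [a/tau + gamma^tau (r + gamma^{tau_I} V)]."""
    if p.chain != "continuing":
        raise ValueError("continuing chain required")
    V = 0.0
    for _ in range(200_000):
        tau = _tau_star_terminating(p.a, p.gamma, v_next=p.r + p.gamma**p.tau_I * V)
        if tau is None:
            raise ValueError("no optimal latency for the continuing problem")
        V_new = p.a / tau + p.gamma**tau * (p.r + p.gamma**p.tau_I * V)
        if abs(V_new - V) < tol:
            return V_new
        V = 0.5 * V + 0.5 * V_new
    raise RuntimeError("value iteration did not converge")


def delta_tau_star(a: float, gamma: float, tau_I: float) -> float | None:
    """tau*(continuing) - tau*(terminating), or None if either is unsolvable.

    The continuing problem prices the reward r = 1 at press completion and
    discounts the inter-trial interval to the next opportunity; when tau_I
    is long relative to -1/ln(gamma) the future is worthless and the
    difference vanishes.
    """
    t_term = _tau_star_terminating(a, gamma, v_next=1.0)
    if t_term is None:
        return None
    p = VigourProblem(a=a, gamma=gamma, r=1.0, chain="continuing", tau_I=tau_I)
    try:
        t_cont = optimal_latency(p)
    except RuntimeError:
        return None
    if t_cont is None:
        return None
    return t_cont - t_term


# ---------------------------------------------------------------------------
# quasi-tonic ramps over goal-approach trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Goal proximity over time: remaining time-to-goal (s) per sample, 0 at goal."""

    times: np.ndarray = field(repr=False)
    proximity: np.ndarray = field(repr=False)
    r: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "proximity", np.asarray(self.proximity, dtype=float))
        if self.times.shape != self.proximity.shape:
            raise ValueError("times and proximity must have equal shape")
        if np.any(self.proximity < 0):
            raise ValueError("proximity must be >= 0")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0


@dataclass(frozen=True)
class RampResult:
    """Quasi-tonic signal, its DRF convolution, and the undiscounted error."""

    quasi_tonic: TimeSeries
    da: TimeSeries
    delta_A: TimeSeries

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.quasi_tonic.times,
                "quasi_tonic": self.quasi_tonic.values,
                "delta_A": self.delta_A.values,
                "da": self.da.values,
            }
        )


def quasi_tonic_trace(
    traj: Trajectory, gamma: float, kernel: DRFKernel | None = None
) -> RampResult:
    """Quasi-tonic signal (1-gamma) V^gamma(s_{t+1}) along a trajectory.

    Values are V^gamma(s) = gamma^proximity * r (discounted worth of the
    goal reward); after the first goal visit the episode has terminated
    and values are 0, with the reward r delivered on the goal-entry step.
    delta_A is the undiscounted error r(s_t) + V(s_{t+1}) - V(s_t), whose
    per-step average the quasi-tonic signal targets.  ``da`` convolves the
    quasi-tonic signal with the DRF (a smoothed, delayed copy); with no
    kernel it equals the raw signal.
    """
    prox = traj.proximity
    n = prox.size
    V = gamma**prox * traj.r
    at_goal = prox == 0.0
    goal_idx = int(np.argmax(at_goal)) if np.any(at_goal) else None
    reward = np.zeros(n)
    if goal_idx is not None:
        V[goal_idx + 1:] = 0.0          # terminated after the goal
        reward[goal_idx] = traj.r
        V[goal_idx] = traj.r            # prox 0 => gamma^0 * r
    V_next = np.append(V[1:], 0.0 if goal_idx is not None else V[-1])
    quasi = (1.0 - gamma) * V_next
    delta_A = reward + V_next - V
    dt = traj.dt
    t0 = float(traj.times[0])
    qt = TimeSeries(t0, dt, quasi)
    if kernel is not None:
        # unit-area (unit DC gain) normalisation: the concentration trace is
        # a smoothed, delayed copy of the quasi-tonic signal on its own scale
        da_raw = convolve_drf(qt, kernel)
        area = float(np.sum(kernel.values) * kernel.dt)
        da = TimeSeries(t0, dt, da_raw.values / area)
    else:
        da = qt
    return RampResult(quasi_tonic=qt, da=da, delta_A=TimeSeries(t0, dt, delta_A))


def approach_trajectory(
    duration: float,
    dt: float = 1.0,
    r: float = 1.0,
    pause: tuple[float, float] | None = None,
    retreat: tuple[float, float, float] | None = None,
) -> Trajectory:
    """Synthesise a goal-approach proximity profile (time as proxy for distance).

    The agent starts ``duration`` seconds from the goal and closes in at
    unit rate.  ``pause=(t_start, t_len)`` holds proximity constant for
    t_len seconds; ``retreat=(t_start, t_len, rate)`` makes proximity
    *increase* for t_len seconds (moving away), emulating non-monotonic
    runs.  The trajectory ends one step after the goal is reached.
    """
    prox = [duration]
    t = [0.0]
    while prox[-1] > 0:
        now = t[-1]
        p = prox[-1]
        if pause is not None and pause[0] <= now < pause[0] + pause[1]:
            step = 0.0
        elif retreat is not None and retreat[0] <= now < retreat[0] + retreat[1]:
            step = -retreat[2] * dt
        else:
            step = dt
        prox.append(max(p - step, 0.0))
        t.append(now + dt)
        if len(t) > 1_000_000:
            raise RuntimeError("trajectory failed to reach the goal")
    prox.append(0.0)  # one post-goal sample so the goal step is visible
    t.append(t[-1] + dt)
    return Trajectory(times=np.array(t), proximity=np.array(prox), r=r)


def discounted_values_markov(P: np.ndarray, rewards: np.ndarray, gamma: float) -> np.ndarray:
    """Exact discounted state values V = (I - gamma P)^{-1} (P r) for a chain
    with rewards on state entry (r received on arriving in a state)."""
    P = np.asarray(P, float)
    rewards = np.asarray(rewards, float)
    n = P.shape[0]
    # expected immediate reward = reward of the successor state
    r_exp = P @ rewards
    return np.linalg.solve(np.eye(n) - gamma * P, r_exp)
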