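"""Drift-diffusion decision process gated by a dopamine gain signal.

Evidence x(t) accumulates as dx = g(t) [A dt + c dW] until |x| reaches a
symmetric threshold z.  The gain g(t) is the modelled dopamine
concentration: an Ornstein-Uhlenbeck process fluctuating around a tonic
mean theta (dg = kappa (theta - g) dt + sigma dW), optionally boosted by a
phasic transient of random magnitude h ~ N(mu_TD, sigma_TD^2) converted to
concentration by the alpha-function DRF.  Averaging the gain aligned to
threshold crossing produces a ramp (crossings preferentially happen when,
and shortly after, the gain is high); with phasic events, larger h means
earlier crossing, giving a negative h-latency correlation.

Conventions (configuration-exposed): the gain is floored at 1e-6 (a
negative gain would invert the evidence); phasic events default to trial
start; trials are censored at 60 s and excluded from aligned averages and
correlations, with the count reported; the crossing time is refined by
linear interpolation of the final step.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import signal as sp_signal

from .signal_kernels import TimeSeries, AlignedAverage, aligned_average, alpha_function

logger = logging.getLogger(__name__)

__all__ = [
    "OUParams",
    "DDMParams",
    "PhasicEventSpec",
    "DecisionTrial",
    "GAIN_FLOOR",
    "simulate_ou",
    "simulate_trial",
    "run_ensemble",
]

GAIN_FLOOR = 1e-6


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck tonic gain: mean theta, reversion kappa, noise sigma."""

    theta: float = 1.0
    kappa: float = 0.01
    sigma: float = 0.1
    dt: float = 0.01

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.kappa < 0 or self.sigma < 0:
            raise ValueError("kappa and sigma must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class DDMParams:
    """Drift A (= Q1 - Q2), diffusion c, symmetric threshold z > 0."""

    A: float = 1.0
    c: float = 1.0
    z: float = 5.0

    def __post_init__(self):
        if self.z <= 0:
            raise ValueError("z must be > 0")
        if self.c < 0:
            raise ValueError("c must be >= 0")


@dataclass(frozen=True)
class PhasicEventSpec:
    """A phasic TD transient added to the gain: h ~ N(mu_TD, sigma_TD^2).

    The event contributes h * f(t - time) to g(t), with f the alpha-function
    DRF of time constant xi.  Defaults put the event at trial start.
    """

    mu_TD: float = 4.0
    sigma_TD: float = 1.0  # standard deviation (variance sigma_TD^2)
    time: float = 0.0
    xi: float = 0.7


@dataclass(frozen=True)
class DecisionTrial:
    """Paired decision-variable and gain paths with the crossing outcome."""

    x_path: TimeSeries
    g_path: TimeSeries
    crossing_time: float | None
    sign: int
    h: float | None


def _ou_path(p: OUParams, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Euler-Maruyama OU path of n_steps+1 samples, g(0) = theta.

    The update g_{i+1} = g_i + kappa (theta - g_i) dt + sigma sqrt(dt) xi_i
    is an AR(1) recursion, evaluated with a linear filter.
    """
    if p.sigma == 0.0 and p.kappa >= 0.0:
        return np.full(n_steps + 1, p.theta)
    noise = p.sigma * np.sqrt(p.dt) * rng.standard_normal(n_steps)
    phi = 1.0 - p.kappa * p.dt
    # deviations from theta follow d_{i+1} = phi * d_i + noise_i, d_0 = 0
    dev = sp_signal.lfilter([1.0], [1.0, -phi], noise)
    return p.theta + np.concatenate([[0.0], dev])


def simulate_ou(p: OUParams, duration: float, seed) -> TimeSeries:
    """Simulate the tonic gain for ``duration`` seconds (Euler-Maruyama)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration / p.dt))
    return TimeSeries(0.0, p.dt, _ou_path(p, n, rng))


def simulate_trial(
    ou: OUParams,
    ddm: DDMParams,
    phasic: PhasicEventSpec | None = None,
    seed=0,
    max_duration: float = 60.0,
    h: float | None = None,
) -> DecisionTrial:
    """Integrate one decision trial until threshold crossing or censoring.

    Per step: x += g_t (A dt + c sqrt(dt) N(0,1)), with g the (floored)
    OU gain plus any phasic transient.  The crossing time is linearly
    interpolated within the crossing step; if |x| never reaches z before
    ``max_duration`` the trial is censored (crossing_time None, sign 0).
    ``h`` overrides the random phasic magnitude (used by ensembles).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = ou.dt
    n_max = int(round(max_duration / dt))

    if phasic is not None and h is None:
        h = float(rng.normal(phasic.mu_TD, phasic.sigma_TD))

    g_all = np.empty(n_max + 1)
    x_all = np.empty(n_max + 1)
    x_all[0] = 0.0
    g_prev_raw = ou.theta
    crossing_time, sign, filled = None, 0, 0

    chunk = 2000
    phi = 1.0 - ou.kappa * dt
    i0 = 0
    while i0 < n_max and crossing_time is None:
        m = min(chunk, n_max - i0)
        if ou.sigma > 0.0:
            g_noise = ou.sigma * np.sqrt(dt) * rng.standard_normal(m)
            dev = sp_signal.lfilter(
                [1.0], [1.0, -phi], g_noise, zi=[phi * (g_prev_raw - ou.theta)]
            )[0]
            g_raw = ou.theta + dev
        else:
            g_raw = np.full(m, g_prev_raw + 0.0) if ou.kappa == 0 else (
                ou.theta + (g_prev_raw - ou.theta) * phi ** np.arange(1, m + 1)
            )
        g_prev_raw = g_raw[-1]
        g = g_raw.copy()
        if phasic is not None:
            t_chunk = (i0 + np.arange(m)) * dt
            g = g + h * alpha_function(t_chunk - phasic.time, xi=phasic.xi)
        low = g < GAIN_FLOOR
        if np.any(low):
            logger.warning("gain floored at %g for %d samples", GAIN_FLOOR, low.sum())
            g = np.maximum(g, GAIN_FLOOR)
        dx = g * (ddm.A * dt + (ddm.c * np.sqrt(dt)) * rng.standard_normal(m))
        x = x_all[i0] + np.cumsum(dx)
        g_all[i0 + 1: i0 + 1 + m] = g
        x_all[i0 + 1: i0 + 1 + m] = x
        filled = i0 + m
        hit = np.flatnonzero(np.abs(x) >= ddm.z)
        if hit.size:
            j = i0 + 1 + hit[0]          # first sample at/over threshold
            x_prev, x_here = x_all[j - 1], x_all[j]
            sign = 1 if x_here > 0 else -1
            frac = (ddm.z * sign - x_prev) / (x_here - x_prev)
            crossing_time = (j - 1 + float(np.clip(frac, 0.0, 1.0))) * dt
            x_all[j] = ddm.z * sign
            filled = j
        i0 += m

    if crossing_time is None:
        logger.warning("trial censored at %g s without crossing", max_duration)

    g_all[0] = ou.theta + (
        h * alpha_function(-phasic.time, xi=phasic.xi) if phasic is not None else 0.0
    )
    return DecisionTrial(
        x_path=TimeSeries(0.0, dt, x_all[: filled + 1]),
        g_path=TimeSeries(0.0, dt, np.maximum(g_all[: filled + 1], GAIN_FLOOR)),
        crossing_time=crossing_time,
        sign=sign,
        h=h,
    )


def run_ensemble(
    ou: OUParams,
    ddm: DDMParams,
    phasic: PhasicEventSpec | None = None,
    n: int = 1000,
    seed: int = 0,
    max_duration: float = 60.0,
    align_window: tuple[float, float] = (4.0, 0.5),
) -> dict:
    """Simulate n trials; return crossing-aligned gain average and statistics.

    Returns a dict with ``aligned`` (AlignedAverage of g around crossing),
    ``latencies``, ``h_values``, ``signs`` (crossed trials only), ``corr``
    (Pearson r between h and latency; None without phasic events or with
    fewer than 2 crossings) and ``n_censored``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    latencies, h_values, signs, g_paths = [], [], [], []
    n_censored = 0
    for i in range(n):
        trial = simulate_trial(
            ou, ddm, phasic, seed=np.random.default_rng(children[i]),
            max_duration=max_duration,
        )
        if trial.crossing_time is None:
            n_censored += 1
            continue
        latencies.append(trial.crossing_time)
        signs.append(trial.sign)
        h_values.append(trial.h)
        g_paths.append(trial.g_path)

    latencies = np.array(latencies)
    signs = np.array(signs, dtype=int)

    aligned = None
    if latencies.size:
        # pad each gain path so the aligned window is always covered
        pre, post = align_window
        padded = []
        for g, lat in zip(g_paths, latencies):
            v = g.values
            need_pre = int(np.ceil(max(0.0, pre - lat) / g.dt)) + 1
            need_post = int(np.ceil(post / g.dt)) + 1
            v = np.concatenate([np.full(need_pre, v[0]), v, np.full(need_post, v[-1])])
            padded.append(TimeSeries(g.t0 - need_pre * g.dt, g.dt, v))
        aligned = aligned_average(padded, list(latencies), align_window)

    corr = None
    if phasic is not None and latencies.size >= 2:
        h_arr = np.array(h_values, dtype=float)
        if np.std(h_arr) > 0 and np.std(latencies) > 0:
            corr = float(np.corrcoef(h_arr, latencies)[0, 1])

    return {
        "aligned": aligned,
        "latencies": latencies,
        "h_values": np.array(h_values, dtype=float) if phasic is not None else None,
        "signs": signs,
        "corr": corr,
        "n_censored": n_censored,
    }


def ddm_mean_decision_time(ddm: DDMParams) -> float:
    """Closed-form mean decision time (z/A) tanh(zA/c^2) of the constant-gain DDM."""
    return (ddm.z / ddm.A) * np.tanh(ddm.z * ddm.A / ddm.c**2)


def ddm_error_rate(ddm: DDMParams) -> float:
    """Closed-form error rate 1/(1 + exp(2 z A / c^2)) at an unbiased start."""
    return 1.0 / (1.0 + np.exp(2.0 * ddm.z * ddm.A / ddm.c**2))
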