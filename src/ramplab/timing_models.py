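"""Distributions over the efference-copy time T.

The critic's expectations about *when* it will be told an action is imminent
are summarised by a distribution over the notification time T: a gamma prior
G(k, theta) when only indirect information is available, or a Gaussian
centred on the chosen latency tau with scalar timing noise (sd = k * tau)
when the actor's choice is communicated directly.  The hazard function of
this distribution shapes the prediction errors generated while waiting.

The Gaussian conditional is truncated to T > 0 and renormalised so that
survival/hazard machinery is well posed (times cannot be negative).
Hazard evaluation is capped where survival underflows (< 1e-12); such points
return NaN as a declared-undefined sentinel and callers must cap their grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GammaTiming",
    "ConditionalTiming",
    "DeterministicTiming",
    "SURVIVAL_FLOOR",
    "hazard",
    "transition_prob",
    "sample_T",
]

SURVIVAL_FLOOR = 1e-12


@dataclass(frozen=True)
class GammaTiming:
    """Gamma-distributed notification time T ~ G(k, theta)."""

    k: float
    theta: float

    def __post_init__(self):
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("shape k and scale theta must be > 0")

    @property
    def mean(self) -> float:
        return self.k * self.theta

    def _frozen(self):
        return stats.gamma(a=self.k, scale=self.theta)

    def pdf(self, t):
        return self._frozen().pdf(t)

    def survival(self, t):
        return self._frozen().sf(t)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(shape=self.k, scale=self.theta, size=n)


@dataclass(frozen=True)
class ConditionalTiming:
    """T | tau ~ N(tau, (k_scalar*tau)^2), truncated to T > 0.

    Scalar timing noise: the sd grows linearly with the chosen latency, so
    longer choices leave the critic more uncertain about when the efference
    copy will arrive.
    """

    tau: float
    k_scalar: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.k_scalar <= 0:
            raise ValueError("k_scalar must be > 0")

    @property
    def sd(self) -> float:
        return self.k_scalar * self.tau

    @property
    def mean(self) -> float:
        return float(self._frozen().mean())

    def _frozen(self):
        a = (0.0 - self.tau) / self.sd
        return stats.truncnorm(a=a, b=np.inf, loc=self.tau, scale=self.sd)

    def pdf(self, t):
        return self._frozen().pdf(t)

    def survival(self, t):
        return self._frozen().sf(t)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)


@dataclass(frozen=True)
class DeterministicTiming:
    """A point mass at T = tau (useful for closed-form checks)."""

    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @property
    def mean(self) -> float:
        return self.tau


def hazard(dist, t):
    """Instantaneous event rate pdf(t)/survival(t).

    NaN where survival has underflowed below ``SURVIVAL_FLOOR`` (declared
    undefined; cap the evaluation grid).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    s = dist.survival(t)
    p = dist.pdf(t)
    out = np.where(s > SURVIVAL_FLOOR, p / np.maximum(s, SURVIVAL_FLOOR), np.nan)
    return out if out.ndim else float(out)


def transition_prob(dist, t, dt):
    """P(T <= t + dt | T > t) = [S(t) - S(t+dt)] / S(t), in [0, 1]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        out = np.zeros_like(t)
        return out if out.ndim else 0.0
    s0 = dist.survival(t)
    s1 = dist.survival(t + dt)
    out = np.where(
        s0 > SURVIVAL_FLOOR,
        np.clip((s0 - s1) / np.maximum(s0, SURVIVAL_FLOOR), 0.0, 1.0),
        np.nan,
    )
    return out if out.ndim else float(out)


def sample_T(dist, n: int, seed) -> np.ndarray:
    """Draw n notification times; identical seeds give identical draws."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    if isinstance(dist, DeterministicTiming):
        return np.full(n, dist.tau)
    return np.asarray(dist.rvs(n, rng))
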