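"""Measurement model turning model activity into dopamine concentration.

Phasic dopaminergic activity is converted to a modelled extracellular
dopamine concentration by convolving it with a dopamine response function
(DRF), an alpha-function impulse response ``f(t) = (t/xi) * exp(1 - t/xi)``
that peaks at 1 a time-constant ``xi`` after the impulse.  Negative
prediction errors may first be scaled down by an asymmetry factor ``d``
(pauses in dopaminergic firing move concentration less than bursts do).
Event-aligned trial averaging produces the mean +/- SEM traces used to
summarise simulated experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "DRFKernel",
    "AsymmetryRule",
    "AlignedAverage",
    "alpha_kernel",
    "asymmetric_rectify",
    "convolve_drf",
    "aligned_average",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled signal trace.

    Parameters
    ----------
    t0 : float
        Time (s) of the first sample.
    dt : float
        Grid step (s), > 0.
    values : ndarray
        Sample values; finite, length >= 1.
    """

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a 1-d array of length >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    def __len__(self) -> int:
        return self.values.size

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation at times ``t`` (no extrapolation)."""
        return np.interp(t, self.times, self.values)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) > 1:
            dt = float(np.median(np.diff(t)))
        else:
            dt = 1.0
        return cls(t0=float(t[0]), dt=dt, values=df["value"].to_numpy())


@dataclass(frozen=True)
class DRFKernel:
    """Sampled dopamine response function on [0, support]."""

    xi: float
    dt: float
    support: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.xi <= 0 or self.dt <= 0:
            raise ValueError("xi and dt must be > 0")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("DRF kernel values must be non-negative")


def alpha_kernel(xi: float = 0.7, dt: float = 0.01, support: float | None = None) -> DRFKernel:
    """Alpha-function DRF ``f(t) = (t/xi) e^{1 - t/xi}`` sampled on [0, support].

    ``f(0) = 0`` and the peak value 1 is attained at ``t = xi``.  The default
    truncation at ``10*xi`` leaves a tail below ``e^-9`` of the peak.
    """
    if xi <= 0:
        raise ValueError(f"xi must be > 0, got {xi}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if support is None:
        support = 10.0 * xi
    if support < 5.0 * xi:
        raise ValueError(f"support must be >= 5*xi, got {support} < {5 * xi}")
    t = np.arange(0.0, support + 0.5 * dt, dt)
    values = (t / xi) * np.exp(1.0 - t / xi)
    return DRFKernel(xi=xi, dt=dt, support=support, values=values)


def alpha_function(t, xi: float = 0.7):
    """Evaluate the alpha-function DRF at arbitrary times (0 for t < 0)."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, (t / xi) * np.exp(1.0 - t / xi), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AsymmetryRule:
    """Scale negative prediction errors by ``d`` in (0, 1]; d=1 is symmetric."""

    d: float = 1.0 / 6.0

    def __post_init__(self):
        if not (0.0 < self.d <= 1.0):
            raise ValueError(f"d must be in (0, 1], got {self.d}")


def asymmetric_rectify(trace: TimeSeries, rule: AsymmetryRule) -> TimeSeries:
    """Scale negative samples by ``rule.d``, leaving non-negative ones unchanged."""
    v = trace.values
    return TimeSeries(trace.t0, trace.dt, np.where(v >= 0, v, rule.d * v))


def convolve_drf(trace: TimeSeries, kernel: DRFKernel) -> TimeSeries:
    """Causal discrete convolution of a trace with the DRF, scaled by dt.

    Scaling by dt conserves impulse *area* rather than sample height, so an
    impulse of unit area (one sample of height 1/dt) maps to the kernel
    itself regardless of grid resolution.  Output keeps the input grid; the
    causal tail beyond it is truncated.
    """
    if abs(trace.dt - kernel.dt) > 1e-12 * max(trace.dt, kernel.dt):
        raise ValueError(
            f"grid mismatch: trace.dt={trace.dt} != kernel.dt={kernel.dt}"
        )
    full = np.convolve(trace.values, kernel.values)[: len(trace)] * trace.dt
    return TimeSeries(trace.t0, trace.dt, full)


@dataclass(frozen=True)
class AlignedAverage:
    """Per-gridpoint mean and SEM of event-aligned traces (t=0 at the event)."""

    window: tuple[float, float]
    mean: TimeSeries
    sem: TimeSeries
    n: int

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.mean.times, "mean": self.mean.values, "sem": self.sem.values}
        ).to_csv(path, index=False)


def aligned_average(
    traces: list[TimeSeries],
    align_times: list[float],
    window: tuple[float, float],
) -> AlignedAverage:
    """Average traces re-indexed so t=0 falls at each trace's alignment event.

    ``window = (pre, post)`` in seconds (both >= 0; the averaged grid runs
    from -pre to +post).  Traces whose grid does not cover the shifted window
    are excluded with a logged warning.  SEM is sample SD (n-1 denominator)
    over sqrt(n); it is 0 for a single trace.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    if len(traces) != len(align_times):
        raise ValueError("traces and align_times must have equal length")
    pre, post = window
    dt = traces[0].dt
    grid = np.arange(-pre, post + 0.5 * dt, dt)
    rows = []
    for i, (tr, at) in enumerate(zip(traces, align_times)):
        lo, hi = tr.t0, tr.t0 + (len(tr) - 1) * tr.dt
        if at - pre < lo - 1e-9 or at + post > hi + 1e-9:
            logger.warning(
                "aligned_average: excluding trace %d (window [%g, %g] s around "
                "t=%g s exceeds trace span [%g, %g] s)", i, -pre, post, at, lo, hi
            )
            continue
        rows.append(tr.interp(at + grid))
    if not rows:
        raise ValueError("no trace covers the requested window")
    arr = np.vstack(rows)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return AlignedAverage(
        window=window,
        mean=TimeSeries(-pre, dt, mean),
        sem=TimeSeries(-pre, dt, sem),
        n=n,
    )
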