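"""Average-reward SMDP critic for the cued lever-press task.

A trial: cue (state 1), the actor picks a press latency; after a random
time T the critic is notified via efference copy that the press is imminent
(state 2, "preparedness"); the press completes tau_post later (state 3),
reward is delivered, and a fixed inter-trial interval tau_I separates trials.

The critic tracks elapsed time within state 1 ("microstates" {1, t}) and its
relative values satisfy a hazard-weighted backward recursion: the value of
waiting is a probability-weighted average of continuing to wait and of
transitioning to preparedness, less the opportunity cost rho*dt of the time
slice.  Prediction-error transients arise only where uncertainty is
resolved: at the (optional) direct report of the actor's choice shortly
after the cue, and at the efference copy itself.  Deterministic intervals
are, by default, tracked by the critic, so their passage produces a smooth
value drift rather than onset surprises.

The critic's valued outcome is the reward r delivered at press completion.
The hyperbolic action cost a/tau + b prices the *choice* of latency (see
:mod:`ramplab.motivation_coupling`) and enters the renewal average-reward
formula, but is not signalled as a reward event in the prediction-error
stream unless ``TaskSpec.cost_in_stream`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging

import numpy as np
from scipy import integrate, stats

from .signal_kernels import (
    AlignedAverage,
    AsymmetryRule,
    TimeSeries,
    aligned_average,
    alpha_kernel,
    asymmetric_rectify,
    convolve_drf,
)
from .timing_models import (
    ConditionalTiming,
    DeterministicTiming,
    GammaTiming,
    SURVIVAL_FLOOR,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TaskSpec",
    "CommunicationMode",
    "RelativeValueTable",
    "TrialTrace",
    "cycle_average_reward",
    "solve_relative_values",
    "td_trace",
    "simulate_experiment",
    "SHORT_LATENCY_BOUNDARY",
]

#: press-time boundary (s) between short- and long-latency trial classes
SHORT_LATENCY_BOUNDARY = 5.0


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of the cued lever-press SMDP.

    a : hyperbolic cost factor (utility*s, <= 0); b : unit press cost
    (utility, <= 0); r : reward utility (> 0); tau_post : preparedness-to-
    press interval (s); tau_I : inter-trial interval (s); dt : microstate
    grid step (s); horizon : end of the microstate grid (s).

    cost_in_stream : whether a/T + b is delivered as part of the rewarding
    outcome the critic predicts (default False: the critic values r only).
    track_intervals : whether the critic times the deterministic intervals
    (default True: no onset surprise at predictable transitions).
    """

    a: float = -1.0
    b: float = 0.0
    r: float = 1.0
    tau_post: float = 0.5
    tau_I: float = 30.0
    dt: float = 0.01
    horizon: float = 25.0
    cost_in_stream: bool = False
    track_intervals: bool = True

    def __post_init__(self):
        if self.a > 0 or self.b > 0:
            raise ValueError("costs a, b must be <= 0")
        if self.tau_post < 0 or self.tau_I < 0:
            raise ValueError("tau_post and tau_I must be >= 0")
        if self.dt <= 0 or self.horizon <= 0:
            raise ValueError("dt and horizon must be > 0")


@dataclass(frozen=True)
class CommunicationMode:
    """What the critic hears about the actor's choice.

    kind : 'indirect' (efference copy just before the press only) or
    'direct_and_indirect' (the chosen latency is additionally reported
    epsilon seconds after the cue, subject to scalar timing noise
    k_scalar when predicting the efference time).
    """

    kind: str = "indirect"
    epsilon: float = 0.1
    k_scalar: float = 0.1

    def __post_init__(self):
        if self.kind not in ("indirect", "direct_and_indirect"):
            raise ValueError(f"unknown communication kind {self.kind!r}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    @property
    def is_direct(self) -> bool:
        return self.kind == "direct_and_indirect"


# ---------------------------------------------------------------------------
# average reward
# ---------------------------------------------------------------------------

def _mean_T(timing) -> float:
    if isinstance(timing, DeterministicTiming):
        return timing.tau
    return float(timing.mean)


def _mean_inverse_T(timing, floor: float) -> float:
    """E[1/max(T, floor)]; the floor regularises the k<=1 gamma divergence."""
    if isinstance(timing, DeterministicTiming):
        return 1.0 / max(timing.tau, floor)
    if isinstance(timing, GammaTiming) and timing.k <= 1.0:
        logger.warning(
            "E[1/T] diverges for gamma shape k=%.3g <= 1; truncating the "
            "hyperbolic cost as a/max(T, %g s)", timing.k, floor,
        )
    upper = (
        stats.gamma(a=timing.k, scale=timing.theta).ppf(1 - 1e-12)
        if isinstance(timing, GammaTiming)
        else timing.mean + 12 * timing.sd
    )
    tail, _ = integrate.quad(lambda t: timing.pdf(t) / t, floor, upper, limit=200)
    head = 1.0 - timing.survival(floor)
    return tail + head / floor


def cycle_average_reward(spec: TaskSpec, timing, include_costs: bool = True) -> float:
    """Renewal-reward average rate rho = E[r + a/T + b] / E[T + tau_post + tau_I].

    The hyperbolic cost is truncated as ``a / max(T, dt)`` where E[1/T]
    diverges (gamma shape <= 1); the truncation is logged.
    With ``include_costs=False`` the numerator is the reward r alone (the
    critic's default prediction-error stream).
    """
    mean_cycle = _mean_T(timing) + spec.tau_post + spec.tau_I
    if include_costs:
        mean_u = spec.r + spec.b + spec.a * (
            _mean_inverse_T(timing, spec.dt) if spec.a != 0.0 else 0.0
        )
    else:
        mean_u = spec.r
    return mean_u / mean_cycle


# ---------------------------------------------------------------------------
# relative values
# ---------------------------------------------------------------------------

def _survival_grid(timing, t: np.ndarray) -> np.ndarray:
    if isinstance(timing, ConditionalTiming):
        # closed-form truncated-normal survival, vectorised
        s = stats.norm.sf((t - timing.tau) / timing.sd)
        s0 = stats.norm.sf(-timing.tau / timing.sd)
        return s / s0
    return timing.survival(t)


def _backward_v1(surv: np.ndarray, v2: float, rho: float, dt: float) -> np.ndarray:
    """Solve the waiting-state recursion v1(t) backward from the horizon.

    v1[i] = p_stay * v1[i+1] + p_go * v2 - rho*dt, with p_go the conditional
    transition probability over one grid step.  Beyond survival underflow
    the transition is treated as certain (v1 = v2).  ``surv`` may be
    (n_t,) or (n_tau, n_t); the recursion runs over the last axis.
    """
    surv = np.asarray(surv, dtype=float)
    squeeze = surv.ndim == 1
    s = np.atleast_2d(surv)
    n = s.shape[1]
    v1 = np.full(s.shape, v2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_go = np.clip((s[:, :-1] - s[:, 1:]) / s[:, :-1], 0.0, 1.0)
    p_go = np.where(s[:, :-1] <= SURVIVAL_FLOOR, 1.0, p_go)
    for i in range(n - 2, -1, -1):
        v1[:, i] = (1.0 - p_go[:, i]) * v1[:, i + 1] + p_go[:, i] * v2 - rho * dt
    return v1[0] if squeeze else v1


@dataclass(frozen=True)
class RelativeValueTable:
    """rho and the relative values of the lever-press SMDP states.

    The free additive constant of relative values is fixed by anchoring the
    inter-trial state at v3 = 0.  In direct mode ``v1`` is a (n_tau, n_t)
    family, one row per latency in ``tau_grid``; indirectly it is (n_t,).
    ``v10`` is the value of the initial state of ignorance {1, 0}.
    """

    rho: float
    t_grid: np.ndarray = field(repr=False)
    v1: np.ndarray = field(repr=False)
    v2: float
    v3: float
    v10: float
    tau_grid: np.ndarray | None = field(default=None, repr=False)
    mean_u: float = 0.0

    def v1_at(self, t: float, tau: float | None = None) -> float:
        if self.tau_grid is None:
            return float(np.interp(t, self.t_grid, self.v1))
        if tau is None:
            raise ValueError("tau required for a direct-mode table")
        i = int(np.argmin(np.abs(self.tau_grid - tau)))
        if abs(self.tau_grid[i] - tau) > 1e-9:
            raise KeyError(f"tau={tau} not in the solved tau grid")
        return float(np.interp(t, self.t_grid, self.v1[i]))

    def recursion_residual(self, surv: np.ndarray, row: int | None = None) -> np.ndarray:
        """Pointwise residual of the waiting-state recursion (self-consistency)."""
        v1 = self.v1 if row is None else self.v1[row]
        dt = float(self.t_grid[1] - self.t_grid[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            p_go = np.clip((surv[:-1] - surv[1:]) / surv[:-1], 0.0, 1.0)
        p_go = np.where(surv[:-1] <= SURVIVAL_FLOOR, 1.0, p_go)
        rhs = (1.0 - p_go) * v1[1:] + p_go * self.v2 - self.rho * dt
        return v1[:-1] - rhs


def _stream_spec(spec: TaskSpec) -> TaskSpec:
    """The utility convention of the critic's prediction-error stream."""
    if spec.cost_in_stream:
        return spec
    return replace(spec, a=0.0, b=0.0)


def solve_relative_values(
    spec: TaskSpec,
    timing,
    mode: CommunicationMode = CommunicationMode(),
    rho: float | None = None,
    tau_grid: np.ndarray | None = None,
) -> RelativeValueTable:
    """Solve rho and the relative values for the lever-press SMDP.

    ``timing`` is the distribution of the efference-copy time T (indirect
    mode) or of the actor's latency tau (direct mode, where T | tau follows
    the scalar-noise Gaussian).  In direct mode one v1 row is solved per
    latency on ``tau_grid`` (default: the gamma quadrature grid), and the
    initial state of ignorance is priced by integrating v1(epsilon; tau)
    over the latency density.
    """
    sspec = _stream_spec(spec)
    if rho is None:
        rho = cycle_average_reward(sspec, timing, include_costs=True)
    mean_u = (
        sspec.r + sspec.b + (sspec.a * _mean_inverse_T(timing, spec.dt) if sspec.a else 0.0)
    )
    t = np.arange(0.0, spec.horizon + 0.5 * spec.dt, spec.dt)
    v3 = 0.0
    v2 = -rho * spec.tau_post + mean_u + v3

    if not mode.is_direct:
        surv = _survival_grid(timing, t)
        v1 = _backward_v1(surv, v2, rho, spec.dt)
        v10 = v1[0]
        return RelativeValueTable(
            rho=rho, t_grid=t, v1=v1, v2=v2, v3=v3, v10=v10, mean_u=mean_u
        )

    if tau_grid is None:
        if isinstance(timing, DeterministicTiming):
            tau_grid = np.array([timing.tau])
        else:
            qs = np.linspace(0.002, 0.998, 120)
            tau_grid = np.unique(
                stats.gamma(a=timing.k, scale=timing.theta).ppf(qs)
            )
    tau_grid = np.asarray(tau_grid, dtype=float)
    sds = mode.k_scalar * tau_grid[:, None]
    surv = stats.norm.sf((t[None, :] - tau_grid[:, None]) / sds)
    surv /= stats.norm.sf(-tau_grid[:, None] / sds)
    v1 = _backward_v1(surv, v2, rho, spec.dt)
    # Value of the initial state of ignorance: -rho*eps plus the latency-
    # density-weighted average of the post-report values v1(eps; tau).
    v_eps = np.array([np.interp(mode.epsilon, t, row) for row in v1])
    if isinstance(timing, DeterministicTiming):
        w = np.ones(1)
    else:
        w = timing.pdf(tau_grid)
    w = w / np.trapezoid(w, tau_grid) if tau_grid.size > 1 else np.ones(1)
    e_veps = (
        float(np.trapezoid(w * v_eps, tau_grid)) if tau_grid.size > 1 else float(v_eps[0])
    )
    v10 = -rho * mode.epsilon + e_veps
    return RelativeValueTable(
        rho=rho, t_grid=t, v1=v1, v2=v2, v3=v3, v10=v10,
        tau_grid=tau_grid, mean_u=mean_u,
    )


# ---------------------------------------------------------------------------
# single-trial TD traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialTrace:
    """Phasic TD error of one trial, with its event times and latency class."""

    delta_p: TimeSeries
    events: dict
    latency_class: str

    @property
    def press_time(self) -> float:
        return self.events["press"]


def _nearest_index(ts: TimeSeries, t: float) -> int:
    return int(round((t - ts.t0) / ts.dt))


def td_trace(
    spec: TaskSpec,
    table: RelativeValueTable,
    T: float,
    tau: float | None = None,
    mode: CommunicationMode = CommunicationMode(),
    include_tonic: bool = False,
    pre: float = 3.5,
    post: float = 3.0,
) -> TrialTrace:
    """Assemble the phasic TD error delta^p(t) of a single trial.

    Components: the cue-onset transient (zero when the critic tracks the
    inter-trial interval, rho*tau_I when it does not); the waiting-period
    value drift (realised, conditioned on no transition; identically zero
    under a flat hazard); the direct-report transient at epsilon (direct
    mode); the efference-copy transient at T; and the reward transient at
    press completion (zero when the outcome is fully predicted).  Value
    steps are represented as impulses of matching area (height = step/dt).
    ``include_tonic`` subtracts rho to give the full error delta.
    """
    if T <= 0 or T > spec.horizon:
        raise ValueError(f"T={T} outside (0, horizon={spec.horizon}]")
    dt = spec.dt
    press = T + spec.tau_post
    t0 = -pre
    n = int(round((press + post - t0) / dt)) + 1
    out = np.zeros(n)
    ts = TimeSeries(t0, dt, out)
    times = ts.times
    rho = table.rho

    iti_rate = rho if spec.track_intervals else 0.0
    i_cue = _nearest_index(ts, 0.0)
    i_T = _nearest_index(ts, T)
    i_press = _nearest_index(ts, press)

    # deterministic intervals: smooth drift at rate rho if tracked
    out[:i_cue] = iti_rate                      # inter-trial interval
    out[i_T:i_press] = iti_rate                 # preparedness interval
    out[i_press:] = iti_rate                    # next inter-trial interval

    if not spec.track_intervals:
        out[i_cue] += (table.v10 - table.v3) / dt          # cue-onset surprise

    if mode.is_direct:
        if tau is None:
            raise ValueError("direct mode requires the chosen tau")
        i_eps = _nearest_index(ts, mode.epsilon)
        out[i_cue:i_eps] = iti_rate if spec.track_intervals else 0.0
        pre_value = table.v10 + (rho * mode.epsilon if spec.track_intervals else 0.0)
        out[i_eps] += (table.v1_at(mode.epsilon, tau) - pre_value) / dt
        wait_lo, row = mode.epsilon, int(np.argmin(np.abs(table.tau_grid - tau)))
        v1_row = table.v1[row]
    else:
        wait_lo, v1_row = 0.0, table.v1

    # waiting-period drift: realised per-step value change given no transition
    mask = (times >= wait_lo + dt / 2) & (times < T - dt / 2)
    if np.any(mask):
        v_here = np.interp(times[mask], table.t_grid, v1_row)
        v_next = np.interp(times[mask] + dt, table.t_grid, v1_row)
        out[mask] = (v_next - v_here) / dt

    out[i_T] += (table.v2 - np.interp(T, table.t_grid, v1_row)) / dt

    # reward transient: realised utility + v3 against the pre-press value
    u = spec.r + (spec.a / max(T, dt) + spec.b if spec.cost_in_stream else 0.0)
    pre_press = table.v2 + (rho * spec.tau_post if spec.track_intervals else 0.0)
    out[i_press] += (u + table.v3 - pre_press) / dt

    if include_tonic:
        out -= rho

    latency_class = "short" if press < SHORT_LATENCY_BOUNDARY else "long"
    return TrialTrace(
        delta_p=TimeSeries(t0, dt, out),
        events={"cue": 0.0, "efference": T, "press": press},
        latency_class=latency_class,
    )


def efference_transient(table: RelativeValueTable, T: float, tau: float | None = None) -> float:
    """Value step at the efference copy, v2 - v1(T) (the press-proximal error)."""
    return table.v2 - table.v1_at(T, tau)


# ---------------------------------------------------------------------------
# simulated experiment (event-aligned averages of modelled [DA])
# ---------------------------------------------------------------------------

def simulate_experiment(
    spec: TaskSpec,
    timing: GammaTiming,
    mode: CommunicationMode,
    asym: AsymmetryRule = AsymmetryRule(),
    n: int = 1000,
    seed: int = 0,
    xi: float = 0.7,
    cue_window: tuple[float, float] = (1.0, 5.0),
    press_window: tuple[float, float] = (3.0, 2.0),
    peak_halfwidth: float = SHORT_LATENCY_BOUNDARY / 2,
) -> dict:
    """Simulate n trials and return event-aligned [DA] averages and peaks.

    Per trial: draw the latency (and, in direct mode, a noisy efference
    time), assemble delta^p, scale negative errors by the asymmetry factor,
    convolve with the DRF, then average aligned to cue and press, split at
    the 5 s press-time boundary.  ``peak_summary`` reports mean +/- SEM of
    the per-trial peak [DA] in +/-``peak_halfwidth`` windows around the cue
    and the press, by latency class.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kernel = alpha_kernel(xi=xi, dt=spec.dt)

    if mode.is_direct:
        taus = timing.rvs(n, rng)
        sds = mode.k_scalar * taus
        lo = (0.0 - taus) / sds
        Ts = stats.truncnorm.rvs(a=lo, b=np.inf, loc=taus, scale=sds, random_state=rng)
    else:
        Ts = timing.rvs(n, rng)
        taus = np.full(n, np.nan)
    Ts = np.minimum(Ts, spec.horizon - 1.0)

    solve_taus = np.unique(taus) if mode.is_direct else None
    table = solve_relative_values(
        spec, timing, mode,
        tau_grid=(
            np.unique(np.concatenate([solve_taus, _quad_taus(timing)]))
            if mode.is_direct else None
        ),
    )

    traces, press_times, classes = [], [], []
    cue_peaks, press_peaks = [], []
    for i in range(n):
        tr = td_trace(
            spec, table, T=float(Ts[i]),
            tau=(float(taus[i]) if mode.is_direct else None), mode=mode,
            post=3.0 + max(0.0, SHORT_LATENCY_BOUNDARY + cue_window[1] - (Ts[i] + spec.tau_post)),
        )
        da = convolve_drf(asymmetric_rectify(tr.delta_p, asym), kernel)
        traces.append(da)
        press_times.append(tr.press_time)
        classes.append(tr.latency_class)
        cue_peaks.append(_window_peak(da, 0.0, peak_halfwidth))
        press_peaks.append(_window_peak(da, tr.press_time, peak_halfwidth))

    classes = np.array(classes)
    cue_peaks = np.array(cue_peaks)
    press_peaks = np.array(press_peaks)
    press_times = np.array(press_times)

    out = {
        "cue_aligned": aligned_average(traces, [0.0] * n, cue_window),
        "trials": {
            "T": Ts, "tau": taus, "press_time": press_times,
            "latency_class": classes,
            "cue_peak": cue_peaks, "press_peak": press_peaks,
        },
    }
    for cls in ("short", "long"):
        sel = classes == cls
        if np.any(sel):
            out[f"press_aligned_{cls}"] = aligned_average(
                [traces[i] for i in np.flatnonzero(sel)],
                list(press_times[sel]), press_window,
            )
        else:
            out[f"press_aligned_{cls}"] = None

    summary = []
    for cls in ("short", "long"):
        sel = classes == cls
        for win, peaks in (("cue", cue_peaks), ("press", press_peaks)):
            k = int(sel.sum())
            mean = float(peaks[sel].mean()) if k else float("nan")
            sem = float(peaks[sel].std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0
            summary.append(
                {"class": cls, "window": win, "mean": mean, "sem": sem, "n": k}
            )
    out["peak_summary"] = summary
    return out


def _quad_taus(timing: GammaTiming) -> np.ndarray:
    qs = np.linspace(0.002, 0.998, 120)
    return np.unique(stats.gamma(a=timing.k, scale=timing.theta).ppf(qs))


def _window_peak(ts: TimeSeries, center: float, halfwidth: float) -> float:
    t = ts.times
    sel = (t >= center - halfwidth) & (t <= center + halfwidth)
    return float(ts.values[sel].max()) if np.any(sel) else float("nan")
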