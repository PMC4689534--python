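# Methods

This note records the models implemented in `ramplab`, the assumptions
behind them, the parameters that matter, and the numerical and design
choices made where the modelling question was genuinely open.

## Measurement model

Modelled dopaminergic activity is converted to a concentration signal
Δ[DA] by causal convolution with a dopamine response function (DRF), an
alpha function f(t) = (t/ξ)·e^{1−t/ξ} with time constant ξ (default
0.7 s), which rises from f(0)=0 to a peak of 1 at t = ξ and decays with
the same constant.  The kernel is truncated at 10ξ, where the tail is
below e⁻⁹ of the peak.  Convolution is scaled by the grid step dt so that
impulse *area* is conserved: a prediction-error transient of size Δv is
represented as a single sample of height Δv/dt, and its convolved response
peaks at Δv regardless of grid resolution.  Negative prediction errors may
first be scaled by an asymmetry factor d ∈ (0,1] (default 1/6),
reflecting the weaker coupling of firing pauses to concentration;
rectification is applied to the error trace *before* convolution.
Event-aligned averages report per-gridpoint mean and SEM (sample SD with
n−1 denominator over √n), linearly interpolating each trace onto the
aligned grid; traces that do not cover the window are excluded with a
logged warning.  The grid step is configuration-exposed (default 0.01 s
throughout).

## Account 1: action-timing uncertainty in an average-reward SMDP

A cued lever-press trial is a semi-Markov cycle: cue (state 1) → a waiting
period of random duration T until the critic is told, via efference copy,
that the press is imminent (state 2, "preparedness") → press completion and
reward r after a further fixed interval τ_post (state 3) → fixed
inter-trial interval τ_I → next cue.  Defaults: r = 1, τ_post = 0.5 s,
τ_I = 30 s, cost parameters a = −1 (utility·s), b = 0.

**Timing distributions.**  With only indirect communication the critic's
expectations over T follow a gamma prior G(k, θ); we focus on G(1,1)
(flat hazard) and G(2,1) (increasing hazard, t/(1+t)).  With an
additional direct report of the chosen latency τ (arriving ε = 0.1 s
after the cue; ε is nowhere constrained, so it is configuration-exposed),
the conditional law is Gaussian with scalar timing noise, sd = k·τ
(k = 0.1), truncated to T > 0 and renormalised so that survival and
hazard are well posed — times cannot be negative, and an untruncated
Gaussian would put mass there.  Hazard evaluation returns NaN where the
survival function has underflowed below 10⁻¹²; callers cap their grids.

**Relative values.**  Within state 1 the critic tracks elapsed time and
the relative values of microstates {1, t} satisfy the hazard-weighted
backward recursion

    v1(t) = p_stay(t) · v1(t+dt) + p_go(t) · v2 − ρ·dt,

solved backward from a horizon covering the timing distribution's mass
(transition treated as certain beyond survival underflow).  Relative
values are fixed up to an additive constant; we anchor the inter-trial
state at v3 = 0.  In steady state v1(t) = v2 − ρ·m(t) with m(t) the mean
residual waiting time — the quantity that makes all transient orderings
transparent — and a Monte-Carlo evaluation of the defining expectation
serves as an independent oracle in the tests.

**What the critic prices.**  The critic's valued outcome is the reward r;
the effort costs a/τ + b price the *choice* of latency (they appear in
the latency objective and in the renewal formula
ρ = E[r + a/T + b] / E[T + τ_post + τ_I] exposed by
`cycle_average_reward`) but are not delivered as reward events in the
prediction-error stream unless `TaskSpec.cost_in_stream` is set.  This is
a deliberate design choice: with the default task parameters (a = −1,
r = 1) and G(2,1) timing, E[a/T] = −1 exactly cancels the reward in
expectation, which would zero the average reward rate and with it every
hazard-driven transient; and for G(1,1), E[1/T] diverges (the
implementation then truncates the cost as a/max(T, dt), with a logged
warning).  A critic that prices only the reward keeps ρ > 0 and produces
the full pattern of transients; the alternative is available behind the
flag for exploration.

**Trace assembly.**  Deterministic intervals (τ_post, τ_I) are tracked by
the critic by default (`TaskSpec.track_intervals`), so predictable
transitions evoke no onset surprise; their smooth value accrual appears
as a constant drift at rate ρ.  Transients then occur only where
uncertainty is resolved: at the direct report (value step from the state
of ignorance to the τ-conditioned value, mean-zero across trials and
strongly negative for long chosen latencies) and at the efference copy
(v2 − v1(T) = ρ·m(T): constant in T under a flat hazard, decreasing
under G(2,1), increasing in τ under direct report with scalar timing
noise).  With lumped intervals (`track_intervals=False`) the classic
cue-onset impulse ρ·τ_I and reward impulse reappear, and the time-average
of the phasic error over a session equals ρ exactly (the impulses
telescope to the cycle's reward) — the convention used by the
unbiasedness test.  The realised waiting-period drift (value change
conditioned on no transition) is included; it is identically zero under a
flat hazard.  The full error δ = δ^p − ρ is available via
`include_tonic`.

**Simulated experiment.**  N trials (default 1000) draw τ from the gamma
policy and T from the conditional law, assemble δ^p, rectify (d = 1/6),
convolve, and average aligned to cue and to press, split at a press time
of 5 s.  Per-trial peak [DA] is taken in windows of half-width 2.5 s
(half the class boundary, so the cue and press windows of every
short-latency trial tile the cue-to-press span without a gap) and
summarised as mean ± SEM per class.  Long-latency trials show a
press-window peak several pooled SEMs above the cue-window peak; in
short-latency trials the two windows usually capture the same early
transient complex and differ by about two pooled SEMs — the model
predicts a *continuum* (press-proximal transients grow with latency), so
"no difference" in the short class is only approximate, and the margin of
this check is sensitive to the latency distribution: gamma G(2,1) places
substantial mass at 2–4.5 s where the asymmetry is already visible,
whereas empirical short-latency presses concentrate near 1 s.

## Account 2: dopaminergic gain control of a drift-diffusion process

Evidence follows dx = g(t)[A dt + c dW], x(0) = 0, deciding at the first
|x| ≥ z (defaults for the tonic-only ensemble: A = 1, c = 1, z = 5; for
the phasic ensemble: A = 2, c = 0.1, z = 5).  The gain is the modelled
dopamine concentration: an Ornstein-Uhlenbeck process
dg = κ(θ − g) dt + σ dW (θ = 1, κ = 0.01 s⁻¹, σ = 0.1 s^{-1/2},
Euler-Maruyama at dt = 0.01 s, g(0) = θ), plus, in the phasic condition,
h·f(t) with h ~ N(μ_TD, σ_TD²) = N(4, 1) drawn per trial and the event at
trial start (the onset time is configuration-exposed; nothing in the
problem fixes it).  Numerical choices: the gain is floored at 10⁻⁶ (a
negative gain would invert the meaning of evidence; hits are logged);
trials are censored at 60 s and excluded from aligned averages and
correlations with the count reported; the crossing time is refined by
linear interpolation of the final step, which removes most of the O(dt)
latency bias (the residual sub-step diffusion bias, ≈ 0.58·c·√dt, is why
the first-passage oracle test integrates at dt = 0.0025 s).

Crossing-aligned averages of g ramp toward decision time in the
tonic-only condition purely through selection (crossings happen when the
autocorrelated gain is high).  In the phasic condition the correlation
between h and latency is strongly negative.  Its *magnitude* deserves
comment: with a mean transient of 4 gain units against z = 5, crossings
occur inside the transient and latency is nearly a deterministic,
monotone function of h, so the ensemble correlation computed by
`scripts/acceptance.py` is ≈ −0.90.  A substantially weaker correlation
would require most of the latency variance to come from sources other
than h — e.g. tonic fluctuations an order of magnitude larger within a
trial, a stationary (rather than reset) trial-start tonic level, or
event times jittered across trials.  These variants were examined and are
available through the parameters (they yield stable means between −0.2
and −0.8 depending on the convention), but the defaults implement the
plain per-second dynamics above.

## Motivational state and the phasic/tonic correlation

With a softmax latency policy P(τ) ∝ exp(β·Q(1,τ)),
Q(1,τ) = a/τ + b + r − ρ(τ + τ_post + τ_I) + const, the policy and its
average utility rate are interdependent; `solve_policy_rho_fixed_point`
alternates policy and renewal-reward updates with damping 0.5 on ρ
(initialised at 0) to |Δρ| < 10⁻¹⁰.  The latency grid defaults to 200
log-spaced points on [0.1, 20] s.  In the greedy limit the maximiser
matches the closed-form opportunity-cost trade-off τ* = √(−a/ρ).
Sweeping the reward utility r (a stand-in for motivational state) at
a = −0.05, b = 0, τ_post = 0.5 s, τ_I = 0, β = 1 raises ρ and shortens
latencies.  The trial-start transient is reported as δ_cue =
ρ·(τ_I + τ_post), the expected value step from the preparedness state
into the new trial; with τ_I = 0 trial start coincides with press
completion, and the naive "cue-onset step" ρ·τ_I would be identically
zero — the chosen definition is the transient that actually occurs at
that moment.  δ_cue rises with ρ and anticorrelates with latency: a
spurious phasic/tonic correlation with no mechanistic coupling.

## Account 3: discounted vigour and the quasi-tonic signal

Latency choice under discounting values a press of latency τ at
Q^γ(τ) = a/τ + γ^τ·v_next, with γ per second.  In the terminating
convention the post-press value is 1 (reward folded in); the continuing
convention prices r at press completion and discounts an inter-trial
interval τ_I to the next opportunity, solved by damped fixed-point
iteration (contraction factor γ^{τ*+τ_I}).  The interior maximiser is
found by bounded golden-section search on (0, 2/|ln γ|] — the rising
branch of the stationarity condition |a| = τ²γ^τ|ln γ| — refined to
10⁻⁶ s and cross-checked against a brute-force grid argmax in the tests.
A maximiser exists iff |a| ≤ |a_min| with a_min = 4/(e²·ln γ); we return
it whenever the stationary point exists, without additionally requiring
Q(τ*) > 0 (close to the bound the maximal value is negative, i.e. acting
is worse than never acting, but the bound itself concerns existence).
When τ_I ≫ −1/ln γ the continuing and terminating optima agree to within
hundredths of a second; short τ_I hastens pressing.

**Quasi-tonic ramps.**  Along a goal-approach trajectory with remaining
time-to-goal ("proximity") p(t) and reward r at the goal, the discounted
value is V^γ(s) = γ^{p}·r (0 after the goal; the episode terminates).
The quasi-tonic signal is (1−γ)V^γ(s_{t+1}); the undiscounted TD error is
δ_A(t) = r(s_t) + V^γ(s_{t+1}) − V^γ(s_t).  On monotone approaches
sampled at unit steps the value is Bellman-consistent at every step and
δ_A ≡ (1−γ)V^γ(s_{t+1}) holds pointwise — the identity the tests check
to 10⁻⁸; with pauses or retreats the value momentarily violates the
one-step consistency and the identity holds only in the long-run average
sense.  The signal's peak is exactly (1−γ)r, independent of trajectory
duration or length; it is linear in r; and it rises, stays flat, or
falls exactly as proximity falls, stalls, or grows.  A 3-state cyclic
chain with exact linear-algebra values verifies the continuity
(1−γ)V^γ → ρ as γ → 1.  The bundled trajectory synthesiser produces
unit-rate approaches with optional pause and retreat segments (time as
proxy for distance); for display, the DRF convolution of the quasi-tonic
signal is normalised to unit DC gain so the concentration trace is a
smoothed, delayed copy on the same scale.

## What the generators do and do not emulate

All inputs are generated internally: gamma and truncated-Gaussian timing
draws, OU and Wiener increments, Gaussian phasic magnitudes, synthetic
goal-proximity profiles.  They emulate the *structure* of cued
lever-press and maze-approach experiments — not their measurement
process: there is no voltammetric noise, electrode drift, baseline
referencing, reuptake kinetics, or spatial heterogeneity of release, and
behavioural latency distributions are exactly the assumed gamma /
softmax laws rather than the heavier-tailed empirical ones.  Passing
tests therefore certify the internal consistency of the models and the
orderings and identities they imply, not quantitative agreement with any
particular recording.

## Problem sizes

Default simulation sizes (1000-trial ensembles, 10-seed correlation
averages, 10⁵ s OU paths, 10⁴-trial first-passage checks) keep the whole
test suite and the acceptance script in the minutes range on a single
CPU while holding Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The press-cost conventions (when effort is "paid", whether the critic
  prices it) are genuinely underdetermined; the flags `cost_in_stream`
  and `track_intervals` expose the alternatives, and the defaults are
  the ones that produce a self-consistent, non-degenerate signal pattern.
- The phasic-ensemble h-latency correlation is parameter-regime
  sensitive (see above); its default magnitude reflects transient-
  dominated crossings.
- No learning dynamics: values are converged solutions, not TD(λ)
  trajectories.
- Exponential discounting only; hyperbolic discounting and
  continuous-space formulations are out of scope.
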