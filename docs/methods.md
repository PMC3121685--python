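# Methods

## Model

Adaptation is represented as a scalar compensation profile over movement
direction, `x_n(θ)`, on a dense 1° grid covering [−180°, 180°) with
wrap-aware arithmetic (angular differences are reduced to (−180°, 180°]).
Units are compensated viscosity, N/(m/s): `x(θ) = B` means a movement
planned along θ is met with feedforward force output that exactly cancels
a curl field of viscosity `B`. A naive subject is identically zero.

Each trial updates the profile with retention `A` and an error-driven
Gaussian increment,

    x_{n+1}(θ) = A·x_n(θ) − η·e_n·g(θ − θ_ref),   g(δ) = exp(−δ²/2σ²),

where `e_n` is the trial's directional error in degrees (actual − planned,
CCW-positive). The sign is fixed by the requirement that learning oppose
the perturbing field: a CW field (positive viscosity) produces negative
errors, and the resulting positive increment drives `x` toward the CW
viscosity. Plan-referenced learning (PRL) centers `g` on the planned
direction; motion-referenced learning (MRL) on the actual direction. Null
and error-clamp trials carry no learnable error and apply pure decay. The
recursion is linear in the error history, which gives a closed-form
geometric superposition used both as a test oracle and as the fast replay
inside model fitting.

### Sign conventions

Directions are degrees CCW from +x, so 90° is straight ahead. The curl
force is `F = B·(v_y, −v_x)`: positive `B` (CW) deflects a 90° reach
toward smaller angles. Interference generalization patterns are plotted
with CCW-appropriate compensation positive (`−x(θ)/|B_ref|`, so CCW-side
probes show positive adaptation under MRL); learning curves against a CW
training field use the trained field itself as regression reference, so
they rise toward +1. Both conventions come out of the same regression of
measured clamp force onto the ideal compensating force for a signed
reference viscosity.

## Closed loop

Each trial is summarized by one direction: reaches are approximately
straight over their initial segment, which is the portion that determines
velocity-dependent learning, so the within-trial time course is not
modeled. On a field trial the initial-direction error is a static-gain map
of the uncompensated viscosity plus Gaussian motor noise:

    e = −k·(B − x(θ_planned)) + ε,   ε ~ N(0, σ_m²).

Error-clamp trials hold lateral displacement at exactly zero (an idealized
force channel: no stiffness/damping parameters), decay the state, and
record the lateral force `x(θ_probe)·speed(t)`.

Reference kinematics are fifth-order minimum-jerk profiles, 10 cm at
200 Hz. The default duration, 0.621 s, makes the peak speed equal the
task's mean of 0.302 m/s (minimum-jerk peak speed is `1.875·d/T`); the
500 ± 50 ms completion-time criterion is treated as a task instruction to
subjects, not as the simulated duration.

## Parameters

| parameter | symbol | default | rationale |
|---|---|---|---|
| retention | `A` | 0.98 /trial | standard single-state trial-to-trial retention in force-field adaptation modeling; recoverable from data (see below), so the default is not load-bearing |
| learning gain (interference task) | `η` | 0.0357 N/(m/s)/deg | a naive trial in the B = 9 field (error ≈ −12.6°) yields ~5% of full compensation at the primitive center |
| primitive width | `σ` | 22.77° | the 0.12 m/s velocity-space primitive width subtended at the mean peak speed: (0.12/0.302)·(180/π) |
| error gain (B = ±9) | `k` | 1.4 °/(N/(m/s)) | calibrated so the mean CW/CCW error separation in interference training is ≈ 25° |
| motor noise | `σ_m` | 3° | typical initial-direction variability for planar reaches |
| error gain (B = 22.5) | `k` | 17/22.5 ≈ 0.76 | directional errors saturate with field strength; this maps the naive uncompensated field to a −17° initial error, the regime the shifted-target construction assumes |
| learning gain (B = 22.5) | `η` | 0.165 | with the error gain above, a single-target error history decays with a time constant of order ten trials, so the 125-trial schedules approach asymptote and the three training groups converge late |
| CW gain scale | — | 1.0 | optional asymmetry emulating faster CW-field learning; off by default |

The two shifted-target-task gains are deliberately calibrated separately
from the interference task: the fields differ by a factor 2.5 and the
error/learning mapping is not assumed to extrapolate linearly across that
range.

## Experimental designs

**Interference schedule.** 254 null baseline trials spread as evenly as
possible (seeded shuffle) over nine directions; 672 field trials at one
target in 48 alternating CW/CCW cycles of 14 trials; a testing block of 40
consecutive error-clamp trials over the nine directions after every 12
cycles, with the field presented last before testing balanced (2 CW / 2
CCW) across the four blocks. Block lengths are "7 ± 2": each even cycle
draws a jitter `j` from the symmetric feasible set keeping both block
lengths in {5..9}, and the next cycle uses `−j`, so the CW:CCW trial ratio
is exact over every cycle pair and over the full run. For the unbalanced
5:9 ratio the feasible set collapses and blocks are exactly (5, 9); for
7:7 lengths genuinely vary over 5–9. How the printed design reconciled
stochastic block lengths with exact ratios is not documented; this is the
package's resolution.

**Shifted-target schedules.** 75 baseline + 125 training trials toward
90°, CW field of 22.5 N/(m/s), error-clamp probes at 90° interspersed with
probability 0.2 in both phases. Probe positions are drawn once per seed
and shared by all three schedules, so group comparisons are matched trial
for trial. The target-shift history is a two-parameter exponential
`a·exp(−n/τ)` least-squares fit of the mean field-trial error history of a
simulated 17-subject single-target pilot cohort. LST presents
`90° − shift_n` (planned plus expected error lands on 90°; with CW errors
negative this places targets leftward/above 90°, and "adding the error
history" in the leftward sense is implemented as subtraction of the signed
error); RST mirrors LST about 90°. Because the true error history
asymptotes at a small nonzero residual while the fitted family decays to
zero, the fitted shifts underestimate the earliest errors somewhat; this
imperfection is part of the construction, not removed.

## Measurement pipeline

The adaptation coefficient is the no-intercept OLS slope of measured
lateral clamp force on the ideal compensating force, restricted to the
movement window (speed above 5% of its peak). No intercept because the
coefficient is defined as a pure gain on the bell-shaped
velocity-dependent profile; window and intercept conventions are choices,
stated here, since the underlying definitions leave them open.

Trials are excluded when peak speed falls outside (0.2, 0.55) m/s or
reaction time outside (0.075, 2.5) s — strict inequalities, so boundary
values are excluded; trials with missing kinematics are flagged in the
report, never silently dropped.

Generalization patterns are per-direction means with standard errors
(across-subject SEs at cohort level). Peak separation is found on a 0.5°
linearly interpolated grid with ties broken toward the training direction
and a noise threshold of twice the pooled SE; a pattern without both a
positive peak and a negative trough above threshold raises a bimodality
error rather than returning a number. Note that the ~60° separation is a
property of the pattern *as sampled at the nine probe directions* (peaks
land on the ±30° probes); the dense underlying state has extrema near
±24°. The package measures what the experiment measures.

Learning curves are summarized by the means of the first three and last
three error-clamp probes. Group comparisons (one-way ANOVA, pairwise
Welch t-tests) are exposed as plain summaries without multiplicity
correction.

## Synthetic raw data

The generator renders every simulated trial as a minimum-jerk reach along
its actual direction with: smooth positional jitter (1 mm SD, Gaussian
low-pass over 75 ms, so velocity-derived peak-speed estimates scatter by
~0.02 m/s without breaking position/velocity consistency); per-trial
durations N(0.621, 0.035) s, putting peak speeds at 0.302 ± ~0.02 m/s;
log-normal reaction times (median 0.3 s, log-SD 0.35); clamp forces with
0.1 N sensor noise; and configurable fractions of planted speed/RT
violations to exercise the inclusion filter. Cohorts derive per-subject
seeds from a master seed via seed sequences and apply mild parameter
jitter (5% log-normal on the gain, 0.005 additive on retention).

The `impaired` profile (0.4× learning gain, 2× motor noise) emulates the
slowed learning and elevated residual errors reported for chronic stroke
patients; its numbers are presets chosen for qualitative fidelity, not
fits to patient data. Under it, the LST-over-STT advantage is larger in
total and persists longer, provided the LST shifts are calibrated to an
impaired pilot cohort (the paradigm's own prescription).

What the synthetic data do **not** emulate: within-trial feedback
corrections and curved late-trajectory segments, reaction-time/kinematic
correlations, biomechanical anisotropies across directions, use-dependent
or multi-timescale (savings) learning, and the empirical time course of
the CW learning bias (only a static CW gain scale is exposed). Passing
tests therefore demonstrate internal consistency of the models and
pipeline and the discriminability of the two hypotheses under the stated
noise model — not that human data would match at these effect sizes.

## Model fitting

`MotorAdaptationModel` treats observed clamp coefficients as the response
and replays each subject's recorded trial history (fields, errors,
directions) through the learning rule, exploiting the linear recursion to
predict every probe as a decayed superposition over prior field trials.
`fit()` runs bounded least squares over (retention, gain, σ) from a
neutral start (0.95, 0.02, 30°), with standard errors from the
Gauss–Newton covariance `s²(JᵀJ)⁻¹`. σ is only identifiable when probes
sample more than one direction relative to the deposited adaptation; a
single-direction clamp series leaves it at its bound, which is why the
recovery fixture appends a shuffled multi-direction probe block to the
single-target schedule. At 16 subjects and default noise, all three
parameters are recovered within 10% (retention and σ within 1%).

## Numerical choices and degenerate inputs

- State interpolation is linear with period 360; grid resolution 1°
  (interpolation error vs. the analytic superposition is < 10⁻³ in
  coefficient units at the default σ).
- The exponential error-history fit is parametrized by a non-negative
  rate, so a constant series is the rate→0 limit rather than a failure;
  fewer than 3 points is an error.
- Zero-variance inputs to correlations, identically-zero ideal forces,
  empty schedules, non-finite forces/viscosities, and invalid parameter
  ranges all raise `ValueError` (specific subclasses for the undefined
  coefficient and missing bimodality) rather than propagating NaNs.
- All experiment runs are deterministic given their config: one seed
  sequence fans out to schedules, subjects and noise streams, and reports
  carry a hash of the full configuration.

## Problem sizes

Default runs use a 12-subject interference cohort (1086 trials each), a
17-subject pilot plus 30-subject cohorts per training paradigm, and a
16-subject recovery cohort — sizes at which the cohort-level patterns are
stable across seeds while a full test-suite run stays comfortably
interactive.

## Known limitations

- The closed loop is a static gain plus white noise; it cannot produce
  trial-to-trial error autocorrelations beyond those induced by learning.
- The error-clamp is idealized (zero lateral motion), so clamp-trial
  kinematic noise enters only through the rendered speed profile.
- The two-parameter exponential shift fit biases the earliest LST shifts
  downward when residual errors are nonzero (see above).
- Generalization is one-dimensional in direction; a full
  two-dimensional velocity-space primitive lattice is not modeled, and σ
  is a direction-space constant rather than speed-dependent.
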