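# credassign

Credit assignment in trial-by-trial motor adaptation: which movements get
the benefit of the learning that an error produces — the movement that was
*planned*, or the movement that actually *happened*?

`credassign` is a simulation and analysis package for reaching-arm
adaptation to viscous curl force-fields. It implements the two competing
credit-assignment hypotheses as trial-indexed state-space learning rules,
couples them to a closed-loop reach simulator, generates the two
experimental designs that discriminate between them (opposite-field
interference training, and single-target vs shifted-target training), and
provides the error-clamp regression pipeline used to measure adaptation.
All data are synthetic: a first-class generator renders each simulated
trial as 200-Hz kinematics and handle forces so that every analysis stage
— trial filtering, force regression, generalization analysis — runs on
realistic raw material.

It is aimed at computational motor-control researchers who want to explore
credit-assignment predictions, prototype training paradigms (e.g. for
neurorehabilitation, where shifted-target designs promise faster
adaptation), or test estimation pipelines against ground truth.

## The model

Adaptation is a compensation profile over movement direction,
`x_n(θ)`, in units of compensated field viscosity (N/(m/s)). Movements are
perturbed by a curl field `F = B [[0, 1], [-1, 0]] v`, and each trial's
directional error `e_n = θ_actual − θ_planned` (degrees, CCW-positive)
drives a local Gaussian update:

```
x_{n+1}(θ) = A · x_n(θ) − η · e_n · exp(−(θ − θ_ref)² / 2σ²)
```

with retention `A`, learning gain `η`, and primitive width `σ`. The two
hypotheses differ only in the center of the update:

* **PRL** (plan-referenced learning): `θ_ref = θ_planned`
* **MRL** (motion-referenced learning): `θ_ref = θ_actual`

The closed loop maps uncompensated field viscosity to the next error,
`e = −k · (B − x(θ_planned)) + noise`, so learning shrinks errors over
trials. Adaptation is measured on error-clamp trials (lateral motion held
at zero) as the no-intercept regression slope of the produced lateral
force onto the ideal field-compensating force: 1 = full compensation.

The discriminating predictions, both reproduced by this package:

* After training with CW/CCW fields alternating in short blocks at one
  target, PRL predicts a flat (cancelled) generalization pattern; MRL
  predicts a bimodal pattern whose peaks sit farther apart (~60°) than the
  mean errors experienced in the two fields (~25°).
* When training a single direction in a strong CW field, MRL predicts that
  *left-shifted* targets (planned + expected error = desired direction)
  speed up learning (LST > STT > RST early), while PRL predicts
  STT > LST = RST.

## Worked example

Simulate the interference experiment (12 subjects, both hypotheses), run
the full measurement pipeline, and inspect the generalization pattern:

```python
from credassign import RunConfig, run_exp1

report = run_exp1(RunConfig(experiment="exp1", hypothesis="both",
                            n_subjects=12, seed=1))
pattern = report["patterns"]["MRL"]
for d, m, se in zip(pattern.directions, pattern.mean, pattern.se):
    print(f"  {d - 270.0:+5.0f} deg   {m:+.3f} +/- {se:.3f}")
print(f"MRL peak separation: {report['mrl_peak_separation_deg']:.1f} deg")
print(f"mean CW/CCW error separation: {report['error_separation_deg']['MRL']:.1f} deg")
print(f"PRL flatness ratio: {report['prl_flatness_ratio']:.3f}")
```

```
    -90 deg   -0.003 +/- 0.000
    -60 deg   -0.092 +/- 0.007
    -30 deg   -0.472 +/- 0.036
    -25 deg   -0.481 +/- 0.033
     +0 deg   +0.006 +/- 0.005
    +15 deg   +0.413 +/- 0.038
    +30 deg   +0.487 +/- 0.042
    +60 deg   +0.093 +/- 0.008
    +90 deg   +0.003 +/- 0.001
MRL peak separation: 55.0 deg
mean CW/CCW error separation: 25.3 deg
PRL flatness ratio: 0.017
```

The motion-referenced pattern is bimodal: probe directions below the
training target carry CW-appropriate (negative) adaptation, directions
above it CCW-appropriate (positive) adaptation, with peaks separated by
more than twice the ~25° separation of the mean movement directions in the
two fields. The plan-referenced pattern is two orders of magnitude flatter
— balanced opposite-field training cancels when credit goes to the plan.

Learning parameters can be recovered from synthetic cohorts with the
statsmodels-style model object:

```python
import numpy as np
from credassign import (MotorAdaptationModel, LearningParams,
                        SubjectProfile, generate_cohort)
from credassign.paradigms import Schedule, probe_block, shifted_schedules

stt, _, _ = shifted_schedules(smoothed_errors=np.zeros(125), seed=7)
probes = probe_block(np.arange(30.0, 151.0, 15.0), repeats=3,
                     reference_viscosity=22.5, seed=11)
schedule = Schedule(entries=stt.entries + probes, metadata=stt.metadata)
profile = SubjectProfile(params=LearningParams(hypothesis="MRL", gain=0.165),
                         error_gain=17 / 22.5)
cohort = generate_cohort(16, profile, schedule, master_seed=42)
print(MotorAdaptationModel.from_subjects(cohort, hypothesis="MRL").fit().summary())
```

```
        Motor Adaptation Model Results
==========================================================
Hypothesis:             MRL    No. clamp obs:   1072
R-squared:           0.8601    Converged:       True
----------------------------------------------------------
                      coef   std err    [0.025    0.975]
----------------------------------------------------------
retention           0.9810    0.0005    0.9800    0.9819
gain                0.1552    0.0030    0.1492    0.1611
primitive_sigma    22.5706    0.5143   21.5625   23.5786
==========================================================
```

All three generating parameters (0.98, 0.165, 22.77°) are recovered within
a few percent from the cohort's clamp series and generalization probes.

A command-line interface wraps the two experiment runners:

```
credassign exp1 --hypothesis both --n-subjects 12 --seed 1 --out results/
credassign exp2 --seed 1
credassign analyze trial_table.csv
credassign simulate --config run.yaml
```

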