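# breathdm

Does the breathing cycle change how we decide?  In psychophysical
experiments where participants categorise near-threshold stimuli — random
dot motion (up vs down) and morphed facial expressions (happy vs angry) —
while a respiration belt records breathing, responses made during
inspiration tend to be faster, and modelling suggests that inspiration
lowers the evidential decision boundary in the motion task and shifts the
starting-point bias toward 'happy' in the face task.

`breathdm` is a tested, fully synthetic-data-driven implementation of that
analysis pipeline, for researchers in respiratory psychophysiology and
computational psychiatry who want to run, extend or power-check this kind
of design:

* **synthetic data** — quasi-periodic breathing traces with known
  trough/peak ground truth, balanced trial schedules (4 blocks x 80 trials,
  jittered 500–2500 ms ITIs), and choices/RTs from a drift-diffusion
  process whose parameters shift with respiratory state;
* **respiratory labelling** — zero-phase 5th-order Butterworth low-pass at
  1 Hz, z-scoring, peak/trough detection (prominence 0.2, distance 10,
  width 2 samples), binarisation into inspiratory (trough→peak) and
  expiratory (peak→trough) segments, transition and artefact handling, and
  circular phase in [-pi, pi);
* **Psi adaptive staircases** — grid-Bayesian threshold estimation with the
  printed motion and face configurations, 75 %-correct thresholds, the
  point of subjective equality, and the four face test levels at
  35/45/55/65 % 'happy';
* **behavioural statistics** — exclusion rules (missed, RT < 100 ms,
  transitions; |criterion| > 0.6 subjects flagged), state-wise hit rates /
  'happy' proportions / median RTs, paired t-tests with JZS Bayes factors;
* **hierarchical Bayesian DDM** — stimulus-coded Wiener model with
  subject-level parameters partially pooled through group normals and
  group-level inspiration-minus-expiration deltas on every parameter
  (`delta_v` per stimulus class, `delta_a`, `delta_z`, `delta_t`), sampled
  with four adaptive Metropolis-within-Gibbs chains, checked with the
  Gelman-Rubin statistic (< 1.02) and posterior predictive RT histograms,
  and reported as 95 % highest-posterior-density intervals with two-sided
  Bayesian P values.

## The model in brief

Evidence `x` accumulates from `z * a` with drift `v` (per stimulus class)
and unit diffusion between absorbing boundaries 0 and `a`; absorption picks
the response, and RT adds a non-decision time `t`.  Respiration enters as
additive group-level deltas: on inspiration-labelled trials every parameter
becomes `theta + delta_theta`, expiration being the reference.  For each
delta the report gives the 95 % HPDI and `P = 2 * min(P(delta>0),
P(delta<0))`, starred at P < 0.05.  See `docs/methods.md` for priors,
sampler details and design choices.

## Worked example

Generate an 8-subject motion cohort with a planted inspiratory boundary
reduction, label it through the preprocessing pipeline, fit the
hierarchical model and print the delta table:

```python
import numpy as np
from breathdm import (
    RespiratoryDeltas, simulate_labelled_cohort, build_model, run_mcmc,
    gelman_rubin, summarize_deltas, SamplingProfile,
)

deltas = RespiratoryDeltas(dv={"up": 0.0, "down": 0.0}, da=-0.2, dz=0.0, dt=0.0)
cohort = simulate_labelled_cohort("RDM", n_subjects=8, deltas=deltas, seed=42)
spec = build_model(cohort, "RDM", locking="stimulus")
chains = run_mcmc(spec, SamplingProfile(4, 3000, 600, 2), seed=7)

grs = gelman_rubin({k: v for k, v in chains.samples.items()
                    if k in chains.group_parameter_names})
print(f"max group-level R-hat: {max(grs.grs.values()):.3f}")
print(summarize_deltas(chains).to_string(index=False))
```

Output of this exact snippet:

```
max group-level R-hat: 1.008
Delta parameter  HPDI low  HPDI high        P sig
           v_up -0.155933   0.420589 0.418750
         v_down -0.104462   0.432275 0.224583
              a -0.254643  -0.102408 0.000417   *
              z -0.037897   0.017711 0.457083
              t -0.008226   0.007561 0.974167
```

All four chains converge (R-hat well under the 1.02 criterion), the planted
`delta_a = -0.2` lies inside a clearly negative starred HPDI, and the null
deltas are not flagged.  The same pipeline is available from the shell:

```bash
breathdm simulate --domain RDM --subjects 2 --seed 7 --out sim/
breathdm staircase --preset rdm --observer observer.json --trials 50 --seed 3
breathdm fit --domain RDM --trials labelled.csv --profile desk --seed 11 --out fit/
breathdm report --chains fit/ --out report/
```

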