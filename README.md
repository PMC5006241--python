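# flickertime

Hierarchical Bayesian analysis of **flicker-induced time dilation** in
duration-reproduction experiments.

A flickering stimulus is judged to last longer than a stable one, and a
flickering *task-irrelevant distractor* can dilate the perceived duration
of a stable target it accompanies — more strongly when the distractor sits
in the same visual hemifield as the target (smaller cortical distance)
than in the opposite one. The behavioural evidence comes from duration
*reproduction*: a participant watches a target disk of 450, 650 or 850 ms
and holds a key for as long as they judged it to have lasted, under four
conditions — SS (stable target, stable distractor), FS (flickering
target, stable distractor), SFi (stable target, flickering ipsilateral
distractor) and SFc (stable target, flickering contralateral distractor).

`flickertime` provides, for that paradigm:

* a **synthetic-experiment generator** with the full counterbalanced
  design (4 sessions with L–R–R–L / R–L–L–R target sides, 15 repetitions
  per condition × duration per session → 180 trials/session and 60
  trials per condition per duration after side merging), long-distractor
  or ±30 %-jittered distractor timing, simulated gaze deviations, and
  reproduced durations drawn from the model below;
* **preprocessing**: the strict 2° fixation-break exclusion, target-side
  merging, and the per-participant × duration Pearson correlation between
  distractor duration and reproduced duration (the check that
  participants reproduce the target, not the distractor);
* the **model and sampler**: a hierarchical location–scale model
  estimated by block-wise adaptive random-walk Metropolis, three runs of
  2000 iterations each, pooling the latter 1000 of each run into 3000
  draws;
* **inference**: posterior medians with equal-tailed 95 % credible
  intervals, one-sided posterior-probability tests of the six
  condition contrasts with Bonferroni correction, split-chain R̂, and
  parameter-recovery reports against simulation truth.

## Model

For a trial of participant *s* in condition *c* at target duration *d*,
the reproduced duration is

```
y ~ Normal( mu(c,d,s), sigma(c,d,s) )
mu(c,d,s)    = beta_mu[c]    * ( gamma_mu[d]    + u_mu[s] )
sigma(c,d,s) = beta_sigma[c] * ( gamma_sigma[d] + u_sigma[s] )
```

with `beta_mu[SS] = beta_sigma[SS] = 1`, so `beta_mu[c]` is the **ratio of
reproduced duration under condition c to the SS baseline** — the time
dilation ratio. `gamma_*` are fixed duration effects (ms), `u_*[s] ~
Normal(0, tau_*)` are participant random effects shared across
conditions. Priors are weakly informative on the millisecond scale
(truncated Normal(1, 0.5²) on the free multipliers, Normal(d, 300²) /
half-Normal(300) on the duration effects, half-Cauchy(100) on the taus);
see `docs/methods.md`.

## Worked example

```python
import flickertime as ft

cfg = ft.DesignConfig.for_experiment(1, n_participants=10)
trials, truth = ft.simulate_experiment(cfg, seed=1)     # 7200 trials
kept, report = ft.apply_gaze_exclusion(trials)          # strict 2 deg rule
res = ft.DurationModel(kept).fit(seed=2)                # 3 x 2000 / 1000
print(res.summary())
```

prints

```
Hierarchical location-scale model of reproduced durations
============================================================
observations: 7071    participants: 10
pooled draws: 3000 (3 chains, warmup 1000)

Dilation ratios vs SS (posterior median [95% CrI])
------------------------------------------------------------
  beta_mu.FS       1.205  [  1.193,   1.216]
  beta_mu.SFi      1.104  [  1.094,   1.116]
  beta_mu.SFc      1.052  [  1.040,   1.062]

Comparisons (one-sided posterior p, Bonferroni x 6)
------------------------------------------------------------
  FS_gt_1      raw p = 0.0000   corrected p = 0.0000
  SFi_gt_1     raw p = 0.0000   corrected p = 0.0000
  SFc_gt_1     raw p = 0.0000   corrected p = 0.0000
  FS_gt_SFi    raw p = 0.0000   corrected p = 0.0000
  FS_gt_SFc    raw p = 0.0000   corrected p = 0.0000
  SFi_gt_SFc   raw p = 0.0000   corrected p = 0.0000
```

The generating truth here was FS 1.20, SFi 1.10, SFc 1.05: all three
conditions dilate perceived duration relative to SS (ratios > 1, every
corrected p < 0.01), the flickering target dilates more than either
flickering distractor, and the ipsilateral distractor dilates more than
the contralateral one — recovered to within ~0.005 with the truth inside
each credible interval. `res.recovery(truth)` reports the per-parameter
bias and coverage; `res.plot_condition_effects()` draws the
ratio-with-CrI figure.

The same pipeline runs from the shell:

```bash
flickertime run --experiment 1 --seed 1 --out runs/exp1
flickertime simulate --experiment 2 --seed 3 --out exp2_trials.csv
flickertime preprocess --trials exp2_trials.csv --out kept.csv \
    --correlations corr.csv
```

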