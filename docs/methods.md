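# Methods

## The measurement problem

In a duration-reproduction task the participant views a target disk for
450, 650 or 850 ms and then holds a key for as long as they judged the
target to have lasted. Flicker — of the target itself (FS) or of a
task-irrelevant distractor in the same (SFi) or opposite (SFc) hemifield
— dilates the reproduced duration relative to the all-stable baseline
(SS). The scientific quantity is the *ratio* of reproduced duration under
each condition to the SS baseline, separated from large, stable
individual differences in both the level and the variability of
reproduction.

## Generative / analysis model

Reproduced durations within a condition × duration × participant cell are
modelled as normal, with condition acting multiplicatively on both
moments and duration and participant effects combining additively inside
the multiplier:

    y ~ Normal(mu, sigma)
    mu    = beta_mu[c]    * (gamma_mu[d]    + u_mu[s])
    sigma = beta_sigma[c] * (gamma_sigma[d] + u_sigma[s])

Identification: `beta_mu[SS] = beta_sigma[SS] = 1`, so each free
`beta_mu[c]` *is* the dilation ratio versus SS. The mean and the SD carry
**separate** condition, duration and participant parameters — the weaker
assumption compared with sharing one set across the two moments — and the
random effects sit inside the condition multiplier, so a participant who
reproduces long under SS reproduces proportionally longer under FS. The
same parameter container drives the synthetic-data generator (truth) and
the model (estimate), which is what makes parameter recovery a
well-posed end-to-end check. Each experiment is fitted on its own.

The additive split of a cell mean into `gamma_mu[d] + u_mu[s]` is only
weakly identified (a constant can move between the two); the hierarchical
shrinkage `u ~ Normal(0, tau)` resolves it softly, and the dilation
ratios — contrasts across conditions within participants — are identified
regardless. The same holds for the SD decomposition.

## Priors

The data are on the millisecond scale; priors are weakly informative on
that scale and proper:

| parameter | prior | rationale |
|---|---|---|
| free `beta_mu`, `beta_sigma` | Normal(1, 0.5²) truncated to (0, ∞) | ratios near 1, positivity |
| `gamma_mu[d]` | Normal(d, 300²) | reproduction roughly veridical |
| `gamma_sigma[d]` | half-Normal(300) | positive, ms scale |
| `u_mu[s]`, `u_sigma[s]` | Normal(0, tau²), hierarchical | shrinkage of individual effects |
| `tau_mu`, `tau_sigma` | half-Cauchy(0, 100) | heavy-tailed scale prior |

Support violations (any multiplier ≤ 0, any cell SD ≤ 0) carry log-density
−∞ rather than raising inside the sampler; the user-facing
`log_likelihood` raises and names the offending cell.

## Sampling

Block-wise Gaussian random-walk Metropolis on an unconstrained
reparameterisation (positive parameters log-transformed, Jacobian
included). Blocks: `beta_mu`, `beta_sigma`, `gamma_mu`, `gamma_sigma`,
`u_mu`, `u_sigma`, taus. Because a constant can shift between a duration
effect and the participant effects without changing any cell moment,
axis-aligned blocks cross that posterior ridge slowly; each iteration
therefore also proposes two coordinated *recentering* moves (`gamma_mu`
up, every `u_mu` down — exactly likelihood-invariant — and the analogous
move for the SD decomposition), which are fixed symmetric directions and
need no acceptance-ratio correction. These moves raise the effective
sample size of the duration effects by two orders of magnitude and that
of the dilation ratios severalfold. During the first half of each run
every proposal scale is multiplied by `exp(rate − 0.3)` every 50
iterations (targeting ~30 % acceptance, clipped to [1e−8, 1e4]); scales
are frozen afterwards, so the retained half comes from a fixed kernel. The default
scheme is three independent runs of 2000 iterations with the latter 1000
of each pooled to 3000 draws; estimates are pooled 50th percentiles,
intervals pooled 2.5/97.5 percentiles (linear-interpolation quantiles).
Random-walk Metropolis is adequate at this dimensionality (~34 parameters
for 10 participants) because the likelihood reduces to per-cell
sufficient statistics (count, sum, sum of squares over ~120 cells), making
each posterior evaluation O(cells) rather than O(trials); a full fit of a
7200-trial experiment takes a few seconds.

Each chain starts from a moment-matching point (multipliers at 1,
duration effects at per-duration sample means/SDs, random effects at 0,
taus at 50/20 ms) plus a small unconstrained-scale jitter per chain.
Convergence QC is the split-chain Gelman–Rubin statistic; the dilation
ratios — the contrasts the analysis reports — mix well (R̂ near 1) and
recover truth with near-nominal interval coverage. The recovery
replicates in the acceptance suite are the operational check of this.

## Inference

Six one-sided comparisons form the fixed family: FS > 1, SFi > 1,
SFc > 1, FS > SFi, FS > SFc, SFi > SFc. The raw p of "a > b" is the
posterior probability of the violation, i.e. the fraction of pooled draws
with a ≤ b, and the corrected p is Bonferroni: min(1, 6 × raw). Bonferroni
was chosen as the most conservative, fully reproducible correction;
equal-tailed percentile intervals (not HPD) match the percentile-based
point estimates.

## Synthetic data

The generator reproduces the design exactly: 4 sessions per participant
with the target side following L–R–R–L or R–L–L–R (alternating across
participants), 15 repetitions of each condition × duration cell per
session (180 trials/session; 60 per condition per duration after sides
merge), SS/FS trials split between ipsi- and contralateral stable
distractors — ceil/floor within a session with the extra trial
alternating across sessions so the four-session totals are exactly
balanced — and session-wise shuffling from one seeded generator.
Distractor timing: in the long-distractor design the distractor leads the
target by uniform 2000–2500 ms and outlasts it by uniform 1000–1500 ms;
in the jittered design the onset and offset asynchronies are independent
uniforms on ±30 % of the target duration (uniform is the minimal
assumption where only ranges are known). Gaze is a two-component uniform
mixture — deviation in [0, 2)° normally, in (2, 6]° on fixation-break
trials — the simplest structure that exercises the strict 2° rule
(exactly 2° is kept; "more than 2°" excludes).

Generator defaults, chosen once as field-realistic values: dilation
ratios FS 1.20 / SFi 1.10 / SFc 1.05 (the long-distractor ordering; the
jittered-design default sets SFi = SFc = 1.08, reflecting that a
near-target-duration distractor shows no ipsi/contra difference);
`beta_sigma` equal to `beta_mu` (scalar timing — reproduction SD roughly
proportional to the mean); `gamma_mu[d] = d` (veridical mean
reproduction); `gamma_sigma[d] = 0.15 d` (a 0.15 Weber fraction);
`tau_mu = 60 ms`, `tau_sigma = 15 ms`; gaze-break probability 0.02.
Reproduced durations are truncated at 1 ms by redraw; at these parameters
the truncated mass is negligible (≥ 6 SD), so the analysis likelihood
remains a plain normal.

What the generator does **not** emulate: sequential effects
(trial-to-trial carry-over, fatigue, learning), the central-tendency
regression of reproduction toward the session mean, motor latency in the
key press, non-normal response tails, and any actual coupling between
distractor duration and response (the distractor-duration diagnostic on
generated data is therefore a *null* calibration — roughly 5 % of cells
nominally significant — whereas real observers can show weak coupling).
Passing recovery on synthetic data shows the estimation machinery is
unbiased and calibrated *under the model's own assumptions*; it does not
certify the model against real-data violations of those assumptions.

## Problem sizes and numerical choices

Recovery and calibration studies use 20 replicate experiments at study
scale (10 participants, 60 trials per condition per duration, the full
3 × 2000/1000 sampling scheme) — enough replicates for binomial 3-SE
bands on coverage and detection rates while keeping a complete run of the
suite plus the acceptance script within a few minutes of CPU. Quantiles
use numpy's linear interpolation; R̂ is undefined (NaN) for zero-variance
parameters; degenerate correlation cells (n < 3 or zero variance) are
flagged rather than raised. All randomness descends from named
substreams of one master `SeedSequence`, so every artifact is
byte-reproducible from (config, seed).

## Known limitations

* Random-walk Metropolis yields far fewer effective samples per draw than
  gradient-based samplers; with the fixed 3 × 2000 scheme the credible
  intervals of the weakly identified additive decompositions should not
  be over-interpreted (the dilation ratios are unaffected).
* The Bonferroni correction and the one-sided posterior-probability test
  are one defensible choice among several; the comparison family is fixed
  at the six listed contrasts.
* The model assumes normal (not lognormal/Weibull) responses and makes no
  scalar-timing constraint (CV constancy) — SD multipliers are free.
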