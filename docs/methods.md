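# Methods

## The model

`opponent_ema` analyses intensive longitudinal (EMA) data collected
around discrete behavioural events — here sexual episodes (pornography
use, masturbation, intercourse) — through the lens of opponent-process
theory: an in-episode hedonic peak (the a-process) followed by an
opposing after-reaction (the b-process) that decays back to baseline,
and possibly an anticipatory build-up (e.g. craving) before the next
episode.

Each cognitive/affective state variable `w`, rated 0–10, is modelled as
a function of time `t` in hours relative to an episode at `t = 0`:

* post-episode spike and decay: `w(t) = a·exp(−|b|·t) + c + ε`, `t ≥ 0`
* pre-episode growth: `w(t) = a·exp(|b|·t) + c + ε`, `t ≤ 0`
  (the mirror image of the decay curve about `t = 0`)
* no-change null: `w(t) = d + ε`

with Gaussian noise `ε ~ N(0, σ²)` and a per-participant random
intercept on the baseline (`c_j = c + u_j`, `d_j = d + u_j`,
`u_j ~ N(0, τ²)`). `a` is the spike amplitude in rating units, `|b|` the
rate constant per hour (`ln2/|b|` is the half-life), `c` the population
baseline.

Priors follow the bounded specification of the analysis this package
operationalises: uniform `a ∈ (−10, 10)` (the full range of initial
effect sizes on a 0–10 scale), uniform `b ∈ (−10, 0)` for decay and
`(0, 10)` for growth — the box edge `|b| = 10` corresponds to a
half-life of `ln2/10 h ≈ 4.2` minutes, so the prior spans half-lives
from roughly five minutes to infinity — and uniform `c ∈ (0, 10)`. The
null grand mean `d` gets a Normal prior with mean and variance taken
from the variable's empirical distribution. The residual scale and
intercept scale, which the original specification leaves open, get
weakly-informative half-Normal priors: `σ ~ half-N(0, 5)`,
`τ ~ half-N(0, 2)` (both generous relative to a 0–10 scale).
Predictions are not clamped to the rating bounds during fitting,
mirroring the Gaussian-likelihood choice.

Model comparison uses Bayes factors `BF10 = Z_exp / Z_null` between the
exponential and null marginal likelihoods, reported as BF10 when the
exponential model is favoured and BF01 otherwise, with the conventional
bands: 1–3 inconclusive, 3–5 weak, 5–10 moderate, 10–100 strong, >100
very strong. Parameter uncertainty is summarised by central 95%
credible intervals.

## Episode-centered datasets

Observations are re-expressed in signed hours relative to each in-group
episode (default horizon 72 h, long enough for any plausible b-process
tail; figures are typically drawn at ±24 h). The event survey itself
(Δt = 0) is excluded from the pre/post model data — it supplies the
in-episode peak-mood measurement instead. In the *full* dataset a
rating between two episodes contributes to the earlier episode's
post-set and the later episode's pre-set. The *truncated* dataset
additionally drops any rating that lies strictly closer to a different
same-participant in-group episode than to the index episode;
equidistant ties are retained for both episodes (a symmetric,
deterministic rule). Truncation distances are measured against episodes
of the same group definition being analysed (Group A = pornography
episodes with or without masturbation/orgasm; Group B = Group A plus
masturbation without pornography; intercourse episodes are never
analysed).

The 12-hour window-difference score per participant and variable is the
mean of ratings within 12 h of an in-group episode on the requested
side minus the mean of ratings more than 12 h from every in-group
episode. Scores are aggregated to one value per participant before
group testing to avoid pseudo-replication; participants with an empty
near or far stratum are flagged missing and excluded from the group
test. Low- vs high-moral-incongruence groups (fixed split: items 0–3
low, 4–6 high, matching the realized median split; a data-driven median
is available) are compared with the default two-sample JZS Bayes
factor — Cauchy(0, √2/2) prior on the standardized effect size,
evaluated by adaptive quadrature of the one-dimensional mixture-of-g
representation.

## Computation

**Sampling.** Posteriors are drawn with `emcee`'s affine-invariant
ensemble sampler (differential-evolution moves, 64 walkers and 16 000
steps by default, half discarded as burn-in; analyses in this
repository's tests and acceptance script use 32 walkers and 8 000–12 000
steps, sized so every gate below passes on the study-scale problems).
Walkers start half in a tight ball around a multi-start MAP estimate
and half overdispersed across the prior support, so that low-density
but high-volume regions — notably the ridge where a very fast decay
with weakly-identified amplitude mimics the null — are populated from
the start. Every fit is gated on split-R̂ ≤ 1.01 and bulk ESS ≥ 400 per
parameter (walkers treated as chains); on failure the budget is doubled
up to twice before raising a convergence error that carries the
diagnostic table.

**Random intercepts are marginalized analytically.** Because the
intercepts are Gaussian and enter a Gaussian likelihood additively,
each participant's marginal covariance is `σ²I + τ²11ᵀ`, which
Sherman–Morrison reduces to a closed form that costs the same as the
conditional likelihood. The sampler therefore explores only the ≤ 5
population-level parameters — the joint `(c, u_1…u_J)` block mixes far
too slowly under ensemble moves to meet the R̂ gate — and per-
participant intercepts are recovered afterwards as exact conditional
Gaussian draws attached to the posterior. The model, its posterior and
its evidence are identical to the explicit-intercept formulation, which
remains available (`ModelDensity(..., marginalize=False)`) and backs
the conditional log-likelihood/log-prior operations.

**Marginal likelihoods.** The default estimator is iterative
(Meng–Wong) bridge sampling between the posterior and a defensive
mixture proposal: a moment-matched Gaussian fitted to the posterior
draws (covariance inflated ×2) mixed 50/50 with the model prior. The
prior component guarantees coverage of the flat fast-decay ridge, whose
mass local MCMC draws systematically under-represent; the posterior-
side bridge points are importance-resampled from an independent
proposal batch so the estimate does not inherit that sampler bias.
Plain defensive importance sampling is available as a fallback, and for
non-hierarchical models with at most three free parameters a
deterministic mid-point tensor-grid quadrature serves as an exact
anchor (the mid-point rule converges exponentially fast for smooth
peaked integrands). Standard errors: bootstrap over both bridge batches
(25 resamples); delta-method for importance sampling. An estimator SE
above 1 nat raises an unstable-evidence error. On fixtures where the
quadrature anchor applies, bridge and importance agree with it to
within ~0.03 nats.

**Determinism.** Every stochastic operation takes an explicit seed;
cohort simulation spawns per-participant child streams from a root
`SeedSequence`, so identical configurations yield byte-identical
tables.

## The synthetic-data generator

The generator reproduces the study design the package targets: 22
participants (12 low / 10 high moral incongruence, scores drawn within
the fixed split bands), 28 days, prompts at 9:00/12:00/15:00/18:00/
21:00 with a 3-h response window, independent per-prompt compliance of
0.27 (between the reported 25% pilot and 29% exploratory rates),
response latency uniform over the window (the latency distribution is
otherwise unreported), and an event survey of all nine state variables
at each episode's report time. Episode timing is a homogeneous Poisson
process at 0.33 episodes per participant-day, which reproduces the
reported total of ~200 episodes over 616 participant-days; the category
mix (~81% pornography, ~13% masturbation-only, ~6.5% intercourse)
matches the reported 162/26/13 split, with log-normal durations whose
medians and spreads echo the reported ranges (pornography long-tailed
up to several hundred minutes; masturbation-only and intercourse short).

True state values superpose the post-episode responses of all past
episodes, the anticipatory response of the next upcoming episode only
(craving anticipates the imminent event; tying growth to all future
episodes would be acausal), a per-participant baseline offset with a
per-variable SD chosen to echo the observed between-person spread
(mood varies little between people, SD 0.8; guilt/shame/loneliness/
connectedness vary a lot, SD 2.2–2.4), and Gaussian noise (SD 1.0),
clamped to [0, 10]. Ratings are continuous
by default — the Gaussian fitting model assumes continuity — with an
optional integer-rounding flag. Default group dynamics qualitatively
mirror the study's fitted pattern (high-incongruence: post-episode mood
drop, guilt/shame/loneliness/difficulty-thinking rises, connectedness
drop, sharp pre-episode craving build-up, smaller in-episode mood peak;
low-incongruence: smaller or absent effects, larger mood peak; anxiety
null in both). Missingness is independent of everything (MCAR) at rate
1 − compliance, and missing data are never imputed.

What the generator does *not* emulate: bursty or habit-locked episode
timing (real episodes cluster at night and around routines), integer
rating granularity by default, contemporaneous residual correlation
between variables (observed within-person correlations such as the
strong guilt–shame association arise in the generator only through
shared episode responses), response-time clustering, non-MCAR
missingness (e.g. avoidance after episodes), trigger covariates, and
allostatic drift of the baseline under repeated episodes. Passing
calibration tests therefore demonstrates correctness of the estimation
machinery under the design's sampling pattern, not robustness to these
real-data features.

## Problem sizes used in tests and the acceptance script

Parameter recovery runs 20 simulated cohorts at full study scale
(22 participants × 28 days, compliance 0.27) with known mood decay
(a = −1.5, |b| = 0.3/h, c = 5, σ = 1), fitting the full episode-centered
dataset; Bayes-factor calibration runs 10 null-generated and 10
strong-effect (a = −3, σ = 0.5) cohorts analysed through the
high-incongruence truncated Group B cell. Recovery is
assessed on the cohort-averaged signed bias (in posterior-SD units) per
parameter — individual cohorts legitimately disagree with the
population truth by about one posterior SD because the realized mean of
22 sampled intercepts differs from zero — together with 95% CI coverage
over all cohort × parameter cells.

## Known limitations

* The bounded-uniform priors put non-trivial mass on the fast-decay
  ridge; at realistic data density this skews posterior means of `a`
  and `b` toward larger magnitudes on *truncated* (smaller) datasets,
  and widens credible intervals. This is a property of the model, not
  of the estimator; the full dataset largely removes it.
* R̂ across interacting ensemble walkers is a necessary but not
  sufficient convergence check; the defensive evidence estimators are
  designed so Bayes factors do not depend on perfect tail mixing.
* The between-group "difference in effect sizes" Bayes factors quoted
  in the source analysis are not reproduced: how they were computed is
  not described. The natural implementation (shared- vs group-specific-
  amplitude model comparison) is noted as future work.
* Wilcoxon/Fisher/FDR descriptive contrasts, instrument scoring and the
  qualitative trigger analysis are out of scope.
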