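# opponent-ema

Opponent-process affective chronometry for ecological momentary
assessment (EMA) data.

Repeated real-time self-reports (here: nine cognitive/affective states
rated 0–10, five times a day for four weeks, plus event-triggered
surveys after sexual episodes) let one ask *how feelings move around
discrete behavioural events*: does mood drop right after pornography
use and recover exponentially? Does craving build up before an episode?
Opponent-process theory predicts exactly this shape — an in-episode
hedonic peak (a-process) followed by an opposing after-reaction
(b-process) that decays back to baseline. This package implements that
analysis as a tested, reusable pipeline for intensive longitudinal
data, and a simulator of the underlying study design so every stage can
be validated against known ground truth.

## The model

For each state variable `w` and each episode placed at relative time
`t = 0` (hours):

* post-episode: `w(t) = a·e^(−|b|t) + c + ε`
* pre-episode: `w(t) = a·e^(|b|t) + c + ε` (mirror image about `t = 0`)
* null: `w(t) = d + ε`

with Gaussian noise and per-participant random intercepts on the
baseline. Priors are uniform boxes `a ∈ (−10, 10)`, `|b| ∈ (0, 10)`
(half-lives from ~5 minutes to infinity), `c ∈ (0, 10)`, and an
empirical Normal prior on `d`. Models are compared by Bayes factors
from bridge-sampled marginal likelihoods (BF10 reported when the
exponential wins, BF01 when the null wins; 3–5 weak, 5–10 moderate,
10–100 strong, >100 very strong), with 95% credible intervals on all
parameters. Group contrasts (low vs high moral incongruence, split 0–3
vs 4–6) use 12-hour window-difference scores and the default two-sample
JZS Bayes factor (Cauchy(0, √2/2) effect-size prior).

See `docs/methods.md` for the full model, priors, dataset-construction
rules and numerical choices.

## Worked example

```python
import opponent_ema as oe

# a cohort with the study's design and default group dynamics
config = oe.CohortConfig(seed=1)
obs, episodes, participants = oe.simulate_cohort(config)

# episode-centered, truncated dataset: mood after Group B episodes,
# high-moral-incongruence participants only
ids = participants.loc[participants.group == "high", "id"]
mood = obs[(obs.variable == "mood") & obs.participant_id.isin(ids)]
eps = episodes[episodes.participant_id.isin(ids)]
group = oe.EpisodeGroup.B()
aligned = oe.truncate(
    oe.center_observations(mood, eps, group, "post", horizon=72.0),
    eps, group)

# exponential decay vs no-change null
result = oe.bayes_factor(
    oe.ModelSpec(form="decay"),
    oe.ModelSpec.null_from_data(aligned["value"]),
    aligned, seed=3)
print(result.reported, round(result.value, 2), result.evidence_label)
print(result.fit_alt.summary.loc[["a", "b", "c"]].round(2))
```

prints

```
BF01 1.05 inconclusive
   mean    sd  median  ci95_lower  ci95_upper
a -3.03  2.21   -2.38       -8.82       -0.29
b -2.94  2.78   -1.70       -9.32       -0.21
c  5.19  0.33    5.19        4.56        5.85
```

The true post-episode mood dynamic in this simulated high-incongruence
group is a drop of 1.5 rating points recovering with a 0.3/h rate
(half-life ≈ 2.3 h); with ten participants' truncated data at ~27%
compliance the evidence is essentially equivocal (BF ≈ 1), and the
amplitude/rate posteriors are wide and skewed toward the fast-decay
ridge — exactly the small-sample behaviour the uncertainty
quantification should show. Larger amplitudes, more data (the full
dataset) or lower noise push BF10 into the strong/very-strong bands.

The same pipeline is scriptable from the shell:

```bash
opponent-ema simulate --seed 1 --out cohort/
opponent-ema align --obs cohort/observations.csv \
    --episodes cohort/episodes.csv --group B --direction post \
    --truncated --out aligned.csv
opponent-ema describe --obs cohort/observations.csv \
    --split cohort/participants.csv --out desc
opponent-ema window-diff --obs cohort/observations.csv \
    --episodes cohort/episodes.csv --group B --out diffs.csv
opponent-ema compare --diffs diffs.csv \
    --split cohort/participants.csv --out comparison.json
opponent-ema fit --obs cohort/observations.csv \
    --episodes cohort/episodes.csv \
    --participants cohort/participants.csv \
    --variable mood --mi-group high --direction post --out mood.json
```

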