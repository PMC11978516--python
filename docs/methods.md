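# Methods

`predforage` simulates and analyzes a continuous foraging-under-threat
task: an avatar collects reward that refreshes every second while
predators repeatedly approach from the edge of the environment, and the
player balances foraging against checking segments of the surroundings
and hiding in a safe space. This note documents the models, the
synthetic-data generator, the estimation contracts, and the numerical
and design choices a maintainer would want to know.

## Task model

Time is continuous within each of 20 blocks of 90 s. Each block has one
predator speed (slow/medium/fast = 20/15/10 s from entry to the center)
and 1-4 checkable segments. A block divides into predator epochs: a
uniform onset delay in [2.0, 10.5] s, then a linear approach. At
arrival the avatar is caught unless fully hidden (hiding requires a
0.5 s transit; returning takes 2.0 s, during which the avatar is
exposed). Actions lock the controls for their time cost (forage 1.5 s,
check 0.5 s, hide 0.5 s, return 2.0 s); presses during lockout are
recorded as inactive presses and serve as a response-vigor measure.
Reward is drawn each second from Normal(per-epoch mean, sd 2), clipped
at zero; each forage credits the current sample to an energy bar that
converts to an extra life every `energy_per_life` units.

Choices the task description leaves open, resolved here:

* **Energy-bar capacity.** Never quantified in the task description;
  default 300 units (a competent player earns a life every 6-8 forages),
  configurable via `TaskConfig.energy_per_life`.
* **Lives floor.** The life counter is clamped at zero; the engine also
  tracks unclamped gain/loss counters so conservation
  (`lives_gained - times_caught`) is testable.
* **Epoch schedule.** Epochs are drawn sequentially until their spans
  cover the block, capped at six (a draw needing a seventh epoch is
  redrawn); the final epoch is truncated at the 90 s block end. This
  reproduces the 3-6 predators-per-block range as a consequence of the
  timing parameters.
* **Certainty reset.** When a predator exits (or is caught), the
  environment is known to be empty, so the full-check clock
  (`last_full_check_t`) resets to the epoch boundary.
* **Blocks are independent**: the avatar starts each block active and
  centered; inter-block time is collapsed to the two mood ratings.
* **Schedules.** Rather than two fixed schedules distributed across the
  sample, each cohort shares one generated schedule by default
  (`CohortSpec.share_schedule`), or draws one per participant. Every
  speed x segment combination (12) appears at least once per schedule,
  and the whole schedule is rejection-sampled until the maximum absolute
  pairwise correlation among block features (speed rank, segment count,
  mean epoch reward) is below 0.3.

## Generative agents

Agents choose via the same logistic models later fit to their behavior.
Pre-discovery, P(check vs forage) is logistic in reward, time pressure
((t - last full check) / (2.5 + speed)), whether a check sequence is
underway, speed rank, cone count, block index and a first-epoch flag.
Post-discovery, P(hide) and then P(forage vs check | not hide) are
logistic in reward, position uncertainty ((t - last seen) / speed),
proximity (t - scheduled arrival) and the same controls. Regressors are
standardized by fixed reference moments (`features.FEATURE_SCALING`,
nominal design moments plus pilot-simulation moments for the threat
features) used identically at generation and at refit time, so
generative and estimated weights share a scale.

Human decision timing is not specified by the task, so the agents'
timing rule is declared, not inferred: an agent is polled when controls
unlock plus an Exponential(1/decision_rate) latency (default rate
2.5 polls/s), and emits inactive presses as a Poisson stream (default
0.15/s) on the button it last used, while locked out. While hiding, the
agent returns at its first poll after the predator leaves, so
return-from-hiding latencies inherit the participant's poll rate.

Default policy weights describe a competent mid-range player (about
4-7 captures per session, about 200 checks, about 70 lives), with
screening-exclusion rates near 10% once between-participant noise is
added — comparable to an attentive online sample. Between-participant
heterogeneity (independent normal noise, sd 0.45 on intercepts and
0.30-0.35 on weights, log-normal on the timing rates) is set so that
policy weights vary on the order of their means, the regime in which
single-session parameter recovery is informative rather than trivial.

## Mood model

The descriptive (analysis) direction regresses post-block stress and
excitement on block features: reward max/min, monotonic speed and cone
count, lives gained, block index, and having been caught. The
generative direction is this package's own construction (only the
descriptive direction is constrained by the analyses): ratings are a
linear function of the standardized block features plus an AR(1)-style
carryover of the previous residual, truncated to [0, 100], with noise
sd 8. Defaults make threat (speed, cones, caught) raise stress, reward
and lives raise excitement, capture lower excitement, and both arousal
ratings drift down with block index.

The homeostatic loop is planted generatively: the stress residual
(rating minus its task-predicted component) shifts the next block's
forage propensity (+0.06 logit per rating point, i.e. gain 0.6 per 10
points) and hide propensity (+0.03), while the block's standardized
foraging rate lowers the next stress rating by 4 points per sd
(`gain_forage_to_stress = -4`). These gains are moderate: they produce
block-to-block mood-behavior coupling detectable at the cohort level
without dominating the task-driven variance.

## Screening and measures

Participant-level exclusion: more than 6 epochs without any action,
fewer than 40 checks, caught more than 9 times, fewer than 5 lives
earned, or mean absolute repeat-question difference above 1. Epochs are
excluded for initial hiding beyond 2.2 s or multiple hides; otherwise
each epoch gets an availability class (full / pre-only / rates and
first action / first action only / within-epoch only) that gates which
measures it feeds. Technical screening strips actions recorded after a
capture and removes epochs (plus the remainder of their block) whose
action gaps undershoot the lockout by more than 100 ms; the
"too many removed epochs" cutoff is the empirical cohort quantile that
removes at most 2.5% of participants. Simulator logs are clean by
construction, so these screens fire only on corrupted or imported data.

The measure registry holds exactly 33 participant-level aggregates.
The ~20 directly named ones (return-from-hiding latency, % time
foraging/checking/hiding, last-action-before-hide, time to first
action, detection latency, predator progress at hide, forage runs,
inactive-press rates per button, earnings, captures, ...) are
implemented as described; the registry is completed to 33 with closely
analogous per-phase variants, each carrying `reconstructed=True`.
Occupancy is a partition: each press owns the interval to the next
press; the leading interval belongs to hiding if the epoch began hidden,
otherwise to the first action taken; return transit and action-free
epochs fall into a transit bucket, so %forage + %check + %hide +
%transit = 1 exactly. Percentages are computed over available
(non-excluded) time only, and "distance at hide" is reported as the
predator's progress fraction since screen geometry is not modeled.

## Estimation contract

All regressions are MAP fits under independent Normal(0, 3^2) priors
(trait-prediction models use Normal(0, 1^2)), with gaussian, bernoulli,
poisson and shifted-lognormal families. Plain gaussian fits use an
exact profile iteration (ridge given sigma, sigma^2 = RSS/n); all other
cases use L-BFGS with analytic gradients. Posterior sds come from the
inverse Hessian at the mode. Ordinal task factors (speed, cones) use
monotonic coding: effect(k) = b * cumsum(zeta)[k] with zeta a simplex,
parameterized through a softmax with a weak Normal(0, 1.5^2) prior on
the unconstrained values — a smooth MAP-friendly stand-in for a flat
Dirichlet that keeps the simplex off degenerate corners. The
shifted-lognormal shift is estimated jointly, bounded to
[0, 0.999 min(y)]. Behavior-model regressors are z-scored within
participant; mood-model regressors across participants (the ambiguity
is resolved this way because mood models compare participants'
sensitivities on a common scale); outcomes are never standardized, so
intercepts capture individual differences. Two optimizer tolerance
profiles exist: tight (default) and coarse (used by the cohort-scale
directional suites, where weights feed sign tests; coefficients agree
with the tight profile to about 5e-4).

Behavior regressions run only when more than 15 epochs are available,
every speed x cones condition occurs, and the outcome varies; otherwise
the measure is recorded as missing for that participant. A never-caught
participant's caught-effect weight is not extracted (the regressor is
constant).

Single-choice models are fit per participant with the same contract:
pre-discovery check-vs-forage on forage/check presses only, then
hide-vs-not and forage-vs-check post-discovery. Ordinal factors enter
these choice models linearly (matching the generative agents);
degenerate regressors (e.g. check-sequence-started in single-segment
designs) are dropped and their weights reported missing.

## Split-sample machinery

Group-level mood hypotheses use compound sign-aligned tests: weights
are flipped to their expected direction, summed per participant, and
tested one-tailed (Wilcoxon signed-rank, exact enumeration for n <= 12
with midranks and zero-dropping, or one-sample t), with hierarchical
gating (children tested only under a significant parent). Two-part
hypotheses use the least-significant-p rule.

Trait prediction is strictly split-sample: models are trained on one
sample, frozen (coefficients and z-scoring constants), and scored on
the other via Pearson r or percent correct, plus out-of-sample R^2
(1 - MSE/MSE_null continuous; 1 - LL/LL_null binary). Significance is a
one-tailed permutation test of the score over label shuffles with the
smoothed estimate p = (1 + #{perm >= obs}) / (n_perm + 1) (the +1
convention guarantees valid, never-zero p values). Correlation Bayes
factors integrate Fisher's exact sampling density of r against a
one-tailed uniform (stretched-beta, rscale 1) prior on rho; proportion
BFs use a uniform prior above chance. Sparse prediction uses the
regularized horseshoe with global scale tau0 = p0/(D - p0) * sigma/sqrt(n)
(expected relevant fraction 20%), fit by alternating conditional
maximization (ridge given local scales; closed-form half-Cauchy update
given beta); measure selection for association listings uses the BF > 3
rule (strict inequality) rather than projection-based selection.

## Planted-effect calibration

Two pilot-calibrated constants are frozen in the code:

* `features.FEATURE_SCALING` threat-feature moments (means/sds of time
  pressure, position uncertainty, proximity) from pilot simulated play;
* `pipeline._INTERCEPT_PATH_ATTENUATION = 0.77`: the measured
  attenuation between a standardized shift of the pre-discovery
  check/forage intercept and the best cross-sample linear prediction of
  the trait from the conceptual measure set. `planted_link_spec(0.3)`
  converts a target trait-behavior correlation into a link coefficient
  through this constant; pilot replicates realize a held-out r of about
  0.25-0.33 around the 0.3 target.

Trait-prediction models combine a small conceptual measure group (the
checking/foraging signature: % foraging/checking, check rate, detection
latency, first-check latency, forage-run length, return latency,
earnings), mirroring how hypothesis-level models combine a handful of
measures rather than the whole registry (an all-measure ridge with
these priors overfits the uninformative measures and roughly halves the
held-out correlation).

## What the generator does and does not emulate

The synthetic cohort reproduces the data *structures* and planted
*effects* of an online sample: correlated trait dimensions observed
through a questionnaire factor model, trait-linked policy parameters,
trait-linked debrief self-reports on 0-6 scales, repeat-item
consistency noise, block-wise mood ratings with a homeostatic loop, and
full event logs. It does not emulate human reaction-time distributions,
within-session learning (block index is a control, not a learning
model), instruction/practice effects, or technical recording errors
(screens for the latter are exercised with hand-corrupted fixtures).
Passing the planted-effect suites therefore demonstrates that the
pipeline recovers what it is designed to recover at realistic noise
levels — not that real human data would show these effects.

## Problem sizes of the Monte-Carlo suites

The acceptance suites run at these sizes (chosen to keep the full test
suite at desk scale while leaving the per-replicate designs at full
size): parameter recovery, 200 parameter sets of one full session each
(~600 choices); planted-link recovery, 10 replicate cohorts of
700 + 374 participants with 10,000-shuffle permutation tests; permutation
type-I calibration, 200 null cohorts of n = 100 with 999 shuffles;
homeostasis sign recovery, 60 cohorts of n = 100; factor analysis,
n = 700 with 5,000 parallel-analysis iterations. The experiment
functions default to these or larger sizes and scale up freely.

## Known limitations

* MAP-only estimation: posterior summaries are mode + curvature; no
  MCMC mode is provided.
* The horseshoe optimization is a conditional-maximization scheme, not
  a posterior mean; it is sparse and well-calibrated in the planted
  tests but can under-shrink borderline coefficients relative to a full
  posterior.
* The agents' decision-timing rule (exponential poll latency) is a
  modeling convention; latency-sensitive measures (time to first
  action, return latency) are only as realistic as that convention.
* Multiple imputation is out of scope; missing measures are mean- or
  chained-mean imputed where a model needs complete cases.
* Items and debrief responses are generated from linear factor models
  with Gaussian noise, then discretized where applicable; they have no
  acquiescence/attention artifacts beyond the planted repeat-item noise.
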