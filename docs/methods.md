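# Methods

## The model

`priorconf` implements a generative Bayesian observer for a dual-decision
random-dot-motion task. On each trial the observer makes two left/right
discriminations. The task rule links them: a correct first ("lead") response
guarantees a rightward second ("target") stimulus, an incorrect one a
leftward target. An ideal observer therefore carries its internal confidence
about the lead decision forward as the prior probability of a rightward
target.

All stimulus strengths are expressed in units of the observer's internal
noise,

    s = (dir * coh - bias) / sigma,

with dir = ±1, coh the motion coherence, and (sigma, bias) the internal
noise and decision bias estimated psychometrically per participant. After
this normalization the internal response to a stimulus is r ~ Normal(s, 1).

**Lead decision.** The lead choice is sign(r_lead); its confidence under a
flat prior is Phi(|r_lead|), the posterior probability that the choice is
correct when the signed stimulus strength itself is unknown (flat prior over
strengths). This quantity doubles as the prior for a rightward target.

**Target choice.** The prior shifts the decision criterion for the target
response:

    theta = -|r_lead| / w_choice,

and the observer responds "right" iff r_target > theta. The free weight
w_choice scales the perceived variance of the prior: w_choice = 1 is the
ideal observer, w_choice > 1 underweights the prior (criterion shifted too
little), w_choice < 1 overweights it. The marginal probability of a
rightward response given the stimuli and the observed lead choice
integrates Phi(s_target - theta(r)) over the truncated-normal density of
r_lead implied by that choice (r_lead > 0 after a rightward lead response,
r_lead < 0 after a leftward one).

**Confidence.** Confidence is the perceived posterior probability that the
target choice is correct, built from a prior term

    p(R)_conf = Phi(|r_lead| / (b * w_conf)),

a likelihood term

    p(r_target | R) = Phi(r_target / b),

and the Bayes-rule combination

    conf_right = p(R) p(r|R) / ((1 - p(R))(1 - p(r|R)) + p(R) p(r|R)),

with confidence in a leftward choice equal to 1 - conf_right. w_conf plays
the same variance-scaling role as w_choice but at the confidence stage, so
the two can be compared directly; the confidence bias b scales the
perceived variance of both prior and likelihood (b > 1 compresses
confidence toward 50%).

**Model variants.** Four variants are fit and compared: *flexible*
(w_choice, w_conf, b free), *equal* (one shared w plus b), *optimal*
(w_choice = w_conf = 1, b free) and *flat prior* (the prior fixed at
exactly 0.5 — implemented as the exact limit rather than a large finite
weight — with b free).

## Parameters and defaults

| parameter | meaning | default | notes |
| --- | --- | --- | --- |
| `w_choice`, `w_conf` | prior-variance scaling in choice / confidence | 1 | > 0; 1 = optimal |
| `b` | confidence bias (joint variance misestimation) | 1 | > 0 |
| `sigma` | internal noise, coherence units | 0.1 | typical of the staircased task |
| `bias` | decision bias, coherence units | 0 | |
| `lapse` | probability a choice is a fair coin flip | 0 | in [0, 0.5] |
| `metacog_noise_sd/_family` | corruption of r entering confidence only | 0 / none | gaussian = additive; lognormal = multiplicative mean-1 on |r| |
| `report_noise_sd` | truncated-Gaussian jitter of the report on [0.5, 1] | 0.1 | see below |

The report-noise field exists because the fitting stage evaluates a
truncated-Gaussian observation density for the continuous confidence
report; a generator without report noise would make that density degenerate
on synthetic data. 0.1 on the [0.5, 1] scale (10 points of the 50–100
rating scale) is a realistic trial-wise rating jitter.

Model confidence in the chosen option can fall below 0.5 when
w_conf ≠ w_choice; reports are clipped to the [0.5, 1] rating scale and the
pre-clip value is retained in the simulation output.

## Synthetic experiment

The generator reproduces the experiment structure: three coherence levels
(L, M, H) combined into Stronger-Lead / Stronger-Target condition pairs at
three posterior levels (L_post = {M+L, L+M}, M_post = {H+L, L+H},
H_post = {H+M, M+H}); 36-trial blocks in which the six (posterior level x
condition) cells appear six times each with balanced lead directions; 10
blocks per session and two sessions (720 main trials per participant); and
a 180-trial prior-free control task at coherences
{0.05, 0.10, 0.12, 0.15, 0.20, 0.30} (30 each).

Difficulty is staircased on the prior-free lead decisions: the medium level
by a 2-down-1-up rule (converging to ~70.7% correct), the high level by a
3-down-1-up rule (~79.4%), and the low level yoked to the medium staircase
minus 5 percentage points of coherence. Step size (1 point of coherence),
bounds ([0.01, 0.90]) and starting coherence (0.15) are package defaults
chosen to keep coherences inside the stimulus range the task uses.
Staircases carry over between the two sessions. Because M and H are staircased independently,
their realized coherences can cross transiently early in a run; condition
labels follow the designed levels, not the realized coherences, exactly as
the condition construction prescribes.

What the generator does *not* emulate: reaction times (and any RT-based
trial exclusion — a random-dropout hook stands in for robustness tests),
session-level learning or drift, stimulus-level visual detail, and
sequential effects such as confidence leak. Passing tests on synthetic data
therefore demonstrate the internal consistency of the pipeline under the
model's own assumptions, not the behaviour of real observers.

## Calibration

Internal noise and decision bias are estimated from all prior-free
decisions (control task plus main-task lead decisions) by maximum
likelihood under four cumulative-Gaussian psychometric variants
(noise; noise+bias; noise+lapse; noise+bias+lapse, with a symmetric
lapse/2 floor and ceiling bounded at 0.5), combined with Akaike weights
w_i ∝ exp(-ΔAIC_i/2). Absent parameters enter the weighted average as 0.
The lapse estimate is used only at calibration; it is not propagated into
the Bayesian model. Optimization is bounded L-BFGS-B from five jittered
starts.

## Likelihoods and estimation

Two likelihood routes are implemented.

**Full likelihood** (individual fits, reference computations): the choice
likelihood marginalizes the latent lead response with fixed-node
Gauss-Legendre quadrature on |r_lead| ∈ (0, U], U = max(8, |s_lead| + 6)
(257 nodes in the reference implementation; 96 in the fitting loop, which
agrees with the reference to < 1e-6 and with a 1e6-draw Monte-Carlo oracle
to < 1e-3). The confidence likelihood integrates over both latent
responses restricted to the region consistent with the observed choices
(tensor Gauss-Legendre, 16–20 nodes per dimension) and evaluates a
truncated-Gaussian report density around the model confidence on [0.5, 1].
Sixteen or more nodes per dimension are needed when b is small (sharp
integrands); coarser grids can create spurious optima.

**Simplified likelihood** (hierarchical fits): the latent internal
responses are replaced by the per-coherence-level mean stimulus strengths,
signed by the true directions. This removes the two-per-trial latent
variables that would otherwise make a hierarchical fit intractable, at a
documented cost: internal samples always land on the correct side of the
criterion, so the model systematically *underestimates* confidence, and
group-level weighting parameters are shrunk relative to the full-process
truth. The simplification is applied to both the choice and the confidence
terms. Recovery tests for the hierarchical estimator therefore resample
responses from the simplified process itself (`resample_from_simplified`),
which isolates estimation error from this simplification bias; the bias
direction (simplified predicted confidence ≤ full predicted confidence) is
asserted separately.

**Sampling.** No Hamiltonian Monte Carlo backend is part of this package's
dependency set; posterior sampling uses the affine-invariant ensemble
sampler (emcee) with differential-evolution moves, which mix well on these
low-dimensional, correlated posteriors. For hierarchical models the
participant-level random effects (log-normal around group-level medians)
are integrated out analytically-numerically with tensor Gauss-Hermite
quadrature (5 nodes per dimension), so the sampler only explores the group
parameters [group medians, between-participant SDs on the log scale, and a
shared report-noise SD] — 3 to 7 dimensions. The quadrature exploits the
model structure: choice terms depend only on the weight axis of the node
grid and confidence terms only on the (w_conf, b) axes, and the
truncated-Gaussian report density is aggregated per participant with
sufficient statistics over the (at most ~36 per participant) distinct
values of the simplified confidence mean, making one posterior evaluation
independent of trial count.

Priors: log-normal(log 1, 1) on w_choice, w_conf, b (support on the
positives, centred on optimality); half-normal(1) on group SDs (log
scale); half-normal(0.15) on the report-noise SD. Ensemble chains start
from a Nelder-Mead posterior mode; defaults are 500 burn-in plus 900 kept
steps across ≥ 2·dim + 4 walkers. Convergence is gated at rank-normalized
split R-hat < 1.1 (computed across walkers with arviz); fits that miss the
gate are returned flagged, never silently accepted. Posterior summaries
report means, SDs, MCSE and 89% equal-tailed credible intervals.

Numerical guards: probabilities entering the posterior-odds combination are
clamped to [1e-9, 1 - 1e-9]; per-trial log-likelihood terms are floored at
-40 (except in the sufficient-statistic hierarchical path, where the
truncated-Gaussian quadratic form is exact and bounded by the sampler's
support limits); probabilities from quadrature are clipped to
[1e-12, 1 - 1e-12]. A tie r_lead = 0 resolves to "right" with probability
0.5 (measure-zero event).

**Outlier exclusion.** Participants whose point estimate of any weighting
parameter lies more than 6 SDs from the group mean are excluded
iteratively, worst first. The z-scores use leave-one-out group statistics:
with the candidate included, the z of one point among n cannot exceed
(n-1)/sqrt(n) (≈ 2.85 at n = 10), which would mask every outlier under a
6-SD rule.

## Model comparison

Leave-one-group-out cross-validation with participants as groups: each
fold refits every model hierarchically on the retained participants and
scores each held-out participant's trials by the pointwise log predictive
density under the group-predictive distribution — for each retained
posterior draw, new participant parameters are drawn from the fitted
group distribution and the per-trial (choice + confidence) likelihood is
averaged over draws. Pairwise comparisons report elpd_diff against the
best model with se_diff = sqrt(n) times the SD of the pointwise
differences; a model is called decisively better when |elpd_diff| ≥ 4 and
≥ 2 se_diff. Fold membership is a seeded exact partition; reruns with the
same seed are bit-identical.

## Problem sizes

Desk-scale defaults chosen for single-CPU runs: recovery studies use MAP
point estimates (full likelihood, simplified-likelihood pre-optimization
for the starting point) for 20 observers at 720 trials each; the
cross-validated model comparison runs 10 participants x 360 trials with
5 folds of 2 held-out participants and shortened chains (300 burn-in, 500
kept). Monte-Carlo checks use 1e5–2e5 trials per cell and 1e6-draw
oracles. The published full-scale analysis (10 folds, 720 trials, full
MCMC) is reproducible with the same code by raising these sizes.

## Known limitations

* The deposited real dataset is not bundled; numerical agreement with the
  published posterior means cannot be asserted offline, and the exact
  hierarchical priors and confidence observation model of the original
  analysis are not public in full detail, so agreement on real data would
  be approximate in any case.
* The Phi-form confidence is the posterior under a flat prior over
  stimulus strength. It is therefore *not* calibrated cell-by-cell against
  a generative process with fixed known strengths (mean confidence
  deviates from accuracy by 1–2 points at the default strengths even for
  the optimal observer); the model's substantive prediction — equality
  between matched Stronger-Lead and Stronger-Target conditions — does hold
  and is tested.
* The simplified hierarchical likelihood shrinks group-level weighting
  parameters relative to full-process truth (see above). Directional
  conclusions (w_choice > w_conf) are preserved in recovery tests.
* Reaction times, the delayed-response manipulation, and the
  exogenous-cue (single-decision) task variant are out of scope.
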