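# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the tests do and do not establish.

## Task model

The LOOP task delivers percentile feedback FB on a closed [0, 100] scale in
four estimation categories forming a 2×2 Ability (High/Low) × Interference
(Agent/NoAgent) design, 20 trials per cell, interleaved with no more than
two consecutive trials of the same condition. Feedback is not a fixed
sequence: each condition carries a sequence of *planned prediction errors*
(High: −18…27 points, 70% positive; Low: −27…18, 30% positive) added to the
participant's rolling ability belief — the mean of their last five
expectation ratings in that condition, initialized at 50 before the first
rating. This keeps realized prediction errors close to the planned ones
wherever the participant's expectations drift.

Design choices where the task description leaves room:

* **Clipping.** When belief + planned PE leaves [0, 100] the feedback is
  clamped and flagged; the realized PE is recomputed from the clamped value
  so FB stays interpretable as a percentile.
* **Planned-PE values.** The original hand-designed sequence is not
  published; sequences are drawn under the stated distributional
  constraints (exact sign counts by half-up rounding, values uniform within
  the signed ranges) and fixed by seed, identical for every subject in a
  session factory. Feedback is continuous by default; an integer mode sits
  behind `TaskConfig.integer_feedback`.
* Trial indices are 1-based; the trial-table CSV schema is frozen in
  `task_engine.TRIAL_COLUMNS`.

## Belief models M1–M5

All models share the within-condition delta rule
`EXP_{t+1} = EXP_t + α_valence · PE_t · (1 − w·ND(FB_t))` with valence-split
learning rates α⁺, α⁻ ∈ [0, 1] and feedback-weight factor w ∈ [0, 1].
M2/M4 replace the single valence pair with separate pairs per interference
level (M2) or per attribution (M4); M3/M5 multiply the update by (1 − s) on
Agent trials (M3) or externally attributed trials (M5), s ∈ [0, 1]. Trials
without an attribution probe count as internal.

* **ND.** The stated purpose of the feedback weight — discounting feedback
  near the scale limits — requires a function *maximal* at the extremes, so
  the default is `ND(f) = 1 − exp(−(f − 50)² / (2·25²))` (one minus the
  max-normalized normal density; center and spread configurable). The
  literal bell-shaped density (peaked mid-scale) is available via
  `FeedbackWeightFn(bell=True)` for sensitivity checks. ND is evaluated at
  each trial's delivered feedback value.
* **Observation model.** Ratings are modelled as Gaussian around the
  model-implied expectation with free per-subject scale σ_obs (percentile
  points). The Gaussian is deliberately untruncated: truncation at the
  scale limits creates boundary pile-up artifacts and is unnecessary at the
  observed noise levels. Each condition's trajectory is anchored at the
  subject's first observed rating — the model explains transitions, not
  starting points — so the likelihood covers trials 2…20 of each condition
  (76 points per session). Predicted expectations are clipped to [0, 100]
  when carried forward but the likelihood is evaluated at the unclipped
  mean.
* **Nesting.** M3 and M5 reduce exactly to M1 at s = 0 (and M5 whenever all
  attributions are internal); M2/M4 reduce to M1 when their rate pairs
  coincide. These are bit-exact log-likelihood equalities and are enforced
  as tests.

## Synthetic cohort

The generator emulates the reference study's sample structure: 64 students,
subclinical depression (PHQ-9 by a discretized gamma transform, mean ≈ 5)
and self-esteem (SDQ-III general-self sum, discretized normal on 12–96)
coupled by a Gaussian copula whose latent correlation `2·sin(π·ρ_s/6)` hits
a Spearman target of −0.62. Learning rates come from a lognormal overall
scale (median 0.175) split by a per-subject valence bias
`b = −0.3 + 0.25·z_selfesteem + noise(sd 0.4)` as `α± = scale·(1 ± b)`, which
reproduces the reference medians (α⁺ ≈ 0.11, α⁻ ≈ 0.24) and trait-bias
correlations (ρ ≈ −0.26 with depression, ≈ +0.44 with self-esteem) in
expectation. The attribution weight s is truncated-normal (0.51, 0.17) on
(0, 1); w ~ Beta(2, 6) (weak extremity discounting, not reported in the
reference analysis); σ_obs ~ Uniform(4, 8) points, a realistic rating-noise
band for a 100-point scale.

Behaviour is generated by the models themselves: each agent keeps one
latent expectation per condition, initialized at 50 plus N(0, 6) jitter
(participants hold slightly different priors about a novel ability; an
exactly common start would make no-learning cohorts degenerate). The first
rating in a condition reports the latent exactly; later ratings add
N(0, σ_obs) noise, matching the fitted likelihood's anchoring. Attributions
on Agent trials follow a logistic policy
`P(external) = logistic(−1.2 + 0.9·1[PE<0] + 0.025·|FB−50| + 0.35·z·1[PE<0])`
(z = latent self-esteem): self-serving, extremity-sensitive, with the
valence × self-esteem interaction in the direction the reference study
reports. All randomness derives from one cohort seed through per-subject
spawned streams.

What the generator does **not** emulate: item-level questionnaires,
demographic covariates, reaction times, within-session drift in noise, or
any misattribution between conditions. Passing recovery tests therefore
show the pipeline is correct and well-calibrated under the model's own
assumptions — not that the model is true of human data.

## Fitting

Per-subject, per-model MCMC with weakly informative priors: Uniform(0, 1)
on α/w/s, HalfNormal(20) on σ_obs. The sampler is a coordinate-wise slice
sampler (stepping-out with a 30-step budget, then shrinkage) running on the
natural parameter scale; three full coordinate sweeps are taken per
recorded draw to decorrelate the mildly coupled (α, w) pairs. The protocol
is 4 chains × 3400 recorded draws (1000 warm-up, thinned by 3 → 800
retained per chain). Initialization draws from the prior with a retry
budget for non-finite likelihoods. R-hat and bulk ESS come from arviz; fits
with any R-hat > 1.05 carry a convergence flag, and the working expectation
is minimum ESS above 1500 (typically 2300–3100 at the default settings).
Likelihood evaluation is a numba-compiled kernel checked bit-for-bit
against the pure reference implementation.

## Model selection

PSIS-LOO treats reciprocal pointwise likelihoods as importance ratios,
Pareto-smooths each trial's tail (arviz `psislw`, the generalized-Pareto
fit of Vehtari et al. with regularized k-hat), and flags trials with
k-hat > 0.7. Subject-level elpd sums enter random-effects BMS: a
variational Dirichlet update over population model frequencies (uniform
Dirichlet(1) prior), exceedance probabilities by 10⁵ seeded Monte Carlo
draws from the Dirichlet posterior (MC tolerance ≈ 0.005), and the Bayesian
omnibus risk from the free-energy comparison against the equal-frequency
null; protected exceedance probabilities are
`pxp = (1 − BOR)·xp + BOR/K`. Using elpd sums as log model evidence is an
approximation inherited from the study protocol.

## Group analysis

The learning-bias score `(α⁺ − α⁻)/(α⁺ + α⁻)` is undefined when both rates
are zero (error). Wilcoxon signed-rank uses exact 2ⁿ enumeration for
n ≤ 12 and a tie- and continuity-corrected normal approximation otherwise,
with r = |z|/√n and the Hodges–Lehmann estimate (median of Walsh averages,
order-statistic CI). One-sample t reports Cohen's d with a noncentral-t CI.
Benjamini–Hochberg runs step-up within explicit joint groups. Spearman CIs
use the Fisher transform with the 1.06/(n−3) variance.

Mixed models are REML fits via statsmodels MixedLM (Powell first, then
gradient optimizers, accepting only converged fits with finite standard
errors; the valence random slope is dropped and flagged on singular fits).
External attributions are modelled at trial level as a linear probability
model — preserving the within/between split of feedback extremity — with
valence coded ±0.5 (so a *negative* coefficient means worse-than-expected
feedback attracts external attributions), the mean-centered trait, their
interaction, and extremity components; random intercept plus valence slope
per subject. The expectation model uses Trial (centered), Ability (±0.5)
and Interference (±0.5) with all interactions and a random Trial slope.
Degrees of freedom use a between-within containment scheme (between-subject
effects: subjects minus between-subject parameters; within: observations
minus subjects minus within parameters) rather than Satterthwaite, which
statsmodels does not expose; only signs and coarse significance of these
effects are consumed downstream. Standardized betas come from refitting
after z-scoring the outcome and continuous predictors. The posterior
predictive check re-runs the expectation model on noise-free trajectories
simulated from per-subject posterior means.

## Problem sizes and known limitations

Recovery studies in the test suite run at a reduced scale chosen as the
package's own fast-verification setting: parameter recovery on 16 subjects
and model recovery on 12 subjects, both with shortened chains (4 × 1300
draws, 400 warm-up, thin 3 → 1200 retained), which leaves Monte Carlo error
well below the effects being checked.

Known limitations:

* **The attribution weight s is weakly identified at realistic noise.**
  With reference-calibrated learning rates (medians ≈ 0.11/0.24) and σ_obs in
  4–8 points, only ~40 Agent trials (of which ~17 externally attributed)
  inform s; per-subject posterior SDs (~0.2) exceed the cohort's true
  spread (~0.17), so true-vs-recovered correlations for s level off around
  0.3–0.6 while α⁺/α⁻ recover at r ≈ 0.8–0.97. Pushing σ_obs below ~4
  would lift r(s) above 0.7, but such noise levels are not representative
  of continuous rating scales. Group-level inferences about the *mean* of
  s are unaffected; per-subject s estimates should be treated as noisy.
* w is essentially unidentified from single sessions (near-flat posterior);
  it is retained for structural fidelity, not interpretation.
* The linear probability model can predict proportions outside [0, 1] for
  extreme covariates; a subject-level aggregation option exists but the
  trial-level model is the default to keep the extremity decomposition.
* BMS consumes elpd approximations, not marginal likelihoods; with very
  similar models (e.g. M5 vs M1 when s ≈ 0) it correctly refuses to
  separate them (high BOR) rather than picking a winner.
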