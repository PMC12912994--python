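# Methods

## The phenomenon being modeled

In the paradigm this package analyzes, a participant sees a social cue on
every trial — a cloud of dots presented as the ratings of previous
participants, drawn with either a high or a low mean, *independently of the
actual stimulus* — then reports an expectation, receives a stimulus at one
of three intensity levels (painful heat, a video of someone in pain, or a
mental-rotation effort task), and finally rates the experience on a 0–180
gLMS scale. Because the cues carry no information about the stimulus, a
normative learner should come to ignore them. Empirically people do not:
cue effects on both expectation and perception persist. The model family
here formalizes two mechanisms that can produce that persistence —
expectation-biased perception and confirmation-biased learning — and the
surrounding statistics quantify them model-free.

## Generative model family

All quantities are computed on the unit scale (ratings divided by the scale
maximum, 180 by default); user-facing outputs are mapped back to rating
units. Stimulus level `S ∈ {1,2,3}` enters as fixed anchors
{0.25, 0.50, 0.75}: equally spaced, interior to the scale, shared by every
model. The anchors are deliberately not free parameters — the model
catalogue's free-parameter counts (e.g. six for the dual-rate
perceptual-carryover model M3c) leave no room for a free stimulus mapping,
and fixing them keeps predictions inside the rating range for every ω.

Per trial, with cue c(t) ∈ {low, high}:

* effective expectation Ẽ_t, built from the learned cue expectancy E_t^cue
  (see carryover variants below);
* predicted perception  Ô_t = ω·Ẽ_t + (1−ω)·S_t;
* prediction error      δ_t = O_t − Ẽ_t, where O_t is the *reported*
  perception — the participant's own experience is the teaching signal;
* delta-rule update     E_{t+1}^cue = E_t^cue + α·δ_t (only the current
  cue's expectancy changes), with E clipped to [0,1] (clip events counted).

Model variants:

| id   | rates | carryover | update target |
|------|-------|-----------|---------------|
| M1   | none  | —         | fixed E_low, E_high (free) |
| M2a / M3a | 1 / 2 | none | cue expectancy |
| M2b / M3b | 1 / 2 | expectation β_E | cue expectancy |
| M2c / M3c | 1 / 2 | perception β_O | cue expectancy |
| M2d / M3d | 1 / 2 | — | general expectancy G plus cue offsets b_low, b_high |

Dual-rate models use α_c on cue-congruent trials (high cue with δ > 0, low
cue with δ < 0) and α_i otherwise; δ = 0 is classed incongruent, which is
inconsequential because the update is zero. Carryover is implemented as a
convex mixture, e.g. Ẽ_t = (1−β_O)·E_t^cue + β_O·O_{t−1} for the
perceptual-carryover variants (first trial: Ẽ = E^cue). The mixture form is
bounded, reduces exactly to the nested no-carryover model at β = 0, and
perturbs the effective expectation without altering the stored learned
value. δ is computed against Ẽ (the quantity the participant reports), not
the stored E^cue; for the no-carryover variants the two coincide.

Initialization: learning models seed E_0^cue from the displayed cue mean of
the first trial of each cue type (0.5 if a cue type never occurs); tracker
variants start G = 0.5 with b offsets free in [−0.5, 0.5]; M1's expectancies
are free parameters.

Ratings are Gaussian around the latents: expectation ~ N(Ẽ, σ_E²),
perception ~ N(Ô, σ_O²), clipped to [0,1] when simulating. The likelihood
is the sum of both rating log-densities over trials; trials with one
missing rating contribute only the observed term, and a missing perceptual
rating freezes learning on that trial (no teaching signal).

### Why the dynamics matter

With a single rate and ω < 1, both cue expectancies are driven toward the
mean stimulus value, so the cue-induced gap extinguishes (for ω = 0 the
expected gap decays by exactly (1−α) per same-cue trial). With α_c > α_i,
updates that confirm the cue are weighted more than those that disconfirm
it, so a cue-seeded gap reaches a stationary value away from zero: an
uninformative cue sustains its own effect. The `recovery.prophecy_experiment`
quantifies this with a persistence ratio: the mean expectation-rating gap
in the final block of a 2,000-trial run divided by the gap in the first 12
trials (the cue-seeded gap). The short baseline window is deliberate:
single-rate extinction completes within ~20 trials, so a long first block
would dilute the baseline toward the stationary noise floor and turn the
ratio into noise/noise. Defaults: 10 blocks, 10 seeds, rating noise
σ = 0.02.

## Fitting and model comparison

A two-stage approximation to hierarchical Bayesian inference:

1. **Per subject, per model: MAP + Laplace.** Parameters are transformed to
   an unconstrained space (logit for [0,1] parameters, scaled logit for the
   tracker offsets, log for variances; exact boundary values nudged inward
   by 1e-6). Priors are Normal(0, 1.5²) on logit-scale parameters (near
   uniform after the logistic) and Normal(log 0.01, 1) on log variances
   (rating noise of a few percent of the scale, weakly constrained). The
   posterior is maximized by multi-start L-BFGS (default 4 starts: prior
   mean plus seeded prior draws). Model evidence is the Laplace expansion
   log Z = log p(D|θ̂)p(θ̂) + (d/2)·log 2π − ½·log det H with H the
   finite-difference Hessian of the negative log posterior (step 1e-4,
   symmetrized; non-positive-definite H regularized by +λI and logged;
   still-singular H yields −∞ and a non-converged flag).
2. **Group: random-effects model selection.** The subjects × models
   evidence matrix feeds a variational Dirichlet model of population model
   frequencies (concentration prior 1): responsibilities
   u_nk ∝ exp(log Z_nk + ψ(a_k) − ψ(Σa)), a_k = 1 + Σ_n u_nk, iterated to
   1e-8. Exceedance probabilities are Monte-Carlo (10⁶ Dirichlet draws,
   seeded); the Bayes omnibus risk compares the variational free energy of
   this model against the null in which every subject's data are explained
   by equal frequencies, BOR = 1/(1+exp(F_rfx − F_null)); protected
   exceedance probabilities are pxp = xp·(1−BOR) + BOR/K.

The full iterative hierarchical scheme (responsibility-weighted empirical-
Bayes priors) is not implemented; on the synthetic cohorts used here the
two-stage route recovers parameters with Spearman ρ ≈ 0.9 and the model
space with a fully diagonal confusion matrix, which is the level of
fidelity the downstream analyses need.

Subjects with fewer than 24 trials (less than two runs) are excluded from
cohort fitting and the model-agnostic analyses, with a logged count.

## Model-agnostic learning rates

The delta rule implies a per-trial learning rate (E_{t+1}−E_t)/δ_t. The
per-trial ratio explodes when δ is small, so the per-condition estimator is
the OLS slope (with intercept) of the expectation update on the prediction
error, over consecutive same-cue trial pairs within a session (sessions are
different days; pairs never cross them). Zero-δ pairs are dropped. The four
cells are cue × PE valence; α_c pools the two congruent cells, α_i the two
incongruent; cells with fewer than 3 pairs are reported missing. The
intercept absorbs carryover- and drift-induced offsets that would otherwise
bias the slope. Slopes far from the group (|bias − median| > 3·MAD) are
flagged, not excluded. Group inference is the Wilcoxon signed-rank test:
exact enumeration of the positive-rank-sum distribution when ≤ 12 nonzero
differences, otherwise a normal approximation with tie and continuity
corrections; effect sizes are mean/sd of paired differences (population
sd, matching the convention of the scale-free worked examples).

## Behavioral effects, reliability, mediation

* **Effects** are cell-mean contrasts on the 2×3 design (cue effect = mean
  high−low across levels; stimulus effect = level 3 − level 1 across cues;
  interaction = cue effect at level 3 minus at level 1) — identical to GLM
  coefficients under a balanced design and robust to missing cells.
  Expectation ratings precede the stimulus, so their stimulus factor
  collapses.
* **Extinction** is the per-subject cue×time OLS coefficient (cue ±½, time
  = chronological rank scaled to [0,1] across all sessions, stimulus level
  centered; a zero-variance stimulus column is dropped), tested across
  subjects by signed rank.
* **Reliability** is the odd/even split-half Pearson correlation of a
  per-subject effect, Spearman–Brown corrected (2r/(1+r)); cross-task
  stability is the Spearman correlation of effects paired by participant.
* **Within-subject error bars** follow Cousineau–Morey: remove each
  subject's row mean, add the grand mean, take per-condition SEM, scale by
  √(C/(C−1)).
* **Trajectory smoothing** uses cubic smoothing splines with
  generalized-cross-validation smoothing by default, evaluated only at
  observed ranks; fewer than 8 points returns the raw series flagged.
* **Mediation** is two-level: per subject, OLS of M on X (+covariates) for
  a_j, Y on M, X (+covariates) for b_j and c′_j; the group indirect effect
  is the mean of products a_j·b_j with a percentile bootstrap over subjects
  (default 10,000 resamples) for CIs and two-sided p-values (floored at
  2/n_boot). Mediation 1 is Cue → Expectation → Perception controlling for
  stimulus level and the previous trial's perception, cue and expectation;
  mediation 2 is Stimulus → Perception → next-trial Expectation controlling
  for current cue and expectation, previous perception and the next trial's
  cue. Lags and leads resolve within session only; subjects with fewer than
  10 usable rows are excluded. This summary-statistics scheme replaces the
  full multilevel-SEM machinery; without covariates it reproduces the
  Baron–Kenny identity c = c′ + ab per subject exactly.

## Synthetic cohorts

`synthdata` emulates the study design: 3 sessions × 2 runs, each run
containing the six cue×intensity cells exactly twice in shuffled order (so
12 trials per condition overall, 72 total, and P(level|cue)=1/3 exactly per
run by construction); cue display means drawn per trial from
Normal(120, 8²) for high and Normal(60, 8²) for low cues on the 0–180
scale, independent of stimulus level. The displayed means are modeling
choices — only the per-trial mean of the dot cloud is modeled, not
individual dots.

Population defaults (used by the recovery pipelines): α_c ~ TruncN(0.45,
0.2²), α_i ~ TruncN(0.15, 0.1²), ω ~ TruncN(0.2, 0.08²) (centered on the
magnitude of empirically reported expectation weights), β_O ~ TruncN(0.3,
0.15²), b offsets ∓0.15 ± 0.08, M1 fixed expectancies 0.33/0.67 ± 0.10,
rating noise σ_E = σ_O = 0.05 of the scale (0.02 in the model-recovery
setting, where identifiability is being probed rather than realism).
Truncation is to each parameter's legal range. An optional cross-task
correlation ρ on chosen parameters is induced by a Gaussian copula with a
shared per-subject factor (ρ=1 duplicates the value across tasks).

What the generator does **not** emulate: response omissions and lapses,
scale-use idiosyncrasies (end-of-scale compression, anchoring drift),
session-level nonstationarity (fatigue, sensitization), heavy-tailed rating
noise, and any correlation between rating noise and parameters. Passing
recovery tests therefore demonstrates internal consistency of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Problem sizes and numerical choices

Default analysis sizes were chosen as the smallest cohorts at which each
property is stably detectable: parameter recovery N = 40 × 72 trials;
model recovery N = 20, 3 replicates, over the reduced pivotal model set
{M1, M2a, M2c, M3a, M3c} (no-learning vs learning, carryover vs none,
single vs dual rate — the full 9-model sweep is a config option); prophecy
horizon 2,000 trials × 10 seeds; mediation 20 subjects × 40 trials.
Winners in model recovery are selected by model frequency with pxp as
tie-break. Monte-Carlo exceedance uses 10⁶ draws by default (10⁵ inside
model recovery). All randomness flows from a single seed through named
SeedSequence spawns, so every stage is independently reproducible.

Known limitations: the Laplace evidence is a local approximation and can
misrank models for subjects with strongly multimodal posteriors (multi-start
mitigates but does not eliminate this); the evidence of boundary solutions
(e.g. α̂ ≈ 0) relies on the logit-space curvature; the cross-task
correlation of *behavioral* cue effects under the default population is
intrinsically weak (ω carries only part of the cue-effect variance, its
ceiling is near r ≈ 0.2), which is why cross-task structure is assessed on
the estimated expectation weight ω itself; and the two-stage fit does not
shrink per-subject estimates toward the group, so extreme subjects are
noisier than a full hierarchical fit would make them.
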