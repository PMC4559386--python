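# Methods

This note documents the models, estimation choices, synthetic-data
assumptions and known limitations of `tempodisc`.

## Task structure

The choice task is fixed by construction: 6 blocks × 18 trials, later option
20 €, sooner amounts on the 9-level 2.50 € grid with each amount presented
twice per block. Delay pairs are (tomorrow, 3), (tomorrow, 6), (tomorrow, 9),
(tomorrow, 12), (6, 9), (6, 12) months; "tomorrow" is encoded as T = 0 so the
β–δ model's immediate branch applies to it. Block order, within-block trial
order and screen side are randomized per participant under the run seed; the
randomization scheme (uniform per trial, per-participant block order) is a
package choice since only "randomized" is specified by the design.

The 0 € and 20 € sooner amounts give 4 catch trials per block, 24 in total —
a derived count used by the exclusion rule: a participant is excluded when
strictly more than half (≥ 13) are answered against the dominant option. The
20 €-now-vs-20 €-later catch is scored correct for the *sooner* choice
(waiting adds nothing).

## Indifference points

Per block, P(choose sooner) = logistic(a + b·amount) is fitted by maximum
likelihood (statsmodels `Logit`); IP = −a/b clipped to [0, 20] €, divided by
20 for the proportion scale. Catch trials stay in the regression — they
anchor the asymptotes of the psychometric curve.

Deterministic responders (common with 18 binary trials on a coarse grid)
produce perfect or quasi-complete separation, where unregularized ML
diverges. Detection: the always-later and always-sooner amount regions do not
overlap, or the ML fit fails to converge, or the fitted slope is ≤ 0. In all
of these the IP falls back to the midpoint between the largest amount at
which the later option was always taken and the smallest at which the sooner
option was always taken (defaults 0 € and 20 € when a region is empty, so
all-later responders get IP = 20 € and all-sooner IP = 0 €). The `separated`
flag records which path produced each IP. The fallback quantizes IPs to
1.25 € offsets on the amount grid, which bounds the achievable parameter
resolution (below).

## Discount models

Both models are least-squares fits to the four tomorrow-anchored IP
proportions at T = {3, 6, 9, 12} months. The extra day implied by the
tomorrow anchor is ignored as negligible relative to the grid resolution.
Blocks 5–6 (sooner option at 6 months) are excluded from fitting; they
contribute to QC and NImp only.

* Hyperbolic: SSE(k) minimized over k ∈ [0, 10]/month by a coarse grid (0
  plus 200 log-spaced points) with bounded scalar refinement. The ceiling of
  10/month is already economically absurd (SV < 0.04 at 3 months); unbounded
  "free" fitting would be unidentifiable above it.
* Quasi-hyperbolic: SSE(β, δ) minimized over [0, 1]² by a 41 × 41 grid with
  bounded `least_squares` refinement from the best 3 starts. Bounds are part
  of the model's definition (β, δ are proportions).
* ln k uses a floor of k = 1e-4 before the log, since the patient boundary
  k̂ = 0 occurs and downstream regressions use ln k.
* AIC uses the least-squares form n·ln(SSE/n) + 2p with SSE floored at 1e-10
  before the log; only AIC *differences* between the two models on the same
  points are interpreted. NImp counts sooner choices on non-catch trials
  (range 0–84).

Tests verify oracle dominance (fitted SSE never above the best dense-grid
point) and agreement with 1e-3/1e-2-resolution grid minimizers.

## Memory scores

FNPA-PF is computed on the proportion scale, hits/20 − FA/20: the stated
hits-minus-false-alarms rule combined with group means near 0.3–0.6 is only
consistent with proportions, so raw counts are divided by 20. The C1 rating
scale is scored 0–3 per dimension so that 4 episodes × 3 dimensions × 3 = 36
matches the instrument's maximum rating score; a 1–4 scoring would imply 48.
The C2 confidence denominator is 3 × (number of yes-answers), since ratings
exist only for yes-items; this puts both C2 components in [0, 1] and
preserves the ceiling of 2. The instrument's proprietary per-topic weighting
is not public; scoring follows the printed component structure only.

## Synthetic cohort

The generator's defaults emulate the analysed study sample and are *study
conditions*, not free knobs: n = 58 with 30 women; age ≈ N(72.6, 6.4²)
clipped to [60, 89]; IQ-screen ≈ N(16.1, 4.6²); lognormal income with gender
means 29 409 € (men) and 15 833 € (women), CV 0.55, missing completely at
random at rate 6/58; memory-score means (male, female): FNPA-PF (0.33, 0.57),
IGD-C1 (1.62, 1.74), IGD-C2 (1.66, 1.77) with SDs 0.20/0.25/0.20 and a
shared-latent correlation of 0.5 between the three scores. The
`memory_gender_gap` knob is a scalar (applied to all three scores) or a
3-tuple; the defaults are the per-score female−male differences above.

Scores are produced by inverting the scoring formulas into raw instrument
responses (hit/FA counts, per-episode events and rating sums, yes/answered/
confidence counts) and re-scoring them, so the memory-scoring code path is
exercised and realized scores carry realistic integer quantization.

Discounting truth: ln k ≈ N(−2.0, 1.5²) clipped to [ln 1e-4, ln 10];
β ≈ N(0.65, 0.2²) and δ ≈ N(0.975, 0.015²) clipped to [0, 1]. An optional
gender × IGD-C2 interaction slope is injected additively into ln k (units:
ln k per unit of mean-centred IGD-C2, women only). No distributional claims
about the real population are implied; these are documented configuration
values centred on the published group means.

Choices are simulated as P(later) = logistic(τ·(SV_later − SV_sooner)) with
subjective values computed for *both* options (necessary in blocks 5–6 where
the sooner option is itself delayed) and τ = 5/€ by default. Any smooth
symmetric noise would do; the logistic is chosen for conjugacy with the IP
logistic regression. τ = ∞ gives deterministic choice with 50/50 ties;
τ = 0 gives pure coin-flips. The generator does not model reaction times,
learning, session effects, or non-stationary preferences — recovery results
therefore speak to estimator behaviour under the stated choice model, not to
all failure modes of real data.

## Statistical analysis

Missing income is imputed by multivariate-normal EM over (age, IQ, income,
FNPA-PF, IGD-C1, IGD-C2): alternating conditional-expectation and
moment-update steps until imputed values move < 1e-6 (max 200 iterations);
observed values are never altered. With missingness confined to one column
this converges to regression imputation from the ML moments, which is the
closed-form check used in tests.

The hierarchy regresses each outcome on (1) the three memory scores, (2) +
gender, age, income, IQ, (3) + three gender × memory interactions built by
multiplying the gender code with mean-centred memory scores. All variables —
outcome, predictors, and the constructed products — are z-scored (ddof = 1)
before fitting, so coefficients are standardized betas comparable across
heterogeneous units. Gender is coded female = 1, male = 0; since this coding
is a convention, only the opposite-slopes *pattern* of an interaction, not
its sign, is scientifically meaningful. Adjacent models are compared with the
R²-change F-test, F = ((R²_f − R²_r)/q)/((1 − R²_f)/(n − p_f − 1)); at
n = 58 with 10 full-model predictors the interaction test has (3, 47)
degrees of freedom.

Group comparisons are gated by Shapiro–Wilk at α = .05 within each gender:
both normal → pooled-variance t-test, otherwise Mann–Whitney U (two-sided).
Memory–covariate correlations use Pearson when both variables pass the same
gate, else Spearman, with Holm–Bonferroni applied within each covariate's
family of three tests (so a family's smallest p is held to α/3 ≈ .0167).
Median splits dichotomize at the within-sample median with ties to the low
group, reporting cell means ± SE by gender × high/low.

## Calibration and problem sizes

The Monte-Carlo experiments use these sizes, chosen to give stable rates at
interactive runtimes:

* β/δ recovery: 200 participants × 108 trials at τ = 5/€, β ~ U(0.5, 1),
  δ ~ U(0.95, 1). The IP grid bounds β resolution at ~0.125 (one 2.50 € step
  as a proportion); δ, entering through the slope across a 9-month span, is
  recoverable to ~0.005 median error.
* AIC model selection: 20 cohorts × 30 participants at τ = 20/€; the
  cohort-mean IP fit prefers the β–δ model whenever data are generated from
  it with a non-trivial present-bias.
* Type-I error of the model-3 gender × IGD-C2 test: 1000 cohorts of n = 58
  generated with zero interaction, outcome = ground-truth ln k. Using the
  generator's truth (rather than re-simulating 108 trials per participant per
  replicate) isolates the regression calibration from estimation noise.
* Sign recovery: 200 cohorts with a strong injected slope (4.0 on ln k,
  residual SD 0.5) — a high-signal regime in which the fitted interaction
  beta should essentially always carry the configured sign.

## Known limitations

* The published study's cohort-level estimates (group means of k, β, δ, the
  exact regression betas and AICs) cannot be reproduced without its raw
  data; the pipeline instead demonstrates recovery of *known* synthetic
  truth and calibration of its tests.
* The midpoint fallback makes per-participant IPs grid-quantized for
  deterministic responders; β is consequently estimated no finer than the
  grid step.
* EM imputation assumes joint normality; income is lognormal in the
  generator, so imputed incomes are conditionally biased at the tails. With
  ~10% missingness in one column this is immaterial to the standardized
  regressions, but heavier missingness would warrant a transformed scale.
* The choice simulator is stationary and memoryless; attention lapses are
  modelled only as a temperature → 0 limit (`n_inattentive`), whose catch
  failures are stochastic rather than guaranteed.
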