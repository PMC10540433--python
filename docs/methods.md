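# Methods

## The generative model

The synthetic cohort instantiates the preconditions under which a
classifier's false positives can constitute a true risk group: risk
factors exert a *persistent* causal influence on the outcome across
waves, the classifier is accurate, and classification is performed at
high specificity.

A single standard-normal latent liability z₁ drives everything at
wave 1. K severity scales are noisy linear images of it,
xₖ = λₖ z₁ + √(1−λₖ²) εₖ, so corr(xₖ, z₁) = λₖ exactly; J additional
features are independent noise. The wave-1 outcome is Bernoulli with
logit α₁ + β₁ z₁. Between waves the liability persists with correlation
ρ: z₂ = ρ z₁ + √(1−ρ²) ε′. Wave-2 participation is Bernoulli and
independent of everything (MCAR), and among participants without a
wave-1 event the first-time outcome is Bernoulli with logit α₂ + β₂ z₂.

A one-dimensional Gaussian liability is the minimal structure satisfying
the persistence precondition while keeping every oracle analytic (group
means, correlations, marginal prevalences are closed-form or one
quadrature away). Real multi-instrument survey data are richer: ordinal
Likert items (available behind the `likert_bins` switch, off by default
since the convergence analysis uses normalized means, which are
insensitive to discretization), heterogeneous and interacting risk
factors, informative dropout, non-monotone effects. Passing tests on
this generator therefore demonstrate correctness of the *audit
machinery* under the stated conditions — not that any particular real
cohort satisfies those conditions.

### Intercept calibration

α₁ solves E_Z[σ(α₁ + β₁ Z)] = p₁ by 96-node probabilists'
Gauss–Hermite quadrature plus Brent root finding (tolerance 1e-6,
explicit failure if the bracket [−40, 40] does not contain a sign
change). α₂ is calibrated against the *realized* z₂ sample of eligible
subjects (wave-1 negatives who responded at wave 2), because the target
2.1% is a prevalence among responders, and conditioning on y₁ = 0
shifts the z₂ distribution away from any closed form worth maintaining.

### Default parameters

| parameter | default | meaning / why |
|---|---|---|
| n_subjects | 10,832 | wave-1 analytic sample size of the emulated study |
| loadings λ | 0.85…0.60 (K = 6) | six severity scales spanning strong-to-moderate reliability |
| n_noise_features | 14 | distractor items; keeps the feature space realistically mixed |
| persistence ρ | 0.8 | strong two-year stability of latent risk |
| β₁ | 2.2 | yields test AUROC ≈ 0.88 for a well-tuned model — the "accurate model" precondition |
| β₂ | 1.8 | follow-up effect size placing the population FP/TN relative risk in the 3–7 range reported for comparable cohort audits |
| target_prev_t1 | 0.0843 | wave-1 attempt prevalence |
| target_prev_t2 | 0.021 | first-attempt prevalence among eligible responders |
| followup_rate | 0.74 | wave-2 participation |
| missing_rate | 0.0752 | MCAR item missingness |

β₁ and β₂ were fixed once against those two published anchors (model
accuracy; relative-risk range) before any downstream analysis and are
not tuned thereafter.

Dropout and item missingness are both MCAR by declaration, not
inference: the emulated study does not model its nonresponse mechanism,
and MCAR keeps the relative-risk estimand unbiased by design, so audit
failures cannot be blamed on (or masked by) informative missingness.
Imputation is a simple training-split mean/mode fill; model-based
imputation is deliberately out of scope, and the imputation statistics
are computed on the training split only to keep the held-out split
untouched.

## Classifier and selection

The learner sits behind a two-method contract (fit; predict
probabilities) with a registry (`gbm` → LightGBM, `logistic` →
scikit-learn; user-registrable). Random search draws hyperparameters
uniformly — trees 50–500, depth 2–8, learning rate log-uniform
0.01–0.3, subsample 0.5–1.0, standard gradient-boosting ranges — and
each candidate is scored by mean AUPRC over stratified CV folds
(stratification stabilizes AUPRC at ~8% prevalence). Ties break by
draw order; the winner is refit on the full training split. The split
is stratified on the wave-1 label by default.

AUROC is computed by average ranks (identical to pairwise concordance
with half-credit ties). AUPRC is step-integrated average precision with
tied scores treated as one block — trapezoidal PR interpolation is
known to be optimistic. Both are implemented here and cross-checked in
the tests against brute-force enumeration and scikit-learn.

Wave-2 columns are structurally invisible to the model: the feature
matrix is built only from declared feature columns, a guard rejects any
wave-2 name, and a test verifies that erasing wave-2 outcomes leaves
the fitted scores byte-identical.

## Threshold semantics

Candidate cutoffs are midpoints between consecutive distinct scores
plus sentinels below the minimum and above the maximum (midpoints avoid
boundary ambiguity under ties); prediction is positive iff
score ≥ cutoff. For a target specificity the pipeline takes the
*smallest* candidate whose achieved specificity is ≥ the target —
conservative exact-step semantics, never less specific than requested,
rather than interpolating between empirical ROC points. Because
achieved and target specificity differ on a finite sample, both are
carried through every downstream table. Two default grids:
0.600–0.975 in steps of 0.025 (16 levels, relative-risk audit) and
0.60–0.97 in steps of 0.01 (38 levels, severity convergence); both
configurable.

## The audit

Counts are restricted to wave-2 responders ("prevalence at follow-up"
is a responder quantity). RR = (a/(a+b))/(c/(c+d)); a = 0 gives 0,
c = 0 with a > 0 gives +∞ with the level flagged, an empty FP or TN
responder cell is a degeneracy that is flagged and excluded from trend
fits but never silently dropped. FP responder cells below 5 raise a
small-cell warning flag.

The one-sided Fisher p-value is the conditional hypergeometric tail
P(X ≥ a) with margins fixed, accumulated via log-gamma for numerical
safety at large margins. Two lower 95% bounds accompany it:

- the exact conditional **odds-ratio** bound, inverting
  P_ψ(X ≥ a) = 0.05 over the noncentral hypergeometric family by
  monotone bisection to 1e-6 (the tail is strictly increasing in ψ);
- a Wald bound on the **log relative risk**,
  exp(log RR − z₀.₉₅ √(1/a − 1/(a+b) + 1/c − 1/(c+d))).

Standard Fisher-test machinery yields the former, epidemiological RR
reporting implies the latter, and published analyses sometimes label
one as the other; emitting both keeps the distinction visible.

## Trend analyses

Simple OLS is computed in closed form (slope = S_xy/S_xx) with R²,
adjusted R² = 1 − (1−R²)(n−1)/(n−2), F = MS_reg/MS_res on (1, n−2) df,
and the F-tail p-value. Degenerate cases are pinned: constant y →
slope 0, F 0, p 1; exact fit → R² 1, F +∞, p 0; constant x or n < 3 →
failure. Internal identities (adjusted R² and F recomputable from R²
and n) hold to 1e-10 and are asserted in the tests.

RR-on-specificity uses the 16-level audit with degenerate/infinite
levels excluded (count reported). Severity convergence min–max
normalizes each scale with reference statistics from the *full test
split* — the declared reading of "normalized average severity", giving
FP and TP one shared scale (z-scoring would serve equally; min–max maps
group means into [0, 1]) — then regresses d(level) = TP mean − FP mean
on the 38-level grid per scale, modelling the difference directly
rather than the two curves separately. Negative slope = convergence.

## Reproducibility and problem sizes

A master seed derives one seed per stage via BLAKE2 keyed by stage name
(all seeds < 2³¹), so stages re-run in isolation and two runs with the
same master seed produce byte-identical outputs (verified by manifest
checksums). All interface files are flat CSV/JSON.

The test suite exercises the replicated simulation studies at n = 4,000
subjects per cohort (500 null-model cohorts for calibration; 100
signal-model cohorts for the directional hypotheses), using the
logistic plug-in learner for the replicated runs — the audit consumes
only the score ranking, and the latent model is logit-linear, so the
logistic learner is near-optimal there while keeping hundreds of
replicates cheap. Single end-to-end runs (acceptance script, analysis
drivers) use the default n = 10,832 with the boosted learner.

## Known limitations

- The latent liability is unidimensional and Gaussian; real risk is
  multifactorial and its scales are ordinal.
- MCAR dropout and missingness are assumptions of convenience declared
  as study conditions, not inferred mechanisms.
- The per-level RR point estimate carries a finite-sample reciprocal
  bias of order 1/c upward (c = TN-responder events); at n = 4,000 and
  low specificity this is ≈ +10% even under the null. The Fisher test
  is unaffected (it conditions on margins), but averages of RR point
  estimates over replicates sit above 1 under the null.
- Under a logit-linear follow-up model the *population* RR-vs-specificity
  curve rises only modestly (tail-mean ratios of an approximately
  lognormal risk bound the rise to ~1.2–1.5× over the sweep), and the
  per-level estimates at high specificity rest on small FP cells, so the
  fitted RR-trend slope has large sampling variance; its sign is a
  weak signal at realistic sample sizes, and steep empirical RR curves
  are evidence of risk structure beyond this model class.
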