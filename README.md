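# truealarms

Are the "false positives" of a suicide-attempt classifier really errors?
When a probabilistic classifier is trained on many psycho-socio-environmental
risk factors whose influence persists over time, the subjects it flags
despite a negative label may carry genuinely elevated latent risk — and go
on to develop the outcome later. `truealarms` is an analysis pipeline for
auditing exactly that claim on two-wave cohort data: it quantifies the
follow-up outcome risk of false positives relative to true negatives as a
function of the classification threshold's specificity.

The package is aimed at biostatisticians and computational psychiatry
researchers who evaluate risk-classification models on longitudinal survey
cohorts. Because real adolescent-cohort data of this kind are
access-restricted, the package ships a first-class synthetic cohort
generator whose statistical skeleton matches the published study
conditions, so every stage is testable end to end.

## The model and the statistic

**Generative model.** Each subject carries a latent liability
z₁ ~ N(0, 1). Observed severity scales load on it
(xₖ = λₖ z₁ + √(1−λₖ²) εₖ); extra features are pure noise. The wave-1
outcome is y₁ ~ Bernoulli(σ(α₁ + β₁ z₁)), with α₁ calibrated by
Gauss–Hermite quadrature so the marginal prevalence hits its target
(8.43% by default). The liability persists between waves,
z₂ = ρ z₁ + √(1−ρ²) ε (ρ = 0.8), wave-2 participation is MCAR (74%), and
first-time attempts among eligible responders follow
y₂ ~ Bernoulli(σ(α₂ + β₂ z₂)) at 2.1% marginal prevalence. Item
missingness is MCAR at 7.52%.

**Pipeline.** A gradient-boosted classifier (pluggable learner) is tuned
by random search with stratified cross-validation, selected by AUPRC, and
scores the held-out 30% test split. For each target specificity s in
0.600–0.975, the cutoff is the smallest candidate whose achieved
specificity is ≥ s; the wave-1 negatives split into false positives (FP,
score ≥ cutoff) and true negatives (TN).

**The audited statistic.** Restricted to wave-2 responders, with a/b the
FP first-attempters/non-attempters and c/d the same for TN:

    RR_FP/TN = (a / (a+b)) / (c / (c+d))

Evidence that RR > 1 is assessed by the one-sided Fisher exact test
(hypergeometric tail, fixed margins); a one-sided exact conditional
odds-ratio lower bound (noncentral hypergeometric inversion) and a Wald
log-RR lower bound are both reported, since they are different estimands.
Two OLS trend analyses close the audit: RR regressed on specificity
level, and — per severity scale — the difference between normalized TP
and FP group means regressed on specificity (a negative slope means the
groups converge).

## Worked example

The numbered drivers under `analysis/` run the study in sequence:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_train_model.py --seed 1
python analysis/03_audit_fp_risk.py
python analysis/04_trend_convergence.py
```

With seed 1 the simulated cohort realizes a wave-1 prevalence of 8.0%,
74.4% wave-2 participation, 152 first-time attempters, and 7.6% item
missingness. The selected booster reaches test AUROC 0.894 and test
AUPRC 0.473. The audit prints one row per specificity level; the last
rows look like:

```
 level  achieved  a    b  c    d     rr   p_one_sided  or_ci_lower
 0.950    0.9502 11  101 35 2079 5.9321        0.0000       3.2651
 0.975    0.9753  8   47 38 2133 8.3100        0.0000       4.2431

levels with RR significantly > 1 (p < 0.05): 16 of 16
```

i.e. at specificity 0.975 the false positives' first-attempt risk at
follow-up is 8.3 times the true negatives', with an exact one-sided 95%
odds-ratio lower bound of 4.2. The convergence analysis reports, per
signal scale, the slope of the TP−FP severity gap across the 38-level
grid — all six negative here (e.g. `scale_1: slope=-0.162, adj R2=0.983`),
meaning flagged-but-negative subjects increasingly resemble true
positives as the threshold rises.

The same pipeline runs as a CLI (`truealarms simulate|train|sweep|audit|trend|run-all`),
and `analysis/05_null_calibration.py` replicates cohorts with β₂ = 0 to
verify the audit is calibrated when no persistent risk effect exists.

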