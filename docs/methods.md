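# Methods

`tacropk` analyses intensively sampled tacrolimus whole-blood
concentration–time profiles over one 12-h dosing interval at steady dosing,
as collected in early post-lung-transplant therapeutic-drug-monitoring
studies. This note documents the models, the statistics, the synthetic-data
generator and the numerical choices.

## Non-compartmental analysis

Each subject contributes a profile sampled at 0, 0.5, 1, 2, 4, 6, 8, 10 and
12 h after the morning dose (the 0-h sample is the pre-dose trough). The
dosing-interval exposure AUC₀₋₁₂ₕ is computed by the linear-up log-down
trapezoidal rule: a segment with C₂ ≥ C₁, or with a zero endpoint, is
integrated as a linear trapezoid (C₁+C₂)/2·Δt; a declining segment between
two positive concentrations as the log trapezoid (C₁−C₂)/ln(C₁/C₂)·Δt, which
is exact under mono-exponential decline and always below the chord. At
steady state the apparent oral clearance is

    CL/F = Dose / AUC₀₋₁₂ₕ,

reported in L/h via the factor 1000 that reconciles mg doses with ng/mL
concentrations. C_max and C_min are the observed extrema over all sampled
points (C_min is the minimum during the interval, not the trough by
definition — the two can differ), and T_max is the earliest time attaining
C_max. Dose-normalised variants divide by the interval dose. There is no
λz extrapolation: at steady state the interval AUC is the complete exposure
measure, so terminal-slope machinery is deliberately absent.

Exposure parameters are treated as log-normal throughout: summaries are the
geometric mean exp(mean ln x), geometric SD exp(sd ln x) (sample, n−1
denominator; defined as 1 for n = 1), and geometric CV% =
100·sqrt(exp(s²)−1) with s = sd(ln x); group comparisons are one-way ANOVA
on ln-transformed values.

Below-quantification (LLOQ 0.5 ng/mL by default) samples are censored —
excluded from the profile with a missing-value flag, never imputed or
zeroed. A profile must retain at least 3 quantifiable points.

## Limited sampling strategies

For every time t on the shared grid, the observed AUC₀₋₁₂ₕ is regressed on
the single concentration C_t by ordinary least squares. Predictive
performance follows the Sheiner–Beal convention on percent relative
prediction errors PE_i = 100·(AUC_pred,i − AUC_obs,i)/AUC_obs,i:

* MPE = mean(PE) (bias), MAE = mean(|PE|) (imprecision);
* medians and ranges of PE (signed) and |PE| for tabular reporting;
* F₁₅/F₂₀/F₂₅ = percentage of subjects with |PE| within ±15/20/25%
  (a value exactly on a threshold counts as within it).

A strategy is *clinically acceptable* when |MPE| ≤ 15%, MAE ≤ 30%,
F₁₅ > 40%, F₂₀ > 45% and F₂₅ > 50%; the acceptability rule uses the means
(not per-subject bounds), which is the reading under which reported 4-h-type
values (MPE −2%, MAE 7%, F 79/93/100) come out acceptable. Predictions are
in-sample, matching the single-fit-per-timepoint design; leave-one-out
cross-validated predictions are available behind a flag. F percentages are
stored unrounded and rounded to integers only for display. Note that
in-sample OLS forces the mean residual to zero in AUC units but not in
percent units, so MPE ≠ 0 in general.

## Pharmacogenetics

Genotypes at CYP3A5*3 (rs776746) and CYP3A4*1G (rs2242480) are
sub-classified into the binary carrier classes used clinically: CYP3A5*3/*3
(non-expressers) versus carriers of at least one functional *1 allele, and
CYP3A4*1/*1 versus *1G carriers.

Hardy–Weinberg equilibrium is tested per locus from genotype counts. The
default rule uses the asymptotic chi-squared test (1 df) when every
HWE-expected cell is at least 5 and otherwise the exact test — full
enumeration of heterozygote counts conditional on the allele counts
(Levene–Haldane distribution), summing the probabilities of all outcomes no
more probable than the observed one. Both tests are available on demand. A
monomorphic sample returns p = 1 by convention. The exact p is discrete and
conservative; it tracks the chi-squared tail closely where decisions are
made but can exceed it visibly near p ≈ 1.

Two-locus haplotype frequencies are estimated from unphased genotypes by
EM: double heterozygotes are phase-ambiguous, so the E-step splits them
between cis and trans configurations in proportion to the current
frequency products and the M-step renormalises expected haplotype counts
(initialisation at linkage equilibrium; convergence when no frequency moves
by more than 1e−8, cap 1000 iterations; the log-likelihood is monotone and
recorded). Linkage disequilibrium is summarised by D = f(*1–*1G) −
p(*1)·p(*1G), D′ = |D|/D_max with the sign-appropriate D_max, and
r² = D²/(p_A p_a p_B p_b). If either locus is monomorphic the result is
flagged and D′/r² left undefined rather than forced to a number.

Continuous covariates are screened against PK parameters with Spearman rank
correlation (mid-rank ties, two-sided p). Raw p-values are reported, as is
conventional for descriptive cohort analyses of this size; no multiplicity
adjustment is applied by default.

## Published covariate clearance models

Three published population-PK covariate formulas for tacrolimus CL/F are
evaluated as printed (see `pubmodels`): Darley (haematocrit only), Chen
(weight, voriconazole trough, daily dose, haematocrit) and Cai (weight,
haematocrit, daily dose, postoperative time, with ×1.3 for CYP3A5*1
carriers and ×0.638 under voriconazole). Each power-law factor equals 1 at
its reference covariate, so the base constants are recovered exactly at the
reference patient. Chen's voriconazole trough defaults to its reference
value 2.02 (treated as a dimensionless ratio; the published formula carries
no units for it) when not supplied. The comparison table evaluates all
three at a typical patient — 64.5 kg, haematocrit 30%, 2 mg/day, 3.5 days
post-transplant, on voriconazole — next to the cohort's own geometric-mean
CL/F.

## Synthetic cohort generator

No public individual-level dataset of this kind exists, so the package
ships a generator whose defaults encode the study conditions the analysis
targets; all tests and examples run against it.

**Genetics.** Subjects receive two haplotypes drawn i.i.d. from a
four-entry frequency vector over (*1–*1G, *1–*1, *3–*1G, *3–*1); pairing
haplotypes makes both loci automatically HWE-consistent and fixes the LD at
exactly the configured value. Defaults (6/28, 4/28, 0, 18/28) reproduce a
CYP3A5*1 allele frequency of 10/28 and a CYP3A4*1G frequency of 6/28 in
complete LD (D′ = 1) — the "strong LD" configuration in which every *1G
allele rides on a *1 background.

**Pharmacokinetics.** Concentrations follow a steady-state one-compartment
model with first-order absorption and no lag,

    C(t) = (D·10³·k_a)/(V/F·(k_a−k_e)) · [e^(−k_e t)/(1−e^(−k_e τ)) −
           e^(−k_a t)/(1−e^(−k_a τ))],  k_e = (CL/F)/(V/F),  τ = 12 h,

the simplest structure reproducing the observed profile shape (rapid
absorption, T_max ≈ 2 h). The flip-flop degenerate case k_a = k_e is
rejected rather than handled by its analytic limit. Key defaults, with
rationale:

| parameter | default | why |
|---|---|---|
| GM CL/F, expresser / non-expresser | 18.13 / 3.37 L/h | genotype-stratified cohort geometric means |
| geometric SD of CL/F | 1.65 / 1.54 | matching between-subject variability per class |
| k_a | 1.5 h⁻¹ | rapid oral absorption; with the volumes below puts single-dose t_max at 2 h |
| V/F | GM(CL/F)/k_e* per class (≈ 203 / 37.7 L) | k_e* ≈ 0.0893 h⁻¹ solves ln(k_a/k_e) = 2(k_a−k_e); one shared k_e* keeps t_max ≈ 2 h in both classes |
| geometric SD of V/F | 1.3 | moderate, less variable than clearance |
| residual error | 10% CV, multiplicative log-normal | LC-MS/MS assays with <15% precision |
| doses | {0.5, 1, 1.5, 2, 3} mg/12 h, mode 1 mg | early-titration dose range, median 1 mg |
| LLOQ | 0.5 ng/mL | assay lower limit; censored samples flagged, not zeroed |

Randomness is split hierarchically: subject *i* draws everything from a
stream seeded by (global seed, *i*), so enlarging the cohort leaves earlier
subjects unchanged and the same seed is bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: time-varying clearance during clinical
instability, drug–drug interaction dynamics (voriconazole exposure is
implicit in the clearance levels, not modelled), correlation between
clearance and volume, dose titration by trough targeting (doses are drawn
independently of genotype, whereas clinicians up-titrate expressers),
enterohepatic recirculation, two-compartment distribution, and
concentration-dependent erythrocyte binding. Recovery results on synthetic
cohorts bound the estimation error of the pipeline, not the biological
adequacy of the one-compartment description.

## Numerical and design choices

* T_max ties break to the earliest time; C_min includes the 0-h and 12-h
  samples.
* Report cells round half-even to 2 decimals; machine-readable outputs keep
  full precision. UTF-8, comma delimiter, decimal point.
* Significance stars *, **, *** at p ≤ 0.05, 0.01, 0.001.
* The pipeline is a pure function of (inputs, config, seed); rerunning a
  simulate-block config reproduces the report bundle byte for byte.
* Validation errors name the offending subject, line or covariate; exit
  codes are 0 (ok), 1 (validation/configuration), 2 (internal).

## Problem sizes used in the checks

Distributional checks use cohorts of 500 (exposure-ratio and recovery
checks, recovering each genotype class's geometric-mean CL/F within 5%),
20 000 (law-of-large-numbers recovery of the generator's own geometric
means within 2%), 10⁴ genotypes for EM haplotype recovery within 0.02, and
200 replicate 14-subject cohorts for the power of the log-scale ANOVA
(rejection at p < 0.001 in well over 80% of replicates given the five-fold
clearance separation). These sizes put the assertion tolerances at several
sampling standard errors.

## Known limitations

* The NCA is interval-only by design: no terminal half-life, V_z/F or
  partial AUCs.
* Single-point LSS only; multi-point combinations and Bayesian MAP
  estimation are out of scope.
* The exact HWE test enumerates a single biallelic locus; no multi-allelic
  extension.
* The published covariate models are evaluated as printed, never
  re-estimated, and carry their original populations' biases.
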