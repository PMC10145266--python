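# tacropk

Dosing-interval pharmacokinetics of tacrolimus for transplant
therapeutic-drug-monitoring studies: non-compartmental analysis of
intensively sampled 12-h profiles, single-point limited-sampling strategies,
CYP3A5*3 / CYP3A4*1G pharmacogenetic statistics, published covariate
clearance models, and a synthetic steady-state cohort generator.

Tacrolimus has a narrow therapeutic index and large between-patient
variability: in early post-lung-transplant cohorts the dose-normalised
exposure differs more than tenfold between patients, much of it explained by
the CYP3A5*3 loss-of-function polymorphism (CYP3A5*3/*3 non-expressers clear
the drug several-fold more slowly than *1 carriers). The package is aimed at
clinical pharmacologists and pharmacometricians who need to turn a table of
timed whole-blood concentrations, doses and genotypes into the standard
analysis set:

* **NCA** — AUC₀₋₁₂ₕ by the linear-up log-down trapezoidal rule,
  CL/F = Dose/AUC₀₋₁₂ₕ, C_max/C_min/T_max, dose-normalised variants, and
  geometric summaries (GM ± geometric SD, geometric CV%).
* **LSS** — per-timepoint OLS of AUC₀₋₁₂ₕ on a single concentration with
  Sheiner–Beal predictive performance (MPE, MAE, F₁₅/F₂₀/F₂₅) and a clinical
  acceptability verdict (|MPE| ≤ 15%, MAE ≤ 30%, F₁₅ > 40%, F₂₀ > 45%,
  F₂₅ > 50%).
* **PGx** — carrier classification, Hardy–Weinberg tests (chi-squared or
  exact), EM haplotype estimation with D′/r², log-scale ANOVA between
  genotype classes, Spearman covariate scans.
* **Published models** — the Darley, Chen and Cai covariate formulas for
  CL/F evaluated at arbitrary covariates for cross-study comparison.
* **Simulation** — steady-state one-compartment cohorts with
  genotype-specific log-normal clearance and controllable two-locus LD, so
  every stage is testable without patient data.

See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
from tacropk import CohortPKModel, SimConfig

model = CohortPKModel.from_simulation(SimConfig(n_subjects=14, seed=1))
results = model.fit()
print(results.summary())
```

prints (abridged):

```text
Tacrolimus dosing-interval PK analysis — 14 subjects (seed 1)

Pharmacokinetic parameters by CYP3A5 carrier class
            parameter                    all           CYP3A5*3/*3          non-CYP3A5*3/*3
      C_max/D (ng/mL)  22.45 ± 2.61 (122.85)  42.91 ± 1.43 (36.69)  6.99 ± 1.36 (31.21) ***
           CL/F (L/h)   5.20 ± 2.68 (128.02)   2.72 ± 1.52 (44.10) 16.76 ± 1.45 (38.46) ***
AUC_0-12h/D (ng*h/mL) 192.20 ± 2.68 (128.02) 368.10 ± 1.52 (44.10) 59.67 ± 1.45 (38.46) ***
            T_max (h)       2.00 (1.00–4.00)      2.00 (1.00–4.00)         2.00 (1.00–2.00)

Single-point limited sampling strategies for AUC_0-12h
sampling_time_h    r2  f15_pct f20_pct f25_pct acceptable
              0 0.937       43      43      57         no
              6 0.989       86     100     100        yes
              8 0.994      100     100     100        yes
             12 0.948       29      50      57         no

Hardy-Weinberg equilibrium
  CYP3A5*3 (rs776746): observed (1, 4, 9), chi2 = 0.321, p = 0.490 (exact)
Linkage disequilibrium (CYP3A5*1 vs CYP3A4*1G)
  D = 0.1403, D' = 1.000, r2 = 0.797 (7 EM iterations)

Published covariate models at the typical patient
      model adjusted_clf ratio_to_own
     darley        21.60         4.15
       chen         6.54         1.26
        cai         5.15         0.99
this cohort         5.20         1.00
```

Reading the output: CL/F cells are geometric mean ± geometric SD with the
geometric CV% in parentheses — in this simulated 14-subject cohort the
CYP3A5*1 carriers clear tacrolimus about six times faster than *3/*3
non-expressers (16.76 vs 2.72 L/h, `***` = p ≤ 0.001 by log-scale ANOVA),
so their dose-normalised exposure is correspondingly lower. In the LSS
block, mid-interval and elimination-phase concentrations predict the full
AUC far better than the 0-h trough (R² 0.99 vs 0.94, and the trough row
fails the acceptability rule), the pattern that motivates sampling a few
hours after the dose rather than relying on troughs. The pharmacogenetic
block confirms both loci sit in Hardy–Weinberg proportions and estimates
complete LD (D′ = 1) between CYP3A5*3 and CYP3A4*1G. The final table places
the cohort's own geometric-mean CL/F next to three published covariate
models evaluated at a common typical patient (64.5 kg, haematocrit 30%,
2 mg/day, postoperative day 3.5, on voriconazole).

The same pipeline runs from the shell on CSV inputs
(`subject_id,time_h,conc_ng_ml`, `subject_id,dose_mg`,
`subject_id,cyp3a5,cyp3a4`):

```sh
tacropk simulate --out-dir cohort --seed 1
tacropk run --conc cohort/concentrations.csv --dose cohort/doses.csv \
            --geno cohort/genotypes.csv --out-dir report
tacropk adjust --model cai --wt 64.5 --hct 30 --dd 2 --pot 3.5 \
               --voriconazole --no-expresser
```

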