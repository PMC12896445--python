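# bedsweep

Radiobiological threshold analysis for radiotherapy toxicity: which α/β
ratio makes the **biologically effective dose (BED)** most predictive of a
normal-tissue complication, and what BED cutoff — hence what physical dose
per fraction — separates high-risk from low-risk treatments?

The motivating setting is peritumoral brain edema (PTBE) after primary
LINAC-based radiotherapy of convexity, parasagittal and falcine
meningiomas, where treatments range from single-fraction radiosurgery to
10-fraction hypofractionated courses and can only be compared on a common
biological dose scale.

## The model

Under the linear–quadratic model, a scheme of `n` fractions of `d` Gy has

```
BED = n·d·(1 + d / (α/β))
```

where α/β (Gy) encodes fractionation sensitivity: low for late-responding
tissue (meningioma itself, α/β ≈ 2–4), high for early-responding processes
such as the vascular/inflammatory injury behind edema. Because the *right*
α/β for predicting toxicity is unknown, `bedsweep`:

1. recomputes every tumor's BED across a grid of α/β ratios (default 2–20);
2. builds the empirical ROC curve of BED against the binary outcome at each
   ratio, with AUC and a tie-corrected Mann–Whitney p-value;
3. picks each curve's optimal cutoff as the point closest to the (0, 1)
   corner, reporting sensitivity, specificity and Youden's J
   (= sens + spec − 1);
4. selects the α/β with the highest J (jointly over cohort and subgroup
   when requested) and inverts its BED cutoff back to physical doses via
   the closed-form positive root
   `d = (−αβ + √(αβ² + 4·αβ·BED/n)) / 2`;
5. supports the surrounding survival analyses — Kaplan–Meier cumulative
   incidence, log-rank, Cox proportional hazards (Breslow/Efron ties), VIF
   collinearity diagnostics, one-way ANOVA — implemented from first
   principles and cross-checked against lifelines/statsmodels in the tests.

A seeded synthetic-cohort generator reproduces the registry's marginal
structure (fractionation mixture, dose, age, volumes, censoring) with a
proportional-hazards event mechanism driven by BED at a configurable true
α/β, so the whole pipeline — including recovery of the true α/β by the
sweep — runs and is tested without any patient data.

## Worked example

```python
from bedsweep import (SyntheticConfig, generate_cohort, sweep_alpha_beta,
                      sweep_to_frame, select_best_alpha_beta, run_report)

cohort = generate_cohort(SyntheticConfig(), seed=11)   # 67 tumors, 16 events
rows = sweep_alpha_beta(cohort, fraction_schemes=(1, 5))
print(sweep_to_frame(rows).round(3).to_string(index=False))
```

```
 alpha_beta   auc  p_value  optimal_bed_gy  sensitivity  specificity  youden_j  dose_1fx_gy  dose_5fx_gy
        2.0 0.786    0.001         178.087        0.688        0.725     0.413       17.899        7.499
        3.0 0.779    0.001         128.667        0.688        0.765     0.452       18.204        7.413
        4.0 0.781    0.001         103.957        0.688        0.765     0.452       18.490        7.336
        5.0 0.787    0.001          88.149        0.688        0.784     0.472       18.642        7.216
        ...
       14.0 0.724    0.007          51.006        0.625        0.784     0.409       20.624        6.850
        ...
       20.0 0.686    0.025          43.880        0.625        0.765     0.390       21.267        6.599
```

Each row evaluates one assumed α/β: the AUC and p-value measure how well
BED at that ratio discriminates tumors that developed edema, `optimal_bed_gy`
is the corner-optimal cutoff, and the dose columns are the physical
prescriptions isoeffective with that cutoff in 1 or 5 fractions. Here
`select_best_alpha_beta(rows)` returns `5.0` (highest Youden J of 0.472 for
this draw); `run_report(cohort, seed=11)` additionally stratifies the
Kaplan–Meier cumulative incidence at the selected cutoff (log-rank
p < 0.001 for this cohort), fits univariate/multivariate Cox models, and
computes VIF and PTV/age cutpoints.

The same pipeline is available from the shell:

```sh
bedsweep simulate --seed 11 --out cohort.csv
bedsweep sweep --input cohort.csv --grid 2:20:1 --fractions 1,5 --out sweep.tsv
bedsweep report --input cohort.csv --out-dir report/
bedsweep bed --invert --bed 40.595 --n 5 --ab 14     # -> 5.75
```

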