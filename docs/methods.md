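# Methods

## Dose model

BED is computed at prescription level from the marginal dose, assuming a
uniform dose per fraction: `BED = n·d·(1 + d/(α/β))`. No repair-kinetics,
repopulation or dose-inhomogeneity corrections are applied — the aim is the
basic LQ comparison of fractionation schemes, not a full biological dose
model. The isoeffective inversion solves `n·d²/(α/β) + n·d − BED = 0` for
its unique positive root; the round trip holds to ~1e−12 Gy and is enforced
in tests at 1e−9. For display, BED cutoffs are conventionally printed at 3
decimals and doses at 2; all internal arithmetic is full precision.

The α/β grid defaults to the integers 2–20 Gy (19 values) but accepts any
strictly increasing positive sequence.

## ROC machinery

- Orientation is fixed: `score ≥ threshold` predicts the positive
  (toxicity) class, since higher BED means higher risk.
- Threshold candidates are the unique observed scores; curves carry the two
  degenerate endpoints (sens 0/spec 1, sens 1/spec 0) for completeness.
  Reported optimal thresholds are therefore attained data values, not
  midpoints — reproducible without interpolation.
- AUC is the trapezoid over (1−specificity, sensitivity), which equals the
  Mann–Whitney concordance probability with ties counted ½ (a tested
  identity, to 1e−12).
- The AUC p-value tests H0: AUC = 0.5 via the normal approximation to the
  Mann–Whitney U statistic with the standard tie correction and no
  continuity correction (the asymptotic two-sided convention of mainstream
  statistical software). At very small n the exact permutation null is
  discrete (steps of 0.1 at 3-vs-3), so only coarse agreement with the
  exact p is possible there; the approximation tracks the exact permutation
  p within 0.02 by n ≈ 20, which the tests verify.
- The optimal cutpoint minimizes the Euclidean distance to the (0, 1)
  corner. Ties are broken by larger Youden J, then by the smaller threshold
  (the more conservative dose). Best-α/β selection is argmax of J with ties
  to the smallest ratio; the joint rule intersects the J-maximizer sets of
  cohort and subgroup first and falls back to the cohort maximizers if the
  sets are disjoint (a case the joint rule's source setting never faced).

## Survival machinery

Implemented from first principles so every quantity is auditable:

- Kaplan–Meier product-limit estimator (right-continuous; equals the
  empirical survival function when nothing is censored) and cumulative
  incidence 1 − S(t).
- Two-group log-rank with the usual hypergeometric variance; χ²(1) p-value.
- Cox proportional hazards by Newton–Raphson with step halving on the log
  partial likelihood; ties handled by Breslow (default — the convention of
  the clinical software this field mostly uses) or Efron. Convergence when
  max |score| < 1e−8 or |Δloglik| < 1e−10; Wald SEs from the inverse
  observed information. Monotone-likelihood separation is detected
  heuristically (|β| > 50, or SE exploding relative to |β|) and reported as
  `converged=False` with a diagnostic rather than raised.
- VIF_j = 1/(1 − R²_j) from auxiliary least-squares regressions with
  intercept; exact collinearity reports `inf`.
- One-way ANOVA from explicit between/within sums of squares; the scipy F
  distribution supplies the p-value only.

Tests cross-check Cox against brute-force 1-D likelihood maximization,
lifelines (no ties) and statsmodels PHReg (Breslow/Efron with ties), and
log-rank against lifelines.

## Synthetic cohort

The generator draws, in fixed order from one seeded RNG: fractionation
category (SRS 1 fx / hf-SRS 2–5 fx / hf-SRT 6–10 fx with probabilities
0.134/0.776/0.090, fraction count uniform within category), total marginal
dose per category (normal, means 17.0/28.5/31.0 Gy, SDs 1.5/2.5/3.0 — free
parameters set so the pooled mean is ≈27.2 Gy; the pooled SD comes out
≈4.7 Gy), age (truncated normal on [30, 95] whose parent parameters are
solved so the post-truncation mean/SD are exactly 68.1/11.4 y), sex (76.1%
female), location (58.2% convexity), PTV (log-normal moment-matched to
mean 9.9 / SD 14.6 cc), GTV = PTV × U(0.75, 0.95), BMI, hypertension
(52.2%), diabetes (17.9%), and a log-normal censoring time with median 678
days and σ = 0.68 (σ chosen from the mean/median ratio of the emulated
follow-up distribution, 854.9/678; matching the printed IQR instead would
imply a heavier tail inconsistent with that mean).

Older patients (≥ 70 y) carry larger, more variable tumors: their PTV scale
is multiplied by 1.8 and the whole distribution renormalized by the
expected multiplier so the pooled mean is unchanged (toggleable).

Events follow proportional hazards with
`log h = log h₀ + β·(BED(α/β*) − threshold)`: linear in BED, not a step at
the threshold, so a finite ROC-optimal cutoff emerges from the data rather
than being baked in — the threshold is only a centering constant. Event
times are exponential at the subject's hazard; observed time is the minimum
of event and censoring times. The baseline hazard h₀ is calibrated by
Brent root finding so the expected incidence given the drawn covariates and
censoring times equals the target (default 23.9%, tolerance 0.005);
calibration is deterministic given the draws, so a (config, seed) pair
always yields a byte-identical cohort.

Defaults: 67 tumors, true α/β = 14, threshold 41.079 Gy, effect size 0.08
per Gy (a registry-scale effect, of the order of published per-Gy hazard
ratios ≈ 1.06–1.08). The recovery experiment uses 0.25 per Gy as its
"strong effect" condition so that α/β is identifiable at a few hundred
tumors.

What the generator does *not* emulate: spatial dose distributions, tumor
growth, repeat courses, correlated tumors within a patient (each record is
independent; multi-tumor patients are treated as independent rows, a known
limitation of the emulated analyses too), or any real covariate joint
distribution beyond the marginals and the age–volume coupling above.
Passing tests therefore demonstrate correctness of the machinery and
identifiability under the assumed mechanism, not clinical validity on real
registries.

## Validation experiments and problem sizes

- α/β recovery: 50 replicates of 300-tumor cohorts per truth, strong
  effect. With truth 14 the median Youden-selected ratio lies in the 10–18
  plateau; with truth 3 it falls below 8. Selection is flat near the truth
  because BED orderings at neighboring ratios are highly correlated — a
  plateau, not a point estimate, is the realistic expectation.
- Null calibration: 100 replicates at effect 0; the α/β = 14 AUC stays in
  [0.35, 0.65] in ≥ 90% of replicates.
- Sizes (300 tumors, 50–100 replicates) were chosen so the full suite runs
  in well under a minute for these experiments while keeping the binomial
  noise on the checked proportions small.

## Degenerate inputs and numerical choices

- Single-class outcomes raise a dedicated error before any analysis runs;
  in the full report, an affected age *subgroup* is marked unavailable and
  the run continues.
- Constant covariates are rejected by `cox_fit`/`vif`; the report drops
  them from the VIF design with a note.
- ROC ties and corner-distance ties are resolved with a 1e−12 comparison
  tolerance to make results invariant to floating-point noise in scores.
- Cohort CSV round-trips exactly: floats are written at shortest repr and
  parsed by numpy's correctly rounded reader.

## Known limitations

- The AUC p-value is asymptotic; no exact option is exposed (the tests use
  permutation enumeration as an oracle only).
- No confidence bands on ROC/AUC, no time-dependent ROC, no competing
  risks or frailty terms, and no multiple-testing correction across the 19
  sweep p-values (matching the emulated analysis style).
- BED variants with overall-time or EQD2 corrections are out of scope.
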