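# Methods

## Score model

The teen STOP-Bang is a count score: eight dichotomous items, total 0–8,
elevated risk at total ≥ threshold (default 3, the instrument's
published operating point). Four items are questionnaire answers on a
six-level ordinal scale, dichotomized as positive iff *frequently* or
*almost always* — *don't know* is negative, following the instrument's
collapsing rule exactly. Three items are measured anthropometrics judged
against pediatric references, and one is sex. Parent- and child-reported
scores differ only in the four questionnaire items: the anthropometric
flags and sex are measurements, shared by both reporters. The neck-free
"STOP-Bag" variant (0–7) simply drops the neck item; no other item or
rule changes.

Boundary conventions, fixed to match the instrument's phrasing: blood
pressure is positive at ≥ the 95th percentile (max of systolic and
diastolic percentiles); BMI and neck are strict (> the cut). The BMI cut
is configurable (90/95/99) for sensitivity analyses. OSA status is AHI ≥
threshold with the threshold recorded (default 1.5 events/hour;
1 and 3 supported for sensitivity analyses). Ages are decimal years;
"teen" means age ≥ 13.0 exactly. The pubertal split is self-reported
sexual maturity rating (SMR, Tanner 1–5) ≥ 4, with missing SMR kept as
an explicit "unknown" stratum rather than imputed.

## Pediatric references

The package computes percentiles from three pluggable CSV tables:

* **LMS growth references** (BMI-for-age, height-for-age): columns
  `sex, age_months, L, M, S`. z = ((x/M)^L − 1)/(L·S), with the
  log-normal limit ln(x/M)/S taken for |L| < 1e-7; percentile =
  Φ(z)·100. L, M and S are each interpolated linearly in age between
  bracketing rows (standard growth-chart practice), which makes the
  percentile continuous in age across knots — a property the tests
  check to 1e-6. The inverse transform x = M(1 + LSz)^(1/L) returns NaN
  outside the Box-Cox support (1 + LSz ≤ 0), where no positive
  measurement exists.
* **Blood pressure**: columns
  `sex, measure, intercept, a1..a4, h1..h4, sd`. Expected pressure =
  intercept + Σⱼ aⱼ(age − 10)ʲ + Σₖ hₖ zₖ_height, a fourth-degree
  polynomial in centered age and in the height-for-age z-score — the
  functional form of the pediatric blood-pressure task-force
  references; percentile = Φ((observed − expected)/sd)·100. The
  observed value is the mean of the 2nd and 3rd seated readings,
  averaged at ingestion.
* **Neck circumference**: columns `sex, age_years, p95_cm`, looked up
  at the nearest integer age (the reference is tabulated by year).

The bundled defaults (`src/stopbang/data/*_synthetic.csv`) are synthetic
tables: smooth curves with realistic magnitudes covering ages 9–18,
*not* the published CDC/task-force values. Correctness of this module
means correctness of the formulas against whatever tables are plugged
in; analyses of real cohorts should substitute the published tables via
`load_reference_set(directory)`. Percentiles are clipped to the open
interval (0, 100) by 1e-12 so downstream flags and logs never see 0 or
100 exactly, and are reported uncapped otherwise (any display capping is
a reporting concern).

## Diagnostic accuracy panel

From a 2×2 table at a score threshold: sens = tp/(tp+fn),
spec = tn/(fp+tn), ppv = tp/(tp+fp), npv = tn/(tn+fn). A quantity whose
denominator is zero is reported as undefined (None, with a note), never
silently zero. LR+ = sens/(1−spec), LR− = (1−sens)/spec.
**Prevalence-adjusted likelihood ratios** are defined as the likelihood
ratio times the pre-test odds p/(1−p) — the post-test odds of disease
after a positive (LR+[P]) or negative (LR−[P]) result. This definition
satisfies LR+[P] = PPV/(1−PPV) and LR−[P] = (1−NPV)/NPV when the
predictive values are computed at the same prevalence via Bayes, an
identity the tests assert to 1e-12. The prevalence defaults to the
analyzed cohort's own (the evaluation convention is to use the whole
cohort's prevalence in every stratum) and is overridable.

Intervals: proportions use the Wilson score interval by default —
verified in the tests against the direct quadratic solution — with
Clopper–Pearson selectable, since small-sample interval choice is a
judgment call and the two bracket common practice. Likelihood-ratio CIs
use the log method, se(ln LR+) = √(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn))
(mutatis mutandis for LR−), with +0.5 added to all four cells and a
recorded flag when a required cell is zero. Adjusted-LR intervals scale
the LR interval by the pre-test odds (the prevalence is treated as
fixed, not estimated). Report display rounds half-up to the
conventional printed precision (1 dp for LRs, 2 dp for proportions);
internal values are never rounded.

## ROC and DeLong

The empirical AUC is tie-corrected pair counting — P(case score >
control score) + ½P(tie) — computed through midranks in O(n log n). It
equals the trapezoidal area under the empirical ROC exactly; the test
suite holds the two implementations together to 1e-12, and checks
AUC(−s) = 1 − AUC(s). Variance and CIs use DeLong's structural
components: each subject's placement value (fraction of the other class
it beats, ties half; midrank convention, consistent with the trapezoid
geometry), with Var(AUC) = var(V₁₀)/m + var(V₀₁)/n (sample variances,
ddof 1). The CI is the normal approximation truncated to [0, 1] with a
truncation flag. Paired comparisons (two scores, same subjects — e.g.
parent vs child report, or STOP-Bang vs STOP-Bag) subtract twice the
placement covariance from the variance of the difference; unpaired
comparisons (disjoint strata: teen vs preteen, SMR ≥ 4 vs < 4) use
z = ΔAUC/√(var₁+var₂). The implementation reproduces R pROC's DeLong
variance, CI and paired test to all printed digits on a fixed fixture.

Coverage behavior, measured with this package's own simulator (ordinal
0–8 scores, n = 312, prevalence 0.08): the 95% DeLong interval covers a
generating AUC of 0.6/0.7/0.8 in about 93.3/93.4/92.2% of replicates.
The mild undercoverage at high AUC is the known small-positive-count
behavior of the Wald-form interval (about 25 cases at this prevalence)
and is what the acceptance band [0.92, 0.98] is checked against.

## Nonparametric tests

Ordinal count scores are far from normal (the package exposes the
one-sample KS check that motivates this, with the Lilliefors caveat
recorded whenever parameters are estimated from the sample, and the
corrected variant as an option). Paired reporter comparisons use the
Wilcoxon signed-rank test with Wilcoxon's zero-drop rule (not Pratt's —
the most common default, recorded in `method_notes`) and midranks for
tied magnitudes. With ≤ 12 nonzero differences the two-sided p-value is
exact, by enumeration of all 2ⁿ sign patterns (valid under ties);
otherwise a tie- and continuity-corrected normal approximation is used.
Group comparisons use Mann-Whitney U: exact null distribution when
tie-free and n_A·n_B ≤ 400, else the tie-corrected normal approximation
with continuity correction. Exact two-sided p-values are defined as
min(1, 2·min(lower tail, upper tail)) with the observed statistic
included in both tails; the tests verify them against brute-force
enumeration oracles over every tie-free configuration up to n = 8.
Quantiles (median, 25th/75th) interpolate linearly between order
statistics.

## Synthetic cohorts

The generator emulates the structure of a community adolescent cohort:
n = 312, OSA prevalence 0.08, ages uniform on 9–17.6, SMR missing for
21/312, AHI log-normal with median ≈ 0.2 for healthy children
(truncated below the 1.5 threshold) and ≈ 2.2 for OSA (shifted above
it), so truth labels and AHI are consistent under the diagnostic rule
in every record by construction.

Given OSA status, the eight items are independent Bernoulli draws,
exchangeable within class. The per-class item probability is calibrated
by inverting the Binomial(8, p) tail so that P(score ≥ 3 | OSA) = 0.64
and P(score ≥ 3 | healthy) = 0.18 — the instrument's headline operating
point — exact to the root-finder tolerance (1e-12). Child questionnaire
answers copy the parent's with probability 0.7 per item, else are
redrawn from the same class-conditional law; 0.7 was chosen once as a
realistic dyad-agreement rate (published parent–child symptom agreement
is moderate, and the pattern of matching medians with imperfect
individual agreement is what this produces) and is configurable.
Positive items are rendered as *frequently*/*almost always* (uniform),
negative items as the four negative levels with weights
0.05/0.45/0.30/0.20.

Anthropometrics are **back-solved from the intended flags** rather than
sampled from realistic joint distributions: height sits at the
reference median, BMI at a percentile clearly on the intended side of
the cut, systolic pressure at expected + 1.8 SD when flagged (else
expected), neck 1 cm above or 2 cm below the tabulated 95th percentile.
Scoring the generated records through the pediatric-reference module
therefore reproduces the generated item flags exactly — the tests
assert record-level equality with the direct item-model totals. The
consequences are deliberate: flags, not raw measurement distributions,
drive the score, so passing simulation tests demonstrates correctness
of the scoring/evaluation machinery and calibration of the interval
estimates, **not** realism of anthropometric covariance (no BMI–OSA
association strength, no ethnicity effects, no item correlation within
class). A correlation knob for items is future work.

## Problem sizes and determinism

One top-level `numpy` generator per simulation, seeded from a single
integer; no global state. Re-running any pipeline or CLI command with
the same inputs and seed is byte-identical (reports embed the
configuration and package version, never timestamps). The standard
simulation studies use the cohort's own scale: operating-point recovery
at n = 176 (the teen stratum size) over 200 replicates, DeLong CI
coverage at n = 312 over 500 replicates, Mann-Whitney type-I error at
n = 30/group over 2000 replicates — sizes at which each study's Monte
Carlo error is small relative to the band being checked, while the
whole suite stays interactive.

## Known limitations

* Bundled reference tables are synthetic; real-cohort analyses must
  plug in published tables.
* The exchangeable-item generative model cannot express item
  correlation or reporter-specific item difficulty.
* DeLong intervals mildly undercover with few positive cases (see
  above); a logit-transformed interval is not implemented.
* The SPSS (.sav) reader depends on the optional `pyreadstat` extra;
  the canonical interchange format is CSV.
* Raw polysomnogram signal scoring is out of scope; the package starts
  from the AHI.
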