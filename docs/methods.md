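# Methods

## The decision rule

`oadx` implements a two-step synovial-fluid test for differentiating
primary osteoarthritis (OA) from inflammatory arthritis (rheumatoid
arthritis, crystalline arthritis, native septic arthritis) in knee
aspirates, built on two biomarkers:

* **COMP** (cartilage oligomeric matrix protein, ng/mL) — released by
  degrading cartilage; elevated in OA but also in other
  cartilage-destroying arthritides.
* **IL-8** (interleukin-8, pg/mL) — a pro-inflammatory chemokine; low in
  primary OA, elevated in inflammatory and septic joints.

A specimen is called *primary-OA positive* iff

    COMP > L_comp   and   COMP/IL-8 > L_ratio

with both comparisons strict ("above the limit"; equality is negative —
covered by a boundary test). The ratio is the plain quotient of the
reported concentrations (ng/mL over pg/mL); no unit conversion is
applied, matching how the score was validated. Failing the first gate
means no measurable cartilage deterioration (reason
`below_comp_limit`; no ratio is computed, mirroring reflex-testing
practice). Passing the first but not the second means cartilage damage
inside an inflamed joint — potential *secondary* OA (reason
`low_ratio`).

Parameters:

* `comp_limit` — 1500 ng/mL, the published clinical decision limit; used
  as the default in the CLI but explicit in the library API.
* `ratio_limit` — **no default anywhere**. The validated ratio limit is
  proprietary and has never been published. Examples and tests use 2.0,
  always labelled illustrative. Sweeping it produces monotone positivity
  curves (a tested invariant), so conclusions about ordering of cohorts
  are insensitive to the exact value.

Values reported at assay quantitation limits (IL-8 LLOQ 102.4 pg/mL,
ULOQ 40,000 pg/mL; COMP LLOQ 0.2 ng/mL) enter the ratio as-is; censor
flags are carried on the specimen for transparency but never alter a
call.

## Diagnostic accuracy

Condition positive is clinically diagnosed primary OA; RA, CA and NSA
are pooled as condition negative. From the 2×2 table: sensitivity
tp/(tp+fn), specificity tn/(tn+fp), overall accuracy (tp+tn)/n.
Proportion intervals are exact Clopper–Pearson (beta quantiles), chosen
because it reproduces the printed validation intervals and is
conservative — tests assert both the defining binomial-tail root
property (to 1e-6 against a `brentq` oracle) and exact coverage ≥
nominal computed by pmf summation, alongside a 50,000-rep seeded
simulation.

Predictive values use Bayes' theorem at an arbitrary prevalence,

    PPV = se·p / (se·p + (1−sp)(1−p)),  NPV = sp(1−p) / (sp(1−p) + (1−se)p),

which at the sample prevalence coincide exactly with the column ratios
tp/(tp+fp) and tn/(tn+fn) (property-tested to 1e-12). Prevalence-
weighted accuracy is p·se + (1−p)·sp. Prevalence must lie strictly in
(0,1); degenerate populations are rejected. Likelihood ratios
LR+ = se/(1−sp), LR− = (1−se)/sp carry standard log-method intervals on
the counts; a zero false-positive margin yields a flagged infinite LR+
(rendered `>999`), not an exception. PPV/NPV intervals use the logit
delta-method (Mercaldo-style); the interval method behind the originally
printed PPV/NPV bounds is not documented anywhere, so these bounds are
informational. Reported percentages round half-up to one decimal, LR+
to one decimal, LR− and Youden's J to two — the conventional printed
precision.

## ROC analysis

The continuous score is the COMP/IL-8 ratio. Because the published
algorithm computes no ratio below the COMP gate, two scoring policies
are explicit: `ratio_everywhere` (default; simplest reading of a
ratio-based ROC) and `gated_zero` (gate failures score 0 — they can
never be positive at any ratio limit). The policy is recorded in
outputs.

The empirical curve uses strict-`>` thresholding at the distinct score
values (ties grouped), runs from (0,0) to (1,1), and AUC is trapezoidal
— identical to the Mann–Whitney pairwise-ordering probability with
half-credit ties, an identity asserted on hundreds of random datasets
and against scipy's U statistic. The AUC interval is DeLong's
(placement-value variances), truncated to [0,1]. The Youden-optimal
threshold maximises tpr − fpr with ties broken toward the larger
(more specific) threshold.

## Supporting statistics

* Median/IQR summaries use linear interpolation between order statistics
  (numpy's default quantile convention; conventions differ between
  packages, so this one is fixed and documented).
* Mann–Whitney: exact null when pooled n ≤ 12 with no ties (verified
  against full enumeration), otherwise normal approximation with midrank
  tie correction and continuity correction.
* Mood's median test: values above vs. not-above the grand median per
  group, chi-square on the 2×k table without continuity correction at
  any k (the Minitab-style convention; uncorrected 2×2 reproduces the
  hand-computed example statistic). All-identical input raises a
  degenerate-table error.
* One-sample proportion: exact two-sided binomial (minimum-likelihood);
  for n ≥ 30 the continuity-corrected normal p is also reported, since
  that is what large-sample software typically prints. Both agree to
  three decimals on the validation cohort's 28/54 sex split (p ≈ 0.892).

## Crystal microscopy rules

The decision table maps coded observations (shape, birefringence
strength, compensated colors, optional intra/extracellular location) to
MSU → gout, CPPD → CPPD disease, plate-like → cholesterol, no
birefringent bodies → none; any partially matching combination is
`indeterminate`, never coerced. The table is total over the valid
observation space (exhaustively enumerated in a test). Location never
alters a call. Cohort prevalence counts a mixed MSU+CPPD specimen once
toward combined positivity but once per class in per-class counts;
cholesterol is excluded from crystal-arthritis positivity. Specimens
without microscopy are excluded from the denominator.

## Synthetic cohorts

Only cohort-level summaries (median and IQR per analyte, censored at
quantitation limits) are published for the four validation cohorts
(54 OA / 57 RA / 30 CA / 30 NSA), so the generator is calibrated to
those. Design choices:

* **Split log-normal marginals.** log X is Gaussian with separate scales
  below/above the median, so the three published quantiles are matched
  *exactly*. The published IQRs are strongly asymmetric in log space
  (the RA COMP quartiles are 0.2 / 0.2 / 2442 ng/mL); no symmetric
  two-parameter log-normal comes close, which is why the simple
  quartile-matching fit (`lognormal_from_median_iqr`, retained as the
  reference parameterisation) is not what the generator samples from.
* **Censoring-aware calibration.** A published quartile sitting at a
  quantitation limit is treated as censored: the latent scale on that
  side is set so the censored mass exceeds that quartile's probability
  by a 0.15 z-margin, so clamping reproduces the published value
  robustly instead of balancing on a knife edge. Clamped draws carry
  censor flags (flags occur iff the value sits at a limit — tested).
  The IL-8 ceiling of 40,000 pg/mL is inferred from the NSA upper
  quartile sitting exactly there.
* **Stratified inverse-CDF sampling through a Gaussian copula.** The two
  analytes' latent normals are drawn jointly (copula correlation
  `rank_correlation`, default 0 — no joint information is published),
  then each margin receives stratified uniforms ordered by the copula
  ranks. Empirical quantiles then deviate from the calibration by at
  most ~1/n in probability, so a 10,000-draw cohort recovers every
  calibration cell to well under the 5% test tolerance at any seed —
  plain iid sampling could not pin the RA COMP upper quartile (its
  quantile density spans four orders of magnitude) at that n. Individual
  draws remain random and seeds reproduce datasets bit-identically.
* The published IL-8/ratio summaries describe only COMP-above-limit
  specimens; the generator calibrates marginals to the printed values
  uniformly — a documented approximation affecting only the synthetic
  data, not the validation-count analyses.

What passing the synthetic tests shows: the pipeline's plumbing,
monotonicity, and separation behaviour on data with the study's marginal
shapes. What it cannot show: real joint COMP–IL-8 dependence, KL-grade
dependence of IL-8, or the study's actual per-specimen ratios — none of
which were published. The printed AUC (0.93) is therefore a qualitative
reference only; synthetic studies land in the high-0.8s with independent
analytes.

## Numerical notes and limitations

* Percent formatting is decimal half-up; two printed CI lower bounds in
  the original write-up differ from exact Clopper–Pearson by 0.1
  percentage point (their calculator's rounding); this package reports
  its computed values.
* The validation-count fixture encodes the printed 2×2 table
  (47/7/13/104), per-grade subgroup counts (KL 2/3/4: 9/25/20 with
  8/22/17 true positives — the unique integers consistent with the
  printed n, sensitivities and margins, marked derived), and per-cohort
  positivity. Fixture specimens for the subgroup table carry placeholder
  biomarker values; only diagnosis, grade and call are meaningful.
* Specimen-integrity QC (spectrophotometry/cell counts) is exposed as a
  pluggable `qc_hook` predicate on the CSV loader, not implemented.
* No multiplicity adjustment is applied anywhere (none was used in the
  validation analysis); no multi-class confusion matrix (the three
  inflammatory cohorts are pooled by design).
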