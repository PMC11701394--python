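# oadx

Synovial-fluid dual-biomarker algorithm for differentiating **primary
osteoarthritis (OA)** from **inflammatory arthritis** (rheumatoid,
crystalline, native septic), with the complete diagnostic-accuracy
analysis around it.

Late-stage OA is hard to tell apart from other arthritides because they
all destroy cartilage. The test combines two knee synovial-fluid
markers: COMP (cartilage oligomeric matrix protein, released by
degrading cartilage) and IL-8 (a pro-inflammatory chemokine, low in
primary OA). A specimen is called primary-OA positive when

```
COMP > L_comp        (cartilage deterioration present)
COMP / IL-8 > L_ratio  (…without an inflammatory drive)
```

both comparisons strict. High COMP with a *low* ratio flags potential
secondary OA (cartilage damage in an inflamed joint); low COMP means no
measurable deterioration. `L_comp` is 1500 ng/mL; the validated
`L_ratio` is unpublished, so it is a required parameter everywhere
(examples use 2.0, illustrative only).

The package provides, as a plain Python library plus a thin `oadx` CLI:

* the two-step classifier with typed specimens, censor flags and reason
  codes (`oadx.model`);
* full diagnostic-accuracy evaluation: exact Clopper–Pearson intervals,
  predictive values and accuracy at arbitrary disease prevalence,
  likelihood ratios with log-method intervals, Youden's J, per-subgroup
  sensitivity tables (`oadx.accuracy`);
* ROC/AUC for the ratio score with DeLong intervals and Youden-optimal
  thresholds (`oadx.roc`);
* supporting nonparametrics: Mann–Whitney (exact for small untied
  samples), Mood's median test, exact one-sample proportion
  (`oadx.cohort_stats`);
* polarized-light crystal microscopy decision rules (MSU/gout,
  CPPD/pseudogout, cholesterol) and cohort crystal prevalence
  (`oadx.crystals`);
* a seeded synthetic-cohort generator calibrated to the validation
  study's published cohort medians/IQRs with assay-limit censoring, plus
  the study's exact printed counts as a built-in fixture
  (`oadx.synthetic`);
* CSV/JSON/TSV I/O and the CLI (`oadx.io`, `oadx.cli`).

## Worked example

```python
from oadx import (DecisionLimits, build_contingency, classify_cohort,
                  full_report, generate_study, render_report)

study = generate_study(seed=17)              # 54 OA / 57 RA / 30 CA / 30 NSA
limits = DecisionLimits(comp_limit=1500.0, ratio_limit=2.0)  # 2.0 illustrative
results, _ = classify_cohort(study.specimens, limits)
ct = build_contingency(results, study.truth)
print(render_report(full_report(ct), "text"))
```

prints (abridged):

```
n = 171   prevalence used = 31.6%   confidence = 95%

              condition+  condition-
test positive         47          27
test negative          7          90

Sensitivity       87.0% (75.1%–94.6%)
Specificity       76.9% (68.2%–84.2%)
LR+               3.8 (2.7–5.3)
Youden J          0.64
```

i.e. on this simulated study the rule finds 47 of the 54 true primary-OA
specimens (sensitivity 87.0%, with its exact 95% interval), while 27 of
117 inflammatory specimens are falsely flagged at this illustrative
ratio gate; a positive result raises the odds of primary OA 3.8-fold.
The `examples/` directory has one short script per capability
(classification, the validation-count report, simulation + ROC, crystal
rules); each prints its numbers with a line on what they mean.

The validation study's own printed counts are built in:

```
oadx fixture-report                     # sensitivity 87.0% (75.1%–94.6%), …
oadx fixture-report --prevalence 0.6    # PPV 92.2%, NPV 82.1%, accuracy 87.8%
```

Other CLI commands: `oadx classify`, `oadx evaluate`, `oadx roc`,
`oadx simulate`, `oadx crystals` (see `--help`).

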