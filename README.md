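# bagpipe

Brain-age-gap estimation and group inference for MRI-derived feature
tables.

## What it does

In brain-age studies, a regression model is trained to predict
chronological age Ω from structural MRI features in a large healthy
cohort, then applied to a clinical sample.  The *brain-age gap*

    BAG = corrected predicted age − Ω      (years)

summarises whether a brain "looks older" than its owner.  Because
imperfect models over-predict the young and under-predict the old, the
raw prediction Y is first de-biased with the line Y = αΩ + β fitted in
the training sample:

    corrected = Y + Ω − (αΩ + β).

`bagpipe` implements that pipeline end to end:

* **Age prediction** — XGBoost regression (depth 3, 180 trees, learning
  rate 0.1) on subject-by-feature tables (T1 morphometry and/or DTI
  tract metrics), validated by 5-fold cross-validation with repeated
  shuffles and an optional nested grid search; R², RMSE, MAE reported
  as mean ± SD over fold records.
* **Age-bias correction and BAG** — the (α, β) line is fitted on
  out-of-fold training predictions by default and applied to the
  patient sample.
* **Group inference** — carrier vs non-carrier comparisons (e.g. APOE
  ε4 status) by multiple linear regression with age, sex and head-coil
  covariates (plus intracranial volume for volumetric outcomes),
  descriptive cohort tables (pooled t / Pearson chi-square), and
  Benjamini–Hochberg FDR control at Q = 0.1 per analysis family.
* **Synthetic cohorts** — a generator with known ground truth (feature
  trajectories evaluated at Ω + δ for carriers) so the whole pipeline
  is testable without clinical data, including exact recovery targets
  for the injected shift δ.

See `docs/methods.md` for the model, the generator's two calibrated
regimes, and numerical conventions.

## Worked example

Run the bundled demo (a scaled-down synthetic study with a 3-year
carrier brain-age shift injected):

```sh
bagpipe run --config examples/demo.yaml --out demo_out
```

This simulates cohorts, trains both modality models, cross-validates,
predicts and bias-corrects patient ages, and compares carriers with
non-carriers.  Key lines from the resulting reports:

```text
# demo_out/test_metrics.tsv
modality  n  r2_raw  rmse_raw  mae_raw  r2_corrected  rmse_corrected  mae_corrected
      T1 80   0.967     2.772    2.327         0.968           2.697          2.257
     DTI 80   0.953     3.303    2.723         0.957           3.144          2.597

# demo_out/bag_regression.tsv (group-term rows)
outcome   beta     se        p  r_squared  fdr_significant
bag_dti 2.0588 0.4258  6.9e-06     0.3950             True
 bag_t1 3.1355 0.3212  5.3e-15     0.5923             True
```

Reading the regression rows: the estimated carrier effect on the
T1-based brain-age gap is β ≈ 3.1 years (SE ≈ 0.32, FDR-significant at
Q = 0.1), recovering the injected 3-year shift; the DTI-based estimate
(β ≈ 2.1) is attenuated because this small demo uses only 48 DTI
features.  `cv_report.tsv` holds the training
cross-validation table and `descriptives.tsv` the carrier vs
non-carrier demographic tests.

The same stages are available as composable subcommands
(`simulate | train | cv | predict | bag | compare | report`) and as
library functions (`bagpipe.fit_age_model`, `bagpipe.fit_bias`,
`bagpipe.compare_groups`, ...).

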