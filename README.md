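# endomark

Analysis pipeline for evaluating proteins of the endocytic machinery as
predictive biomarkers for antibody–drug conjugates (ADCs), built around the
case of RAB5A and trastuzumab emtansine (T-DM1) in HER2-positive breast
cancer.

Unlike plain monoclonal antibodies, an ADC must be internalized by
receptor-mediated endocytosis before its cytotoxic payload can act, so the
drug target (HER2) alone may not predict response: proteins controlling
endosomal transport — such as the early-endosome GTPase RAB5A — are
candidate biomarkers in their own right. This package implements the full
statistical chain needed to evaluate such a candidate, from cell-line
dose–response to trial-level subgroup estimation:

- **Dose–response** (`endomark.dose_response`): the sigmoid viability model
  *v = a/(1 + exp(−(x − x₀)/b))* on x = log₁₀ concentration, IC50 as the
  absolute half-viability concentration (closed form
  x\* = x₀ − b·ln(a/0.5 − 1)), and OLS of sensitivity 1/IC50 on marker
  expression with R².
- **Qualifying-biomarker tests** (`endomark.association`): per-arm logistic
  association of marker with pathologic complete response (pCR), reported as
  odds ratio per 1 SD of expression with likelihood-ratio (LR) χ²₁ p-values;
  the biomarker×treatment interaction model across experimental and control
  arms; HR-status adjustment; Fisher exact and Mann–Whitney tests for
  balance checks.
- **Threshold discovery** (`endomark.threshold_cv`): Monte-Carlo 2-fold
  cross-validation — per iteration, a balanced half-split, a scan of every
  unique training value in the 10th–90th percentile window as a candidate
  dichotomizing threshold, interaction LR p minimization on the training
  half, evaluation on the held-out half — with test-set p-values combined by
  the logit method (Student-t with 5k+4 df).
- **Bayesian subgroups** (`endomark.bayes`): the saturated subtype×treatment
  logistic model (subtype = HR status × marker group) with N(0,1) priors,
  sampled by adaptive random-walk Metropolis, giving posterior pCR
  probabilities with 95% probability intervals per arm and marker subset.
- **ROC analysis** (`endomark.roc`): ROC curves of expression against pCR,
  trapezoidal AUC (≡ Mann–Whitney U/(n₊n₋)), Youden-index optimal cutoff.
- **IHC verification** (`endomark.allred`): Allred scoring
  (intensity 0–3 + stained proportion 0–5), dichotomization at scores 7–8,
  and the rank-sum progression-free-survival comparison.
- **Synthetic cohorts** (`endomark.simulate`): fully seeded generators for
  the trial cohort (arm sizes 52/31/44, arm-specific biomarker shift, pCR
  from a logistic model with a biomarker×treatment interaction and an
  HR-status covariate), the five-line in-vitro panel, and the IHC cohort.
- **Preprocessing** (`endomark.preprocess`): probe-to-gene collapsing by
  averaging and a per-gene location–scale cross-platform adjustment.

Everything is orchestrated by `endomark.pipeline.run_pipeline` (JSON report
validated against `docs/report.schema.json`) and the `endomark` CLI; the
numbered scripts under `analysis/` run the stages as a narrative and write
tables under `results/`.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/04_threshold_cv.py
python analysis/05_bayesian_subgroups.py
```

On the default synthetic cohort (seed 1) this prints a selected RAB5A
threshold of 11.007 with a combined test-set interaction p of 7.5e-18, and
the posterior pCR estimates:

```
  arm  subset  mean_pcr_pct  pi95_low_pct  pi95_high_pct
TDM1P overall          51.5          39.9           63.2
TDM1P    high          64.4          39.7           85.9
TDM1P     low          49.5          36.5           62.7
   TH overall          31.3          21.3           42.7
   TH    high          35.5          18.5           55.1
   TH     low          29.4          17.5           43.6
```

Read: in the experimental arm the marker-high subgroup has a clearly higher
estimated pCR probability (64%) than the control arm (36%), while the
marker-low subgroups differ much less — the signature of a predictive (not
merely prognostic) biomarker. The corresponding ROC AUCs
(`analysis/06_roc_cutoff.py`) are 0.770 in the experimental arm and 0.333
in the control arm. Real patient-level tables can replace the simulated
cohort anywhere via `--cohort-csv` (columns
`patient_id,arm,hr_status,pcr,platform,RAB4A,RAB5A,RAB11A,ERBB2`).

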