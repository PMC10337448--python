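# schedquit

Computational core of a scheduled-smoking (gradual reduction) cessation
trial: a deterministic 21-day reduction-schedule generator, expired-CO
compliance metrics, ITT / respondent-only abstinence analysis with
logistic effect estimates, and compliance-adjusted causal (complier
average effect) estimation via both the Bloom estimator and a
full-information maximum-likelihood bivariate probit. A seeded
synthetic three-arm trial generator emulates the design's statistical
structure (stratified allocation, confounded compliance, CO
measurements, visit-wise missingness) so the whole pipeline is testable
end to end without real data.

## Modules

| Module | What it does |
| --- | --- |
| `schedquit.schedule_engine` | 21-day quota / prompt-time schedule from a smoker profile (stepped percentage-point reduction, quarter-hour grid, weekly first-prompt delay, bedtime truncation, 3–4 cigarette endgame floor). |
| `schedquit.synthetic_trial` | Seeded three-arm trial datasets: stratified allocation, latent bivariate-normal compliance/outcome confounding, CO pairs consistent with the ≥50% reduction classification, per-arm per-visit response rates. |
| `schedquit.compliance_metrics` | CO percent-reduction score with the inclusive ≥50% compliance cutoff; ±5-minute on-schedule adherence matching. |
| `schedquit.outcome_analysis` | Verified point-prevalence abstinence (self-report + CO &lt; 10 ppm) under ITT/RO rules; logistic odds ratios with Wald CIs, covariate adjustment, Bonferroni families; compliance subgroup construction. |
| `schedquit.late_estimation` | Bloom estimator (with an uncentered variant and a participant-resampling bootstrap) and FIML biprobit with endogenous binary compliance; complier-effect probability differences with delta-method CIs. |

## CLI

```bash
# 21-day schedule for a 23 cpd smoker awake 07:00-23:00
schedquit schedule --cpd 23 --wake 07:00 --bed 23:00 --out schedule.csv

# synthetic trial (optional YAML overrides for any TrialConfig field)
schedquit simulate --config trial.yaml --seed 42 --out trial.csv

# arm (or --subgroups compliance) odds ratios for one visit
schedquit analyze --in trial.csv --visit 2wk --rule ITT --adjusted --out effects.csv

# complier probability differences (bloom | biprobit)
schedquit late --in trial.csv --visit 2wk --method biprobit --seed 7 --out late.csv
```

## Notes

* Baseline-CO distribution and some covariate prevalences in the
  generator are documented placeholders (`COBaselineModel`,
  `CovariateModel`); they do not affect the calibrated compliance or
  abstinence probabilities.
* The generator's complier thresholds are calibrated against the latent
  selection, so the configured complier effects are the exact
  generating causal differences — that is what the estimator-recovery
  tests check.
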