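# tcdasym

Transcranial-Doppler (TCD) middle-cerebral-artery (MCA) asymmetry
analysis for stroke-outcome prediction, with a seeded synthetic-cohort
generator so the whole pipeline is testable without patient data.

From bilateral spectral-Doppler measurements (peak systolic velocity
PSV, end-diastolic velocity EDV, insonation depth) the package computes:

- **mean flow velocity** `MV = EDV + (PSV − EDV)/3` and
  **pulsatility index** `PI = (PSV − EDV)/MV`;
- segment classification by depth: proximal M1 (58–68 mm), distal M2
  (44–56 mm); out-of-window depths are rejected, not reassigned;
- the composite **MCA index** `100·(MV + 10·PI)/(MV − 10·PI)` (percent,
  undefined and flagged when `MV ≤ 10·PI`), its proximal/distal mean,
  and bilateral **asymmetry indices** `200·|R − L|/(R + L)` for the MCA
  index, MV and PI;
- two-group descriptive comparisons (Mann-Whitney/t test,
  chi-square/Fisher exact with small-expected-count routing);
- univariable and covariate-adjusted logistic regression for poor
  3-month outcome (modified Rankin Scale ≥ 3, or ≥ 2 as a sensitivity
  threshold) with Wald 95% CIs;
- ROC analysis of the overall asymmetry index with Youden-optimal cutoff
  selection (strict `score > cutoff` rule, ties to the smallest cutoff);
- two-rater intraclass correlation, ICC(2,1) absolute agreement;
- a calibrated log-normal cohort simulator whose planted mechanism is a
  lower between-side correlation in the poor-outcome group.

## CLI

```sh
# generate a synthetic cohort (patients.csv + velocities.csv)
tcdasym simulate --seed 42 --out cohort/            # optionally --params params.json --n 500

# per-patient MCA index profiles
tcdasym profile --velocities cohort/velocities.csv --out profiles.csv

# full analysis: descriptive tables, models, ROC cutoff
tcdasym analyze --patients cohort/patients.csv \
    --velocities cohort/velocities.csv --out results/ \
    --threshold 3            # or --cutoff 9 to fix the dichotomization

# inter-rater reliability (velocity file with two raters)
tcdasym reliability --velocities velocities.csv --out icc.csv
```

`analyze` writes `table1.csv` (covariates), `table2.csv` (TCD indices),
`roc_curve.csv`, `profiles.csv` and `models.json` (univariable screen,
adjusted continuous fit, dichotomized-indicator fit, ROC summary).  The
whole chain is byte-deterministic for a fixed seed.

Input formats (plain CSV, UTF-8):

- velocities: `patient_id,side,depth_mm,psv_cms,edv_cms,rater`
  with `side ∈ {R, L}`;
- patients: `patient_id,age,sex,nihss,mrs_3mo,hemoglobin,esr,d_dimer,
  time_to_tcd,htn,dm,chol,smoker,cad,pad`.

## Library use

```python
from tcdasym import (
    default_params, generate_cohort, patient_profile, roc_youden,
)
from tcdasym.pipeline import run_analysis

records = generate_cohort(default_params(), seed=42)
profile = patient_profile(records[0].samples)
print(profile.overall_asym)

results = run_analysis(records, threshold=3)
print(results["roc"].youden_cutoff, results["adjusted"].summary_frame())
```
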