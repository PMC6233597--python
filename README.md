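# icisskit

Tools for scoring injury severity from routinely collected hospital data
and for internally validating outcome-prediction models built on those
scores. The intended users are injury epidemiologists and health-services
researchers working with linked hospitalisation–mortality extracts, where
chart-review severity scales (AIS/ISS) are unavailable and severity must be
derived from the ICD diagnosis codes already on the record.

## The method

For each injury diagnosis code *d*, the **survival risk ratio** is

    SRR(d) = (carriers of d who survived 90 days from index admission) / (carriers of d)

estimated over all index injury admissions (principal diagnosis S00–T89).
A patient's **ICISS** (ICD-based Injury Severity Score) is either

* multiplicative: `ICISS = Π_d SRR(d)` over their distinct injury codes, or
* single worst-injury: `ICISS = min_d SRR(d)`.

Logistic models predict 90-day mortality and ICU admission from an ICISS
variant plus incremental covariates (age group, sex, Charlson comorbidity
group, mental-health/alcohol/drug flags, trauma service level, injury
mechanism, nature of injury) — a registry of eight nested mortality models
and seven ICU models. Discrimination, fit and calibration (c-statistic,
AIC, Nagelkerke R², Hosmer–Lemeshow) are corrected for optimism by a
non-parametric bootstrap: refit on each resample, evaluate on resample and
original, subtract the mean excess. Because real linked extracts cannot be
shipped, a calibrated synthetic generator with known ground truth stands in
for the data and makes every stage testable; see `docs/methods.md` for the
model details and its limits.

## Worked example

```python
from icisskit.synth import default_config, generate
from icisskit.linkage import build_periods, select_index_admissions, flag_death90
from icisskit.comorbidity import attach_comorbidity
from icisskit.severity import SurvivalRiskRatioScorer
from icisskit.models import model_registry
from icisskit.validation import bootstrap_optimism

cfg = default_config(n_persons=20_000, seed=1)
episodes, deaths, truth = generate(cfg)

periods = build_periods(episodes)
index = select_index_admissions(periods, cfg.study_start, cfg.study_end)
index["death90"] = flag_death90(index, deaths).to_numpy()
index = attach_comorbidity(index, episodes).rename(
    columns={"icu_any": "icu", "treating_trauma_level": "trauma_level"})

scorer = SurvivalRiskRatioScorer(outcome="death90").fit(index)
scored = scorer.transform(index)          # adds iciss_mult, iciss_worst

spec = model_registry("death90", "worst")[1]   # M2: age group, sex, CCI group
report = bootstrap_optimism(scored, spec, B=50, seed=42)
```

With this seed the run prints (via the fields of `report`):

```
index admissions: 20000
90-day deaths: 1.9%  ICU: 3.1%
SRR table codes: 87
M2 worst-injury, B=50:
  apparent c = 0.865   adjusted c = 0.862 (95% CI 0.849-0.877)
  adjusted R2 = 0.214   adjusted AIC = 3086
```

Read: of 20,000 simulated injury admissions, 1.9% died within 90 days; 87
distinct injury codes received an SRR; the worst-injury model with age, sex
and Charlson group discriminates survivors from non-survivors with apparent
c = 0.865, of which 0.003 is optimism from evaluating the model on its own
training data — the honest (adjusted) estimate is 0.862.

The same stages are available from a shell:

```
iciss synth --n-persons 20000 --seed 1 --out data/
iciss link --episodes data/episodes.csv --deaths data/deaths.csv --out periods.csv
iciss srr --periods periods.csv --out scored.csv --srr-out srr_table.csv
iciss fit --periods scored.csv --outcome death90 --variant worst --out fits.jsonl
iciss validate --periods scored.csv --model M2 -B 50 --seed 42 --out report.json
iciss run --out run_dir --n-persons 10000     # whole pipeline + manifest
iciss describe --periods scored.csv           # descriptive counts/percents
```

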