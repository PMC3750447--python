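# rxpatterns

Treatment-pattern analysis for pharmacy claims: classify each new user's
**first treatment modification** — discontinuation, switching, or
intensification — and compare time-to-modification between two drug cohorts
with propensity-score matching and survival analysis.

The package targets the standard pharmacoepidemiology question "how durable
is therapy X versus therapy Y in routine care?" for two glucose-lowering
index drugs in type 2 diabetes — a twice-daily GLP-1 receptor agonist
(exenatide) and a basal insulin (glargine) — but every rule window, drug
class, and threshold is configuration. It is written for
pharmacoepidemiologists and health-services researchers who work with
administrative claims (dispense date, days' supply, units dispensed) and
need a tested, reproducible implementation of gap-based persistence rules
rather than a one-off SQL script. Because real claims databases are
proprietary, a synthetic-claims generator with per-patient ground truth is a
first-class component: it is how the classifier is validated.

## The rules in brief

With run-out = fill day + days' supply, and a 545-day (18-month) follow-up
horizon:

- **Discontinuation** — a 90-day gap after an index run-out with no other
  glucose-lowering fill in the gap; dated at the run-out.
- **Switching** — a non-index glucose-lowering fill in such a gap, itself
  refilled within 90 days; dated at that fill.
- **Intensification** — addition of a glucose-lowering class not used in the
  365-day baseline window, overlapping index supply, with both drugs
  subsequently refilled; for the basal-insulin arm, alternatively a ≥100%
  claim-to-claim rise in estimated daily dose (units dispensed ÷ days to
  the next dispense).
- Otherwise the patient is **censored** at day 545.

The earliest event wins; ties resolve intensification > switch >
discontinuation. Cohort comparison: 1:1 greedy propensity-score matching on
the logit score (caliper 0.2 SD), then Kaplan–Meier curves S(t), the
log-rank test, and a Cox model giving the hazard ratio
HR = exp(β) for glargine vs exenatide, overall and per modification type
(competing types censored — cause-specific hazards). See `docs/methods.md`
for the full conventions and the generator's design.

## Worked example

```python
from rxpatterns.config import PipelineConfig, SimConfig
from rxpatterns.report import run_pipeline

cfg = PipelineConfig(simulate=SimConfig(n_patients=2000), seed=42,
                     output_dir="out")
res = run_pipeline(cfg)
print(res.manifest["stages"])
```

prints the stage row counts

```
{'population': 2000, 'cohort': 1729, 'excluded': 271,
 'matched_pairs': 543, 'unmatched_treated': 41, 'classified': 1086}
```

— of 2,000 simulated patients, 1,729 survive the selection funnel (adults,
continuous enrollment, no disqualifying diagnoses, true new users), 543
glargine initiators are matched 1:1 to exenatide initiators (41 fall outside
the caliper), and the 1,086 matched patients are classified. The survival
bundle then shows, for this run:

```
glargine  any-modification by day 545: 75.9%
exenatide any-modification by day 545: 66.9%
any:             HR=1.30 (95% CI 1.13-1.50), log-rank p=2.2e-04
discontinuation: HR=1.33 (95% CI 1.11-1.60)
switch:          HR=1.08 (95% CI 0.75-1.55)   # null not excluded at n=543 pairs
intensification: HR=1.38 (95% CI 1.04-1.84)
max |standardized difference|: 49.8 pre-match -> 7.2 post-match
```

i.e. the insulin arm modifies therapy ~30% faster overall (HR 1.30), and
matching repairs the deliberately channelled covariate imbalance (all
post-match standardized differences below the conventional threshold of 10).
Artifacts land in `out/`: `cohort.csv`, `exclusions.csv`, `pairs.csv`,
`balance.csv`, `events.csv`, frequency/timing and switch/add-on drug tables
(`table2.csv`, `table3.csv`), `km_curves.tsv`, `results.json`, and a
`manifest.json` with the config hash — two runs with the same config and
seed are byte-identical.

The same pipeline runs from the shell:

```bash
rxpatterns simulate --config cfg.yaml --out data/   # synthetic CSVs + truth
rxpatterns run --config cfg.yaml                    # full pipeline
rxpatterns cohort|match|classify|survive ...        # individual stages
```

To analyse real extracts instead, point `input_dir` at CSVs with the
documented schemas: `patients.csv` (patient_id, birth_year, sex, region,
plan_type), `enrollment.csv` (patient_id, start_day, end_day, rx_benefit,
database), `pharmacy.csv` (patient_id, fill_day, drug_class, days_supply,
units), `medical.csv` (patient_id, service_day, flag_type, setting, cost);
all days are integers on a common origin.

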