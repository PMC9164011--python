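# pvsignal

Case/non-case disproportionality analysis for spontaneous adverse-event
report databases: report-level 2×2 contingency tables, Reporting Odds
Ratio (ROR) with Woolf 95% CI, Information Component (IC) with the IC025
signal rule, eligibility filtering, subgroup/sensitivity strata and
descriptive characteristics tables — plus a synthetic-report simulator
with known injected signals so the whole pipeline can be validated
end-to-end without access to a proprietary safety database.

## Method summary

* A **case** is a report whose reaction set contains the target MedDRA
  preferred term (exact match after normalization). A report is
  **exposed** to a drug or drug group when a drug entry names a member
  with role *suspect* or *interacting* (concomitant never exposes, by
  default). Counting is report-level, so `a+b+c+d = N` for every table.
* **ROR** = (a·d)/(b·c) with the log-normal (Woolf) interval
  `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`; Haldane–Anscombe +0.5 correction
  on all four cells when any cell is zero (flagged).
* **IC** = log2((O+0.5)/(E+0.5)) with O = a, E = (a+b)(a+c)/N, and
  `IC025 = IC − 3.3(O+0.5)^−1/2 − 2(O+0.5)^−3/2`; a gamma-posterior
  Monte-Carlo sampler (`ic025_mc`) provides an independent cross-check.
  The **signal rule** is strictly positive IC025; the ROR lower-limit
  rule is reported alongside.
* Drugs suspect/interacting in ≥ 4 cases are eligible for the ranked
  signal table; subgroup analyses rebuild N, margins and E within each
  stratum.

## CLI

```bash
pvsignal fixture  --out fixture.jsonl                 # deterministic demo store
pvsignal run      --reports fixture.jsonl --config analysis.yaml --out results/
pvsignal descriptives --reports fixture.jsonl \
    --target-pt "transient global amnesia" --out chars.tsv
pvsignal simulate --config sim.yaml --out sim.jsonl   # synthetic database
```

`run` writes `signal_table.tsv` (label, parent_group, n_cases,
pct_of_cases, pct_of_group, ror, ci_low, ci_high, ic, ic025, signal,
ror_signal, corrected), `subgroups.tsv` and `sensitivity.tsv`.
Minimal analysis config:

```yaml
target_pt: transient global amnesia
min_cases: 4
ranking: by_ror          # or by_cases
# groups: {my group: [drug a, drug b]}   # default: COVID-19 vaccine group
```

## Reports on disk

JSON-Lines (one object per report with keys `report_id`, `drugs`
(list of `{active_ingredient, role, start_date}`), `reactions`, `sex`,
`age_band`, `country`, `reporter`, `serious`, `reaction_onset_date`,
optional `age_years`) or CSV with drugs/reactions as pipe-delimited
subfields (`name:role[:start-date]`). Both round-trip exactly.

## Layout

```
src/pvsignal/
  report_store.py    # data model, JSONL/CSV I/O, stratum filtering
  contingency.py     # case/exposure rules, 2x2 tables, eligibility, groups
  disprop_stats.py   # ROR+CI, IC/IC025 (+ Monte-Carlo oracle), signal rule
  signal_pipeline.py # ranked signal table, subgroups, sensitivity, screening
  descriptives.py    # characteristics tables, median/IQR, co-reported terms
  synthetic_data.py  # simulator with injected signals; deterministic fixture
  cli.py
```
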