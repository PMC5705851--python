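# bcellmon

Rule-based clinical response classification and B-cell biomarker analysis
for anti-CD20 (rituximab) therapy in systemic lupus erythematosus (SLE),
with a calibrated synthetic-cohort simulator and the statistical pipeline
needed to analyse longitudinal treatment cohorts.

## The problem

Rituximab depletes CD20⁺ B-cells and is widely used off-label in refractory
SLE. Three clinical questions dominate its pragmatic use:

1. **Who responds?** Response at 6 months is judged on the BILAG-2004 index,
   which grades disease activity A (severe) … E (never active) in nine organ
   domains. A *major* response improves every active (A/B) domain to grade C
   or better with no A/B flare; a *partial* response leaves at most one
   persistent grade B; everything else is non-response. The numerical global
   score Σ(A=12, B=8, C=1, D/E=0) tracks overall activity.
2. **Who relapses early?** B-cell repopulation precedes relapse. A 6-month
   plasmablast count above 0.0008×10⁹/L predicts relapse within the next
   twelve months (≈73% sensitivity, ≈90% specificity); complete depletion
   (total B-cells < 0.0001×10⁹/L by highly sensitive flow cytometry)
   predicts response.
3. **Who stops responding?** A subset of repeat-cycle patients develop
   *secondary non-depletion non-response* (2NDNR): a severe infusion
   reaction at the second infusion, failure to deplete CD20⁺ (naïve +
   memory) B-cells, and clinical non-response — despite having depleted and
   responded before. 2NDNR is strongly associated with anti-drug antibodies
   (positive > 140 AU/mL) and is managed by switching to humanised
   anti-CD20 agents.

`bcellmon` implements these definitions as a tested rule engine
(`bilag`, `response`, `bcell` modules), a longitudinal cohort simulator
whose defaults encode the reported cohort structure (`simulate`), the
statistical toolkit used on such cohorts — exact Fisher and Mann-Whitney
tests, threshold sensitivity/specificity/ROC, guarded logistic regression —
and an end-to-end analysis runner (`stats`), plus CSV I/O and a CLI
(`io`, `cli`).

## Worked example

```python
from bcellmon import CohortParams, simulate_cohort, run_paper_analysis

cohort = simulate_cohort(CohortParams(n_patients=500, seed=42))
report = run_paper_analysis(cohort)
```

Printing the headline fields of `report` gives:

```
cycle-1 response: 81.2% responders (48.6% major) of n=500
complete depletion -> response: 91.9% vs incomplete 65.3%
global BILAG median (IQR): 26 (20-34) -> 6 (4-11)
retreated: 304, cycle-2 response 80.6%, 2NDNR incidence 16.1%
```

Reading: of 500 simulated patients, 81% respond to cycle 1 (half of them
major responders); responders with complete 6-week depletion respond at
~92% versus ~65% with incomplete depletion; the median global BILAG score
falls from 26 to 6 by 6 months; 304 relapsing responders are retreated, 81%
respond again, and ~16% of retreated patients meet the 2NDNR criteria in
this draw (the configured incidence is 11.7%; at n=304 the Monte-Carlo
standard error is ~1.8 percentage points). The same analyses run on any
cohort supplied as CSVs.

The command-line interface mirrors the library:

```bash
bcellmon simulate --n 200 --seed 7 --out cohort/
bcellmon classify --cohort cohort/ --out outcomes.csv
bcellmon analyze  --cohort cohort/ --out report/
bcellmon report report/report.json
```

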