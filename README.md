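# srspv — signal detection and time-to-onset analysis for spontaneous adverse-event reports

`srspv` is a tested, reusable implementation of the standard pharmacovigilance
workflow over spontaneous-reporting-system (SRS) data in the four-table JADER
layout (`demo`, `drug`, `reac`, `hist`, keyed by report identifier). It is
aimed at drug-safety researchers who want to screen a database for
drug–event associations and characterise *when* the event occurs after
administration and *how it resolves* — for example, chemotherapy-induced
peripheral neuropathy (MedDRA PT 10029331) across antineoplastic drug classes.

The pipeline has four statistical stages:

1. **Disproportionality screen.** For each drug (or ATC class) the reports are
   cross-classified into the 2×2 table (a: drug & event, b: drug only,
   c: event only, d: neither) and the reporting odds ratio
   ROR = (a·d)/(b·c) is estimated with the Woolf (logit) 95% interval,
   exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). A *signal* requires
   ROR > 1, CI lower bound > 1, and at least two case reports.
2. **Time-to-onset.** Per (report, drug), the latency in days from the earliest
   complete administration start date to the first complete event onset is
   derived (incomplete dates, negative latencies, and latencies beyond a
   365-day window are excluded and counted; duplicate prescriptions collapse).
   Latencies are summarised by median/IQR ((n+1)p quantiles) and fitted with a
   Weibull distribution by maximum likelihood; the shape parameter β and its
   Wald 95% CI classify the hazard as *initial failure* (CI < 1, early-onset),
   *random failure* (CI spans 1), or *wear-out failure* (CI > 1).
3. **Two-arm onset comparison.** Kaplan–Meier onset curves and the Mantel–Cox
   log-rank test between two exposure groups (e.g. solvent-based vs
   albumin-bound paclitaxel), significant at P < 0.05.
4. **Outcome profile.** Counts over the five informative outcome categories
   (death, with sequelae, not recovered, improved, recovered; unknown/blank
   excluded), combined favourable/unfavourable fractions, and mosaic-plot
   geometry.

A calibrated synthetic-data generator (`srspv.synthetic`) produces four-table
datasets with configurable association strength (on the odds scale, so the
configured multiplier *is* the ROR estimand), Weibull onset latencies,
outcome mixtures, partial dates and duplicate prescriptions — with closed-form
expected 2×2 cells as test oracles.

## Worked example

```python
from srspv import ContingencyTable, compute_ror

# 622,289 reports in the database, 1,883 with the focal event;
# 8,737 reports list oxaliplatin as a suspected drug, 491 of them cases.
table = ContingencyTable(a=491, b=8737 - 491, c=1883 - 491,
                         d=622_289 - 8737 - (1883 - 491))
print(compute_ror(table, label="oxaliplatin").summary())
```

prints

```
oxaliplatin: n_case=491, ROR 26.2 (23.6–29.1) *
```

i.e. the event is reported 26.2 times more often (on the odds scale) with
oxaliplatin than with the rest of the database, the Woolf 95% CI excludes 1,
and the asterisk marks a signal under the two-case rule. A full synthetic run:

```python
from srspv import DrugSpec, RunConfig, SimConfig, render_report, run_full_analysis

config = RunConfig(
    pt_codes=[10029331],
    targets=["oxaliplatin", "sb-paclitaxel", "nab-paclitaxel", "L01CD"],
    output_dir="out",
    simulate=SimConfig(
        n_reports=12_000, background_event_prob=0.005,
        drugs=[
            DrugSpec("oxaliplatin", "L01XA03", 0.02, event_odds_multiplier=20.0,
                     latency_alpha_days=50.0, latency_beta=0.9),
            DrugSpec("sb-paclitaxel", "L01CD01", 0.03, event_odds_multiplier=12.0,
                     latency_alpha_days=56.0, latency_beta=0.78),
            DrugSpec("nab-paclitaxel", "L01CD01", 0.02, event_odds_multiplier=8.0,
                     latency_alpha_days=13.0, latency_beta=0.74),
        ],
        missing_date_prob=0.05, duplicate_prescription_prob=0.03, seed=101,
    ),
    atc_level=5, compare=("sb-paclitaxel", "nab-paclitaxel"), seed=5,
)
print(render_report(run_full_analysis(config)))
```

writes `signals.csv`, `time_to_onset.csv`, `km_curves.csv`, `outcomes.csv`,
`mosaic.csv` and a seeded run log under `out/`, and prints the signal table,
per-target median/IQR with Weibull hazard classes, the two-arm log-rank
comparison, and outcome fractions. The same pipeline is scriptable through the
`srspv` CLI (`simulate`, `screen`, `tto`, `compare-onset`, `outcomes`,
`run-all`, `report`); real data are supplied as the four CSV tables plus a
product-name → (canonical drug, ATC code) vocabulary file.

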