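# prepmonitor

Quarterly monitoring indicators for publicly funded HIV pre-exposure
prophylaxis (PrEP) programs, computed from pharmacy dispensation, laboratory
and adverse-drug-reaction event streams.

PrEP — daily or on-demand oral antiretroviral medication taken by
HIV-negative people — only prevents HIV acquisition when programs retain
clients, keep them supplied and screen them regularly. Program teams
therefore monitor a standard battery of indicators each calendar quarter:
who is being reached (gender identity, age, health authority, enrolling
provider type), how the program is used (new clients, clients per provider,
qualifying risk factors, daily vs on-demand use, 30-tablet supply units
dispensed), whether clients stay engaged (active vs inactive status), and
whether use is safe (syphilis and HIV testing around dispensations,
incident infections, adverse drug reaction events). `prepmonitor`
implements a fourteen-indicator battery of this kind — the set developed
for a Canadian province-wide program — as a reusable, tested pipeline for
epidemiologists and program analysts, together with a synthetic-cohort
generator so every stage is exercisable without access to confidential
registry data.

## The indicators

Each indicator is reported per calendar quarter as stratum rows
(numerator *n*, denominator *N*, percentage rounded to the nearest integer,
half away from zero):

| # | Indicator | Denominator |
|---|-----------|-------------|
| 1–3 | Gender identity, age bin (<18, 18–28, 29–40, 41–48, ≥49), health authority (residence and practice) | unique clients dispensed PrEP in the quarter |
| 4–5 | New enrolments by provider type / health authority | clients authorized in the quarter |
| 6 | Clients dispensed PrEP for the first time | first-ever dispensations in the quarter |
| 7 | Providers by caseload bin (1, 2–5, 6–19, 20–49, ≥50) and clients covered per bin | providers / clients dispensing in the quarter |
| 8 | Qualifying HIV risk factors: per factor (non-exclusive) and exact combinations (cumulative) | first-time-dispensed clients |
| 9 | Active vs inactive client status | clients ever dispensed by quarter end |
| 10 | Daily vs non-daily prescribed use | clients active at quarter end |
| 11 | 30-tablet supply units dispensed, by health authority | total supply units |
| 12 | Syphilis testing around dispensations; incident syphilis cases | dispensations among active clients |
| 13 | Days from last negative HIV test to first dispensation (median, IQR); HIV testing around dispensations | clients / dispensations |
| 14 | Adverse drug reaction events (deduplicated, "unlikely" causality excluded) | — |

Three definitional engines sit underneath:

* **Testing window** — a test is linked to a dispensation when it falls in
  `[d − 30, d + 15]` days of the effective dispense date (pickup date if
  recorded, else fill date), endpoints inclusive.
* **Client status** — active from the first dispensation until a formal
  discontinuation notification or a prescription lapse of more than six
  calendar months (gap between prescriptions before a configurable 2019-Q2
  rule cutover; lapse past the expected refill date — effective date +
  tablets days of supply — after it). A later dispensation after a lapse
  re-activates the client.
* **Small-cell suppression** — counts of 1–4 are masked before publication,
  with complementary masking inside partition blocks so a lone masked cell
  cannot be recovered by subtraction.

See `docs/methods.md` for the full conventions, parameters and design
rationale.

## Worked example

```python
from prepmonitor import (
    Quarter, SimulationConfig, simulate,
    build_quarterly_report, suppress_small_cells, write_report,
)

store, truth = simulate(SimulationConfig(seed=7))   # ~2,000-client cohort, 2018Q1–2020Q4
report = build_quarterly_report(store, Quarter(2020, 4))
```

Printing a few blocks (`examples/02_quarterly_report.py`) gives:

```
indicator 1 — Client gender identity, 2020Q4:
  cis_male            1346  (98%)
  cis_female            13  (1%)
  trans_male             5  (0%)
  trans_female           7  (1%)
  other_unspecified      4  (0%)
  denominator: 1375 unique clients dispensed PrEP

indicator 9 — Client status (active vs inactive):
  active              1471  (77%)
  inactive             440  (23%)

indicator 12a — syphilis testing around dispensations:
  2156 of 2737 dispensations (79%) had a
  syphilis test within 30 days before to 15 days after the fill
```

1,375 unique clients picked up PrEP in the final quarter, 98% of them
cisgender men — the population the qualifying criteria focus on. Of the
1,911 clients ever dispensed, 23% have drifted to inactive (lapsed more
than six months past their expected refill, or formally discontinued), and
79% of the quarter's 2,737 dispensations had a syphilis screen in the
linked testing window. `suppress_small_cells(report)` masks the small
cells, and `write_report(report, "markdown"|"csv"|"json", path)` serialises
the full fourteen-block report.

The `examples/` directory has one short script per capability: cohort
simulation, report building, status timelines, the testing window, and
suppression. A thin CLI wraps the same functions:

```bash
prep-monitor simulate --seed 1 --out events/
prep-monitor validate --events events/
prep-monitor report --events events/ --quarter 2020Q4 --out out/
```

## Synthetic cohorts with exact ground truth

`simulate()` scripts whole client storylines (enrolment, refill cadence,
tests scheduled around dispensations, silent lapses and formal
discontinuations, rare HIV seroconversions, syphilis incidents, duplicate
and "unlikely" ADR reports) and bookkeeps, at generation time, the exact
integer value of every indicator numerator and denominator. The bookkeeping
never calls the indicator engine — testing-coverage truth, for instance, is
a brute-force all-pairs window enumeration — so requiring the engine to
match it exactly (see `prepmonitor.oracle.compare_to_truth`) is a genuine
two-route check, and the test suite enforces it across many seeds.

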