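# Methods

`prepmonitor` computes the fourteen monitoring indicators used to run a
publicly funded HIV pre-exposure prophylaxis (PrEP) program from flat event
tables, and generates synthetic cohorts with exact scripted ground truth for
testing. This note records the model, its conventions, the parameters that
matter, and the choices made where the published definitions leave room.

## The data model

Seven delimited tables (see `prepmonitor.events`): a client roster carrying
a dated gender-identity history, enrolment authorizations with the recorded
qualifying HIV risk factors, pharmacy dispensations, laboratory results
(HIV and syphilis), adverse-drug-reaction (ADR) reports, a provider roster,
and optional formal discontinuation notifications. All dates are ISO-8601
calendar dates; every comparison in the package is whole-day. Referential
integrity (every client/provider id resolving to its roster) and domain
validity are enforced at construction; validation failures name the
offending table, column, ids, or line.

Two conventions are applied uniformly:

* **Effective dispense date** — the pickup date when recorded, otherwise
  the prescription fill date. The published definitions state this fallback
  for the quantity-dispensed indicator only; applying it to every indicator
  keeps a single client timeline. Raw fields are preserved at ingest (a
  missing pickup stays an empty field) and the fallback is applied at
  computation time.
* **Most recent recorded gender identity** — resolved at the reporting
  quarter's end; same-day ties break by file order (the later row wins),
  since the definition names no tie rule.

## Indicator conventions

* Quarters are calendar quarters (Q2 = April–June). Each indicator is
  computed "within the specified quarter" except the risk-factor
  combination profile (8b, cumulative through quarter end) and the
  HIV-test-to-first-dispensation summary (13a, cumulative).
* Percentages are whole numbers, rounded half away from zero; a zero
  denominator yields an absent percentage, never an error. The rounding
  mode is configurable (`percent_rounding`).
* Age bins are closed ranges over completed years at the client's first
  dispensation of the quarter: <18, 18–28, 29–40, 41–48, ≥49.
* Provider caseload bins (1, 2–5, 6–19, 20–49, ≥50) count distinct clients
  dispensed by the provider within the quarter. In part (b) of the
  clients-per-provider indicator, a client seen by providers in several
  caseload bins counts once in each such bin (the published definition does
  not address multi-provider clients); the percentage base stays distinct
  clients, so part (b) rows may overlap and are not a partition.
* Testing coverage (12a syphilis, 13b HIV): a dispensation is covered when
  a matching-assay test falls within `lookback_days` (30) before through
  `grace_days` (15) after the effective dispense date. Both endpoints are
  inclusive by default — the published rule states no endpoint convention,
  so it is a config switch (`window_inclusive`) and every report footer
  names the active convention. One test may satisfy several dispensations.
  The denominator takes dispensations whose client is active *at the
  dispense date* (the published wording, "among active clients", names no
  timepoint; the dispense date is the natural one since a dispensation
  itself re-activates a lapsed client).
* The day-gap summary (13a) uses linear interpolation between order
  statistics for the quartiles (`quantile_method`, any numpy convention);
  clients with no negative HIV test on/before their first dispensation are
  excluded and counted separately.
* ADR events (14): reports are collapsed to clinical events on (client,
  event date, event label), keeping the first report in file order; events
  judged "unlikely" to be medication-related are excluded. Both steps
  precede all counting, so the event count, distinct-client count and
  discontinuation-linked count use the same retained set.
* Incident cases (12b) are dated by the laboratory test date, and the
  "active" restriction is assessed at that date.

## The client-status algorithm

A client is **active** from their first dispensation until the earliest of:

1. the formal discontinuation notification date — terminal: later
   dispensations do not re-activate (re-enrolment semantics are undefined
   in the source program; a notification filed on/before the first
   dispensation is clamped to the day after it);
2. a prescription **lapse of more than `lapse_months` (6) calendar
   months**, computed with end-of-month clamping (Jan 31 + 1 month =
   Feb 28/29), in one of two forms:
   * *gap rule* — more than six months elapse after a dispensation's
     effective date with no further dispensation; the client turns inactive
     on the first day past the six-month mark;
   * *expected-refill rule* — more than six months elapse beyond the date
     the supply was projected to run out: effective date + tablets days for
     daily use, tablets × `non_daily_stretch_factor` days for non-daily
     use. On-demand dosing has no fixed cadence, so the stretch factor
     (default 2) is a convention, flagged in every report footer.

A dispensation after a lapse re-activates the client, so the timeline
alternates active/inactive states. On a date tie between a lapse and a
notification, the notification wins.

The program the definitions come from switched lapse rules at the end of
2019 Q2, and its published wording is ambiguous about whether both rules
applied only before that date. Rather than guessing, the cutover is a
three-way config (`lapse_rule_mode`): `switch_at_cutover` (default — gap
rule for lapse dates on/before the cutover quarter's last day,
expected-refill rule after), `pre_cutover_only` (both lapse rules only
before the cutover; afterwards only a formal notification inactivates), and
`refill_always`. Other jurisdictions can drop the cutover entirely.

Timelines are truncation-consistent: the timeline computed at a late
assessment date agrees, on any earlier date, with the one computed at that
earlier date — so one pass at the horizon serves every quarter end (tested).

## Small-cell suppression

Public-health convention: stratum counts strictly between 0 and the
threshold (default 5, i.e. counts 1–4) are masked. Inside partition
indicators a lone masked cell would be recoverable by subtracting the other
rows from the denominator, so the smallest remaining cell (preferring a
nonzero one) is masked as well. Suppression returns a new report and never
alters unsuppressed counts; masked cells serialise as `*` in markdown and
as empty values in CSV/JSON. The threshold is a convention of this package;
the source program suppresses low HIV-incidence detail without publishing a
numeric threshold.

## The synthetic cohort generator

`cohort_sim.simulate` scripts whole client storylines and emits both the
event tables and a `GroundTruth` object with the exact value of every
indicator numerator and denominator. Truth is bookkept from the scripted
storylines by separate, deliberately simple counting code (testing-coverage
truth is a brute-force all-pairs window enumeration), never by calling the
indicator engine — so engine-vs-truth equality is a genuine dual-route
check. The two routes necessarily share the indicator *definitions* and the
calendar primitives; what they do not share is the engine's event-scanning
and vectorised implementation.

Default study conditions mirror the program's reported cohort: ~98.5%
cisgender-male clients; a 29–40 modal age bin (45%); two-thirds of clients
in the Vancouver Coastal health authority; provider types 61% family
physician / 25% specialist / 14% nurse practitioner with a skewed
(power-law) caseload distribution spanning all five volume bins; risk-factor
mix dominated by "HIRI-MSM score ≥10 only" (72%) with "HIRI + syphilis/STI"
second (16%); 97% daily use at enrolment with very rare switching (clients
on longer supply cadences face fewer stop decisions per refill, so the
active-client daily share settles just above 95%); 30-tablet fills (85%,
else 90); test-scheduling probabilities of 0.75 (syphilis) and 0.88 (HIV)
per dispensation at offsets uniform over the −30…+15-day window; rare HIV
seroconversion (8 × 10⁻⁴ per client); syphilis incidents at 4 × 10⁻³ per
dispensation plus occasional incidents during lost-to-follow-up periods;
ADR reports at 2% of clients with 15% duplicate reports, 10% "unlikely"
causality and an 84% discontinuation link; ~3.5% of authorized clients
never dispensed. Arrivals grow 6% per quarter from 120 over 12 quarters
(2018Q1–2020Q4), giving a cohort of roughly 2,000 clients; an optional
arrival-dip scenario emulates a pandemic-style drop. Where the source
program reports no value (refill jitter −3…+10 days, pickup recorded 80% of
the time with 0–5-day delay, formal-discontinuation and silent-lapse
hazards of 1% and 2% per 30 supplied days with a 20% return probability),
values were chosen once as plausible program magnitudes. Stop hazards scale
with the supplied days so attrition per unit time does not depend on fill
size or dosing cadence.

The generator is deterministic per seed, with a sub-stream per concern
(providers, client storylines, tests, incidents, ADRs) so adding events of
one kind does not perturb the others. Scripted storylines avoid
knife-edge cases by construction — refill cadences are capped at 150 days
so an on-schedule refill never brushes the 6-month gap rule, and scripted
returns happen strictly after the lapse date — because the generator's job
is known truth, not boundary exploration; boundary behaviour is covered by
the hand-built fixture suite (`fixture_suite()`: window-boundary,
lapse-boundary, duplicate-ADR, multi-provider, risk-factor-combination
stores with hand-worked annotations).

### What the simulator does and does not emulate

It reproduces the *structure* real registry data would have: growing
quarterly enrolment, refill cadences implied by 30-tablet supplies, tests
clustered around dispensations, silent lapses vs formal discontinuations,
duplicate and "unlikely" ADR reports. It has no behavioural or epidemic
realism — no transmission model, no adherence-within-supply variation, no
claims reversals, no seasonal effects. Passing the oracle suite therefore
demonstrates that the engine implements the indicator definitions exactly
on data of the right shape; it says nothing about data-quality problems
real registries have (lagged notifications, under-reported risk factors),
which the validation layer can only partially surface.

## Numerical and degenerate-input choices

* Quarters with no events produce zero counts and absent percentages; an
  entirely empty store still yields all fourteen blocks.
* A client with an enrolment but no dispensation has *undefined* status
  (error on direct query) and is outside the active/inactive denominator,
  but still counts in the enrolment indicators.
* Fractional 30-tablet supply units are kept exact internally and rendered
  to one decimal; per-health-authority units conserve the quarter total to
  floating-point precision.
* Report generation is pure: the same store, quarter and config produce
  byte-identical serialisations; provenance records the engine version and
  a config digest.

## Problem sizes used in the shipped test suite

The oracle equivalence suite runs 20 seeds of the default cohort
(~2,000 clients, 12 quarters each) and requires exact integer equality on
every indicator; the randomized invariant suite runs >1,000 property cases
over arbitrary small stores and suppression inputs; mix-convergence checks
use a single 5,000-arrival quarter against binomial standard errors. These
sizes were chosen to exercise every code path with comfortable statistical
power while keeping the suite quick to run locally.

## Known limitations

* Re-enrolment after formal discontinuation is representable in the data
  model but has no defined indicator semantics; the engine treats the
  notification as terminal.
* The non-daily expected-refill stretch factor is a convention; programs
  with event-driven dosing data should calibrate it or supply their own.
* The HIRI-MSM risk score is consumed as a recorded qualifying flag, never
  computed.
* No statistical inference: the indicators are counts and percentages by
  design; trends, confidence intervals and joinpoint analysis are out of
  scope.
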