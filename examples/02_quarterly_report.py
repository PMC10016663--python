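"""Build the 14-indicator quarterly monitoring report for a simulated cohort.

Each indicator is a set of (stratum, numerator, denominator, percent) rows
for one calendar quarter; percentages are whole numbers rounded half away
from zero, and small cells can be masked before publication.
"""

from pathlib import Path

from prepmonitor import (
    Quarter,
    SimulationConfig,
    build_quarterly_report,
    simulate,
    suppress_small_cells,
    write_report,
)

store, _ = simulate(SimulationConfig(seed=7))
quarter = Quarter(2020, 4)
report = build_quarterly_report(store, quarter)

gender = report.block("1").parts["gender"]
print(f"indicator 1 — {report.block('1').title}, {quarter}:")
for row in gender.rows:
    if row.numerator:
        print(f"  {row.stratum:<18} {row.numerator:>5}  ({row.percent}%)")
print(f"  denominator: {gender.denominator} unique clients dispensed PrEP")

status = report.block("9").parts["status"]
print(f"\nindicator 9 — {report.block('9').title}:")
for row in status.rows:
    print(f"  {row.stratum:<18} {row.numerator:>5}  ({row.percent}%)")

coverage = report.block("12").parts["a"]
row = coverage.rows[0]
print(f"\nindicator 12a — syphilis testing around dispensations:")
print(f"  {row.numerator} of {row.denominator} dispensations ({row.percent}%) had a")
print("  syphilis test within 30 days before to 15 days after the fill")

out = Path("scratch/example_report")
public = suppress_small_cells(report)
for fmt, ext in (("csv", "csv"), ("json", "json"), ("markdown", "md")):
    write_report(public, fmt, out / f"report_{quarter}.{ext}")
print(f"\nsuppressed public report written under {out}/")
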