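"""The laboratory-testing window linked to a dispensation.

A syphilis or HIV test counts toward a dispensation when it falls within 30
days before through 15 days after the effective dispense date (both
endpoints inclusive) — a 46-day window.
"""

import datetime as dt

from prepmonitor import Quarter, in_test_window
from prepmonitor.cohort_sim import fixture_suite
from prepmonitor.indicators import testing_coverage

disp = dt.date(2020, 4, 10)
for offset in (-31, -30, 0, 15, 16):
    test = disp + dt.timedelta(days=offset)
    mark = "in " if in_test_window(disp, test) else "out"
    print(f"test at {offset:+3d} days ({test}): {mark} of window")

store, ann = fixture_suite()["window-boundary"]
r = testing_coverage(store, Quarter.parse(ann["quarter"]), "syphilis")
row = r.rows[0]
print(f"\nboundary fixture: {row.numerator} of {int(r.denominator)} dispensations covered")
print("(tests exactly 30 days before and 15 days after count; 31/16 do not)")
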