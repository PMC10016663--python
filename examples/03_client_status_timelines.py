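"""Classify client status (active vs lost to follow-up vs discontinued).

A client is active from their first dispensation until a formal
discontinuation notification or a >6-month prescription lapse; a later
dispensation after a lapse re-activates them. The worked example below
shows a lapse-and-return storyline.
"""

import datetime as dt

from prepmonitor import DispensationRecord, classify_status

disp = lambda d: DispensationRecord(  # noqa: E731
    client_id="demo", prescriber_id="P1", fill_date=d, tablets=30
)

# monthly refills, then silence from March 2019, then a return in early 2020
dates = [dt.date(2018, 10, 1), dt.date(2018, 11, 2), dt.date(2018, 12, 1),
         dt.date(2019, 1, 3), dt.date(2019, 2, 1), dt.date(2019, 3, 2),
         dt.date(2020, 2, 10)]
timeline = classify_status("demo", [disp(d) for d in dates], dt.date(2020, 12, 31))

print("status timeline:")
for e in timeline.entries:
    print(f"  {e.effective_date}  {e.state:<9} ({e.reason})")

for probe in (dt.date(2019, 6, 1), dt.date(2019, 11, 1), dt.date(2020, 6, 1)):
    print(f"status on {probe}: {timeline.status_at(probe)}")

print("\nThe client lapsed six months after the March 2019 supply ran out,")
print("was re-activated by the February 2020 dispensation, and lapsed again")
print("six months after that supply ended.")
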