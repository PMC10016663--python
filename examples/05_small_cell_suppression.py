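"""Small-cell suppression for public release.

Counts of 1-4 could identify individuals (for example, the rare HIV
seroconversions), so they are masked. Inside a partition indicator, a lone
masked cell would be recoverable by subtracting the other rows from the
denominator, so a complementary cell is masked as well.
"""

from prepmonitor import IndicatorConfig, Quarter, StratifiedResult, StratumRow
from prepmonitor.report import IndicatorBlock, QuarterlyReport, percent, suppress_small_cells

counts = {"cis_male": 412, "cis_female": 3, "trans_female": 9}
denom = sum(counts.values())
result = StratifiedResult(
    "1", "2020Q4",
    [StratumRow(k, v, denom, percent(v, denom)) for k, v in counts.items()],
    partition=True,
)
report = QuarterlyReport(
    Quarter(2020, 4), [IndicatorBlock("1", "Client gender identity", {"gender": result})]
)

public = suppress_small_cells(report, IndicatorConfig(suppression_threshold=5))
print("stratum        raw  published")
for raw, pub in zip(result.rows, public.all_results()[0].rows):
    shown = "*" if pub.suppressed else pub.numerator
    print(f"{raw.stratum:<13} {raw.numerator:>4}  {shown}")
print("\ncis_female (3) is below the threshold of 5; trans_female is masked as")
print("the complementary cell so the small count cannot be recovered by")
print("subtraction from the denominator.")
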