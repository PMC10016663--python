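"""Shared result containers: stratified counts with rounded percentages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

__all__ = ["percent", "StratumRow", "StratifiedResult"]


def percent(numerator: float, denominator: float, cfg=None) -> Optional[int]:
    """Whole-number percentage, rounded half away from zero by default.

    A zero denominator yields ``None`` (percentage not displayable), never a
    division error.
    """
    if denominator == 0:
        return None
    x = 100.0 * numerator / denominator
    mode = getattr(cfg, "percent_rounding", "half_away_from_zero")
    if mode == "half_even":
        return int(round(x))
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class StratumRow:
    stratum: str
    numerator: float  # integer count except for tablet-supply units
    denominator: float
    percent: Optional[int] = None
    suppressed: bool = False

    def masked(self) -> "StratumRow":
        return replace(self, suppressed=True)


@dataclass
class StratifiedResult:
    """One indicator's output for one reporting period.

    ``partition`` marks indicators whose stratum numerators partition the
    denominator (so they must sum to it, and small-cell suppression must
    also mask a complementary cell).
    """

    indicator_id: str
    period: str  # e.g. "2020Q4" or "cumulative"
    rows: list[StratumRow] = field(default_factory=list)
    partition: bool = False
    notes: str = ""

    def row(self, stratum: str) -> StratumRow:
        for r in self.rows:
            if r.stratum == stratum:
                return r
        raise KeyError(stratum)

    @property
    def denominator(self) -> float:
        return self.rows[0].denominator if self.rows else 0

    def numerator_sum(self) -> float:
        return sum(r.numerator for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: indicator_id, period, stratum, numerator, denominator,
        percent, suppressed. Suppressed cells carry no counts."""
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "indicator_id": self.indicator_id,
                    "period": self.period,
                    "stratum": r.stratum,
                    "numerator": None if r.suppressed else r.numerator,
                    "denominator": r.denominator,
                    "percent": None if r.suppressed else r.percent,
                    "suppressed": r.suppressed,
                }
            )
        return pd.DataFrame(
            recs,
            columns=[
                "indicator_id",
                "period",
                "stratum",
                "numerator",
                "denominator",
                "percent",
                "suppressed",
            ],
        )

    def to_dict(self) -> dict:
        return {
            "indicator_id": self.indicator_id,
            "period": self.period,
            "partition": self.partition,
            "notes": self.notes,
            "rows": [
                {
                    "stratum": r.stratum,
                    "numerator": None if r.suppressed else r.numerator,
                    "denominator": r.denominator,
                    "percent": None if r.suppressed else r.percent,
                    "suppressed": r.suppressed,
                }
                for r in self.rows
            ],
        }


def make_result(
    indicator_id: str,
    period: str,
    counts: Sequence[tuple[str, float]],
    denominator: float,
    cfg=None,
    partition: bool = False,
    notes: str = "",
) -> StratifiedResult:
    """Assemble a StratifiedResult, computing percentages per row."""
    rows = [
        StratumRow(s, n, denominator, percent(n, denominator, cfg)) for s, n in counts
    ]
    return StratifiedResult(indicator_id, period, rows, partition=partition, notes=notes)
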