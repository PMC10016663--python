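"""Calendar quarters, date-window arithmetic and the indicator configuration.

Every monitoring indicator is reported per calendar quarter (Q2 = April to
June), and two of them hinge on day-level window checks: laboratory testing
linked to a dispensation (30-day lookback, 15-day grace) and the >6-month
prescription-lapse rule behind the active/inactive client status. The numeric
conventions for all of these live in :class:`IndicatorConfig` so that a report
is fully determined by (event store, quarter, config).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from functools import total_ordering
from typing import Iterator

import yaml
from dateutil.relativedelta import relativedelta

__all__ = [
    "Quarter",
    "IndicatorConfig",
    "quarter_of",
    "in_test_window",
    "add_months",
    "AGE_BIN_LABELS",
    "PROVIDER_VOLUME_BIN_LABELS",
]

#: Age bins in completed years at the dispensation date; closed ranges.
AGE_BINS: tuple[tuple[int | None, int | None], ...] = (
    (None, 17),
    (18, 28),
    (29, 40),
    (41, 48),
    (49, None),
)
AGE_BIN_LABELS: tuple[str, ...] = ("<18", "18-28", "29-40", "41-48", ">=49")

#: Provider caseload bins (distinct clients dispensed in the quarter).
PROVIDER_VOLUME_BINS: tuple[tuple[int, int | None], ...] = (
    (1, 1),
    (2, 5),
    (6, 19),
    (20, 49),
    (50, None),
)
PROVIDER_VOLUME_BIN_LABELS: tuple[str, ...] = ("1", "2-5", "6-19", "20-49", ">=50")


@total_ordering
@dataclass(frozen=True)
class Quarter:
    """A calendar quarter: Q1=Jan-Mar, Q2=Apr-Jun, Q3=Jul-Sep, Q4=Oct-Dec."""

    year: int
    index: int

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3, 4):
            raise ValueError(f"quarter index must be 1-4, got {self.index}")

    @property
    def start(self) -> dt.date:
        return dt.date(self.year, 3 * (self.index - 1) + 1, 1)

    @property
    def end(self) -> dt.date:
        """Last calendar day of the quarter."""
        if self.index == 4:
            return dt.date(self.year, 12, 31)
        return dt.date(self.year, 3 * self.index + 1, 1) - dt.timedelta(days=1)

    def next(self) -> "Quarter":
        if self.index == 4:
            return Quarter(self.year + 1, 1)
        return Quarter(self.year, self.index + 1)

    def __contains__(self, d: dt.date) -> bool:
        return self.start <= d <= self.end

    def __lt__(self, other: "Quarter") -> bool:
        return (self.year, self.index) < (other.year, other.index)

    def __str__(self) -> str:
        return f"{self.year}Q{self.index}"

    @classmethod
    def parse(cls, text: str) -> "Quarter":
        """Parse labels like ``2020Q4`` or ``2020-Q4``."""
        t = text.strip().upper().replace("-", "")
        if "Q" not in t:
            raise ValueError(f"cannot parse quarter label {text!r}")
        y, _, q = t.partition("Q")
        return cls(int(y), int(q))

    @classmethod
    def range(cls, first: "Quarter", last: "Quarter") -> Iterator["Quarter"]:
        """Inclusive iterator from ``first`` through ``last``."""
        q = first
        while q <= last:
            yield q
            q = q.next()


def quarter_of(d: dt.date) -> Quarter:
    """Calendar quarter containing date ``d``."""
    return Quarter(d.year, (d.month - 1) // 3 + 1)


@dataclass
class IndicatorConfig:
    """All numeric conventions used by the indicator engine.

    Parameters
    ----------
    lookback_days
        Days before a dispensation in which a laboratory test counts as
        linked to it (default 30).
    grace_days
        Days after the dispensation still counted as linked (default 15).
    window_inclusive
        Whether both window endpoints are inclusive. The published rule does
        not state an endpoint convention; inclusive is the default and the
        switch keeps the choice auditable.
    lapse_months
        Calendar months a prescription may lapse before a client is
        considered lost to follow-up (default 6, strictly greater-than).
    tablet_unit
        Tablets per reporting supply unit (default 30).
    non_daily_stretch_factor
        Days of coverage attributed to one tablet under non-daily
        (on-demand) use when projecting the expected refill date. On-demand
        dosing has no fixed cadence, so this is a convention, not a fact;
        default 2 and flagged in report footers.
    suppression_threshold
        Counts in ``(0, threshold)`` are masked in public reports
        (default 5: counts 1-4 suppressed).
    status_cutover_year / status_cutover_index
        The quarter (default 2019 Q2) at which the lapse rule switches from
        the gap-between-prescriptions form to the expected-refill form.
    lapse_rule_mode
        ``switch_at_cutover`` (default): gap rule for lapse assessment dates
        on/before the cutover quarter's last day, expected-refill rule after.
        ``pre_cutover_only``: both lapse rules apply only to assessment dates
        on/before the cutover; afterwards only a formal notification
        inactivates. ``refill_always``: expected-refill rule at all times.
    percent_rounding
        ``half_away_from_zero`` (default) or ``half_even``.
    quantile_method
        Quantile convention for the HIV-test-to-first-dispensation summary;
        any method accepted by :func:`numpy.quantile` (default ``linear``).
    """

    lookback_days: int = 30
    grace_days: int = 15
    window_inclusive: bool = True
    lapse_months: int = 6
    tablet_unit: int = 30
    non_daily_stretch_factor: float = 2.0
    suppression_threshold: int = 5
    status_cutover_year: int = 2019
    status_cutover_index: int = 2
    lapse_rule_mode: str = "switch_at_cutover"
    percent_rounding: str = "half_away_from_zero"
    quantile_method: str = "linear"
    age_bins: tuple = field(default=AGE_BINS)
    provider_volume_bins: tuple = field(default=PROVIDER_VOLUME_BINS)

    def __post_init__(self) -> None:
        if self.lapse_rule_mode not in (
            "switch_at_cutover",
            "pre_cutover_only",
            "refill_always",
        ):
            raise ValueError(f"unknown lapse_rule_mode {self.lapse_rule_mode!r}")
        if self.percent_rounding not in ("half_away_from_zero", "half_even"):
            raise ValueError(f"unknown percent_rounding {self.percent_rounding!r}")
        for name in ("lookback_days", "grace_days", "lapse_months", "tablet_unit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # normalise bins loaded from YAML (lists of lists) to tuples
        self.age_bins = tuple(tuple(b) for b in self.age_bins)
        self.provider_volume_bins = tuple(tuple(b) for b in self.provider_volume_bins)

    @property
    def status_cutover_quarter(self) -> Quarter:
        return Quarter(self.status_cutover_year, self.status_cutover_index)

    @property
    def cutover_end(self) -> dt.date:
        """Last day of the status-rule cutover quarter."""
        return self.status_cutover_quarter.end

    # -- serialisation ----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["age_bins"] = [list(b) for b in self.age_bins]
        d["provider_volume_bins"] = [list(b) for b in self.provider_volume_bins]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "IndicatorConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


def in_test_window(
    dispense_date: dt.date, test_date: dt.date, cfg: IndicatorConfig | None = None
) -> bool:
    """True when a test is linked to a dispensation.

    A test counts toward a dispensation when it falls within
    ``lookback_days`` before the dispensation through ``grace_days`` after
    it; by default both endpoints are inclusive, giving a 46-day window for
    the 30/15 defaults.
    """
    cfg = cfg or IndicatorConfig()
    lo = dispense_date - dt.timedelta(days=cfg.lookback_days)
    hi = dispense_date + dt.timedelta(days=cfg.grace_days)
    if cfg.window_inclusive:
        return lo <= test_date <= hi
    return lo < test_date < hi


def add_months(d: dt.date, m: int) -> dt.date:
    """Calendar-month shift with end-of-month clamping.

    ``2018-01-31 + 1 month`` is 2018-02-28. Used for the ">6 months" lapse
    rule, which is phrased in months rather than days.
    """
    return d + relativedelta(months=m)
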