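"""Active/inactive client status from the dispensation timeline.

A client is active from their first PrEP dispensation until either a formal
notification of program discontinuation or a prescription lapse of more than
six calendar months (lost to follow-up). Two lapse formulations exist,
switched at a configurable cutover quarter (2019 Q2 by default):

* **gap rule** — more than six months elapse after a dispensation's
  effective date with no further dispensation;
* **expected-refill rule** — more than six months elapse beyond the date
  the dispensed supply was projected to run out (effective date + tablets
  days for daily use, tablets x stretch-factor days for non-daily use).

A later dispensation after a lapse re-activates the client; a formal
notification is terminal. On a date tie the formal notification wins.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calendars import IndicatorConfig, Quarter, add_months
from .events import EventStore
from .results import StratifiedResult, make_result

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "TimelineEntry",
    "ClientStatusTimeline",
    "UndefinedStatusError",
    "expected_refill_date",
    "classify_status",
    "compute_timelines",
    "status_counts",
    "timelines_to_frame",
]

ACTIVE = "active"
INACTIVE = "inactive"

REASON_FIRST = "first_dispensation"
REASON_REDISP = "re_dispensation"
REASON_NOTIFICATION = "formal_notification"
REASON_GAP = "lapse_between_prescriptions"
REASON_REFILL = "lapse_past_expected_refill"


class UndefinedStatusError(ValueError):
    """Raised for clients with no dispensation: status is undefined and the
    client is outside the active/inactive indicator denominator."""


@dataclass(frozen=True)
class TimelineEntry:
    effective_date: dt.date
    state: str
    reason: str


@dataclass
class ClientStatusTimeline:
    client_id: str
    entries: list[TimelineEntry] = field(default_factory=list)

    def status_at(self, d: dt.date) -> Optional[str]:
        """State on date ``d``; None before the first dispensation."""
        state = None
        for e in self.entries:
            if e.effective_date <= d:
                state = e.state
            else:
                break
        return state

    @property
    def first_dispensation(self) -> dt.date:
        return self.entries[0].effective_date


@dataclass(frozen=True)
class _Disp:
    """Minimal dispensation view used by the status scan."""

    effective_date: dt.date
    tablets: int
    usage_type: str


def _effective(disp) -> dt.date:
    pickup = getattr(disp, "pickup_date", None)
    base = pickup if pickup is not None else disp.fill_date
    return base


def expected_refill_date(disp, cfg: IndicatorConfig | None = None) -> dt.date:
    """Date the dispensed supply is projected to run out.

    Daily use covers one day per tablet; non-daily (on-demand) use is
    stretched by ``cfg.non_daily_stretch_factor`` (default 2x) since it has
    no fixed cadence.
    """
    cfg = cfg or IndicatorConfig()
    if disp.tablets <= 0:
        raise ValueError("tablets must be positive")
    eff = disp.effective_date
    days = disp.tablets
    if disp.usage_type == "non_daily":
        days = int(round(disp.tablets * cfg.non_daily_stretch_factor))
    return eff + dt.timedelta(days=days)


def _lapse_candidate(disp: _Disp, cfg: IndicatorConfig) -> tuple[Optional[dt.date], str]:
    """First date on which this dispensation's lapse rule trips, absent any
    further dispensation, plus the reason label. None when no lapse rule
    applies (pre-cutover-only mode, post-cutover dates)."""
    gap_date = add_months(disp.effective_date, cfg.lapse_months) + dt.timedelta(days=1)
    refill_date = add_months(
        expected_refill_date(disp, cfg), cfg.lapse_months
    ) + dt.timedelta(days=1)
    mode = cfg.lapse_rule_mode
    if mode == "refill_always":
        return refill_date, REASON_REFILL
    if mode == "pre_cutover_only":
        if gap_date <= cfg.cutover_end:
            return gap_date, REASON_GAP
        if refill_date <= cfg.cutover_end:
            return refill_date, REASON_REFILL
        return None, ""
    # switch_at_cutover
    if gap_date <= cfg.cutover_end:
        return gap_date, REASON_GAP
    return refill_date, REASON_REFILL


def classify_status(
    client_id: str,
    dispensations: Sequence,
    as_of: dt.date,
    cfg: IndicatorConfig | None = None,
    notification_dates: Iterable[dt.date] = (),
) -> ClientStatusTimeline:
    """Build a client's active/inactive timeline up to ``as_of``.

    ``dispensations`` may be :class:`~prepmonitor.events.DispensationRecord`
    objects or any objects exposing ``effective_date``, ``tablets`` and
    ``usage_type``. Dispensations effective after ``as_of`` are ignored, as
    are notifications dated after ``as_of``. Truncation is consistent: the
    timeline computed at a later ``as_of`` agrees with the one computed at
    an earlier ``as_of`` on all dates up to the earlier one.
    """
    cfg = cfg or IndicatorConfig()
    disps = []
    for d in dispensations:
        eff = d.effective_date if not hasattr(d, "fill_date") else _effective(d)
        disps.append(_Disp(eff, int(d.tablets), d.usage_type))
    disps.sort(key=lambda d: d.effective_date)
    disps = [d for d in disps if d.effective_date <= as_of]
    if not disps:
        raise UndefinedStatusError(
            f"client {client_id!r}: no dispensation on/before {as_of}; status undefined"
        )

    notes = sorted(n for n in notification_dates if n <= as_of)
    note = notes[0] if notes else None
    if note is not None:
        # terminal: dispensations after the notification never re-activate.
        kept = [d for d in disps if d.effective_date <= note]
        if not kept:  # notification precedes the first dispensation (data lag)
            kept = disps[:1]
            note = disps[0].effective_date + dt.timedelta(days=1)
        disps = kept

    entries = [TimelineEntry(disps[0].effective_date, ACTIVE, REASON_FIRST)]
    state = ACTIVE
    for i, d in enumerate(disps):
        if i > 0 and state == INACTIVE:
            entries.append(TimelineEntry(d.effective_date, ACTIVE, REASON_REDISP))
            state = ACTIVE
        nxt = disps[i + 1].effective_date if i + 1 < len(disps) else None
        cand, reason = _lapse_candidate(d, cfg)
        if cand is None or cand > as_of:
            continue
        if nxt is not None and cand >= nxt:
            continue  # refilled in time
        if note is not None and note <= cand:
            continue  # formal notification wins on/before the lapse date
        entries.append(TimelineEntry(cand, INACTIVE, reason))
        state = INACTIVE
    if note is not None and state == ACTIVE:
        entries.append(TimelineEntry(note, INACTIVE, REASON_NOTIFICATION))
    return ClientStatusTimeline(client_id, entries)


def _client_dispensations(store: EventStore) -> dict[str, list[_Disp]]:
    d = store.dispensations_effective()
    if not len(d):
        return {}
    d = d.sort_values("effective_date", kind="stable")
    out: dict[str, list[_Disp]] = {}
    for cid, eff, tabs, usage in zip(
        d["client_id"],
        d["effective_date"].dt.date,
        d["tablets"],
        d["usage_type"],
    ):
        out.setdefault(cid, []).append(_Disp(eff, int(tabs), usage))
    return out


def compute_timelines(
    store: EventStore, as_of: dt.date, cfg: IndicatorConfig | None = None
) -> dict[str, ClientStatusTimeline]:
    """Status timeline for every ever-dispensed client, as of ``as_of``.

    Clients whose first dispensation is after ``as_of`` are omitted (their
    status is undefined at that date).
    """
    cfg = cfg or IndicatorConfig()
    notes: dict[str, list[dt.date]] = {}
    n = store.notifications
    if len(n):
        for cid, nd in zip(n["client_id"], n["notification_date"].dt.date):
            notes.setdefault(cid, []).append(nd)
    out = {}
    for cid, disps in _client_dispensations(store).items():
        if disps[0].effective_date > as_of:
            continue
        out[cid] = classify_status(cid, disps, as_of, cfg, notes.get(cid, ()))
    return out


def status_counts(
    store: EventStore,
    quarter: Quarter,
    cfg: IndicatorConfig | None = None,
    timelines: Mapping[str, ClientStatusTimeline] | None = None,
) -> StratifiedResult:
    """Active vs inactive clients at quarter end, over ever-dispensed clients."""
    cfg = cfg or IndicatorConfig()
    if timelines is None:
        timelines = compute_timelines(store, quarter.end, cfg)
    states = [
        t.status_at(quarter.end)
        for t in timelines.values()
        if t.first_dispensation <= quarter.end
    ]
    n_active = sum(1 for s in states if s == ACTIVE)
    n_inactive = sum(1 for s in states if s == INACTIVE)
    denom = n_active + n_inactive
    return make_result(
        "9",
        str(quarter),
        [(ACTIVE, n_active), (INACTIVE, n_inactive)],
        denom,
        cfg,
        partition=True,
        notes="denominator: clients ever dispensed PrEP by quarter end",
    )


def timelines_to_frame(timelines: Mapping[str, ClientStatusTimeline]) -> pd.DataFrame:
    """Audit export: one row per status change."""
    recs = [
        {
            "client_id": t.client_id,
            "effective_date": e.effective_date.isoformat(),
            "state": e.state,
            "reason": e.reason,
        }
        for t in timelines.values()
        for e in t.entries
    ]
    return pd.DataFrame(
        recs, columns=["client_id", "effective_date", "state", "reason"]
    )
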