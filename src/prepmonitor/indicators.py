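"""The fourteen quarterly monitoring indicators.

Each operation takes the validated :class:`~prepmonitor.events.EventStore`,
a :class:`~prepmonitor.calendars.Quarter` and an
:class:`~prepmonitor.calendars.IndicatorConfig`, and returns
:class:`~prepmonitor.results.StratifiedResult` rows of
(stratum, numerator, denominator, percent).

Conventions applied uniformly (see docs/methods.md):

* the *effective dispense date* is the pickup date when recorded, otherwise
  the prescription fill date;
* ages are completed years at the client's first dispensation of the
  quarter, with closed bins <18, 18-28, 29-40, 41-48, >=49;
* the most recent recorded gender identity on/before quarter end is used,
  same-day ties broken by file order;
* client status (active/inactive) comes from the status engine and gates
  the usage-type, testing-coverage and incident-case indicators.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .calendars import (
    AGE_BIN_LABELS,
    PROVIDER_VOLUME_BIN_LABELS,
    IndicatorConfig,
    Quarter,
)
from .events import GENDER_LABELS, HA_LABELS, RISK_FACTORS, EventStore
from .results import StratifiedResult, make_result
from .status import ACTIVE, ClientStatusTimeline, compute_timelines

__all__ = [
    "dispensed_distribution",
    "new_enrolments",
    "first_dispensations",
    "provider_volume",
    "risk_factor_profile",
    "usage_type_distribution",
    "quantity_dispensed",
    "testing_coverage",
    "days_to_first_dispensation",
    "incident_cases",
    "adr_event_count",
    "risk_category_label",
    "age_bin",
    "volume_bin",
    "GapSummary",
]


# ---------------------------------------------------------------------------
# binning helpers


def age_bin(age_years: int, cfg: IndicatorConfig | None = None) -> str:
    """Closed-range age bin for an age in completed years."""
    cfg = cfg or IndicatorConfig()
    for (lo, hi), label in zip(cfg.age_bins, AGE_BIN_LABELS):
        if (lo is None or age_years >= lo) and (hi is None or age_years <= hi):
            return label
    raise ValueError(f"age {age_years} fits no bin")


def volume_bin(n_clients: int, cfg: IndicatorConfig | None = None) -> str:
    """Provider caseload bin for a count of distinct clients."""
    cfg = cfg or IndicatorConfig()
    for (lo, hi), label in zip(cfg.provider_volume_bins, PROVIDER_VOLUME_BIN_LABELS):
        if n_clients >= lo and (hi is None or n_clients <= hi):
            return label
    raise ValueError(f"volume {n_clients} fits no bin")


def risk_category_label(factors) -> str:
    """Canonical, order-insensitive label for a risk-factor combination.

    Single factors read e.g. ``d only``; combinations join the short codes,
    e.g. ``a+d``; an empty set is ``none recorded``.
    """
    letters = sorted(f[0] for f in factors)
    if not letters:
        return "none recorded"
    if len(letters) == 1:
        return f"{letters[0]} only"
    return "+".join(letters)


def completed_years(dob: pd.Series, at: pd.Series) -> pd.Series:
    """Vectorised age in completed years of ``dob`` at date ``at``."""
    before_birthday = (at.dt.month < dob.dt.month) | (
        (at.dt.month == dob.dt.month) & (at.dt.day < dob.dt.day)
    )
    return at.dt.year - dob.dt.year - before_birthday.astype(int)


def _q_bounds(q: Quarter) -> tuple[pd.Timestamp, pd.Timestamp]:
    return pd.Timestamp(q.start), pd.Timestamp(q.end)


def _disp_in_quarter(store: EventStore, q: Quarter) -> pd.DataFrame:
    d = store.dispensations_effective()
    lo, hi = _q_bounds(q)
    return d[(d["effective_date"] >= lo) & (d["effective_date"] <= hi)]


def _first_disp_of_quarter(d: pd.DataFrame) -> pd.DataFrame:
    """One row per client: their first in-quarter dispensation (ties by
    file order)."""
    return (
        d.reset_index()
        .sort_values(["effective_date", "index"], kind="stable")
        .groupby("client_id", as_index=False)
        .head(1)
    )


def _counts(series: pd.Series, order: tuple[str, ...]) -> list[tuple[str, int]]:
    vc = series.value_counts()
    rows = [(s, int(vc.get(s, 0))) for s in order]
    extra = [s for s in vc.index if s not in order]
    rows.extend((s, int(vc[s])) for s in sorted(extra))
    return rows


# ---------------------------------------------------------------------------
# indicators 1-3: clients dispensed in the quarter


def dispensed_distribution(
    store: EventStore,
    quarter: Quarter,
    dimension: str,
    cfg: IndicatorConfig | None = None,
) -> StratifiedResult:
    """Indicators 1-3: unique clients dispensed PrEP in the quarter, by
    gender identity, age bin, health authority of residence, or prescriber
    health authority of practice."""
    cfg = cfg or IndicatorConfig()
    d = _disp_in_quarter(store, quarter)
    first = _first_disp_of_quarter(d)
    clients = first["client_id"]
    denom = len(clients)

    if dimension == "gender":
        gender = store.gender_as_of(quarter.end)
        labels = gender.reindex(clients).fillna("other_unspecified")
        return make_result(
            "1", str(quarter), _counts(labels, GENDER_LABELS), denom, cfg, partition=True
        )
    if dimension == "age":
        dob = store.date_of_birth().reindex(clients).reset_index(drop=True)
        at = first["effective_date"].reset_index(drop=True)
        known = dob.notna()
        ages = completed_years(dob[known], at[known])
        labels = pd.Series([age_bin(int(a), cfg) for a in ages], dtype="object")
        rows = _counts(labels, AGE_BIN_LABELS)
        n_unknown = int((~known).sum())
        if n_unknown:
            rows.append(("Unknown", n_unknown))
        return make_result("2", str(quarter), rows, denom, cfg, partition=True)
    if dimension == "ha_residence":
        ha = store.ha_of_residence().reindex(clients).fillna("Unknown")
        return make_result(
            "3.residence", str(quarter), _counts(ha, HA_LABELS), denom, cfg, partition=True
        )
    if dimension == "ha_practice":
        ha = first["prescriber_ha_of_practice"].fillna("Unknown")
        return make_result(
            "3.practice", str(quarter), _counts(ha, HA_LABELS), denom, cfg, partition=True
        )
    raise ValueError(f"unknown dimension {dimension!r}")


# ---------------------------------------------------------------------------
# indicators 4-5: new enrolments


def new_enrolments(
    store: EventStore,
    quarter: Quarter,
    dimension: str,
    cfg: IndicatorConfig | None = None,
) -> StratifiedResult:
    """Indicators 4-5: clients newly authorized for enrolment in the
    quarter, by enrolling provider type or health authority."""
    cfg = cfg or IndicatorConfig()
    lo, hi = _q_bounds(quarter)
    e = store.enrolments
    e = e[(e["authorization_date"] >= lo) & (e["authorization_date"] <= hi)]
    denom = e["client_id"].nunique()
    prov = store.providers.set_index("provider_id")

    if dimension == "provider_type":
        ptype = e["enrolling_provider_id"].map(prov["provider_type"]).fillna("Unknown")
        order = ("family_physician", "nurse_practitioner", "specialist_physician")
        return make_result("4", str(quarter), _counts(ptype, order), denom, cfg, partition=True)
    if dimension == "ha_residence":
        ha = store.ha_of_residence().reindex(e["client_id"]).fillna("Unknown")
        return make_result(
            "5.residence", str(quarter), _counts(ha, HA_LABELS), denom, cfg, partition=True
        )
    if dimension == "ha_practice":
        ha = e["enrolling_provider_id"].map(prov["ha_of_practice"]).fillna("Unknown")
        return make_result(
            "5.practice", str(quarter), _counts(ha, HA_LABELS), denom, cfg, partition=True
        )
    raise ValueError(f"unknown dimension {dimension!r}")


# ---------------------------------------------------------------------------
# indicator 6: first-ever dispensations


def _first_ever_dispensation(store: EventStore) -> pd.DataFrame:
    d = store.dispensations_effective()
    return (
        d.reset_index()
        .sort_values(["effective_date", "index"], kind="stable")
        .groupby("client_id", as_index=False)
        .head(1)
    )


def first_dispensations(
    store: EventStore,
    quarter: Quarter,
    cfg: IndicatorConfig | None = None,
    dimension: str = "ha_residence",
) -> StratifiedResult:
    """Indicator 6: clients dispensed PrEP for the first time ever in the
    quarter, by health authority."""
    cfg = cfg or IndicatorConfig()
    lo, hi = _q_bounds(quarter)
    first = _first_ever_dispensation(store)
    first = first[(first["effective_date"] >= lo) & (first["effective_date"] <= hi)]
    denom = len(first)
    if dimension == "ha_residence":
        ha = store.ha_of_residence().reindex(first["client_id"]).fillna("Unknown")
        rid = "6.residence"
    elif dimension == "ha_practice":
        ha = first["prescriber_ha_of_practice"].fillna("Unknown")
        rid = "6.practice"
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    return make_result(rid, str(quarter), _counts(ha, HA_LABELS), denom, cfg, partition=True)


# ---------------------------------------------------------------------------
# indicator 7: clients per provider


def provider_volume(
    store: EventStore, quarter: Quarter, cfg: IndicatorConfig | None = None
) -> tuple[StratifiedResult, StratifiedResult]:
    """Indicator 7: (a) providers by caseload bin; (b) clients covered by
    each provider-caseload bin.

    A provider's caseload is the number of distinct clients it dispensed to
    within the quarter. In part (b) a client seen by providers in several
    bins counts once in each such bin, so part (b) numerators may overlap;
    the percentage base stays distinct clients.
    """
    cfg = cfg or IndicatorConfig()
    d = _disp_in_quarter(store, quarter)
    pairs = d[["prescriber_id", "client_id"]].drop_duplicates()
    vol = pairs.groupby("prescriber_id")["client_id"].nunique()
    bins = vol.map(lambda v: volume_bin(int(v), cfg))

    part_a = make_result(
        "7a",
        str(quarter),
        _counts(bins, PROVIDER_VOLUME_BIN_LABELS),
        int(len(vol)),
        cfg,
        partition=True,
    )

    client_bins = pairs.assign(bin=pairs["prescriber_id"].map(bins))
    per_bin = client_bins.drop_duplicates(["client_id", "bin"]).groupby("bin")[
        "client_id"
    ].nunique()
    n_clients = int(pairs["client_id"].nunique())
    rows = [(lbl, int(per_bin.get(lbl, 0))) for lbl in PROVIDER_VOLUME_BIN_LABELS]
    part_b = make_result(
        "7b",
        str(quarter),
        rows,
        n_clients,
        cfg,
        partition=False,
        notes="clients with providers in several bins count once per bin",
    )
    return part_a, part_b


# ---------------------------------------------------------------------------
# indicator 8: qualifying risk factors


def _risk_sets(store: EventStore) -> pd.Series:
    """client_id -> frozenset of recorded qualifying risk factors."""
    e = store.enrolments.drop_duplicates("client_id")
    return pd.Series(
        [frozenset(filter(None, s.split(";"))) for s in e["risk_factors"].fillna("")],
        index=e["client_id"],
        dtype="object",
    )


def risk_factor_profile(
    store: EventStore, quarter: Quarter, cfg: IndicatorConfig | None = None
) -> tuple[StratifiedResult, StratifiedResult]:
    """Indicator 8: qualifying HIV risk factors among clients dispensed PrEP
    for the first time.

    Part (a) is per quarter and non-mutually exclusive (one row per factor;
    numerators may jointly exceed the denominator). Part (b) is cumulative
    through quarter end, one row per exact factor combination; every client
    belongs to exactly one combination.
    """
    cfg = cfg or IndicatorConfig()
    lo, hi = _q_bounds(quarter)
    first = _first_ever_dispensation(store)
    sets = _risk_sets(store)

    in_q = first[(first["effective_date"] >= lo) & (first["effective_date"] <= hi)]
    q_sets = [sets.get(c, frozenset()) for c in in_q["client_id"]]
    rows_a = [
        (f, sum(1 for s in q_sets if f in s)) for f in RISK_FACTORS
    ]
    part_a = make_result(
        "8a",
        str(quarter),
        rows_a,
        len(q_sets),
        cfg,
        partition=False,
        notes="non-mutually exclusive: a client may qualify under several factors",
    )

    cum = first[first["effective_date"] <= hi]
    cum_sets = [sets.get(c, frozenset()) for c in cum["client_id"]]
    labels = pd.Series([risk_category_label(s) for s in cum_sets], dtype="object")
    vc = labels.value_counts()
    rows_b = [(str(k), int(v)) for k, v in sorted(vc.items(), key=lambda kv: (-kv[1], kv[0]))]
    part_b = make_result(
        "8b",
        "cumulative",
        rows_b,
        len(cum_sets),
        cfg,
        partition=True,
        notes=f"cumulative through {quarter}; one exact combination per client",
    )
    return part_a, part_b


# ---------------------------------------------------------------------------
# indicator 10: usage type among active clients


def usage_type_distribution(
    store: EventStore,
    quarter: Quarter,
    cfg: IndicatorConfig | None = None,
    timelines: Mapping[str, ClientStatusTimeline] | None = None,
) -> StratifiedResult:
    """Indicator 10: daily vs non-daily prescribed use among clients active
    at quarter end, from each client's most recent dispensation."""
    cfg = cfg or IndicatorConfig()
    if timelines is None:
        timelines = compute_timelines(store, quarter.end, cfg)
    active = {
        cid
        for cid, t in timelines.items()
        if t.first_dispensation <= quarter.end and t.status_at(quarter.end) == ACTIVE
    }
    d = store.dispensations_effective()
    d = d[(d["effective_date"] <= pd.Timestamp(quarter.end)) & d["client_id"].isin(active)]
    latest = (
        d.reset_index()
        .sort_values(["effective_date", "index"], kind="stable")
        .groupby("client_id", as_index=False)
        .tail(1)
    )
    return make_result(
        "10",
        str(quarter),
        _counts(latest["usage_type"], ("daily", "non_daily")),
        len(active),
        cfg,
        partition=True,
    )


# ---------------------------------------------------------------------------
# indicator 11: quantity dispensed


def quantity_dispensed(
    store: EventStore,
    quarter: Quarter,
    cfg: IndicatorConfig | None = None,
    dimension: str = "ha_residence",
) -> StratifiedResult:
    """Indicator 11: 30-tablet supply units dispensed in the quarter, by
    health authority. Numerators are fractional supply units (tablets /
    tablet_unit); reports render them to one decimal."""
    cfg = cfg or IndicatorConfig()
    d = _disp_in_quarter(store, quarter)
    if dimension == "ha_residence":
        ha = store.ha_of_residence().reindex(d["client_id"]).fillna("Unknown").to_numpy()
        rid = "11.residence"
    elif dimension == "ha_practice":
        ha = d["prescriber_ha_of_practice"].fillna("Unknown").to_numpy()
        rid = "11.practice"
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    tablets = pd.Series(d["tablets"].to_numpy(), index=ha).groupby(level=0).sum()
    total_units = float(d["tablets"].sum()) / cfg.tablet_unit
    rows = [
        (lbl, float(tablets.get(lbl, 0)) / cfg.tablet_unit) for lbl in HA_LABELS
    ]
    return make_result(
        rid,
        str(quarter),
        rows,
        total_units,
        cfg,
        partition=True,
        notes="numerators are 30-tablet supply units (one-decimal display)",
    )


# ---------------------------------------------------------------------------
# indicators 12a / 13b: testing coverage around dispensations


def testing_coverage(
    store: EventStore,
    quarter: Quarter,
    assay: str,
    cfg: IndicatorConfig | None = None,
    timelines: Mapping[str, ClientStatusTimeline] | None = None,
) -> StratifiedResult:
    """Indicators 12a (syphilis) and 13b (HIV): dispensations in the quarter
    among active clients with a matching test inside the testing window
    (``lookback_days`` before through ``grace_days`` after the effective
    dispense date). One test may satisfy several dispensations."""
    cfg = cfg or IndicatorConfig()
    if timelines is None:
        timelines = compute_timelines(store, quarter.end, cfg)
    d = _disp_in_quarter(store, quarter)
    # status at the dispense date: excludes dispensations recorded after a
    # formal discontinuation (which never re-activates the client)
    eff_dates = d["effective_date"].dt.date
    keep = [
        (cid in timelines) and timelines[cid].status_at(ed) == ACTIVE
        for cid, ed in zip(d["client_id"], eff_dates)
    ]
    d = d[np.asarray(keep, dtype=bool)] if len(d) else d
    denom = len(d)

    t = store.lab_tests
    t = t[t["assay"] == assay]
    tests_by_client: dict[str, np.ndarray] = {
        cid: np.sort(grp["test_date"].to_numpy(dtype="datetime64[D]").astype(int))
        for cid, grp in t.groupby("client_id")
    }
    eff = d["effective_date"].to_numpy(dtype="datetime64[D]").astype(int)
    lo_off, hi_off = cfg.lookback_days, cfg.grace_days
    shrink = 0 if cfg.window_inclusive else 1
    covered = 0
    for cid, e in zip(d["client_id"], eff):
        tests = tests_by_client.get(cid)
        if tests is None:
            continue
        lo = e - lo_off + shrink
        hi = e + hi_off - shrink
        if np.searchsorted(tests, lo, "left") < np.searchsorted(tests, hi, "right"):
            covered += 1
    rid = "12a" if assay == "syphilis" else "13b"
    return make_result(
        rid,
        str(quarter),
        [("tested_in_window", covered)],
        denom,
        cfg,
        partition=False,
        notes=f"{assay} test within -{lo_off}/+{hi_off} days of dispensation",
    )


# ---------------------------------------------------------------------------
# indicator 13a: days from last negative HIV test to first dispensation


@dataclass(frozen=True)
class GapSummary:
    """Median and quartiles of per-client day gaps, plus counts."""

    median: Optional[float]
    q25: Optional[float]
    q75: Optional[float]
    n: int
    n_excluded: int  # clients with no negative HIV test on/before first dispensation

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "n": self.n,
            "n_excluded": self.n_excluded,
        }


def days_to_first_dispensation(
    store: EventStore, cfg: IndicatorConfig | None = None
) -> GapSummary:
    """Indicator 13a: days between the most recent negative HIV test and
    the first dispensed prescription, per client; clients with no prior
    negative test are excluded and counted separately."""
    cfg = cfg or IndicatorConfig()
    first = _first_ever_dispensation(store).set_index("client_id")["effective_date"]
    t = store.lab_tests
    neg = t[(t["assay"] == "hiv") & (t["result"] == "negative")]
    gaps = []
    n_excluded = 0
    neg_by_client = {
        cid: np.sort(grp["test_date"].to_numpy(dtype="datetime64[D]").astype(int))
        for cid, grp in neg.groupby("client_id")
    }
    for cid, eff in first.items():
        e = eff.to_datetime64().astype("datetime64[D]").astype(int)
        tests = neg_by_client.get(cid)
        if tests is None or tests[0] > e:
            n_excluded += 1
            continue
        idx = np.searchsorted(tests, e, "right") - 1
        gaps.append(int(e - tests[idx]))
    if not gaps:
        return GapSummary(None, None, None, 0, n_excluded)
    q25, med, q75 = np.quantile(gaps, [0.25, 0.5, 0.75], method=cfg.quantile_method)
    return GapSummary(float(med), float(q25), float(q75), len(gaps), n_excluded)


# ---------------------------------------------------------------------------
# indicator 12b (and HIV counterpart): incident cases


def incident_cases(
    store: EventStore,
    quarter: Quarter,
    assay: str,
    require_active: bool = True,
    cfg: IndicatorConfig | None = None,
    timelines: Mapping[str, ClientStatusTimeline] | None = None,
) -> int:
    """Clients with an incident (newly confirmed) infection dated in the
    quarter; restricted to clients active at the test date when
    ``require_active``."""
    cfg = cfg or IndicatorConfig()
    lo, hi = _q_bounds(quarter)
    t = store.lab_tests
    t = t[
        (t["assay"] == assay)
        & (t["result"] == "positive_incident")
        & (t["test_date"] >= lo)
        & (t["test_date"] <= hi)
    ]
    if not require_active:
        return int(t["client_id"].nunique())
    if timelines is None:
        timelines = compute_timelines(store, quarter.end, cfg)
    hit = set()
    for cid, td in zip(t["client_id"], t["test_date"].dt.date):
        tl = timelines.get(cid)
        if tl is not None and tl.status_at(td) == ACTIVE:
            hit.add(cid)
    return len(hit)


# ---------------------------------------------------------------------------
# indicator 14: adverse drug reaction events


def adr_event_count(
    store: EventStore,
    quarter: Quarter | None = None,
    cfg: IndicatorConfig | None = None,
) -> tuple[int, int, int]:
    """Indicator 14: (events, distinct clients, discontinuation-linked).

    Reports are collapsed to clinical events on (client, event date, event
    label), keeping the first report in file order; events classified
    "unlikely" to be medication-related are excluded. ``quarter=None``
    counts over the whole record (cumulative)."""
    cfg = cfg or IndicatorConfig()
    r = store.adr_reports
    if quarter is not None:
        lo, hi = _q_bounds(quarter)
        r = r[(r["event_date"] >= lo) & (r["event_date"] <= hi)]
    events = r.drop_duplicates(["client_id", "event_date", "event_label"], keep="first")
    events = events[events["causality"] != "unlikely"]
    n_events = int(len(events))
    n_clients = int(events["client_id"].nunique())
    n_disc = int(events["resulted_in_discontinuation"].astype(bool).sum())
    return n_events, n_clients, n_disc
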