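"""Synthetic PrEP-program cohort generator with bookkept ground truth.

The generator scripts whole client storylines — enrolment, refill cadence,
laboratory tests scheduled around dispensations, silent refill lapses and
formal discontinuations, rare HIV seroconversions, syphilis incidents, and
adverse-drug-reaction reports including duplicates — and emits both the
event tables and a :class:`GroundTruth` object holding the exact integer
value of every indicator numerator and denominator.

Ground truth is bookkept from the scripted storylines by straightforward
counting (with a brute-force all-pairs enumeration for testing-coverage
windows), never by invoking the indicator engine, so an engine-vs-truth
comparison is a genuine dual-route check. Defaults mirror the cohort the
program reports: ~99% cisgender-male clients, a 29-40 modal age bin,
enrolment concentrated in the Vancouver Coastal health authority,
quarterly-growing arrivals, >95% daily use, and testing-coverage targets of
roughly 75% (syphilis) and 88% (HIV).
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .calendars import IndicatorConfig, Quarter, add_months
from .events import (
    ADRReport,
    ClientRecord,
    DispensationRecord,
    EnrolmentRecord,
    EventStore,
    LabTestRecord,
    ProviderRecord,
    RISK_FACTORS,
    StatusNotification,
    write_event_store,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "fixture_suite"]

_FACTOR_BY_LETTER = {f[0]: f for f in RISK_FACTORS}

ADR_LABELS = ("nausea", "headache", "rash", "fatigue", "dizziness", "renal_flag")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    The defaults are the generator's study conditions; they are not tuned
    per run. Mixes must sum to 1.
    """

    n_quarters: int = 12
    start_year: int = 2018
    start_index: int = 1
    base_arrivals: float = 120.0
    arrival_growth: float = 1.06
    #: optional pandemic-style dip: (0-based quarter index, multiplier)
    arrival_dip: Optional[tuple[int, float]] = None
    never_dispensed_prob: float = 0.035

    gender_mix: dict = field(
        default_factory=lambda: {
            "cis_male": 0.985,
            "cis_female": 0.005,
            "trans_male": 0.003,
            "trans_female": 0.004,
            "other_unspecified": 0.003,
        }
    )
    gender_update_prob: float = 0.005
    age_bin_mix: dict = field(
        default_factory=lambda: {
            "<18": 0.002,
            "18-28": 0.27,
            "29-40": 0.45,
            "41-48": 0.16,
            ">=49": 0.118,
        }
    )
    ha_mix: dict = field(
        default_factory=lambda: {
            "Vancouver Coastal": 0.67,
            "Fraser": 0.14,
            "Vancouver Island": 0.09,
            "Interior": 0.05,
            "Northern": 0.02,
            "Unknown": 0.03,
        }
    )
    n_providers: int = 260
    provider_type_mix: dict = field(
        default_factory=lambda: {
            "family_physician": 0.61,
            "nurse_practitioner": 0.14,
            "specialist_physician": 0.25,
        }
    )
    provider_popularity_exponent: float = 1.1
    enrol_by_home_provider_prob: float = 0.9
    switch_provider_prob: float = 0.05

    risk_mix: dict = field(
        default_factory=lambda: {
            ("d",): 0.72,
            ("a", "d"): 0.16,
            ("a",): 0.04,
            ("a", "b", "d"): 0.012,
            ("c",): 0.02,
            ("e",): 0.02,
            ("f",): 0.01,
            (): 0.018,
        }
    )

    tablets_mix: dict = field(default_factory=lambda: {30: 0.85, 90: 0.15})
    #: enrolment mix; non-daily users face fewer refill decisions (longer
    #: cadence) and so are retained slightly better, leaving >95% of *active*
    #: clients on daily use each quarter
    usage_mix: dict = field(default_factory=lambda: {"daily": 0.97, "non_daily": 0.03})
    usage_switch_prob: float = 0.002  # per refill; keeps daily use >95% of clients
    pickup_recorded_prob: float = 0.8
    pickup_delay_max: int = 5
    first_fill_delay_max: int = 21
    refill_jitter: tuple[int, int] = (-3, 10)

    formal_disc_hazard: float = 0.01  # per 30 supplied days
    silent_lapse_hazard: float = 0.02  # per 30 supplied days
    restart_prob: float = 0.2  # return after a scripted lapse
    restart_delay_days: tuple[int, int] = (30, 120)  # after the lapse date
    notification_delay_days: tuple[int, int] = (31, 60)

    syphilis_test_prob: float = 0.75
    hiv_test_prob: float = 0.88
    test_offset: tuple[int, int] = (-30, 15)
    pre_enrol_hiv_test_prob: float = 0.95
    pre_enrol_gap_max: int = 30

    syphilis_incident_prob: float = 0.004  # per dispensation
    lapsed_incident_prob: float = 0.1  # syphilis incident while lost to follow-up
    hiv_sero_prob: float = 0.0008  # per client
    adr_prob: float = 0.02  # per client
    adr_duplicate_prob: float = 0.15
    adr_unlikely_prob: float = 0.1
    adr_discontinuation_prob: float = 0.84

    seed: int = 0

    def validate(self) -> None:
        for name in ("gender_mix", "age_bin_mix", "ha_mix", "provider_type_mix",
                     "risk_mix", "tablets_mix", "usage_mix"):
            mix = getattr(self, name)
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has a negative probability")
        for name in (
            "never_dispensed_prob", "gender_update_prob", "formal_disc_hazard",
            "silent_lapse_hazard", "restart_prob", "syphilis_test_prob",
            "hiv_test_prob", "pre_enrol_hiv_test_prob", "syphilis_incident_prob",
            "lapsed_incident_prob", "hiv_sero_prob", "adr_prob",
            "adr_duplicate_prob", "adr_unlikely_prob", "adr_discontinuation_prob",
            "pickup_recorded_prob", "enrol_by_home_provider_prob",
            "switch_provider_prob", "usage_switch_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_quarters < 1:
            raise ValueError("n_quarters must be >= 1")

    def quarters(self) -> list[Quarter]:
        qs = [Quarter(self.start_year, self.start_index)]
        for _ in range(self.n_quarters - 1):
            qs.append(qs[-1].next())
        return qs

    def arrivals(self) -> list[int]:
        out = []
        for i in range(self.n_quarters):
            n = self.base_arrivals * self.arrival_growth**i
            if self.arrival_dip is not None and i == self.arrival_dip[0]:
                n *= self.arrival_dip[1]
            out.append(int(round(n)))
        return out


@dataclass
class GroundTruth:
    """Exact indicator values the generator scripted, per quarter and
    cumulative. Stratum maps hold only nonzero counts."""

    quarters: dict = field(default_factory=dict)  # "2018Q1" -> {indicator: ...}
    cumulative: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"quarters": self.quarters, "cumulative": self.cumulative},
                fh,
                indent=2,
                default=str,
            )


# ---------------------------------------------------------------------------
# scripted storyline containers


@dataclass
class _Client:
    cid: str
    dob: dt.date
    ha: str
    gender_history: list  # [(date, label)]
    auth_date: dt.date
    enrol_provider: str
    risk_letters: tuple
    dispensations: list = field(default_factory=list)  # (eff, provider, ha, tablets, usage)
    #: active segments [(start, end_or_None)]; end is the inactive-from date
    segments: list = field(default_factory=list)
    notification: Optional[dt.date] = None

    @property
    def first_eff(self) -> Optional[dt.date]:
        return self.dispensations[0]["eff"] if self.dispensations else None

    def active_at(self, d: dt.date) -> Optional[bool]:
        """True/False once dispensed, None before the first dispensation."""
        if self.first_eff is None or d < self.first_eff:
            return None
        for start, end in self.segments:
            if start <= d and (end is None or d < end):
                return True
        return False


def _age_years(dob: dt.date, at: dt.date) -> int:
    return at.year - dob.year - ((at.month, at.day) < (dob.month, dob.day))


def _age_bin_label(age: int) -> str:
    if age < 18:
        return "<18"
    if age <= 28:
        return "18-28"
    if age <= 40:
        return "29-40"
    if age <= 48:
        return "41-48"
    return ">=49"


def _volume_bin_label(v: int) -> str:
    if v == 1:
        return "1"
    if v <= 5:
        return "2-5"
    if v <= 19:
        return "6-19"
    if v <= 49:
        return "20-49"
    return ">=50"


def _combo_label(letters) -> str:
    ls = sorted(letters)
    if not ls:
        return "none recorded"
    if len(ls) == 1:
        return f"{ls[0]} only"
    return "+".join(ls)


def _supply_days(tablets: int, usage: str, cfg: IndicatorConfig) -> int:
    if usage == "non_daily":
        return int(round(tablets * cfg.non_daily_stretch_factor))
    return tablets


def _inactive_from(
    eff: dt.date, tablets: int, usage: str, cfg: IndicatorConfig
) -> Optional[dt.date]:
    """Date a client becomes lost to follow-up after their last dispensation,
    under the configured lapse rule; None if no lapse rule applies."""
    one = dt.timedelta(days=1)
    gap = add_months(eff, cfg.lapse_months) + one
    refill = add_months(
        eff + dt.timedelta(days=_supply_days(tablets, usage, cfg)), cfg.lapse_months
    ) + one
    mode = cfg.lapse_rule_mode
    if mode == "refill_always":
        return refill
    if mode == "pre_cutover_only":
        if gap <= cfg.cutover_end:
            return gap
        if refill <= cfg.cutover_end:
            return refill
        return None
    return gap if gap <= cfg.cutover_end else refill


def _choice(rng: np.random.Generator, mix: dict):
    keys = list(mix.keys())
    idx = rng.choice(len(keys), p=np.array(list(mix.values()), dtype=float))
    return keys[int(idx)]


def _rand_day(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    span = (hi - lo).days
    return lo + dt.timedelta(days=int(rng.integers(0, span + 1)))


# ---------------------------------------------------------------------------
# generation


def simulate(
    sim: SimulationConfig, cfg: IndicatorConfig | None = None
) -> tuple[EventStore, GroundTruth]:
    """Generate an event store and its scripted ground truth.

    Deterministic for a fixed ``sim.seed``: sub-streams are spawned per
    concern so adding events of one kind does not perturb the others.
    """
    sim.validate()
    cfg = cfg or IndicatorConfig()
    quarters = sim.quarters()
    horizon = quarters[-1].end

    ss = np.random.SeedSequence(sim.seed)
    rng_prov, rng_client, rng_tests, rng_inc, rng_adr = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # provider pool with skewed popularity so caseloads span all bins
    providers = []
    for i in range(sim.n_providers):
        providers.append(
            ProviderRecord(
                provider_id=f"P{i + 1:04d}",
                provider_type=_choice(rng_prov, sim.provider_type_mix),
                ha_of_practice=_choice(rng_prov, sim.ha_mix),
            )
        )
    weights = np.array(
        [1.0 / (i + 1) ** sim.provider_popularity_exponent for i in range(sim.n_providers)]
    )
    weights /= weights.sum()
    prov_ha = {p.provider_id: p.ha_of_practice for p in providers}

    def pick_provider(rng) -> str:
        return providers[int(rng.choice(sim.n_providers, p=weights))].provider_id

    clients: list[_Client] = []
    tests: list[LabTestRecord] = []
    adr_reports: list[ADRReport] = []
    adr_events: list[dict] = []
    incidents: list[dict] = []  # {"cid", "date", "assay"}

    cid_counter = 0
    for qi, (q, n_arrivals) in enumerate(zip(quarters, sim.arrivals())):
        for _ in range(n_arrivals):
            cid_counter += 1
            cid = f"C{cid_counter:06d}"
            auth = _rand_day(rng_client, q.start, q.end)
            age_lo, age_hi = {
                "<18": (16, 17),
                "18-28": (18, 28),
                "29-40": (29, 40),
                "41-48": (41, 48),
                ">=49": (49, 70),
            }[_choice(rng_client, sim.age_bin_mix)]
            age = int(rng_client.integers(age_lo, age_hi + 1))
            dob = add_months(auth, -12 * age) - dt.timedelta(
                days=int(rng_client.integers(0, 300))
            )
            g0 = _choice(rng_client, sim.gender_mix)
            gender_history = [(auth, g0)]
            if rng_client.random() < sim.gender_update_prob:
                upd = auth + dt.timedelta(days=int(rng_client.integers(180, 540)))
                if upd <= horizon:
                    alternatives = [g for g in sim.gender_mix if g != g0]
                    gender_history.append(
                        (upd, alternatives[int(rng_client.integers(0, len(alternatives)))])
                    )
            home = pick_provider(rng_client)
            enrol_provider = (
                home
                if rng_client.random() < sim.enrol_by_home_provider_prob
                else pick_provider(rng_client)
            )
            risk = tuple(_choice(rng_client, sim.risk_mix))
            c = _Client(
                cid=cid,
                dob=dob,
                ha=_choice(rng_client, sim.ha_mix),
                gender_history=gender_history,
                auth_date=auth,
                enrol_provider=enrol_provider,
                risk_letters=risk,
            )
            clients.append(c)

            if rng_client.random() < sim.never_dispensed_prob:
                continue

            # ---- dispensation storyline -------------------------------
            usage = _choice(rng_client, sim.usage_mix)
            sero_client = rng_client.random() < sim.hiv_sero_prob
            fill = auth + dt.timedelta(
                days=int(rng_client.integers(0, sim.first_fill_delay_max + 1))
            )
            seg_start: Optional[dt.date] = None
            stopped_reason = None  # None | "lapse" | "formal" | "sero"
            while True:
                pickup = None
                if rng_client.random() < sim.pickup_recorded_prob:
                    pickup = fill + dt.timedelta(
                        days=int(rng_client.integers(0, sim.pickup_delay_max + 1))
                    )
                eff = pickup if pickup is not None else fill
                if eff > horizon:
                    break
                tablets = int(_choice(rng_client, sim.tablets_mix))
                prescriber = home
                if rng_client.random() < sim.switch_provider_prob:
                    prescriber = pick_provider(rng_client)
                c.dispensations.append(
                    {
                        "fill": fill,
                        "pickup": pickup,
                        "eff": eff,
                        "provider": prescriber,
                        "ha_practice": prov_ha[prescriber],
                        "tablets": tablets,
                        "usage": usage,
                    }
                )
                if seg_start is None:
                    seg_start = eff

                # laboratory tests scheduled around the dispensation
                for assay, p in (("syphilis", sim.syphilis_test_prob), ("hiv", sim.hiv_test_prob)):
                    if rng_tests.random() < p:
                        td = eff + dt.timedelta(
                            days=int(
                                rng_tests.integers(sim.test_offset[0], sim.test_offset[1] + 1)
                            )
                        )
                        if td <= horizon:
                            tests.append(LabTestRecord(cid, td, assay, "negative"))

                # syphilis incident tied to an active moment
                if rng_inc.random() < sim.syphilis_incident_prob:
                    idate = eff + dt.timedelta(days=int(rng_inc.integers(1, 11)))
                    if idate <= horizon:
                        incidents.append({"cid": cid, "date": idate, "assay": "syphilis"})

                # continuation decision; hazards scale with the supplied
                # days so attrition per unit time is cadence-neutral
                u = rng_client.random()
                scale = _supply_days(tablets, usage, cfg) / 30.0
                if sero_client:
                    sero_date = eff + dt.timedelta(days=int(rng_client.integers(1, 21)))
                    if sero_date <= horizon:
                        incidents.append({"cid": cid, "date": sero_date, "assay": "hiv"})
                    stopped_reason = "sero"
                elif u < sim.formal_disc_hazard * scale:
                    stopped_reason = "formal"
                elif u < (sim.formal_disc_hazard + sim.silent_lapse_hazard) * scale:
                    stopped_reason = "lapse"
                if stopped_reason in ("sero", "lapse"):
                    inact = _inactive_from(eff, tablets, usage, cfg)
                    end = inact if (inact is not None and inact <= horizon) else None
                    c.segments.append((seg_start, end))
                    seg_start = None
                    restart = (
                        stopped_reason == "lapse"
                        and end is not None
                        and rng_client.random() < sim.restart_prob
                    )
                    if restart:
                        lo, hi = sim.restart_delay_days
                        fill = end + dt.timedelta(days=int(rng_client.integers(lo, hi + 1)))
                        stopped_reason = None
                        continue
                    break
                if stopped_reason == "formal":
                    lo, hi = sim.notification_delay_days
                    note = eff + dt.timedelta(days=int(rng_client.integers(lo, hi + 1)))
                    if note <= horizon:
                        c.notification = note
                        c.segments.append((seg_start, note))
                    else:
                        c.segments.append((seg_start, None))
                    seg_start = None
                    break
                if rng_client.random() < sim.usage_switch_prob:
                    usage = "non_daily" if usage == "daily" else "daily"
                # clients refill before a long supply runs out, so an
                # on-schedule refill never brushes the 6-month gap rule
                cadence = min(_supply_days(tablets, usage, cfg), 150)
                jl, jh = sim.refill_jitter
                fill = eff + dt.timedelta(days=cadence + int(rng_client.integers(jl, jh + 1)))
            if seg_start is not None:
                c.segments.append((seg_start, None))

            # syphilis incident while lost to follow-up (inactive)
            closed = [s for s in c.segments if s[1] is not None]
            if (
                closed
                and c.notification is None
                and rng_inc.random() < sim.lapsed_incident_prob
            ):
                idate = closed[0][1] + dt.timedelta(days=30)
                nxt = [s for s in c.segments if s[0] > closed[0][1]]
                if idate <= horizon and (not nxt or idate < nxt[0][0]):
                    incidents.append({"cid": cid, "date": idate, "assay": "syphilis"})

            # pre-enrolment negative HIV test (screening before start)
            if c.dispensations and rng_tests.random() < sim.pre_enrol_hiv_test_prob:
                g = int(rng_tests.integers(0, sim.pre_enrol_gap_max + 1))
                tests.append(
                    LabTestRecord(
                        cid,
                        c.dispensations[0]["eff"] - dt.timedelta(days=g),
                        "hiv",
                        "negative",
                    )
                )

            # adverse drug reaction reports
            if c.dispensations and rng_adr.random() < sim.adr_prob:
                disp = c.dispensations[int(rng_adr.integers(0, len(c.dispensations)))]
                edate = disp["eff"] + dt.timedelta(days=int(rng_adr.integers(0, 11)))
                if edate <= horizon:
                    label = ADR_LABELS[int(rng_adr.integers(0, len(ADR_LABELS)))]
                    unlikely = rng_adr.random() < sim.adr_unlikely_prob
                    disc = rng_adr.random() < sim.adr_discontinuation_prob
                    n_reports = 2 if rng_adr.random() < sim.adr_duplicate_prob else 1
                    adr_events.append(
                        {
                            "cid": cid,
                            "date": edate,
                            "label": label,
                            "unlikely": unlikely,
                            "disc": disc,
                        }
                    )
                    for k in range(n_reports):
                        adr_reports.append(
                            ADRReport(
                                report_id=f"R{len(adr_reports) + 1:06d}",
                                client_id=cid,
                                event_date=edate,
                                event_label=label,
                                causality="unlikely" if unlikely else "possible_or_higher",
                                resulted_in_discontinuation=disc,
                            )
                        )

    # incident lab records
    for inc in incidents:
        tests.append(LabTestRecord(inc["cid"], inc["date"], inc["assay"], "positive_incident"))

    store = _build_store(clients, providers, tests, adr_reports)
    truth = _bookkeep_truth(
        sim, cfg, quarters, clients, providers, tests, incidents, adr_events
    )
    return store, truth


def _build_store(clients, providers, tests, adr_reports) -> EventStore:
    recs = []
    enrols = []
    disps = []
    notes = []
    for c in clients:
        recs.append(
            ClientRecord(
                client_id=c.cid,
                date_of_birth=c.dob,
                gender_identity_history=tuple(c.gender_history),
                ha_of_residence=c.ha,
            )
        )
        enrols.append(
            EnrolmentRecord(
                client_id=c.cid,
                authorization_date=c.auth_date,
                enrolling_provider_id=c.enrol_provider,
                risk_factors=frozenset(_FACTOR_BY_LETTER[l] for l in c.risk_letters),
                risk_factors_unknown=not c.risk_letters,
            )
        )
        for d in c.dispensations:
            disps.append(
                DispensationRecord(
                    client_id=c.cid,
                    prescriber_id=d["provider"],
                    fill_date=d["fill"],
                    pickup_date=d["pickup"],
                    tablets=d["tablets"],
                    usage_type=d["usage"],
                    prescriber_ha_of_practice=d["ha_practice"],
                )
            )
        if c.notification is not None:
            notes.append(StatusNotification(c.cid, c.notification))
    tests_sorted = sorted(tests, key=lambda t: (t.client_id, t.test_date, t.assay))
    return EventStore.from_records(
        clients=recs,
        enrolments=enrols,
        dispensations=disps,
        lab_tests=tests_sorted,
        adr_reports=adr_reports,
        providers=providers,
        notifications=notes,
    )


# ---------------------------------------------------------------------------
# ground-truth bookkeeping (independent of the indicator engine)


def _quantile_sorted(vals: list, p: float) -> float:
    """Sort-and-index quantile with linear interpolation."""
    s = sorted(vals)
    h = (len(s) - 1) * p
    lo = int(math.floor(h))
    frac = h - lo
    if frac == 0:
        return float(s[lo])
    return float(s[lo] + frac * (s[lo + 1] - s[lo]))


def _bookkeep_truth(
    sim, cfg, quarters, clients, providers, tests, incidents, adr_events
) -> GroundTruth:
    truth = GroundTruth()
    win_lo, win_hi = cfg.lookback_days, cfg.grace_days
    ptype = {p.provider_id: p.provider_type for p in providers}
    pha = {p.provider_id: p.ha_of_practice for p in providers}

    tests_by_client: dict[str, list] = {}
    for t in tests:
        tests_by_client.setdefault(t.client_id, []).append(t)

    dispensed = [c for c in clients if c.dispensations]

    for q in quarters:
        key = str(q)
        qt: dict = {}
        in_q = [
            (c, [d for d in c.dispensations if q.start <= d["eff"] <= q.end])
            for c in dispensed
        ]
        in_q = [(c, ds) for c, ds in in_q if ds]
        denom = len(in_q)

        def tally(pairs) -> dict:
            out: dict = {}
            for k in pairs:
                out[k] = out.get(k, 0) + 1
            return {k: v for k, v in out.items() if v}

        qt["1"] = {
            "rows": tally(
                max(
                    ((d, g) for d, g in c.gender_history if d <= q.end),
                    key=lambda x: x[0],
                )[1]
                for c, _ in in_q
            ),
            "denominator": denom,
        }
        qt["2"] = {
            "rows": tally(
                _age_bin_label(_age_years(c.dob, ds[0]["eff"])) for c, ds in in_q
            ),
            "denominator": denom,
        }
        qt["3.residence"] = {"rows": tally(c.ha for c, _ in in_q), "denominator": denom}
        qt["3.practice"] = {
            "rows": tally(ds[0]["ha_practice"] for c, ds in in_q),
            "denominator": denom,
        }

        enrolled = [c for c in clients if q.start <= c.auth_date <= q.end]
        qt["4"] = {
            "rows": tally(ptype[c.enrol_provider] for c in enrolled),
            "denominator": len(enrolled),
        }
        qt["5.residence"] = {
            "rows": tally(c.ha for c in enrolled),
            "denominator": len(enrolled),
        }
        qt["5.practice"] = {
            "rows": tally(pha[c.enrol_provider] for c in enrolled),
            "denominator": len(enrolled),
        }

        first_in_q = [c for c in dispensed if q.start <= c.first_eff <= q.end]
        qt["6.residence"] = {
            "rows": tally(c.ha for c in first_in_q),
            "denominator": len(first_in_q),
        }
        qt["6.practice"] = {
            "rows": tally(c.dispensations[0]["ha_practice"] for c in first_in_q),
            "denominator": len(first_in_q),
        }

        # indicator 7: provider caseloads
        pairs = set()
        for c, ds in in_q:
            for d in ds:
                pairs.add((d["provider"], c.cid))
        vol: dict[str, int] = {}
        for p, cid in pairs:
            vol[p] = vol.get(p, 0) + 1
        qt["7a"] = {
            "rows": tally(_volume_bin_label(v) for v in vol.values()),
            "denominator": len(vol),
        }
        cov: dict[str, set] = {}
        for p, cid in pairs:
            cov.setdefault(_volume_bin_label(vol[p]), set()).add(cid)
        qt["7b"] = {
            "rows": {b: len(s) for b, s in cov.items() if s},
            "denominator": len({cid for _, cid in pairs}),
        }

        # indicator 8
        qt["8a"] = {
            "rows": {
                _FACTOR_BY_LETTER[l]: n
                for l, n in tally(
                    l for c in first_in_q for l in c.risk_letters
                ).items()
            },
            "denominator": len(first_in_q),
        }
        cum_first = [c for c in dispensed if c.first_eff <= q.end]
        qt["8b"] = {
            "rows": tally(_combo_label(c.risk_letters) for c in cum_first),
            "denominator": len(cum_first),
        }

        # indicator 9
        states = [c.active_at(q.end) for c in dispensed if c.first_eff <= q.end]
        qt["9"] = {
            "rows": {
                "active": sum(1 for s in states if s),
                "inactive": sum(1 for s in states if s is False),
            },
            "denominator": len(states),
        }

        # indicator 10: usage of the latest dispensation among active clients
        usage_rows: dict[str, int] = {}
        n_active = 0
        for c in dispensed:
            if c.first_eff <= q.end and c.active_at(q.end):
                n_active += 1
                last = max(
                    (d for d in c.dispensations if d["eff"] <= q.end),
                    key=lambda d: d["eff"],
                )
                usage_rows[last["usage"]] = usage_rows.get(last["usage"], 0) + 1
        qt["10"] = {"rows": usage_rows, "denominator": n_active}

        # indicator 11: tablet units by HA
        res_tabs: dict[str, int] = {}
        prac_tabs: dict[str, int] = {}
        total_tabs = 0
        for c, ds in in_q:
            for d in ds:
                res_tabs[c.ha] = res_tabs.get(c.ha, 0) + d["tablets"]
                prac_tabs[d["ha_practice"]] = (
                    prac_tabs.get(d["ha_practice"], 0) + d["tablets"]
                )
                total_tabs += d["tablets"]
        unit = cfg.tablet_unit
        qt["11.residence"] = {
            "rows": {k: v / unit for k, v in res_tabs.items()},
            "denominator": total_tabs / unit,
        }
        qt["11.practice"] = {
            "rows": {k: v / unit for k, v in prac_tabs.items()},
            "denominator": total_tabs / unit,
        }

        # indicators 12a / 13b: brute-force all-pairs window check
        for assay, rid in (("syphilis", "12a"), ("hiv", "13b")):
            num = 0
            den = 0
            for c, ds in in_q:
                ctests = [
                    t.test_date
                    for t in tests_by_client.get(c.cid, ())
                    if t.assay == assay
                ]
                for d in ds:
                    if c.active_at(d["eff"]) is not True:
                        continue
                    den += 1
                    lo = d["eff"] - dt.timedelta(days=win_lo)
                    hi = d["eff"] + dt.timedelta(days=win_hi)
                    if cfg.window_inclusive:
                        hit = any(lo <= td <= hi for td in ctests)
                    else:
                        hit = any(lo < td < hi for td in ctests)
                    num += hit
            qt[rid] = {"numerator": num, "denominator": den}

        # indicator 12b
        by_cid = {c.cid: c for c in clients}
        for label, restrict in (("12b_active", True), ("12b_all", False)):
            hit = set()
            for inc in incidents:
                if inc["assay"] != "syphilis" or not (q.start <= inc["date"] <= q.end):
                    continue
                if restrict and by_cid[inc["cid"]].active_at(inc["date"]) is not True:
                    continue
                hit.add(inc["cid"])
            qt[label] = len(hit)

        # indicator 14
        ev_q = [
            e
            for e in adr_events
            if q.start <= e["date"] <= q.end and not e["unlikely"]
        ]
        qt["14"] = {
            "events": len(ev_q),
            "distinct_clients": len({e["cid"] for e in ev_q}),
            "discontinuation_linked": sum(1 for e in ev_q if e["disc"]),
        }
        truth.quarters[key] = qt

    # cumulative blocks
    ever = len(dispensed)
    gaps = []
    n_excl = 0
    for c in dispensed:
        negs = [
            t.test_date
            for t in tests_by_client.get(c.cid, ())
            if t.assay == "hiv" and t.result == "negative" and t.test_date <= c.first_eff
        ]
        if not negs:
            n_excl += 1
            continue
        gaps.append((c.first_eff - max(negs)).days)
    summary = {
        "median": _quantile_sorted(gaps, 0.5) if gaps else None,
        "q25": _quantile_sorted(gaps, 0.25) if gaps else None,
        "q75": _quantile_sorted(gaps, 0.75) if gaps else None,
        "n": len(gaps),
        "n_excluded": n_excl,
    }
    ev_all = [e for e in adr_events if not e["unlikely"]]
    truth.cumulative = {
        "total_clients": len(clients),
        "ever_dispensed": ever,
        "13a": summary,
        "14": {
            "events": len(ev_all),
            "distinct_clients": len({e["cid"] for e in ev_all}),
            "discontinuation_linked": sum(1 for e in ev_all if e["disc"]),
        },
    }
    return truth


def write_simulation(
    sim: SimulationConfig, out_dir, cfg: IndicatorConfig | None = None
) -> tuple[EventStore, GroundTruth]:
    """Write the event tables plus ``ground_truth.json`` to ``out_dir``."""
    store, truth = simulate(sim, cfg)
    out = Path(out_dir)
    write_event_store(store, out)
    truth.to_json(out / "ground_truth.json")
    return store, truth


# ---------------------------------------------------------------------------
# hand-built fixtures


def _mini_clients(ids, dob=dt.date(1985, 3, 12), ha="Vancouver Coastal"):
    return [
        ClientRecord(
            client_id=c,
            date_of_birth=dob,
            gender_identity_history=((dt.date(2018, 1, 1), "cis_male"),),
            ha_of_residence=ha,
        )
        for c in ids
    ]


def fixture_suite() -> dict[str, tuple[EventStore, dict]]:
    """Tiny hand-built stores with annotated expectations.

    Returns ``name -> (store, annotations)``; annotations hold the
    hand-worked values the engine is expected to reproduce.
    """
    out: dict[str, tuple[EventStore, dict]] = {}
    providers = [
        ProviderRecord("P1", "family_physician", "Vancouver Coastal"),
        ProviderRecord("P2", "specialist_physician", "Fraser"),
    ]

    # --- window-boundary: tests exactly on/off the 46-day window edges ----
    disp = lambda cid, d: DispensationRecord(  # noqa: E731
        client_id=cid, prescriber_id="P1", fill_date=d, pickup_date=None, tablets=30
    )
    store = EventStore.from_records(
        clients=_mini_clients(["A", "B"]),
        dispensations=[
            disp("A", dt.date(2020, 5, 1)),
            disp("A", dt.date(2020, 6, 1)),
            disp("B", dt.date(2020, 5, 1)),
        ],
        lab_tests=[
            LabTestRecord("A", dt.date(2020, 4, 1), "syphilis", "negative"),  # -30: in
            LabTestRecord("A", dt.date(2020, 6, 16), "syphilis", "negative"),  # +15: in
            LabTestRecord("B", dt.date(2020, 3, 31), "syphilis", "negative"),  # -31: out
            LabTestRecord("B", dt.date(2020, 5, 17), "syphilis", "negative"),  # +16: out
        ],
        providers=providers,
    )
    out["window-boundary"] = (
        store,
        {"quarter": "2020Q2", "syphilis_coverage": {"numerator": 2, "denominator": 3}},
    )

    # --- lapse-boundary: hand-worked status timelines ---------------------
    store = EventStore.from_records(
        clients=_mini_clients(["L1", "L2", "L3", "L4"]),
        dispensations=[
            # L1 refills exactly on the gap-rule boundary day: stays active
            disp("L1", dt.date(2018, 1, 10)),
            disp("L1", dt.date(2018, 7, 11)),
            # L2 stops after one fill well before the cutover
            disp("L2", dt.date(2018, 1, 10)),
            # L3 stops after one fill after the cutover
            disp("L3", dt.date(2019, 12, 1)),
            # L4 keeps refilling but formally discontinues
            disp("L4", dt.date(2019, 1, 5)),
            disp("L4", dt.date(2019, 2, 4)),
        ],
        notifications=[StatusNotification("L4", dt.date(2019, 5, 10))],
        providers=providers,
    )
    out["lapse-boundary"] = (
        store,
        {
            "as_of": "2020-12-31",
            # L1 refills on 2018-07-11, the first day the gap from 2018-01-10
            # would exceed six months: the refill itself must not lapse,
            # checked at the mid-date below. L1's second fill then lapses
            # later (gap rule: 2019-01-12; refill rule: supply to 2018-08-10,
            # so 2019-02-11).
            "mid_check": {"client": "L1", "date": "2018-12-31", "state": "active"},
            # mode -> client -> (final state, reason of last entry, date)
            "expected": {
                "switch_at_cutover": {
                    "L1": ("inactive", "lapse_between_prescriptions", "2019-01-12"),
                    "L2": ("inactive", "lapse_between_prescriptions", "2018-07-11"),
                    "L3": ("inactive", "lapse_past_expected_refill", "2020-07-01"),
                    "L4": ("inactive", "formal_notification", "2019-05-10"),
                },
                "pre_cutover_only": {
                    "L1": ("inactive", "lapse_between_prescriptions", "2019-01-12"),
                    "L2": ("inactive", "lapse_between_prescriptions", "2018-07-11"),
                    "L3": ("active", "first_dispensation", "2019-12-01"),
                    "L4": ("inactive", "formal_notification", "2019-05-10"),
                },
                "refill_always": {
                    "L1": ("inactive", "lapse_past_expected_refill", "2019-02-11"),
                    "L2": ("inactive", "lapse_past_expected_refill", "2018-08-10"),
                    "L3": ("inactive", "lapse_past_expected_refill", "2020-07-01"),
                    "L4": ("inactive", "formal_notification", "2019-05-10"),
                },
            },
        },
    )

    # --- dup-adr ----------------------------------------------------------
    store = EventStore.from_records(
        clients=_mini_clients(["A", "B"]),
        dispensations=[disp("A", dt.date(2020, 4, 10)), disp("B", dt.date(2020, 4, 12))],
        adr_reports=[
            ADRReport("R1", "A", dt.date(2020, 5, 2), "nausea"),
            ADRReport("R2", "A", dt.date(2020, 5, 2), "nausea"),  # duplicate of R1
            ADRReport("R3", "A", dt.date(2020, 6, 1), "rash", causality="unlikely"),
            ADRReport("R4", "B", dt.date(2020, 5, 20), "headache",
                      resulted_in_discontinuation=True),
        ],
        providers=providers,
    )
    out["dup-adr"] = (
        store,
        {
            "quarter": "2020Q2",
            "events": 2,
            "distinct_clients": 2,
            "discontinuation_linked": 1,
        },
    )

    # --- multi-provider client --------------------------------------------
    store = EventStore.from_records(
        clients=_mini_clients(["A", "B", "C"]),
        dispensations=[
            DispensationRecord("A", "P1", dt.date(2020, 4, 5), tablets=30),
            DispensationRecord("A", "P2", dt.date(2020, 5, 6), tablets=30),
            DispensationRecord("B", "P2", dt.date(2020, 4, 8), tablets=30),
            DispensationRecord("C", "P2", dt.date(2020, 4, 9), tablets=30),
        ],
        providers=providers,
    )
    out["multi-provider"] = (
        store,
        {
            "quarter": "2020Q2",
            "part_a": {"rows": {"1": 1, "2-5": 1}, "denominator": 2},
            "part_b": {"rows": {"1": 1, "2-5": 3}, "denominator": 3},
        },
    )

    # --- risk-factor combinations ----------------------------------------
    mk_enrol = lambda cid, letters: EnrolmentRecord(  # noqa: E731
        client_id=cid,
        authorization_date=dt.date(2020, 4, 1),
        enrolling_provider_id="P1",
        risk_factors=frozenset(_FACTOR_BY_LETTER[l] for l in letters),
        risk_factors_unknown=not letters,
    )
    store = EventStore.from_records(
        clients=_mini_clients(["A", "B", "C", "D"]),
        enrolments=[
            mk_enrol("A", "d"),
            mk_enrol("B", "ad"),
            mk_enrol("C", "abd"),
            mk_enrol("D", ""),
        ],
        dispensations=[
            disp("A", dt.date(2020, 4, 10)),
            disp("B", dt.date(2020, 4, 11)),
            disp("C", dt.date(2020, 5, 12)),
            disp("D", dt.date(2020, 6, 13)),
        ],
        providers=providers,
    )
    out["risk-combo"] = (
        store,
        {
            "quarter": "2020Q2",
            "part_a": {
                "rows": {
                    "a_syphilis_or_rectal_sti": 2,
                    "b_recurrent_npep": 1,
                    "d_hiri_msm_ge10": 3,
                },
                "denominator": 4,
            },
            "part_b": {
                "rows": {"d only": 1, "a+d": 1, "a+b+d": 1, "none recorded": 1},
                "denominator": 4,
            },
        },
    )
    return out
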