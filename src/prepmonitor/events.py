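"""Domain data model for PrEP-program event streams.

The monitoring engine consumes seven flat, comma-delimited UTF-8 tables with
header rows (the discontinuation-notification table is optional and may be
absent or empty):

``clients``
    One row per recorded gender identity per client: ``client_id``,
    ``date_of_birth``, ``ha_of_residence``, ``gender_effective_date``,
    ``gender_identity``. Date of birth and health authority of residence
    must agree across a client's rows; row order breaks same-day ties when
    resolving the most recent gender identity.
``enrolments``
    ``client_id``, ``authorization_date``, ``enrolling_provider_id``,
    ``risk_factors`` (semicolon-joined codes), ``risk_factors_unknown``.
``dispensations``
    ``client_id``, ``prescriber_id``, ``fill_date``, ``pickup_date`` (may be
    empty), ``tablets``, ``usage_type``, ``prescriber_ha_of_practice``.
``lab_tests``
    ``client_id``, ``test_date``, ``assay``, ``result``.
``adr_reports``
    ``report_id``, ``client_id``, ``event_date``, ``event_label``,
    ``causality``, ``resulted_in_discontinuation``.
``providers``
    ``provider_id``, ``provider_type``, ``ha_of_practice``.
``notifications``
    ``client_id``, ``notification_date``, ``kind``.

All dates are ISO-8601 calendar dates without times; comparisons everywhere
in the package are whole-day. A missing pickup date is stored as an empty
field and preserved on round trip; the pickup-else-fill fallback is applied
at computation time, never at ingest.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GENDER_LABELS",
    "HA_LABELS",
    "RISK_FACTORS",
    "ClientRecord",
    "EnrolmentRecord",
    "DispensationRecord",
    "LabTestRecord",
    "ADRReport",
    "ProviderRecord",
    "StatusNotification",
    "EventStore",
    "SchemaError",
    "IntegrityError",
    "RowError",
    "read_event_store",
    "write_event_store",
    "export_table_schemas",
]

GENDER_LABELS = (
    "cis_male",
    "cis_female",
    "trans_male",
    "trans_female",
    "other_unspecified",
)

#: The five BC regional health authorities plus the explicit Unknown category.
HA_LABELS = (
    "Interior",
    "Fraser",
    "Vancouver Coastal",
    "Vancouver Island",
    "Northern",
    "Unknown",
)

#: The six key qualifying HIV risk factors recorded at program enrolment.
#: The HIRI-MSM >=10 criterion (factor d) is an input flag; the score itself
#: is never computed here.
RISK_FACTORS = (
    "a_syphilis_or_rectal_sti",
    "b_recurrent_npep",
    "c_serodiscordant_partner_msm",
    "d_hiri_msm_ge10",
    "e_heterosexual_condomless_serodiscordant",
    "f_pwid_shared_equipment",
)

PROVIDER_TYPES = ("family_physician", "specialist_physician", "nurse_practitioner")
USAGE_TYPES = ("daily", "non_daily")
ASSAYS = ("hiv", "syphilis")
LAB_RESULTS = ("negative", "positive_incident", "positive_prevalent", "indeterminate")


class SchemaError(ValueError):
    """A table is missing a required column or has an unknown layout."""


class IntegrityError(ValueError):
    """Cross-table referential integrity or an invariant is violated."""


class RowError(ValueError):
    """A row holds an unparseable or out-of-domain value (carries line no)."""


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class ClientRecord:
    client_id: str
    date_of_birth: dt.date
    gender_identity_history: tuple  # of (effective_date, label)
    ha_of_residence: str = "Unknown"


@dataclass(frozen=True)
class EnrolmentRecord:
    client_id: str
    authorization_date: dt.date
    enrolling_provider_id: str
    risk_factors: frozenset = frozenset()
    risk_factors_unknown: bool = False


@dataclass(frozen=True)
class DispensationRecord:
    client_id: str
    prescriber_id: str
    fill_date: dt.date
    pickup_date: dt.date | None = None
    tablets: int = 30
    usage_type: str = "daily"
    prescriber_ha_of_practice: str = "Unknown"

    @property
    def effective_date(self) -> dt.date:
        """Pickup date when recorded, otherwise the prescription fill date."""
        return self.pickup_date if self.pickup_date is not None else self.fill_date


@dataclass(frozen=True)
class LabTestRecord:
    client_id: str
    test_date: dt.date
    assay: str
    result: str


@dataclass(frozen=True)
class ADRReport:
    report_id: str
    client_id: str
    event_date: dt.date
    event_label: str
    causality: str = "possible_or_higher"
    resulted_in_discontinuation: bool = False


@dataclass(frozen=True)
class ProviderRecord:
    provider_id: str
    provider_type: str
    ha_of_practice: str = "Unknown"


@dataclass(frozen=True)
class StatusNotification:
    client_id: str
    notification_date: dt.date
    kind: str = "formal_discontinuation"


# ---------------------------------------------------------------------------
# table schemas

TABLE_SCHEMAS: dict[str, dict] = {
    "clients": {
        "columns": [
            "client_id",
            "date_of_birth",
            "ha_of_residence",
            "gender_effective_date",
            "gender_identity",
        ],
        "date_columns": ["date_of_birth", "gender_effective_date"],
    },
    "enrolments": {
        "columns": [
            "client_id",
            "authorization_date",
            "enrolling_provider_id",
            "risk_factors",
            "risk_factors_unknown",
        ],
        "date_columns": ["authorization_date"],
    },
    "dispensations": {
        "columns": [
            "client_id",
            "prescriber_id",
            "fill_date",
            "pickup_date",
            "tablets",
            "usage_type",
            "prescriber_ha_of_practice",
        ],
        "date_columns": ["fill_date", "pickup_date"],
    },
    "lab_tests": {
        "columns": ["client_id", "test_date", "assay", "result"],
        "date_columns": ["test_date"],
    },
    "adr_reports": {
        "columns": [
            "report_id",
            "client_id",
            "event_date",
            "event_label",
            "causality",
            "resulted_in_discontinuation",
        ],
        "date_columns": ["event_date"],
    },
    "providers": {
        "columns": ["provider_id", "provider_type", "ha_of_practice"],
        "date_columns": [],
    },
    "notifications": {
        "columns": ["client_id", "notification_date", "kind"],
        "date_columns": ["notification_date"],
    },
}

OPTIONAL_TABLES = ("notifications",)


def export_table_schemas(path) -> None:
    """Write the documented table schemas as a JSON file."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(TABLE_SCHEMAS, fh, indent=2)


# ---------------------------------------------------------------------------
# the store


def _parse_date_column(df: pd.DataFrame, table: str, col: str) -> None:
    raw = df[col]
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        # +2: header row plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise RowError(
            f"{table}: unparseable date {raw[bad.idxmax()]!r} in column "
            f"{col!r} at line {line}"
        )
    df[col] = parsed


@dataclass
class EventStore:
    """Validated in-memory collection of the program event tables.

    Date columns are ``datetime64[ns]`` (midnight timestamps standing in for
    calendar dates); string columns are plain ``object``.
    """

    clients: pd.DataFrame
    enrolments: pd.DataFrame
    dispensations: pd.DataFrame
    lab_tests: pd.DataFrame
    adr_reports: pd.DataFrame
    providers: pd.DataFrame
    notifications: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.notifications is None:
            self.notifications = _empty_frame("notifications")
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        clients: Iterable[ClientRecord] = (),
        enrolments: Iterable[EnrolmentRecord] = (),
        dispensations: Iterable[DispensationRecord] = (),
        lab_tests: Iterable[LabTestRecord] = (),
        adr_reports: Iterable[ADRReport] = (),
        providers: Iterable[ProviderRecord] = (),
        notifications: Iterable[StatusNotification] = (),
    ) -> "EventStore":
        client_rows = []
        for c in clients:
            history = c.gender_identity_history or ((c.date_of_birth, "other_unspecified"),)
            for eff, label in history:
                client_rows.append(
                    {
                        "client_id": c.client_id,
                        "date_of_birth": pd.Timestamp(c.date_of_birth),
                        "ha_of_residence": c.ha_of_residence,
                        "gender_effective_date": pd.Timestamp(eff),
                        "gender_identity": label,
                    }
                )
        enrol_rows = [
            {
                "client_id": e.client_id,
                "authorization_date": pd.Timestamp(e.authorization_date),
                "enrolling_provider_id": e.enrolling_provider_id,
                "risk_factors": ";".join(sorted(e.risk_factors)),
                "risk_factors_unknown": bool(e.risk_factors_unknown),
            }
            for e in enrolments
        ]
        disp_rows = [
            {
                "client_id": d.client_id,
                "prescriber_id": d.prescriber_id,
                "fill_date": pd.Timestamp(d.fill_date),
                "pickup_date": pd.Timestamp(d.pickup_date) if d.pickup_date else pd.NaT,
                "tablets": int(d.tablets),
                "usage_type": d.usage_type,
                "prescriber_ha_of_practice": d.prescriber_ha_of_practice,
            }
            for d in dispensations
        ]
        lab_rows = [
            {
                "client_id": t.client_id,
                "test_date": pd.Timestamp(t.test_date),
                "assay": t.assay,
                "result": t.result,
            }
            for t in lab_tests
        ]
        adr_rows = [
            {
                "report_id": r.report_id,
                "client_id": r.client_id,
                "event_date": pd.Timestamp(r.event_date),
                "event_label": r.event_label,
                "causality": r.causality,
                "resulted_in_discontinuation": bool(r.resulted_in_discontinuation),
            }
            for r in adr_reports
        ]
        prov_rows = [dataclasses.asdict(p) for p in providers]
        note_rows = [
            {
                "client_id": n.client_id,
                "notification_date": pd.Timestamp(n.notification_date),
                "kind": n.kind,
            }
            for n in notifications
        ]

        def frame(name: str, rows: list[dict]) -> pd.DataFrame:
            if not rows:
                return _empty_frame(name)
            return pd.DataFrame(rows, columns=TABLE_SCHEMAS[name]["columns"])

        return cls(
            clients=frame("clients", client_rows),
            enrolments=frame("enrolments", enrol_rows),
            dispensations=frame("dispensations", disp_rows),
            lab_tests=frame("lab_tests", lab_rows),
            adr_reports=frame("adr_reports", adr_rows),
            providers=frame("providers", prov_rows),
            notifications=frame("notifications", note_rows),
        )

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Enforce schemas, domains and referential integrity. Raises."""
        for name in TABLE_SCHEMAS:
            df = getattr(self, name)
            missing = [c for c in TABLE_SCHEMAS[name]["columns"] if c not in df.columns]
            if missing:
                raise SchemaError(f"{name}: missing column(s) {missing}")

        known_clients = set(self.clients["client_id"])
        known_providers = set(self.providers["provider_id"])

        for name, col, pool in (
            ("enrolments", "client_id", known_clients),
            ("dispensations", "client_id", known_clients),
            ("lab_tests", "client_id", known_clients),
            ("adr_reports", "client_id", known_clients),
            ("notifications", "client_id", known_clients),
            ("enrolments", "enrolling_provider_id", known_providers),
            ("dispensations", "prescriber_id", known_providers),
        ):
            df = getattr(self, name)
            if len(df):
                orphans = sorted(set(df[col]) - pool)
                if orphans:
                    raise IntegrityError(
                        f"{name}.{col} references unknown id(s): {orphans[:10]}"
                    )

        # multiple rows per client are the gender history; the per-client
        # attributes must nonetheless agree across rows
        dup = self.clients.groupby("client_id")[["date_of_birth", "ha_of_residence"]].nunique()
        inconsistent = dup[(dup > 1).any(axis=1)].index.tolist()
        if inconsistent:
            raise IntegrityError(
                f"clients: inconsistent date_of_birth/ha_of_residence for {inconsistent[:10]}"
            )
        # gender history dates non-decreasing in file order per client
        g = self.clients
        if len(g):
            shifted = g.groupby("client_id")["gender_effective_date"].diff()
            if (shifted.dropna() < pd.Timedelta(0)).any():
                bad = g.loc[shifted < pd.Timedelta(0), "client_id"].unique().tolist()
                raise IntegrityError(f"clients: gender history out of order for {bad[:10]}")

        if len(self.adr_reports):
            if self.adr_reports["report_id"].duplicated().any():
                dups = self.adr_reports.loc[
                    self.adr_reports["report_id"].duplicated(), "report_id"
                ].tolist()
                raise IntegrityError(f"adr_reports: duplicate report_id(s) {dups[:10]}")

        d = self.dispensations
        if len(d):
            if (d["tablets"] <= 0).any():
                raise IntegrityError("dispensations: tablets must be positive")
            has_pickup = d["pickup_date"].notna()
            if (d.loc[has_pickup, "pickup_date"] < d.loc[has_pickup, "fill_date"]).any():
                raise IntegrityError("dispensations: pickup_date precedes fill_date")
            bad_usage = sorted(set(d["usage_type"]) - set(USAGE_TYPES))
            if bad_usage:
                raise RowError(f"dispensations: unknown usage_type {bad_usage}")

        for name, col, domain in (
            ("clients", "gender_identity", GENDER_LABELS),
            ("clients", "ha_of_residence", HA_LABELS),
            ("dispensations", "prescriber_ha_of_practice", HA_LABELS),
            ("lab_tests", "assay", ASSAYS),
            ("lab_tests", "result", LAB_RESULTS),
            ("adr_reports", "causality", ("possible_or_higher", "unlikely")),
            ("providers", "provider_type", PROVIDER_TYPES),
            ("providers", "ha_of_practice", HA_LABELS),
        ):
            df = getattr(self, name)
            if len(df):
                bad = sorted(set(df[col].dropna()) - set(domain))
                if bad:
                    raise RowError(f"{name}.{col}: out-of-domain value(s) {bad[:10]}")

        if len(self.enrolments):
            empty = (self.enrolments["risk_factors"].fillna("") == "") & ~self.enrolments[
                "risk_factors_unknown"
            ].astype(bool)
            if empty.any():
                raise IntegrityError(
                    "enrolments: empty risk_factors without risk_factors_unknown flag"
                )
            for cell in self.enrolments["risk_factors"].fillna(""):
                bad = set(filter(None, cell.split(";"))) - set(RISK_FACTORS)
                if bad:
                    raise RowError(f"enrolments.risk_factors: unknown factor(s) {sorted(bad)}")

    # -- accessors --------------------------------------------------------

    def dispensations_effective(self) -> pd.DataFrame:
        """Dispensations with an ``effective_date`` column (pickup else fill)."""
        d = self.dispensations.copy()
        d["effective_date"] = d["pickup_date"].fillna(d["fill_date"])
        return d

    def date_of_birth(self) -> pd.Series:
        """client_id -> date of birth."""
        return self.clients.drop_duplicates("client_id").set_index("client_id")[
            "date_of_birth"
        ]

    def ha_of_residence(self) -> pd.Series:
        return self.clients.drop_duplicates("client_id").set_index("client_id")[
            "ha_of_residence"
        ]

    def gender_as_of(self, as_of: dt.date) -> pd.Series:
        """Most recent recorded gender identity on/before ``as_of`` per client.

        Same-day ties are broken by file order (the later row wins). Clients
        whose whole history is after ``as_of`` resolve to
        ``other_unspecified``.
        """
        g = self.clients
        eligible = g[g["gender_effective_date"] <= pd.Timestamp(as_of)]
        latest = (
            eligible.reset_index()
            .sort_values(["gender_effective_date", "index"], kind="stable")
            .groupby("client_id")
            .tail(1)
            .set_index("client_id")["gender_identity"]
        )
        return latest.reindex(self.clients["client_id"].unique()).fillna("other_unspecified")

    def events_for_client(self, client_id: str) -> dict[str, pd.DataFrame]:
        """All rows referencing one client, per table."""
        out = {}
        for name in TABLE_SCHEMAS:
            df = getattr(self, name)
            if "client_id" in df.columns:
                out[name] = df[df["client_id"] == client_id]
        return out

    def equals(self, other: "EventStore") -> bool:
        for name in TABLE_SCHEMAS:
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            if not a.equals(b):
                return False
        return True


def _empty_frame(name: str) -> pd.DataFrame:
    cols = TABLE_SCHEMAS[name]["columns"]
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
    for c in TABLE_SCHEMAS[name]["date_columns"]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    if name == "dispensations":
        df["tablets"] = pd.Series(dtype="int64")
    if name in ("adr_reports", "enrolments"):
        flag = "resulted_in_discontinuation" if name == "adr_reports" else "risk_factors_unknown"
        df[flag] = pd.Series(dtype="bool")
    return df[cols]


# ---------------------------------------------------------------------------
# readers / writers


def read_event_store(
    paths: Mapping[str, str | Path] | str | Path, schema_dialect: str = "csv"
) -> EventStore:
    """Read and validate the event tables.

    ``paths`` is either a mapping table-name -> file path, or a directory
    containing ``<table>.csv`` files. The optional ``notifications`` table
    may be absent.
    """
    if schema_dialect != "csv":
        raise SchemaError(f"unknown schema dialect {schema_dialect!r}")
    if not isinstance(paths, Mapping):
        root = Path(paths)
        paths = {
            name: root / f"{name}.csv"
            for name in TABLE_SCHEMAS
            if (root / f"{name}.csv").exists() or name not in OPTIONAL_TABLES
        }

    frames: dict[str, pd.DataFrame] = {}
    for name, schema in TABLE_SCHEMAS.items():
        if name not in paths:
            if name in OPTIONAL_TABLES:
                frames[name] = _empty_frame(name)
                continue
            raise SchemaError(f"no path given for required table {name!r}")
        p = Path(paths[name])
        if not p.exists():
            raise FileNotFoundError(p)
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        missing = [c for c in schema["columns"] if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} ({p}): missing column(s) {missing}")
        df = df[schema["columns"]]
        df = df.replace({"": None})
        for col in schema["date_columns"]:
            _parse_date_column(df, name, col)
        if name == "dispensations":
            try:
                df["tablets"] = df["tablets"].astype("int64")
            except (TypeError, ValueError) as exc:
                raise RowError(f"dispensations: unparseable tablets count ({exc})")
        for flag in ("resulted_in_discontinuation", "risk_factors_unknown"):
            if flag in df.columns:
                df[flag] = (
                    df[flag].map(lambda v: str(v).strip().lower() in ("true", "1", "yes"))
                    if len(df)
                    else df[flag].astype(bool)
                )
        if name == "enrolments" and len(df):
            df["risk_factors"] = df["risk_factors"].fillna("")
        frames[name] = df
    return EventStore(**frames)


def write_event_store(store: EventStore, directory: str | Path) -> dict[str, Path]:
    """Write the tables as ``<table>.csv`` plus a ``schemas.json`` sidecar.

    Dates serialise as ISO-8601; a missing pickup date serialises as an
    empty field. ``read_event_store(write_event_store(s)) == s``.
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name, schema in TABLE_SCHEMAS.items():
        df = getattr(store, name).copy()
        for col in schema["date_columns"]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        p = root / f"{name}.csv"
        df.to_csv(p, index=False)
        out[name] = p
    export_table_schemas(root / "schemas.json")
    return out
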