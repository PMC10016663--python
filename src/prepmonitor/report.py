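"""Quarterly monitoring report: all fourteen indicators, small-cell
suppression and serialisation to CSV / JSON / markdown."""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .calendars import IndicatorConfig, Quarter
from .events import EventStore
from .results import StratifiedResult, StratumRow, percent  # noqa: F401 (re-export)
from . import indicators as ind
from .status import compute_timelines, status_counts

__all__ = [
    "INDICATOR_TITLES",
    "IndicatorBlock",
    "QuarterlyReport",
    "percent",
    "build_quarterly_report",
    "suppress_small_cells",
    "write_report",
]

SUPPRESSED_TOKEN = "*"

INDICATOR_TITLES = {
    "1": "Client gender identity",
    "2": "Client age",
    "3": "Health authority",
    "4": "New clients enrolled by provider type",
    "5": "New clients enrolled by health authority",
    "6": "New clients dispensed PrEP",
    "7": "Clients per provider",
    "8": "Key qualifying HIV risk factor(s) reported at enrolment",
    "9": "Client status (active vs inactive)",
    "10": "PrEP usage type",
    "11": "PrEP quantity dispensed (per 30-tablet supply)",
    "12": "Infectious syphilis testing and incident cases",
    "13": "HIV testing",
    "14": "Adverse drug reaction events",
}


@dataclass
class IndicatorBlock:
    indicator_id: str
    title: str
    #: part label -> StratifiedResult, or a plain dict for summaries
    parts: dict = field(default_factory=dict)

    def stratified_parts(self) -> list[StratifiedResult]:
        return [p for p in self.parts.values() if isinstance(p, StratifiedResult)]


@dataclass
class QuarterlyReport:
    quarter: Quarter
    blocks: list[IndicatorBlock]
    footnotes: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def block(self, indicator_id: str) -> IndicatorBlock:
        for b in self.blocks:
            if b.indicator_id == indicator_id:
                return b
        raise KeyError(indicator_id)

    def all_results(self) -> list[StratifiedResult]:
        return [r for b in self.blocks for r in b.stratified_parts()]

    def to_dict(self) -> dict:
        return {
            "quarter": str(self.quarter),
            "blocks": [
                {
                    "indicator_id": b.indicator_id,
                    "title": b.title,
                    "parts": {
                        k: (p.to_dict() if isinstance(p, StratifiedResult) else p)
                        for k, p in b.parts.items()
                    },
                }
                for b in self.blocks
            ],
            "footnotes": self.footnotes,
            "provenance": self.provenance,
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV schema: one row per stratum across all indicators."""
        parts = [r.to_frame() for r in self.all_results()]
        records = [rec for f in parts for rec in f.to_dict("records")]
        return pd.DataFrame(records, columns=StratifiedResult("", "").to_frame().columns)


def _config_digest(cfg: IndicatorConfig) -> str:
    blob = yaml.safe_dump(
        {k: str(v) for k, v in vars(cfg).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_quarterly_report(
    store: EventStore, quarter: Quarter, cfg: IndicatorConfig | None = None
) -> QuarterlyReport:
    """Compute all fourteen indicator blocks for one quarter.

    Deterministic: the same store, quarter and config always produce an
    identical report (and identical serialisations).
    """
    cfg = cfg or IndicatorConfig()
    timelines = compute_timelines(store, quarter.end, cfg)
    q = quarter

    blocks = [
        IndicatorBlock("1", INDICATOR_TITLES["1"], {
            "gender": ind.dispensed_distribution(store, q, "gender", cfg),
        }),
        IndicatorBlock("2", INDICATOR_TITLES["2"], {
            "age": ind.dispensed_distribution(store, q, "age", cfg),
        }),
        IndicatorBlock("3", INDICATOR_TITLES["3"], {
            "residence": ind.dispensed_distribution(store, q, "ha_residence", cfg),
            "practice": ind.dispensed_distribution(store, q, "ha_practice", cfg),
        }),
        IndicatorBlock("4", INDICATOR_TITLES["4"], {
            "provider_type": ind.new_enrolments(store, q, "provider_type", cfg),
        }),
        IndicatorBlock("5", INDICATOR_TITLES["5"], {
            "residence": ind.new_enrolments(store, q, "ha_residence", cfg),
            "practice": ind.new_enrolments(store, q, "ha_practice", cfg),
        }),
        IndicatorBlock("6", INDICATOR_TITLES["6"], {
            "residence": ind.first_dispensations(store, q, cfg, "ha_residence"),
            "practice": ind.first_dispensations(store, q, cfg, "ha_practice"),
        }),
    ]
    part_a, part_b = ind.provider_volume(store, q, cfg)
    blocks.append(IndicatorBlock("7", INDICATOR_TITLES["7"], {"a": part_a, "b": part_b}))
    rf_a, rf_b = ind.risk_factor_profile(store, q, cfg)
    blocks.append(IndicatorBlock("8", INDICATOR_TITLES["8"], {"a": rf_a, "b": rf_b}))
    blocks.append(
        IndicatorBlock("9", INDICATOR_TITLES["9"], {
            "status": status_counts(store, q, cfg, timelines=timelines),
        })
    )
    blocks.append(
        IndicatorBlock("10", INDICATOR_TITLES["10"], {
            "usage": ind.usage_type_distribution(store, q, cfg, timelines=timelines),
        })
    )
    blocks.append(
        IndicatorBlock("11", INDICATOR_TITLES["11"], {
            "residence": ind.quantity_dispensed(store, q, cfg, "ha_residence"),
            "practice": ind.quantity_dispensed(store, q, cfg, "ha_practice"),
        })
    )
    syl_cov = ind.testing_coverage(store, q, "syphilis", cfg, timelines=timelines)
    syl_inc = ind.incident_cases(store, q, "syphilis", True, cfg, timelines=timelines)
    blocks.append(
        IndicatorBlock("12", INDICATOR_TITLES["12"], {
            "a": syl_cov,
            "b": StratifiedResult(
                "12b", str(q), [StratumRow("incident_cases", syl_inc, 0, None)]
            ),
        })
    )
    gap = ind.days_to_first_dispensation(store, cfg)
    hiv_cov = ind.testing_coverage(store, q, "hiv", cfg, timelines=timelines)
    blocks.append(
        IndicatorBlock("13", INDICATOR_TITLES["13"], {"a": gap.to_dict(), "b": hiv_cov})
    )
    n_ev, n_cl, n_disc = ind.adr_event_count(store, q, cfg)
    blocks.append(
        IndicatorBlock("14", INDICATOR_TITLES["14"], {
            "events": StratifiedResult(
                "14",
                str(q),
                [
                    StratumRow("events", n_ev, n_ev, percent(n_ev, n_ev, cfg)),
                    StratumRow("distinct_clients", n_cl, n_ev, percent(n_cl, n_ev, cfg)),
                    StratumRow(
                        "resulted_in_discontinuation",
                        n_disc,
                        n_ev,
                        percent(n_disc, n_ev, cfg),
                    ),
                ],
                notes="duplicates of the same event and 'unlikely' causality excluded",
            ),
        })
    )

    footnotes = [
        f"testing window: {cfg.lookback_days} days before through "
        f"{cfg.grace_days} days after the effective dispense date, endpoints "
        f"{'inclusive' if cfg.window_inclusive else 'exclusive'}",
        f"lapse rule: >{cfg.lapse_months} calendar months, mode "
        f"{cfg.lapse_rule_mode} (cutover {cfg.status_cutover_quarter})",
        f"non-daily use projected at {cfg.non_daily_stretch_factor} days of "
        "coverage per tablet (convention; on-demand dosing has no fixed cadence)",
        f"counts below {cfg.suppression_threshold} are suppressed in public outputs",
        "effective dispense date = pickup date when recorded, else fill date",
    ]
    provenance = {
        "engine_version": __version__,
        "config_sha256": _config_digest(cfg),
        "quarter": str(quarter),
    }
    return QuarterlyReport(quarter, blocks, footnotes, provenance)


# ---------------------------------------------------------------------------
# small-cell suppression


def _suppress_result(r: StratifiedResult, threshold: int) -> None:
    if threshold <= 0:
        return
    for row in r.rows:
        if 0 < row.numerator < threshold:
            row.suppressed = True
    if r.partition:
        masked = [row for row in r.rows if row.suppressed]
        if len(masked) == 1:
            # the masked count is recoverable as denominator minus the rest:
            # complementary-suppress the smallest remaining cell
            rest = [row for row in r.rows if not row.suppressed]
            if rest:
                nonzero = [row for row in rest if row.numerator > 0]
                target = min(nonzero or rest, key=lambda row: row.numerator)
                target.suppressed = True


def suppress_small_cells(
    report: QuarterlyReport, cfg: IndicatorConfig | None = None
) -> QuarterlyReport:
    """Mask stratum counts in ``(0, threshold)`` and apply complementary
    suppression inside partition blocks; returns a new report, the input is
    untouched. A threshold of 0 disables suppression."""
    cfg = cfg or IndicatorConfig()
    out = copy.deepcopy(report)
    for r in out.all_results():
        _suppress_result(r, cfg.suppression_threshold)
    return out


# ---------------------------------------------------------------------------
# writers


def _fmt_num(v, indicator_id: str) -> str:
    if v is None:
        return SUPPRESSED_TOKEN
    if indicator_id.startswith("11"):
        return f"{v:.1f}"
    return str(int(v)) if float(v).is_integer() else f"{v:g}"


def _markdown_table(r: StratifiedResult) -> str:
    lines = [
        "| stratum | numerator | denominator | percent |",
        "| --- | ---: | ---: | ---: |",
    ]
    for row in r.rows:
        num = SUPPRESSED_TOKEN if row.suppressed else _fmt_num(row.numerator, r.indicator_id)
        pct = (
            SUPPRESSED_TOKEN
            if row.suppressed
            else ("" if row.percent is None else f"{row.percent}%")
        )
        lines.append(
            f"| {row.stratum} | {num} | {_fmt_num(row.denominator, r.indicator_id)} | {pct} |"
        )
    return "\n".join(lines)


def _to_markdown(report: QuarterlyReport) -> str:
    out = [f"# PrEP program monitoring report — {report.quarter}", ""]
    for b in report.blocks:
        out.append(f"## {b.indicator_id}. {b.title}")
        out.append("")
        for label, part in b.parts.items():
            if isinstance(part, StratifiedResult):
                out.append(f"### {label} ({part.period})")
                if part.notes:
                    out.append(f"_{part.notes}_")
                out.append("")
                out.append(_markdown_table(part))
            else:  # summary dict (indicator 13a)
                out.append(f"### {label}")
                out.append("")
                out.append(
                    "; ".join(f"{k}: {v}" for k, v in part.items())
                )
            out.append("")
    out.append("## Notes")
    out.extend(f"- {f}" for f in report.footnotes)
    out.append("")
    return "\n".join(out)


def write_report(
    report: QuarterlyReport, format: str, path: str | Path
) -> Path:
    """Serialise a built report. ``format`` is ``csv`` (tidy per-stratum
    rows), ``json`` (full structure) or ``markdown`` (one table per
    indicator part). Suppressed cells render as ``*`` / null, never as the
    underlying count."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        report.to_frame().to_csv(path, index=False)
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=False)
    elif format == "markdown":
        path.write_text(_to_markdown(report), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path
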