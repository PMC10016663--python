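"""Cross-checking the indicator engine against scripted ground truth.

Used in QA: run the engine over a simulated store and diff every numerator
and denominator against the :class:`~prepmonitor.cohort_sim.GroundTruth`
bookkept at generation time. Counts must match exactly; the only tolerance
is floating-point noise on tablet-supply units and day-gap quantiles.
"""

from __future__ import annotations

import math

from .calendars import IndicatorConfig, Quarter
from .cohort_sim import GroundTruth
from .events import EventStore
from . import indicators as ind
from .results import StratifiedResult
from .status import compute_timelines, status_counts

__all__ = ["engine_quarter_values", "engine_cumulative_values", "compare_to_truth"]


def _rows_dict(r: StratifiedResult) -> dict:
    return {row.stratum: row.numerator for row in r.rows if row.numerator}


def _as_truth(r: StratifiedResult) -> dict:
    return {"rows": _rows_dict(r), "denominator": r.denominator}


def engine_quarter_values(
    store: EventStore, quarter: Quarter, cfg: IndicatorConfig | None = None
) -> dict:
    """All per-quarter indicator values, keyed like the ground-truth tables."""
    cfg = cfg or IndicatorConfig()
    tl = compute_timelines(store, quarter.end, cfg)
    out: dict = {}
    out["1"] = _as_truth(ind.dispensed_distribution(store, quarter, "gender", cfg))
    out["2"] = _as_truth(ind.dispensed_distribution(store, quarter, "age", cfg))
    out["3.residence"] = _as_truth(
        ind.dispensed_distribution(store, quarter, "ha_residence", cfg)
    )
    out["3.practice"] = _as_truth(
        ind.dispensed_distribution(store, quarter, "ha_practice", cfg)
    )
    out["4"] = _as_truth(ind.new_enrolments(store, quarter, "provider_type", cfg))
    out["5.residence"] = _as_truth(ind.new_enrolments(store, quarter, "ha_residence", cfg))
    out["5.practice"] = _as_truth(ind.new_enrolments(store, quarter, "ha_practice", cfg))
    out["6.residence"] = _as_truth(
        ind.first_dispensations(store, quarter, cfg, "ha_residence")
    )
    out["6.practice"] = _as_truth(
        ind.first_dispensations(store, quarter, cfg, "ha_practice")
    )
    a, b = ind.provider_volume(store, quarter, cfg)
    out["7a"], out["7b"] = _as_truth(a), _as_truth(b)
    a, b = ind.risk_factor_profile(store, quarter, cfg)
    out["8a"], out["8b"] = _as_truth(a), _as_truth(b)
    out["9"] = _as_truth(status_counts(store, quarter, cfg, timelines=tl))
    out["10"] = _as_truth(ind.usage_type_distribution(store, quarter, cfg, timelines=tl))
    out["11.residence"] = _as_truth(
        ind.quantity_dispensed(store, quarter, cfg, "ha_residence")
    )
    out["11.practice"] = _as_truth(
        ind.quantity_dispensed(store, quarter, cfg, "ha_practice")
    )
    cov = ind.testing_coverage(store, quarter, "syphilis", cfg, timelines=tl)
    out["12a"] = {"numerator": cov.rows[0].numerator, "denominator": cov.denominator}
    cov = ind.testing_coverage(store, quarter, "hiv", cfg, timelines=tl)
    out["13b"] = {"numerator": cov.rows[0].numerator, "denominator": cov.denominator}
    out["12b_active"] = ind.incident_cases(store, quarter, "syphilis", True, cfg, timelines=tl)
    out["12b_all"] = ind.incident_cases(store, quarter, "syphilis", False, cfg)
    ev, cl, disc = ind.adr_event_count(store, quarter, cfg)
    out["14"] = {"events": ev, "distinct_clients": cl, "discontinuation_linked": disc}
    return out


def engine_cumulative_values(store: EventStore, cfg: IndicatorConfig | None = None) -> dict:
    cfg = cfg or IndicatorConfig()
    gap = ind.days_to_first_dispensation(store, cfg)
    ev, cl, disc = ind.adr_event_count(store, None, cfg)
    d = store.dispensations_effective()
    return {
        "total_clients": int(store.clients["client_id"].nunique()),
        "ever_dispensed": int(d["client_id"].nunique()),
        "13a": gap.to_dict(),
        "14": {"events": ev, "distinct_clients": cl, "discontinuation_linked": disc},
    }


def _diff(path: str, got, want, errors: list[str], tol: float = 0.0) -> None:
    if isinstance(want, dict):
        for k in set(want) | set(got or {}):
            _diff(f"{path}.{k}", (got or {}).get(k, 0), want.get(k, 0), errors, tol)
        return
    if want is None or got is None:
        if want != got:
            errors.append(f"{path}: engine={got!r} truth={want!r}")
        return
    if isinstance(want, float) or isinstance(got, float):
        if not math.isclose(float(got), float(want), rel_tol=0, abs_tol=max(tol, 1e-9)):
            errors.append(f"{path}: engine={got} truth={want}")
        return
    if got != want:
        errors.append(f"{path}: engine={got} truth={want}")


def compare_to_truth(
    store: EventStore, truth: GroundTruth, cfg: IndicatorConfig | None = None
) -> list[str]:
    """Diff every indicator the engine computes against the scripted ground
    truth; returns a list of mismatch descriptions (empty = exact match)."""
    cfg = cfg or IndicatorConfig()
    errors: list[str] = []
    for qlabel, want in truth.quarters.items():
        got = engine_quarter_values(store, Quarter.parse(qlabel), cfg)
        for key in want:
            _diff(f"{qlabel}:{key}", got.get(key), want[key], errors)
    got = engine_cumulative_values(store, cfg)
    for key in truth.cumulative:
        _diff(f"cumulative:{key}", got.get(key), truth.cumulative[key], errors)
    return errors
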