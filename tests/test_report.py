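import json

import pandas as pd
import pytest

from prepmonitor.calendars import IndicatorConfig, Quarter
from prepmonitor.events import EventStore
from prepmonitor.report import (
    INDICATOR_TITLES,
    SUPPRESSED_TOKEN,
    build_quarterly_report,
    percent,
    suppress_small_cells,
    write_report,
)
from prepmonitor.results import StratifiedResult, StratumRow


@pytest.fixture(scope="module")
def sim_report(sim_store):
    return build_quarterly_report(sim_store, Quarter(2020, 4))


class TestPercent:
    @pytest.mark.parametrize(
        "n,d,expected",
        [(0, 10, 0), (1, 8, 13), (1, 3, 33), (2, 3, 67), (10, 10, 100)],
    )
    def test_rounds_half_away_from_zero(self, n, d, expected):
        assert percent(n, d) == expected

    def test_zero_denominator_is_absent_not_an_error(self):
        assert percent(5, 0) is None

    def test_half_even_mode(self):
        cfg = IndicatorConfig(percent_rounding="half_even")
        assert percent(1, 8, cfg) == 12  # 12.5 rounds to even
        assert percent(3, 8, cfg) == 38


class TestBuildReport:
    def test_empty_store_still_has_fourteen_blocks(self):
        store = EventStore.from_records()
        rep = build_quarterly_report(store, Quarter(2020, 4))
        assert [b.indicator_id for b in rep.blocks] == [str(i) for i in range(1, 15)]
        for r in rep.all_results():
            assert r.numerator_sum() == 0

    def test_block_titles_match_the_published_indicator_set(self, sim_report):
        assert len(sim_report.blocks) == 14
        for b in sim_report.blocks:
            assert b.title == INDICATOR_TITLES[b.indicator_id]

    def test_report_is_deterministic(self, sim_store):
        a = build_quarterly_report(sim_store, Quarter(2020, 4))
        b = build_quarterly_report(sim_store, Quarter(2020, 4))
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())

    def test_footnotes_flag_the_non_daily_convention(self, sim_report):
        assert any("non-daily" in f for f in sim_report.footnotes)


class TestSuppression:
    def _result(self, counts, partition=True):
        denom = sum(counts.values())
        return StratifiedResult(
            "9", "2020Q4",
            [StratumRow(k, v, denom, percent(v, denom)) for k, v in counts.items()],
            partition=partition,
        )

    def _wrap(self, result):
        from prepmonitor.report import IndicatorBlock, QuarterlyReport

        return QuarterlyReport(
            Quarter(2020, 4), [IndicatorBlock("9", INDICATOR_TITLES["9"], {"x": result})]
        )

    def test_counts_below_threshold_are_masked(self):
        rep = self._wrap(self._result({"a": 3, "b": 100, "c": 40}))
        out = suppress_small_cells(rep, IndicatorConfig(suppression_threshold=5))
        rows = {r.stratum: r for r in out.all_results()[0].rows}
        assert rows["a"].suppressed

    def test_complementary_suppression_in_partition(self):
        rep = self._wrap(self._result({"a": 3, "b": 100, "c": 40}))
        out = suppress_small_cells(rep, IndicatorConfig(suppression_threshold=5))
        rows = {r.stratum: r for r in out.all_results()[0].rows}
        # "a" alone would be recoverable as denominator - b - c
        assert rows["c"].suppressed and not rows["b"].suppressed

    def test_no_complementary_mask_outside_partitions(self):
        rep = self._wrap(self._result({"a": 3, "b": 100, "c": 40}, partition=False))
        out = suppress_small_cells(rep, IndicatorConfig(suppression_threshold=5))
        rows = {r.stratum: r for r in out.all_results()[0].rows}
        assert rows["a"].suppressed and not rows["b"].suppressed and not rows["c"].suppressed

    def test_threshold_zero_is_identity(self, sim_report):
        out = suppress_small_cells(sim_report, IndicatorConfig(suppression_threshold=0))
        assert json.dumps(out.to_dict()) == json.dumps(sim_report.to_dict())

    def test_suppression_never_alters_unsuppressed_counts(self, sim_report):
        out = suppress_small_cells(sim_report, IndicatorConfig())
        for before, after in zip(sim_report.all_results(), out.all_results()):
            for rb, ra in zip(before.rows, after.rows):
                if not ra.suppressed:
                    assert ra.numerator == rb.numerator
                    assert ra.percent == rb.percent
        # and the original report was left untouched
        assert not any(r.suppressed for res in sim_report.all_results() for r in res.rows)


class TestWriters:
    def test_csv_round_trip_preserves_counts(self, sim_report, tmp_path):
        p = write_report(sim_report, "csv", tmp_path / "r.csv")
        back = pd.read_csv(p)
        want = sim_report.to_frame()
        assert len(back) == len(want)
        assert (back["numerator"].fillna(-1) == want["numerator"].fillna(-1)).all()
        assert (back["denominator"] == want["denominator"]).all()

    def test_json_contains_all_blocks_and_provenance(self, sim_report, tmp_path):
        p = write_report(sim_report, "json", tmp_path / "r.json")
        d = json.loads(p.read_text())
        assert len(d["blocks"]) == 14
        assert d["provenance"]["quarter"] == "2020Q4"

    def test_markdown_has_fourteen_indicator_headings(self, sim_report, tmp_path):
        p = write_report(sim_report, "markdown", tmp_path / "r.md")
        text = p.read_text()
        for i, title in INDICATOR_TITLES.items():
            assert f"## {i}. {title}" in text

    def test_suppressed_cells_render_as_mask_token(self, tmp_path):
        r = StratifiedResult(
            "9", "2020Q4",
            [StratumRow("a", 3, 103, 3, suppressed=True), StratumRow("b", 100, 103, 97)],
            partition=True,
        )
        from prepmonitor.report import IndicatorBlock, QuarterlyReport

        rep = QuarterlyReport(Quarter(2020, 4), [IndicatorBlock("9", "t", {"x": r})])
        md = write_report(rep, "markdown", tmp_path / "r.md").read_text()
        assert f"| a | {SUPPRESSED_TOKEN} |" in md
        assert "| a | 3 |" not in md
        csv = pd.read_csv(write_report(rep, "csv", tmp_path / "r.csv"))
        assert csv.loc[csv["stratum"] == "a", "numerator"].isna().all()

    def test_unknown_format_raises(self, sim_report, tmp_path):
        with pytest.raises(ValueError):
            write_report(sim_report, "pdf", tmp_path / "r.pdf")
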