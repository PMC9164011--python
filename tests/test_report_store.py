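from __future__ import annotations

import json
import logging
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal import (DrugEntry, Report, ReportStore, filter_reports,
                      read_reports, write_reports)
from pvsignal.report_store import (AGE_BANDS, REPORTERS, SEXES,
                                   DuplicateReportError, ReportParseError,
                                   TimeToOnset, bin_age, normalize_name)

from conftest import TGA, mk_report


# ---------------------------------------------------------------- model

class TestModel:
    def test_drug_entry_role_validated(self):
        with pytest.raises(ValueError):
            DrugEntry("x", "bystander")
        with pytest.raises(ValueError):
            DrugEntry("", "suspect")

    def test_report_requires_drugs_and_reactions(self):
        with pytest.raises(ValueError, match="zero drugs"):
            Report(report_id="R", drugs=(), reactions=frozenset({"a"}))
        with pytest.raises(ValueError):
            mk_report("R", [("x", "suspect")], [])

    def test_duplicate_ids_raise(self):
        r = mk_report("R1", [("x", "suspect")], ["a"])
        with pytest.raises(DuplicateReportError):
            ReportStore([r, r])

    def test_normalize_name(self):
        assert normalize_name("  Tozinameran\t X ") == "tozinameran x"

    @pytest.mark.parametrize("age,band", [
        (0, "unknown"), (1.9, "unknown"), (2, "2-11"), (11, "2-11"),
        (12, "12-17"), (17, "12-17"), (18, "18-44"), (44, "18-44"),
        (45, "45-64"), (64, "45-64"), (65, "65-74"), (74, "65-74"),
        (75, "75+"), (101, "75+"),
    ])
    def test_bin_age_lower_bound_inclusive(self, age, band):
        assert bin_age(age) == band

    def test_time_to_onset_floor_days(self):
        r = Report(
            report_id="R",
            drugs=(DrugEntry("x", "suspect", start_date=date(2021, 6, 1)),),
            reactions=frozenset({"a"}),
            reaction_onset_date=date(2021, 6, 8),
        )
        assert r.time_to_onset() == TimeToOnset(days=7)

    def test_time_to_onset_uses_earliest_exposing_start(self):
        r = Report(
            report_id="R",
            drugs=(
                DrugEntry("c", "concomitant", start_date=date(2021, 1, 1)),
                DrugEntry("x", "suspect", start_date=date(2021, 6, 10)),
                DrugEntry("y", "interacting", start_date=date(2021, 6, 1)),
            ),
            reactions=frozenset({"a"}),
            reaction_onset_date=date(2021, 6, 11),
        )
        assert r.time_to_onset().days == 10  # concomitant start ignored

    def test_negative_onset_flagged_not_dropped(self):
        r = Report(
            report_id="R",
            drugs=(DrugEntry("x", "suspect", start_date=date(2021, 6, 10)),),
            reactions=frozenset({"a"}),
            reaction_onset_date=date(2021, 6, 1),
        )
        tto = r.time_to_onset()
        assert tto.flagged and tto.days is None

    def test_onset_absent_when_dates_missing(self):
        r = mk_report("R", [("x", "suspect")], ["a"])
        assert r.time_to_onset() is None


# ---------------------------------------------------------------- I/O

def _write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestReadWrite:
    def test_empty_file_gives_empty_store(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("")
        assert read_reports(p).n_total == 0

    def test_three_valid_records(self, tmp_path):
        recs = [
            {"report_id": f"R{i}", "drugs": [{"active_ingredient": "x",
                                              "role": "suspect"}],
             "reactions": ["a"]}
            for i in range(3)
        ]
        p = tmp_path / "r.jsonl"
        _write_lines(p, [json.dumps(r) for r in recs])
        assert read_reports(p).n_total == 3

    def test_duplicate_id_raises(self, tmp_path):
        rec = {"report_id": "R1", "drugs": [{"active_ingredient": "x",
                                             "role": "suspect"}],
               "reactions": ["a"]}
        p = tmp_path / "r.jsonl"
        _write_lines(p, [json.dumps(rec), json.dumps(rec)])
        with pytest.raises(DuplicateReportError):
            read_reports(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        rec = {"report_id": "R1", "drugs": [{"active_ingredient": "x",
                                             "role": "suspect"}],
               "reactions": ["a"]}
        p = tmp_path / "r.jsonl"
        _write_lines(p, [json.dumps(rec), "{not json"])
        with pytest.raises(ReportParseError, match="line 2"):
            read_reports(p)

    def test_invalid_enum_maps_to_unknown_with_warning(self, tmp_path, caplog):
        rec = {"report_id": "R1", "drugs": [{"active_ingredient": "x",
                                             "role": "suspect"}],
               "reactions": ["a"], "sex": "martian"}
        p = tmp_path / "r.jsonl"
        _write_lines(p, [json.dumps(rec)])
        with caplog.at_level(logging.WARNING):
            store = read_reports(p)
        assert store.reports[0].sex == "unknown"
        assert any("martian" in m for m in caplog.messages)

    def test_exact_age_binned_on_read(self, tmp_path):
        rec = {"report_id": "R1", "drugs": [{"active_ingredient": "x",
                                             "role": "suspect"}],
               "reactions": ["a"], "age_years": 67}
        p = tmp_path / "r.jsonl"
        _write_lines(p, [json.dumps(rec)])
        r = read_reports(p).reports[0]
        assert r.age_band == "65-74" and r.age_years == 67.0

    @pytest.mark.parametrize("fmt", ["jsonl", "csv"])
    def test_round_trip_identity(self, tmp_path, fmt):
        store = ReportStore([
            Report(
                report_id="R1",
                drugs=(DrugEntry("tozinameran", "suspect", date(2021, 6, 1)),
                       DrugEntry("aspirin", "concomitant")),
                reactions=frozenset({TGA, "headache"}),
                sex="female", age_band="45-64", country="france",
                reporter="physician", serious=True,
                reaction_onset_date=date(2021, 6, 8), age_years=52.0,
            ),
            mk_report("R2", [("y", "interacting")], ["naïve-térm ω"],
                      serious=False),
            mk_report("R3", [("z", "suspect")], ["b"]),
            mk_report("R4", [("z", "suspect")], ["b"], sex="male"),
            mk_report("R5", [("z", "suspect")], ["b", "c"], serious=None),
        ])
        path = tmp_path / f"store.{fmt}"
        write_reports(store, path, format=fmt)
        assert read_reports(path, format=fmt) == store

    @pytest.mark.parametrize("fmt", ["jsonl", "csv"])
    def test_empty_store_round_trips(self, tmp_path, fmt):
        path = tmp_path / f"empty.{fmt}"
        write_reports(ReportStore([]), path, format=fmt)
        assert read_reports(path, format=fmt).n_total == 0

    def test_csv_rejects_delimiter_in_name(self, tmp_path):
        store = ReportStore([mk_report("R1", [("a:b", "suspect")], ["x"])])
        with pytest.raises(ValueError, match="delimiter"):
            write_reports(store, tmp_path / "s.csv", format="csv")


# hypothesis round-trip over random small stores
_names = st.text(
    alphabet=st.characters(whitelist_categories=("Ll",), max_codepoint=0x24F),
    min_size=1, max_size=8).map(lambda s: " ".join(s.split()) or "x")
_reports = st.builds(
    Report,
    report_id=st.uuids().map(str),
    drugs=st.lists(
        st.builds(DrugEntry, active_ingredient=_names,
                  role=st.sampled_from(("suspect", "interacting",
                                        "concomitant")),
                  start_date=st.none() | st.dates(date(1990, 1, 1),
                                                  date(2021, 12, 6))),
        min_size=1, max_size=3).map(tuple),
    reactions=st.frozensets(_names, min_size=1, max_size=3),
    sex=st.sampled_from(SEXES),
    age_band=st.sampled_from(AGE_BANDS),
    country=_names,
    reporter=st.sampled_from(REPORTERS),
    serious=st.none() | st.booleans(),
    reaction_onset_date=st.none() | st.dates(date(1990, 1, 1),
                                             date(2021, 12, 6)),
    age_years=st.none() | st.floats(0, 110, allow_nan=False).map(
        lambda v: round(v, 2)),
)


@settings(max_examples=30, deadline=None)
@given(reports=st.lists(_reports, max_size=6,
                        unique_by=lambda r: r.report_id),
       fmt=st.sampled_from(["jsonl", "csv"]))
def test_round_trip_property(tmp_path_factory, reports, fmt):
    store = ReportStore(reports)
    path = tmp_path_factory.mktemp("rt") / f"s.{fmt}"
    write_reports(store, path, format=fmt)
    assert read_reports(path, format=fmt) == store


# ---------------------------------------------------------------- filtering

class TestFilter:
    def test_sex_stratum(self, toy_store):
        out = filter_reports(toy_store, {"sex": "female"})
        assert out.n_total == 3
        assert toy_store.n_total == 6  # original untouched

    def test_empty_stratum(self, toy_store):
        assert filter_reports(toy_store, {"reporter": "pharmacist"}).n_total == 0

    def test_unknown_field_raises(self, toy_store):
        with pytest.raises(KeyError):
            filter_reports(toy_store, {"species": "human"})
        with pytest.raises(KeyError):
            filter_reports(toy_store, {"sex": "other"})

    def test_composition_equals_conjunction(self, toy_store):
        # brute-force oracle: set intersection over the toy store
        expected = {r.report_id for r in toy_store
                    if r.sex == "female" and r.age_band == "45-64"}
        composed = filter_reports(filter_reports(toy_store, {"sex": "female"}),
                                  {"age_band": "45-64"})
        conjoined = filter_reports(toy_store,
                                   {"sex": "female", "age_band": "45-64"})
        assert {r.report_id for r in composed} == expected
        assert {r.report_id for r in conjoined} == expected

    @pytest.mark.parametrize("field,levels", [
        ("sex", SEXES), ("age_band", AGE_BANDS), ("reporter", REPORTERS),
        ("serious", ("true", "false", "unknown")),
    ])
    def test_levels_partition_store(self, toy_store, field, levels):
        total = sum(filter_reports(toy_store, {field: lvl}).n_total
                    for lvl in levels)
        assert total == toy_store.n_total

    def test_filter_never_increases(self, toy_store):
        for lvl in SEXES:
            assert filter_reports(toy_store, {"sex": lvl}).n_total <= 6
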