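"""Data model and I/O for individual case safety reports.

A :class:`Report` is one spontaneous adverse-event report: the drugs it
mentions (with their reporter-assigned role), the reaction preferred terms
(PTs, treated as opaque labels), demographics, reporter qualification,
seriousness and onset dates.  A :class:`ReportStore` is an immutable
collection of reports with unique ids; its size is the ``N`` of every
2x2 table built downstream.

Two line-oriented text serializations are supported: JSON-Lines (one
object per report) and CSV (drugs and reactions packed into pipe-delimited
subfields).  Both round-trip exactly.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

ROLES = ("suspect", "interacting", "concomitant")
SEXES = ("female", "male", "unknown")
AGE_BANDS = ("2-11", "12-17", "18-44", "45-64", "65-74", "75+", "unknown")
REPORTERS = (
    "physician",
    "pharmacist",
    "other_health_professional",
    "consumer",
    "lawyer",
    "unknown",
)

#: lower bound (inclusive) of each age band, in years
_AGE_BAND_EDGES = ((2, "2-11"), (12, "12-17"), (18, "18-44"),
                   (45, "45-64"), (65, "65-74"), (75, "75+"))

# accepted spellings for age bands (dashes, unicode >= sign)
_AGE_BAND_ALIASES = {
    "2-11": "2-11", "2–11": "2-11",
    "12-17": "12-17", "12–17": "12-17",
    "18-44": "18-44", "18–44": "18-44",
    "45-64": "45-64", "45–64": "45-64",
    "65-74": "65-74", "65–74": "65-74",
    "75+": "75+", ">=75": "75+", "≥75": "75+",
    "unknown": "unknown",
}

_WS = re.compile(r"\s+")


class ReportParseError(ValueError):
    """A record could not be parsed; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class DuplicateReportError(ValueError):
    """Two records share a report_id."""


def normalize_name(name: str) -> str:
    """Trim, lowercase and collapse internal whitespace.

    No spelling reconciliation is attempted; distinct spellings stay
    distinct ingredients/terms.
    """
    return _WS.sub(" ", name.strip().lower())


def bin_age(age_years: float) -> str:
    """Map an exact age in years onto the closed band list.

    Band edges are inclusive of their lower bound; ages below the first
    band (``< 2``) map to ``unknown``.
    """
    band = "unknown"
    for lower, label in _AGE_BAND_EDGES:
        if age_years >= lower:
            band = label
    return band


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report: normalized ingredient, role, start date."""

    active_ingredient: str
    role: str
    start_date: date | None = None

    def __post_init__(self) -> None:
        if not self.active_ingredient:
            raise ValueError("active_ingredient must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class TimeToOnset:
    """Reaction onset minus earliest suspect/interacting drug start, in days.

    ``days`` is the floor of the date difference and is never negative:
    records with onset before drug start are kept but flagged
    (``days is None`` and ``flagged`` is True) rather than silently dropped.
    """

    days: int | None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.days is not None and self.days < 0:
            raise ValueError("days must be non-negative; use flagged=True")


@dataclass(frozen=True)
class Report:
    """One individual case safety report."""

    report_id: str
    drugs: tuple[DrugEntry, ...]
    reactions: frozenset[str]
    sex: str = "unknown"
    age_band: str = "unknown"
    country: str = "unknown"
    reporter: str = "unknown"
    serious: bool | None = None
    reaction_onset_date: date | None = None
    #: exact age in years when the source recorded one; only descriptives
    #: use it (the band is the analytic granularity)
    age_years: float | None = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if len(self.drugs) < 1:
            raise ValueError(
                f"report {self.report_id}: a case/non-case design is "
                "undefined for reports with zero drugs"
            )
        if len(self.reactions) < 1:
            raise ValueError(f"report {self.report_id}: reactions must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"invalid age_band {self.age_band!r}")
        if self.reporter not in REPORTERS:
            raise ValueError(f"invalid reporter {self.reporter!r}")

    def time_to_onset(self) -> TimeToOnset | None:
        """Days from earliest suspect/interacting start to reaction onset.

        Returns None when either date is absent.
        """
        if self.reaction_onset_date is None:
            return None
        starts = [
            d.start_date
            for d in self.drugs
            if d.role in ("suspect", "interacting") and d.start_date is not None
        ]
        if not starts:
            return None
        diff = (self.reaction_onset_date - min(starts)).days
        if diff < 0:
            return TimeToOnset(days=None, flagged=True)
        return TimeToOnset(days=diff)


class ReportStore:
    """An immutable collection of reports with distinct ids."""

    def __init__(self, reports: Iterable[Report]):
        self._reports = tuple(reports)
        seen: set[str] = set()
        for r in self._reports:
            if r.report_id in seen:
                raise DuplicateReportError(f"duplicate report_id {r.report_id!r}")
            seen.add(r.report_id)

    @property
    def reports(self) -> tuple[Report, ...]:
        return self._reports

    @property
    def n_total(self) -> int:
        return len(self._reports)

    def __len__(self) -> int:
        return len(self._reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self._reports)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportStore):
            return NotImplemented
        return self._reports == other._reports

    def __repr__(self) -> str:
        return f"ReportStore(n_total={self.n_total})"


# --------------------------------------------------------------------------
# stratum filtering

_STRATUM_FIELDS = {
    "sex": SEXES,
    "age_band": AGE_BANDS,
    "reporter": REPORTERS,
    "country": None,  # open vocabulary
    "serious": ("true", "false", "unknown"),
}


def _serious_level(serious: bool | None) -> str:
    if serious is None:
        return "unknown"
    return "true" if serious else "false"


def filter_reports(store: ReportStore, stratum: Mapping[str, str]) -> ReportStore:
    """Return the sub-store of reports matching every (field, level) pair.

    Supported fields: sex, age_band, reporter, country, serious (levels
    "true"/"false"/"unknown").  Filtering on an "unknown" level is
    supported, so the levels of a field partition the store.
    """
    for name, level in stratum.items():
        if name not in _STRATUM_FIELDS:
            raise KeyError(f"unknown stratum field {name!r}")
        allowed = _STRATUM_FIELDS[name]
        if allowed is not None and level not in allowed:
            raise KeyError(f"unknown level {level!r} for stratum field {name!r}")

    def matches(r: Report) -> bool:
        for name, level in stratum.items():
            if name == "serious":
                if _serious_level(r.serious) != level:
                    return False
            elif getattr(r, name) != level:
                return False
        return True

    return ReportStore(r for r in store if matches(r))


# --------------------------------------------------------------------------
# parsing helpers

def _lenient_enum(value: str | None, allowed: Sequence[str], field_name: str,
                  line_no: int) -> str:
    if value is None or value == "":
        return "unknown"
    value = str(value).strip().lower()
    if field_name == "age_band":
        value = _AGE_BAND_ALIASES.get(value, value)
    if value not in allowed:
        logger.warning("line %d: invalid %s %r mapped to 'unknown'",
                       line_no, field_name, value)
        return "unknown"
    return value


def _parse_serious(value, line_no: int) -> bool | None:
    if value is None or value == "" or str(value).strip().lower() == "unknown":
        return None
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    logger.warning("line %d: invalid serious %r mapped to unknown", line_no, value)
    return None


def _parse_date(value, line_no: int, field_name: str) -> date | None:
    if value is None or value == "":
        return None
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ReportParseError(line_no, f"bad {field_name} {value!r}: {exc}") from exc


def _report_from_record(rec: Mapping, line_no: int) -> Report:
    try:
        report_id = str(rec["report_id"])
        raw_drugs = rec["drugs"]
        raw_reactions = rec["reactions"]
    except KeyError as exc:
        raise ReportParseError(line_no, f"missing key {exc}") from exc
    drugs = []
    for rd in raw_drugs:
        role = str(rd.get("role", "")).strip().lower()
        if role not in ROLES:
            raise ReportParseError(line_no, f"invalid drug role {role!r}")
        try:
            drugs.append(DrugEntry(
                active_ingredient=normalize_name(str(rd["active_ingredient"])),
                role=role,
                start_date=_parse_date(rd.get("start_date"), line_no, "start_date"),
            ))
        except (ValueError, KeyError) as exc:
            if isinstance(exc, ReportParseError):
                raise
            raise ReportParseError(line_no, str(exc)) from exc
    age_years = rec.get("age_years")
    age_band = rec.get("age_band")
    if age_band in (None, "") and age_years is not None:
        age_band = bin_age(float(age_years))
    try:
        return Report(
            report_id=report_id,
            drugs=tuple(drugs),
            reactions=frozenset(normalize_name(str(t)) for t in raw_reactions),
            sex=_lenient_enum(rec.get("sex"), SEXES, "sex", line_no),
            age_band=_lenient_enum(age_band, AGE_BANDS, "age_band", line_no),
            country=normalize_name(str(rec.get("country") or "unknown")),
            reporter=_lenient_enum(rec.get("reporter"), REPORTERS, "reporter", line_no),
            serious=_parse_serious(rec.get("serious"), line_no),
            reaction_onset_date=_parse_date(rec.get("reaction_onset_date"),
                                            line_no, "reaction_onset_date"),
            age_years=float(age_years) if age_years not in (None, "") else None,
        )
    except ValueError as exc:
        raise ReportParseError(line_no, str(exc)) from exc


# --------------------------------------------------------------------------
# JSON-Lines

def _record_from_report(r: Report) -> dict:
    rec = {
        "report_id": r.report_id,
        "drugs": [
            {
                "active_ingredient": d.active_ingredient,
                "role": d.role,
                "start_date": d.start_date.isoformat() if d.start_date else None,
            }
            for d in r.drugs
        ],
        "reactions": sorted(r.reactions),
        "sex": r.sex,
        "age_band": r.age_band,
        "country": r.country,
        "reporter": r.reporter,
        "serious": r.serious,
        "reaction_onset_date": (r.reaction_onset_date.isoformat()
                                if r.reaction_onset_date else None),
    }
    if r.age_years is not None:
        rec["age_years"] = r.age_years
    return rec


_CSV_FIELDS = ["report_id", "drugs", "reactions", "sex", "age_band", "country",
               "reporter", "serious", "reaction_onset_date", "age_years"]


def _csv_row(r: Report) -> dict:
    for d in r.drugs:
        if ":" in d.active_ingredient or "|" in d.active_ingredient:
            raise ValueError(
                f"ingredient {d.active_ingredient!r} contains a CSV subfield "
                "delimiter; use the jsonl format"
            )
    for t in r.reactions:
        if "|" in t:
            raise ValueError(f"reaction {t!r} contains '|'; use the jsonl format")
    drugs = "|".join(
        f"{d.active_ingredient}:{d.role}"
        + (f":{d.start_date.isoformat()}" if d.start_date else "")
        for d in r.drugs
    )
    return {
        "report_id": r.report_id,
        "drugs": drugs,
        "reactions": "|".join(sorted(r.reactions)),
        "sex": r.sex,
        "age_band": r.age_band,
        "country": r.country,
        "reporter": r.reporter,
        "serious": "" if r.serious is None else str(r.serious).lower(),
        "reaction_onset_date": (r.reaction_onset_date.isoformat()
                                if r.reaction_onset_date else ""),
        "age_years": "" if r.age_years is None else repr(r.age_years),
    }


def _record_from_csv_row(row: Mapping[str, str], line_no: int) -> dict:
    drugs = []
    for part in (row.get("drugs") or "").split("|"):
        if not part:
            continue
        bits = part.split(":")
        if len(bits) == 2:
            name, role = bits
            start = None
        elif len(bits) == 3:
            name, role, start = bits
        else:
            raise ReportParseError(line_no, f"bad drug subfield {part!r}")
        drugs.append({"active_ingredient": name, "role": role, "start_date": start})
    reactions = [t for t in (row.get("reactions") or "").split("|") if t]
    return {
        "report_id": row.get("report_id"),
        "drugs": drugs,
        "reactions": reactions,
        "sex": row.get("sex"),
        "age_band": row.get("age_band"),
        "country": row.get("country"),
        "reporter": row.get("reporter"),
        "serious": row.get("serious"),
        "reaction_onset_date": row.get("reaction_onset_date"),
        "age_years": row.get("age_years") or None,
    }


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"format must be 'jsonl' or 'csv', got {fmt!r}")
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_reports(path: str | Path, format: str | None = None) -> ReportStore:
    """Read a report collection from a JSONL or CSV file.

    Invalid closed-vocabulary values (sex, age band, reporter) are mapped
    to "unknown" with a logged warning; structurally malformed records
    raise :class:`ReportParseError` naming the line; duplicate report ids
    raise :class:`DuplicateReportError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    reports: list[Report] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ReportParseError(line_no, f"bad JSON: {exc}") from exc
                reports.append(_report_from_record(rec, line_no))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for line_no, row in enumerate(reader, start=2):
                reports.append(
                    _report_from_record(_record_from_csv_row(row, line_no), line_no))
    return ReportStore(reports)


def write_reports(store: ReportStore, path: str | Path,
                  format: str | None = None) -> Path:
    """Write a store to JSONL or CSV; round-trips exactly through read_reports."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in store:
                fh.write(json.dumps(_record_from_report(r), ensure_ascii=False))
                fh.write("\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            for r in store:
                writer.writerow(_csv_row(r))
    return path
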