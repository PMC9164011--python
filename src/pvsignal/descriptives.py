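"""Descriptive characterization of case reports.

Produces a two-column characteristics table (all cases vs cases exposed to
a chosen drug group): counts and percentages per level of sex, age band,
country, reporter and seriousness; medians with IQR for exact age (when
recorded) and time to onset; and co-reported preferred-term frequencies.

Percentages use half-away-from-zero rounding to one decimal; quartiles use
linear interpolation between order statistics, so fractional bounds such
as 63.75 can arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import pct
from .contingency import DEFAULT_ROLES, DrugGroup, is_case, is_exposed
from .report_store import (AGE_BANDS, REPORTERS, SEXES, Report, ReportStore,
                           _serious_level)

_SERIOUS_LEVELS = ("true", "false", "unknown")


@dataclass(frozen=True)
class MedianIQR:
    median: float
    q1: float
    q3: float
    n: int
    n_missing: int = 0


@dataclass(frozen=True)
class CharacteristicsTable:
    """Counts/percentages per variable level, for all cases and group cases."""

    n_cases: int
    n_group_cases: int
    #: variable -> level -> (count, percent) over all cases
    all_cases: Mapping[str, Mapping[str, tuple[int, float]]]
    #: same layout, restricted to group-exposed cases
    group_cases: Mapping[str, Mapping[str, tuple[int, float]]]
    age_all: MedianIQR | None
    age_group: MedianIQR | None
    onset_days_all: MedianIQR | None
    onset_days_group: MedianIQR | None
    n_onset_flagged: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for variable, levels in self.all_cases.items():
            for level, (count, share) in levels.items():
                g_count, g_share = self.group_cases[variable].get(level, (0, 0.0))
                rows.append({
                    "variable": variable, "level": level,
                    "count_all": count, "pct_all": share,
                    "count_group": g_count, "pct_group": g_share,
                })
        return pd.DataFrame(rows, columns=["variable", "level", "count_all",
                                           "pct_all", "count_group", "pct_group"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def median_iqr(values: Iterable[float | None]) -> MedianIQR | None:
    """Median and quartiles by linear interpolation; absents excluded.

    Returns None when no values remain after excluding absents (the
    "not estimable" marker).
    """
    raw = list(values)
    kept = [float(v) for v in raw if v is not None and not np.isnan(float(v))]
    if not kept:
        return None
    arr = np.asarray(kept, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return MedianIQR(median=float(med), q1=float(q1), q3=float(q3),
                     n=len(kept), n_missing=len(raw) - len(kept))


def _level_counts(reports: Sequence[Report]) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {
        "sex": {lvl: 0 for lvl in SEXES},
        "age_band": {lvl: 0 for lvl in AGE_BANDS},
        "country": {},
        "reporter": {lvl: 0 for lvl in REPORTERS},
        "serious": {lvl: 0 for lvl in _SERIOUS_LEVELS},
    }
    for r in reports:
        counts["sex"][r.sex] += 1
        counts["age_band"][r.age_band] += 1
        counts["country"][r.country] = counts["country"].get(r.country, 0) + 1
        counts["reporter"][r.reporter] += 1
        counts["serious"][_serious_level(r.serious)] += 1
    # countries ordered by count desc then name, like the published layout
    counts["country"] = dict(sorted(counts["country"].items(),
                                    key=lambda kv: (-kv[1], kv[0])))
    return counts


def _with_pcts(counts: Mapping[str, Mapping[str, int]],
               total: int) -> dict[str, dict[str, tuple[int, float]]]:
    out: dict[str, dict[str, tuple[int, float]]] = {}
    for variable, levels in counts.items():
        out[variable] = {
            level: (n, pct(n, total) if total else 0.0)
            for level, n in levels.items()
        }
    return out


def _onset_days(reports: Sequence[Report]) -> tuple[list[float | None], int]:
    days: list[float | None] = []
    flagged = 0
    for r in reports:
        tto = r.time_to_onset()
        if tto is None:
            days.append(None)
        elif tto.flagged:
            flagged += 1
            days.append(None)
        else:
            days.append(float(tto.days))
    return days, flagged


def characteristics(store: ReportStore, target_pt: str,
                    group: DrugGroup,
                    roles: frozenset[str] = DEFAULT_ROLES) -> CharacteristicsTable:
    """Two-column descriptive table over the cases of a store.

    Both columns are computed over cases only; the second column is
    restricted to cases exposed to ``group``.
    """
    if store.n_total == 0:
        raise ValueError("cannot describe an empty store")
    cases = [r for r in store if is_case(r, target_pt)]
    group_cases = [r for r in cases if is_exposed(r, group, roles)]

    all_counts = _level_counts(cases)
    grp_counts = _level_counts(group_cases)
    onset_all, flagged_all = _onset_days(cases)
    onset_grp, flagged_grp = _onset_days(group_cases)

    return CharacteristicsTable(
        n_cases=len(cases),
        n_group_cases=len(group_cases),
        all_cases=_with_pcts(all_counts, len(cases)),
        group_cases=_with_pcts(grp_counts, len(group_cases)),
        age_all=median_iqr(r.age_years for r in cases),
        age_group=median_iqr(r.age_years for r in group_cases),
        onset_days_all=median_iqr(onset_all),
        onset_days_group=median_iqr(onset_grp),
        n_onset_flagged=flagged_all,
    )


def co_reported_terms(store: ReportStore, target_pt: str, group: DrugGroup,
                      roles: frozenset[str] = DEFAULT_ROLES
                      ) -> list[tuple[str, int, float]]:
    """Frequency of each non-target PT among group-exposed cases.

    Returns (term, count, percent-of-group-cases) sorted by count
    descending, ties alphabetically.
    """
    if store.n_total == 0:
        raise ValueError("cannot describe an empty store")
    from .report_store import normalize_name
    target = normalize_name(target_pt)
    group_cases = [r for r in store
                   if is_case(r, target_pt) and is_exposed(r, group, roles)]
    counts: dict[str, int] = {}
    for r in group_cases:
        for term in r.reactions:
            if term != target:
                counts[term] = counts.get(term, 0) + 1
    total = len(group_cases)
    out = [(term, n, pct(n, total)) for term, n in counts.items()]
    out.sort(key=lambda item: (-item[1], item[0]))
    return out
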