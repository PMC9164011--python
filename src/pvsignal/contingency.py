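"""Case definition, exposure, eligibility and 2x2 table construction.

Cases are reports whose reaction set contains the target preferred term
(exact match after normalization — no substring or hierarchy matching).
Exposure is report-level: a report is exposed to a drug group when any of
its drug entries names a group member with an exposing role (by default
suspect or interacting; concomitant-only mentions do not expose).

Counting is report-level: each report lands in exactly one cell of each
table, so a + b + c + d always equals the store size N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .report_store import ROLES, Report, ReportStore, normalize_name

#: roles that confer exposure unless overridden
DEFAULT_ROLES = frozenset({"suspect", "interacting"})


@dataclass(frozen=True)
class DrugGroup:
    """A named set of active ingredients analysed jointly."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("DrugGroup.members must be non-empty")
        object.__setattr__(self, "members",
                           frozenset(normalize_name(m) for m in self.members))

    @classmethod
    def single(cls, ingredient: str) -> "DrugGroup":
        """A singleton group, equivalent to its lone ingredient."""
        return cls(name=normalize_name(ingredient),
                   members=frozenset({ingredient}))


#: the built-in COVID-19 vaccine group (four members plus "unspecified")
COVID19_VACCINE_GROUP = DrugGroup(
    name="covid-19 vaccine",
    members=frozenset({
        "tozinameran",
        "elasomeran",
        "azd1222",
        "jnj-78436735",
        "covid-19 vaccine unspecified",
    }),
)


def load_drug_groups(path: str | Path) -> list[DrugGroup]:
    """Load group definitions from a YAML mapping of name -> member list."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("drug-group config must be a mapping name -> members")
    groups = []
    for name, members in raw.items():
        if isinstance(members, str):
            members = [members]
        groups.append(DrugGroup(name=str(name), members=frozenset(members)))
    return groups


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case/non-case x exposed/unexposed counts.

    a: exposed cases, b: exposed non-cases, c: unexposed cases,
    d: unexposed non-cases.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_exposed(self) -> int:
        return self.a + self.b


def is_case(report: Report, target_pt: str) -> bool:
    """True iff the normalized target PT is one of the report's reactions."""
    if not target_pt:
        raise ValueError("target_pt must be non-empty")
    return normalize_name(target_pt) in report.reactions


def is_exposed(report: Report, group: DrugGroup,
               roles: frozenset[str] = DEFAULT_ROLES) -> bool:
    """True iff some drug entry names a group member with an exposing role."""
    if not roles <= set(ROLES):
        raise ValueError(f"roles must be a subset of {ROLES}")
    return any(d.role in roles and d.active_ingredient in group.members
               for d in report.drugs)


def build_table(store: ReportStore, target_pt: str, group: DrugGroup,
                roles: frozenset[str] = DEFAULT_ROLES) -> ContingencyTable:
    """Build the report-level 2x2 table for one drug(-group)/event pair."""
    if store.n_total == 0:
        raise ValueError("cannot build a contingency table from an empty store")
    a = b = c = d = 0
    for r in store:
        case = is_case(r, target_pt)
        exposed = is_exposed(r, group, roles)
        if exposed:
            if case:
                a += 1
            else:
                b += 1
        elif case:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def eligible_drugs(store: ReportStore, target_pt: str, min_cases: int = 4,
                   roles: frozenset[str] = DEFAULT_ROLES) -> list[tuple[str, int]]:
    """Ingredients suspect/interacting in at least ``min_cases`` case reports.

    Returns (ingredient, case-count) pairs sorted by case count descending,
    ties broken alphabetically.  Concomitant-only mentions never count.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    counts: dict[str, int] = {}
    for r in store:
        if not is_case(r, target_pt):
            continue
        seen = {d.active_ingredient for d in r.drugs if d.role in roles}
        for name in seen:
            counts[name] = counts.get(name, 0) + 1
    out = [(name, n) for name, n in counts.items() if n >= min_cases]
    out.sort(key=lambda item: (-item[1], item[0]))
    return out


# --------------------------------------------------------------------------
# vectorized helpers used by pair screening and simulation experiments

def exposure_matrix(store: ReportStore,
                    roles: frozenset[str] = DEFAULT_ROLES,
                    drugs: Sequence[str] | None = None
                    ) -> tuple[np.ndarray, list[str]]:
    """Boolean reports x drugs exposure indicator.

    When ``drugs`` is None the columns are all ingredients seen with an
    exposing role, sorted alphabetically.
    """
    if drugs is None:
        names = sorted({d.active_ingredient for r in store for d in r.drugs
                        if d.role in roles})
    else:
        names = [normalize_name(d) for d in drugs]
    col = {name: j for j, name in enumerate(names)}
    mat = np.zeros((store.n_total, len(names)), dtype=bool)
    for i, r in enumerate(store):
        for d in r.drugs:
            if d.role in roles:
                j = col.get(d.active_ingredient)
                if j is not None:
                    mat[i, j] = True
    return mat, names


def reaction_matrix(store: ReportStore,
                    events: Sequence[str] | None = None
                    ) -> tuple[np.ndarray, list[str]]:
    """Boolean reports x reactions indicator (all PTs, sorted, by default)."""
    if events is None:
        names = sorted({t for r in store for t in r.reactions})
    else:
        names = [normalize_name(e) for e in events]
    col = {name: j for j, name in enumerate(names)}
    mat = np.zeros((store.n_total, len(names)), dtype=bool)
    for i, r in enumerate(store):
        for t in r.reactions:
            j = col.get(t)
            if j is not None:
                mat[i, j] = True
    return mat, names
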