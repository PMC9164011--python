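"""Orchestration of the full disproportionality analysis.

``run_disproportionality`` produces the ranked signal table: one row per
eligible ingredient and per configured drug group, with member rows nested
under their group.  ``run_subgroup`` re-runs the analysis for one group
inside a demographic stratum (N, margins and E all recomputed within the
stratum), and ``run_sensitivity_physician`` is the reporter=physician
sensitivity analysis.  ``screen_pairs`` is a vectorized drug x event
screen used by simulation experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import pct
from .contingency import (COVID19_VACCINE_GROUP, DEFAULT_ROLES,
                          ContingencyTable, DrugGroup, build_table,
                          eligible_drugs, exposure_matrix, is_case,
                          reaction_matrix)
from .disprop_stats import (DisproportionalityResult, _ic_arrays,
                            _ror_ci_arrays, _zcrit, evaluate_table,
                            not_estimable)
from .report_store import ReportStore, filter_reports

RANKINGS = ("by_ror", "by_cases")

#: the default subgroup grid: sex and age strata (mirrors the published
#: subgroup analyses), estimable levels only are reported as rows
DEFAULT_STRATA: tuple[Mapping[str, str], ...] = (
    {"sex": "female"},
    {"sex": "male"},
    {"age_band": "18-44"},
    {"age_band": "45-64"},
    {"age_band": "65-74"},
    {"age_band": "75+"},
)


@dataclass(frozen=True)
class AnalysisConfig:
    """All parameters of one analysis run."""

    target_pt: str
    min_cases: int = 4
    roles: frozenset[str] = DEFAULT_ROLES
    groups: tuple[DrugGroup, ...] = (COVID19_VACCINE_GROUP,)
    strata: tuple[Mapping[str, str], ...] = DEFAULT_STRATA
    ranking: str = "by_ror"
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not self.target_pt:
            raise ValueError("target_pt must be non-empty")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.ranking not in RANKINGS:
            raise ValueError(f"ranking must be one of {RANKINGS}")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        groups = tuple(
            DrugGroup(name=str(name), members=frozenset(members))
            for name, members in (raw.get("groups") or {}).items()
        ) or (COVID19_VACCINE_GROUP,)
        strata = tuple(dict(s) for s in raw.get("strata", DEFAULT_STRATA))
        return cls(
            target_pt=raw["target_pt"],
            min_cases=int(raw.get("min_cases", 4)),
            roles=frozenset(raw.get("roles", DEFAULT_ROLES)),
            groups=groups,
            strata=strata,
            ranking=raw.get("ranking", "by_ror"),
            confidence=float(raw.get("confidence", 0.95)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            raw = (json.load(fh) if path.suffix.lower() == ".json"
                   else yaml.safe_load(fh))
        return cls.from_dict(raw)


@dataclass(frozen=True)
class SignalRow:
    """One signal-table row; member rows carry their parent group's name."""

    result: DisproportionalityResult
    parent_group: str | None = None
    #: percent of all cases exposed to this row's drug(-group)
    share_of_cases_pct: float = 0.0
    #: for member rows: percent of the parent group's cases
    share_of_group_pct: float | None = None

    @property
    def label(self) -> str:
        return self.result.label


@dataclass(frozen=True)
class SignalTable:
    rows: tuple[SignalRow, ...]
    n_cases_total: int
    n_total: int

    def row(self, label: str) -> SignalRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            res = row.result
            recs.append({
                "label": res.label,
                "parent_group": row.parent_group or "",
                "n_cases": res.n_cases,
                "pct_of_cases": row.share_of_cases_pct,
                "pct_of_group": ("" if row.share_of_group_pct is None
                                 else row.share_of_group_pct),
                "ror": res.ror, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "ic": res.ic, "ic025": res.ic025,
                "signal": res.signal, "ror_signal": res.ror_signal,
                "corrected": res.corrected,
            })
        cols = ["label", "parent_group", "n_cases", "pct_of_cases",
                "pct_of_group", "ror", "ci_low", "ci_high", "ic", "ic025",
                "signal", "ror_signal", "corrected"]
        return pd.DataFrame(recs, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _rank_key(ranking: str):
    if ranking == "by_ror":
        return lambda row: (-row.result.ror, -row.result.n_cases, row.label)
    return lambda row: (-row.result.n_cases, -row.result.ror, row.label)


def run_disproportionality(store: ReportStore,
                           config: AnalysisConfig) -> SignalTable:
    """The ranked signal table (groups + eligible single ingredients).

    Ingredients belonging to a configured group appear only as member rows
    nested under that group, mirroring the published table layout.  Both
    member rows and top-level rows obey the ``min_cases`` eligibility
    threshold.  An absence of eligible drugs yields an empty table.
    """
    if store.n_total == 0:
        raise ValueError("cannot analyse an empty store")
    n_cases_total = sum(1 for r in store if is_case(r, config.target_pt))
    grouped_members = {m for g in config.groups for m in g.members}

    key = _rank_key(config.ranking)
    top_rows: list[SignalRow] = []
    members_of: dict[str, list[SignalRow]] = {}

    for group in config.groups:
        table = build_table(store, config.target_pt, group, config.roles)
        if table.a < config.min_cases:
            continue
        res = evaluate_table(table, group.name, config.confidence)
        top_rows.append(SignalRow(
            result=res,
            share_of_cases_pct=pct(table.a, n_cases_total),
        ))
        member_rows = []
        for member in sorted(group.members):
            mtable = build_table(store, config.target_pt,
                                 DrugGroup.single(member), config.roles)
            if mtable.a < config.min_cases:
                continue
            mres = evaluate_table(mtable, member, config.confidence)
            member_rows.append(SignalRow(
                result=mres,
                parent_group=group.name,
                share_of_cases_pct=pct(mtable.a, n_cases_total),
                share_of_group_pct=pct(mtable.a, table.a),
            ))
        members_of[group.name] = sorted(member_rows, key=key)

    for name, n_cases in eligible_drugs(store, config.target_pt,
                                        config.min_cases, config.roles):
        if name in grouped_members:
            continue
        table = build_table(store, config.target_pt, DrugGroup.single(name),
                            config.roles)
        res = evaluate_table(table, name, config.confidence)
        top_rows.append(SignalRow(
            result=res,
            share_of_cases_pct=pct(table.a, n_cases_total),
        ))

    top_rows.sort(key=key)
    ordered: list[SignalRow] = []
    for row in top_rows:
        ordered.append(row)
        ordered.extend(members_of.get(row.label, ()))
    return SignalTable(rows=tuple(ordered), n_cases_total=n_cases_total,
                       n_total=store.n_total)


def run_subgroup(store: ReportStore, config: AnalysisConfig,
                 stratum: Mapping[str, str],
                 group: DrugGroup | None = None) -> DisproportionalityResult:
    """Disproportionality for one group within a demographic stratum.

    Identical to running the analysis on the filtered store: N, margins
    and the expected count are all recomputed within the stratum.  Empty
    strata and strata without exposure or without both cases and
    non-cases yield a structured not-estimable result.
    """
    group = group or config.groups[0]
    sub = filter_reports(store, stratum)
    if sub.n_total == 0:
        return not_estimable(group.name)
    table = build_table(sub, config.target_pt, group, config.roles)
    if table.a + table.b == 0 or table.c + table.d == 0:
        return not_estimable(group.name, n_cases=table.a)
    return evaluate_table(table, group.name, config.confidence)


def run_sensitivity_physician(store: ReportStore, config: AnalysisConfig,
                              group: DrugGroup | None = None
                              ) -> DisproportionalityResult:
    """The physician-reported-only sensitivity analysis."""
    return run_subgroup(store, config, {"reporter": "physician"}, group)


def subgroup_table(store: ReportStore, config: AnalysisConfig,
                   group: DrugGroup | None = None) -> pd.DataFrame:
    """All configured strata as one tidy frame (one row per stratum)."""
    group = group or config.groups[0]
    recs = []
    for stratum in config.strata:
        res = run_subgroup(store, config, stratum, group)
        recs.append({
            "stratum": ";".join(f"{k}={v}" for k, v in stratum.items()),
            "label": res.label,
            "n_cases": res.n_cases,
            "ror": res.ror, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "ic": res.ic, "ic025": res.ic025,
            "signal": res.signal, "estimable": res.estimable,
        })
    cols = ["stratum", "label", "n_cases", "ror", "ci_low", "ci_high",
            "ic", "ic025", "signal", "estimable"]
    return pd.DataFrame(recs, columns=cols)


# --------------------------------------------------------------------------
# vectorized pair screening (simulation experiments, null calibration)

def screen_pairs(store: ReportStore,
                 roles: frozenset[str] = DEFAULT_ROLES,
                 min_cases: int = 4,
                 confidence: float = 0.95,
                 drugs: Sequence[str] | None = None,
                 events: Sequence[str] | None = None) -> pd.DataFrame:
    """Report-level 2x2 screen of every drug x event pair.

    Returns one row per pair with a >= ``min_cases``, columns: drug,
    event, a, b, c, d, ror, ci_low, ci_high, ic, ic025, signal,
    ror_covers_one.  Pairs where the ROR is undefined (a+b or c+d zero)
    are dropped.
    """
    dmat, dnames = exposure_matrix(store, roles, drugs)
    emat, enames = reaction_matrix(store, events)
    n = store.n_total
    # float32 matmul hits BLAS; counts stay exact below 2**24
    a = np.rint(dmat.astype(np.float32).T @ emat.astype(np.float32)
                ).astype(np.int64)                               # drugs x events
    drug_tot = dmat.sum(axis=0).astype(np.int64)[:, None]
    event_tot = emat.sum(axis=0).astype(np.int64)[None, :]
    b = drug_tot - a
    c = event_tot - a
    d = n - drug_tot - event_tot + a

    keep = (a >= min_cases) & ((a + b) > 0) & ((c + d) > 0)
    di, ei = np.nonzero(keep)
    aa, bb, cc, dd = a[keep], b[keep], c[keep], d[keep]
    z = _zcrit(confidence)
    ror, lo, hi, corrected = _ror_ci_arrays(aa, bb, cc, dd, z)
    ic, ic025 = _ic_arrays(aa, bb, cc, dd)
    return pd.DataFrame({
        "drug": [dnames[i] for i in di],
        "event": [enames[j] for j in ei],
        "a": aa, "b": bb, "c": cc, "d": dd,
        "ror": ror, "ci_low": lo, "ci_high": hi,
        "ic": ic, "ic025": ic025,
        "signal": ic025 > 0,
        "ror_covers_one": (lo <= 1.0) & (1.0 <= hi),
        "corrected": corrected,
    })
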