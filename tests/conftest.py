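from __future__ import annotations

import pytest

from pvsignal import DrugEntry, Report, ReportStore, build_paper_fixture

TGA = "transient global amnesia"


def mk_report(rid, drugs, reactions, **kw):
    """Terse report builder: drugs as (name, role) pairs."""
    return Report(
        report_id=rid,
        drugs=tuple(DrugEntry(n, r) for n, r in drugs),
        reactions=frozenset(reactions),
        **kw,
    )


@pytest.fixture
def toy_store():
    """6 reports: 3 expose drug x (2 cases), 3 unexposed (1 case)."""
    return ReportStore([
        mk_report("R1", [("x", "suspect")], [TGA], sex="female",
                  reporter="physician"),
        mk_report("R2", [("x", "interacting")], [TGA, "headache"],
                  sex="female", age_band="45-64"),
        mk_report("R3", [("x", "suspect")], ["nausea"], sex="male"),
        mk_report("R4", [("y", "suspect")], [TGA], sex="female",
                  age_band="45-64", reporter="physician"),
        mk_report("R5", [("y", "suspect")], ["rash"], sex="male"),
        mk_report("R6", [("z", "concomitant")], ["nausea"], sex="unknown"),
    ])


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture()
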