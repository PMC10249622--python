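from __future__ import annotations

import pytest
from hypothesis import settings

from mxprime import SequenceRecord, SpeciesAlignment, builtin_panel

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy_aln() -> SpeciesAlignment:
    """Three species, two identical records each, 10 columns.

    Species B is uniquely C at column 3; species C is uniquely T at column 9;
    species A shares every residue with at least one other species.
    """
    def pair(label: str, seq: str) -> list[SequenceRecord]:
        return [SequenceRecord(f"{label}{i}", seq) for i in (1, 2)]

    return SpeciesAlignment(
        columns=10,
        groups={
            "A": pair("a", "ACGTACGTAC"),
            "B": pair("b", "ACCTACGTAC"),
            "C": pair("c", "ACGTACGTTC"),
        },
    )


@pytest.fixture(scope="session")
def coi_panel():
    return builtin_panel("coi")


@pytest.fixture(scope="session")
def cr_panel():
    return builtin_panel("cr")


@pytest.fixture(scope="session")
def nontarget_species() -> list[str]:
    """Congeners and pimelodids commonly sold alongside the target catfish."""
    return [
        "B. platynemum",
        "P. hemioliopterus",
        "Z. zungaro",
        "P. fasciatum",
        "P. reticulatum",
    ]
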