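"""Shared fixtures and independent oracles for the test suite."""

from collections import Counter
from itertools import chain, combinations_with_replacement

import pytest

from panelval.star import (
    GeneDefinitionTable,
    StarAlleleDefinition,
    star_sort_key,
)

# Two defining variants v1, v2 on a toy gene; the classic ambiguous
# layout: *1 = reference, *2 = {v1}, *3 = {v2}, *4 = {v1, v2}.
V1 = ("chr9", 100, "A", "G")
V2 = ("chr9", 200, "C", "T")


@pytest.fixture
def four_allele_table() -> GeneDefinitionTable:
    return GeneDefinitionTable(
        "TOYGENE",
        (
            StarAlleleDefinition("TOYGENE", "*1", frozenset()),
            StarAlleleDefinition("TOYGENE", "*2", frozenset({V1})),
            StarAlleleDefinition("TOYGENE", "*3", frozenset({V2})),
            StarAlleleDefinition("TOYGENE", "*4", frozenset({V1, V2})),
        ),
    )


def brute_force_diplotypes(
    table: GeneDefinitionTable, dosages: dict
) -> list[tuple[str, str]]:
    """Exhaustive oracle, written independently of the implementation:
    for every unordered allele pair, tally the multiset of defining
    variants carried by the pair and require it to equal the observed
    dosage map restricted to constrained positions."""
    valid = set()
    for a, b in combinations_with_replacement(table.alleles, 2):
        carried = Counter(chain(a.defining_variants, b.defining_variants))
        if all(carried.get(key, 0) == want for key, want in dosages.items()):
            valid.add(
                tuple(sorted((a.allele_name, b.allele_name), key=star_sort_key))
            )
    return sorted(valid, key=lambda p: (star_sort_key(p[0]), star_sort_key(p[1])))
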