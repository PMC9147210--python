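"""HLA allele nomenclature and genotype concordance.

HLA alleles are named ``Gene*Group:Protein[:...]`` — e.g. ``A*02:01`` or
``DRB1*15:01:01:02`` — where the first field is the gene, the second the
allele group and the third the specific protein. "Low resolution"
identity means agreement on the first two fields; "high resolution"
additionally requires the third. Fields are zero-padded identifiers,
not numbers (``"2" != "02"``), and expression suffixes (e.g. a trailing
``N``) participate in equality.

Genotypes are unordered pairs of alleles at one gene; concordance is
counted per allele under the pairing of observed to expected alleles
that maximizes matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .formatting import round_percent

logger = logging.getLogger(__name__)

__all__ = [
    "HlaAllele",
    "HlaGenotype",
    "parse_hla",
    "match_alleles",
    "genotype_concordance",
    "ConcordanceTally",
    "read_comparison_table",
]

LOW = "low"
HIGH = "high"


@dataclass(frozen=True)
class HlaAllele:
    """A parsed HLA allele name. ``extra_fields`` (synonymous/noncoding
    fields beyond the third) are kept for display but never matched."""

    gene: str
    group: str
    protein: str | None = None
    extra_fields: tuple[str, ...] = ()

    def __str__(self) -> str:
        fields = [self.group]
        if self.protein is not None:
            fields.append(self.protein)
        fields.extend(self.extra_fields)
        return f"{self.gene}*{':'.join(fields)}"


def parse_hla(name: str) -> HlaAllele:
    """Parse ``[HLA-]Gene*Group[:Protein[:...]]``; round-trips through
    ``str()`` (modulo the optional ``HLA-`` prefix)."""
    text = name.strip()
    if text.upper().startswith("HLA-"):
        text = text[4:]
    if "*" not in text:
        raise ValueError(f"not an HLA allele name (no '*'): {name!r}")
    gene, _, rest = text.partition("*")
    if not gene:
        raise ValueError(f"missing gene field: {name!r}")
    fields = rest.split(":") if rest else []
    if not fields or not fields[0]:
        raise ValueError(f"missing allele-group field: {name!r}")
    return HlaAllele(
        gene=gene.upper(),
        group=fields[0],
        protein=fields[1] if len(fields) > 1 else None,
        extra_fields=tuple(fields[2:]),
    )


@dataclass(frozen=True)
class HlaGenotype:
    """Unordered allele pair for one gene in one sample."""

    allele1: HlaAllele
    allele2: HlaAllele

    def __post_init__(self) -> None:
        if self.allele1.gene != self.allele2.gene:
            raise ValueError(
                f"genotype alleles must share a gene: "
                f"{self.allele1.gene} vs {self.allele2.gene}"
            )

    @property
    def gene(self) -> str:
        return self.allele1.gene


def match_alleles(a: HlaAllele, b: HlaAllele, resolution: str = LOW) -> bool:
    """Field-wise identity at the requested resolution.

    Low: gene and group. High: gene, group and protein — a missing
    protein field never matches a present one (and two missing protein
    fields match, there being nothing to distinguish them).
    """
    if resolution not in (LOW, HIGH):
        raise ValueError(f"resolution must be 'low' or 'high', got {resolution!r}")
    low = a.gene == b.gene and a.group == b.group
    if resolution == LOW:
        return low
    return low and a.protein == b.protein


@dataclass(frozen=True)
class ConcordanceTally:
    matched: int
    total: int

    @property
    def concordance(self) -> float | None:
        return None if self.total == 0 else self.matched / self.total

    @property
    def concordance_pct(self) -> float | None:
        frac = self.concordance
        return None if frac is None else round_percent(frac)


def genotype_concordance(
    pairs: Sequence[tuple[HlaGenotype, HlaGenotype]],
    resolution: str = LOW,
) -> ConcordanceTally:
    """Allele-level concordance over (expected, observed) genotype pairs.

    Each genotype contributes two alleles to the denominator. Within a
    genotype the two possible observed-to-expected assignments are both
    scored and the better one kept (the pairing rule is unordered). A
    gene mismatch between expected and observed counts both alleles as
    mismatched.
    """
    matched = 0
    total = 0
    for exp, obs in pairs:
        total += 2
        if exp.gene != obs.gene:
            logger.warning(
                "gene mismatch between expected (%s) and observed (%s) genotype; "
                "counting both alleles as mismatched",
                exp.gene,
                obs.gene,
            )
            continue
        straight = int(match_alleles(exp.allele1, obs.allele1, resolution)) + int(
            match_alleles(exp.allele2, obs.allele2, resolution)
        )
        crossed = int(match_alleles(exp.allele1, obs.allele2, resolution)) + int(
            match_alleles(exp.allele2, obs.allele1, resolution)
        )
        matched += max(straight, crossed)
    return ConcordanceTally(matched, total)


def read_comparison_table(
    path: str | Path,
) -> list[tuple[HlaGenotype, HlaGenotype]]:
    """Read a TSV of sample, gene, expected_allele_1, expected_allele_2,
    observed_allele_1, observed_allele_2 into genotype pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [
        "sample",
        "gene",
        "expected_allele_1",
        "expected_allele_2",
        "observed_allele_1",
        "observed_allele_2",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    pairs = []
    for _, row in df.iterrows():
        expected = HlaGenotype(
            parse_hla(row["expected_allele_1"]), parse_hla(row["expected_allele_2"])
        )
        observed = HlaGenotype(
            parse_hla(row["observed_allele_1"]), parse_hla(row["observed_allele_2"])
        )
        pairs.append((expected, observed))
    return pairs
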