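"""Star-allele diplotype enumeration from unphased genotypes.

A star allele is a named haplotype of a pharmacogene, defined by a
unique set of variants on one chromosome; the reference allele (usually
``*1``) is the empty set. A short-read VCF gives per-site alt-allele
dosages without phase, so a sample's diplotype is generally not unique:
this module enumerates *every* unordered pair of defined alleles whose
per-position membership sums reproduce the observed dosages, and all
valid diplotypes are reported. With the allele universe A, a pair
(h_i, h_j) is valid iff for every defining position p:

    [p in h_i] + [p in h_j] = dosage(p)

Positions that are uncovered or whose call was disapproved either void
the result (``strict`` mode — such variants go to orthogonal
confirmation) or are treated as unconstrained (``wildcard`` mode).

Concordance scoring against externally characterized haplotypes follows
the validation convention of excluding haplotypes without a
cross-laboratory consensus and haplotypes outside the assay's
detectable set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formatting import round_percent
from .variants import (
    APPROVED,
    DISAPPROVED,
    NO_COVERAGE,
    VariantKey,
    GenotypeCall,
    SiteStatus,
    WILD_TYPE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "COVERED",
    "UNCOVERED",
    "DISAPPROVED_SITE",
    "StarAlleleDefinition",
    "GeneDefinitionTable",
    "DosageVector",
    "DiplotypeResult",
    "parse_star_name",
    "star_sort_key",
    "load_definitions",
    "build_dosage_vector",
    "enumerate_diplotypes",
    "ExpectedHaplotype",
    "HaplotypeConcordance",
    "score_haplotype_concordance",
]

COVERED = "covered"
UNCOVERED = "uncovered"
DISAPPROVED_SITE = "disapproved"

CONSENSUS = "consensus"
NO_CONSENSUS = "no_consensus"
OUTSIDE_HAPLOTYPE = "outside_haplotype"

_STAR_RE = re.compile(r"^\*(\d+)([A-Za-z0-9]*)$")


def parse_star_name(name: str) -> tuple[str, int]:
    """Split a star-allele name into (base name, copy multiplier).

    Tandem names like ``"*1 × 2"`` or ``"*2x2"`` carry a copy-number
    multiplier; it is parsed for representation only — enumeration never
    emits multi-copy alleles (structural decomposition is a separate
    tool's job).
    """
    m = re.match(r"^(.*?)\s*[×x]\s*(\d+)$", name.strip())
    if m and m.group(1).strip().startswith("*"):
        return m.group(1).strip(), int(m.group(2))
    return name.strip(), 1


def star_sort_key(name: str) -> tuple:
    """Canonical ordering: star alleles by number then suffix then copy
    count, non-star names (e.g. rsIDs) after, alphabetically."""
    base, mult = parse_star_name(name)
    m = _STAR_RE.match(base)
    if m:
        return (0, int(m.group(1)), m.group(2), mult)
    return (1, base, "", mult)


@dataclass(frozen=True)
class StarAlleleDefinition:
    """One named haplotype: a unique set of defining variants."""

    gene: str
    allele_name: str
    defining_variants: frozenset[VariantKey]

    @property
    def is_reference(self) -> bool:
        return not self.defining_variants

    @property
    def base_name(self) -> str:
        return parse_star_name(self.allele_name)[0]

    @property
    def copy_multiplier(self) -> int:
        return parse_star_name(self.allele_name)[1]


@dataclass(frozen=True)
class GeneDefinitionTable:
    """All defined alleles of one gene, validated.

    Exactly one allele (the reference) has an empty defining set, and no
    two alleles may share a defining set — otherwise they would be the
    same haplotype under two names and diplotypes could never be
    distinguished.
    """

    gene: str
    alleles: tuple[StarAlleleDefinition, ...]

    def __post_init__(self) -> None:
        names = [a.allele_name for a in self.alleles]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"{self.gene}: duplicate allele name(s) {dupes}")
        seen: dict[frozenset, str] = {}
        for a in self.alleles:
            if a.defining_variants in seen:
                raise ValueError(
                    f"{self.gene}: alleles {seen[a.defining_variants]!r} and "
                    f"{a.allele_name!r} share an identical defining-variant set"
                )
            seen[a.defining_variants] = a.allele_name
        refs = [a for a in self.alleles if a.is_reference]
        if len(refs) != 1:
            raise ValueError(
                f"{self.gene}: need exactly one reference (empty-set) allele, "
                f"found {len(refs)}"
            )

    @property
    def reference_allele(self) -> StarAlleleDefinition:
        return next(a for a in self.alleles if a.is_reference)

    @property
    def defining_positions(self) -> frozenset[VariantKey]:
        out: set[VariantKey] = set()
        for a in self.alleles:
            out |= a.defining_variants
        return frozenset(out)

    def allele(self, name: str) -> StarAlleleDefinition:
        for a in self.alleles:
            if a.allele_name == name:
                return a
        raise KeyError(f"{self.gene}: no allele named {name!r}")


@dataclass(frozen=True)
class DosageVector:
    """Observed alt dosage and coverage status at each defining variant.

    ``dosages`` holds an entry only for covered positions; every
    defining position appears in ``status``.
    """

    gene: str
    dosages: Mapping[VariantKey, int]
    status: Mapping[VariantKey, str]

    def __post_init__(self) -> None:
        for key, st in self.status.items():
            if st == COVERED and key not in self.dosages:
                raise ValueError(f"covered position {key} lacks a dosage")
            if st != COVERED and key in self.dosages:
                raise ValueError(f"dosage present for non-covered position {key}")

    @property
    def problem_positions(self) -> tuple[VariantKey, ...]:
        return tuple(
            sorted(k for k, st in self.status.items() if st != COVERED)
        )


@dataclass(frozen=True)
class DiplotypeResult:
    """All diplotypes consistent with a sample's unphased dosages."""

    gene: str
    valid_diplotypes: tuple[tuple[str, str], ...]
    qc_flags: tuple[VariantKey, ...] = ()
    notes: tuple[str, ...] = ()

    @property
    def no_call(self) -> bool:
        return not self.valid_diplotypes

    def format_diplotypes(self) -> str:
        if self.no_call:
            return "no_call"
        return ";".join(f"{a}/{b}" for a, b in self.valid_diplotypes)


# ---------------------------------------------------------------------------
# Loading definitions


def load_definitions(path: str | Path) -> dict[str, GeneDefinitionTable]:
    """Load allele definitions from TSV (gene, allele, chrom, pos, ref, alt).

    One row per defining variant; the reference allele is a single row
    with empty variant columns. Tables are validated on load (unique
    names, unique sets, exactly one reference allele per gene).
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    required = ["gene", "allele", "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    tables: dict[str, GeneDefinitionTable] = {}
    for gene, gdf in df.groupby("gene", sort=False):
        alleles = []
        for allele, adf in gdf.groupby("allele", sort=False):
            variants: set[VariantKey] = set()
            for _, row in adf.iterrows():
                if row["chrom"] == "" and row["pos"] == "":
                    continue  # reference allele row
                variants.add(
                    (row["chrom"], int(row["pos"]), row["ref"].upper(), row["alt"].upper())
                )
            alleles.append(StarAlleleDefinition(gene, allele, frozenset(variants)))
        alleles.sort(key=lambda a: star_sort_key(a.allele_name))
        tables[gene] = GeneDefinitionTable(gene, tuple(alleles))
    return tables


def write_definitions(
    tables: Mapping[str, GeneDefinitionTable], path: str | Path
) -> None:
    rows = []
    for gene in tables:
        for a in tables[gene].alleles:
            if a.is_reference:
                rows.append((gene, a.allele_name, "", "", "", ""))
            else:
                for chrom, pos, ref, alt in sorted(a.defining_variants):
                    rows.append((gene, a.allele_name, chrom, str(pos), ref, alt))
    pd.DataFrame(rows, columns=["gene", "allele", "chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Dosage vectors


def build_dosage_vector(
    calls: Sequence[GenotypeCall],
    site_statuses: Sequence[SiteStatus],
    table: GeneDefinitionTable,
) -> DosageVector:
    """Project a sample's approved calls onto a gene's defining positions.

    Wild-type positions get dosage 0 (they must be *affirmatively*
    wild-type via the reference backfill, not merely absent from the
    VCF); uncovered positions and positions whose only call was
    disapproved are marked for QC instead of being given a dosage.
    """
    status_by_pos = {(s.chrom, s.pos): s for s in site_statuses}
    calls_by_key: dict[VariantKey, GenotypeCall] = {}
    for c in calls:
        calls_by_key.setdefault(c.key, c)
    dosages: dict[VariantKey, int] = {}
    status: dict[VariantKey, str] = {}
    for key in sorted(table.defining_positions):
        chrom, pos, _ref, _alt = key
        site = status_by_pos.get((chrom, pos))
        call = calls_by_key.get(key)
        if call is not None and call.approved == APPROVED:
            dosages[key] = call.dosage
            status[key] = COVERED
        elif call is not None and call.approved == DISAPPROVED:
            status[key] = DISAPPROVED_SITE
        elif site is None or site.status == NO_COVERAGE:
            status[key] = UNCOVERED
        else:
            # wild-type (or a different alt at the position): dosage 0
            dosages[key] = 0
            status[key] = COVERED
    return DosageVector(table.gene, dosages, status)


# ---------------------------------------------------------------------------
# Enumeration


def _order_pair(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b), key=star_sort_key))  # type: ignore[return-value]


def enumerate_diplotypes(
    dosages: DosageVector,
    table: GeneDefinitionTable,
    mode: str = "strict",
) -> DiplotypeResult:
    """Enumerate every unordered allele pair consistent with the dosages.

    A pair (h_i, h_j) is valid iff, at every constrained defining
    position p, membership of p in h_i plus membership in h_j equals the
    observed dosage. In ``strict`` mode any uncovered/disapproved
    position yields a no-call with those positions in ``qc_flags``; in
    ``wildcard`` mode such positions are simply unconstrained. An empty
    result is a no-call, not an error.
    """
    if mode not in ("strict", "wildcard"):
        raise ValueError(f"mode must be 'strict' or 'wildcard', got {mode!r}")
    flags = dosages.problem_positions
    if flags and mode == "strict":
        return DiplotypeResult(table.gene, (), qc_flags=flags)

    constrained = dict(dosages.dosages)
    valid: list[tuple[str, str]] = []
    for a, b in combinations_with_replacement(table.alleles, 2):
        if all(
            (key in a.defining_variants) + (key in b.defining_variants) == want
            for key, want in constrained.items()
        ):
            valid.append(_order_pair(a.allele_name, b.allele_name))
    valid.sort(key=lambda p: (star_sort_key(p[0]), star_sort_key(p[1])))
    return DiplotypeResult(table.gene, tuple(valid), qc_flags=flags)


def novel_variant_notes(
    calls: Sequence[GenotypeCall], table: GeneDefinitionTable
) -> tuple[str, ...]:
    """Note approved non-reference calls at non-defining positions.

    Such variants cannot influence matching against the defined alleles
    but may indicate an allele the table does not describe.
    """
    defined = table.defining_positions
    notes = []
    for c in calls:
        if c.approved == APPROVED and c.is_non_reference and c.key not in defined:
            notes.append(
                f"possible novel allele: {c.chrom}:{c.pos} {c.ref}>{c.alt} "
                f"(dosage {c.dosage}) is not a defining variant of {table.gene}"
            )
    return tuple(notes)


# ---------------------------------------------------------------------------
# Concordance against characterized haplotypes


@dataclass(frozen=True)
class ExpectedHaplotype:
    """One externally characterized haplotype for a sample/gene, with
    its comparability label."""

    sample: str
    gene: str
    haplotype: str
    label: str = CONSENSUS

    def __post_init__(self) -> None:
        if self.label not in (CONSENSUS, NO_CONSENSUS, OUTSIDE_HAPLOTYPE):
            raise ValueError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class HaplotypeConcordance:
    detected: int
    evaluable: int
    excluded: tuple[ExpectedHaplotype, ...] = ()

    @property
    def sensitivity(self) -> float | None:
        if self.evaluable == 0:
            return None
        return self.detected / self.evaluable

    @property
    def sensitivity_pct(self) -> float | None:
        frac = self.sensitivity
        return None if frac is None else round_percent(frac)


def score_haplotype_concordance(
    expected: Sequence[ExpectedHaplotype],
    observed: Mapping[tuple[str, str], DiplotypeResult],
) -> HaplotypeConcordance:
    """Tally detection of expected haplotypes among enumerated diplotypes.

    Haplotypes labeled ``no_consensus`` (discrepant between reference
    laboratories) or ``outside_haplotype`` (not in the assay's
    detectable set) are excluded from the denominator. An expected
    haplotype counts as detected if it appears in *any* valid diplotype
    for that sample/gene; a sample/gene absent from ``observed`` counts
    as missed.
    """
    detected = 0
    evaluable = 0
    excluded = []
    for exp in expected:
        if exp.label != CONSENSUS:
            excluded.append(exp)
            continue
        evaluable += 1
        result = observed.get((exp.sample, exp.gene))
        if result is None:
            logger.warning(
                "no observed diplotype for sample=%s gene=%s; counting as missed",
                exp.sample,
                exp.gene,
            )
            continue
        names = {name for pair in result.valid_diplotypes for name in pair}
        if exp.haplotype in names:
            detected += 1
    return HaplotypeConcordance(detected, evaluable, tuple(excluded))
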