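"""Variant-call IO and site-status resolution.

This module is the boundary between VCF files and the rest of the
toolkit. It reads per-sample calls (decomposing multi-allelic records
and normalizing indels), builds the artificial reference-position VCF
that lets joint processing carry depth for positions where every sample
is reference, applies per-call approval thresholds, and resolves each
targeted position into one of three states: ``variant``, ``wild_type``
(affirmatively reference, backed by adequate depth) or ``no_coverage``
(uninformative). The wild-type / no-coverage distinction is what the
reference backfill exists for: a position absent from a VCF is only a
reference genotype if reads actually covered it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pysam

from .intervals import TargetInterval

__all__ = [
    "APPROVED",
    "DISAPPROVED",
    "UNEVALUATED",
    "VARIANT",
    "WILD_TYPE",
    "NO_COVERAGE",
    "GenotypeCall",
    "SiteStatus",
    "BackfillRecord",
    "ApprovalThresholds",
    "normalize_variant",
    "is_normalized",
    "variant_class",
    "read_vcf",
    "write_vcf",
    "build_reference_backfill",
    "write_backfill_vcf",
    "approve_call",
    "resolve_site_status",
]

# Approval tri-state
APPROVED = "approved"
DISAPPROVED = "disapproved"
UNEVALUATED = "unevaluated"

# Site status
VARIANT = "variant"
WILD_TYPE = "wild_type"
NO_COVERAGE = "no_coverage"

#: A variant identity key: (chrom, pos, ref, alt).
VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class GenotypeCall:
    """One sample variant call, decomposed to a single alt allele.

    ``dosage`` is the count of this alt allele in the genotype (0, 1 or
    2; haploid calls on e.g. chrX use 0/1). Depth, genotype quality and
    per-strand alt-read counts carry the evidence used by
    :func:`approve_call`.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dosage: int
    total_depth: int | None = None
    genotype_quality: float | None = None
    forward_alt_depth: int | None = None
    reverse_alt_depth: int | None = None
    approved: str = UNEVALUATED
    disapproval_reason: str | None = None

    def __post_init__(self) -> None:
        if self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1 or 2, got {self.dosage}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        fwd = self.forward_alt_depth or 0
        rev = self.reverse_alt_depth or 0
        if fwd < 0 or rev < 0:
            raise ValueError("strand depths must be non-negative")
        if self.total_depth is not None and self.total_depth < fwd + rev:
            raise ValueError(
                f"total depth {self.total_depth} < strand alt depths {fwd}+{rev}"
            )
        if self.approved not in (APPROVED, DISAPPROVED, UNEVALUATED):
            raise ValueError(f"bad approval state {self.approved!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_non_reference(self) -> bool:
        return self.dosage > 0


@dataclass(frozen=True)
class SiteStatus:
    """Resolved state of one targeted position for one sample."""

    chrom: str
    pos: int
    status: str  # VARIANT | WILD_TYPE | NO_COVERAGE
    depth_at_site: int = 0

    def __post_init__(self) -> None:
        if self.status not in (VARIANT, WILD_TYPE, NO_COVERAGE):
            raise ValueError(f"bad site status {self.status!r}")


@dataclass(frozen=True)
class BackfillRecord:
    """A reference-position record for the artificial joint-call VCF.

    The allele of interest at these positions *is* the reference base,
    so joint processing reports depth/genotype evidence even when no
    sample carries a non-reference allele there.
    """

    chrom: str
    pos: int  # 1-based
    ref: str

    @property
    def allele_of_interest(self) -> str:
        return self.ref


@dataclass(frozen=True)
class ApprovalThresholds:
    """Minimum evidence for a call to be approved.

    Defaults (depth >= 20, GQ >= 20, >= 1 alt read on each strand) are
    package choices; override via config. The per-strand criterion only
    applies to non-reference calls — a dosage-0 call has no alt reads
    by definition.
    """

    min_depth: int = 20
    min_genotype_quality: float = 20.0
    min_strand_alt_depth: int = 1


# ---------------------------------------------------------------------------
# Normalization


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference_base: Callable[[str, int], str | None] | None = None,
) -> tuple[int, str, str]:
    """Left-align and parsimony-trim one allele pair.

    Returns the normalized (pos, ref, alt). ``reference_base`` supplies
    the base at a given (chrom, 1-based pos) for left extension; without
    it, alleles are trimmed to parsimony but indels in repeat tracts
    cannot be shifted left.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError(f"empty allele at {chrom}:{pos}")
    # Right-trim, extending left through repeat tracts when possible.
    while ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
            continue
        prev = reference_base(chrom, pos - 1) if reference_base else None
        if prev is None:
            break
        pos -= 1
        ref, alt = prev.upper() + ref[:-1], prev.upper() + alt[:-1]
    # Left-trim shared prefix down to the parsimonious anchor.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def is_normalized(ref: str, alt: str) -> bool:
    """True if the allele pair is parsimony-trimmed (no shared prefix or
    suffix removable while keeping both alleles non-empty)."""
    if len(ref) > 1 and len(alt) > 1 and (ref[0] == alt[0] or ref[-1] == alt[-1]):
        return False
    return True


def variant_class(ref: str, alt: str) -> str:
    """``"snv"`` for length-preserving substitutions, ``"indel"`` for
    length-changing alleles."""
    return "snv" if len(ref) == len(alt) else "indel"


# ---------------------------------------------------------------------------
# VCF reading / writing

_HEADER_FORMATS = [
    ("GT", "1", "String", "Genotype"),
    ("DP", "1", "Integer", "Read depth at this position"),
    ("GQ", "1", "Integer", "Genotype quality"),
    ("ALTF", "1", "Integer", "Alt allele read depth on the forward strand"),
    ("ALTR", "1", "Integer", "Alt allele read depth on the reverse strand"),
]


def _build_header(
    contigs: Iterable[str], samples: Sequence[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for cid, number, vtype, desc in _HEADER_FORMATS:
        header.formats.add(cid, number, vtype, desc)
    for contig in contigs:
        header.contigs.add(contig)
    for sample in samples:
        header.add_sample(sample)
    return header


def read_vcf(
    path: str | Path,
    sample: str,
    reference_base: Callable[[str, int], str | None] | None = None,
) -> list[GenotypeCall]:
    """Read one sample's calls from a VCF, one :class:`GenotypeCall` per
    alt allele.

    Multi-allelic records are decomposed by allele index (GT ``1/2``
    becomes two dosage-1 calls); alleles are normalized with
    :func:`normalize_variant`. Raises ``KeyError`` naming the available
    samples if ``sample`` is absent, and ``ValueError`` with the record
    position if a record cannot be interpreted.
    """
    path = str(path)
    with pysam.VariantFile(path) as vf:
        available = list(vf.header.samples)
        if sample not in available:
            raise KeyError(
                f"sample {sample!r} not in {path}; available samples: {available}"
            )
        calls: list[GenotypeCall] = []
        for idx, rec in enumerate(vf, 1):
            try:
                calls.extend(_decompose_record(rec, sample, reference_base))
            except (ValueError, TypeError, KeyError) as exc:
                raise ValueError(
                    f"{path}: malformed record #{idx} at "
                    f"{rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return calls


def _decompose_record(
    rec: "pysam.VariantRecord",
    sample: str,
    reference_base: Callable[[str, int], str | None] | None,
) -> list[GenotypeCall]:
    fmt = rec.samples[sample]
    gt = fmt.get("GT")
    if gt is None:
        raise ValueError("missing GT")
    alleles = [a for a in gt if a is not None]
    alts = rec.alts or ()
    dp = fmt.get("DP")
    gq = fmt.get("GQ")
    # Strand alt depths: our own scalar ALTF/ALTR (records are biallelic
    # when we write them), falling back to standard Number=R ADF/ADR.
    altf, altr = fmt.get("ALTF"), fmt.get("ALTR")
    adf, adr = fmt.get("ADF"), fmt.get("ADR")
    calls = []
    for alt_index, alt in enumerate(alts, 1):
        if alt in (".", "*", "<NON_REF>"):
            continue
        dosage = sum(1 for a in alleles if a == alt_index)
        pos, ref_n, alt_n = normalize_variant(
            rec.chrom, rec.pos, rec.ref, alt, reference_base
        )
        calls.append(
            GenotypeCall(
                chrom=rec.chrom,
                pos=pos,
                ref=ref_n,
                alt=alt_n,
                dosage=min(dosage, 2),
                total_depth=dp,
                genotype_quality=gq,
                forward_alt_depth=altf if altf is not None else _at(adf, alt_index),
                reverse_alt_depth=altr if altr is not None else _at(adr, alt_index),
            )
        )
    return calls


def _at(values, i):
    if values is None:
        return None
    try:
        return values[i]
    except (IndexError, TypeError):
        return None


_GT_FOR_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(
    calls: Sequence[GenotypeCall], path: str | Path, sample: str = "SAMPLE"
) -> None:
    """Write calls as a biallelic-record VCF (one record per call)."""
    contigs = sorted({c.chrom for c in calls})
    header = _build_header(contigs, [sample])
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in ordered:
            rec = vf.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt),
            )
            fmt = rec.samples[sample]
            fmt["GT"] = _GT_FOR_DOSAGE[call.dosage]
            if call.total_depth is not None:
                fmt["DP"] = call.total_depth
            if call.genotype_quality is not None:
                fmt["GQ"] = int(call.genotype_quality)
            if call.forward_alt_depth is not None:
                fmt["ALTF"] = call.forward_alt_depth
            if call.reverse_alt_depth is not None:
                fmt["ALTR"] = call.reverse_alt_depth
            vf.write(rec)


# ---------------------------------------------------------------------------
# Reference backfill


def build_reference_backfill(
    targets: Sequence[TargetInterval],
    reference_alleles: Mapping[tuple[str, int], str],
) -> list[BackfillRecord]:
    """One record per distinct targeted position, allele of interest =
    the reference base.

    ``reference_alleles`` maps (chrom, 1-based pos) to the reference
    base; a targeted position without one is an error. Overlapping
    intervals yield a single record per position.
    """
    positions = sorted(
        {(iv.chrom, pos) for iv in targets for pos in iv.vcf_positions()}
    )
    records = []
    for chrom, pos in positions:
        base = reference_alleles.get((chrom, pos))
        if base is None:
            raise ValueError(f"no reference base for targeted position {chrom}:{pos}")
        records.append(BackfillRecord(chrom, pos, base.upper()))
    return records


def write_backfill_vcf(records: Sequence[BackfillRecord], path: str | Path) -> None:
    """Serialize backfill records as monomorphic-reference VCF sites
    (ALT = '.', since VCF cannot list REF as an alternate allele)."""
    contigs = sorted({r.chrom for r in records})
    header = _build_header(contigs, [])
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec_in in sorted(records, key=lambda r: (r.chrom, r.pos)):
            rec = vf.new_record(
                contig=rec_in.chrom,
                start=rec_in.pos - 1,
                stop=rec_in.pos,
                alleles=(rec_in.ref,),
            )
            vf.write(rec)


# ---------------------------------------------------------------------------
# Approval and site status


def approve_call(
    call: GenotypeCall, thresholds: ApprovalThresholds = ApprovalThresholds()
) -> GenotypeCall:
    """Return a copy of ``call`` with the approval tri-state resolved.

    Criteria are checked in a fixed order — depth, genotype quality,
    per-strand alt reads — and the first failure is recorded as the
    disapproval reason. Missing (unevaluated) evidence fails its
    criterion.
    """
    reason = None
    if call.total_depth is None or call.total_depth < thresholds.min_depth:
        reason = "depth"
    elif (
        call.genotype_quality is None
        or call.genotype_quality < thresholds.min_genotype_quality
    ):
        reason = "genotype_quality"
    elif call.is_non_reference and (
        call.forward_alt_depth is None
        or call.reverse_alt_depth is None
        or call.forward_alt_depth < thresholds.min_strand_alt_depth
        or call.reverse_alt_depth < thresholds.min_strand_alt_depth
    ):
        reason = "strand"
    if reason is None:
        return dataclasses.replace(call, approved=APPROVED, disapproval_reason=None)
    return dataclasses.replace(call, approved=DISAPPROVED, disapproval_reason=reason)


def resolve_site_status(
    chrom: str,
    pos: int,
    calls: Sequence[GenotypeCall],
    depth_at_site: int,
    coverage_floor: int = 20,
) -> SiteStatus:
    """Classify one targeted position as variant / wild-type / no-coverage.

    ``variant`` if an approved non-reference call sits at the position;
    otherwise ``wild_type`` when depth from the backfilled joint output
    reaches ``coverage_floor``, else ``no_coverage``. This is the
    distinction the reference backfill enables: absence of a call only
    means reference when reads were actually there.
    """
    has_variant = any(
        c.chrom == chrom and c.pos == pos and c.is_non_reference and c.approved == APPROVED
        for c in calls
    )
    if has_variant:
        status = VARIANT
    elif depth_at_site >= coverage_floor:
        status = WILD_TYPE
    else:
        status = NO_COVERAGE
    return SiteStatus(chrom, pos, status, depth_at_site)
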