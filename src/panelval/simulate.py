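"""Deterministic synthetic-data generators with recorded ground truth.

Every generator is a pure function of its arguments (including the
seed) and returns, alongside the generated inputs, a manifest that
records exactly what was planted — planted false positives/negatives,
planted replicate discordances, true diplotypes. The manifest is the
oracle the test suite scores results against.

Data live on synthetic contigs (``chrT1`` ...) with reference bases
carried in a sidecar mapping, so no reference genome is needed. Indel
plants are 1-5 bp and emitted pre-normalized (left-aligned anchored
form) so the normalization path is exercised without ambiguity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import TargetInterval, write_bed
from .star import (
    GeneDefinitionTable,
    StarAlleleDefinition,
    star_sort_key,
    write_definitions,
)
from .variants import (
    APPROVED,
    VariantKey,
    GenotypeCall,
    SiteStatus,
    WILD_TYPE,
    write_vcf,
)

__all__ = [
    "TruthPair",
    "ReplicateSet",
    "StarPanel",
    "make_truth_pair",
    "make_replicates",
    "make_star_panel",
]

_BASES = np.array(list("ACGT"))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _write_manifest(manifest: dict, path: Path) -> None:
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _keys_json(keys: Sequence[VariantKey]) -> list[list]:
    return [list(k) for k in sorted(keys)]


# ---------------------------------------------------------------------------
# Truth / observed callset pairs


@dataclass(frozen=True)
class TruthPair:
    """A truth callset, an observed callset derived from it by planting
    misses and spurious calls, the confident mask, and the manifest."""

    truth: tuple[GenotypeCall, ...]
    observed: tuple[GenotypeCall, ...]
    confident: tuple[TargetInterval, ...]
    reference: Mapping[tuple[str, int], str]
    manifest: dict


def _random_call(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    ref_base: str,
    vclass: str,
) -> GenotypeCall:
    dosage = int(rng.integers(1, 3))
    if vclass == "snv":
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        ref = ref_base
    else:
        tail = "".join(rng.choice(_BASES, size=int(rng.integers(1, 6))))
        if rng.random() < 0.5:  # insertion
            ref, alt = ref_base, ref_base + tail
        else:  # deletion
            ref, alt = ref_base + tail, ref_base
    depth = int(rng.integers(30, 120))
    half = depth // 2
    return GenotypeCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        dosage=dosage,
        total_depth=depth,
        genotype_quality=99,
        forward_alt_depth=max(1, half // 2),
        reverse_alt_depth=max(1, half // 2),
        approved=APPROVED,
    )


def make_truth_pair(
    n_targeted_bases: int = 1000,
    n_snv: int = 100,
    n_indel: int = 0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    chrom: str = "chrT1",
) -> TruthPair:
    """Generate a (truth, observed) callset pair with planted errors.

    The observed set is the truth set minus ``round(fn_rate * n)``
    dropped variants plus ``round(fp_rate * n)`` spurious ones at
    otherwise-reference positions (n = total truth variants). The
    confident mask covers the whole targeted span. With ``out_dir``,
    writes truth.vcf, observed.vcf, confident.bed, reference.tsv and
    manifest.json; identical arguments give byte-identical files.
    """
    if not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    n_variants = n_snv + n_indel
    n_fp = int(round(fp_rate * n_variants))
    # Indels consume up to 6 bases; space plants so spans never collide.
    spacing = 8
    needed = (n_variants + n_fp) * spacing
    if needed > n_targeted_bases:
        raise ValueError(
            f"{n_variants + n_fp} variants need {needed} bases at spacing "
            f"{spacing}, but only {n_targeted_bases} are targeted"
        )
    rng = _rng(seed)
    ref_seq = rng.choice(_BASES, size=n_targeted_bases)
    reference = {
        (chrom, pos): str(ref_seq[pos - 1]) for pos in range(1, n_targeted_bases + 1)
    }
    slots = rng.permutation(n_targeted_bases // spacing)[: n_variants + n_fp]
    positions = [int(s) * spacing + 1 for s in slots]

    truth_calls = []
    for i in range(n_variants):
        pos = positions[i]
        vclass = "snv" if i < n_snv else "indel"
        truth_calls.append(_random_call(rng, chrom, pos, reference[(chrom, pos)], vclass))

    n_fn = int(round(fn_rate * n_variants))
    fn_idx = set(rng.choice(n_variants, size=n_fn, replace=False).tolist()) if n_fn else set()
    observed_calls = [c for i, c in enumerate(truth_calls) if i not in fn_idx]

    fp_calls = []
    for j in range(n_fp):
        pos = positions[n_variants + j]
        vclass = "snv" if rng.random() < 0.5 or n_indel == 0 else "indel"
        if n_snv == 0:
            vclass = "indel"
        fp_calls.append(_random_call(rng, chrom, pos, reference[(chrom, pos)], vclass))
    observed_calls.extend(fp_calls)

    confident = (TargetInterval(chrom, 0, n_targeted_bases, "confident"),)
    from .variants import variant_class as _vc

    manifest = {
        "seed": seed,
        "n_targeted_bases": n_targeted_bases,
        "planted": {
            "truth_snv": _keys_json([c.key for c in truth_calls if _vc(c.ref, c.alt) == "snv"]),
            "truth_indel": _keys_json([c.key for c in truth_calls if _vc(c.ref, c.alt) == "indel"]),
            "fn": _keys_json([truth_calls[i].key for i in fn_idx]),
            "fp": _keys_json([c.key for c in fp_calls]),
        },
        "expected_counts": _expected_counts(truth_calls, fn_idx, fp_calls, n_targeted_bases),
    }

    truth_t = tuple(sorted(truth_calls, key=lambda c: c.pos))
    observed_t = tuple(sorted(observed_calls, key=lambda c: c.pos))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(truth_t, out / "truth.vcf", sample="TRUTH")
        write_vcf(observed_t, out / "observed.vcf", sample="OBSERVED")
        write_bed(confident, out / "confident.bed")
        _write_reference_tsv(reference, out / "reference.tsv")
        _write_manifest(manifest, out / "manifest.json")
    return TruthPair(truth_t, observed_t, confident, reference, manifest)


def _expected_counts(truth_calls, fn_idx, fp_calls, n_bases) -> dict:
    """Per-class confusion counts implied by the plants (the oracle)."""
    from .variants import variant_class as _vc

    out = {}
    for vclass in ("snv", "indel"):
        t_keys = {c.key for c in truth_calls if _vc(c.ref, c.alt) == vclass}
        fn_keys = {truth_calls[i].key for i in fn_idx} & t_keys
        fp_keys = {c.key for c in fp_calls if _vc(c.ref, c.alt) == vclass}
        occupied = {(k[0], k[1]) for k in t_keys | fp_keys}
        out[vclass] = {
            "tp": len(t_keys) - len(fn_keys),
            "fn": len(fn_keys),
            "fp": len(fp_keys),
            "tn": n_bases - len(occupied),
        }
    return out


def _write_reference_tsv(
    reference: Mapping[tuple[str, int], str], path: Path
) -> None:
    lines = [f"{c}\t{p}\t{b}" for (c, p), b in sorted(reference.items())]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Replicates


@dataclass(frozen=True)
class ReplicateSet:
    replicates: tuple[tuple[GenotypeCall, ...], ...]
    manifest: dict


def make_replicates(
    base_calls: Sequence[GenotypeCall],
    n_replicates: int = 3,
    discordance_count: int = 0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ReplicateSet:
    """Replicate a callset with exactly ``discordance_count`` planted
    disagreements.

    Each planted discordance either drops the variant from one replicate
    or flips its dosage there, so exactly that many union keys fail the
    all-replicates-agree rule. Triplicates (the usual precision-study
    design) are the default.
    """
    base = [c for c in base_calls if c.is_non_reference]
    if discordance_count > len(base):
        raise ValueError(
            f"cannot plant {discordance_count} discordances among {len(base)} calls"
        )
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = _rng(seed)
    discordant_idx = (
        set(rng.choice(len(base), size=discordance_count, replace=False).tolist())
        if discordance_count
        else set()
    )
    replicates: list[list[GenotypeCall]] = [list(base) for _ in range(n_replicates)]
    planted = []
    for i in sorted(discordant_idx):
        call = base[i]
        victim = int(rng.integers(n_replicates))
        if rng.random() < 0.5:
            replicates[victim] = [c for c in replicates[victim] if c.key != call.key]
            kind = "dropped"
        else:
            new_dosage = 2 if call.dosage == 1 else 1
            replicates[victim] = [
                dataclasses.replace(c, dosage=new_dosage) if c.key == call.key else c
                for c in replicates[victim]
            ]
            kind = "dosage_flip"
        planted.append({"key": list(call.key), "replicate": victim, "kind": kind})
    manifest = {
        "seed": seed,
        "n_replicates": n_replicates,
        "discordance_count": discordance_count,
        "union_size": len(base),
        "planted_discordances": planted,
    }
    reps = tuple(tuple(r) for r in replicates)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, rep in enumerate(reps, 1):
            write_vcf(rep, out / f"replicate_{i}.vcf", sample=f"REP{i}")
        _write_manifest(manifest, out / "manifest.json")
    return ReplicateSet(reps, manifest)


# ---------------------------------------------------------------------------
# Star-allele panels


@dataclass(frozen=True)
class StarPanelSample:
    sample: str
    true_diplotype: tuple[str, str]
    calls: tuple[GenotypeCall, ...]
    site_statuses: tuple[SiteStatus, ...]


@dataclass(frozen=True)
class StarPanel:
    table: GeneDefinitionTable
    samples: tuple[StarPanelSample, ...]
    manifest: dict


def _random_definition_table(
    rng: np.random.Generator,
    gene: str,
    chrom: str,
    n_alleles: int,
    n_positions: int,
    max_tries: int = 2000,
) -> GeneDefinitionTable:
    if n_alleles < 2:
        raise ValueError("need at least the reference allele plus one")
    if n_alleles > 2**n_positions:
        raise ValueError(
            f"{n_alleles} unique subsets impossible with {n_positions} positions"
        )
    positions = sorted(rng.choice(np.arange(1, 10 * n_positions + 1), size=n_positions, replace=False).tolist())
    keys: list[VariantKey] = []
    for pos in positions:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        keys.append((chrom, int(pos), str(ref), str(alt)))
    subsets: list[frozenset[VariantKey]] = [frozenset()]
    tries = 0
    while len(subsets) < n_alleles:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not draw {n_alleles} unique defining sets "
                f"over {n_positions} positions in {max_tries} tries"
            )
        mask = rng.random(n_positions) < 0.5
        subset = frozenset(k for k, keep in zip(keys, mask) if keep)
        if subset and subset not in subsets:
            subsets.append(subset)
    alleles = tuple(
        StarAlleleDefinition(gene, f"*{i + 1}", s) for i, s in enumerate(subsets)
    )
    return GeneDefinitionTable(gene, alleles)


def make_star_panel(
    n_alleles: int = 4,
    n_positions: int = 2,
    n_samples: int = 3,
    seed: int = 0,
    gene: str = "GENE1",
    chrom: str = "chrT2",
    out_dir: str | Path | None = None,
) -> StarPanel:
    """Generate a random allele-definition table plus samples with known
    diplotypes and VCF-consistent calls.

    Each sample's true diplotype is drawn uniformly from the unordered
    allele pairs; its calls carry exactly the dosages that diplotype
    implies, and every defining position gets an affirmative wild-type
    site status when dosage is 0. Unique defining sets are enforced by
    bounded rejection sampling.
    """
    rng = _rng(seed)
    table = _random_definition_table(rng, gene, chrom, n_alleles, n_positions)
    pairs = list(combinations_with_replacement(table.alleles, 2))
    samples = []
    manifest_samples = {}
    for s in range(n_samples):
        name = f"S{s + 1}"
        a, b = pairs[int(rng.integers(len(pairs)))]
        calls = []
        statuses = []
        for key in sorted(table.defining_positions):
            dosage = int(key in a.defining_variants) + int(key in b.defining_variants)
            kchrom, kpos, kref, kalt = key
            depth = int(rng.integers(40, 100))
            if dosage > 0:
                calls.append(
                    GenotypeCall(
                        chrom=kchrom,
                        pos=kpos,
                        ref=kref,
                        alt=kalt,
                        dosage=dosage,
                        total_depth=depth,
                        genotype_quality=99,
                        forward_alt_depth=depth // 4,
                        reverse_alt_depth=depth // 4,
                        approved=APPROVED,
                    )
                )
                statuses.append(SiteStatus(kchrom, kpos, "variant", depth))
            else:
                statuses.append(SiteStatus(kchrom, kpos, WILD_TYPE, depth))
        true_pair = tuple(sorted((a.allele_name, b.allele_name), key=star_sort_key))
        samples.append(
            StarPanelSample(name, true_pair, tuple(calls), tuple(statuses))
        )
        manifest_samples[name] = list(true_pair)
    manifest = {
        "seed": seed,
        "gene": gene,
        "n_alleles": n_alleles,
        "n_positions": n_positions,
        "true_diplotypes": manifest_samples,
    }
    panel = StarPanel(table, tuple(samples), manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_definitions({gene: table}, out / "definitions.tsv")
        for sample in panel.samples:
            write_vcf(sample.calls, out / f"{sample.sample}.vcf", sample=sample.sample)
            depth_lines = [
                f"{st.chrom}\t{st.pos}\t{st.depth_at_site}"
                for st in sample.site_statuses
            ]
            (out / f"{sample.sample}.depth.tsv").write_text(
                "\n".join(depth_lines) + "\n"
            )
        _write_manifest(manifest, out / "manifest.json")
    return panel
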