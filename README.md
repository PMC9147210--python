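# panelval

A validation toolkit for targeted NGS screening panels. It implements
the bespoke computational stages such an assay needs beyond standard
alignment and variant calling:

- **Star-allele diplotyping** — enumerate every pharmacogene diplotype
  consistent with a sample's *unphased* genotypes against an
  allele-definition table, reporting all valid pairs when phase
  ambiguity allows more than one.
- **HLA nomenclature** — parse `Gene*Group:Protein` allele names and
  score genotype concordance at low (two-field) and high (three-field)
  resolution.
- **Reference-position backfill** — build the artificial
  reference-position VCF that lets joint genotyping distinguish an
  affirmative wild-type genotype from a no-coverage gap, plus per-call
  approval on depth/quality/strand evidence.
- **Coverage QC** — per-sample uniformity, ≥20× fraction, per-interval
  depth and read-rate metrics with configurable pass/re-sequence gates.
- **Validation statistics** — truth-set comparison into confusion
  counts; accuracy, sensitivity, specificity, PPV and NPV; replicate
  genotype concordance; clinical sensitivity with documented
  exclusions; and a pooled-variance two-sample t-test for allele
  frequencies.
- **Fixture generators** — deterministic synthetic VCF/BED/TSV inputs
  with a manifest recording exactly what was planted, so every stage is
  testable without external data.

## The core computations

**Diplotype enumeration.** A star allele *h* is a set of defining
variants on one chromosome (the reference allele is the empty set).
Given observed alt dosages *d(p)* at each defining position *p*, a
diplotype (*h_i*, *h_j*) is valid iff for every *p*:

    [p ∈ h_i] + [p ∈ h_j] = d(p)

All unordered pairs over the gene's allele universe are checked; an
empty result is a no-call. Positions without adequate coverage or with
a disapproved call either void the result (`strict`) or are left
unconstrained (`wildcard`).

**Performance metrics** from confusion counts:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)        specificity = TN / (FP + TN)
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)

**Pooled t-test** for sample vs population allele frequencies, with
n₁ + n₂ − 2 degrees of freedom:

    S² = [ Σᵢ(xᵢ − x̄₁)² + Σⱼ(xⱼ − x̄₂)² ] / (n₁ + n₂ − 2)
    t  = (x̄₁ − x̄₂) / sqrt( S² (1/n₁ + 1/n₂) )

## Worked example

```python
from panelval.star import (COVERED, DosageVector, GeneDefinitionTable,
                           StarAlleleDefinition, enumerate_diplotypes)

V1 = ("chr10", 94781859, "A", "G")
V2 = ("chr10", 94852738, "C", "T")
table = GeneDefinitionTable("DEMOGENE", (
    StarAlleleDefinition("DEMOGENE", "*1", frozenset()),
    StarAlleleDefinition("DEMOGENE", "*2", frozenset({V1})),
    StarAlleleDefinition("DEMOGENE", "*3", frozenset({V2})),
    StarAlleleDefinition("DEMOGENE", "*4", frozenset({V1, V2})),
))
dv = DosageVector("DEMOGENE", {V1: 1, V2: 1}, {V1: COVERED, V2: COVERED})
print(enumerate_diplotypes(dv, table).format_diplotypes())
```

prints

```
*1/*4;*2/*3
```

— a sample heterozygous at both defining variants is phase-ambiguous:
the variants may lie in cis (one *4 chromosome plus a reference *1) or
in trans (*2 and *3), and both diplotypes are reported. The
`examples/` directory has one short script per capability
(`python examples/star_diplotypes.py` etc.), each printing its numbers
with a note on what they mean.

A thin CLI wraps the same functions:

```bash
panelval simulate star-panel --seed 4 --out fx/
panelval star-call --vcf fx/S1.vcf --depth fx/S1.depth.tsv --definitions fx/definitions.tsv
panelval validate --truth t.vcf --observed o.vcf --confident c.bed --reportable r.bed
```

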