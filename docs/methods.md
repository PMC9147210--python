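# Methods

This note documents the models and procedures panelval implements, the
parameters that matter, the numerical conventions, and what the
synthetic fixtures do and do not establish about real data.

## Star-allele diplotype enumeration

Pharmacogene haplotypes ("star alleles") are defined as unique sets of
variants on a single chromosome; within a gene the toolkit requires
exactly one reference allele with an empty defining set, and rejects
tables in which two allele names share a defining set (they would be
indistinguishable by construction). A short-read VCF carries per-site
alt dosages without phase, so the diplotype consistent with a sample is
in general not unique. The enumerator checks every unordered pair of
defined alleles against the constraint that, at each defining position,
the pair's membership count equals the observed dosage, and reports
*all* valid pairs. For the panel sizes this targets (≤ a few dozen
alleles, ≤ a few dozen defining positions per gene), the exhaustive
O(|A|² · |P|) scan is instantaneous and has the virtue of being
obviously complete; no pruning heuristics are used.

Positions that could not be genotyped confidently are handled in one of
two modes:

- `strict` (default): any defining position that is uncovered or whose
  call was disapproved yields a no-call with the offending positions in
  `qc_flags`. This mirrors a lab workflow in which such variants go to
  orthogonal confirmation (e.g. Sanger) rather than being guessed.
- `wildcard`: such positions are unconstrained, which unions the
  diplotype sets over their possible dosages. Useful for triage, not
  for reporting.

A dosage of zero must be *affirmative*: the site has to resolve as
wild-type (adequate depth, no variant), not merely be absent from the
VCF. That is the purpose of the reference-position backfill (below).
Approved variants at non-defining positions inside the gene do not
influence matching but are surfaced as possible-novel-allele notes.
Tandem names such as `*1 × 2` are parsed and representable (the copy
multiplier is retained), but enumeration never emits them: structural
copy-number decomposition is out of scope.

Canonical ordering: alleles sort by star number, then suffix, then copy
multiplier, with non-star names (rsIDs) after; within a pair the lower
allele comes first, and pair lists sort likewise. This makes outputs
reproducible and diffable.

## Reference backfill, call approval and site status

Joint genotyping only carries information for positions where some
sample is non-reference. The backfill constructs one record per
distinct targeted position whose allele of interest *is* the reference
base (serialized as a monomorphic-reference VCF site, since VCF cannot
list REF as ALT), so depth evidence is present for every targeted
position. Site status then resolves per position to `variant`
(an approved non-reference call), `wild_type` (depth at or above the
coverage floor, default 20×) or `no_coverage`.

Call approval checks, in fixed order: total depth (default ≥ 20),
genotype quality (default ≥ 20), and at least one alt read on each
strand (non-reference calls only). The first failing criterion is
recorded. The defaults are package choices — the validation workflow
this models uses such gates but does not publish numbers — and are
configurable (`approval:` block in YAML, or flags).

Variant representation is normalized before any comparison: alleles are
parsimony-trimmed and, where a reference-base lookup is available,
left-aligned by the standard truncate-or-extend loop. The truth-set
comparison refuses trimmable alleles outright rather than silently
mismatching representations.

## Coverage QC

Uniformity is the percent of targeted bases whose depth strictly
exceeds 0.2 × the sample's mean depth over targeted bases — a
scale-free evenness measure (multiplying all depths by a constant
leaves it unchanged). The ≥ 20× fraction uses an inclusive threshold.
Depth input follows the samtools-depth convention: absent positions are
depth 0. The average base depth is taken over reportable intervals
only; per-interval 20× gating can use the interval's mean (default) or
minimum depth (`interval_rule`). Aligned and duplicate rates are
fractions of total reads; the on-target denominator defaults to aligned
reads and is configurable (`on_target_of`), since either convention is
seen in practice. The QC gate defaults (uniformity ≥ 90%, aligned
≥ 95%, duplicates ≤ 10%, bases ≥ 20× ≥ 85%) are likewise package
choices, and failures are listed in a stable declaration order.

## HLA concordance

Allele names parse as `Gene*Group[:Protein[:...]]` with an optional
`HLA-` prefix. Fields are zero-padded identifiers compared literally
(`"2" ≠ "02"`), expression suffixes (trailing `N` etc.) participate in
equality, and fields beyond the third are retained for display but
ignored for matching. Low resolution compares gene+group; high
resolution adds the protein field, where a missing field never matches
a present one. Genotypes are unordered pairs: concordance is counted
per allele (two per genotype) under the better of the two possible
observed-to-expected assignments. The pairing rule is a design choice —
published concordances are allele-denominated, which fixes the
denominator but not the assignment; best-of-two is the charitable and
deterministic option.

## Validation statistics

**Truth comparison.** Variants match on (chrom, pos, ref, alt) after
normalization and multi-allelic decomposition. Within the confident
mask: TP/FN partition truth variants by whether an observed call
matches; FP are observed calls absent from truth; TN counts targeted
confident reference positions carrying neither a truth nor an observed
variant of the class in question, which makes TN the same order as the
panel's base count. Classes are SNV (length-preserving) vs indel
(length-changing); strata are all targeted bases vs the reportable
subset. The confident ("truth mask") regions are a user-supplied BED —
the toolkit does not fetch any external truth resource.

**Replicate concordance.** Over the union of variant keys that are
non-reference in any replicate, a key is concordant iff every replicate
carries it with an identical genotype — same dosage, not merely allele
presence (agreement is otherwise underspecified, and dosage identity is
the stricter, safer reading). Per-replicate counts report each
replicate's non-reference total; the percentage is concordant / union.

**Clinical sensitivity.** detected/evaluable after removing documented
exclusions from the denominator (and the numerator, when the excluded
item had been detected). Exclusions always carry a reason string;
star-allele scoring additionally excludes expected haplotypes labeled
`no_consensus` (no cross-laboratory agreement on the expectation) or
`outside_haplotype` (outside the assay's detectable allele set) before
the tally.

**Pooled t-test.** Hand-coded equal-variance two-sample t (formulas in
the README), two-sided p from the t distribution with n₁+n₂−2 df.
Degenerate inputs: zero pooled variance gives t = 0 (equal means) or a
signed infinity with p = 0 (unequal means); groups smaller than 2 are
rejected. Category concordance is the percent of alleles whose null is
not rejected at `alpha` (default 0.05, configurable); how the published
workflow aggregated its per-category tests (test granularity, n per
test, alpha) is not specified, so this implementation's aggregation is
one documented interpretation and its absolute values are not
comparable to published per-category figures.

## Percent display convention

All printed percentages round half-up to two decimals. A rate that is
not exactly 1 is never displayed as 100.00%: it caps at 99.99%, the
conventional way clinical validation tables avoid overstating a metric
that still has errors in the numerator or denominator (e.g. a
specificity of 366657/366667). Raw fractions are preserved in all
machine-readable output; zero-denominator metrics print `NA` rather
than 0 or 100.

## Synthetic fixtures

Generators are pure functions of their arguments including the seed
(same seed ⇒ byte-identical files) and live on synthetic contigs with a
sidecar reference-base table, so nothing is downloaded. Each generator
returns a manifest recording exactly what was planted — FP/FN keys and
implied confusion counts, discordant replicate keys, true diplotypes —
and the manifest is the oracle tests score against.

- Truth/observed pairs: variants at spaced positions (spacing 8 bp so
  1–5 bp indel spans never collide), FN plants dropped from and FP
  plants added to the observed set, counts = round(rate × n).
- Replicates: planted disagreements are per-key drops or dosage flips
  in one replicate, so the discordance count is exact by construction.
- Star panels: random definition tables with unique defining sets
  (bounded rejection sampling), a true diplotype drawn uniformly per
  sample, and calls/site statuses derived exactly from it.

What these fixtures emulate is the *bookkeeping* structure of a
validation: known truth, known error plants, deterministic replay. They
do not emulate read-level error profiles, alignment artifacts,
repeat-region ambiguity, or the coverage correlations of real capture
data — so passing tests establish correctness of the computational
stages, not field performance of an assay.

## Problem sizes and test design

The default suite exercises: 500 random panels (≤ 12 alleles, ≤ 8
positions) against an independently coded exhaustive oracle plus
planted-diplotype recovery; 100 seeded truth/observed fixtures with
exact confusion-count recovery; 1000 random t-test instances against
scipy's equal-variance test at 1e-10 relative tolerance; a 1000-allele
null simulation whose non-rejection rate must sit within three binomial
standard errors of 100(1−α); and property tests (seeded hypothesis)
for the invariants — uniformity scale-invariance, 20×-fraction
monotonicity, resolution monotonicity (high-resolution match implies
low), accuracy bounded by sensitivity and specificity, metric symmetry
under (TP↔TN, FP↔FN), enumeration invariance to table row order, and
replicate-order invariance. These sizes keep the full suite under a
few seconds while giving the oracle comparisons enough variety to be
informative.

## Known limitations

- Enumeration assumes a diploid locus; haploid/hemizygous handling is
  limited to accepting dosage-1 genotypes.
- CYP2D6-style structural decomposition (tandems, hybrids, fusions) is
  representational only; no copy-number inference is performed.
- The TN definition is per targeted base, which differs from tools that
  count confident reference *sites* or exclude indel-adjacent bases;
  absolute TN-dependent metrics are only comparable under the same
  convention.
- On-target and duplicate-rate definitions vary between instrument
  vendors; the read-level tallies are inputs here, not recomputed from
  alignments.
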