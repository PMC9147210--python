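"""Assay-validation statistics.

Truth-set comparison into confusion counts, the five classical
performance metrics, replicate genotype concordance, clinical
sensitivity with documented exclusions, and a pooled-variance two-sample
t-test for comparing observed allele frequencies against population
frequencies.

The five metrics, from TP/TN/FP/FN tallies:

    accuracy     = (TP + TN) / (TP + FP + TN + FN)
    sensitivity  = TP / (TP + FN)
    specificity  = TN / (FP + TN)
    PPV          = TP / (TP + FP)
    NPV          = TN / (TN + FN)

The pooled t-test with group sizes n1, n2:

    S^2 = [ sum_i (x_i - xbar1)^2 + sum_j (x_j - xbar2)^2 ] / (n1 + n2 - 2)
    t   = (xbar1 - xbar2) / sqrt( S^2 (1/n1 + 1/n2) )

with n1 + n2 - 2 degrees of freedom and a two-sided p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .formatting import NA, format_percent, round_percent
from .intervals import IntervalSet, TargetInterval
from .variants import GenotypeCall, VariantKey, variant_class

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "ConcordanceReport",
    "FrequencyTTest",
    "SensitivityReport",
    "Exclusion",
    "compare_callsets",
    "compute_metrics",
    "metrics_table",
    "replicate_concordance",
    "pooled_t_test",
    "category_concordance",
    "clinical_sensitivity",
]

SNV = "snv"
INDEL = "indel"
REPORTABLE = "reportable"
ALL = "all"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies for one variant class in one region stratum."""

    tp: int
    tn: int
    fp: int
    fn: int
    variant_class: str = SNV
    stratum: str = ALL

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass(frozen=True)
class MetricReport:
    """The five performance metrics as raw fractions (None where the
    denominator is zero) plus 2-dp percent display strings."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def formatted(self) -> dict[str, str]:
        return {
            "Accuracy": format_percent(self.accuracy),
            "Sensitivity": format_percent(self.sensitivity),
            "Specificity": format_percent(self.specificity),
            "Positive predictive value": format_percent(self.ppv),
            "Negative predictive value": format_percent(self.npv),
        }


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, specificity, PPV and NPV from confusion
    counts; a metric with a zero denominator is None (printed "NA")."""
    return MetricReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.fp + c.tn),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


# ---------------------------------------------------------------------------
# Truth-set comparison


def _require_normalized(calls: Sequence[GenotypeCall], label: str) -> None:
    from .variants import is_normalized

    for c in calls:
        if not is_normalized(c.ref, c.alt):
            raise ValueError(
                f"{label} callset contains unnormalized alleles at "
                f"{c.chrom}:{c.pos} {c.ref}>{c.alt}; left-align and trim first"
            )


def compare_callsets(
    truth: Sequence[GenotypeCall],
    observed: Sequence[GenotypeCall],
    confident_regions: Sequence[TargetInterval],
    reportable_regions: Sequence[TargetInterval] | None = None,
) -> dict[tuple[str, str], ConfusionCounts]:
    """Compare an observed callset against a truth set within confident
    regions, stratified by variant class and region stratum.

    Variants match on (chrom, pos, ref, alt); both callsets must be
    normalized and decomposed. TP/FN come from truth variants inside the
    confident mask, FP from observed calls inside the mask absent from
    truth, and TN counts targeted confident reference positions carrying
    neither a truth nor an observed variant of that class. The
    ``reportable`` stratum additionally intersects the reportable-region
    mask; results are keyed by (variant_class, stratum).
    """
    if not confident_regions:
        raise ValueError("confident regions must be non-empty")
    _require_normalized(truth, "truth")
    _require_normalized(observed, "observed")

    confident = IntervalSet(confident_regions)
    strata: dict[str, set[tuple[str, int]]] = {ALL: confident.positions()}
    if reportable_regions:
        reportable = IntervalSet(reportable_regions)
        strata[REPORTABLE] = confident.positions() & reportable.positions()

    truth_nonref = [c for c in truth if c.is_non_reference]
    obs_nonref = [c for c in observed if c.is_non_reference]

    out: dict[tuple[str, str], ConfusionCounts] = {}
    for stratum, mask in strata.items():
        t_in = [c for c in truth_nonref if (c.chrom, c.pos) in mask]
        o_in = [c for c in obs_nonref if (c.chrom, c.pos) in mask]
        for vclass in (SNV, INDEL):
            t_keys = {c.key for c in t_in if variant_class(c.ref, c.alt) == vclass}
            o_keys = {c.key for c in o_in if variant_class(c.ref, c.alt) == vclass}
            tp = len(t_keys & o_keys)
            fn = len(t_keys - o_keys)
            fp = len(o_keys - t_keys)
            occupied = {(k[0], k[1]) for k in t_keys | o_keys}
            tn = len(mask) - len(occupied & mask)
            out[(vclass, stratum)] = ConfusionCounts(
                tp=tp, tn=tn, fp=fp, fn=fn, variant_class=vclass, stratum=stratum
            )
    return out


_METRIC_ROWS = [
    "True positives",
    "True negatives",
    "False positives",
    "False negatives",
    "Accuracy",
    "Sensitivity",
    "Specificity",
    "Positive predictive value",
    "Negative predictive value",
]


def metrics_table(counts: Mapping[tuple[str, str], ConfusionCounts]) -> pd.DataFrame:
    """Arrange confusion counts and metrics as a validation table:
    rows TP/TN/FP/FN + five metrics, one column per (stratum, class)."""
    columns = {}
    order = [
        (REPORTABLE, SNV),
        (REPORTABLE, INDEL),
        (ALL, SNV),
        (ALL, INDEL),
    ]
    for stratum, vclass in order:
        c = counts.get((vclass, stratum))
        if c is None:
            continue
        rep = compute_metrics(c).formatted()
        columns[f"{stratum}:{vclass}"] = [
            c.tp,
            c.tn,
            c.fp,
            c.fn,
            rep["Accuracy"],
            rep["Sensitivity"],
            rep["Specificity"],
            rep["Positive predictive value"],
            rep["Negative predictive value"],
        ]
    return pd.DataFrame(columns, index=_METRIC_ROWS)


# ---------------------------------------------------------------------------
# Replicate concordance


@dataclass(frozen=True)
class ConcordanceReport:
    """Genotype agreement across replicates of one sample.

    A union variant key is concordant iff every replicate carries it
    with an identical genotype (same dosage); anything else — absent
    from any replicate, or dosage disagreement — is discordant.
    """

    concordant: int
    discordant: int
    per_replicate_variant_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.concordant < 0 or self.discordant < 0:
            raise ValueError("counts must be non-negative")
        for n in self.per_replicate_variant_counts:
            if n < self.concordant:
                raise ValueError(
                    "a replicate cannot carry fewer variants than the "
                    "number concordant across all replicates"
                )

    @property
    def union_size(self) -> int:
        return self.concordant + self.discordant

    @property
    def concordance(self) -> float | None:
        return _ratio(self.concordant, self.union_size)

    @property
    def concordance_pct(self) -> float | None:
        frac = self.concordance
        return None if frac is None else round_percent(frac)


def replicate_concordance(
    replicates: Sequence[Sequence[GenotypeCall]],
) -> ConcordanceReport:
    """Score genotype concordance across >= 2 replicates of one sample.

    Works over the union of variant keys that are non-reference in any
    replicate; per-replicate counts are each replicate's non-reference
    call count. Order of replicates does not affect the result.
    """
    if len(replicates) < 2:
        raise ValueError(f"need >= 2 replicates, got {len(replicates)}")
    genotype_maps: list[dict[VariantKey, int]] = []
    for rep in replicates:
        genotype_maps.append({c.key: c.dosage for c in rep if c.is_non_reference})
    union: set[VariantKey] = set()
    for gmap in genotype_maps:
        union |= set(gmap)
    concordant = sum(
        1
        for key in union
        if len({gmap.get(key) for gmap in genotype_maps}) == 1
    )
    return ConcordanceReport(
        concordant=concordant,
        discordant=len(union) - concordant,
        per_replicate_variant_counts=tuple(len(g) for g in genotype_maps),
    )


# ---------------------------------------------------------------------------
# Pooled-variance t-test


@dataclass(frozen=True)
class FrequencyTTest:
    """A two-sample equal-variance t-test record."""

    mean_sample: float
    mean_population: float
    n1: int
    n2: int
    pooled_variance: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float

    def rejected(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def pooled_t_test(
    sample_freqs: Sequence[float], population_freqs: Sequence[float]
) -> FrequencyTTest:
    """Two-sample equal-variance (pooled) t-test.

    The pooled variance S^2 divides the summed within-group squared
    deviations by n1 + n2 - 2; the statistic is
    (xbar1 - xbar2) / sqrt(S^2 (1/n1 + 1/n2)) with a two-sided p-value.
    Degenerate S^2 = 0: t is 0 for equal means, signed infinity (p = 0)
    otherwise.
    """
    x1 = np.asarray(sample_freqs, dtype=float)
    x2 = np.asarray(population_freqs, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 values per group, got n1={n1}, n2={n2}")
    m1, m2 = float(x1.mean()), float(x2.mean())
    df = n1 + n2 - 2
    ss = float(((x1 - m1) ** 2).sum() + ((x2 - m2) ** 2).sum())
    s2 = ss / df
    if s2 == 0.0:
        if m1 == m2:
            t, p = 0.0, 1.0
        else:
            t = math.inf if m1 > m2 else -math.inf
            p = 0.0
    else:
        t = (m1 - m2) / math.sqrt(s2 * (1 / n1 + 1 / n2))
        p = 2 * float(sps.t.sf(abs(t), df))
    return FrequencyTTest(
        mean_sample=m1,
        mean_population=m2,
        n1=n1,
        n2=n2,
        pooled_variance=s2,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
    )


def category_concordance(
    tests: Sequence[FrequencyTTest], alpha: float = 0.05
) -> float | None:
    """Percent of alleles whose null (sample frequency = population
    frequency) is NOT rejected at ``alpha``; None ("NA") if no tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not tests:
        return None
    kept = sum(1 for t in tests if not t.rejected(alpha))
    return round_percent(kept / len(tests))


# ---------------------------------------------------------------------------
# Clinical sensitivity


@dataclass(frozen=True)
class Exclusion:
    """One expected item removed from a sensitivity tally, with reason.

    ``detected`` records whether the excluded item had been detected —
    an excluded detection leaves both numerator and denominator, an
    excluded miss leaves the denominator only.
    """

    item: str
    reason: str
    detected: bool


@dataclass(frozen=True)
class SensitivityReport:
    detected: int
    evaluable: int
    exclusions: tuple[Exclusion, ...] = ()

    @property
    def sensitivity(self) -> float | None:
        return _ratio(self.detected, self.evaluable)

    @property
    def sensitivity_pct(self) -> float | None:
        frac = self.sensitivity
        return None if frac is None else round_percent(frac)

    def describe_exclusions(self) -> list[str]:
        return [f"{e.item}: excluded ({e.reason})" for e in self.exclusions]


def clinical_sensitivity(
    detected: int,
    evaluable: int,
    exclusions: Sequence[Exclusion] = (),
) -> SensitivityReport:
    """Detection sensitivity after documented exclusions.

    Starts from raw (detected, evaluable) and removes each exclusion
    from the denominator — and from the numerator when the excluded item
    had been detected.
    """
    if detected > evaluable:
        raise ValueError(f"detected ({detected}) exceeds evaluable ({evaluable})")
    adj_detected = detected - sum(1 for e in exclusions if e.detected)
    adj_evaluable = evaluable - len(exclusions)
    if adj_detected < 0 or adj_evaluable < 0 or adj_detected > adj_evaluable:
        raise ValueError("exclusions inconsistent with the tally")
    return SensitivityReport(adj_detected, adj_evaluable, tuple(exclusions))
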