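"""Per-sample sequencing QC metrics for a targeted panel.

Computes the standard run metrics a targeted assay gates samples on:
total/aligned/duplicate/on-target read tallies, mean depth over
reportable regions, the fraction of targeted bases at >= 20x, coverage
uniformity, and per-interval depth summaries. Uniformity is the percent
of targeted bases whose depth strictly exceeds 0.2 x the sample's mean
depth — a scale-free measure of how evenly the capture performed. A
sample failing any configured gate is flagged for re-sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formatting import round_percent
from .intervals import IntervalSet, TargetInterval

__all__ = [
    "DepthProfile",
    "IntervalDepth",
    "SampleQcMetrics",
    "QcThresholds",
    "QcVerdict",
    "read_depth_tsv",
    "compute_sample_qc",
    "evaluate_qc",
]


@dataclass(frozen=True)
class DepthProfile:
    """Per-base depths over the panel plus read-level tallies.

    ``depths`` maps (chrom, 1-based pos) to read depth; targeted
    positions absent from the mapping count as depth 0 (the
    samtools-depth convention of omitting uncovered positions).
    """

    depths: Mapping[tuple[str, int], int]
    total_reads: int = 0
    aligned_reads: int = 0
    duplicate_reads: int = 0
    on_target_reads: int = 0

    def __post_init__(self) -> None:
        for name in ("total_reads", "aligned_reads", "duplicate_reads", "on_target_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.aligned_reads > self.total_reads:
            raise ValueError("aligned_reads cannot exceed total_reads")
        if self.duplicate_reads > self.aligned_reads:
            raise ValueError("duplicate_reads cannot exceed aligned_reads")

    def depth_at(self, chrom: str, pos: int) -> int:
        return self.depths.get((chrom, pos), 0)


@dataclass(frozen=True)
class IntervalDepth:
    interval: TargetInterval
    mean_depth: float
    min_depth: int
    passes_20x: bool


@dataclass(frozen=True)
class SampleQcMetrics:
    total_reads: int
    aligned_pct: float
    duplicate_pct: float
    on_target_pct: float
    avg_base_depth: float  # over reportable intervals
    pct_bases_ge_20x: float
    uniformity_pct: float
    per_interval: tuple[IntervalDepth, ...] = ()

    def as_row(self) -> dict[str, float | int]:
        """Metrics in the conventional QC-table column order."""
        return {
            "Uniformity %": round_percent(self.uniformity_pct / 100),
            "Aligned %": round_percent(self.aligned_pct / 100),
            "Duplicate %": round_percent(self.duplicate_pct / 100),
            "On Target %": round_percent(self.on_target_pct / 100),
            "Total Reads": self.total_reads,
            "Avg. Base Depth": round(self.avg_base_depth, 2),
            "Base Depth>=20x": round_percent(self.pct_bases_ge_20x / 100),
        }


def read_depth_tsv(path: str | Path) -> dict[tuple[str, int], int]:
    """Read a samtools-depth style TSV (chrom, 1-based pos, depth)."""
    depths: dict[tuple[str, int], int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: need 3 columns (chrom, pos, depth)")
        depths[(fields[0], int(fields[1]))] = int(fields[2])
    return depths


def compute_sample_qc(
    profile: DepthProfile,
    targets: Sequence[TargetInterval],
    *,
    uniformity_factor: float = 0.2,
    depth_threshold: int = 20,
    interval_rule: str = "mean",
    on_target_of: str = "aligned",
) -> SampleQcMetrics:
    """Compute per-sample QC metrics over the targeted intervals.

    ``interval_rule`` decides whether an interval "passes 20x" by its
    mean or its minimum depth. ``on_target_of`` sets the denominator for
    the on-target rate ("aligned" or "total"); aligned/duplicate rates
    are always fractions of total reads.
    """
    if not targets:
        raise ValueError("empty target set")
    if interval_rule not in ("mean", "min"):
        raise ValueError(f"interval_rule must be 'mean' or 'min', got {interval_rule!r}")
    if on_target_of not in ("aligned", "total"):
        raise ValueError(f"on_target_of must be 'aligned' or 'total', got {on_target_of!r}")

    iset = IntervalSet(targets)
    target_depths = np.array(
        [profile.depth_at(c, p) for c, p in sorted(iset.positions())], dtype=float
    )
    mean_depth = float(target_depths.mean())
    uniformity = float(np.mean(target_depths > uniformity_factor * mean_depth)) * 100
    pct_ge = float(np.mean(target_depths >= depth_threshold)) * 100

    per_interval = []
    for iv in targets:
        d = np.array([profile.depth_at(iv.chrom, p) for p in iv.vcf_positions()], dtype=float)
        iv_mean = float(d.mean())
        iv_min = int(d.min())
        gate = iv_mean if interval_rule == "mean" else iv_min
        per_interval.append(IntervalDepth(iv, iv_mean, iv_min, gate >= depth_threshold))

    reportable = IntervalSet([iv for iv in targets if iv.reportable])
    if reportable.n_bases:
        rep_depths = [profile.depth_at(c, p) for c, p in reportable.positions()]
        avg_base_depth = float(np.mean(rep_depths))
    else:
        avg_base_depth = float("nan")

    total = profile.total_reads
    aligned_pct = 100 * profile.aligned_reads / total if total else 0.0
    duplicate_pct = 100 * profile.duplicate_reads / total if total else 0.0
    on_target_den = profile.aligned_reads if on_target_of == "aligned" else total
    on_target_pct = 100 * profile.on_target_reads / on_target_den if on_target_den else 0.0

    return SampleQcMetrics(
        total_reads=total,
        aligned_pct=aligned_pct,
        duplicate_pct=duplicate_pct,
        on_target_pct=on_target_pct,
        avg_base_depth=avg_base_depth,
        pct_bases_ge_20x=pct_ge,
        uniformity_pct=uniformity,
        per_interval=tuple(per_interval),
    )


@dataclass(frozen=True)
class QcThresholds:
    """Sample-level QC gates. A sample crossing any gate is flagged for
    re-sequencing. Values are package defaults, not published ones."""

    min_uniformity_pct: float = 90.0
    min_aligned_pct: float = 95.0
    max_duplicate_pct: float = 10.0
    min_pct_bases_ge_20x: float = 85.0
    min_avg_base_depth: float | None = None
    min_on_target_pct: float | None = None

    _KNOWN = (
        "min_uniformity_pct",
        "min_aligned_pct",
        "max_duplicate_pct",
        "min_pct_bases_ge_20x",
        "min_avg_base_depth",
        "min_on_target_pct",
    )

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "QcThresholds":
        unknown = set(data) - set(cls._KNOWN)
        if unknown:
            raise ValueError(f"unknown QC threshold(s): {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class QcVerdict:
    passed: bool
    failing_metrics: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (not self.failing_metrics):
            raise ValueError("verdict passes iff no failing metrics")


# (metric name, threshold attribute, direction) in stable report order.
_CHECKS = (
    ("uniformity_pct", "min_uniformity_pct", "min"),
    ("aligned_pct", "min_aligned_pct", "min"),
    ("duplicate_pct", "max_duplicate_pct", "max"),
    ("on_target_pct", "min_on_target_pct", "min"),
    ("pct_bases_ge_20x", "min_pct_bases_ge_20x", "min"),
    ("avg_base_depth", "min_avg_base_depth", "min"),
)


def evaluate_qc(
    metrics: SampleQcMetrics, thresholds: QcThresholds = QcThresholds()
) -> QcVerdict:
    """Gate a sample on its QC metrics; failures listed in stable order."""
    failing = []
    for metric, attr, direction in _CHECKS:
        limit = getattr(thresholds, attr)
        if limit is None:
            continue
        value = getattr(metrics, metric)
        bad = value < limit if direction == "min" else value > limit
        if bad:
            failing.append(metric)
    return QcVerdict(passed=not failing, failing_metrics=tuple(failing))
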