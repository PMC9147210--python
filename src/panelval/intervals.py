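"""Target/reportable interval handling.

Intervals follow the BED dialect: 0-based start, half-open end. VCF
positions are 1-based. :func:`vcf_pos_to_bed` / :func:`bed_pos_to_vcf`
are the single place that conversion lives; everything else asks
"does this 1-based position fall in these intervals" through
:class:`IntervalSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "TargetInterval",
    "IntervalSet",
    "read_bed",
    "write_bed",
    "vcf_pos_to_bed",
    "bed_pos_to_vcf",
]


def vcf_pos_to_bed(pos: int) -> int:
    """1-based VCF position -> 0-based BED coordinate."""
    return pos - 1


def bed_pos_to_vcf(coord: int) -> int:
    """0-based BED coordinate -> 1-based VCF position."""
    return coord + 1


@dataclass(frozen=True)
class TargetInterval:
    """One targeted region (BED dialect: 0-based half-open)."""

    chrom: str
    start: int
    end: int
    label: str | None = None
    reportable: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative interval start: {self.start}")

    def contains_vcf_pos(self, chrom: str, pos: int) -> bool:
        """Membership test for a 1-based VCF position."""
        return chrom == self.chrom and self.start <= vcf_pos_to_bed(pos) < self.end

    @property
    def width(self) -> int:
        return self.end - self.start

    def vcf_positions(self) -> Iterator[int]:
        """Iterate the 1-based positions covered by this interval."""
        return iter(range(self.start + 1, self.end + 1))


class IntervalSet:
    """A queryable collection of :class:`TargetInterval`.

    Membership is by exact per-position lookup (panels here are small);
    overlapping intervals are tolerated and de-duplicated positionally.
    """

    def __init__(self, intervals: Iterable[TargetInterval]):
        self.intervals: list[TargetInterval] = list(intervals)
        self._positions: set[tuple[str, int]] = {
            (iv.chrom, pos) for iv in self.intervals for pos in iv.vcf_positions()
        }

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[TargetInterval]:
        return iter(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position lies in any interval."""
        return (chrom, pos) in self._positions

    def positions(self) -> set[tuple[str, int]]:
        """Distinct (chrom, 1-based pos) pairs covered by the set."""
        return set(self._positions)

    @property
    def n_bases(self) -> int:
        """Number of distinct targeted bases (overlaps counted once)."""
        return len(self._positions)


def read_bed(path: str | Path) -> list[TargetInterval]:
    """Read a 3+ column BED file; column 4 is the label, column 5 (if
    present) marks reportability ("1"/"reportable" true, else false)."""
    out: list[TargetInterval] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED line needs >=3 columns: {raw!r}")
        label = fields[3] if len(fields) > 3 and fields[3] != "." else None
        reportable = True
        if len(fields) > 4:
            reportable = fields[4].lower() in {"1", "true", "reportable", "yes"}
        out.append(
            TargetInterval(fields[0], int(fields[1]), int(fields[2]), label, reportable)
        )
    return out


def write_bed(intervals: Iterable[TargetInterval], path: str | Path) -> None:
    lines = []
    for iv in intervals:
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    iv.label or ".",
                    "1" if iv.reportable else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
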