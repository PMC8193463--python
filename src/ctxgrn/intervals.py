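"""Core genomic domain types: intervals, genes, evidence tracks, abundances.

All coordinates are 0-based half-open (BED convention) internally; formats
using other conventions are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional

from intervaltree import IntervalTree

GENE_TYPES = ("TF", "miRNA", "coding", "noncoding")
TRACK_KINDS = ("methylation", "accessibility", "histone_mark", "chip_peak", "tfbs")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open, 0-based genomic span with optional name/score/strand."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in interval {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end} (start must be < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand {self.strand!r}")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    @property
    def coord_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:  # used in edge-list evidence columns
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what network construction needs: TSS, strand, type.

    ``tss`` is the 5'-most transcribed position in 0-based coordinates
    (feature start for + strand genes, feature end - 1 for - strand).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_type: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")
        if self.gene_type not in GENE_TYPES:
            raise ValueError(f"gene {self.gene_id}: unknown gene_type {self.gene_type!r}")

    def upstream_window(self, d: int) -> tuple:
        """Strand-aware upstream window of width ``d``, half-open at the TSS.

        + strand: [TSS - d, TSS); - strand: (TSS, TSS + d] i.e. the half-open
        span [TSS + 1, TSS + d + 1). Clipped at position 0. May be empty
        (start == end) for a + strand gene with TSS at 0.
        """
        if d <= 0:
            raise ValueError("window width d must be positive")
        if self.strand == "+":
            return (self.chrom, max(0, self.tss - d), self.tss)
        return (self.chrom, self.tss + 1, self.tss + d + 1)


class EvidenceTrack:
    """A named collection of genomic intervals with fast overlap queries.

    Backed by one interval tree per chromosome. Intervals are stored in
    input order; overlap queries return every stored interval intersecting
    the half-open query span by at least 1 bp.
    """

    def __init__(self, label: str, kind: str, intervals: Iterable[GenomicInterval] = ()):
        if kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {kind!r}")
        self.label = label
        self.kind = kind
        self.intervals: List[GenomicInterval] = list(intervals)
        self._trees: Dict[str, IntervalTree] = {}
        # payload carries the input index so exact duplicates stay distinct
        for i, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (i, iv))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def chroms(self) -> set:
        return set(self._trees)

    def overlapping(self, chrom: str, start: int, end: int) -> List[GenomicInterval]:
        """All intervals intersecting [start, end) on ``chrom``."""
        if start >= end:
            return []
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(node.data for node in tree.overlap(start, end))
        return [iv for _, iv in sorted(hits, key=lambda t: (t[1].start, t[1].end, t[0]))]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        if start >= end:
            return False
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def deduplicated(self) -> "EvidenceTrack":
        """Drop exact-coordinate duplicate intervals (first occurrence kept)."""
        seen = set()
        kept = []
        for iv in self.intervals:
            if iv.coord_key not in seen:
                seen.add(iv.coord_key)
                kept.append(iv)
        return EvidenceTrack(self.label, self.kind, kept)


@dataclass
class AbundanceTable:
    """gene_id -> non-negative abundance (counts, RPKM or FPKM as provided)."""

    values: Dict[str, float] = field(default_factory=dict)
    label: str = "expression"

    def __post_init__(self) -> None:
        for gid, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative abundance for {gid}: {v}")

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def get(self, gene_id: str, default: float = 0.0) -> float:
        return self.values.get(gene_id, default)

    def is_expressed(self, gene_id: str, threshold: float = 0.0) -> bool:
        """Strictly-greater-than-threshold rule; absent genes are not expressed."""
        return self.values.get(gene_id, 0.0) > threshold

    def total(self) -> float:
        return float(sum(self.values.values()))


def check_chrom_consistency(tracks: Iterable[EvidenceTrack], genes: Iterable[GeneModel]) -> List[str]:
    """Warn about chromosomes present in evidence but absent from the annotation.

    Chromosome names are matched by exact string comparison; no prefix
    aliasing is attempted. Returns the offending chromosome names.
    """
    gene_chroms = {g.chrom for g in genes}
    orphans = sorted(
        {c for t in tracks for c in t.chroms if c not in gene_chroms}
    )
    if orphans:
        warnings.warn(
            "evidence tracks cover chromosomes absent from the annotation: "
            + ", ".join(orphans),
            stacklevel=2,
        )
    return orphans
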