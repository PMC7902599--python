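"""Genomic interval model, locus grouping and annotation-overlap queries.

Coordinates are 0-based half-open internally; GTF/GFF3's 1-based inclusive
convention is converted at I/O time only.  "Overlap" always means at least
one shared base; transcript overlap tests are exon-level, reference genes
are treated as whole gene bodies.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}

#: biotype tags understood by :class:`AnnotationSet`
BIOTYPES = {"protein_coding", "other_gene", "TE"}


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Bases strictly between the intervals; 0 on overlap; None across chroms."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass
class TranscriptModel:
    """One assembled transcript (TCONS): an exon chain on one chrom/strand."""

    tcons_id: str
    exons: list[GenomicInterval]
    strand: str = "."
    xloc_id: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.tcons_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"{self.tcons_id}: exons span chromosomes {chroms}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.tcons_id}: overlapping exons")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exonic_overlap(self, other: "TranscriptModel", stranded: bool = False) -> bool:
        """Exon-level overlap; strand restricts only when both strands known."""
        if self.chrom != other.chrom:
            return False
        if (
            stranded
            and self.strand != "."
            and other.strand != "."
            and self.strand != other.strand
        ):
            return False
        for a in self.exons:
            for b in other.exons:
                if a.overlaps(b):
                    return True
        return False


@dataclass
class AnnotationSet:
    """Reference features tagged with a biotype, indexed for overlap/nearest.

    The interval-tree index is an implementation detail; by construction it
    returns exactly what a linear scan over ``features`` returns.
    """

    features: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _starts: dict[str, list[tuple[int, int]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for iv, biotype in self.features:
            if biotype not in BIOTYPES:
                raise ValueError(f"unknown biotype {biotype!r}")
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, biotype)
        # sorted (start, end) per chrom for nearest-gap queries
        for chrom, tree in self._trees.items():
            self._starts[chrom] = sorted((i.begin, i.end) for i in tree)

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, biotypes: set[str]) -> "AnnotationSet":
        return AnnotationSet([(iv, b) for iv, b in self.features if b in biotypes])

    def overlapping(self, query: GenomicInterval) -> list[tuple[GenomicInterval, str]]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return [
            (GenomicInterval(query.chrom, h.begin, h.end), h.data)
            for h in sorted(tree.overlap(query.start, query.end))
        ]

    def any_overlap(self, intervals: list[GenomicInterval]) -> bool:
        return any(self.overlapping(iv) for iv in intervals)

    def nearest_distance(self, query: GenomicInterval) -> int | None:
        """Gap (bp strictly between) to the closest feature; 0 on overlap.

        Returns None when the set holds no feature on ``query.chrom`` —
        callers must treat that as "distance undefined".
        """
        ivs = self._starts.get(query.chrom)
        if not ivs:
            return None
        if self.overlapping(query):
            return 0
        best: int | None = None
        # candidate neighbours around the insertion point; ends are not
        # sorted with starts so widen the scan window on the left
        i = bisect.bisect_left(ivs, (query.start, -1))
        for s, e in ivs[max(0, i - len(ivs)): i]:
            gap = query.start - e
            if gap >= 0 and (best is None or gap < best):
                best = gap
        for s, e in ivs[i:]:
            gap = s - query.end
            if gap >= 0:
                if best is None or gap < best:
                    best = gap
                break
        return best


def group_into_loci(
    transcripts: list[TranscriptModel], stranded: bool = True, prefix: str = "XLOC"
) -> dict[str, str]:
    """Assign cuffmerge-style locus (XLOC) identifiers to transcripts.

    Two transcripts share a locus iff they are connected by a chain of
    pairwise exonic overlaps on the same chromosome.  When ``stranded`` is
    true, overlap requires matching strands, but only where both strands
    are known (non-strand-specific models with strand '.' join either).
    Identifiers are assigned by leftmost coordinate, so the numbering is
    deterministic for a given input set.

    Returns a mapping ``tcons_id -> xloc_id`` and also writes ``xloc_id``
    onto each model in place.
    """
    n = len(transcripts)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # sweep per chromosome to avoid the full quadratic comparison
    order = sorted(range(n), key=lambda i: (transcripts[i].chrom, transcripts[i].start))
    active: list[int] = []
    for idx in order:
        t = transcripts[idx]
        active = [
            j for j in active
            if transcripts[j].chrom == t.chrom and transcripts[j].end > t.start
        ]
        for j in active:
            if t.exonic_overlap(transcripts[j], stranded=stranded):
                union(idx, j)
        active.append(idx)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    keyed = sorted(
        clusters.values(),
        key=lambda idxs: min((transcripts[i].chrom, transcripts[i].start) for i in idxs),
    )
    assignment: dict[str, str] = {}
    for k, idxs in enumerate(keyed, start=1):
        xloc = f"{prefix}_{k:06d}"
        for i in idxs:
            transcripts[i].xloc_id = xloc
            assignment[transcripts[i].tcons_id] = xloc
    return assignment


def classify_novelty(
    exons: list[GenomicInterval],
    tair_like: AnnotationSet,
    araport_like: AnnotationSet,
) -> str:
    """Novelty of a locus against the older and the newer gene annotation.

    Any exonic bp of overlap with a gene of the older (TAIR10-like)
    annotation makes the locus 'known' — such loci are excluded from the
    novel cohort.  Otherwise overlap with the newer (Araport11-like)
    annotation makes it 'recent'; with neither it is 'novel'.
    """
    gene_types = {"protein_coding", "other_gene"}
    if tair_like.subset(gene_types).any_overlap(exons):
        return "known"
    if araport_like.subset(gene_types).any_overlap(exons):
        return "recent"
    return "novel"


def distance_to_nearest_gene(
    exons: list[GenomicInterval], genes: AnnotationSet
) -> int:
    """Gap between the locus span and the nearest gene body; 0 on overlap.

    Raises ValueError when the annotation holds no feature on the locus
    chromosome (distance undefined).
    """
    chrom = exons[0].chrom
    span = GenomicInterval(chrom, min(e.start for e in exons), max(e.end for e in exons))
    d = genes.nearest_distance(span)
    if d is None:
        raise ValueError(f"no annotated gene on {chrom}: distance undefined")
    return d


def te_overlap(exons: list[GenomicInterval], te_set: AnnotationSet) -> bool:
    """True iff any exon shares >= 1 bp with a transposable-element feature."""
    return te_set.subset({"TE"}).any_overlap(exons)
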