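"""Replichore partitioning of circular bacterial chromosomes.

A circular chromosome replicates bidirectionally from the origin (ori) to
the terminus (ter), splitting the molecule into two arcs (replichores). On
the arc running ori -> ter in the direction of increasing published-sequence
coordinates, the published (+) strand is the leading strand; on the
complementary arc ter -> ori the leading strand is the reverse complement of
the published strand.

This module owns that partition: building the two arcs from ori/ter,
classifying genes as leading- or lagging-strand by their midpoint, and
counting bases on the composite leading strand (published-strand bases over
the first arc plus complemented bases over the second).

Coordinates are 0-based half-open throughout; conversion from 1-based GFF3
happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidCoordinatesError, SequenceAlphabetError, UndefinedStatisticError

LEADING = "leading"
LAGGING = "lagging"

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
# IUPAC one-letter nucleotide codes; everything outside ACGT counts as ambiguous
IUPAC_ALPHABET = set("ACGTRYSWKMBDHVN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene locus on the published sequence.

    ``start``/``end`` are 0-based half-open. A gene spanning the circular
    origin of coordinates carries ``wraps=True`` and covers
    [start, length) + [0, end).
    """

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    cog_groups: tuple = ()  # of (group_id, subcategory-letter string)
    kegg_pathways: tuple = ()
    wraps: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InvalidCoordinatesError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.wraps and self.start >= self.end:
            raise InvalidCoordinatesError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end} "
                "on a non-wrapping gene"
            )

    def span(self, length: int) -> int:
        if self.wraps:
            return length - self.start + self.end
        return self.end - self.start

    def midpoint(self, length: int) -> int:
        """Gene midpoint, modulo chromosome length for wrapping genes."""
        return (self.start + self.span(length) // 2) % length


@dataclass
class GenomeRecord:
    """One circular chromosome with sequence, replication coordinates, genes."""

    genome_id: str
    sequence: str
    ori: int
    ter: int
    genes: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.sequence)
        if not (0 <= self.ori < n and 0 <= self.ter < n):
            raise InvalidCoordinatesError(
                f"{self.genome_id}: ori/ter ({self.ori}, {self.ter}) outside "
                f"[0, {n})"
            )
        if self.ori == self.ter:
            raise InvalidCoordinatesError(
                f"{self.genome_id}: ori == ter == {self.ori}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReplichoreMap:
    """The two arcs of a circular chromosome.

    arc1 = [ori, ter) in published coordinates, leading strand on the
    published (+) strand; arc2 = [ter, ori), leading strand on the reverse
    complement. Arcs wrap modulo ``length``.
    """

    ori: int
    ter: int
    length: int

    @property
    def arc1_len(self) -> int:
        return (self.ter - self.ori) % self.length

    @property
    def arc2_len(self) -> int:
        return (self.ori - self.ter) % self.length

    def in_arc1(self, position: int) -> bool:
        return (position - self.ori) % self.length < self.arc1_len

    def arc1_intervals(self) -> list[tuple[int, int]]:
        """arc1 as non-wrapping half-open intervals in published coordinates."""
        return _unwrap(self.ori, self.ter, self.length)

    def arc2_intervals(self) -> list[tuple[int, int]]:
        return _unwrap(self.ter, self.ori, self.length)


def _unwrap(a: int, b: int, length: int) -> list[tuple[int, int]]:
    if a < b:
        return [(a, b)]
    parts = []
    if a < length:
        parts.append((a, length))
    if b > 0:
        parts.append((0, b))
    return parts


@dataclass(frozen=True)
class BaseCounts:
    """Base tallies over a (composite leading) strand."""

    A: int = 0
    C: int = 0
    G: int = 0
    T: int = 0
    n_ambiguous: int = 0

    @property
    def total_unambiguous(self) -> int:
        return self.A + self.C + self.G + self.T

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(
            self.A + other.A,
            self.C + other.C,
            self.G + other.G,
            self.T + other.T,
            self.n_ambiguous + other.n_ambiguous,
        )

    def complemented(self) -> "BaseCounts":
        return BaseCounts(self.T, self.G, self.C, self.A, self.n_ambiguous)


def build_replichore_map(ori: int, ter: int, length: int) -> ReplichoreMap:
    """Partition a circular chromosome of ``length`` bp at ori and ter."""
    if length <= 0:
        raise InvalidCoordinatesError(f"length must be positive, got {length}")
    if not (0 <= ori < length and 0 <= ter < length):
        raise InvalidCoordinatesError(
            f"ori/ter ({ori}, {ter}) out of range [0, {length})"
        )
    if ori == ter:
        raise InvalidCoordinatesError("ori and ter coincide")
    return ReplichoreMap(ori=ori, ter=ter, length=length)


def classify_gene(gene: GeneAnnotation, rmap: ReplichoreMap) -> str:
    """Classify a gene as leading- or lagging-strand by its midpoint.

    A gene is leading iff it is coded on the leading strand of the arc its
    midpoint falls in: '+' genes in arc1 and '-' genes in arc2.
    """
    mid_in_arc1 = rmap.in_arc1(gene.midpoint(rmap.length))
    if (gene.strand == "+") == mid_in_arc1:
        return LEADING
    return LAGGING


def _seq_counts(seq_bytes: np.ndarray, offset: int = 0) -> BaseCounts:
    counts = np.bincount(seq_bytes, minlength=256)
    a, c, g, t = (int(counts[ord(ch)]) for ch in "ACGT")
    known = a + c + g + t
    ambiguous = int(seq_bytes.size - known)
    if ambiguous:
        amb = 0
        for ch in "RYSWKMBDHVN":
            amb += int(counts[ord(ch)])
        if amb != ambiguous:
            bad = ~np.isin(seq_bytes, np.frombuffer(b"ACGTRYSWKMBDHVN", np.uint8))
            pos = int(np.argmax(bad))
            raise SequenceAlphabetError(offset + pos, chr(int(seq_bytes[pos])))
    return BaseCounts(A=a, C=c, G=g, T=t, n_ambiguous=ambiguous)


def leading_strand_counts(record: GenomeRecord, rmap: ReplichoreMap) -> BaseCounts:
    """Count bases of the composite leading strand.

    Published-strand bases over arc1, plus complemented bases over arc2.
    Ambiguity codes are tallied in ``n_ambiguous``; characters outside the
    IUPAC alphabet raise :class:`SequenceAlphabetError` with their position.
    """
    if record.length != rmap.length:
        raise InvalidCoordinatesError(
            f"{record.genome_id}: sequence length {record.length} != map "
            f"length {rmap.length}"
        )
    seq = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    total = BaseCounts()
    for lo, hi in rmap.arc1_intervals():
        total = total + _seq_counts(seq[lo:hi], offset=lo)
    for lo, hi in rmap.arc2_intervals():
        total = total + _seq_counts(seq[lo:hi], offset=lo).complemented()
    return total


def gene_density_leading(genes: list, rmap: ReplichoreMap) -> float:
    """Fraction of genes classified as leading-strand."""
    if not genes:
        raise UndefinedStatisticError("gene density undefined for an empty gene list")
    n_leading = sum(1 for g in genes if classify_gene(g, rmap) == LEADING)
    return n_leading / len(genes)
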