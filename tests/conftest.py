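"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's interval arithmetic:
replichore membership is resolved by walking positions from ori in the
fork direction, leading-strand counts by classifying and complementing one
base at a time, and Spearman by an O(n^2) midrank + plain Pearson formula.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from strandbias.replichore import GeneAnnotation, GenomeRecord

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def arc1_positions_bruteforce(ori: int, ter: int, length: int) -> set:
    """Walk from ori in the fork direction until ter; those positions are arc1."""
    positions = set()
    p = ori
    while p != ter:
        positions.add(p)
        p = (p + 1) % length
    return positions


def leading_counts_bruteforce(sequence: str, ori: int, ter: int) -> dict:
    """Per-position classify-then-complement tally of the leading strand."""
    length = len(sequence)
    arc1 = arc1_positions_bruteforce(ori, ter, length)
    counts = {"A": 0, "C": 0, "G": 0, "T": 0, "n_ambiguous": 0}
    for p, base in enumerate(sequence):
        if base not in "ACGT":
            counts["n_ambiguous"] += 1
            continue
        counts[base if p in arc1 else COMPLEMENT[base]] += 1
    return counts


def spearman_bruteforce(x, y) -> float:
    """Midranks computed by counting, then the textbook Pearson formula."""

    def midranks(v):
        return [
            sum(1 for u in v if u < w) + (sum(1 for u in v if u == w) + 1) / 2
            for w in v
        ]

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def random_genome(rng, length=None, n_genes=None) -> GenomeRecord:
    """A small random genome with uniform bases and random gene intervals."""
    length = length or int(rng.integers(200, 2000))
    n_genes = n_genes if n_genes is not None else int(rng.integers(3, 12))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    ori, ter = 0, 0
    while ori == ter:
        ori, ter = int(rng.integers(0, length)), int(rng.integers(0, length))
    genes = []
    for i in range(n_genes):
        glen = int(rng.integers(30, max(31, length // 4)))
        start = int(rng.integers(0, length - glen))
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i}",
                start=start,
                end=start + glen,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return GenomeRecord(
        genome_id="rand", sequence=seq, ori=ori, ter=ter, genes=genes
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
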