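"""Per-genome strand composition statistics.

The composition-bias score of a genome is

    score = (|G - C| + |T - A|) / chromosome length

with G, C, T, A counted on the composite leading strand. By base
complementarity the lagging strand yields the same score. A genome whose
strands obey Chargaff's second parity rule (A ~ T, G ~ C within a strand)
scores near zero; strong replication-associated mutation bias pushes the
score up.

The recombination-counteraction indices gcRF and taRF summarise how
uniformly that bias is expressed across the leading-strand genes: for the
per-gene skews (Gi - Ci)/Li (resp. (Ti - Ai)/Li) of the N leading genes,

    RF = [ sum_i (skew_i - mean)^2 / (N - 1) ] / mean

i.e. the sample variance of the per-gene skews divided by their mean.
Rearrangements that move genes between strands mix positive- and
negative-skew genes, inflating the variance and deflating the mean, so
higher RF indicates more bias-counteracting recombination. A
coefficient-of-variation variant (standard deviation over mean) is
available via ``variant="sd_over_mean"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import UndefinedStatisticError
from .replichore import (
    LEADING,
    BaseCounts,
    GeneAnnotation,
    ReplichoreMap,
    classify_gene,
    reverse_complement,
)

RF_VARIANTS = ("variance_over_mean", "sd_over_mean")


@dataclass(frozen=True)
class SkewVector:
    """Per-gene skew values for the leading-strand genes of one genome."""

    values: tuple
    gene_ids: tuple = ()

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RFResult:
    mean_skew: float
    rf: float


def composition_bias_score(counts: BaseCounts, length: int) -> float:
    """(|G - C| + |T - A|) / length, bases counted on the leading strand.

    Ambiguous bases are excluded from the numerator tallies but the
    denominator stays the full chromosome length.
    """
    if length <= 0:
        raise UndefinedStatisticError("score undefined for zero-length chromosome")
    return (abs(counts.G - counts.C) + abs(counts.T - counts.A)) / length


def gc_content(counts: BaseCounts) -> float:
    """(G + C) / (A + C + G + T) over unambiguous bases."""
    total = counts.total_unambiguous
    if total == 0:
        raise UndefinedStatisticError("GC content undefined: no unambiguous bases")
    return (counts.G + counts.C) / total


def _gene_leading_sequence(gene: GeneAnnotation, sequence: str) -> str:
    """The gene's coding-orientation sequence (= leading-strand reading for
    leading genes)."""
    length = len(sequence)
    if gene.wraps:
        raw = sequence[gene.start:] + sequence[: gene.end]
    else:
        raw = sequence[gene.start : gene.end]
    assert len(raw) == gene.span(length)
    return raw if gene.strand == "+" else reverse_complement(raw)


def per_gene_skews(
    genes: list, sequence: str, rmap: ReplichoreMap
) -> tuple[SkewVector, SkewVector]:
    """GC and TA skew per leading-strand gene.

    Lagging genes are excluded; each leading gene contributes
    (G - C)/L and (T - A)/L computed on its coding-orientation sequence,
    where L is the number of unambiguous bases. Genes whose sequence is
    entirely ambiguous are dropped.
    """
    gc_vals, ta_vals, ids = [], [], []
    for gene in genes:
        if classify_gene(gene, rmap) != LEADING:
            continue
        seq = _gene_leading_sequence(gene, sequence)
        g, c, t, a = seq.count("G"), seq.count("C"), seq.count("T"), seq.count("A")
        li = g + c + t + a
        if li == 0:
            continue
        gc_vals.append((g - c) / li)
        ta_vals.append((t - a) / li)
        ids.append(gene.gene_id)
    if not gc_vals:
        raise UndefinedStatisticError("no leading-strand genes with countable bases")
    ids = tuple(ids)
    return SkewVector(tuple(gc_vals), ids), SkewVector(tuple(ta_vals), ids)


def rf_index(skews: SkewVector, variant: str = "variance_over_mean") -> RFResult:
    """Dispersion-over-mean of a per-gene skew vector.

    Returns ``rf = s^2 / mean`` (sample variance, N-1 denominator) or, with
    ``variant="sd_over_mean"``, the coefficient of variation ``s / mean``.
    A zero mean leaves RF undefined and raises.
    """
    if variant not in RF_VARIANTS:
        raise ValueError(f"unknown rf variant {variant!r}; choose from {RF_VARIANTS}")
    n = skews.n
    if n < 2:
        raise UndefinedStatisticError(f"RF needs >= 2 leading genes, got {n}")
    mean = sum(skews.values) / n
    if mean == 0.0:
        raise UndefinedStatisticError("RF undefined: mean skew is exactly zero")
    var = sum((v - mean) ** 2 for v in skews.values) / (n - 1)
    disp = var if variant == "variance_over_mean" else math.sqrt(var)
    return RFResult(mean_skew=mean, rf=disp / mean)
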