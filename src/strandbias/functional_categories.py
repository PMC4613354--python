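"""COG functional-category and KEGG pathway statistics.

COG ortholog groups carry one-letter functional subcategories (A-Z); the
regulatory/unknown-function letters R, S and X are excluded throughout. A
genome's pCOG vector is the fraction of its (gene, letter) assignments in
each retained subcategory. At cohort level, genomes are split into a
strong-biased group (SBG, the top half by composition-bias score) and a
weak-biased group (WBG); for each COG ortholog group the ratio of SBG to
WBG gene counts (Diff_SBG/WBG) measures how concentrated the group is in
strongly biased genomes, and the per-subcategory mean of those ratios is
the AVDT (average value of discrepant times). Groups with ratio > 5 are
strong-biased COG groups (SCOGs), ratio < 0.2 weak-biased (WCOGs); each
genome's SCOG/WCOG proportions then become cohort features.

KEGG side: the fraction of a genome's annotated genes in each of the ten
replication-and-repair pathway classes.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

from .errors import ParseError, UndefinedStatisticError

logger = logging.getLogger(__name__)

EXCLUDED_SUBCATEGORIES = frozenset("RSX")
COG_SUBCATEGORIES = tuple(
    ch for ch in "ABCDEFGHIJKLMNOPQTUVWYZ"  # A..Z minus R, S, X
)

#: The ten KEGG replication-and-repair pathway classes: DNA replication,
#: DNA replication proteins, chromosome and associated proteins, DNA repair
#: and recombination proteins, base excision repair, nucleotide excision
#: repair, mismatch repair, homologous recombination, non-homologous
#: end-joining, Fanconi anemia pathway.
REPAIR_PATHWAYS = (
    "ko03030",
    "ko03032",
    "ko03036",
    "ko03400",
    "ko03410",
    "ko03420",
    "ko03430",
    "ko03440",
    "ko03450",
    "ko03460",
)

DIFF_HI_DEFAULT = 5.0
DIFF_LO_DEFAULT = 0.2


@dataclass(frozen=True)
class DiffRecord:
    """SBG:WBG gene-count ratio for one COG ortholog group (or subcategory)."""

    cog_group_id: str
    n_sbg: int
    n_wbg: int
    ratio: float


@dataclass(frozen=True)
class AVDTRecord:
    subcategory: str
    avdt: float
    n_groups: int


@dataclass(frozen=True)
class COGGroupSets:
    scog_ids: frozenset
    wcog_ids: frozenset


def filter_letters(letters: str) -> str:
    """Drop the excluded subcategory letters R, S, X."""
    return "".join(ch for ch in letters if ch not in EXCLUDED_SUBCATEGORIES)


def pcog(assignments: list) -> dict:
    """Per-subcategory fractions from (gene_id, subcategory-letters) pairs.

    Each (gene, letter) pair counts once; a multi-letter assignment such as
    "KL" contributes one count to K and one to L. Letters R, S, X are
    dropped before counting. The returned dict covers all 23 retained
    letters and sums to 1.
    """
    counts: Counter = Counter()
    for _gene_id, letters in assignments:
        for ch in filter_letters(letters):
            if ch not in COG_SUBCATEGORIES:
                raise ParseError(f"unknown COG subcategory letter {ch!r}")
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise UndefinedStatisticError(
            "pCOG undefined: no assignments survive the R/S/X filter"
        )
    return {ch: counts[ch] / total for ch in COG_SUBCATEGORIES}


def split_cohort(scores: list) -> tuple[list, list]:
    """Split (genome_id, score) pairs into SBG (top floor(N/2)) and WBG.

    Ties are broken by genome_id lexicographic order so the split is
    deterministic. With N = 1111 the SBG holds 555 genomes.
    """
    if len(scores) < 2:
        raise UndefinedStatisticError("cohort split needs >= 2 genomes")
    ordered = sorted(scores, key=lambda gs: (-gs[1], gs[0]))
    k = len(ordered) // 2
    sbg = [gid for gid, _ in ordered[:k]]
    wbg = [gid for gid, _ in ordered[k:]]
    return sbg, wbg


def diff_ratios(
    sbg_counts: dict, wbg_counts: dict, pseudocount: float = 0.0
) -> list[DiffRecord]:
    """Per-group SBG:WBG gene-count ratios.

    Groups absent from the WBG are excluded (and logged) unless a positive
    ``pseudocount`` is given, in which case it is added to both counts.
    Output is sorted by group id for determinism.
    """
    records = []
    for gid in sorted(set(sbg_counts) | set(wbg_counts)):
        n_sbg = int(sbg_counts.get(gid, 0))
        n_wbg = int(wbg_counts.get(gid, 0))
        if n_sbg < 0 or n_wbg < 0:
            raise ValueError(f"negative count for group {gid}")
        num, den = n_sbg + pseudocount, n_wbg + pseudocount
        if den == 0:
            logger.warning(
                "COG group %s absent from WBG (n_sbg=%d); ratio undefined, "
                "group excluded",
                gid,
                n_sbg,
            )
            continue
        records.append(DiffRecord(gid, n_sbg, n_wbg, num / den))
    return records


def avdt(records: list, group_to_subcats: dict) -> list[AVDTRecord]:
    """Per-subcategory mean of group ratios (AVDT).

    A group mapped to several letters contributes its ratio to each
    letter's mean. Subcategories with no contributing group are omitted
    with a warning. Output sorted by letter.
    """
    by_letter: dict = defaultdict(list)
    for rec in records:
        letters = group_to_subcats.get(rec.cog_group_id)
        if not letters:
            raise ParseError(
                f"COG group {rec.cog_group_id} has no subcategory mapping"
            )
        for ch in filter_letters(letters):
            by_letter[ch].append(rec.ratio)
    out = []
    for ch in COG_SUBCATEGORIES:
        ratios = by_letter.get(ch)
        if not ratios:
            logger.warning("subcategory %s has no contributing COG groups", ch)
            continue
        out.append(AVDTRecord(ch, sum(ratios) / len(ratios), len(ratios)))
    return out


def select_scog_wcog(
    records: list,
    hi: float = DIFF_HI_DEFAULT,
    lo: float = DIFF_LO_DEFAULT,
) -> COGGroupSets:
    """Strong-/weak-biased COG groups: ratio > hi -> SCOG, ratio < lo -> WCOG."""
    if not (hi > lo > 0):
        raise ValueError(f"thresholds must satisfy hi > lo > 0, got {hi}, {lo}")
    scog = frozenset(r.cog_group_id for r in records if r.ratio > hi)
    wcog = frozenset(r.cog_group_id for r in records if r.ratio < lo)
    return COGGroupSets(scog_ids=scog, wcog_ids=wcog)


def genome_group_proportions(
    assignments: list, sets: COGGroupSets
) -> tuple[float, float]:
    """Fractions of a genome's COG-annotated genes in SCOG / WCOG groups.

    ``assignments`` holds (gene_id, cog_group_id) pairs; a genome with no
    annotated genes yields (nan, nan).
    """
    total = len(assignments)
    if total == 0:
        return (math.nan, math.nan)
    n_s = sum(1 for _, gid in assignments if gid in sets.scog_ids)
    n_w = sum(1 for _, gid in assignments if gid in sets.wcog_ids)
    return (n_s / total, n_w / total)


def pathway_proportions(gene_pathways: list, n_genes_annotated: int | None = None) -> dict:
    """Per-pathway fraction of genes for the ten replication/repair classes.

    ``gene_pathways`` holds (gene_id, pathway_id) pairs; the denominator is
    the number of distinct annotated genes unless overridden. Pathways with
    no genes report 0; unknown pathway ids raise.
    """
    genes_by_pathway: dict = defaultdict(set)
    all_genes = set()
    for gene_id, pid in gene_pathways:
        if pid not in REPAIR_PATHWAYS:
            raise ParseError(f"unknown KEGG pathway id {pid!r}")
        genes_by_pathway[pid].add(gene_id)
        all_genes.add(gene_id)
    denom = n_genes_annotated if n_genes_annotated is not None else len(all_genes)
    if denom <= 0:
        raise UndefinedStatisticError("pathway proportions undefined: no genes")
    return {pid: len(genes_by_pathway[pid]) / denom for pid in REPAIR_PATHWAYS}
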