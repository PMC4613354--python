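"""Synthetic circular bacterial genomes with known strand-bias structure.

The generator is deliberately minimal: the composition-bias score and the
RF indices depend only on per-strand base frequencies, so bases are drawn
site-independently on the composite leading strand with

    P(G) = gc/2 + delta_gc/2      P(C) = gc/2 - delta_gc/2
    P(T) = (1-gc)/2 + delta_ta/2  P(A) = (1-gc)/2 - delta_ta/2

and complemented onto the published strand over the second replichore.
With no rearrangements the expected composition-bias score is
|delta_gc| + |delta_ta| exactly. Non-overlapping genes are placed uniformly
and put on the leading strand with probability ``leading_prob`` (optionally
shifted per COG subcategory); inversion events reverse-complement segments
in place, moving genes between strands, which is the mechanism by which
recombination erodes a uniform skew.

Cohort simulation draws one bias level b per genome (the score it will
have, up to sampling noise) and plants the cohort-level relationships under
study: leading-gene density rises with b, GC content and genome size fall
with b, obligate-intracellular genomes get a bias offset, and the COG label
distribution tilts with b so that strong-/weak-biased ortholog groups exist
by construction. Every drawn parameter lands in a ground-truth table so
expected feature values are known in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PackingError
from .functional_categories import COG_SUBCATEGORIES, REPAIR_PATHWAYS
from .io_formats import GenomeBundle, write_cohort
from .replichore import (
    GeneAnnotation,
    GenomeRecord,
    build_replichore_map,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Subcategories whose prevalence is tilted up (down) with the bias level
#: in cohort simulation, yielding strong-/weak-biased COG groups and the
#: corresponding pCOG correlation signs.
STRONG_LETTERS = ("D", "F", "J", "L", "V")
WEAK_LETTERS = ("A", "C", "I", "Q")
NEUTRAL_LETTERS = tuple(
    ch for ch in COG_SUBCATEGORIES if ch not in STRONG_LETTERS + WEAK_LETTERS
)

# fixed within-tier relative weights; neutral profile loosely mirrors the
# prevalence of housekeeping categories in real annotations
_NEUTRAL_PROFILE = {
    "E": 2.0, "K": 1.8, "G": 1.6, "M": 1.4, "P": 1.4, "T": 1.2, "H": 1.2,
    "O": 1.0, "N": 0.6, "U": 0.6, "B": 0.2, "W": 0.2, "Y": 0.2, "Z": 0.4,
}


@dataclass(frozen=True)
class GenomeSimParams:
    """Parameters for one simulated genome."""

    seed: int
    genome_id: str = "sim"
    length: int = 500_000
    gc_target: float = 0.5
    delta_gc: float = 0.03
    delta_ta: float = 0.02
    ori: int = 0
    ter: int | None = None  # default: length // 2
    n_genes: int | None = None  # default: ~85% coding coverage
    gene_length: tuple = (300, 1500)
    leading_prob: float = 0.7
    cog_weights: dict | None = None  # subcategory letter -> weight
    cog_leading_coupling: dict = field(default_factory=dict)
    cog_annotation_rate: float = 0.85
    groups_per_subcategory: int = 6
    n_inversions: int = 0
    inversion_length: tuple = (2_000, 10_000)
    pathway_rates: dict | None = None  # pathway id -> per-gene probability

    def base_probs(self) -> np.ndarray:
        """Leading-strand probabilities for A, C, G, T (in that order)."""
        gc, dgc, dta = self.gc_target, self.delta_gc, self.delta_ta
        p = np.array(
            [
                (1 - gc) / 2 - dta / 2,  # A
                gc / 2 - dgc / 2,        # C
                gc / 2 + dgc / 2,        # G
                (1 - gc) / 2 + dta / 2,  # T
            ]
        )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(
                "infeasible base probabilities: gc_target "
                f"{gc} with delta_gc {dgc}, delta_ta {dta} gives {p.tolist()}"
            )
        return p

    def resolved_ter(self) -> int:
        return self.length // 2 if self.ter is None else self.ter

    def expected_score(self) -> float:
        """Expected composition-bias score with no inversions."""
        return abs(self.delta_gc) + abs(self.delta_ta)


def _default_cog_weights() -> dict:
    w = {ch: 0.05 / len(STRONG_LETTERS) for ch in STRONG_LETTERS}
    w.update({ch: 0.05 / len(WEAK_LETTERS) for ch in WEAK_LETTERS})
    total_neutral = sum(_NEUTRAL_PROFILE.values())
    w.update({ch: 0.9 * v / total_neutral for ch, v in _NEUTRAL_PROFILE.items()})
    return w


def _default_pathway_rates() -> dict:
    # ~2% of genes in replication/repair pathways overall
    return {pid: 0.002 for pid in REPAIR_PATHWAYS}


def simulate_genome(params: GenomeSimParams):
    """Draw one genome; returns (GenomeRecord, cog_map, kegg_map).

    Deterministic given ``params.seed``. The cog_map holds
    (gene_id, cog_group_id, subcategory letters) triples, the kegg_map
    (gene_id, pathway_id) pairs.
    """
    rng = np.random.default_rng(params.seed)
    L = params.length
    ter = params.resolved_ter()
    rmap = build_replichore_map(params.ori, ter, L)
    probs = params.base_probs()

    # -- sequence: draw the composite leading strand, complement onto the
    #    published strand over arc2 (site-independent, so no reversal needed)
    codes = np.searchsorted(np.cumsum(probs), rng.random(L), side="right")
    codes = np.minimum(codes, 3).astype(np.uint8)  # guard cumsum rounding
    in_arc2 = np.ones(L, dtype=bool)
    for lo, hi in rmap.arc1_intervals():
        in_arc2[lo:hi] = False
    codes[in_arc2] = 3 - codes[in_arc2]  # A<->T, C<->G
    sequence = _BASES[codes].tobytes().decode("ascii")

    # -- gene placement: non-overlapping, uniform gaps
    lmin, lmax = params.gene_length
    mean_len = (lmin + lmax) / 2
    auto_n = params.n_genes is None
    n_genes = params.n_genes or max(2, int(0.82 * L / mean_len))
    lengths = rng.integers(lmin, lmax + 1, size=n_genes)
    total = int(lengths.sum())
    if total > 0.9 * L:
        if not auto_n:
            raise PackingError(
                f"{params.genome_id}: total gene length {total} exceeds 90% of "
                f"chromosome length {L}"
            )
        # auto-sized gene set: trim trailing genes until it packs
        while n_genes > 2 and total > 0.88 * L:
            n_genes -= 1
            total -= int(lengths[n_genes])
        lengths = lengths[:n_genes]
        logger.info("%s: trimmed auto gene set to %d genes to fit",
                    params.genome_id, n_genes)
    gaps = rng.multinomial(L - total, np.full(n_genes + 1, 1 / (n_genes + 1)))
    starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    ends = starts + lengths
    mids = starts + lengths // 2
    mid_in_arc1 = np.array([rmap.in_arc1(int(m)) for m in mids])

    # -- COG labels first (leading probability may be letter-coupled)
    weights = params.cog_weights or _default_cog_weights()
    letters = np.array(COG_SUBCATEGORIES)
    wvec = np.array([weights.get(ch, 0.0) for ch in COG_SUBCATEGORIES], dtype=float)
    wvec = wvec / wvec.sum()
    letter_idx = rng.choice(len(letters), size=n_genes, p=wvec)
    annotated = rng.random(n_genes) < params.cog_annotation_rate
    group_no = rng.integers(0, params.groups_per_subcategory, size=n_genes)

    p_lead = np.full(n_genes, params.leading_prob)
    for ch, shift in params.cog_leading_coupling.items():
        p_lead[annotated & (letters[letter_idx] == ch)] += shift
    p_lead = np.clip(p_lead, 0.0, 1.0)
    is_leading = rng.random(n_genes) < p_lead
    # leading gene in arc1 -> '+', in arc2 -> '-'; lagging is the reverse
    strands = np.where(is_leading == mid_in_arc1, "+", "-")

    genes, cog_map = [], []
    for i in range(n_genes):
        gene_id = f"{params.genome_id}_g{i:05d}"
        ch = str(letters[letter_idx[i]])
        cogs = ()
        if annotated[i]:
            group_id = f"{ch}{group_no[i]:02d}"
            cogs = ((group_id, ch),)
            cog_map.append((gene_id, group_id, ch))
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                start=int(starts[i]),
                end=int(ends[i]),
                strand=str(strands[i]),
                cog_groups=cogs,
            )
        )

    # -- KEGG pathway assignment (at most one pathway per gene)
    rates = params.pathway_rates or _default_pathway_rates()
    pids = list(rates)
    cum = np.cumsum([rates[p] for p in pids])
    if cum[-1] > 1:
        raise ValueError("pathway_rates sum to more than 1")
    draw = rng.random(n_genes)
    kegg_map = []
    for i in range(n_genes):
        j = int(np.searchsorted(cum, draw[i], side="right"))
        if j < len(pids):
            kegg_map.append((genes[i].gene_id, pids[j]))

    record = GenomeRecord(
        genome_id=params.genome_id, sequence=sequence, ori=params.ori,
        ter=ter, genes=genes,
    )
    if params.n_inversions:
        record = apply_inversions(
            record, params.n_inversions, params.inversion_length,
            seed=int(rng.integers(2**31)),
        )
        kept = {g.gene_id for g in record.genes}
        cog_map = [t for t in cog_map if t[0] in kept]
        kegg_map = [t for t in kegg_map if t[0] in kept]
    return record, cog_map, kegg_map


def apply_inversions(
    record: GenomeRecord, n: int, length_range: tuple, seed: int,
    max_retries: int = 200,
) -> GenomeRecord:
    """Reverse-complement ``n`` random segments in place.

    Segments never contain ori or ter (and never wrap coordinate 0), so
    the replichore map stays well defined; an event that cannot be placed
    after ``max_retries`` draws is skipped with a warning. Genes fully
    inside a segment get mirrored coordinates and a flipped strand; genes
    straddling a breakpoint are deleted and logged.
    """
    if n == 0:
        return record
    rng = np.random.default_rng(seed)
    L = record.length
    seq = record.sequence
    genes = list(record.genes)
    lo, hi = length_range
    for _event in range(n):
        placed = False
        for _try in range(max_retries):
            seg_len = int(rng.integers(lo, hi + 1))
            s = int(rng.integers(0, L - seg_len + 1))
            e = s + seg_len
            if s <= record.ori < e or s <= record.ter < e:
                continue
            placed = True
            break
        if not placed:
            logger.warning(
                "%s: could not place an inversion avoiding ori/ter; event skipped",
                record.genome_id,
            )
            continue
        seq = seq[:s] + reverse_complement(seq[s:e]) + seq[e:]
        new_genes = []
        for g in genes:
            g_start, g_end = g.start, g.end
            if g.wraps:
                overlaps = g_start < e or g_end > s  # two pieces, conservative
                if overlaps and not (g_end <= s and g_start >= e):
                    logger.info("%s: wrapping gene %s hit by inversion; deleted",
                                record.genome_id, g.gene_id)
                    continue
                new_genes.append(g)
                continue
            if g_end <= s or g_start >= e:
                new_genes.append(g)
            elif g_start >= s and g_end <= e:
                new_genes.append(
                    replace(
                        g,
                        start=s + e - g_end,
                        end=s + e - g_start,
                        strand="-" if g.strand == "+" else "+",
                    )
                )
            else:
                logger.info(
                    "%s: gene %s straddles inversion breakpoint; deleted",
                    record.genome_id, g.gene_id,
                )
        genes = new_genes
    genes.sort(key=lambda g: (g.start, g.gene_id))
    return GenomeRecord(
        genome_id=record.genome_id, sequence=seq, ori=record.ori,
        ter=record.ter, genes=genes,
    )


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class CohortSimParams:
    """Parameters for a whole synthetic cohort.

    Each genome draws a bias level ``b ~ U(bias_min, bias_max)`` (its
    expected composition-bias score, split 60/40 between delta_gc and
    delta_ta). Planted relationships, all switchable to zero:

    * density_coef: leading_prob = 0.7 + density_coef * (b - b_mid) + noise
    * gc_coef:      gc_target  = 0.5 - gc_coef * (b - b_mid) + noise
    * size_coef:    length     = base_length * (1 - size_coef*(b - b_mid) + noise)
    * cog_coupling (kappa in [0, 1]): the share of strong-tier subcategories
      grows ~ t^4 with the normalized bias t while the weak tier decays
      symmetrically, so SBG:WBG count ratios exceed 5 (fall below 0.2) for
      strong (weak) groups when kappa = 1
    * obligate_offset: obligate-intracellular genomes add this to b

    The gcRF/taRF anticorrelation with the score is not planted: it emerges
    because per-gene skew variance is ~1/gene length regardless of b while
    the mean skew equals delta, so variance/mean falls as b rises.
    """

    seed: int
    n_genomes: int = 200
    base_length: int = 500_000
    bias_min: float = 0.005
    bias_max: float = 0.075
    gc_base: float = 0.5
    density_coef: float = 3.0
    density_noise: float = 0.03
    gc_coef: float = 2.0
    gc_noise: float = 0.02
    size_coef: float = 10.0
    size_noise: float = 0.08
    cog_coupling: float = 1.0
    obligate_rate: float = 0.2
    obligate_offset: float = 0.015
    n_inversions: int = 0
    inversion_length: tuple = (2_000, 10_000)
    phyla: tuple = (
        "Proteobacteria", "Firmicutes", "Actinobacteria", "Bacteroidetes",
        "Cyanobacteria", "Spirochaetes", "Tenericutes", "Fusobacteria",
    )
    optional_metadata_rate: float = 0.4

    @classmethod
    def null(cls, seed: int, **overrides) -> "CohortSimParams":
        """All planted effects off: zero bias, zero couplings.

        The bias level itself must be zero, not merely constant: at any
        fixed nonzero delta the realized genome-wide skew and the per-gene
        skew mean fluctuate together (they are computed from the same
        bases), which couples the score to RF = variance/mean mechanically.
        With delta = 0 the score is pure folded sampling noise and every
        cohort correlation has expectation zero.
        """
        defaults = dict(
            bias_min=0.0, bias_max=0.0, density_coef=0.0, gc_coef=0.0,
            size_coef=0.0, cog_coupling=0.0, obligate_offset=0.0,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


def _tilted_cog_weights(t: float, kappa: float) -> dict:
    """Subcategory weights at normalized bias t in [0, 1], coupling kappa."""
    share_strong = 0.05 * (1 - kappa) + kappa * (0.01 + 0.2 * t**4)
    share_weak = 0.05 * (1 - kappa) + kappa * (0.01 + 0.2 * (1 - t) ** 4)
    share_neutral = 1.0 - share_strong - share_weak
    w = {ch: share_strong / len(STRONG_LETTERS) for ch in STRONG_LETTERS}
    w.update({ch: share_weak / len(WEAK_LETTERS) for ch in WEAK_LETTERS})
    total = sum(_NEUTRAL_PROFILE.values())
    w.update({ch: share_neutral * v / total for ch, v in _NEUTRAL_PROFILE.items()})
    return w


def simulate_cohort(params: CohortSimParams, out_dir=None):
    """Simulate a cohort; returns (bundles, ground_truth DataFrame).

    With ``out_dir`` the cohort is also written to disk in the layout
    ``CohortManifest.from_dir`` reads, plus a ground_truth.tsv of every
    drawn parameter. Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    span = params.bias_max - params.bias_min
    b_mid = (params.bias_min + params.bias_max) / 2
    bundles, truth_rows = [], []
    for i in range(params.n_genomes):
        gid = f"sim{i:04d}"
        b = float(rng.uniform(params.bias_min, params.bias_max))
        obligate = bool(rng.random() < params.obligate_rate)
        b_eff = b + (params.obligate_offset if obligate else 0.0)
        t = (b_eff - params.bias_min) / span if span > 0 else 0.5
        t = min(max(t, 0.0), 1.0)

        gc = params.gc_base - params.gc_coef * (b_eff - b_mid) + rng.normal(0, params.gc_noise)
        gc = float(np.clip(gc, 0.25, 0.75))
        rho = 0.7 + params.density_coef * (b_eff - b_mid) + rng.normal(0, params.density_noise)
        rho = float(np.clip(rho, 0.05, 0.95))
        size_factor = 1.0 - params.size_coef * (b_eff - b_mid) + rng.normal(0, params.size_noise)
        length = int(params.base_length * float(np.clip(size_factor, 0.3, 2.0)))

        gparams = GenomeSimParams(
            seed=int(rng.integers(2**31)),
            genome_id=gid,
            length=length,
            gc_target=gc,
            delta_gc=0.6 * b_eff,
            delta_ta=0.4 * b_eff,
            leading_prob=rho,
            cog_weights=_tilted_cog_weights(t, params.cog_coupling),
            n_inversions=params.n_inversions,
            inversion_length=params.inversion_length,
        )
        record, cog_map, kegg_map = simulate_genome(gparams)

        metadata = {
            "phylum": str(rng.choice(list(params.phyla))),
            "obligate_intracellular": obligate,
            "s_value": float(rng.normal(1.0, 0.5))
            if rng.random() < params.optional_metadata_rate else float("nan"),
            "generation_time": float(rng.lognormal(0.0, 1.0))
            if rng.random() < params.optional_metadata_rate else float("nan"),
        }
        bundles.append(GenomeBundle(record, cog_map, kegg_map, metadata))
        truth_rows.append(
            {
                "genome_id": gid,
                "bias_level": b,
                "bias_effective": b_eff,
                "delta_gc": gparams.delta_gc,
                "delta_ta": gparams.delta_ta,
                "expected_score": gparams.expected_score(),
                "gc_target": gc,
                "leading_prob": rho,
                "length": length,
                "obligate_intracellular": int(obligate),
                "cog_tilt": t,
                "n_inversions": params.n_inversions,
            }
        )
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        write_cohort(bundles, out_dir, ground_truth=truth)
    return bundles, truth
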