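"""Orchestration: per-genome feature extraction and the cohort report.

``compute_features`` turns a list of genome bundles into one feature row
per genome (score, size, GC, leading-gene density, gcRF/taRF, pCOG vector,
SCOG/WCOG fractions, repair-pathway fractions, metadata) plus the
cohort-level Diff/AVDT tables; ``cohort_report`` runs the correlation
battery, the obligate-intracellular group test, phylum summaries and the
PCR decomposition on that table. All outputs are deterministic given
(inputs, config, seed) and write with fixed 6-significant-digit formatting.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bias_metrics, cohort_stats, functional_categories as fc, replichore
from .errors import StrandBiasError, UndefinedStatisticError
from .io_formats import MISSING, GenomeBundle

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Flat run configuration with the analysis conventions as defaults."""

    cohort_dir: str = "cohort"
    out_dir: str = "results"
    seed: int = 42
    # simulation
    n_genomes: int = 200
    base_length: int = 500_000
    n_inversions: int = 0
    null_cohort: bool = False
    # analysis conventions
    rf_variant: str = "variance_over_mean"
    diff_level: str = "group"  # or "subcategory"
    diff_hi: float = fc.DIFF_HI_DEFAULT
    diff_lo: float = fc.DIFF_LO_DEFAULT
    pseudocount: float = 0.0
    t_test_equal_var: bool = False
    p_overall: float = cohort_stats.P_OVERALL_DEFAULT
    p_cog: float = cohort_stats.P_COG_DEFAULT
    pcr_features: list | None = None  # None = auto-select at p < p_cog

    def __post_init__(self):
        if not self.diff_hi > self.diff_lo > 0:
            raise ValueError("need diff_hi > diff_lo > 0")
        for p in (self.p_overall, self.p_cog):
            if not 0 < p < 1:
                raise ValueError("significance cutoffs must lie in (0, 1)")
        if self.diff_level not in ("group", "subcategory"):
            raise ValueError(f"unknown diff_level {self.diff_level!r}")
        if self.rf_variant not in bias_metrics.RF_VARIANTS:
            raise ValueError(f"unknown rf_variant {self.rf_variant!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def genome_features(bundle: GenomeBundle, config: RunConfig | None = None) -> dict:
    """Per-genome features that need no cohort context."""
    config = config or RunConfig()
    rec = bundle.record
    rmap = replichore.build_replichore_map(rec.ori, rec.ter, rec.length)
    counts = replichore.leading_strand_counts(rec, rmap)
    row: dict = {"genome_id": rec.genome_id, "genome_size": rec.length}

    if counts.total_unambiguous == 0:
        logger.warning("%s: no unambiguous bases; score and GC set to NA",
                       rec.genome_id)
        row["score"] = math.nan
        row["gc_content"] = math.nan
    else:
        row["score"] = bias_metrics.composition_bias_score(counts, rec.length)
        row["gc_content"] = bias_metrics.gc_content(counts)

    try:
        row["gene_density_leading"] = replichore.gene_density_leading(rec.genes, rmap)
    except UndefinedStatisticError:
        logger.warning("%s: no genes; leading density NA", rec.genome_id)
        row["gene_density_leading"] = math.nan

    try:
        gc_skews, ta_skews = bias_metrics.per_gene_skews(rec.genes, rec.sequence, rmap)
        for name, vec in (("gcRF", gc_skews), ("taRF", ta_skews)):
            try:
                row[name] = bias_metrics.rf_index(vec, variant=config.rf_variant).rf
            except UndefinedStatisticError as exc:
                logger.warning("%s: %s undefined (%s)", rec.genome_id, name, exc)
                row[name] = math.nan
    except UndefinedStatisticError as exc:
        logger.warning("%s: per-gene skews undefined (%s)", rec.genome_id, exc)
        row["gcRF"] = row["taRF"] = math.nan

    letter_assignments = [(gid, letters) for gid, _grp, letters in bundle.cog_map]
    try:
        pvec = fc.pcog(letter_assignments)
    except UndefinedStatisticError:
        logger.warning("%s: no COG assignments; pCOG NA", rec.genome_id)
        pvec = {ch: math.nan for ch in fc.COG_SUBCATEGORIES}
    for ch in fc.COG_SUBCATEGORIES:
        row[f"pCOG_{ch}"] = pvec[ch]

    n_genes = len(rec.genes)
    if n_genes > 0:
        pw = fc.pathway_proportions(bundle.kegg_map, n_genes_annotated=n_genes)
    else:
        pw = {pid: math.nan for pid in fc.REPAIR_PATHWAYS}
    for pid in fc.REPAIR_PATHWAYS:
        row[f"pw_{pid}"] = pw[pid]

    row["phylum"] = bundle.metadata.get("phylum", "unknown")
    row["obligate_intracellular"] = bool(
        bundle.metadata.get("obligate_intracellular", False)
    )
    row["s_value"] = bundle.metadata.get("s_value", math.nan)
    row["generation_time"] = bundle.metadata.get("generation_time", math.nan)
    return row


def _cog_gene_counts(bundles, genome_ids, level: str):
    """Aggregate gene counts per COG unit over a set of genomes.

    ``level="group"`` counts per ortholog group id; ``level="subcategory"``
    counts per (gene, letter) pair under the letter.
    """
    wanted = set(genome_ids)
    counts: dict = {}
    for b in bundles:
        if b.genome_id not in wanted:
            continue
        for _gene_id, group_id, letters in b.cog_map:
            if level == "group":
                counts[group_id] = counts.get(group_id, 0) + 1
            else:
                for ch in fc.filter_letters(letters):
                    counts[ch] = counts.get(ch, 0) + 1
    return counts


@dataclass
class FeatureResult:
    table: pd.DataFrame
    diff_records: list
    avdt_table: pd.DataFrame
    cog_sets: fc.COGGroupSets
    sbg_ids: list
    wbg_ids: list


FEATURE_COLUMNS = (
    ["genome_id", "score", "genome_size", "gc_content", "gene_density_leading",
     "gcRF", "taRF"]
    + [f"pCOG_{ch}" for ch in fc.COG_SUBCATEGORIES]
    + ["scog_fraction", "wcog_fraction"]
    + [f"pw_{pid}" for pid in fc.REPAIR_PATHWAYS]
    + ["s_value", "generation_time", "phylum", "obligate_intracellular"]
)


def compute_features(bundles: list, config: RunConfig | None = None) -> FeatureResult:
    """Per-genome feature table plus the cohort-level COG group statistics."""
    config = config or RunConfig()
    rows = [genome_features(b, config) for b in bundles]
    table = pd.DataFrame(rows)

    scored = [(r["genome_id"], r["score"]) for r in rows if not math.isnan(r["score"])]
    if len(scored) >= 2:
        sbg_ids, wbg_ids = fc.split_cohort(scored)
    else:
        logger.warning("fewer than 2 scored genomes: no SBG/WBG statistics")
        sbg_ids, wbg_ids = [], []

    level = config.diff_level
    sbg_counts = _cog_gene_counts(bundles, sbg_ids, level)
    wbg_counts = _cog_gene_counts(bundles, wbg_ids, level)
    diff_records = fc.diff_ratios(sbg_counts, wbg_counts, pseudocount=config.pseudocount)

    if level == "group":
        group_to_subcats = {}
        for b in bundles:
            for _gene, group_id, letters in b.cog_map:
                group_to_subcats.setdefault(group_id, letters)
    else:
        group_to_subcats = {ch: ch for ch in fc.COG_SUBCATEGORIES}
    avdt_records = fc.avdt(diff_records, group_to_subcats)
    avdt_table = pd.DataFrame(
        [{"subcategory": r.subcategory, "avdt": r.avdt, "n_groups": r.n_groups}
         for r in avdt_records]
    )

    sets = fc.select_scog_wcog(diff_records, hi=config.diff_hi, lo=config.diff_lo)
    fractions = []
    for b in bundles:
        if level == "group":
            assignments = [(gene, group) for gene, group, _l in b.cog_map]
        else:
            assignments = [
                (gene, ch)
                for gene, _g, letters in b.cog_map
                for ch in fc.filter_letters(letters)
            ]
        fractions.append(fc.genome_group_proportions(assignments, sets))
    table["scog_fraction"] = [f[0] for f in fractions]
    table["wcog_fraction"] = [f[1] for f in fractions]
    table = table[list(FEATURE_COLUMNS)]
    return FeatureResult(table, diff_records, avdt_table, sets, sbg_ids, wbg_ids)


# ---------------------------------------------------------------------------
# Cohort report

@dataclass
class CohortReport:
    features: pd.DataFrame
    correlations: pd.DataFrame
    group_test: cohort_stats.GroupTestResult | None
    phylum_summary: pd.DataFrame
    avdt_table: pd.DataFrame
    pcr: cohort_stats.PCRResult | None
    pcr_features: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> Path:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, na_rep=MISSING, float_format=FLOAT_FMT)
        self.features.to_csv(d / "features.tsv", **kw)
        self.correlations.to_csv(d / "correlations.tsv", **kw)
        self.phylum_summary.to_csv(d / "phylum_summary.tsv", **kw)
        self.avdt_table.to_csv(d / "avdt.tsv", **kw)
        gt = self.group_test
        pd.DataFrame(
            [] if gt is None else [{
                "mean_obligate": gt.mean_group1, "mean_other": gt.mean_group2,
                "t_statistic": gt.t_statistic, "p_value": gt.p_value,
                "n_obligate": gt.n1, "n_other": gt.n2,
            }],
            columns=["mean_obligate", "mean_other", "t_statistic", "p_value",
                     "n_obligate", "n_other"],
        ).to_csv(d / "group_test.tsv", **kw)
        pcr_rows = []
        if self.pcr is not None:
            pcr_rows = [
                {"feature": f, "r2_contribution": c}
                for f, c in zip(self.pcr.features, self.pcr.contributions)
            ]
            pcr_rows.append({"feature": "TOTAL", "r2_contribution": self.pcr.total_r2})
        pd.DataFrame(pcr_rows, columns=["feature", "r2_contribution"]).to_csv(
            d / "pcr.tsv", **kw
        )
        with open(d / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return d


def cohort_report(
    feature_result: FeatureResult, config: RunConfig | None = None
) -> CohortReport:
    """Correlation battery, group test, phylum summaries and PCR."""
    config = config or RunConfig()
    table = feature_result.table
    if len(table) < 3:
        raise StrandBiasError("cohort statistics need >= 3 feature rows")
    usable = table[~table["score"].isna()].reset_index(drop=True)
    if len(usable) < len(table):
        logger.warning("dropped %d rows with NA score from cohort statistics",
                       len(table) - len(usable))

    correlations = cohort_stats.run_correlation_battery(
        usable, p_overall=config.p_overall, p_cog=config.p_cog
    )

    obligate = usable[usable["obligate_intracellular"]]["score"]
    others = usable[~usable["obligate_intracellular"]]["score"]
    try:
        group_test = cohort_stats.group_t_test(
            obligate, others, equal_var=config.t_test_equal_var
        )
    except UndefinedStatisticError as exc:
        logger.warning("group t-test skipped: %s", exc)
        group_test = None

    phylum_summary = cohort_stats.phylum_summaries(usable)

    pcr, selected = None, []
    if config.pcr_features:
        selected = list(config.pcr_features)
    else:
        strict = correlations[correlations["significant_strict"]]
        selected = [
            f for f in strict["feature"]
            if f not in cohort_stats.OPTIONAL_FEATURES
        ]
        if len(selected) < 2:
            logger.info(
                "fewer than 2 features pass p < %g; PCR falls back to the "
                "core feature set", config.p_cog,
            )
            selected = list(cohort_stats.CORE_FEATURES)
    constant = [
        f for f in selected
        if usable[f].isna().all() or usable[f].nunique(dropna=True) < 2
    ]
    if constant:
        logger.info("PCR: dropping constant feature(s) %s", constant)
        selected = [f for f in selected if f not in constant]
    try:
        pcr = cohort_stats.pcr_decomposition(usable[selected], usable["score"])
    except (UndefinedStatisticError, ValueError) as exc:
        logger.warning("PCR skipped: %s", exc)
        pcr, selected = None, []

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_genomes": int(len(table)),
        "pcr_features": selected,
    }
    return CohortReport(
        features=table,
        correlations=correlations,
        group_test=group_test,
        phylum_summary=phylum_summary,
        avdt_table=feature_result.avdt_table,
        pcr=pcr,
        pcr_features=selected,
        provenance=provenance,
    )
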