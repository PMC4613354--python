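"""File I/O for the cohort analysis.

Formats, all plain text:

* FASTA — one chromosome per file, read/written through Bio.SeqIO with a
  60-column wrap.
* GFF3 — gene features with ``ID`` attributes; 1-based inclusive on disk,
  converted to 0-based half-open in memory. Genes spanning the circular
  origin of coordinates carry a ``wraps=true`` attribute.
* TSVs — tab-separated, header required, UTF-8, ``.`` or empty for
  missing, no quoting:
  ori/ter table (point form ``genome_id  ori  ter`` or interval form
  ``genome_id  ori_start  ori_end  ter_start  ter_end``, 0-based inclusive
  interval bounds collapsed to midpoints), COG map
  (``genome_id  gene_id  cog_group_id  subcategories``), KEGG map
  (``genome_id  gene_id  pathway_id``) and cohort metadata
  (``genome_id  phylum  obligate_intracellular  s_value  generation_time``).

Readers reject malformed rows rather than coercing them; every skipped
genome is logged with its id and the reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, SequenceAlphabetError
from .replichore import IUPAC_ALPHABET, GeneAnnotation, GenomeRecord

logger = logging.getLogger(__name__)

MISSING = "."

_GFF_FEATURE_TYPES = {"gene", "CDS"}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (genome_id, uppercased sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ParseError(
            f"{path}: expected exactly one record (one chromosome per file), "
            f"found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_ALPHABET:
            raise SequenceAlphabetError(i, ch)
    return rec.id, seq


def write_fasta(path, genome_id: str, sequence: str) -> None:
    rec = SeqRecord(Seq(sequence), id=genome_id, description="")
    SeqIO.write([rec], str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff(path) -> list[GeneAnnotation]:
    """Read gene/CDS features from a GFF3 file, sorted by (start, gene_id)."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            _seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in _GFF_FEATURE_TYPES:
                continue
            attr_map = _parse_attributes(attrs, path, lineno)
            if "ID" not in attr_map:
                raise ParseError(f"{path}:{lineno}: feature lacks an ID attribute")
            wraps = attr_map.get("wraps", "false").lower() == "true"
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1 and not wraps:
                raise ParseError(
                    f"{path}:{lineno}: end < start without wraps=true"
                )
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            genes.append(
                GeneAnnotation(
                    gene_id=attr_map["ID"],
                    start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=strand,
                    wraps=wraps,
                )
            )
    genes.sort(key=lambda g: (g.start, g.gene_id))
    return genes


def _parse_attributes(attrs: str, path, lineno: int) -> dict:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"{path}:{lineno}: malformed attribute {item!r}")
        key, val = item.split("=", 1)
        out[key] = val
    return out


def write_gff(path, genome_id: str, genes: list) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.start, g.gene_id)):
            attrs = f"ID={g.gene_id}"
            if g.wraps:
                attrs += ";wraps=true"
            fh.write(
                f"{genome_id}\tstrandbias\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# TSV helpers

def _read_tsv(path, required: tuple) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING, ""], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def interval_midpoint(start: int, end: int, length: int) -> int:
    """Midpoint of a (possibly origin-wrapping) 0-based inclusive interval."""
    span = (end - start) % length
    return (start + span // 2) % length


def read_oriter(path, lengths: dict | None = None) -> dict:
    """Map genome_id -> (ori, ter) from a point-form or interval-form TSV.

    Interval forms are collapsed to midpoints; wrapping intervals (end <
    start) need the chromosome length, supplied via ``lengths``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING, ""], keep_default_na=False)
    if {"ori", "ter"}.issubset(df.columns):
        interval = False
    elif {"ori_start", "ori_end", "ter_start", "ter_end"}.issubset(df.columns):
        interval = True
    else:
        raise ParseError(
            f"{path}: need columns (genome_id, ori, ter) or "
            "(genome_id, ori_start, ori_end, ter_start, ter_end)"
        )
    if "genome_id" not in df.columns:
        raise ParseError(f"{path}: missing genome_id column")
    out: dict = {}
    for _, row in df.iterrows():
        gid = row["genome_id"]
        if gid in out:
            raise ParseError(f"{path}: duplicate genome_id {gid!r}")
        if not interval:
            out[gid] = (int(row["ori"]), int(row["ter"]))
            continue
        o_s, o_e = int(row["ori_start"]), int(row["ori_end"])
        t_s, t_e = int(row["ter_start"]), int(row["ter_end"])
        if (o_e < o_s or t_e < t_s) and (lengths is None or gid not in lengths):
            raise ParseError(
                f"{path}: wrapping interval for {gid} needs a chromosome length"
            )
        n = lengths[gid] if lengths and gid in lengths else max(o_e, t_e) + 1
        out[gid] = (interval_midpoint(o_s, o_e, n), interval_midpoint(t_s, t_e, n))
    return out


def write_oriter(path, oriter: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tori\tter\n")
        for gid in sorted(oriter):
            ori, ter = oriter[gid]
            fh.write(f"{gid}\t{ori}\t{ter}\n")


def read_cog_map(path) -> dict:
    """genome_id -> list of (gene_id, cog_group_id, subcategory letters)."""
    df = _read_tsv(path, ("genome_id", "gene_id", "cog_group_id", "subcategories"))
    out: dict = {}
    for _, row in df.iterrows():
        letters = row["subcategories"]
        if pd.isna(letters) or not letters:
            raise ParseError(f"{path}: empty subcategories for gene {row['gene_id']}")
        out.setdefault(row["genome_id"], []).append(
            (row["gene_id"], row["cog_group_id"], letters)
        )
    return out


def write_cog_map(path, cog_maps: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tgene_id\tcog_group_id\tsubcategories\n")
        for gid in sorted(cog_maps):
            for gene_id, group_id, letters in sorted(cog_maps[gid]):
                fh.write(f"{gid}\t{gene_id}\t{group_id}\t{letters}\n")


def read_kegg_map(path) -> dict:
    """genome_id -> list of (gene_id, pathway_id)."""
    df = _read_tsv(path, ("genome_id", "gene_id", "pathway_id"))
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(row["genome_id"], []).append((row["gene_id"], row["pathway_id"]))
    return out


def write_kegg_map(path, kegg_maps: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tgene_id\tpathway_id\n")
        for gid in sorted(kegg_maps):
            for gene_id, pid in sorted(kegg_maps[gid]):
                fh.write(f"{gid}\t{gene_id}\t{pid}\n")


_BOOL_STRINGS = {"0": False, "1": True, "false": False, "true": True}


def read_metadata(path) -> dict:
    """genome_id -> metadata dict (phylum, obligate flag, optional columns)."""
    df = _read_tsv(path, ("genome_id", "phylum", "obligate_intracellular"))
    out: dict = {}
    for _, row in df.iterrows():
        gid = row["genome_id"]
        if gid in out:
            raise ParseError(f"{path}: duplicate genome_id {gid!r}")
        phylum = row["phylum"]
        if pd.isna(phylum) or not phylum:
            raise ParseError(f"{path}: empty phylum for {gid}")
        flag_s = str(row["obligate_intracellular"]).lower()
        if flag_s not in _BOOL_STRINGS:
            raise ParseError(
                f"{path}: obligate_intracellular for {gid} must be one of "
                f"0/1/true/false, got {row['obligate_intracellular']!r}"
            )
        rec = {
            "phylum": phylum,
            "obligate_intracellular": _BOOL_STRINGS[flag_s],
            "s_value": math.nan,
            "generation_time": math.nan,
        }
        for opt in ("s_value", "generation_time"):
            if opt in df.columns and not pd.isna(row[opt]):
                rec[opt] = float(row[opt])
        out[gid] = rec
    return out


def write_metadata(path, metadata: dict) -> None:
    def fmt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return MISSING
        if isinstance(v, bool):
            return "1" if v else "0"
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tphylum\tobligate_intracellular\ts_value\tgeneration_time\n")
        for gid in sorted(metadata):
            m = metadata[gid]
            fh.write(
                f"{gid}\t{m['phylum']}\t{fmt(m['obligate_intracellular'])}\t"
                f"{fmt(m.get('s_value', math.nan))}\t"
                f"{fmt(m.get('generation_time', math.nan))}\n"
            )


# ---------------------------------------------------------------------------
# Cohort assembly

@dataclass
class GenomeBundle:
    """Everything the pipeline needs about one genome."""

    record: GenomeRecord
    cog_map: list = field(default_factory=list)  # (gene_id, group_id, letters)
    kegg_map: list = field(default_factory=list)  # (gene_id, pathway_id)
    metadata: dict = field(default_factory=dict)

    @property
    def genome_id(self) -> str:
        return self.record.genome_id


@dataclass
class CohortManifest:
    """Paths making up one cohort on disk."""

    fasta_paths: dict  # genome_id -> path
    gff_paths: dict
    oriter_path: Path
    cog_path: Path
    kegg_path: Path
    metadata_path: Path

    @classmethod
    def from_dir(cls, cohort_dir) -> "CohortManifest":
        d = Path(cohort_dir)
        fasta = {p.stem: p for p in sorted((d / "genomes").glob("*.fasta"))}
        gff = {p.stem: p for p in sorted((d / "genomes").glob("*.gff"))}
        manifest = cls(
            fasta_paths=fasta,
            gff_paths=gff,
            oriter_path=d / "oriter.tsv",
            cog_path=d / "cog.tsv",
            kegg_path=d / "kegg.tsv",
            metadata_path=d / "metadata.tsv",
        )
        manifest.validate()
        return manifest

    def validate(self) -> None:
        for gid, p in {**self.fasta_paths, **self.gff_paths}.items():
            if not Path(p).exists():
                raise ParseError(f"manifest references missing file {p} ({gid})")
        for p in (self.oriter_path, self.cog_path, self.kegg_path, self.metadata_path):
            if not Path(p).exists():
                raise ParseError(f"manifest references missing file {p}")
        if set(self.fasta_paths) != set(self.gff_paths):
            odd = set(self.fasta_paths) ^ set(self.gff_paths)
            raise ParseError(f"fasta/gff genome_id mismatch: {sorted(odd)}")


def load_cohort(manifest: CohortManifest) -> list[GenomeBundle]:
    """Load a cohort, skipping (with a warning) genomes without ori/ter."""
    lengths = {}
    sequences = {}
    for gid, path in sorted(manifest.fasta_paths.items()):
        fasta_id, seq = read_fasta(path)
        if fasta_id != gid:
            raise ParseError(
                f"{path}: record id {fasta_id!r} does not match manifest id {gid!r}"
            )
        sequences[gid] = seq
        lengths[gid] = len(seq)
    oriter = read_oriter(manifest.oriter_path, lengths=lengths)
    cog_maps = read_cog_map(manifest.cog_path)
    kegg_maps = read_kegg_map(manifest.kegg_path)
    metadata = read_metadata(manifest.metadata_path)

    known = set(sequences)
    for name, table in (("ori/ter", oriter), ("COG", cog_maps),
                        ("KEGG", kegg_maps), ("metadata", metadata)):
        stray = sorted(set(table) - known)
        if stray:
            raise ParseError(f"{name} table references unknown genome_id(s): {stray}")

    bundles = []
    for gid in sorted(sequences):
        if gid not in oriter:
            logger.warning("genome %s: no ori/ter entry; skipped", gid)
            continue
        if gid not in metadata:
            raise ParseError(f"genome {gid} missing from metadata table")
        ori, ter = oriter[gid]
        genes = read_gff(manifest.gff_paths[gid])
        record = GenomeRecord(
            genome_id=gid, sequence=sequences[gid], ori=ori, ter=ter, genes=genes
        )
        gene_ids = {g.gene_id for g in genes}
        for gene_id, _g, _l in cog_maps.get(gid, []):
            if gene_id not in gene_ids:
                raise ParseError(f"COG map references unknown gene {gene_id} in {gid}")
        bundles.append(
            GenomeBundle(
                record=record,
                cog_map=cog_maps.get(gid, []),
                kegg_map=kegg_maps.get(gid, []),
                metadata=metadata[gid],
            )
        )
    return bundles


def write_cohort(bundles: list, out_dir, ground_truth: pd.DataFrame | None = None) -> Path:
    """Write a cohort directory in the layout ``CohortManifest.from_dir`` reads."""
    d = Path(out_dir)
    (d / "genomes").mkdir(parents=True, exist_ok=True)
    oriter, cogs, keggs, meta = {}, {}, {}, {}
    for b in sorted(bundles, key=lambda b: b.genome_id):
        gid = b.genome_id
        write_fasta(d / "genomes" / f"{gid}.fasta", gid, b.record.sequence)
        write_gff(d / "genomes" / f"{gid}.gff", gid, b.record.genes)
        oriter[gid] = (b.record.ori, b.record.ter)
        cogs[gid] = b.cog_map
        keggs[gid] = b.kegg_map
        meta[gid] = b.metadata
    write_oriter(d / "oriter.tsv", oriter)
    write_cog_map(d / "cog.tsv", cogs)
    write_kegg_map(d / "kegg.tsv", keggs)
    write_metadata(d / "metadata.tsv", meta)
    if ground_truth is not None:
        ground_truth.to_csv(d / "ground_truth.tsv", sep="\t", index=False,
                            na_rep=MISSING, float_format="%.6g")
    return d
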