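"""Readers and writers for the file formats the pipeline touches.

Gene models come in as BED12 or GFF3 and are normalised to the internal
0-based half-open convention; deletions as BED with a sample column; gene
networks as a 3-column edge list; per-gene scores go out as 5-column BED.
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from .intervals import CNVCall, GenomeInterval, GeneModelSet, Transcript, ValidationError

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed line, reported with its 1-based line number."""


def _normalize_chrom(chrom: str, strip_chr_prefix: bool) -> str:
    if strip_chr_prefix and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


# ---------------------------------------------------------------- gene models

def read_gene_models(
    path: str | os.PathLike,
    format: str = "bed12",
    strip_chr_prefix: bool = False,
) -> GeneModelSet:
    """Read transcript models from BED12 or GFF3 into a :class:`GeneModelSet`.

    BED12 blocks become exons and the thickStart/thickEnd region, clipped
    to the exons, becomes the CDS. GFF3 mRNA/exon/CDS features are attached
    via Parent attributes and converted from 1-based closed to 0-based
    half-open coordinates.
    """
    if format == "bed12":
        return _read_bed12(path, strip_chr_prefix)
    if format == "gff3":
        return _read_gff3(path, strip_chr_prefix)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_bed12(path, strip_chr_prefix: bool) -> GeneModelSet:
    models = GeneModelSet()
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            try:
                chrom = _normalize_chrom(fields[0], strip_chr_prefix)
                start, end = int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != block_count or len(offsets) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount {block_count} does not match "
                    f"block lists"
                )
            # gene id may ride along as "gene_id|transcript_id" or column 13
            if len(fields) >= 13:
                gene_id = fields[12]
            elif "|" in name:
                gene_id, name = name.split("|", 1)
            else:
                gene_id = name
            exons = [
                GenomeInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            cds = []
            if thick_end > thick_start:
                thick = GenomeInterval(chrom, thick_start, thick_end, strand)
                for e in exons:
                    ov = e.overlap_bp(thick)
                    if ov > 0:
                        cds.append(
                            GenomeInterval(
                                chrom,
                                max(e.start, thick.start),
                                min(e.end, thick.end),
                                strand,
                            )
                        )
            try:
                tx = Transcript(
                    id=name,
                    gene_id=gene_id,
                    interval=GenomeInterval(chrom, start, end, strand),
                    exons=exons,
                    cds=cds,
                )
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            models.add(tx)
            n += 1
    if n == 0:
        logger.warning("no transcript records parsed from %s", path)
        warnings.warn(f"no transcript records parsed from {path}", stacklevel=2)
    return models


def _read_gff3(path, strip_chr_prefix: bool) -> GeneModelSet:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = GeneModelSet()
    tx_types = ("mRNA", "transcript")
    found = False
    for ttype in tx_types:
        for tx_feat in db.features_of_type(ttype):
            found = True
            parents = tx_feat.attributes.get("Parent", [])
            gene_id = parents[0] if parents else tx_feat.id
            chrom = _normalize_chrom(tx_feat.seqid, strip_chr_prefix)
            strand = tx_feat.strand if tx_feat.strand in ("+", "-") else "."
            exons = [
                GenomeInterval(chrom, f.start - 1, f.end, strand)
                for f in db.children(tx_feat, featuretype="exon", order_by="start")
            ]
            cds = [
                GenomeInterval(chrom, f.start - 1, f.end, strand)
                for f in db.children(tx_feat, featuretype="CDS", order_by="start")
            ]
            try:
                models.add(
                    Transcript(
                        id=tx_feat.id,
                        gene_id=gene_id,
                        interval=GenomeInterval(
                            chrom, tx_feat.start - 1, tx_feat.end, strand
                        ),
                        exons=exons,
                        cds=cds,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: transcript {tx_feat.id}: {exc}")
    # orphan CDS features (Parent not a known transcript) violate the model
    known = {t.id for t in models.transcripts()}
    for f in db.features_of_type("CDS"):
        for parent in f.attributes.get("Parent", []) or [None]:
            if parent is None or parent not in known:
                raise ValidationError(
                    f"{path}: CDS {f.id or f.start} has unknown Parent {parent!r}"
                )
    if not found:
        logger.warning("no transcript records parsed from %s", path)
    return models


def write_gene_models_bed12(models: GeneModelSet, path: str | os.PathLike) -> None:
    """Serialize a GeneModelSet as BED12 (gene id in column 13)."""
    with open(path, "w") as fh:
        for gid in sorted(models.genes):
            for tx in sorted(models.genes[gid], key=lambda t: (t.interval.start, t.id)):
                start = tx.interval.start
                if tx.cds:
                    thick_start = min(c.start for c in tx.cds)
                    thick_end = max(c.end for c in tx.cds)
                else:
                    thick_start = thick_end = start
                sizes = ",".join(str(len(e)) for e in tx.exons)
                offsets = ",".join(str(e.start - start) for e in tx.exons)
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            tx.chrom,
                            start,
                            tx.interval.end,
                            tx.id,
                            0,
                            tx.strand,
                            thick_start,
                            thick_end,
                            0,
                            len(tx.exons),
                            sizes,
                            offsets,
                            gid,
                        )
                    )
                    + "\n"
                )


# ------------------------------------------------------------------ deletions

def read_cnvs(path: str | os.PathLike, strip_chr_prefix: bool = False) -> list[CNVCall]:
    """Read deletion calls from a BED-like file: chrom, start, end, sample_id.

    Duplicate (sample, interval) rows collapse to one call.
    """
    calls: dict[tuple, CNVCall] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: need chrom, start, end, sample_id"
                )
            chrom = _normalize_chrom(fields[0], strip_chr_prefix)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: end {end} <= start {start}"
                )
            call = CNVCall(
                sample_id=fields[3],
                interval=GenomeInterval(chrom, start, end, "."),
            )
            calls[(call.sample_id, chrom, start, end)] = call
    return list(calls.values())


def write_cnvs(cnvs: list[CNVCall], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in sorted(cnvs, key=lambda c: (c.interval.chrom, c.interval.start, c.sample_id)):
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.sample_id}\n"
            )


# --------------------------------------------------------------------- scores

def write_scores_bed(
    scores: dict[str, float],
    gene_intervals: dict[str, GenomeInterval],
    path: str | os.PathLike,
) -> int:
    """Write per-gene p(HI) as 5-column BED (6-decimal precision).

    Genes without coordinates are skipped; the number skipped is returned
    and logged.
    """
    skipped = 0
    with open(path, "w") as fh:
        for gid in sorted(scores):
            iv = gene_intervals.get(gid)
            if iv is None:
                skipped += 1
                continue
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gid}\t{scores[gid]:.6f}\n")
    if skipped:
        logger.warning("write_scores_bed: skipped %d genes without coordinates", skipped)
    return skipped


def read_scores_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a score BED back into a DataFrame (chrom, start, end, gene_id, phi)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "phi"],
        dtype={"chrom": str, "gene_id": str},
        comment="#",
    )
    return df


# ------------------------------------------------------------------- networks

def read_network(path: str | os.PathLike) -> nx.Graph:
    """Read a weighted undirected edge list: geneA<TAB>geneB<TAB>weight.

    Weights are the log-likelihood scores of the functional links.
    Self-loops are rejected; a repeated pair keeps the first weight.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: need geneA, geneB, weight")
            a, b = fields[0], fields[1]
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop on {a}")
            if not (w == w and abs(w) != float("inf")):
                raise ValidationError(f"{path}:{lineno}: non-finite weight")
            if not g.has_edge(a, b):
                g.add_edge(a, b, weight=w)
    return g


def write_network(g: nx.Graph, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:.6g}\n")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene symbol per line (used for the known-HI seed list)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# ------------------------------------------------------------- feature tables

def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Per-gene predictor table: TSV with header, gene_id column, empty = missing."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: feature table needs a gene_id column")
    return df.set_index("gene_id")


def write_feature_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", na_rep="")


# ------------------------------------------------------ control distributions

_DATA_DIR = Path(__file__).parent / "data"


def read_percentile_table(path: str | os.PathLike) -> pd.DataFrame:
    """Percentile -> LOD table, one row per population.

    Columns: population, n, then percentile columns named like "p50".
    """
    df = pd.read_csv(path, sep="\t", dtype={"population": str})
    pct_cols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    if not pct_cols:
        raise ParseError(f"{path}: no percentile columns (p50, p90, ...)")
    return df


def packaged_control_percentiles() -> pd.DataFrame:
    """The shipped control maximal-LOD percentile summaries (GWAS controls).

    Percentiles of the distribution of per-individual maximal deletion LOD
    scores in African-American (AA, n=889) and European-American (EA,
    n=1433) control cohorts.
    """
    return read_percentile_table(_DATA_DIR / "control_percentiles.tsv")


def read_control_values(path: str | os.PathLike) -> pd.Series:
    """Raw per-individual maximal LOD values, one per line or TSV sample\tlod."""
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            vals.append(float(fields[-1]))
    return pd.Series(sorted(vals), dtype=float)
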