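"""Genome annotation: genes/exons (GFF3), TEs (BED), derived features.

Coordinates are 0-based half-open internally ([start, end)); GFF3 input
is 1-based inclusive and converted on load, BED input is used as-is.
Introns are the gene body minus its exons; promoters are the 2 kb
upstream of the TSS (strand-aware, clipped at chromosome bounds).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenomicFeatureSet", "load_annotation", "derive_promoters"]

PROMOTER_LENGTH = 2000

_FEATURE_COLS = ["chrom", "start", "end", "strand", "gene_id"]


@dataclass
class GenomicFeatureSet:
    """Genes, exons, derived introns, TEs and derived promoters.

    All member frames share the columns chrom/start/end/strand/gene_id
    (gene_id empty for TEs); ``chrom_sizes`` maps chromosome → length.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    tes: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    promoter_length: int = PROMOTER_LENGTH
    introns: pd.DataFrame = field(init=False)
    promoters: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        for name in ("genes", "exons", "tes"):
            df = getattr(self, name)
            for col in ("chrom", "start", "end"):
                if col not in df.columns:
                    raise ValueError(f"{name} frame lacks column {col!r}")
        bad = set(self.genes["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"unknown strand token(s) {sorted(bad)}")
        # exons must lie within their gene
        gene_span = self.genes.set_index("gene_id")[["start", "end"]]
        for row in self.exons.itertuples(index=False):
            span = gene_span.loc[row.gene_id]
            if row.start < span["start"] or row.end > span["end"]:
                raise ValueError(
                    f"exon {row.chrom}:{row.start}-{row.end} outside gene "
                    f"{row.gene_id} bounds"
                )
        self.introns = _derive_introns(self.genes, self.exons)
        self.promoters = derive_promoters(
            self.genes, self.promoter_length, self.chrom_sizes
        )


def _derive_introns(genes: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    rows = []
    by_gene = dict(tuple(exons.groupby("gene_id", sort=False))) if len(exons) else {}
    for g in genes.itertuples(index=False):
        ex = by_gene.get(g.gene_id)
        if ex is None or len(ex) == 0:
            continue
        ex = ex.sort_values("start")
        prev_end = None
        for e in ex.itertuples(index=False):
            if prev_end is not None and e.start > prev_end:
                rows.append((g.chrom, prev_end, e.start, g.strand, g.gene_id))
            prev_end = e.end if prev_end is None else max(prev_end, e.end)
    return pd.DataFrame(rows, columns=_FEATURE_COLS)


def derive_promoters(
    genes: pd.DataFrame,
    length: int = PROMOTER_LENGTH,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Strand-aware promoter intervals: the ``length`` bp upstream of the
    TSS (gene start on +, gene end on −), clipped to the chromosome."""
    rows = []
    sizes = chrom_sizes or {}
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            start, end = max(g.start - length, 0), g.start
        else:
            start, end = g.end, g.end + length
            if g.chrom in sizes:
                end = min(end, sizes[g.chrom])
        if end > start:
            rows.append((g.chrom, start, end, g.strand, g.gene_id))
    return pd.DataFrame(rows, columns=_FEATURE_COLS)


def load_annotation(
    gff3_source: str | Path,
    te_bed: str | Path | None = None,
    chrom_sizes: dict[str, int] | None = None,
    promoter_length: int = PROMOTER_LENGTH,
) -> GenomicFeatureSet:
    """Build a :class:`GenomicFeatureSet` from GFF3 genes/exons and a TE BED.

    ``gff3_source`` may be a path or GFF3 text.  TE BED columns:
    chrom, start, end[, family] (0-based half-open, '#' comments).
    """
    import gffutils

    text = None
    if isinstance(gff3_source, Path) or (
        "\n" not in str(gff3_source) and Path(gff3_source).exists()
    ):
        text = Path(gff3_source).read_text()
    else:
        text = str(gff3_source)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    gene_rows, exon_rows = [], []
    for g in db.features_of_type("gene"):
        gene_rows.append((g.seqid, g.start - 1, g.end, g.strand, g.id))
    gene_ids = {r[4] for r in gene_rows}
    for e in db.features_of_type("exon"):
        parents = list(e.attributes.get("Parent", []))
        # Parent may be an mRNA; walk up until a gene is found
        gene_id = None
        frontier = parents
        seen = set()
        while frontier:
            p = frontier.pop()
            if p in seen:
                continue
            seen.add(p)
            if p in gene_ids:
                gene_id = p
                break
            try:
                frontier.extend(db[p].attributes.get("Parent", []))
            except Exception:
                pass
        if gene_id is None:
            raise ValueError(f"exon {e.id or e.start} has no gene ancestor")
        exon_rows.append((e.seqid, e.start - 1, e.end, e.strand, gene_id))

    genes = pd.DataFrame(gene_rows, columns=_FEATURE_COLS)
    exons = pd.DataFrame(exon_rows, columns=_FEATURE_COLS)
    if te_bed is not None:
        src = te_bed
        if not isinstance(te_bed, Path) and "\n" in str(te_bed):
            src = _io.StringIO(str(te_bed))
        te = pd.read_csv(
            src, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "family"],
            usecols=[0, 1, 2, 3] if _bed_has_4_cols(te_bed) else [0, 1, 2],
        )
        if "family" not in te.columns:
            te["family"] = ""
    else:
        te = pd.DataFrame(columns=["chrom", "start", "end", "family"])
    te["strand"] = "."
    te["gene_id"] = ""
    te = te[_FEATURE_COLS + ["family"]] if "family" in te.columns else te[_FEATURE_COLS]
    return GenomicFeatureSet(
        genes, exons, te, chrom_sizes or {}, promoter_length
    )


def _bed_has_4_cols(src) -> bool:
    try:
        if not isinstance(src, Path) and "\n" in str(src):
            first = next(
                l for l in str(src).splitlines() if l.strip() and not l.startswith("#")
            )
        else:
            with open(src) as fh:
                first = next(
                    l for l in fh if l.strip() and not l.startswith("#")
                )
        return len(first.rstrip("\n").split("\t")) >= 4
    except StopIteration:
        return False
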