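"""Methylome–transcriptome integration.

DMRs are assigned to genomic feature categories with the precedence
promoter > exon > intron > extragenic TE > intergenic (any-overlap,
≥ 1 bp); a promoter- or intron-assigned DMR that also overlaps a
transposable element is re-labelled TE-promoter / TE-intron.  The
categories partition any DMR set.

DEGs are the genes passing CPM > 10, padj < 0.05 and |log2FC| > 1.
Promoter-category DMRs over DEGs form promDMEG records, classified into
the four quadrants of (methylation change, expression change) signs;
the correlation sign is negative exactly when the two signs differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomicFeatureSet

__all__ = [
    "CATEGORIES",
    "DegFilter",
    "assign_dmr_features",
    "filter_degs",
    "link_dmr_degs",
    "classify_quadrants",
    "QuadrantSummary",
]

CATEGORIES = (
    "TE",
    "TE-intron",
    "TE-promoter",
    "promoter",
    "exon",
    "intron",
    "intergenic",
)

GENIC_CATEGORIES = ("exon", "intron", "TE-intron")
PROMOTER_CATEGORIES = ("promoter", "TE-promoter")


def _best_overlap(
    dmr: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Per-DMR largest-overlap feature of one class (pyranges join).

    ``dmr`` columns: idx, chrom, start, end (0-based half-open).
    Returns a frame indexed by idx with columns overlap and gene_id;
    ties broken by larger overlap then leftmost feature start.
    """
    import pyranges as pr

    if len(features) == 0 or len(dmr) == 0:
        return pd.DataFrame(columns=["overlap", "gene_id"])
    left = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": dmr["chrom"],
                "Start": dmr["start"],
                "End": dmr["end"],
                "idx": dmr["idx"],
            }
        )
    )
    right = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": features["chrom"],
                "Start": features["start"],
                "End": features["end"],
                "gene_id": features.get("gene_id", ""),
            }
        )
    )
    joined = left.join(right).df
    if len(joined) == 0:
        return pd.DataFrame(columns=["overlap", "gene_id"])
    joined["overlap"] = (
        np.minimum(joined["End"], joined["End_b"])
        - np.maximum(joined["Start"], joined["Start_b"])
    )
    joined = joined[joined["overlap"] > 0]
    joined = joined.sort_values(
        ["idx", "overlap", "Start_b"], ascending=[True, False, True]
    )
    best = joined.drop_duplicates("idx").set_index("idx")
    return best[["overlap", "gene_id"]]


def assign_dmr_features(
    dmrs: pd.DataFrame,
    features: GenomicFeatureSet,
    coords: str = "report",
) -> pd.DataFrame:
    """Assign each DMR exactly one feature category.

    ``dmrs`` needs chrom/start/end columns; ``coords="report"`` means
    1-based inclusive (the DMR caller's output), ``coords="bed"`` means
    0-based half-open.  Returns the input columns plus category and
    gene_id (for promoter/genic categories).
    """
    out = dmrs.reset_index(drop=True).copy()
    out["idx"] = out.index
    internal = out[["idx", "chrom", "start", "end"]].copy()
    if coords == "report":
        internal["start"] = internal["start"] - 1
    elif coords != "bed":
        raise ValueError(f"unknown coords convention {coords!r}")

    known = set()
    for df in (features.genes, features.tes, features.promoters):
        known |= set(df["chrom"])
    if features.chrom_sizes:
        known |= set(features.chrom_sizes)
    unknown = set(internal["chrom"]) - known
    if unknown and known:
        raise ValueError(f"DMR(s) on unknown chromosome(s): {sorted(unknown)}")

    tiers = {
        "promoter": _best_overlap(internal, features.promoters),
        "exon": _best_overlap(internal, features.exons),
        "intron": _best_overlap(internal, features.introns),
        "TE": _best_overlap(internal, features.tes),
    }
    te_hits = tiers["TE"]

    categories = []
    gene_ids = []
    for i in internal["idx"]:
        category, gene = "intergenic", ""
        for tier in ("promoter", "exon", "intron", "TE"):
            hits = tiers[tier]
            if i in hits.index:
                category = tier
                gene = hits.loc[i, "gene_id"]
                break
        if category in ("promoter", "intron") and i in te_hits.index:
            category = f"TE-{category}"
        if category == "TE":
            gene = ""
        categories.append(category)
        gene_ids.append(gene)
    out["category"] = categories
    out["gene_id"] = gene_ids
    return out.drop(columns="idx")


@dataclass(frozen=True)
class DegFilter:
    min_cpm: float = 10.0
    max_padj: float = 0.05
    min_abs_l2fc: float = 1.0


def filter_degs(
    table: pd.DataFrame, criteria: DegFilter = DegFilter()
) -> pd.DataFrame:
    """Flag differentially expressed genes.

    ``table`` needs columns gene, log2FC, padj, cpm.  Adds ``is_deg``
    (CPM > 10 AND padj < 0.05 AND |log2FC| > 1 by default) and
    ``direction`` (up/down for DEGs, empty otherwise).
    """
    required = {"gene", "log2FC", "padj", "cpm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DEG table lacks column(s) {sorted(missing)}")
    out = table.copy()
    padj = out["padj"].fillna(1.0)
    out["is_deg"] = (
        (out["cpm"] > criteria.min_cpm)
        & (padj < criteria.max_padj)
        & (out["log2FC"].abs() > criteria.min_abs_l2fc)
    )
    out["direction"] = np.where(
        out["is_deg"], np.where(out["log2FC"] > 0, "up", "down"), ""
    )
    return out


def link_dmr_degs(
    annotated_dmrs: pd.DataFrame,
    degs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(DMEG, promDMEG) pair lists.

    DMEGs pair genic-category DMRs (exon/intron/TE-intron) with DEGs;
    promDMEGs pair promoter-category DMRs (promoter/TE-promoter) with
    DEGs.  Each (DMR, gene) pair is one record, so a gene with two
    promoter DMRs appears twice.
    """
    deg_map = degs[degs["is_deg"]].set_index("gene")["log2FC"]

    def _pairs(categories) -> pd.DataFrame:
        sel = annotated_dmrs[
            annotated_dmrs["category"].isin(categories)
            & annotated_dmrs["gene_id"].isin(deg_map.index)
        ].copy()
        sel["diff_exp"] = sel["gene_id"].map(deg_map)
        sel = sel.rename(columns={"mean_delta": "diff_meth"})
        cols = ["gene_id", "chrom", "start", "end", "context", "category",
                "diff_exp", "diff_meth"]
        return sel[[c for c in cols if c in sel.columns]].reset_index(drop=True)

    return _pairs(GENIC_CATEGORIES), _pairs(PROMOTER_CATEGORIES)


@dataclass
class QuadrantSummary:
    n_records: int
    n_classified: int
    n_unclassifiable: int
    quadrant_counts: dict[str, int]
    negative_correlation: int
    positive_correlation: int
    hyper: int
    hypo: int
    context_by_me_state: dict[str, dict[str, int]]


def classify_quadrants(
    promdmegs: pd.DataFrame,
) -> tuple[pd.DataFrame, QuadrantSummary]:
    """Quadrant (Me±/Exp±) classification of promoter-DMR × DEG pairs.

    Records with zero methylation or expression difference are flagged
    unclassifiable and excluded from the tallies (with a warning).
    Returns the annotated records and a :class:`QuadrantSummary`.
    """
    out = promdmegs.copy()
    me = np.sign(out["diff_meth"].values)
    ex = np.sign(out["diff_exp"].values)
    classifiable = (me != 0) & (ex != 0)
    if (~classifiable).any():
        warnings.warn(
            f"{int((~classifiable).sum())} record(s) with zero difference "
            "are unclassifiable and excluded from tallies",
            stacklevel=2,
        )
    out["me_state"] = np.where(classifiable, np.where(me > 0, "+", "-"), "")
    out["exp_state"] = np.where(classifiable, np.where(ex > 0, "+", "-"), "")
    out["quadrant"] = np.where(
        classifiable,
        "Me" + out["me_state"] + "/Exp" + out["exp_state"],
        "unclassifiable",
    )
    out["correlation_sign"] = np.where(
        classifiable,
        np.where(out["me_state"] != out["exp_state"], "negative", "positive"),
        "",
    )
    cls = out[classifiable]
    quad_counts = cls["quadrant"].value_counts().to_dict()
    ctx_by_state = {
        state: cls[cls["me_state"] == state]["context"].value_counts().to_dict()
        for state in ("+", "-")
    }
    summary = QuadrantSummary(
        n_records=len(out),
        n_classified=len(cls),
        n_unclassifiable=int((~classifiable).sum()),
        quadrant_counts=quad_counts,
        negative_correlation=int((cls["correlation_sign"] == "negative").sum()),
        positive_correlation=int((cls["correlation_sign"] == "positive").sum()),
        hyper=int((cls["me_state"] == "+").sum()),
        hypo=int((cls["me_state"] == "-").sum()),
        context_by_me_state=ctx_by_state,
    )
    return out, summary
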