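"""Metagene methylation profiles over genes/TEs with 2 kb flanks.

Each feature contributes its upstream flank (fixed-width bins), its body
(rescaled to a fixed number of bins) and its downstream flank; features
on the minus strand are reversed so bin 0 is always the 5′ end.  Bin
values are pooled proportions (Σ meth / Σ total over all contributing
loci and features), computed per context and per sample group.  Bins
that receive no coverage anywhere (e.g. flanks truncated by a
chromosome edge) are NaN, not zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CONTEXTS, CytosineCountTable

__all__ = ["metagene_profile"]


def metagene_profile(
    table: CytosineCountTable,
    features: pd.DataFrame,
    flank_bp: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 20,
    feature_class: str = "gene",
) -> pd.DataFrame:
    """Pooled metagene profile for one feature class.

    ``features`` needs columns chrom, start, end (1-based inclusive) and
    strand.  Returns a tidy frame with columns feature_class, bin,
    segment (upstream/body/downstream), context, group, meth, total,
    level; ``bin`` runs 5′→3′ over flank+body+flank.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    if len(features) == 0:
        raise ValueError("empty feature set")
    if "strand" not in features.columns:
        raise ValueError("features need a strand column")
    n_bins = 2 * flank_bins + body_bins
    groups = sorted(set(table.groups.values()))
    ctx_index = {c: i for i, c in enumerate(CONTEXTS)}

    meth_by_group = {}
    total_by_group = {}
    for g in groups:
        meth_by_group[g], total_by_group[g] = table.pooled_counts(g)

    # per chromosome: sorted positions with context codes
    sums = np.zeros((n_bins, len(CONTEXTS), len(groups)))
    tots = np.zeros_like(sums)
    df = table.df
    chrom_order = {c: np.where(df["chrom"].values == c)[0] for c in df["chrom"].unique()}
    for c, idx in chrom_order.items():
        order = np.argsort(df["pos"].values[idx], kind="stable")
        chrom_order[c] = idx[order]

    flank_width = flank_bp / flank_bins
    for row in features.itertuples(index=False):
        idx = chrom_order.get(row.chrom)
        if idx is None:
            continue
        pos = df["pos"].values[idx]
        lo = np.searchsorted(pos, row.start - flank_bp, side="left")
        hi = np.searchsorted(pos, row.end + flank_bp, side="right")
        sel = idx[lo:hi]
        if sel.size == 0:
            continue
        p = df["pos"].values[sel].astype(float)
        body_len = max(row.end - row.start + 1, 1)
        bins = np.empty(p.size, dtype=np.int64)
        up = p < row.start
        down = p > row.end
        body = ~(up | down)
        bins[up] = np.minimum(
            ((p[up] - (row.start - flank_bp)) // flank_width).astype(np.int64),
            flank_bins - 1,
        )
        bins[body] = flank_bins + np.minimum(
            ((p[body] - row.start) * body_bins // body_len).astype(np.int64),
            body_bins - 1,
        )
        bins[down] = (
            flank_bins
            + body_bins
            + np.minimum(
                ((p[down] - row.end - 1) // flank_width).astype(np.int64),
                flank_bins - 1,
            )
        )
        if row.strand == "-":
            bins = n_bins - 1 - bins
        ctx_codes = np.array(
            [ctx_index.get(c, -1) for c in df["context"].values[sel]], dtype=np.int64
        )
        keep = ctx_codes >= 0
        for gi, g in enumerate(groups):
            np.add.at(
                sums[:, :, gi],
                (bins[keep], ctx_codes[keep]),
                meth_by_group[g][sel][keep],
            )
            np.add.at(
                tots[:, :, gi],
                (bins[keep], ctx_codes[keep]),
                total_by_group[g][sel][keep],
            )

    rows = []
    for b in range(n_bins):
        segment = (
            "upstream" if b < flank_bins
            else "body" if b < flank_bins + body_bins
            else "downstream"
        )
        for ci, c in enumerate(CONTEXTS):
            for gi, g in enumerate(groups):
                t = tots[b, ci, gi]
                rows.append(
                    {
                        "feature_class": feature_class,
                        "bin": b,
                        "segment": segment,
                        "context": c,
                        "group": g,
                        "meth": sums[b, ci, gi],
                        "total": t,
                        "level": sums[b, ci, gi] / t if t > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
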