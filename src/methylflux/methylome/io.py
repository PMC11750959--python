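"""Cytosine-report input and global methylation summaries.

Input files follow the Bismark cytosine-report layout, one row per
cytosine: chrom, 1-based position, strand, count methylated, count
unmethylated, context (CG/CHG/CHH), trinucleotide.  One file per sample;
samples are merged on (chrom, pos) into a single wide table, and a locus
absent from a sample simply has zero coverage there.

Global levels mirror standard bisulfite sequencing reports: the overall
percent of methylated cytosine calls is taken over *all* contexts
(including calls in unknown context), the apparent conversion rate is
its complement to 100, and per-context percentages are count-weighted
within each context.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
_KNOWN_CONTEXTS = set(CONTEXTS) | {"unknown"}

REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "tricontext",
]


@dataclass
class CytosineCountTable:
    """Wide per-cytosine count table across samples.

    ``df`` columns: chrom, pos, strand, context plus ``meth_<sample>``
    and ``total_<sample>`` for every sample; ``groups`` maps sample name
    to its experimental group (e.g. ``"G+"``/``"G-"``).
    """

    df: pd.DataFrame
    groups: dict[str, str]

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    def group_samples(self, group: str) -> list[str]:
        out = [s for s, g in self.groups.items() if g == group]
        if not out:
            raise ValueError(f"no samples in group {group!r}")
        return out

    def pooled_counts(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """(meth, total) summed over the samples of a group, per locus."""
        samples = self.group_samples(group)
        meth = sum(self.df[f"meth_{s}"].values for s in samples)
        total = sum(self.df[f"total_{s}"].values for s in samples)
        return np.asarray(meth, dtype=float), np.asarray(total, dtype=float)

    def sample_counts(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.df[f"meth_{sample}"].values.astype(float),
            self.df[f"total_{sample}"].values.astype(float),
        )

    def with_groups_swapped(self) -> "CytosineCountTable":
        """Relabel every sample with the other group (two-group tables)."""
        gs = sorted(set(self.groups.values()))
        if len(gs) != 2:
            raise ValueError("group swap needs exactly two groups")
        flip = {gs[0]: gs[1], gs[1]: gs[0]}
        return CytosineCountTable(self.df, {s: flip[g] for s, g in self.groups.items()})


def _read_report(path_or_df, sample: str) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
        if list(df.columns[: len(REPORT_COLUMNS) - 1]) != REPORT_COLUMNS[:-1]:
            df.columns = REPORT_COLUMNS[: len(df.columns)]
    else:
        df = pd.read_csv(
            path_or_df, sep="\t", header=None, comment="#",
            names=REPORT_COLUMNS, usecols=range(len(REPORT_COLUMNS)),
        )
    bad_ctx = set(df["context"].unique()) - _KNOWN_CONTEXTS
    if bad_ctx:
        raise ValueError(f"sample {sample}: unknown context token(s) {sorted(bad_ctx)}")
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        raise ValueError(f"sample {sample}: negative count")
    df[f"meth_{sample}"] = df["count_methylated"].astype(np.int64)
    df[f"total_{sample}"] = (
        df["count_methylated"] + df["count_unmethylated"]
    ).astype(np.int64)
    return df[["chrom", "pos", "strand", "context", f"meth_{sample}", f"total_{sample}"]]


def load_cytosine_report(
    paths: Mapping[str, object],
    sample_groups: Mapping[str, str],
) -> CytosineCountTable:
    """Merge per-sample cytosine reports into one :class:`CytosineCountTable`.

    ``paths`` maps sample name → file path (or a pre-read DataFrame); all
    samples must appear in ``sample_groups``.  Loci missing from a sample
    get zero total there.  Inconsistent strand or context at the same
    (chrom, pos) across samples is an error.
    """
    missing = set(paths) - set(sample_groups)
    if missing:
        raise ValueError(f"samples without group assignment: {sorted(missing)}")
    merged: pd.DataFrame | None = None
    for sample, src in paths.items():
        df = _read_report(src, sample)
        if merged is None:
            merged = df
        else:
            before = merged[["chrom", "pos", "strand", "context"]]
            merged = merged.merge(
                df, on=["chrom", "pos"], how="outer", suffixes=("", "_new")
            )
            for col in ("strand", "context"):
                new = merged.pop(f"{col}_new")
                conflict = merged[col].notna() & new.notna() & (merged[col] != new)
                if conflict.any():
                    loc = merged.loc[conflict, ["chrom", "pos"]].iloc[0]
                    raise ValueError(
                        f"inconsistent {col} at {loc['chrom']}:{loc['pos']} "
                        f"across samples"
                    )
                merged[col] = merged[col].where(merged[col].notna(), new)
            del before
    assert merged is not None, "no input files"
    count_cols = [c for c in merged.columns if c.startswith(("meth_", "total_"))]
    merged[count_cols] = merged[count_cols].fillna(0).astype(np.int64)
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    known = [s for s in sample_groups if s in paths]
    return CytosineCountTable(merged, {s: sample_groups[s] for s in known})


def collapse_cg_strands(table: CytosineCountTable) -> CytosineCountTable:
    """Merge symmetric CG sites (plus-strand C at p, minus-strand C at
    p+1) into one locus at the plus-strand position, summing counts.

    Off by default: the cytosine report is normally taken at face value
    with each strand's cytosine tested separately.  Non-CG contexts and
    unpaired CG sites pass through unchanged.
    """
    df = table.df
    cg = df[df["context"] == "CG"]
    plus = cg[cg["strand"] == "+"]
    minus = cg[cg["strand"] == "-"]
    key_plus = list(zip(plus["chrom"], plus["pos"] + 1))
    minus_lookup = {
        (c, p): i for c, p, i in zip(minus["chrom"], minus["pos"], minus.index)
    }
    partner = {
        plus.index[k]: minus_lookup[key]
        for k, key in enumerate(key_plus)
        if key in minus_lookup
    }
    count_cols = [c for c in df.columns if c.startswith(("meth_", "total_"))]
    out = df.copy()
    for i_plus, i_minus in partner.items():
        out.loc[i_plus, count_cols] = (
            df.loc[i_plus, count_cols].values + df.loc[i_minus, count_cols].values
        )
    out = out.drop(index=list(partner.values())).reset_index(drop=True)
    return CytosineCountTable(out, dict(table.groups))


@dataclass(frozen=True)
class GlobalMethylationSummary:
    sample: str
    total_analyzed: int
    percent_mC_overall: float
    conversion_rate: float
    percent_by_context: dict[str, float]


def summary_from_counts(
    sample: str,
    total_analyzed: int,
    meth_by_context: Mapping[str, int],
    total_by_context: Mapping[str, int] | None = None,
) -> GlobalMethylationSummary:
    """Build a summary from aggregate counts.

    ``total_analyzed`` is the number of cytosine calls over all contexts;
    the overall percent methylated is 100·Σmeth/total_analyzed (unknown-
    context calls included in the numerator), and the conversion rate is
    exactly its complement to 100.  Per-context percentages need the
    per-context totals and are NaN when those are not supplied.
    """
    if total_analyzed <= 0:
        raise ValueError(f"sample {sample}: zero total coverage")
    total_meth = float(sum(meth_by_context.values()))
    pct = 100.0 * total_meth / float(total_analyzed)
    per_ctx = {}
    for ctx in CONTEXTS:
        if total_by_context and total_by_context.get(ctx, 0) > 0:
            per_ctx[ctx] = 100.0 * meth_by_context.get(ctx, 0) / total_by_context[ctx]
        else:
            per_ctx[ctx] = float("nan")
    return GlobalMethylationSummary(sample, int(total_analyzed), pct, 100.0 - pct, per_ctx)


def global_methylation_levels(table: CytosineCountTable) -> list[GlobalMethylationSummary]:
    """Per-sample global methylation report from a merged count table."""
    if len(table.df) == 0:
        raise ValueError("empty count table")
    ctx = table.df["context"].values
    out = []
    for sample in table.samples:
        meth, total = table.sample_counts(sample)
        meth_by_ctx = {c: int(meth[ctx == c].sum()) for c in _KNOWN_CONTEXTS}
        total_by_ctx = {c: int(total[ctx == c].sum()) for c in _KNOWN_CONTEXTS}
        out.append(
            summary_from_counts(sample, int(total.sum()), meth_by_ctx, total_by_ctx)
        )
    return out
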