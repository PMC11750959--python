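"""Report aggregation: every printed total is recomputed from its parts.

The tables mirror the study-style summaries: per-sample global
methylation, DMC/DMR counts per context with hyper/hypo splits, DMR
feature-category tallies, DEG up/down totals, promDMEG quadrants and
the flux/activity time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .integrate import QuadrantSummary

__all__ = ["ReportTables", "count_summary", "aggregate_report"]


def count_summary(per_part: Mapping[str, int], part_name: str = "context") -> pd.DataFrame:
    """Counts per part plus a recomputed TOTAL row."""
    if not per_part:
        return pd.DataFrame(columns=[part_name, "count"])
    rows = [{part_name: k, "count": int(v)} for k, v in per_part.items()]
    rows.append({part_name: "TOTAL", "count": int(sum(per_part.values()))})
    return pd.DataFrame(rows)


@dataclass
class ReportTables:
    global_summary: pd.DataFrame | None = None
    dmc_counts: pd.DataFrame | None = None
    dmr_counts: pd.DataFrame | None = None
    dmr_categories: pd.DataFrame | None = None
    deg_counts: pd.DataFrame | None = None
    quadrant_counts: pd.DataFrame | None = None
    flux: pd.DataFrame | None = None
    activity: pd.DataFrame | None = None

    def validate_totals(self) -> None:
        """Every TOTAL row must equal the sum of its parts."""
        for name in ("dmc_counts", "dmr_counts", "dmr_categories", "deg_counts",
                     "quadrant_counts"):
            df = getattr(self, name)
            if df is None or len(df) == 0:
                continue
            key = df.columns[0]
            total = int(df.loc[df[key] == "TOTAL", "count"].sum())
            parts = int(df.loc[df[key] != "TOTAL", "count"].sum())
            if total != parts:
                raise AssertionError(
                    f"{name}: TOTAL {total} != sum of parts {parts}"
                )

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self.__dataclass_fields__:
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def aggregate_report(
    global_summaries: list | None = None,
    dmc_table: pd.DataFrame | None = None,
    dmr_table: pd.DataFrame | None = None,
    annotated_dmrs: pd.DataFrame | None = None,
    deg_table: pd.DataFrame | None = None,
    quadrant_summary: QuadrantSummary | None = None,
    flux_table: pd.DataFrame | None = None,
    activity_table: pd.DataFrame | None = None,
) -> ReportTables:
    """Assemble :class:`ReportTables` from stage outputs (any subset)."""
    if all(
        x is None
        for x in (
            global_summaries, dmc_table, dmr_table, annotated_dmrs,
            deg_table, quadrant_summary, flux_table, activity_table,
        )
    ):
        raise ValueError("no stage outputs to aggregate")
    tables = ReportTables(flux=flux_table, activity=activity_table)
    if global_summaries is not None:
        tables.global_summary = pd.DataFrame(
            [
                {
                    "sample": s.sample,
                    "total_analyzed": s.total_analyzed,
                    "percent_mC": s.percent_mC_overall,
                    "conversion": s.conversion_rate,
                    **{f"percent_{c}": v for c, v in s.percent_by_context.items()},
                }
                for s in global_summaries
            ]
        )
    if dmc_table is not None:
        dmcs = dmc_table[dmc_table["is_dmc"]]
        rows = []
        for ctx, grp in dmcs.groupby("context", observed=True):
            rows.append(
                {
                    "context": ctx,
                    "count": len(grp),
                    "hyper": int((grp["delta"] > 0).sum()),
                    "hypo": int((grp["delta"] < 0).sum()),
                }
            )
        total = {
            "context": "TOTAL",
            "count": sum(r["count"] for r in rows),
            "hyper": sum(r["hyper"] for r in rows),
            "hypo": sum(r["hypo"] for r in rows),
        }
        tables.dmc_counts = pd.DataFrame(rows + [total])
    if dmr_table is not None:
        rows = []
        for ctx, grp in dmr_table.groupby("context", observed=True):
            rows.append(
                {
                    "context": ctx,
                    "count": len(grp),
                    "hyper": int((grp["direction"] == "hyper").sum()),
                    "hypo": int((grp["direction"] == "hypo").sum()),
                    "weak": int((grp["direction"] == "weak").sum()),
                }
            )
        total = {
            "context": "TOTAL",
            **{
                k: sum(r[k] for r in rows)
                for k in ("count", "hyper", "hypo", "weak")
            },
        }
        tables.dmr_counts = pd.DataFrame(rows + [total]) if rows else pd.DataFrame(
            [dict(context="TOTAL", count=0, hyper=0, hypo=0, weak=0)]
        )
    if annotated_dmrs is not None:
        counts = annotated_dmrs["category"].value_counts().to_dict()
        tables.dmr_categories = count_summary(counts, "category")
    if deg_table is not None:
        degs = deg_table[deg_table["is_deg"]]
        tables.deg_counts = count_summary(
            {
                "up": int((degs["log2FC"] > 0).sum()),
                "down": int((degs["log2FC"] < 0).sum()),
            },
            "direction",
        )
    if quadrant_summary is not None:
        tables.quadrant_counts = count_summary(
            quadrant_summary.quadrant_counts, "quadrant"
        )
    tables.validate_totals()
    return tables
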