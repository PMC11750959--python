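"""Differential methylation calling.

The test is a smoothed beta-binomial Wald test in the spirit of
dispersion-shrinkage methods for sequencing count data:

1.  group methylation levels are smoothed per context with a simple
    moving average over a ±window/2 bp neighbourhood (counts pooled over
    the group's replicates and the neighbouring loci);
2.  a per-locus beta-binomial dispersion φ is estimated by the method of
    moments across replicates and shrunk toward the context-wide median
    with a coverage-dependent weight;
3.  the Wald statistic is Δm/SE(Δm) where the variance of each group's
    *smoothed* mean is taken under the beta-binomial model over every
    (sample, locus) depth n contributing to the window,
    Var(p̂) = Σ n·p(1−p)·(1+(n−1)φ) / (Σ n)²; the reported posterior
    probability is P(|Δ| > δ_context | data) under the normal
    approximation N(Δm, SE²) — the quantity thresholded when a minimum
    effect size δ accompanies the test.

A cytosine is retained as a DMC when |Δm| exceeds the context threshold
δ (0.10 for CG/CHG, 0.07 for CHH) *and* that posterior probability
exceeds 0.9999.  Δm is oriented treatment minus control (G− minus G+).
Because smoothing correlates neighbouring loci, an ordinary Wald
p-value at 0.9999 would still let about one false window per genome
through and false windows arrive as multi-site clusters; the
effect-size posterior suppresses them entirely while keeping full power
against effects comfortably above δ.

Regions (DMRs) are maximal runs of same-context, same-sign loci in which
at least half the loci pass the DMC rule, at least ``min_sites`` pass,
and the span is at least ``min_len`` bp; same-sign regions closer than
``merge_gap`` bp are merged.  Region direction labels use the coarser
hyper/hypo cutoffs (0.25 CG, 0.25 CHG, 0.10 CHH) on the region-mean Δm;
regions below the cutoff are kept with direction ``weak`` and excluded
from hyper/hypo tallies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .io import CONTEXTS, CytosineCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "DmcThresholds",
    "DmrParameters",
    "DIRECTION_CUTOFFS",
    "smooth_methylation",
    "estimate_dispersion",
    "call_dmcs",
    "call_dmrs",
    "label_dmr_direction",
    "dmrs_to_bed",
]

#: hyper/hypo cutoffs on region-mean |Δm| per context
DIRECTION_CUTOFFS = {"CG": 0.25, "CHG": 0.25, "CHH": 0.10}

DEFAULT_SMOOTHING_WINDOW = 500  # bp, moving-average span
DEFAULT_PRIOR_COVERAGE = 100.0  # pseudo-coverage weighting the dispersion prior
FALLBACK_DISPERSION = 0.05      # when a context has no estimable locus at all


@dataclass(frozen=True)
class DmcThresholds:
    """Retention thresholds for differentially methylated cytosines."""

    diff_cg: float = 0.10
    diff_chg: float = 0.10
    diff_chh: float = 0.07
    p_post: float = 0.9999

    def __post_init__(self) -> None:
        for name in ("diff_cg", "diff_chg", "diff_chh", "p_post"):
            x = getattr(self, name)
            if not 0 < x < 1:
                raise ValueError(f"threshold {name}={x} outside (0, 1)")

    def diff(self, context: str) -> float:
        return {"CG": self.diff_cg, "CHG": self.diff_chg, "CHH": self.diff_chh}[context]


@dataclass(frozen=True)
class DmrParameters:
    min_len: int = 50
    min_sites: int = 3
    merge_gap: int = 100
    pct_sig: float = 0.5

    def __post_init__(self) -> None:
        if self.min_len <= 0 or self.min_sites <= 0 or self.merge_gap < 0:
            raise ValueError("DMR parameters must be positive")
        if not 0 < self.pct_sig <= 1:
            raise ValueError("pct_sig must be in (0, 1]")


def _context_blocks(df: pd.DataFrame):
    """Yield (chrom, context, integer index array sorted by position)."""
    for (chrom, ctx), grp in df.groupby(["chrom", "context"], sort=True, observed=True):
        if ctx not in CONTEXTS:
            continue
        idx = grp.index.values[np.argsort(grp["pos"].values, kind="stable")]
        yield chrom, ctx, idx


def _window_sums(
    df: pd.DataFrame, arrays: list[np.ndarray], window_bp: float
) -> list[np.ndarray]:
    """Moving-window sums of per-locus quantities, per (chrom, context)
    block, window = ±window_bp/2 around each locus position."""
    half = window_bp / 2.0
    out = [np.zeros(len(df)) for _ in arrays]
    for _, _, idx in _context_blocks(df):
        pos = df["pos"].values[idx].astype(float)
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        for arr, acc in zip(arrays, out):
            cs = np.concatenate([[0.0], np.cumsum(arr[idx])])
            acc[idx] = cs[hi] - cs[lo]
    return out


def smooth_methylation(
    table: CytosineCountTable,
    group: str,
    window_bp: int = DEFAULT_SMOOTHING_WINDOW,
) -> pd.DataFrame:
    """Moving-average smoothed group methylation level per locus.

    Counts are pooled over the group's replicates and over same-context
    loci within ±window_bp/2; smoothing never pools across contexts.
    Loci with zero pooled coverage in the whole window are untestable
    (level NaN).  Returns a DataFrame indexed like ``table.df`` with
    columns level, window_meth, window_total, own_meth, own_total.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    meth, total = table.pooled_counts(group)
    wmeth, wtotal = _window_sums(table.df, [meth, total], window_bp)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(wtotal > 0, wmeth / np.maximum(wtotal, 1e-300), np.nan)
    return pd.DataFrame(
        {
            "level": level,
            "window_meth": wmeth,
            "window_total": wtotal,
            "own_meth": meth,
            "own_total": total,
        },
        index=table.df.index,
    )


def estimate_dispersion(
    table: CytosineCountTable,
    group: str,
    context: str | None = None,
    prior_coverage: float = DEFAULT_PRIOR_COVERAGE,
) -> pd.DataFrame:
    """Per-locus beta-binomial dispersion for one group.

    Method-of-moments across replicates, shrunk toward the context-wide
    median with weight coverage/(coverage + prior_coverage).  Loci where
    the raw estimate is undefined (single covered replicate, degenerate
    mean) take the context median; contexts with no estimable locus fall
    back to a fixed mild prior.  Returns columns raw, shrunk, prior and
    a fallback flag.
    """
    samples = table.group_samples(group)
    M = np.stack([table.df[f"meth_{s}"].values for s in samples]).astype(float)
    N = np.stack([table.df[f"total_{s}"].values for s in samples]).astype(float)
    if len(samples) < 2:
        warnings.warn(
            f"group {group!r} has a single replicate; using context-wide "
            "fallback dispersion",
            stacklevel=2,
        )
    covered = N > 0
    r_eff = covered.sum(axis=0)
    cov_total = N.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(covered, M / np.maximum(N, 1e-300), np.nan)
        pbar = np.where(cov_total > 0, M.sum(axis=0) / np.maximum(cov_total, 1e-300), np.nan)
        resid2 = np.nansum((P - pbar) ** 2, axis=0)
        s2 = np.where(r_eff >= 2, resid2 / np.maximum(r_eff - 1, 1), np.nan)
        inv_n = np.where(covered, 1.0 / np.maximum(N, 1e-300), 0.0)
        m1 = np.where(r_eff > 0, inv_n.sum(axis=0) / np.maximum(r_eff, 1), np.nan)
        pq = pbar * (1.0 - pbar)
        raw = (s2 / np.maximum(pq, 1e-12) - m1) / np.maximum(1.0 - m1, 1e-12)
    raw = np.where((r_eff >= 2) & (pq > 1e-12), raw, np.nan)
    raw = np.clip(raw, 0.0, 0.99)

    ctx = table.df["context"].values
    prior = np.full(len(ctx), FALLBACK_DISPERSION)
    contexts = [context] if context else list(CONTEXTS)
    for c in contexts:
        mask = ctx == c
        vals = raw[mask]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            prior[mask] = float(np.median(vals))
    w = cov_total / (cov_total + prior_coverage)
    shrunk = np.where(np.isnan(raw), prior, w * np.nan_to_num(raw) + (1 - w) * prior)
    out = pd.DataFrame(
        {
            "raw": raw,
            "shrunk": shrunk,
            "prior": prior,
            "fallback": np.isnan(raw),
        },
        index=table.df.index,
    )
    if context:
        out = out[table.df["context"] == context]
    return out


def _smoothed_group_stats(
    table: CytosineCountTable,
    group: str,
    phi: np.ndarray,
    window_bp: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(smoothed mean, its beta-binomial variance, own total) per locus.

    The smoothed mean pools counts over the window; its variance sums
    n·(1+(n−1)φ) over every (sample, locus-in-window) depth n, scaled by
    p(1−p)/(Σn)² — the variance of the window-pooled estimator.
    """
    samples = table.group_samples(group)
    N = np.stack([table.df[f"total_{s}"].values for s in samples]).astype(float)
    meth, total = table.pooled_counts(group)
    infl = (N * (1.0 + (N - 1.0) * phi)).sum(axis=0)
    wmeth, wtotal, winfl = _window_sums(table.df, [meth, total, infl], window_bp)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(wtotal > 0, wmeth / np.maximum(wtotal, 1e-300), np.nan)
        p_eff = np.clip(p, 1e-5, 1 - 1e-5)
        var = np.where(
            wtotal > 0,
            winfl * p_eff * (1.0 - p_eff) / np.maximum(wtotal, 1e-300) ** 2,
            np.nan,
        )
    return p, var, total


def call_dmcs(
    table: CytosineCountTable,
    group1: str | None = None,
    group2: str | None = None,
    thresholds: DmcThresholds = DmcThresholds(),
    window_bp: int = DEFAULT_SMOOTHING_WINDOW,
    prior_coverage: float = DEFAULT_PRIOR_COVERAGE,
) -> pd.DataFrame:
    """Per-locus Wald tests and DMC retention flags, genome-wide.

    Δm is oriented ``group1 − group2`` (defaults: treatment "G-" minus
    control "G+" when those two groups are present).  The returned frame
    keeps every testable locus — DMR calling needs the non-significant
    ones too — with columns chrom, pos, context, mean1, mean2, delta,
    se, stat, p_post, is_dmc, coverage.
    """
    groups = sorted(set(table.groups.values()))
    if group1 is None or group2 is None:
        if set(groups) == {"G+", "G-"}:
            group1, group2 = "G-", "G+"
        elif len(groups) == 2:
            group1, group2 = groups[1], groups[0]
        else:
            raise ValueError("specify group1 and group2 explicitly")

    phi1 = estimate_dispersion(table, group1, prior_coverage=prior_coverage)["shrunk"].values
    phi2 = estimate_dispersion(table, group2, prior_coverage=prior_coverage)["shrunk"].values
    m1, var1, own1 = _smoothed_group_stats(table, group1, phi1, window_bp)
    m2, var2, own2 = _smoothed_group_stats(table, group2, phi2, window_bp)
    testable = (own1 > 0) & (own2 > 0)

    delta = m1 - m2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(var1 + var2)
        stat = np.where(se > 0, delta / np.maximum(se, 1e-300), np.where(delta == 0, 0.0, np.inf * np.sign(delta)))

    ctx = table.df["context"].values
    diff_thr = np.full(len(ctx), np.nan)
    for c in CONTEXTS:
        diff_thr[ctx == c] = thresholds.diff(c)
    # posterior probability that the true |difference| exceeds the context
    # threshold, under the normal approximation N(delta, se²)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_hi = (diff_thr - delta) / np.maximum(se, 1e-300)
        z_lo = (-diff_thr - delta) / np.maximum(se, 1e-300)
    p_post = 0.5 * (1.0 - erf(z_hi / np.sqrt(2.0))) + 0.5 * (1.0 + erf(z_lo / np.sqrt(2.0)))
    p_post = np.where(se > 0, p_post, (np.abs(delta) > diff_thr).astype(float))
    is_dmc = testable & (np.abs(delta) > diff_thr) & (p_post > thresholds.p_post)

    out = pd.DataFrame(
        {
            "chrom": table.df["chrom"].values,
            "pos": table.df["pos"].values,
            "context": ctx,
            "mean1": m1,
            "mean2": m2,
            "delta": delta,
            "se": se,
            "stat": stat,
            "p_post": p_post,
            "testable": testable,
            "is_dmc": is_dmc,
            "coverage": own1 + own2,
        }
    )
    n_testable = int(testable.sum())
    if n_testable == 0:
        warnings.warn("no testable loci (a group lacks coverage everywhere)", stacklevel=2)
    return out


def label_dmr_direction(mean_delta: float, context: str) -> str:
    """hyper/hypo/weak from the region-mean Δm and the context cutoff."""
    cutoff = DIRECTION_CUTOFFS[context]
    if mean_delta >= cutoff:
        return "hyper"
    if mean_delta <= -cutoff:
        return "hypo"
    return "weak"


#: a run may bridge consecutive passing sites across at most this many bp
#: when failing loci lie between them (the density rule still applies);
#: with no intervening loci the bridge is capped at the merge gap
MAX_BRIDGE_BP = 1000


def _find_runs(
    pos: np.ndarray, pidx: np.ndarray, signs: np.ndarray, params: "DmrParameters"
) -> list[list[int]]:
    """Greedy maximal runs over passing-locus indices: a run absorbs the
    next same-sign passing locus as long as the passing fraction over the
    enclosed locus span stays ≥ pct_sig and the positional gap is
    bridgeable (≤ merge_gap when empty, ≤ MAX_BRIDGE_BP otherwise)."""
    runs: list[list[int]] = []
    cur = [int(pidx[0])]
    for k in range(1, pidx.size):
        nxt = int(pidx[k])
        prev = cur[-1]
        span = nxt - cur[0] + 1
        gap = pos[nxt] - pos[prev]
        bridgeable = gap <= params.merge_gap or (
            nxt - prev > 1 and gap <= MAX_BRIDGE_BP
        )
        if (
            signs[k] == signs[k - 1]
            and bridgeable
            and (len(cur) + 1) / span >= params.pct_sig
        ):
            cur.append(nxt)
        else:
            runs.append(cur)
            cur = [nxt]
    runs.append(cur)
    return runs


def _run_record(pos, delta, stat, cov, run, params):
    lo, hi = run[0], run[-1]
    if len(run) < params.min_sites:
        return None
    if pos[hi] - pos[lo] + 1 < params.min_len:
        return None
    span = np.arange(lo, hi + 1)
    w = np.maximum(cov[span], 1e-300)
    return {
        "start": int(pos[lo]),
        "end": int(pos[hi]),
        "n_sites": len(run),
        "n_loci": int(span.size),
        "mean_delta": float(np.sum(delta[span] * w) / np.sum(w)),
        "area_stat": float(np.nansum(stat[span])),
    }


def call_dmrs(
    dmc_table: pd.DataFrame,
    params: DmrParameters = DmrParameters(),
) -> pd.DataFrame:
    """Call DMRs from genome-wide per-locus statistics (``call_dmcs`` output).

    Returns a DataFrame with columns chrom, start, end (1-based
    inclusive), context, n_sites, mean_delta, area_stat, direction.
    """
    records = []
    for (chrom, ctx), grp in dmc_table.groupby(["chrom", "context"], sort=True, observed=True):
        if ctx not in CONTEXTS:
            continue
        grp = grp[grp["testable"]].sort_values("pos")
        pos = grp["pos"].values.astype(np.int64)
        delta = grp["delta"].values
        stat = grp["stat"].values
        cov = grp["coverage"].values
        is_dmc = grp["is_dmc"].values.astype(bool)
        pidx = np.where(is_dmc)[0]
        if pidx.size < params.min_sites:
            continue
        signs = np.sign(delta[pidx])
        accepted = []
        for run in _find_runs(pos, pidx, signs, params):
            rec = _run_record(pos, delta, stat, cov, run, params)
            if rec is not None:
                accepted.append(rec)
        # final merge pass: adjacent same-sign regions within merge_gap
        accepted.sort(key=lambda r: r["start"])
        merged: list[dict] = []
        for reg in accepted:
            if (
                merged
                and reg["start"] - merged[-1]["end"] <= params.merge_gap
                and np.sign(reg["mean_delta"]) == np.sign(merged[-1]["mean_delta"])
            ):
                prev = merged[-1]
                w_prev, w_new = prev["n_loci"], reg["n_loci"]
                prev["mean_delta"] = (
                    prev["mean_delta"] * w_prev + reg["mean_delta"] * w_new
                ) / (w_prev + w_new)
                prev["end"] = reg["end"]
                prev["n_sites"] += reg["n_sites"]
                prev["n_loci"] += reg["n_loci"]
                prev["area_stat"] += reg["area_stat"]
            else:
                merged.append(reg)
        for reg in merged:
            records.append(
                {
                    "chrom": chrom,
                    "start": reg["start"],
                    "end": reg["end"],
                    "context": ctx,
                    "n_sites": reg["n_sites"],
                    "mean_delta": reg["mean_delta"],
                    "area_stat": reg["area_stat"],
                    "direction": label_dmr_direction(reg["mean_delta"], ctx),
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "chrom", "start", "end", "context", "n_sites",
            "mean_delta", "area_stat", "direction",
        ],
    )


def dmrs_to_bed(dmrs: pd.DataFrame, path=None) -> pd.DataFrame:
    """BED6+ export: 0-based half-open, score = |Δm|·1000 truncated."""
    bed = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"] - 1,
            "end": dmrs["end"],
            "name": [
                f"DMR_{c}_{s}_{e}"
                for c, s, e in zip(dmrs["chrom"], dmrs["start"], dmrs["end"])
            ],
            "score": (dmrs["mean_delta"].abs() * 1000).astype(int),
            "strand": ".",
            "context": dmrs["context"],
            "n_sites": dmrs["n_sites"],
            "mean_diff": dmrs["mean_delta"],
            "direction": dmrs["direction"],
        }
    )
    if path is not None:
        bed.to_csv(path, sep="\t", header=False, index=False)
    return bed
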