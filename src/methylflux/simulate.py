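"""Synthetic data generators for every pipeline stage.

All generators are pure functions of (spec, seed): the same inputs give
byte-identical outputs, and every generator emits its planted ground
truth alongside the data.

* :func:`make_toy_network` builds a miniature heterotrophic-cell model:
  substrate uptake feeding biomass synthesis (cell wall, protein,
  optional extra sink chains) plus a one-carbon THF/SAM-style methyl
  cycle whose net flux drains into methylated products.  The ground
  truth satisfies steady state exactly by construction.
* :func:`simulate_concentration_timecourse` integrates the ground-truth
  exchange fluxes into linear content curves (piecewise-constant fluxes)
  and adds multiplicative replicate noise — the inverse problem the
  time-series module solves.
* :func:`simulate_methylome` lays out a toy annotated genome (genes with
  exons, TEs that are extragenic, intronic or promoter-resident),
  scatters cytosines with CG/CHG/CHH context labels, and draws
  beta-binomial counts per sample with context-specific baseline levels
  and planted differentially methylated regions.
* :func:`simulate_expression_table` draws negative-binomial counts for
  3 vs 3 replicates, runs a real two-group test on log2 CPM with
  Benjamini–Hochberg adjustment (so the downstream DEG filter is
  exercised end-to-end), and plants fold changes — optionally
  anticorrelated with planted promoter DMRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomicFeatureSet
from .methylome.io import CytosineCountTable
from .network import Metabolite, Reaction, ReactionNetwork

__all__ = [
    "SyntheticFluxSpec",
    "SyntheticMethylomeSpec",
    "SyntheticExpressionSpec",
    "PlantedDmr",
    "SimulatedMethylome",
    "make_toy_network",
    "simulate_concentration_timecourse",
    "simulate_methylome",
    "simulate_expression_table",
    "example_planted_dmrs",
]


# ---------------------------------------------------------------------------
# flux ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticFluxSpec:
    """Stated world for the flux arm.

    ``sam_cycle_flux`` is the G+ one-carbon cycle magnitude
    (mmol·gDW⁻¹·day⁻¹); ``condition_scales`` multiply the whole ground
    truth per condition (glucose-poor cells run at a fraction of the
    glucose-rich fluxes).
    """

    cell_wall_flux: float = 1.2
    protein_flux: float = 0.8
    sam_cycle_flux: float = 0.075
    extra_chain_fluxes: tuple[float, ...] = (0.5, 0.3)
    condition_scales: tuple[tuple[str, float], ...] = (("G+", 1.0), ("G-", 0.15))
    days: tuple[int, ...] = (4, 5, 6, 7, 8)
    replicates: int = 4
    noise_cv: float = 0.05

    def scales(self) -> dict[str, float]:
        return dict(self.condition_scales)


def make_toy_network(
    spec: SyntheticFluxSpec = SyntheticFluxSpec(), seed: int = 0
) -> tuple[ReactionNetwork, np.ndarray]:
    """Toy metabolic network plus a feasible ground-truth flux vector.

    The seed only affects nothing structural today (the topology is a
    stated world, not a random draw) but is part of the signature so
    every generator funnels through one seed argument.
    """
    if any(f < 0 for f in spec.extra_chain_fluxes) or min(
        spec.cell_wall_flux, spec.protein_flux, spec.sam_cycle_flux
    ) < 0:
        raise ValueError(
            "irreversible toy reactions cannot carry a negative requested flux"
        )
    internal = ["A", "B", "THF", "MTHF", "HCY", "MET", "SAM", "SAH"]
    external = ["GLC_ext", "CW_ext", "PROT_ext", "CH3_ext"]
    mets = [Metabolite(m, is_internal=True) for m in internal]
    mets += [Metabolite(m, is_internal=False) for m in external]
    f = spec.sam_cycle_flux
    cw, prot = spec.cell_wall_flux, spec.protein_flux
    rxns = [
        ("upt", {"GLC_ext": -1, "A": 1}, cw + prot + f + sum(spec.extra_chain_fluxes)),
        ("growth", {"A": -1, "B": 1}, cw + prot),
        ("cw_syn", {"B": -1, "CW_ext": 1}, cw),
        ("prot_syn", {"B": -1, "PROT_ext": 1}, prot),
        ("ch2_donor", {"A": -1, "THF": -1, "MTHF": 1}, f),
        ("met_syn", {"MTHF": -1, "HCY": -1, "MET": 1, "THF": 1}, f),
        ("sam_syn", {"MET": -1, "SAM": 1}, f),
        ("methylation", {"SAM": -1, "SAH": 1, "CH3_ext": 1}, f),
        ("sah_hydrolase", {"SAH": -1, "HCY": 1}, f),
    ]
    for i, flux in enumerate(spec.extra_chain_fluxes, start=1):
        x = f"X{i}"
        mets.append(Metabolite(x, is_internal=True))
        mets.append(Metabolite(f"XS{i}_ext", is_internal=False))
        rxns.append((f"chain{i}_syn", {"A": -1, x: 1}, flux))
        rxns.append((f"chain{i}_exp", {x: -1, f"XS{i}_ext": 1}, flux))
    reactions = [
        Reaction(rid, stoich, reversible=False, lower_bound=0.0)
        for rid, stoich, _ in rxns
    ]
    network = ReactionNetwork(mets, reactions)
    v_true = np.array([v for _, _, v in rxns], dtype=float)
    residual = np.max(np.abs(network.S_internal @ v_true))
    if residual > 1e-12:
        raise AssertionError(f"ground truth violates steady state ({residual:.3g})")
    return network, v_true


#: exchange reactions whose products/substrates are "measured" in the
#: synthetic time course, mapped to the measured component name
MEASURED_EXCHANGES = {
    "upt": "glucose_uptake",
    "cw_syn": "cell_wall",
    "prot_syn": "protein",
    "methylation": "methylated_products",
}


def simulate_concentration_timecourse(
    network: ReactionNetwork,
    v_true: np.ndarray,
    spec: SyntheticFluxSpec = SyntheticFluxSpec(),
    seed: int = 0,
    content0: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concentration CSV rows + ground-truth constraint table.

    Content is linear, content(t) = content(0) + v·t with t measured
    from the first sampled day; replicates get multiplicative Gaussian
    noise of the given CV.  Returns (measurements, truth) where truth
    has one row per (condition, day, reaction) giving the generating
    exchange flux.
    """
    rng = np.random.default_rng(seed)
    measured = dict(MEASURED_EXCHANGES)
    for r in network.reaction_ids:
        if r.startswith("chain") and r.endswith("_exp"):
            measured[r] = f"{r[:-4]}_product"
    days = np.array(spec.days, dtype=float)
    t = days - days[0]
    rows, truth_rows = [], []
    for cond, scale in spec.scales().items():
        v = v_true * scale
        for rid, comp in measured.items():
            j = network.reaction_index(rid)
            slope = float(v[j])
            # auto baseline: pools start the subculture window at ~20% of
            # what they will accumulate, so the multiplicative measurement
            # noise stays proportional to the signal even for small fluxes
            if content0 is not None:
                c0 = content0
            else:
                span = abs(slope) * t[-1]
                c0 = 0.2 * span + max(0.0, -slope * t[-1]) + (0.1 if span == 0 else 0.0)
            content = c0 + slope * t
            if np.any(content < 0):
                raise ValueError(
                    f"content of {comp} goes negative over the day range; "
                    "use a larger content(0)"
                )
            noise = rng.normal(
                1.0, spec.noise_cv, size=(spec.replicates, len(days))
            ) if spec.noise_cv > 0 else np.ones((spec.replicates, len(days)))
            for rep in range(spec.replicates):
                for k, d in enumerate(days):
                    rows.append(
                        (comp, cond, f"rep{rep + 1}", d, max(content[k] * noise[rep, k], 0.0))
                    )
            for d in days:
                truth_rows.append((cond, int(d), rid, comp, slope))
    measurements = pd.DataFrame(
        rows, columns=["component", "condition", "replicate", "day", "value"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["condition", "day", "reaction_id", "component", "flux"]
    )
    return measurements, truth


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedDmr:
    location: str  # promoter | gene | TE | intergenic
    context: str
    delta: float  # G- minus G+
    width: int = 400


@dataclass(frozen=True)
class SyntheticMethylomeSpec:
    """Stated world for the methylome arm.

    Baselines mirror the glucose-rich global levels of a heterotrophic
    grapevine culture (≈48% CG, 32% CHG, 3% CHH); coverage is Poisson
    with the given mean, counts beta-binomial with the given dispersion.
    """

    n_chroms: int = 3
    chrom_length: int = 700_000
    n_genes: int = 120
    n_tes: int = 150
    n_loci: int = 200_000
    baseline: tuple[tuple[str, float], ...] = (("CG", 0.48), ("CHG", 0.32), ("CHH", 0.03))
    context_fractions: tuple[tuple[str, float], ...] = (
        ("CG", 0.25),
        ("CHG", 0.25),
        ("CHH", 0.5),
    )
    dispersion: float = 0.05
    coverage: float = 30.0
    reps_per_group: int = 3
    planted: tuple[PlantedDmr, ...] = ()

    def baselines(self) -> dict[str, float]:
        return dict(self.baseline)


def example_planted_dmrs() -> tuple[PlantedDmr, ...]:
    """A default planting mix: CHH-hyper TEs and promoters plus CG/CHG
    effects of both signs, echoing context-specific stress responses."""
    planted = []
    planted += [PlantedDmr("TE", "CHH", +0.15, 800)] * 8
    planted += [PlantedDmr("promoter", "CHH", +0.15, 800)] * 6
    planted += [PlantedDmr("promoter", "CG", -0.40, 1200)] * 3
    planted += [PlantedDmr("promoter", "CHG", +0.30, 1200)] * 3
    planted += [PlantedDmr("gene", "CG", +0.40, 1200)] * 4
    planted += [PlantedDmr("gene", "CHG", -0.30, 1200)] * 2
    planted += [PlantedDmr("intergenic", "CG", -0.40, 1200)] * 4
    return tuple(planted)


@dataclass
class SimulatedMethylome:
    spec: SyntheticMethylomeSpec
    features: GenomicFeatureSet
    table: CytosineCountTable
    truth: pd.DataFrame  # planted DMRs: chrom, start, end, context, delta, location, gene_id

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit GFF3 + TE BED + per-sample cytosine reports + truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        gff = outdir / "annotation.gff3"
        gff.write_text(_to_gff3(self.features))
        paths["gff3"] = gff
        bed = outdir / "tes.bed"
        te = self.features.tes
        te_cols = te[["chrom", "start", "end"]].copy()
        te_cols["family"] = te["family"] if "family" in te.columns else "TE"
        te_cols.to_csv(bed, sep="\t", header=False, index=False)
        paths["te_bed"] = bed
        df = self.table.df
        for sample in self.table.samples:
            rep = pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "pos": df["pos"],
                    "strand": df["strand"],
                    "count_methylated": df[f"meth_{sample}"],
                    "count_unmethylated": df[f"total_{sample}"] - df[f"meth_{sample}"],
                    "context": df["context"],
                    "tricontext": df["tricontext"] if "tricontext" in df else df["context"],
                }
            )
            p = outdir / f"{sample}.CX_report.txt"
            rep.to_csv(p, sep="\t", header=False, index=False)
            paths[sample] = p
        tp = outdir / "planted_dmrs.tsv"
        self.truth.to_csv(tp, sep="\t", index=False)
        paths["truth"] = tp
        return paths


def _to_gff3(features: GenomicFeatureSet) -> str:
    lines = ["##gff-version 3"]
    for chrom, size in sorted(features.chrom_sizes.items()):
        lines.append(f"##sequence-region {chrom} 1 {size}")
    exons_by_gene = (
        dict(tuple(features.exons.groupby("gene_id", sort=False)))
        if len(features.exons)
        else {}
    )
    for g in features.genes.itertuples(index=False):
        lines.append(
            f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        ex = exons_by_gene.get(g.gene_id)
        if ex is None:
            continue
        for k, e in enumerate(ex.sort_values("start").itertuples(index=False), 1):
            lines.append(
                f"{e.chrom}\tsynthetic\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.exon{k};Parent={g.gene_id}"
            )
    return "\n".join(lines) + "\n"


def _layout_genome(spec: SyntheticMethylomeSpec, rng: np.random.Generator) -> GenomicFeatureSet:
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    sizes = {c: spec.chrom_length for c in chroms}
    gene_rows, exon_rows = [], []
    per_chrom = int(math.ceil(spec.n_genes / spec.n_chroms))
    gid = 0
    for c in chroms:
        cursor = 3000
        for _ in range(per_chrom):
            if gid >= spec.n_genes:
                break
            length = int(rng.integers(2000, 6000))
            gap = int(rng.integers(3000, 9000))
            start = cursor + gap
            end = start + length
            if end + 3000 > spec.chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene{gid + 1:04d}"
            gene_rows.append((c, start, end, strand, gene_id))
            n_ex = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(200, length - 200), 2 * n_ex - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            for k in range(n_ex):
                es, ee = start + int(bounds[2 * k]), start + int(bounds[2 * k + 1])
                if ee > es:
                    exon_rows.append((c, es, ee, strand, gene_id))
            cursor = end
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "strand", "gene_id"])

    # TEs: intronic / promoter-resident / extragenic
    tmp = GenomicFeatureSet(genes, exons, pd.DataFrame(columns=["chrom", "start", "end", "family"]), sizes)
    te_rows = []
    n_intron = spec.n_tes // 5
    n_prom = spec.n_tes // 5
    introns = tmp.introns
    promoters = tmp.promoters
    for i in range(spec.n_tes):
        length = int(rng.integers(300, 1500))
        if i < n_intron and len(introns):
            host = introns.iloc[int(rng.integers(len(introns)))]
            start = int(host["start"]) + 1
            end = min(start + length, int(host["end"]))
        elif i < n_intron + n_prom and len(promoters):
            host = promoters.iloc[int(rng.integers(len(promoters)))]
            start = int(host["start"]) + 1
            end = min(start + length, int(host["end"]))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1000, spec.chrom_length - 2000))
            end = start + length
            te_rows.append((chrom, start, end, f"TEfam{int(rng.integers(1, 6))}"))
            continue
        te_rows.append((host["chrom"], start, end, f"TEfam{int(rng.integers(1, 6))}"))
    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "family"])
    return GenomicFeatureSet(genes, exons, tes, sizes)


def _place_planted(
    spec: SyntheticMethylomeSpec,
    features: GenomicFeatureSet,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose genomic intervals for the planted DMRs.

    Planted regions keep a minimum separation (2.5 kb) from each other:
    closer truths would be fused by smoothing + region merging into a
    single region and stop being individually recoverable ground truth.
    """
    min_separation = 2500
    pools = {
        "promoter": features.promoters,
        "gene": features.genes,
        "TE": features.tes,
    }
    taken: dict[str, list[tuple[int, int]]] = {}
    rows = []
    for k, p in enumerate(spec.planted):
        if abs(p.delta) >= 0.96:
            raise ValueError("planted delta too large to keep means inside [0, 1]")
        placed = False
        for _ in range(200):
            if p.location in pools and len(pools[p.location]):
                pool = pools[p.location]
                host = pool.iloc[int(rng.integers(len(pool)))]
                chrom = host["chrom"]
                lo, hi = int(host["start"]), int(host["end"])
                if hi - lo < 50:
                    continue
                start = int(rng.integers(lo, max(hi - p.width, lo + 1)))
            elif p.location == "intergenic":
                chrom = f"chr{int(rng.integers(spec.n_chroms)) + 1}"
                # crude: sample until away from genes/promoters
                start = int(rng.integers(1000, spec.chrom_length - p.width - 1000))
                g = features.genes
                near = g[
                    (g["chrom"] == chrom)
                    & (g["start"] - 2500 < start + p.width)
                    & (g["end"] + 500 > start)
                ]
                if len(near):
                    continue
            else:
                raise ValueError(f"unknown planted location {p.location!r}")
            end = start + p.width
            if end > spec.chrom_length:
                continue
            overlap = any(
                s - min_separation < end and start < e + min_separation
                for s, e in taken.get(chrom, [])
            )
            if overlap:
                continue
            taken.setdefault(chrom, []).append((start, end))
            gene_id = host["gene_id"] if p.location in ("promoter", "gene") else ""
            rows.append(
                (chrom, start, end, p.context, p.delta, p.location, gene_id)
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place planted DMR #{k} ({p.location}, {p.context})"
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "delta", "location", "gene_id"]
    )


_TRINUC = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}


def simulate_methylome(
    spec: SyntheticMethylomeSpec = SyntheticMethylomeSpec(),
    seed: int = 0,
) -> SimulatedMethylome:
    """Full synthetic methylome: annotation, counts, planted truth."""
    rng = np.random.default_rng(seed)
    features = _layout_genome(spec, rng)
    truth = (
        _place_planted(spec, features, rng)
        if spec.planted
        else pd.DataFrame(
            columns=["chrom", "start", "end", "context", "delta", "location", "gene_id"]
        )
    )

    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    per_chrom = np.full(spec.n_chroms, spec.n_loci // spec.n_chroms)
    per_chrom[: spec.n_loci % spec.n_chroms] += 1
    ctx_names = [c for c, _ in spec.context_fractions]
    ctx_probs = np.array([f for _, f in spec.context_fractions])
    baselines = spec.baselines()

    frames = []
    for c, n in zip(chroms, per_chrom):
        pos = np.sort(rng.choice(np.arange(1, spec.chrom_length + 1), size=n, replace=False))
        ctx = rng.choice(ctx_names, size=n, p=ctx_probs / ctx_probs.sum())
        strand = rng.choice(["+", "-"], size=n)
        frames.append(pd.DataFrame({"chrom": c, "pos": pos, "strand": strand, "context": ctx}))
    df = pd.concat(frames, ignore_index=True)
    df["tricontext"] = df["context"].map(_TRINUC)

    # per-locus baseline means (beta-distributed around the context level)
    mean_gplus = np.empty(len(df))
    conc = {"CG": 6.0, "CHG": 6.0, "CHH": 15.0}
    for c in ctx_names:
        mask = (df["context"] == c).values
        m = baselines[c]
        k = conc[c]
        mean_gplus[mask] = rng.beta(m * k, (1 - m) * k, size=int(mask.sum()))
    mean_gplus = np.clip(mean_gplus, 0.002, 0.998)
    mean_gminus = mean_gplus.copy()

    # planted regions: flat region-level baseline so the planted delta is exact
    for t in truth.itertuples(index=False):
        mask = (
            (df["chrom"] == t.chrom).values
            & (df["pos"].values >= t.start)
            & (df["pos"].values < t.end)
            & (df["context"] == t.context).values
        )
        if not mask.any():
            continue
        lo = max(0.02, 0.02 - t.delta)
        hi = min(0.98, 0.98 - t.delta)
        base = rng.uniform(lo, hi)
        mean_gplus[mask] = base
        mean_gminus[mask] = base + t.delta

    phi = spec.dispersion
    groups: dict[str, str] = {}
    for group, means in (("G+", mean_gplus), ("G-", mean_gminus)):
        a = means * (1 - phi) / phi
        b = (1 - means) * (1 - phi) / phi
        for r in range(spec.reps_per_group):
            sample = f"{group}_{r + 1}"
            groups[sample] = group
            n_cov = rng.poisson(spec.coverage, size=len(df))
            p = rng.beta(a, b)
            df[f"meth_{sample}"] = rng.binomial(n_cov, p)
            df[f"total_{sample}"] = n_cov
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    table = CytosineCountTable(df, groups)
    return SimulatedMethylome(spec, features, table, truth)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Stated world for the expression arm: negative-binomial counts,
    3 vs 3 replicates, planted log2 fold changes of magnitude 2–4."""

    genes: tuple[str, ...] = ()
    frac_deg: float = 0.15
    l2fc_magnitude: tuple[float, float] = (2.0, 4.0)
    nb_dispersion: float = 0.1
    mean_log_expression: float = 5.0
    sd_log_expression: float = 1.2
    reps_per_group: int = 3
    anticorrelation_links: tuple[tuple[str, float], ...] = ()
    # (gene_id, promoter-DMR delta) pairs; the planted L2FC sign opposes delta


def simulate_expression_table(
    spec: SyntheticExpressionSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DEG-results table (gene, log2FC, padj, cpm) plus planted truth.

    Counts are NB(μ, dispersion) per replicate; the reported log2FC is
    the observed group difference of mean log2 CPM, padj comes from a
    Welch t-test on log2 CPM with Benjamini–Hochberg adjustment.
    """
    if not 0 <= spec.frac_deg <= 1:
        raise ValueError("frac_deg outside [0, 1]")
    if not spec.genes:
        raise ValueError("spec.genes is empty")
    rng = np.random.default_rng(seed)
    genes = list(spec.genes)
    n = len(genes)
    links = dict(spec.anticorrelation_links)

    base_mu = np.exp(rng.normal(spec.mean_log_expression, spec.sd_log_expression, n))
    true_l2fc = np.zeros(n)
    lo, hi = spec.l2fc_magnitude
    n_planted = int(round(spec.frac_deg * n))
    planted_idx = rng.choice(n, size=n_planted, replace=False)
    true_l2fc[planted_idx] = rng.uniform(lo, hi, n_planted) * rng.choice([-1, 1], n_planted)
    for i, g in enumerate(genes):
        if g in links:
            true_l2fc[i] = -math.copysign(rng.uniform(lo, hi), links[g])

    r = spec.reps_per_group
    mu1 = np.broadcast_to(base_mu[:, None], (n, r)).copy()                      # G+
    mu2 = np.broadcast_to((base_mu * 2.0 ** true_l2fc)[:, None], (n, r)).copy()  # G-
    alpha = spec.nb_dispersion

    def _nb(mu):
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
        return rng.poisson(lam)

    counts1 = _nb(mu1)
    counts2 = _nb(mu2)
    lib1 = counts1.sum(axis=0)
    lib2 = counts2.sum(axis=0)
    cpm1 = counts1 / lib1 * 1e6
    cpm2 = counts2 / lib2 * 1e6
    log1 = np.log2(cpm1 + 0.5)
    log2_ = np.log2(cpm2 + 0.5)
    obs_l2fc = log2_.mean(axis=1) - log1.mean(axis=1)             # G- minus G+
    # moderated two-group t on log2 CPM: per-gene pooled variance shrunk
    # toward the experiment-wide mean (prior df 4), which keeps genes with
    # a zero-count group testable instead of degenerate
    resid = np.concatenate(
        [log1 - log1.mean(axis=1, keepdims=True), log2_ - log2_.mean(axis=1, keepdims=True)],
        axis=1,
    )
    df_resid = 2 * r - 2
    s2 = (resid**2).sum(axis=1) / df_resid
    d0 = 4.0
    s2_prior = float(np.mean(s2))
    s2_mod = (d0 * s2_prior + df_resid * s2) / (d0 + df_resid)
    tstat = obs_l2fc / np.sqrt(s2_mod * (2.0 / r))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=d0 + df_resid)
    pval = np.where(np.isnan(pval), 1.0, pval)
    from statsmodels.stats.multitest import multipletests

    padj = multipletests(pval, method="fdr_bh")[1]
    cpm_mean = np.concatenate([cpm1, cpm2], axis=1).mean(axis=1)

    table = pd.DataFrame(
        {"gene": genes, "log2FC": obs_l2fc, "padj": padj, "cpm": cpm_mean}
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "true_l2fc": true_l2fc,
            "is_planted": true_l2fc != 0,
            "linked": [g in links for g in genes],
        }
    )
    return table, truth
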