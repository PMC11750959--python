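# Methods

This note documents the models implemented in `methylflux`, their
assumptions, the parameters that matter, and the numerical choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Snapshot flux balance

### Model

Each sampling day of a culture is treated as an independent
steady-state snapshot. For a stoichiometric matrix `S` (rows =
metabolites, columns = reactions) with internal rows `S_int`, the flux
vector `v` (mmol·gDW⁻¹·day⁻¹) solves

    minimize   Σⱼ wⱼ vⱼ²
    subject to S_int · v = 0,
               v_j = m_j            for measured reactions j,
               lb ≤ v ≤ ub.

The measured values `m_j` are accumulation rates obtained by
differentiating curves fitted through concentration/biomass time
courses (§2). The quadratic objective (default weights `w = 1`) is an
assumption: it is strictly convex, so the reported flux distribution is
*unique* — two solver runs agree to machine precision — and it
penalizes futile cycles the way a parsimony principle should. A
per-reaction weight vector is accepted for sensitivity analysis.
Reversible reactions are kept as single signed variables; bounds encode
reversibility (irreversible ⇒ `lb ≥ 0`).

Because constraints are homogeneous apart from the measured values,
scaling all measurements by α > 0 scales the optimum by α; this is
verified as a property test.

### Solver

Problems here are dense and tiny (tens of variables), so the solver is
plain linear algebra rather than a QP library: the equality-constrained
stationary point comes from the KKT block system solved with
`numpy.linalg.lstsq` (rank-deficient constraint matrices are fine when
consistent); bounds are handled by a clamping active-set loop with
multiplier checks; if that loop fails to settle, SLSQP provides a
feasible point that is then re-polished through the exact reduced KKT
solve. Primal feasibility tolerance is 1e-9; steady-state residuals
are recomputed from the returned vector (never taken from solver
bookkeeping) and a solution is only labelled `optimal` if
`max |S_int·v| ≤ 1e-8`.

### Relaxation of inconsistent measurements

Noisy derivatives generally violate steady state jointly. Rather than
failing, the solver then runs a two-stage relaxation: (1) minimize the
*unweighted* sum of squared constraint violations subject to steady
state and bounds; (2) minimize the flux norm with the violations pinned
at their stage-1 values. The solution is flagged `relaxed` and the
per-constraint residuals are reported.

A consequence worth knowing: the unweighted stage 1 splits
inconsistency in *absolute* terms, so a small measured flux (the SAM
cycle at 0.075 mmol·gDW⁻¹·day⁻¹) can inherit error from a large one
(substrate uptake at ~2.9). Per-day snapshot estimates of small fluxes
under 5 % measurement noise therefore scatter; averaging over days, or
converting measurements to bands (`relative_tolerance` in the solver
config), stabilizes them.

### Flux activity

For internal metabolite m, `producing = Σⱼ max(S[m,j]·vⱼ, 0)` and
`consuming = −Σⱼ min(S[m,j]·vⱼ, 0)`; contributions are signed, so a
reversible reaction running backwards counts on the correct side. At an
optimal (steady-state) solution the two sums agree to ≤ 1e-8.

## 2. Time series → exchange constraints

Rates are estimated from replicate *means* per day (matching per-day
mean ± CI reporting practice), never from pooled raw points; the
replicate count and SEMs travel with the fit.

The default fit is a **not-a-knot interpolating cubic spline** through
the replicate means (local quadratic for series shorter than 4 days).
A GCV-tuned smoothing spline was considered and is available as
`method="smooth"`, but scipy's implementation carries natural boundary
conditions, which cannot reproduce a cubic — measured error ~0.5 on the
derivative of a noiseless cubic — whereas the not-a-knot spline
reproduces any polynomial of degree ≤ 3 exactly. Exactness on smooth
data was judged the more important property for daily snapshots; the
derivative-consistency tests pin it at 1e-6.

No extrapolation: derivatives are evaluated only inside the sampled day
range, one-sided at the boundary days. Because fit + differentiation is
linear in the replicate means, standard errors propagate exactly
(`FittedCurve.derivative_se`, and `average_derivative` for a day-mean
rate when the underlying flux is believed constant — this also
suppresses the boundary-day noise amplification of spline derivatives).

Fresh-weight values convert to dry weight as
`value / (1 − water_content)`. Growth summaries report
`mean_to/mean_from` rounded half-up to one decimal (197.6/160 = 1.235
reports as 1.2-fold).

## 3. Differential methylation

### Per-cytosine test

For each group g, locus i and context c:

* **Smoothed mean.** Counts are pooled over the group's replicates and
  over same-context loci within ±250 bp (window 500 bp, configurable):
  `p̂ = Σ meth / Σ total`. Smoothing never crosses contexts; a locus
  with zero pooled coverage is untestable.
* **Dispersion.** Beta-binomial dispersion φ per locus by method of
  moments across replicates, shrunk toward the context-wide median with
  weight `cov/(cov + n₀)` (prior pseudo-coverage n₀ = 100). Loci where
  the raw estimate is undefined take the context median; a context with
  no estimable locus falls back to φ = 0.05. Exact numerical equality
  with any reference implementation is not claimed — threshold logic
  and qualitative behaviour are the contract.
* **Variance of the smoothed mean.** Over every (sample, locus) depth n
  contributing to the window:
  `Var(p̂) = p(1−p) · Σ n(1+(n−1)φ) / (Σ n)²`.
  Testing the smoothed mean against a locus-own-coverage SE is
  mis-calibrated (a true Δm = 0.4 at 30× would sit near the decision
  boundary); the window-pooled variance is the variance of the
  estimator actually used.
* **Decision.** Δm = p̂(G−) − p̂(G+) (treatment minus control). A locus
  is a DMC when |Δm| > δ_c — δ = 0.10 (CG), 0.10 (CHG), 0.07 (CHH) —
  *and* the posterior probability that the true difference exceeds δ_c,
  `P(|Δ| > δ_c) = Φ((Δm−δ)/SE) + Φ((−Δm−δ)/SE)`, exceeds 0.9999.
  The effect-size posterior (rather than an ordinary Wald p-value) is
  deliberate: smoothing correlates neighbouring loci, so false
  positives arrive as multi-site windows, and only the effect-size
  criterion keeps whole null genomes clean (measured: 10/10 null seeds
  with zero DMCs and zero DMRs at 200 000 loci) while leaving effects
  comfortably above δ at full power.

Both-group coverage at the locus itself is required for testability.
Symmetric-strand CG sites are *not* collapsed by default (the cytosine
report is taken at face value); `collapse_cg_strands` /
`methylflux methylome --collapse-cg` merges them when desired.

### Regions

Per chromosome and context, candidate regions are greedy maximal runs
of passing loci: a run absorbs the next passing locus if it has the
same sign, the passing fraction over the enclosed locus span stays
≥ 50 %, and the positional gap is bridgeable — ≤ 100 bp when no locus
lies between, ≤ 1 kb when intervening (failing) loci exist. Runs need
≥ 3 passing sites and ≥ 50 bp span; same-sign regions closer than
100 bp are merged. Region Δm is the coverage-weighted mean of the
(smoothed) site Δm over all loci in the span; an areaStat-like score
sums the site statistics. Reported coordinates are 1-based inclusive;
internal intervals and BED exports are 0-based.

Direction labels use coarser cutoffs on region-mean Δm: hyper if
Δm ≥ 0.25 (CG), 0.25 (CHG), 0.10 (CHH); hypo if ≤ −cutoff; otherwise
the region is kept with direction `weak` and excluded from hyper/hypo
tallies. Applying the cutoff to the region mean (not per site) is an
assumption.

### Metagene profiles

Genes/TEs contribute a 2 kb upstream flank (fixed-width bins), a body
rescaled to a fixed bin count, and a 2 kb downstream flank;
minus-strand features are reversed so bin 0 is always 5′. Bin values
are pooled proportions per context and group; bins with no coverage
anywhere (e.g. flanks truncated at a chromosome edge) are NaN, never 0.

## 4. Integration

Promoters are the 2 kb upstream of the TSS (strand-aware, clipped at
chromosome bounds). DMR categories follow the precedence
promoter > exon > intron > extragenic-TE > intergenic with ≥ 1 bp
overlap; ties inside a tier go to the larger overlap, then the leftmost
feature; a promoter- or intron-assigned DMR that also overlaps a TE is
re-labelled TE-promoter / TE-intron. The categories partition any DMR
set — a property test asserts the tally always sums to the set size.

DEGs satisfy CPM > 10 AND padj < 0.05 AND |log2FC| > 1 (padj is
consumed, never computed here). Genic-category DMRs (exon, intron,
TE-intron) over DEGs form DMEGs; promoter-category DMRs (promoter,
TE-promoter) form promDMEGs, one record per (DMR, gene) pair — the same
gene can legitimately appear twice. Quadrants are the joint signs of
(region Δm, log2FC); the correlation sign is negative exactly when they
differ; zero differences are flagged unclassifiable and excluded from
tallies with a warning.

## 5. Synthetic worlds

Every generator is a pure function of (spec, seed); identical inputs
give byte-identical outputs, and planted truth is always emitted with
the data. What a green test establishes is calibration *within these
worlds*; real data add alignment artefacts, coverage biases, context
misassignment and batch structure that the generators deliberately do
not model.

* **Flux world.** Fixed topology (uptake → biomass plus a THF/SAM-like
  methyl cycle and optional extra sink chains); ground truth satisfies
  `S_int·v = 0` identically. Defaults: SAM-cycle flux 0.075
  mmol·gDW⁻¹·day⁻¹ (the published glucose-rich magnitude at day 6),
  cell wall 1.2, protein 0.8; the glucose-poor condition runs at 15 %
  of glucose-rich. Time courses are linear (piecewise-constant fluxes),
  days 4–8, 4 replicates, 5 % multiplicative noise. Measured pools
  start the window at 20 % of what they will accumulate, keeping the
  multiplicative noise proportional to signal even for small fluxes.
* **Methylome world.** 3 chromosomes × 700 kb; 120 genes with 2–4
  exons; 150 TEs (≈20 % intronic, 20 % promoter-resident, 60 %
  extragenic). Default 200 000 cytosines (contexts 25/25/50 %
  CG/CHG/CHH); recall suites use 500 000 — about one in-context
  cytosine per 4 bp, the density of a real plant cytosine report.
  Per-locus baselines are beta-distributed around 0.48/0.32/0.03
  (CG/CHG/CHH, the glucose-rich global magnitudes); coverage
  Poisson(30); counts beta-binomial with dispersion 0.05. Planted DMRs
  (default width 1000 bp ≈ 2× the smoothing window, so region cores are
  undiluted) use a flat region baseline so the planted Δm is exact, and
  keep ≥ 2.5 kb separation — closer truths would be fused by smoothing
  and merging and stop being individually recoverable.
* **Expression world.** Negative-binomial counts (dispersion 0.1,
  log-normal baseline means), 3 vs 3 replicates. padj comes from an
  actual test — a variance-moderated two-group t on log2 CPM (prior
  df 4, limma-style) with Benjamini–Hochberg adjustment — not from
  sampled p-values, so the DEG filter is exercised end-to-end; the
  moderation keeps genes with an all-zero count group testable.
  Planted |log2FC| is uniform on [2, 4]; genes linked to a planted
  promoter DMR receive the opposite sign.

## 6. Known limitations

* No dynamic FBA, thermodynamic constraints or flux variability
  analysis; the SBML reader is a deliberate subset (species, reactions,
  stoichiometry, reversibility, boundaryCondition).
* Relaxed snapshots spread inconsistency in absolute terms (§1); small
  fluxes are best read as day averages.
* The differential-methylation test is a simplified
  dispersion-shrinkage Wald test; it does not numerically replicate any
  specific reference tool.
* The context labels of the synthetic genome come from a random
  trinucleotide model, not a sequence; only the labels are consumed
  downstream.
* padj for real expression data must come from a proper differential
  expression tool; the built-in test exists to fabricate calibrated
  synthetic tables only.
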