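"""Smoothing, dispersion estimation, DMC/DMR calling and direction labels."""

import numpy as np
import pandas as pd
import pytest

from methylflux.methylome import (
    DmcThresholds,
    DmrParameters,
    call_dmcs,
    call_dmrs,
    estimate_dispersion,
    label_dmr_direction,
    smooth_methylation,
)

from conftest import make_count_table


def _loci(positions, context="CG", chrom="chr1"):
    ctx = [context] * len(positions) if isinstance(context, str) else context
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "strand": "+", "context": ctx}
    )


def _two_group_table(loci, meth1, total1, meth2, total2, reps=3):
    """reps identical replicates per group (simplest deterministic case)."""
    counts = {}
    groups = {}
    for r in range(reps):
        counts[f"G-_{r+1}"] = (meth1, total1)
        groups[f"G-_{r+1}"] = "G-"
        counts[f"G+_{r+1}"] = (meth2, total2)
        groups[f"G+_{r+1}"] = "G+"
    return make_count_table(loci, counts, groups)


class TestSmoothing:
    def test_isolated_locus_is_own_proportion(self):
        loci = _loci([100, 5000, 9000])
        table = _two_group_table(
            loci, [2, 5, 9], [10, 10, 10], [0, 0, 0], [10, 10, 10], reps=1
        )
        sm = smooth_methylation(table, "G-", window_bp=500)
        np.testing.assert_allclose(sm["level"].values, [0.2, 0.5, 0.9])

    def test_three_locus_window_mean(self):
        """Equal coverage at 10 bp spacing, proportions .2/.4/.6: the
        middle locus smooths to .4."""
        loci = _loci([100, 110, 120])
        table = _two_group_table(
            loci, [2, 4, 6], [10, 10, 10], [0, 0, 0], [10, 10, 10], reps=1
        )
        sm = smooth_methylation(table, "G-", window_bp=100)
        assert sm["level"].values[1] == pytest.approx(0.4)

    def test_never_pools_across_contexts(self):
        loci = _loci([100, 110, 120], context=["CG", "CHH", "CG"])
        table = _two_group_table(
            loci, [10, 0, 10], [10, 10, 10], [0, 0, 0], [10, 10, 10], reps=1
        )
        sm = smooth_methylation(table, "G-", window_bp=200)
        assert sm["level"].values[1] == 0.0  # CHH locus untouched by CG neighbours

    def test_smoothed_level_is_convex_combination(self):
        rng = np.random.default_rng(42)
        n = 200
        loci = _loci(np.sort(rng.choice(20_000, n, replace=False)) + 1)
        meth = rng.integers(0, 11, n)
        table = _two_group_table(loci, meth, np.full(n, 10), meth, np.full(n, 10))
        sm = smooth_methylation(table, "G-", window_bp=500)
        props = sm["own_meth"] / sm["own_total"]
        pos = table.df["pos"].values
        for i in range(n):
            window = (pos >= pos[i] - 250) & (pos <= pos[i] + 250)
            assert props[window].min() - 1e-12 <= sm["level"].iloc[i] <= props[window].max() + 1e-12

    def test_zero_window_coverage_flagged(self):
        loci = _loci([100])
        table = _two_group_table(loci, [0], [0], [0], [10], reps=1)
        sm = smooth_methylation(table, "G-", window_bp=500)
        assert np.isnan(sm["level"].values[0])


class TestDispersion:
    def test_identical_replicates_near_zero(self):
        n = 50
        loci = _loci(np.arange(1, n + 1) * 100)
        meth = np.full(n, 40)
        table = _two_group_table(loci, meth, np.full(n, 100), meth, np.full(n, 100))
        disp = estimate_dispersion(table, "G-")
        assert disp["shrunk"].median() < 0.01

    def test_recovers_generating_dispersion(self):
        """Beta-binomial loci simulated at dispersion 0.1 (coverage 30,
        3 reps): the median raw estimate lands in [0.05, 0.2]."""
        rng = np.random.default_rng(11)
        n = 2000
        phi = 0.1
        loci = _loci(np.arange(1, n + 1) * 100)
        counts, groups = {}, {}
        mean = 0.4
        a, b = mean * (1 - phi) / phi, (1 - mean) * (1 - phi) / phi
        for grp in ("G-", "G+"):
            for r in range(3):
                cov = rng.poisson(30, n)
                p = rng.beta(a, b, n)
                counts[f"{grp}_{r+1}"] = (rng.binomial(cov, p), cov)
                groups[f"{grp}_{r+1}"] = grp
        table = make_count_table(loci, counts, groups)
        disp = estimate_dispersion(table, "G-")
        assert 0.05 <= np.nanmedian(disp["raw"]) <= 0.2

    def test_zero_coverage_locus_takes_prior(self):
        loci = _loci([100, 200])
        counts = {
            "G-_1": ([5, 0], [10, 0]),
            "G-_2": ([4, 0], [10, 0]),
        }
        table = make_count_table(loci, counts, {"G-_1": "G-", "G-_2": "G-"})
        disp = estimate_dispersion(table, "G-")
        assert bool(disp["fallback"].iloc[1])
        assert disp["shrunk"].iloc[1] == disp["prior"].iloc[1]

    def test_single_replicate_warns(self):
        loci = _loci([100])
        table = make_count_table(loci, {"G-_1": ([5], [10])}, {"G-_1": "G-"})
        with pytest.warns(UserWarning, match="single replicate"):
            estimate_dispersion(table, "G-")


class TestDmcCalling:
    def test_identical_groups_no_dmcs(self):
        rng = np.random.default_rng(3)
        n = 500
        loci = _loci(np.arange(1, n + 1) * 40)
        meth = rng.integers(0, 20, n)
        table = _two_group_table(loci, meth, np.full(n, 20), meth, np.full(n, 20))
        res = call_dmcs(table)
        assert res["is_dmc"].sum() == 0
        np.testing.assert_allclose(res["delta"], 0.0, atol=1e-12)

    def test_planted_strong_effect_called_hyper(self):
        """A CG region at true proportions 0.6 (G−) vs 0.1 (G+) at 50x is
        retained with Δm ≈ +0.5."""
        rng = np.random.default_rng(5)
        n = 60
        loci = _loci(np.arange(1, n + 1) * 25)
        counts, groups = {}, {}
        for grp, p in (("G-", 0.6), ("G+", 0.1)):
            for r in range(3):
                cov = np.full(n, 50)
                counts[f"{grp}_{r+1}"] = (rng.binomial(cov, p), cov)
                groups[f"{grp}_{r+1}"] = grp
        table = make_count_table(loci, counts, groups)
        res = call_dmcs(table)
        assert res["is_dmc"].mean() > 0.95
        assert res["delta"].mean() == pytest.approx(0.5, abs=0.05)

    def test_small_effect_excluded_by_magnitude_filter(self):
        """True Δm = 0.05 at enormous coverage: the 0.1 magnitude rule
        excludes the locus regardless of significance."""
        n = 20
        loci = _loci(np.arange(1, n + 1) * 30)
        cov = np.full(n, 100_000)
        table = _two_group_table(
            loci, np.full(n, 45_000), cov, np.full(n, 40_000), cov
        )
        res = call_dmcs(table)
        np.testing.assert_allclose(res["delta"], 0.05, atol=1e-3)
        assert res["is_dmc"].sum() == 0

    def test_orientation_flip(self):
        """Negating the group labels negates every Δm exactly."""
        rng = np.random.default_rng(9)
        n = 200
        loci = _loci(np.arange(1, n + 1) * 40)
        counts, groups = {}, {}
        for grp, p in (("G-", 0.5), ("G+", 0.2)):
            for r in range(3):
                cov = rng.poisson(30, n).clip(min=1)
                counts[f"{grp}_{r+1}"] = (rng.binomial(cov, p), cov)
                groups[f"{grp}_{r+1}"] = grp
        table = make_count_table(loci, counts, groups)
        res = call_dmcs(table)
        res_flipped = call_dmcs(table.with_groups_swapped())
        np.testing.assert_allclose(
            res["delta"].values, -res_flipped["delta"].values, atol=1e-12
        )
        assert (res["is_dmc"] == res_flipped["is_dmc"]).all()

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            DmcThresholds(diff_cg=1.5)

    def test_no_testable_loci_warns(self, uniform_table):
        empty = uniform_table.df.copy()
        for s in uniform_table.samples:
            empty[f"total_{s}"] = 0
            empty[f"meth_{s}"] = 0
        from methylflux.methylome.io import CytosineCountTable

        with pytest.warns(UserWarning, match="no testable"):
            call_dmcs(CytosineCountTable(empty, uniform_table.groups))


def _dmc_frame(positions, deltas, passing, context="CG", chrom="chr1"):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "context": context,
            "mean1": 0.5,
            "mean2": 0.5 - np.asarray(deltas),
            "delta": deltas,
            "se": 0.02,
            "stat": np.asarray(deltas) / 0.02,
            "p_post": np.where(passing, 1.0, 0.0),
            "testable": True,
            "is_dmc": passing,
            "coverage": np.full(n, 60.0),
        }
    )


class TestDmrCalling:
    def test_single_passing_locus_no_dmr(self):
        df = _dmc_frame([100], [0.4], [True])
        assert len(call_dmrs(df)) == 0

    def test_planted_block_single_dmr(self):
        """20 passing CG sites over 500 bp with null flanks give exactly
        one DMR spanning the block (± one site spacing)."""
        block = list(range(1000, 1500, 25))
        flank_left = [200, 600]
        flank_right = [1900, 2300]
        pos = flank_left + block + flank_right
        deltas = [0.0] * 2 + [0.4] * 20 + [0.0] * 2
        passing = [False] * 2 + [True] * 20 + [False] * 2
        dmrs = call_dmrs(_dmc_frame(pos, deltas, passing))
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d["start"] == 1000 and d["end"] == 1475
        assert d["n_sites"] == 20
        assert d["mean_delta"] == pytest.approx(0.4)
        assert d["direction"] == "hyper"

    @pytest.mark.parametrize("gap,expected", [(80, 1), (150, 2)])
    def test_merge_rule(self, gap, expected):
        """Two same-sign passing blocks merge iff separated by ≤ 100 bp."""
        block1 = list(range(1000, 1100, 10))
        block2 = [p + 100 + gap for p in block1]
        pos = block1 + block2
        n = len(pos)
        dmrs = call_dmrs(_dmc_frame(pos, [0.3] * n, [True] * n))
        assert len(dmrs) == expected

    def test_opposite_sign_blocks_never_merge(self):
        block1 = list(range(1000, 1100, 10))
        block2 = [p + 150 for p in block1]
        deltas = [0.3] * len(block1) + [-0.3] * len(block2)
        dmrs = call_dmrs(
            _dmc_frame(block1 + block2, deltas, [True] * (len(block1) * 2))
        )
        assert len(dmrs) == 2
        assert set(dmrs["direction"]) == {"hyper", "hypo"}

    def test_low_density_run_rejected(self):
        """3 passing sites drowned among 17 failing ones fail the ≥50%
        density rule."""
        pos = list(range(1000, 1200, 10))
        passing = [False] * 8 + [True, False, True, False, True] + [False] * 7
        deltas = [0.4 if p else 0.0 for p in passing]
        assert len(call_dmrs(_dmc_frame(pos, deltas, passing))) == 0

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            DmrParameters(min_len=0)
        with pytest.raises(ValueError):
            DmrParameters(pct_sig=0.0)


class TestDirectionLabels:
    @pytest.mark.parametrize(
        "delta,context,expected",
        [
            (0.12, "CHH", "hyper"),   # above the 10% CHH cutoff
            (0.12, "CHG", "weak"),    # below the 25% CHG cutoff
            (-0.31, "CG", "hypo"),    # published promoter DMR magnitude
            (0.25, "CG", "hyper"),    # boundary: cutoff is inclusive
            (-0.09, "CHH", "weak"),
        ],
    )
    def test_cutoffs(self, delta, context, expected):
        assert label_dmr_direction(delta, context) == expected


class TestNullCalibration:
    def test_null_simulation_type_i_control(self):
        """Ten independent null genomes (no planted differences): the
        locus-level retention rate stays ≤ 1e-3 and no multi-site DMR is
        called in at least 9 of 10 seeds."""
        from methylflux.simulate import SyntheticMethylomeSpec, simulate_methylome

        clean_seeds = 0
        for seed in range(10):
            sim = simulate_methylome(
                SyntheticMethylomeSpec(n_loci=200_000), seed=1000 + seed
            )
            res = call_dmcs(sim.table)
            frac = res["is_dmc"].sum() / res["testable"].sum()
            assert frac <= 1e-3
            if len(call_dmrs(res)) == 0:
                clean_seeds += 1
        assert clean_seeds >= 9
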