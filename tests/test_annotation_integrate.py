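"""Feature annotation, DMR categories, DEG filtering, quadrants."""

import numpy as np
import pandas as pd
import pytest

from methylflux.annotation import GenomicFeatureSet, derive_promoters, load_annotation
from methylflux.datasets import load_promdmeg_table
from methylflux.integrate import (
    CATEGORIES,
    assign_dmr_features,
    classify_quadrants,
    filter_degs,
    link_dmr_degs,
)

GFF = """##gff-version 3
chr1\ttest\tgene\t1001\t5000\t.\t+\t.\tID=g1
chr1\ttest\texon\t1001\t2000\t.\t+\t.\tID=g1.e1;Parent=g1
chr1\ttest\texon\t4001\t5000\t.\t+\t.\tID=g1.e2;Parent=g1
chr1\ttest\tgene\t20001\t24000\t.\t-\t.\tID=g2
chr1\ttest\texon\t20001\t24000\t.\t-\t.\tID=g2.e1;Parent=g2
"""

TE_BED = "chr1\t2500\t3200\tfamA\nchr1\t24500\t24900\tfamB\nchr1\t40000\t41000\tfamC\n"


@pytest.fixture
def features():
    return load_annotation(GFF, TE_BED, chrom_sizes={"chr1": 60000})


class TestAnnotationLoading:
    def test_intron_derivation(self, features):
        """Gene 1000–5000 with exons 1000–2000 and 4000–5000 leaves one
        intron at 2000–4000 (0-based half-open)."""
        introns = features.introns
        assert len(introns) == 1
        assert (introns.iloc[0]["start"], introns.iloc[0]["end"]) == (2000, 4000)

    def test_exon_outside_gene_rejected(self):
        bad = GFF.replace(
            "chr1\ttest\texon\t4001\t5000", "chr1\ttest\texon\t4001\t7000"
        )
        with pytest.raises(ValueError, match="outside gene"):
            load_annotation(bad, None)

    def test_unknown_strand_rejected(self):
        genes = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [10], "strand": ["?"],
             "gene_id": ["g"]}
        )
        empty = pd.DataFrame(columns=["chrom", "start", "end", "strand", "gene_id"])
        with pytest.raises(ValueError, match="strand"):
            GenomicFeatureSet(genes, empty, empty)

    def test_empty_te_file_is_valid(self):
        ann = load_annotation(GFF, None)
        assert len(ann.tes) == 0


class TestPromoters:
    def test_plus_strand(self):
        genes = pd.DataFrame(
            {"chrom": ["c"], "start": [5000], "end": [8000], "strand": ["+"],
             "gene_id": ["g"]}
        )
        p = derive_promoters(genes, 2000)
        assert (p.iloc[0]["start"], p.iloc[0]["end"]) == (3000, 5000)

    def test_minus_strand(self):
        genes = pd.DataFrame(
            {"chrom": ["c"], "start": [5000], "end": [8000], "strand": ["-"],
             "gene_id": ["g"]}
        )
        p = derive_promoters(genes, 2000)
        assert (p.iloc[0]["start"], p.iloc[0]["end"]) == (8000, 10000)

    def test_clipped_at_chromosome_start(self):
        genes = pd.DataFrame(
            {"chrom": ["c"], "start": [1200], "end": [4000], "strand": ["+"],
             "gene_id": ["g"]}
        )
        p = derive_promoters(genes, 2000)
        assert (p.iloc[0]["start"], p.iloc[0]["end"]) == (0, 1200)

    def test_deterministic(self, features):
        a = derive_promoters(features.genes)
        b = derive_promoters(features.genes)
        pd.testing.assert_frame_equal(a, b)


def _dmr(start, end, context="CG", chrom="chr1", delta=0.3):
    return {
        "chrom": chrom, "start": start, "end": end, "context": context,
        "mean_delta": delta, "direction": "hyper",
    }


class TestDmrFeatureAssignment:
    def test_te_in_promoter(self, features):
        """g2 is minus-strand: promoter 24000–26000 holds a TE at
        24500–24900; a DMR there is TE-promoter."""
        out = assign_dmr_features(pd.DataFrame([_dmr(24601, 24700)]), features)
        assert out.iloc[0]["category"] == "TE-promoter"
        assert out.iloc[0]["gene_id"] == "g2"

    def test_exon_only(self, features):
        out = assign_dmr_features(pd.DataFrame([_dmr(1201, 1400)]), features)
        assert out.iloc[0]["category"] == "exon"
        assert out.iloc[0]["gene_id"] == "g1"

    def test_te_in_intron(self, features):
        out = assign_dmr_features(pd.DataFrame([_dmr(2601, 2800)]), features)
        assert out.iloc[0]["category"] == "TE-intron"

    def test_extragenic_te(self, features):
        out = assign_dmr_features(pd.DataFrame([_dmr(40101, 40300)]), features)
        assert out.iloc[0]["category"] == "TE"
        assert out.iloc[0]["gene_id"] == ""

    def test_intergenic(self, features):
        out = assign_dmr_features(pd.DataFrame([_dmr(50001, 50100)]), features)
        assert out.iloc[0]["category"] == "intergenic"

    def test_promoter_beats_exon(self, features):
        """A DMR spanning the g1 promoter/exon boundary is promoter."""
        out = assign_dmr_features(pd.DataFrame([_dmr(901, 1100)]), features)
        assert out.iloc[0]["category"] == "promoter"

    def test_category_partition(self, features):
        rng = np.random.default_rng(0)
        starts = rng.integers(1, 59000, 60)
        dmrs = pd.DataFrame([_dmr(int(s), int(s) + 150) for s in starts])
        out = assign_dmr_features(dmrs, features)
        counts = out["category"].value_counts()
        assert counts.sum() == len(dmrs)
        assert set(counts.index) <= set(CATEGORIES)

    def test_unknown_chromosome_rejected(self, features):
        with pytest.raises(ValueError, match="unknown chromosome"):
            assign_dmr_features(pd.DataFrame([_dmr(1, 10, chrom="chrX")]), features)

    def test_mirror_symmetry(self, features):
        """Reverse-complementing the toy genome (coordinate reflection +
        strand flip) leaves the category tally unchanged."""
        L = 60000
        rng = np.random.default_rng(1)
        starts = rng.integers(1, L - 200, 50)
        dmrs = pd.DataFrame([_dmr(int(s), int(s) + 150) for s in starts])
        fwd = assign_dmr_features(dmrs, features)

        def flip_df(df):
            out = df.copy()
            s = out["start"].copy()
            out["start"] = L - out["end"]
            out["end"] = L - s
            if "strand" in out:
                out["strand"] = out["strand"].map({"+": "-", "-": "+", ".": "."})
            return out

        mirrored = GenomicFeatureSet(
            flip_df(features.genes).sort_values("start").reset_index(drop=True),
            flip_df(features.exons).sort_values("start").reset_index(drop=True),
            flip_df(features.tes).sort_values("start").reset_index(drop=True),
            {"chr1": L},
        )
        dmrs_m = dmrs.copy()
        # report coords are 1-based inclusive: mirror accordingly
        s = dmrs_m["start"].copy()
        dmrs_m["start"] = L - dmrs_m["end"] + 1
        dmrs_m["end"] = L - s + 1
        rev = assign_dmr_features(dmrs_m, mirrored)
        assert (
            fwd["category"].value_counts().to_dict()
            == rev["category"].value_counts().to_dict()
        )


class TestDegFilter:
    def test_chromatin_remodeler_row_is_deg(self):
        """The DDM1-like row: log2FC −1.1 at padj 7.22e−22 and high CPM
        passes the filter as downregulated."""
        table = pd.DataFrame(
            {"gene": ["Vitvi04g01275"], "log2FC": [-1.1], "padj": [7.22e-22],
             "cpm": [120.0]}
        )
        out = filter_degs(table)
        assert bool(out.iloc[0]["is_deg"]) and out.iloc[0]["direction"] == "down"

    @pytest.mark.parametrize(
        "l2fc,padj,cpm,expected",
        [
            (0.9, 1e-10, 100.0, False),   # magnitude filter
            (2.0, 0.06, 100.0, False),    # padj filter
            (2.0, 0.01, 5.0, False),      # CPM filter
            (1.01, 0.049, 10.1, True),
        ],
    )
    def test_conjunction(self, l2fc, padj, cpm, expected):
        table = pd.DataFrame(
            {"gene": ["g"], "log2FC": [l2fc], "padj": [padj], "cpm": [cpm]}
        )
        assert bool(filter_degs(table).iloc[0]["is_deg"]) is expected

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="lacks column"):
            filter_degs(pd.DataFrame({"gene": ["g"]}))


class TestLinking:
    def _setup(self, features):
        dmrs = pd.DataFrame(
            [
                _dmr(24601, 24700),          # TE-promoter of g2
                _dmr(24901, 25000),          # promoter of g2 (second DMR)
                _dmr(1201, 1400),            # exon of g1
                _dmr(50001, 50100),          # intergenic
            ]
        )
        annotated = assign_dmr_features(dmrs, features)
        degs = filter_degs(
            pd.DataFrame(
                {
                    "gene": ["g1", "g2"],
                    "log2FC": [0.2, -2.0],
                    "padj": [0.9, 1e-6],
                    "cpm": [50.0, 80.0],
                }
            )
        )
        return annotated, degs

    def test_promoter_dmr_over_non_deg_not_linked(self, features):
        annotated, degs = self._setup(features)
        dmegs, promdmegs = link_dmr_degs(annotated, degs)
        assert "g1" not in set(promdmegs["gene_id"])
        assert len(dmegs) == 0  # g1's exon DMR is genic but g1 is not a DEG

    def test_two_promoter_dmrs_give_two_records(self, features):
        annotated, degs = self._setup(features)
        _, promdmegs = link_dmr_degs(annotated, degs)
        assert len(promdmegs) == 2
        assert set(promdmegs["gene_id"]) == {"g2"}


class TestQuadrants:
    def test_single_record_classification(self):
        """log2FC +1.35 with promoter Δm −0.49 is Me−/Exp+, a negative
        correlation."""
        rec, summary = classify_quadrants(
            pd.DataFrame(
                {"gene_id": ["g"], "diff_exp": [1.35], "diff_meth": [-0.49],
                 "context": ["CHG"]}
            )
        )
        assert rec.iloc[0]["quadrant"] == "Me-/Exp+"
        assert rec.iloc[0]["correlation_sign"] == "negative"

    def test_published_34_pair_table(self):
        """The packaged 34-record promoter-DMR × DEG table: 17 negative
        correlations, 28 hyper-methylated (22 of them CHH), 6 hypo."""
        rec, summary = classify_quadrants(load_promdmeg_table())
        assert summary.n_records == 34
        assert summary.negative_correlation == 17
        assert summary.hyper == 28
        assert summary.context_by_me_state["+"]["CHH"] == 22
        assert summary.hypo == 6
        # partition: quadrant counts sum to classified count
        assert sum(summary.quadrant_counts.values()) == summary.n_classified == 34

    def test_all_positive_fixture(self):
        rec, summary = classify_quadrants(
            pd.DataFrame(
                {"gene_id": list("abc"), "diff_exp": [1.0, 2.0, 3.0],
                 "diff_meth": [0.2, 0.3, 0.4], "context": ["CG"] * 3}
            )
        )
        assert summary.negative_correlation == 0
        assert summary.positive_correlation == 3

    def test_zero_difference_unclassifiable(self):
        with pytest.warns(UserWarning, match="unclassifiable"):
            rec, summary = classify_quadrants(
                pd.DataFrame(
                    {"gene_id": ["a", "b"], "diff_exp": [0.0, 1.0],
                     "diff_meth": [0.2, 0.3], "context": ["CG", "CG"]}
                )
            )
        assert summary.n_unclassifiable == 1
        assert summary.n_classified + summary.n_unclassifiable == summary.n_records
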