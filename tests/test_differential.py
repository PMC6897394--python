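import numpy as np
import pandas as pd
import pytest

from epidomains.differential import (
    CONTROL,
    TREATED,
    RegionCounts,
    annotate_location,
    assign_genes,
    count_in_regions,
    differential_regions,
    expression_change_by_category,
    gene_model_from_records,
    read_gene_model,
    welch_t_test,
)
from epidomains.intervals import GenomicInterval, IntervalSet
from epidomains.simulate import simulate_expression, simulate_treatment

from .oracles import exact_binom_two_sided, midpoint_count


def iv(c, s, e):
    return GenomicInterval(c, s, e)


def regions_grid(n, width=1_000, spacing=10_000):
    return IntervalSet(
        intervals=[iv("chr1", i * spacing, i * spacing + width) for i in range(n)]
    )


def rc_from_pooled(t, c):
    """Single-replicate RegionCounts from pooled count vectors."""
    counts = pd.DataFrame({"t1": t, "c1": c})
    return RegionCounts(
        regions=regions_grid(len(t)),
        counts=counts,
        condition_of={"t1": TREATED, "c1": CONTROL},
    )


class TestCountInRegions:
    def test_midpoint_containment(self):
        region = regions_grid(1)  # chr1:[0,1000)
        frags = IntervalSet(
            intervals=[iv("chr1", 100, 200), iv("chr1", 0, 1_000), iv("chr1", 900, 1_000)]
        )
        rc = count_in_regions(
            region, {"s": frags, "c": frags}, {"s": TREATED, "c": CONTROL}
        )
        assert rc.counts.loc[0, "s"] == 3

    def test_midpoint_at_region_end_not_counted(self):
        regions = regions_grid(2)
        # first fragment's midpoint is exactly at region 0's end (half-open)
        frags = IntervalSet(
            intervals=[iv("chr1", 990, 1_010), iv("chr1", 10_100, 10_200)]
        )
        rc = count_in_regions(
            regions, {"s": frags, "c": frags}, {"s": TREATED, "c": CONTROL}
        )
        assert rc.counts.loc[0, "s"] == 0
        assert rc.counts.loc[1, "s"] == 1

    def test_matches_per_fragment_oracle(self, rng):
        from .conftest import random_intervals

        regions = regions_grid(8, width=800, spacing=1_200)
        frags = random_intervals(rng, n_max=60)
        rc = count_in_regions(
            regions,
            {"s": IntervalSet(intervals=frags),
             "c": IntervalSet(intervals=frags)},
            {"s": TREATED, "c": CONTROL},
        )
        for i, region in enumerate(regions):
            assert rc.counts.loc[i, "s"] == midpoint_count(frags, region)

    def test_zero_library_rejected(self):
        region = regions_grid(1)
        empty = IntervalSet()
        with pytest.raises(ValueError):
            count_in_regions(
                region, {"s": empty, "c": empty}, {"s": TREATED, "c": CONTROL}
            )


class TestDifferentialRegions:
    def test_exact_binomial_example(self):
        # pad with null regions so library sizes are equal and dominated by them
        n_pad = 0
        t = np.array([100])
        c = np.array([50])
        rc = rc_from_pooled(t, c)
        # override library sizes to be equal, per the symmetric-null example
        rc.library_size = pd.Series({"t1": 1_000, "c1": 1_000})
        res = differential_regions(rc)
        # frozen from the exact tail-sum oracle: 2 * P(X >= 100 | Bin(150, .5))
        assert res["p_value"][0] == pytest.approx(5.447533103392586e-05, rel=1e-9)
        assert res["p_value"][0] == pytest.approx(
            exact_binom_two_sided(100, 150, 0.5), rel=1e-6
        )
        assert res["direction"][0] == "increased"

    def test_symmetric_null_unchanged(self):
        rc = rc_from_pooled(np.array([40]), np.array([40]))
        rc.library_size = pd.Series({"t1": 500, "c1": 500})
        res = differential_regions(rc)
        assert res["p_value"][0] == 1.0
        assert res["direction"][0] == "unchanged"
        assert res["log2fc"][0] == 0.0

    def test_single_region_fdr_equals_p(self):
        rc = rc_from_pooled(np.array([30]), np.array([10]))
        res = differential_regions(rc)
        assert res["fdr"][0] == pytest.approx(res["p_value"][0])

    def test_zero_count_region(self):
        rc = rc_from_pooled(np.array([0, 50]), np.array([0, 50]))
        res = differential_regions(rc)
        assert res["p_value"][0] == 1.0 and res["log2fc"][0] == 0.0

    def test_condition_swap_negates_log2fc_preserves_p(self, rng):
        t = rng.poisson(30, size=50)
        c = rng.poisson(30, size=50)
        res = differential_regions(rc_from_pooled(t, c))
        res_sw = differential_regions(rc_from_pooled(c, t))
        np.testing.assert_allclose(res_sw["log2fc"], -res["log2fc"], rtol=1e-12)
        np.testing.assert_allclose(res_sw["p_value"], res["p_value"], rtol=1e-9)

    def test_planted_power_and_fdp(self):
        regions = regions_grid(2_000)
        rc, truth = simulate_treatment(
            regions, frac_increased=0.1, effect_fold=4.0,
            poisson_mean=20.0, n_reps=2, seed=5,
        )
        res = differential_regions(rc, 0.1)
        called = (res["direction"] == "increased").to_numpy()
        planted = truth == "increased"
        sensitivity = (called & planted).sum() / planted.sum()
        fdp = (called & ~planted).sum() / max(1, called.sum())
        assert sensitivity >= 0.9
        assert fdp <= 0.15

    def test_null_calibration(self):
        regions = regions_grid(2_000)
        rc, _ = simulate_treatment(
            regions, frac_increased=0.0, effect_fold=1.0,
            poisson_mean=20.0, n_reps=2, seed=6,
        )
        res = differential_regions(rc, 0.1)
        assert (res["direction"] != "unchanged").mean() <= 0.12


class TestAnnotateLocation:
    GENES = gene_model_from_records(
        [
            {"gene_id": "gA", "chrom": "chr1", "strand": "+",
             "start": 50_000, "end": 80_000},
            {"gene_id": "gB", "chrom": "chr1", "strand": "-",
             "start": 200_000, "end": 240_000},
        ]
    )

    @pytest.mark.parametrize(
        "region,expected",
        [
            (iv("chr1", 49_000, 51_000), "promoter"),  # spans gA TSS
            (iv("chr1", 60_000, 61_000), "intragenic"),  # inside gA body
            (iv("chr1", 239_000, 241_000), "promoter"),  # minus-strand TSS at end-1
            (iv("chr1", 210_000, 211_000), "intragenic"),
            (iv("chr1", 1_000_000, 1_001_000), "distal intergenic"),
            (iv("chr2", 60_000, 61_000), "distal intergenic"),
        ],
    )
    def test_precedence_and_strand(self, region, expected):
        labels = annotate_location(IntervalSet(intervals=[region]), self.GENES)
        assert labels[0] == expected

    def test_labels_partition(self, rng):
        regions = IntervalSet(
            intervals=[iv("chr1", int(s), int(s) + 500)
                       for s in rng.integers(0, 400_000, 50)]
        )
        labels = annotate_location(regions, self.GENES)
        assert set(labels) <= {"promoter", "intragenic", "distal intergenic"}
        assert len(labels) == 50

    def test_empty_gene_model_rejected(self):
        with pytest.raises(ValueError):
            annotate_location(
                IntervalSet(intervals=[iv("chr1", 0, 10)]), pd.DataFrame()
            )


class TestAssignGenes:
    GENES = gene_model_from_records(
        [
            {"gene_id": "near", "chrom": "chr1", "strand": "+",
             "start": 150_000, "end": 160_000},  # TSS 150_000
            {"gene_id": "far", "chrom": "chr1", "strand": "+",
             "start": 251_000, "end": 260_000},  # TSS 251_000
            {"gene_id": "inside", "chrom": "chr1", "strand": "-",
             "start": 40_000, "end": 90_500},  # TSS 90_499
        ]
    )

    def test_window_and_distances(self):
        regions = IntervalSet(intervals=[iv("chr1", 90_000, 100_001)])
        links = assign_genes(regions, self.GENES, window=100_000)
        got = dict(zip(links["gene_id"], links["distance"]))
        assert got == {"near": 50_000, "inside": 0}  # "far" is 150,500 bp away

    def test_zero_window_only_internal_tss(self):
        regions = IntervalSet(intervals=[iv("chr1", 90_000, 100_001)])
        links = assign_genes(regions, self.GENES, window=0)
        assert list(links["gene_id"]) == ["inside"]


class TestExpressionChange:
    def test_identical_groups_p_is_one(self):
        assert welch_t_test(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))[1] == 1.0

    def test_separated_groups_tiny_p(self, rng):
        x = rng.normal(1.0, 0.1, 50)
        y = rng.normal(0.0, 0.1, 50)
        assert welch_t_test(x, y)[1] < 1e-10

    def test_category_comparison_with_planted_effect(self):
        genes = gene_model_from_records(
            [{"gene_id": f"g{i}", "chrom": "chr1", "strand": "+",
              "start": i * 10_000, "end": i * 10_000 + 5_000} for i in range(100)]
        )
        cat = {f"g{i}": ("increased" if i < 50 else "null") for i in range(100)}
        _, fc = simulate_expression(genes, cat, group_effect=1.0, noise_sd=0.1, seed=3)
        dists, pairs = expression_change_by_category(
            {"increased": [f"g{i}" for i in range(50)],
             "null": [f"g{i}" for i in range(50, 100)]},
            fc,
        )
        assert pairs.iloc[0]["p_value"] < 1e-10
        assert dists["increased"].mean() > dists["null"].mean()

    def test_small_category_excluded(self):
        dists, pairs = expression_change_by_category(
            {"a": ["g1"], "b": ["g2", "g3"]}, {"g1": 1.0, "g2": 0.0, "g3": 0.1}
        )
        assert "a" not in dists and pairs.empty

    def test_null_p_values_uniform(self, rng):
        # permuting labels of a null simulation: p ~ U(0,1)
        from scipy import stats

        ps = []
        for rep in range(500):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 20)
            ps.append(welch_t_test(x, y)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGeneModelIO:
    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text(
            "gene_id\tchrom\tstrand\ttss\tstart\tend\n"
            "g1\tchr1\t+\t100\t100\t500\n"
            "g2\tchr1\t-\t899\t600\t900\n"
        )
        df = read_gene_model(p)
        assert list(df["tss"]) == [100, 899]

    def test_bed_style_tss_by_strand(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t500\tg1\t0\t+\nchr1\t600\t900\tg2\t0\t-\n")
        df = read_gene_model(p)
        assert list(df["tss"]) == [100, 899]
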