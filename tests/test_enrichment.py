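"""Random-interval background, per-site enrichment, and set-level tests."""

import numpy as np
import pytest

from fusescan.core import FusionSite, GenomeLayout
from fusescan.enrichment import (
    BackgroundDist,
    count_outliers_in_interval,
    enrichment_scan,
    genomewide_test,
    pooled_background,
    sample_background,
    site_enrichment,
    site_interval,
    site_set_test,
)
from conftest import flag_table, random_flag_table


class TestCounting:
    def test_midpoint_membership_half_open(self, layout):
        # windows of 10 kb / 5 kb step have midpoints at 5000, 10000, ...
        table = flag_table(layout.chromosomes, {"chr1": {5_000, 10_000, 20_000}})
        assert count_outliers_in_interval(table, "top5", "chr1", 0, 10_000) == 1
        assert count_outliers_in_interval(table, "top5", "chr1", 0, 10_001) == 2
        assert count_outliers_in_interval(table, "top5", "chr1", 5_000, 20_000) == 2
        assert count_outliers_in_interval(table, "top5", "chr1", 0, 50_000) == 3
        assert count_outliers_in_interval(table, "top5", "chr2", 0, 50_000) == 0

    def test_site_interval_clipping(self):
        assert site_interval(FusionSite("c", 500_000, "s", False),
                             1_000_000, 5_000_000) == (0, 1_000_000)
        assert site_interval(FusionSite("c", 4_900_000, "s", False),
                             1_000_000, 5_000_000) == (4_000_000, 5_000_000)
        assert site_interval(FusionSite("c", 2_500_000, "s", False),
                             1_000_000, 5_000_000) == (2_000_000, 3_000_000)


class TestBackground:
    def test_mean_count_matches_flag_density(self, layout):
        """Uniform random flags: E[count in L-bp interval] ~ density * L / step."""
        rng = np.random.default_rng(11)
        density = 0.2
        table = random_flag_table(layout.chromosomes, density, rng)
        bg = sample_background(table, "top5", layout, "chr1", 1_000_000,
                               n=20_000, seed=5)
        expected = density * 1_000_000 / 5_000
        assert bg.counts.mean() == pytest.approx(expected, rel=0.05)

    def test_interval_longer_than_chromosome_rejected(self, layout):
        table = flag_table(layout.chromosomes, {})
        with pytest.raises(ValueError, match="chr1"):
            sample_background(table, "top5", layout, "chr1", 5_000_000, n=10)

    def test_deterministic_for_seed(self, layout):
        rng = np.random.default_rng(2)
        table = random_flag_table(layout.chromosomes, 0.1, rng)
        a = sample_background(table, "top5", layout, "chr1", 1_000_000,
                              n=1000, seed=9)
        b = sample_background(table, "top5", layout, "chr1", 1_000_000,
                              n=1000, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestSiteEnrichment:
    def test_p_emp_formula_against_hand_background(self, layout):
        """p_emp and the significance call recomputed by hand from a
        constructed background sample."""
        table = flag_table(layout.chromosomes, {"chr1": {1_500_000, 1_505_000,
                                                         1_510_000}})
        counts = np.array([0] * 90 + [1] * 6 + [2] * 3 + [5])
        bg = BackgroundDist("chr1", 1_000_000, counts, 100, 0)
        site = FusionSite("chr1", 1_500_000, "Chr1#1", True)
        res = site_enrichment(site, table, "top5", bg, layout)
        assert res.observed_count == 3
        # hand: #{bg >= 3} = 1 -> p = (1+1)/(1+100)
        assert res.p_emp == pytest.approx(2 / 101)
        # q95 of the counts (type 7) is 1.0; 3 >= 1.0 -> significant
        assert res.significant

    def test_zero_observed_not_significant(self, layout):
        table = flag_table(layout.chromosomes, {})
        counts = np.array([0] * 50 + [1] * 50)
        bg = BackgroundDist("chr1", 1_000_000, counts, 100, 0)
        site = FusionSite("chr1", 1_500_000, "Chr1#1", True)
        res = site_enrichment(site, table, "top5", bg, layout)
        assert res.observed_count == 0
        assert res.p_emp == pytest.approx(101 / 101)
        assert not res.significant

    def test_chromosome_mismatch_rejected(self, layout):
        table = flag_table(layout.chromosomes, {})
        bg = BackgroundDist("chr2", 1_000_000, np.zeros(10, dtype=np.int64),
                            10, 0)
        with pytest.raises(ValueError):
            site_enrichment(FusionSite("chr1", 1_500_000, "s", False),
                            table, "top5", bg, layout)

    def test_p_floor_is_one_over_n_plus_one(self, layout):
        table = flag_table(
            layout.chromosomes,
            {"chr1": set(range(1_005_000, 2_000_000, 5_000))},
        )
        bg = BackgroundDist("chr1", 1_000_000, np.zeros(1000, dtype=np.int64),
                            1000, 0)
        res = site_enrichment(FusionSite("chr1", 1_500_000, "s", False),
                              table, "top5", bg, layout)
        assert res.p_emp == pytest.approx(1 / 1001)


class TestSetTests:
    def test_enriched_sites_shift_detected(self, layout):
        rng = np.random.default_rng(4)
        bg_counts = rng.poisson(2.0, 5000)
        bg = BackgroundDist("chr1", 1_000_000, bg_counts, 5000, 0)
        ks, cm = site_set_test([15, 18, 12, 20], bg, seed=1)
        assert ks.p < 1e-3
        assert cm.p < 1e-2

    def test_null_site_counts_not_detected(self, layout):
        rng = np.random.default_rng(4)
        bg_counts = rng.poisson(2.0, 5000)
        bg = BackgroundDist("chr1", 1_000_000, bg_counts, 5000, 0)
        sites = rng.poisson(2.0, 6).tolist()
        ks, cm = site_set_test(sites, bg, seed=1)
        assert ks.p > 0.05

    def test_empty_sites_rejected(self):
        bg = BackgroundDist("chr1", 1_000_000, np.zeros(10, dtype=np.int64),
                            10, 0)
        with pytest.raises(ValueError):
            site_set_test([], bg)


class TestPooledBackground:
    def test_length_weighting(self):
        layout = GenomeLayout(chromosomes=[("a", 9_000_000), ("b", 1_000_000)])
        bgs = {
            "a": BackgroundDist("a", 1, np.zeros(10_000, dtype=np.int64),
                                10_000, 0),
            "b": BackgroundDist("b", 1, np.full(10_000, 7, dtype=np.int64),
                                10_000, 0),
        }
        pooled = pooled_background(bgs, layout, n=50_000, seed=3)
        frac_b = (pooled == 7).mean()
        assert frac_b == pytest.approx(0.1, abs=0.01)

    def test_genomewide_needs_two_chromosomes_with_sites(self, layout):
        table = flag_table(layout.chromosomes, {})
        bg = BackgroundDist("chr1", 1_000_000, np.zeros(10, dtype=np.int64),
                            10, 0)
        one_chrom = GenomeLayout(
            chromosomes=[("chr1", 5_000_000)],
            fusion_sites=[FusionSite("chr1", 1_500_000, "s", False)],
        )
        with pytest.raises(ValueError):
            genomewide_test({"chr1": bg}, table, "top5", one_chrom)


class TestScan:
    def test_scan_structure_and_determinism(self, layout):
        rng = np.random.default_rng(8)
        table = random_flag_table(layout.chromosomes, 0.1, rng)
        df1, tests1 = enrichment_scan(table, layout, measures=("top5",),
                                      interval_lengths=(1_000_000,),
                                      n=2_000, seed=12, cvm_permutations=500)
        df2, tests2 = enrichment_scan(table, layout, measures=("top5",),
                                      interval_lengths=(1_000_000,),
                                      n=2_000, seed=12, cvm_permutations=500)
        assert len(df1) == 4  # 4 sites x 1 measure x 1 length
        assert set(df1["site"]) == {"Chr1#1", "Chr1#2", "Chr2#1", "Chr2#2"}
        assert "genome|top5|1000000" in tests1
        assert df1.equals(df2)
        assert tests1 == tests2

    def test_planted_enrichment_found_by_scan(self, layout):
        """Flags planted densely around Chr1#2 only."""
        rng = np.random.default_rng(21)
        table = random_flag_table(layout.chromosomes, 0.02, rng)
        around = (table["chrom"] == "chr1") & \
            ((table["start"] + table["end"]) // 2).between(3_200_000, 3_800_000)
        table.loc[around, "flag_top5"] = True
        df, _ = enrichment_scan(table, layout, measures=("top5",),
                                interval_lengths=(1_000_000,),
                                n=20_000, seed=7, cvm_permutations=500)
        planted = df[df["site"] == "Chr1#2"].iloc[0]
        others = df[df["site"] != "Chr1#2"]
        assert planted["significant"]
        # a random 1 Mb interval fully covering the 600 kb block ties the
        # observed count, so p_emp is bounded below by that coverage
        # probability (~10%), not by 1/N
        assert planted["p_emp"] < 0.12
        assert planted["p_emp"] < others["p_emp"].min()
        assert not others["significant"].any()
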