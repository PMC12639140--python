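"""Generator distributional guarantees and fixture determinism."""

import json

import numpy as np
import pytest

import fusescan.io as fio
from fusescan.ld import ld_profile, pairwise_r2
from fusescan.repositioning import position_values
from fusescan.simulate import (
    SimConfig,
    beta_shape_for_mean,
    fusion_intervals,
    make_fixture_set,
    make_layout,
    mean_position_value_beta,
    simulate_genes,
    simulate_genotypes,
    simulate_pools,
    sweep_regions,
)
from fusescan.windows import compute_site_stats, filter_snps


def small_config(**kw):
    defaults = dict(chrom_lengths=[1_000_000, 1_000_000], n_snps=2_000, seed=1)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(drift_c=0.0)
        with pytest.raises(ValueError):
            SimConfig(fusion_site_fractions=[0.0, 0.5])
        with pytest.raises(ValueError):
            SimConfig(salinity_native=[25.0])

    def test_hash_changes_with_config(self):
        assert SimConfig(seed=1).hash() != SimConfig(seed=2).hash()
        assert SimConfig(seed=1).hash() == SimConfig(seed=1).hash()


class TestLayoutAndSweeps:
    def test_layout_structure(self):
        layout = make_layout(SimConfig())
        assert [c for c, _ in layout.chromosomes] == ["chr1", "chr2"]
        assert len(layout.fusion_sites) == 4
        assert layout.fusion_sites[0].position == 1_500_000
        assert layout.fusion_sites[0].is_centromere

    def test_sweeps_centered_on_fusion_sites(self):
        cfg = small_config(n_sweeps=4, sweep_width=100_000)
        layout = make_layout(cfg)
        regions = sweep_regions(cfg, layout, np.random.default_rng(0))
        assert len(regions) == 4
        for (chrom, start, end), site in zip(regions, layout.fusion_sites):
            assert chrom == site.chrom
            assert start <= site.position < end

    def test_background_sweeps_uniform(self):
        cfg = small_config(n_sweeps=4, sweep_fusion_fraction=0.0,
                           sweep_width=50_000)
        regions = sweep_regions(cfg, make_layout(cfg), np.random.default_rng(0))
        assert len(regions) == 4
        for chrom, start, end in regions:
            assert end - start == 50_000


class TestPools:
    def test_shapes_and_depth_bounds(self):
        cfg = small_config()
        counts, _ = simulate_pools(cfg)
        assert counts.n_snps == cfg.n_snps
        assert counts.n_pools == 4
        depths = counts.ref_counts + counts.alt_counts
        assert depths.min() >= cfg.depth_min
        assert depths.max() <= cfg.depth_max
        assert (np.diff(counts.sites["pos"][counts.sites["chrom"] == "chr1"])
                > 0).all()

    def test_drift_c_recovered_as_fst(self):
        """Balding-Nichols closed form: mean per-site F_ST ratio-of-sums
        matches the drift parameter (no sweeps)."""
        for c in (0.05, 0.2):
            cfg = small_config(n_snps=6_000, drift_c=c, n_sweeps=0, seed=3)
            counts, _ = simulate_pools(cfg)
            kept, _ = filter_snps(counts)
            stats = compute_site_stats(kept)
            fst = stats.fst_num.sum() / stats.fst_den.sum()
            assert fst == pytest.approx(c, abs=0.02)

    def test_sweep_elevates_fst_and_cuts_invasive_diversity(self):
        cfg = small_config(n_snps=8_000, n_sweeps=2, sweep_width=300_000,
                           seed=4)
        counts, regions = simulate_pools(cfg)
        kept, _ = filter_snps(counts)
        stats = compute_site_stats(kept)
        pos = kept.sites["pos"].to_numpy()
        chroms = kept.sites["chrom"].to_numpy()
        in_sweep = np.zeros(kept.n_snps, dtype=bool)
        for rc, rs, re in regions:
            in_sweep |= (chroms == rc) & (pos >= rs) & (pos < re)
        assert in_sweep.sum() > 50
        fst_in = stats.fst_num[in_sweep].sum() / stats.fst_den[in_sweep].sum()
        fst_out = stats.fst_num[~in_sweep].sum() / stats.fst_den[~in_sweep].sum()
        assert fst_in > 2 * fst_out
        pi_inv = stats.pi[:, stats.invasive_idx].mean(axis=1)
        pi_inv_in = pi_inv[in_sweep].mean()
        pi_inv_out = pi_inv[~in_sweep].mean()
        assert pi_inv_in < 0.5 * pi_inv_out

    def test_deterministic(self):
        cfg = small_config(seed=9)
        a, ra = simulate_pools(cfg)
        b, rb = simulate_pools(cfg)
        assert ra == rb
        np.testing.assert_array_equal(a.alt_counts, b.alt_counts)


class TestGenes:
    def test_beta_mean_oracle_values(self):
        # closed-form checkpoints: uniform -> 25; Beta(2,2) -> 31.25
        assert mean_position_value_beta(1.0) == pytest.approx(25.0, abs=1e-6)
        assert mean_position_value_beta(2.0) == pytest.approx(31.25, abs=1e-6)

    def test_shape_solver_roundtrip(self):
        for target in (10.0, 23.5, 32.8, 45.0):
            a = beta_shape_for_mean(target)
            assert mean_position_value_beta(a) == pytest.approx(target, abs=1e-6)
        assert beta_shape_for_mean(31.25) == pytest.approx(2.0, abs=1e-6)
        with pytest.raises(ValueError):
            beta_shape_for_mean(55.0)

    def test_selected_means_match_targets(self):
        cfg = small_config(n_selected=4_000, n_family=10, n_ion=10,
                           n_other=10, gene_width=200)
        layout = make_layout(cfg)
        genes_a, genes_b = simulate_genes(cfg, layout)
        sel_a = [g for g in genes_a if g.set_label == "selected25"]
        sel_b = [g for g in genes_b if g.set_label == "selected25"]
        pa = position_values(sel_a, layout)
        pb = position_values(sel_b, layout)
        # SE of the mean is ~14.4/sqrt(4000) ~ 0.23
        assert pa.mean() == pytest.approx(cfg.selected_mean_a, abs=1.0)
        assert pb.mean() == pytest.approx(cfg.selected_mean_b, abs=1.0)

    def test_gene_ids_shared_and_sets_sized(self):
        cfg = small_config()
        genes_a, genes_b = simulate_genes(cfg)
        ids_a = {g.gene_id for g in genes_a}
        ids_b = {g.gene_id for g in genes_b}
        assert ids_a == ids_b
        assert len(ids_a) == (cfg.n_selected + cfg.n_family + cfg.n_ion
                              + cfg.n_other)
        sel = [g for g in genes_a if g.set_label == "selected25"]
        assert len(sel) == cfg.n_selected


class TestGenotypes:
    def test_shapes_and_dosage_range(self):
        cfg = small_config(gt_spacing=10_000)
        dosages, sites = simulate_genotypes(cfg)
        assert dosages.shape == (cfg.n_individuals, len(sites))
        assert set(np.unique(dosages)) <= {0.0, 1.0, 2.0}

    def test_fusion_regions_have_higher_ld(self):
        """Lower recombination inside fusion intervals produces higher mean
        short-range r^2 there than outside."""
        cfg = SimConfig(chrom_lengths=[4_000_000],
                        fusion_site_fractions=[0.5],
                        fusion_region_width=1_000_000,
                        fusion_recomb_factor=0.05, gt_spacing=4_000,
                        n_individuals=30, seed=6)
        layout = make_layout(cfg)
        dosages, sites = simulate_genotypes(cfg, layout)
        pos = sites["pos"].to_numpy()
        pairs = pairwise_r2(dosages, pos, max_dist=60_000)
        fusion = fusion_intervals(cfg, layout, "chr1")
        prof_in = ld_profile(pairs, positions=pos, region_mask=fusion)
        outside = [(0, fusion[0][0]), (fusion[0][1], 4_000_000)]
        prof_out = ld_profile(pairs, positions=pos, region_mask=outside)
        merged = prof_in.merge(prof_out, on="dist", suffixes=("_in", "_out"))
        assert (merged["mean_r2_in"] > merged["mean_r2_out"]).mean() > 0.8
        assert merged["mean_r2_in"].mean() > 1.3 * merged["mean_r2_out"].mean()

    def test_grid_positions_shared_distances(self):
        cfg = small_config(gt_spacing=5_000)
        _, sites = simulate_genotypes(cfg)
        for chrom in ("chr1", "chr2"):
            pos = sites.loc[sites["chrom"] == chrom, "pos"].to_numpy()
            assert (np.diff(pos) == 5_000).all()


class TestFixtures:
    def test_byte_identical_and_readable(self, tmp_path):
        cfg = small_config(n_snps=300, gt_spacing=100_000, n_selected=5,
                           n_family=5, n_ion=5, n_other=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = make_fixture_set(cfg, d1)
        m2 = make_fixture_set(cfg, d2)
        assert m1 == m2
        for name in sorted(m1["files"].values()):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

        # every artifact parses back through the package readers
        layout = fio.read_layout(d1 / "layout.bed")
        counts = fio.read_sync(d1 / "pools.sync", d1 / "pools.tsv")
        genes_a = fio.read_genes_bed(d1 / "genes_speciesA.bed",
                                     d1 / "gene_sets.tsv", layout)
        dosages, _ = fio.read_vcf_genotypes(d1 / "genotypes.vcf")
        assert counts.n_snps == cfg.n_snps
        assert len(genes_a) == 20
        assert dosages.shape[0] == cfg.n_individuals
        manifest = json.loads((d1 / "manifest.json").read_text())
        assert manifest["config_hash"] == cfg.hash()

    def test_sync_roundtrip_preserves_counts_up_to_orientation(self, tmp_path):
        """read_sync orients ref to the majority allele, so sites where the
        simulated alt dominates come back flipped; depths and the unordered
        count pair are preserved exactly (the estimators are invariant)."""
        cfg = small_config(n_snps=200)
        make_fixture_set(cfg, tmp_path)
        counts = fio.read_sync(tmp_path / "pools.sync", tmp_path / "pools.tsv")
        direct, _ = simulate_pools(cfg)
        np.testing.assert_array_equal(counts.sites["pos"], direct.sites["pos"])
        np.testing.assert_array_equal(counts.depths, direct.depths)
        same = (counts.ref_counts == direct.ref_counts).all(axis=1) & \
            (counts.alt_counts == direct.alt_counts).all(axis=1)
        flipped = (counts.ref_counts == direct.alt_counts).all(axis=1) & \
            (counts.alt_counts == direct.ref_counts).all(axis=1)
        assert (same | flipped).all()
        assert same.any() and flipped.any()
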