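"""Synthetic data with the statistical structure every pipeline stage assumes.

Three generators share one :class:`SimConfig`:

* ``simulate_pools`` — pooled allele counts for native-saline vs
  invasive-freshwater populations. Ancestral frequencies are uniform on
  (0.05, 0.95); each pool's frequency is a Balding-Nichols draw
  Beta(p(1-c)/c, (1-p)(1-c)/c) around the ancestral p, so the drift
  parameter c is also the expected F_ST (closed form, which makes estimator
  recovery testable without a coalescent simulator). Inside sweep regions
  the invasive-class frequency is pushed toward fixation,
  p' = (1-s) * p_pool + s * round(p), emulating a selective sweep's joint
  signal of elevated differentiation and depressed invasive diversity.
  Read depths are Poisson around the mean coverage, truncated to the
  analysis depth bounds; allele counts are binomial reads.
* ``simulate_genes`` — gene coordinates for two "species". Non-selected
  gene midpoints are uniform along chromosomes; the selected set's
  midpoints follow a symmetric Beta(a, a) whose shape is solved from the
  target mean position value per species (a > 1 centralizes, a < 1 pushes
  toward the edges).
* ``simulate_genotypes`` — diploid dosages for a small panel of
  individuals, built by mosaic copying from a fixed pool of founder
  haplotypes with a per-bp switch probability; the switch rate is
  multiplied by a factor < 1 inside fusion-site regions, producing the
  elevated short-range LD the regional comparison is designed to detect.

Defaults mirror the study conditions: 100-diploid pools at mean 25x
coverage (range clipped to the 20-200 analysis bounds), two saline (25 and
30 PSU) and two freshwater (0.2 and 0.5 PSU) pools, 14 individuals for LD,
and selected-gene centralization of 32.8% vs 23.5% mean position value in
the fused vs unfused genome.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .core import (
    FusionSite,
    GeneRecord,
    GenomeLayout,
    Pool,
    PoolAlleleCounts,
)
from . import io as fio


@dataclass
class SimConfig:
    """All knobs for the synthetic genome, pools, genes and genotypes."""

    chrom_lengths: list[int] = field(default_factory=lambda: [5_000_000, 5_000_000])
    # fusion sites as fractions of each chromosome's length; the first on
    # each chromosome is marked as the centromere
    fusion_site_fractions: list[float] = field(default_factory=lambda: [0.3, 0.7])

    # pooled sequencing
    n_pools_per_class: int = 2
    salinity_native: list[float] = field(default_factory=lambda: [25.0, 30.0])
    salinity_invasive: list[float] = field(default_factory=lambda: [0.2, 0.5])
    mean_depth: float = 25.0
    depth_min: int = 20
    depth_max: int = 200
    n_snps: int = 20_000
    drift_c: float = 0.1

    # sweeps
    n_sweeps: int = 4
    sweep_width: int = 200_000
    sweep_strength: float = 0.9
    sweep_fusion_fraction: float = 1.0

    # genes
    n_selected: int = 25
    n_family: int = 36
    n_ion: int = 253
    n_other: int = 500
    gene_width: int = 2_000
    selected_mean_a: float = 32.8  # mean position value, fused genome
    selected_mean_b: float = 23.5  # mean position value, unfused genome

    # genotypes / LD
    n_individuals: int = 14
    n_founders: int = 20
    recomb_per_bp: float = 2e-5
    fusion_recomb_factor: float = 0.1
    fusion_region_width: int = 1_000_000
    gt_spacing: int = 2_000

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.drift_c < 1.0:
            raise ValueError("drift_c must be in (0, 1)")
        if not 0.0 <= self.sweep_strength <= 1.0:
            raise ValueError("sweep_strength must be in [0, 1]")
        if not 0.0 <= self.sweep_fusion_fraction <= 1.0:
            raise ValueError("sweep_fusion_fraction must be in [0, 1]")
        if any(f <= 0.0 or f >= 1.0 for f in self.fusion_site_fractions):
            raise ValueError("fusion site fractions must be in (0, 1)")
        if len(self.salinity_native) != self.n_pools_per_class or len(
            self.salinity_invasive
        ) != self.n_pools_per_class:
            raise ValueError("salinity lists must match n_pools_per_class")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def make_layout(config: SimConfig) -> GenomeLayout:
    chroms = [(f"chr{i + 1}", length) for i, length in enumerate(config.chrom_lengths)]
    sites = []
    for ci, (name, length) in enumerate(chroms):
        for si, frac in enumerate(config.fusion_site_fractions):
            sites.append(
                FusionSite(
                    chrom=name,
                    position=int(frac * length),
                    label=f"Chr{ci + 1}#{si + 1}",
                    is_centromere=(si == 0),
                )
            )
    return GenomeLayout(chromosomes=chroms, fusion_sites=sites)


def make_pools(config: SimConfig) -> list[Pool]:
    pools = [
        Pool(f"native{i + 1}", "native_saline", s)
        for i, s in enumerate(config.salinity_native)
    ]
    pools += [
        Pool(f"invasive{i + 1}", "invasive_freshwater", s)
        for i, s in enumerate(config.salinity_invasive)
    ]
    return pools


def sweep_regions(
    config: SimConfig, layout: GenomeLayout, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Half-open sweep intervals; a configurable fraction centered on fusion
    sites (cycling through them), the rest placed uniformly."""
    n_at_fusion = int(round(config.n_sweeps * config.sweep_fusion_fraction))
    regions = []
    sites = layout.fusion_sites
    lengths = layout.chrom_lengths
    for k in range(n_at_fusion):
        site = sites[k % len(sites)]
        half = config.sweep_width // 2
        start = max(0, min(site.position - half,
                           lengths[site.chrom] - config.sweep_width))
        regions.append((site.chrom, start, start + config.sweep_width))
    names = [c for c, _ in layout.chromosomes]
    probs = np.array([lengths[c] for c in names], dtype=float)
    probs /= probs.sum()
    for _ in range(config.n_sweeps - n_at_fusion):
        chrom = names[rng.choice(len(names), p=probs)]
        start = int(rng.integers(0, lengths[chrom] - config.sweep_width + 1))
        regions.append((chrom, start, start + config.sweep_width))
    return regions


def simulate_pools(
    config: SimConfig,
    layout: GenomeLayout | None = None,
    seed: int | None = None,
) -> tuple[PoolAlleleCounts, list[tuple[str, int, int]]]:
    """Pooled allele counts plus the sweep regions that were planted."""
    layout = layout or make_layout(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pools = make_pools(config)
    lengths = np.array([l for _, l in layout.chromosomes], dtype=float)
    per_chrom = np.floor(config.n_snps * lengths / lengths.sum()).astype(int)
    per_chrom[0] += config.n_snps - per_chrom.sum()

    regions = sweep_regions(config, layout, rng)
    c = config.drift_c
    a_scale = (1.0 - c) / c

    frames, refs, alts = [], [], []
    nat = slice(0, config.n_pools_per_class)
    inv = slice(config.n_pools_per_class, 2 * config.n_pools_per_class)
    for (chrom, length), n_c in zip(layout.chromosomes, per_chrom):
        pos = np.sort(rng.choice(length, size=n_c, replace=False))
        p = rng.uniform(0.05, 0.95, size=n_c)
        q = rng.beta(
            np.maximum(p * a_scale, 1e-9)[:, None],
            np.maximum((1.0 - p) * a_scale, 1e-9)[:, None],
            size=(n_c, len(pools)),
        )
        in_sweep = np.zeros(n_c, dtype=bool)
        for rc, rs, re in regions:
            if rc == chrom:
                in_sweep |= (pos >= rs) & (pos < re)
        s = config.sweep_strength
        target = np.round(p)[:, None]
        q_inv = q[:, inv]
        q[:, inv] = np.where(
            in_sweep[:, None], (1.0 - s) * q_inv + s * target, q_inv
        )
        depth = rng.poisson(config.mean_depth, size=(n_c, len(pools)))
        depth = np.clip(depth, config.depth_min, config.depth_max)
        alt = rng.binomial(depth, q)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        refs.append(depth - alt)
        alts.append(alt)
    counts = PoolAlleleCounts(
        sites=pd.concat(frames, ignore_index=True),
        ref_counts=np.vstack(refs),
        alt_counts=np.vstack(alts),
        pools=pools,
    )
    return counts, regions


# ---------------------------------------------------------------------------
# genes


def mean_position_value_beta(a: float) -> float:
    """E[100 * min(U, 1-U)] for U ~ Beta(a, a), by numerical integration."""
    from scipy.stats import beta as beta_dist

    val, _ = integrate.quad(
        lambda u: min(u, 1.0 - u) * beta_dist.pdf(u, a, a), 0.0, 1.0
    )
    return 100.0 * val


def beta_shape_for_mean(target_mean: float) -> float:
    """Solve Beta(a, a) shape giving the target mean position value.

    Uniform (a = 1) gives 25; targets above 25 need a > 1 (centralized),
    below 25 need a < 1 (edge-biased). Valid targets lie in (0, 50).
    """
    if not 0.0 < target_mean < 50.0:
        raise ValueError("target mean position value must be in (0, 50)")
    return float(
        optimize.brentq(
            lambda a: mean_position_value_beta(a) - target_mean, 1e-3, 1e3
        )
    )


def simulate_genes(
    config: SimConfig,
    layout: GenomeLayout | None = None,
    seed: int | None = None,
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Gene records for species A (fused, centralized selected genes) and
    species B (unfused); gene ids match across species."""
    layout = layout or make_layout(config)
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    )
    a_shape = beta_shape_for_mean(config.selected_mean_a)
    b_shape = beta_shape_for_mean(config.selected_mean_b)

    names = [c for c, _ in layout.chromosomes]
    lengths = layout.chrom_lengths
    w = config.gene_width

    def place(gene_id, set_label, chrom, mid_frac, genes):
        length = lengths[chrom]
        mid = mid_frac * length
        start = int(np.clip(mid - w / 2, 0, length - w))
        genes.append(GeneRecord(gene_id, chrom, start, start + w, set_label))

    sets = [
        ("sel", "selected25", config.n_selected),
        ("fam", "family36", config.n_family),
        ("ion", "ion253", config.n_ion),
        ("oth", "other", config.n_other),
    ]
    genes_a: list[GeneRecord] = []
    genes_b: list[GeneRecord] = []
    for prefix, label, n in sets:
        chroms = [names[int(i)] for i in rng.integers(0, len(names), size=n)]
        if label == "selected25":
            fr_a = rng.beta(a_shape, a_shape, size=n)
            fr_b = rng.beta(b_shape, b_shape, size=n)
        else:
            fr_a = rng.uniform(0, 1, size=n)
            fr_b = rng.uniform(0, 1, size=n)
        for k in range(n):
            gid = f"{prefix}{k + 1:04d}"
            place(gid, label, chroms[k], fr_a[k], genes_a)
            place(gid, label, chroms[k], fr_b[k], genes_b)
    return genes_a, genes_b


# ---------------------------------------------------------------------------
# genotypes


def fusion_intervals(config: SimConfig, layout: GenomeLayout,
                     chrom: str) -> list[tuple[int, int]]:
    """Fixed-width intervals centered on each fusion site of one chromosome."""
    out = []
    length = layout.chrom_lengths[chrom]
    half = config.fusion_region_width // 2
    for site in layout.sites_on(chrom):
        start = max(0, min(site.position - half,
                           length - config.fusion_region_width))
        out.append((start, start + config.fusion_region_width))
    return out


def simulate_genotypes(
    config: SimConfig,
    layout: GenomeLayout | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Diploid dosage matrix (individuals x SNPs) and site table.

    Haplotypes are mosaics over ``n_founders`` founder haplotypes: between
    consecutive SNPs the copied founder switches with probability
    1 - exp(-r * gap), r being the per-bp rate times the fusion-region
    factor where the inter-SNP midpoint lies inside a fusion interval. SNPs
    sit on a regular grid so LD profiles from different regions share exact
    integer distances.
    """
    layout = layout or make_layout(config)
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 2_000_003
    )
    n_hap = 2 * config.n_individuals
    all_dosages = []
    frames = []
    for chrom, length in layout.chromosomes:
        pos = np.arange(config.gt_spacing, length, config.gt_spacing,
                        dtype=np.int64)
        n_snps = len(pos)
        freq = rng.uniform(0.1, 0.9, size=n_snps)
        founders = (rng.random((config.n_founders, n_snps)) < freq).astype(np.int8)

        regions = fusion_intervals(config, layout, chrom)
        gaps = np.diff(pos)
        gap_mid = (pos[:-1] + pos[1:]) // 2
        rate = np.full(n_snps - 1, config.recomb_per_bp)
        for start, end in regions:
            rate[(gap_mid >= start) & (gap_mid < end)] *= config.fusion_recomb_factor
        p_switch = 1.0 - np.exp(-rate * gaps)

        current = rng.integers(0, config.n_founders, size=n_hap)
        haps = np.empty((n_hap, n_snps), dtype=np.int8)
        haps[:, 0] = founders[current, 0]
        for j in range(1, n_snps):
            switch = rng.random(n_hap) < p_switch[j - 1]
            if switch.any():
                current = np.where(
                    switch, rng.integers(0, config.n_founders, size=n_hap), current
                )
            haps[:, j] = founders[current, j]
        dosage = haps[0::2].astype(float) + haps[1::2].astype(float)
        all_dosages.append(dosage)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    dosages = np.hstack(all_dosages)
    sites = pd.concat(frames, ignore_index=True)
    return dosages, sites


# ---------------------------------------------------------------------------
# fixtures on disk


def write_sync(counts: PoolAlleleCounts, path: str | Path) -> None:
    """Write counts as a PoPoolation2 sync file (ref allele A, alt allele C)."""
    with open(path, "w") as fh:
        for i in range(counts.n_snps):
            fields = [
                f"{counts.ref_counts[i, j]}:0:{counts.alt_counts[i, j]}:0:0:0"
                for j in range(counts.n_pools)
            ]
            fh.write(
                f"{counts.sites['chrom'].iat[i]}\t{counts.sites['pos'].iat[i] + 1}"
                f"\tA\t" + "\t".join(fields) + "\n"
            )


def write_pool_meta(pools: list[Pool], path: str | Path) -> None:
    pd.DataFrame(
        [(p.name, p.habitat_class, p.salinity) for p in pools],
        columns=["name", "habitat_class", "salinity"],
    ).to_csv(path, sep="\t", index=False)


def make_fixture_set(config: SimConfig, outdir: str | Path) -> dict:
    """Write the full set of on-disk fixtures every other module consumes.

    Emits layout BED, sync + pool metadata, gene BED/sets TSV per species,
    genotype VCF, and a manifest JSON with the seed and config hash.
    Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = make_layout(config)
    counts, regions = simulate_pools(config, layout)
    genes_a, genes_b = simulate_genes(config, layout)
    dosages, gt_sites = simulate_genotypes(config, layout)

    paths = {
        "layout": outdir / "layout.bed",
        "sync": outdir / "pools.sync",
        "pool_meta": outdir / "pools.tsv",
        "genes_a": outdir / "genes_speciesA.bed",
        "genes_b": outdir / "genes_speciesB.bed",
        "gene_sets": outdir / "gene_sets.tsv",
        "genotypes": outdir / "genotypes.vcf",
        "manifest": outdir / "manifest.json",
    }
    fio.write_layout(layout, paths["layout"])
    write_sync(counts, paths["sync"])
    write_pool_meta(counts.pools, paths["pool_meta"])
    fio.write_genes_bed(genes_a, paths["genes_a"], paths["gene_sets"])
    fio.write_genes_bed(genes_b, paths["genes_b"])
    fio.write_vcf_genotypes(dosages, gt_sites, layout, paths["genotypes"])
    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": asdict(config),
        "sweep_regions": [list(r) for r in regions],
        "files": {k: str(v.name) for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
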