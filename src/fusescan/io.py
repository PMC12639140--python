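"""Readers and writers for the standard formats the pipeline touches.

Supported inputs: a BED-like genome layout (chromosomes + fusion sites),
PoPoolation2 "sync" allele counts, VCF with per-sample allelic depths (AD),
gene records as BED4 or GFF3 with a TSV of set-membership labels, and
per-SNP Bayes-factor tables. All readers reject coordinate violations
rather than clamping, and every table writer round-trips losslessly with
its reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import (
    FusionSite,
    GeneRecord,
    GenomeLayout,
    Pool,
    PoolAlleleCounts,
    ValidationError,
    WINDOW_COLUMNS,
    empty_window_table,
)

logger = logging.getLogger("fusescan")

# sync count fields are A:T:C:G:N:del; only the four bases are alleles
SYNC_BASES = ("A", "T", "C", "G")
# deterministic tie-break for biallelic reduction
BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# genome layout


def read_layout(path: str | Path) -> GenomeLayout:
    """Read a BED-like layout file into a :class:`GenomeLayout`.

    The file holds BED5 records ``chrom start end label kind`` where *kind*
    is ``chromosome`` (the record spans the whole chromosome and defines its
    length), ``fusion`` or ``centromere`` (point records; the site position
    is the start coordinate). Coordinates are 0-based half-open; a site at
    ``position == length`` is rejected.
    """
    # '#' only introduces a comment at the start of a line; it is a legal
    # character inside site labels
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    from io import StringIO

    df = pd.read_csv(
        StringIO("\n".join(lines)), sep="\t", header=None,
        names=["chrom", "start", "end", "label", "kind"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "label": str, "kind": str},
    )
    chroms: list[tuple[str, int]] = []
    sites: list[FusionSite] = []
    for rec in df.itertuples(index=False):
        kind = rec.kind.lower()
        if kind == "chromosome":
            if rec.start != 0:
                raise ValidationError(
                    f"chromosome record {rec.label!r} must start at 0"
                )
            chroms.append((rec.chrom, int(rec.end)))
        elif kind in ("fusion", "centromere"):
            sites.append(
                FusionSite(
                    chrom=rec.chrom,
                    position=int(rec.start),
                    label=rec.label,
                    is_centromere=(kind == "centromere"),
                )
            )
        else:
            raise ValidationError(f"unknown layout record kind {rec.kind!r}")
    lengths = dict(chroms)
    for site in sites:
        if site.chrom in lengths and not 0 <= site.position < lengths[site.chrom]:
            raise ValidationError(
                f"fusion site {site.label!r} at {site.chrom}:{site.position} "
                f"is outside [0, {lengths[site.chrom]})"
            )
    return GenomeLayout(chromosomes=chroms, fusion_sites=sites)


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    rows = [
        (name, 0, length, name, "chromosome")
        for name, length in layout.chromosomes
    ]
    rows += [
        (s.chrom, s.position, s.position + 1, s.label,
         "centromere" if s.is_centromere else "fusion")
        for s in layout.fusion_sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# pooled allele counts


def read_pool_meta(path: str | Path) -> list[Pool]:
    """TSV with columns name, habitat_class, salinity, in pool-column order."""
    meta = pd.read_csv(path, sep="\t", dtype={"name": str, "habitat_class": str})
    return [
        Pool(r.name_, r.habitat_class, float(r.salinity))
        for r in meta.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def _biallelic_reduce(totals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick ref/alt allele indices from per-base totals (n_sites, 4).

    Ref is the highest-count base, alt the second highest; ties broken by
    base order A < C < G < T. Sites with more than two observed bases are
    masked out (returned keep mask False).
    """
    n_observed = (totals > 0).sum(axis=1)
    keep = n_observed <= 2
    # rank by (count desc, base order asc): sort key = -count * 8 + order
    order_key = np.array([BASE_ORDER[b] for b in SYNC_BASES])
    # lexsort: last key is primary
    idx = np.argsort(order_key[None, :] - totals * 8, axis=1, kind="stable")
    ref_idx = idx[:, 0]
    alt_idx = idx[:, 1]
    return keep, ref_idx, alt_idx


def read_sync(path: str | Path, pool_meta: str | Path | list[Pool]) -> PoolAlleleCounts:
    """Read a PoPoolation2 sync file into biallelic :class:`PoolAlleleCounts`.

    Sync columns: chrom, 1-based position, reference base, then one
    ``A:T:C:G:N:del`` count field per pool. Sites with more than two
    observed bases (summed over pools) are dropped and the count logged.
    """
    pools = pool_meta if isinstance(pool_meta, list) else read_pool_meta(pool_meta)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 3 + len(pools):
        raise ValidationError(
            f"sync file has {df.shape[1] - 3} pool columns but metadata "
            f"describes {len(pools)} pools"
        )
    n_sites, n_pools = len(df), len(pools)
    counts = np.zeros((n_sites, n_pools, 4), dtype=np.int64)
    for j in range(n_pools):
        fields = df.iloc[:, 3 + j].str.split(":", expand=True).to_numpy()
        counts[:, j, :] = fields[:, :4].astype(np.int64)  # drop N and del
    totals = counts.sum(axis=1)  # (n_sites, 4)
    keep, ref_idx, alt_idx = _biallelic_reduce(totals)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_sync: dropped %d non-biallelic sites", n_dropped)
    rows = np.arange(n_sites)
    ref_counts = counts[rows, :, ref_idx][keep]
    alt_counts = counts[rows, :, alt_idx][keep]
    sites = pd.DataFrame(
        {
            "chrom": df.iloc[:, 0].to_numpy()[keep],
            "pos": df.iloc[:, 1].astype(np.int64).to_numpy()[keep] - 1,  # to 0-based
        }
    )
    return PoolAlleleCounts(sites, ref_counts, alt_counts, pools)


def read_vcf_pool_counts(
    path: str | Path, pool_meta: str | Path | list[Pool]
) -> PoolAlleleCounts:
    """Read biallelic pool counts from a VCF carrying per-sample AD fields.

    Sample order in the VCF must match the pool metadata order. Sites with
    more than one ALT allele are dropped (logged), mirroring the sync
    reader's biallelic reduction.
    """
    pools = pool_meta if isinstance(pool_meta, list) else read_pool_meta(pool_meta)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[list[int]] = []
    alts: list[list[int]] = []
    n_dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != len(pools):
            raise ValidationError(
                f"VCF has {len(samples)} samples but metadata describes "
                f"{len(pools)} pools"
            )
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_dropped += 1
                continue
            ad = [rec.samples[s]["AD"] for s in samples]
            refs.append([int(a[0]) for a in ad])
            alts.append([int(a[1]) for a in ad])
            chroms.append(rec.chrom)
            positions.append(rec.start)  # pysam start is already 0-based
    if n_dropped:
        logger.info("read_vcf_pool_counts: dropped %d non-biallelic sites", n_dropped)
    sites = pd.DataFrame({"chrom": chroms, "pos": np.array(positions, dtype=np.int64)})
    return PoolAlleleCounts(
        sites,
        np.array(refs, dtype=np.int64).reshape(len(sites), len(pools)),
        np.array(alts, dtype=np.int64).reshape(len(sites), len(pools)),
        pools,
    )


def read_pool_counts(
    path: str | Path, pool_meta: str | Path | list[Pool]
) -> PoolAlleleCounts:
    """Dispatch on extension: ``.sync`` → sync reader, ``.vcf`` → VCF reader."""
    suffix = Path(path).suffix.lower()
    if suffix == ".vcf":
        return read_vcf_pool_counts(path, pool_meta)
    return read_sync(path, pool_meta)


# ---------------------------------------------------------------------------
# window tables


def write_window_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a window table as TSV; boolean flags serialized as 0/1."""
    out = table[WINDOW_COLUMNS].copy()
    for col in ("flag_top5", "flag_top1", "flag_bf"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_window_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if len(df) == 0:
        return empty_window_table()
    for col in ("flag_top5", "flag_top1", "flag_bf"):
        df[col] = df[col].astype(bool)
    for col in ("start", "end", "n_snps"):
        df[col] = df[col].astype(np.int64)
    return df[WINDOW_COLUMNS]


# ---------------------------------------------------------------------------
# genes


def read_genes_bed(
    path: str | Path,
    sets: str | Path | dict[str, str] | None = None,
    layout: GenomeLayout | None = None,
) -> list[GeneRecord]:
    """Read gene records from BED4 (chrom start end gene_id).

    ``sets`` maps gene_id to a set label (dict, or TSV with columns
    gene_id, set_label); unlisted genes get label "other". When a layout is
    given, genes outside chromosome bounds are rejected.
    """
    labels = _load_set_labels(sets)
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "gene_id": str},
    )
    return _make_genes(df, labels, layout)


def read_genes_gff3(
    path: str | Path,
    sets: str | Path | dict[str, str] | None = None,
    layout: GenomeLayout | None = None,
    feature: str = "gene",
) -> list[GeneRecord]:
    """Read gene records from GFF3; 1-based closed coords converted to
    0-based half-open. Gene id from the ``ID=`` (or ``gene_id=``) attribute."""
    labels = _load_set_labels(sets)
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise ValidationError(f"GFF3 {feature} record without ID: {line!r}")
            rows.append((f[0], int(f[3]) - 1, int(f[4]), gid))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    return _make_genes(df, labels, layout)


def _load_set_labels(sets) -> dict[str, str]:
    if sets is None:
        return {}
    if isinstance(sets, dict):
        return sets
    df = pd.read_csv(sets, sep="\t", dtype=str)
    return dict(zip(df["gene_id"], df["set_label"]))


def _make_genes(df: pd.DataFrame, labels: dict[str, str],
                layout: GenomeLayout | None) -> list[GeneRecord]:
    lengths = layout.chrom_lengths if layout is not None else None
    genes = []
    for r in df.itertuples(index=False):
        if lengths is not None:
            if r.chrom not in lengths or not (0 <= r.start < r.end <= lengths[r.chrom]):
                raise ValidationError(
                    f"gene {r.gene_id!r} at {r.chrom}:{r.start}-{r.end} "
                    "outside chromosome bounds"
                )
        genes.append(
            GeneRecord(r.gene_id, r.chrom, int(r.start), int(r.end),
                       labels.get(r.gene_id, "other"))
        )
    return genes


def write_genes_bed(genes: list[GeneRecord], path: str | Path,
                    sets_path: str | Path | None = None) -> None:
    pd.DataFrame(
        [(g.chrom, g.start, g.end, g.gene_id) for g in genes]
    ).to_csv(path, sep="\t", header=False, index=False)
    if sets_path is not None:
        pd.DataFrame(
            [(g.gene_id, g.set_label) for g in genes],
            columns=["gene_id", "set_label"],
        ).to_csv(sets_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bayes-factor tables and genotype matrices


def read_bf_table(path: str | Path) -> pd.DataFrame:
    """Per-SNP Bayes factors: TSV with columns chrom, pos, bf (0-based pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "bf"} - set(df.columns)
    if missing:
        raise ValidationError(f"BF table missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(np.int64)
    df["bf"] = df["bf"].astype(float)
    return df[["chrom", "pos", "bf"]]


def read_vcf_genotypes(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Diploid dosage matrix (individuals x SNPs) from VCF GT fields.

    Missing genotypes become NaN. Returns (dosages, sites DataFrame with
    chrom, pos in 0-based coordinates).
    """
    chroms, positions, columns = [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            col = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is not None and None not in gt:
                    col[i] = sum(gt)
            columns.append(col)
            chroms.append(rec.chrom)
            positions.append(rec.start)
    dosages = (
        np.array(columns).T if columns else np.empty((0, 0))
    )
    sites = pd.DataFrame({"chrom": chroms, "pos": np.array(positions, dtype=np.int64)})
    return dosages, sites


def write_vcf_genotypes(
    dosages: np.ndarray, sites: pd.DataFrame, layout: GenomeLayout,
    path: str | Path, sample_prefix: str = "ind",
) -> None:
    """Write a dosage matrix as a minimal unphased VCF (GT only)."""
    n_ind, n_snps = dosages.shape
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in layout.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"{sample_prefix}{i}" for i in range(n_ind))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(n_snps):
            gts = "\t".join(
                "./." if np.isnan(dosages[i, j]) else gt_map[int(dosages[i, j])]
                for i in range(n_ind)
            )
            fh.write(
                f"{sites['chrom'].iat[j]}\t{sites['pos'].iat[j] + 1}\t.\tA\tT\t.\t"
                f"PASS\t.\tGT\t{gts}\n"
            )
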