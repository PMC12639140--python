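"""SNP filtering and sliding-window F_ST / theta-pi from pooled counts.

Estimator choices (recorded in output metadata by the CLI):

* F_ST is a Hudson-type estimator with a pool-size bias correction that
  uses read depth as sample size, combined per window as a ratio of
  averages (sum of per-site numerators over sum of denominators), which is
  robust to variable SNP density across windows. With pools from multiple
  populations per habitat class, the (num, den) sums are pooled over all
  native x invasive pool pairs.
* Nucleotide diversity uses the unbiased per-site estimator
  pi = (d / (d - 1)) * 2 p (1 - p) with d the read depth, summed over sites
  and divided by window length in bp (callable-site masks are not modelled).
* The diversity ratio is log2((pi_invasive + eps) / (pi_native + eps)) with
  eps = 1e-8, so windows monomorphic in both classes get ratio 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeLayout, PoolAlleleCounts, WINDOW_COLUMNS

LOG2_EPS = 1e-8


def filter_snps(
    counts: PoolAlleleCounts,
    maf_min: float = 0.05,
    min_allele_reads: int = 4,
    depth_min: int = 20,
    depth_max: int = 200,
    depth_rule: str = "per_pool",
) -> tuple[PoolAlleleCounts, dict[str, int]]:
    """Apply the SNP quality filters; returns (kept counts, removal tally).

    Rules, each applied to the full input (a SNP failing several rules is
    tallied under the first in this order):

    * ``depth``: total read depth within [depth_min, depth_max], inclusive,
      in every pool (``depth_rule="per_pool"``, default) or summed across
      pools (``depth_rule="summed"``).
    * ``allele_reads``: every observed allele supported by at least
      ``min_allele_reads`` reads summed over pools.
    * ``maf``: minor-allele frequency pooled across pools strictly above
      ``maf_min``.
    """
    d = counts.depths
    if depth_rule == "per_pool":
        depth_ok = ((d >= depth_min) & (d <= depth_max)).all(axis=1)
    elif depth_rule == "summed":
        total = d.sum(axis=1)
        depth_ok = (total >= depth_min) & (total <= depth_max)
    else:
        raise ValueError(f"unknown depth_rule {depth_rule!r}")

    ref_tot = counts.ref_counts.sum(axis=1)
    alt_tot = counts.alt_counts.sum(axis=1)
    reads_ok = ((ref_tot == 0) | (ref_tot >= min_allele_reads)) & (
        (alt_tot == 0) | (alt_tot >= min_allele_reads)
    )

    site_tot = ref_tot + alt_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(ref_tot, alt_tot) / np.maximum(site_tot, 1)
    maf_ok = maf > maf_min

    tally = {
        "depth": int((~depth_ok).sum()),
        "allele_reads": int((depth_ok & ~reads_ok).sum()),
        "maf": int((depth_ok & reads_ok & ~maf_ok).sum()),
    }
    keep = depth_ok & reads_ok & maf_ok
    return counts.take(keep), tally


def site_pi(alt: int, depth: int) -> float:
    """Unbiased per-site heterozygosity from pooled read counts.

    pi = (d / (d - 1)) * 2 p (1 - p) with p = alt / depth. Undefined for
    depth < 2 (callers skip such sites).
    """
    if depth < 2:
        raise ValueError("site_pi requires depth >= 2")
    p = alt / depth
    return (depth / (depth - 1)) * 2.0 * p * (1.0 - p)


def site_fst(alt1: int, depth1: int, alt2: int, depth2: int) -> tuple[float, float]:
    """Hudson-type per-site F_ST components with read-depth bias correction.

    Returns (num, den) with
    num = (p1 - p2)^2 - p1(1-p1)/(d1-1) - p2(1-p2)/(d2-1) and
    den = p1(1-p2) + p2(1-p1). Sites fixed for the same allele in both
    pools (den = 0) contribute (0, 0).
    """
    if depth1 < 2 or depth2 < 2:
        raise ValueError("site_fst requires depth >= 2 in both pools")
    p1, p2 = alt1 / depth1, alt2 / depth2
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    if den == 0.0:
        return 0.0, 0.0
    num = (
        (p1 - p2) ** 2
        - p1 * (1.0 - p1) / (depth1 - 1)
        - p2 * (1.0 - p2) / (depth2 - 1)
    )
    return num, den


@dataclass
class SiteStats:
    """Per-SNP components feeding the window scan.

    ``fst_num``/``fst_den`` are the per-site Hudson components summed over
    all native x invasive pool pairs; ``pi`` is the per-site, per-pool
    diversity matrix (0 where depth < 2).
    """

    sites: pd.DataFrame
    fst_num: np.ndarray
    fst_den: np.ndarray
    pi: np.ndarray
    depths: np.ndarray
    native_idx: np.ndarray
    invasive_idx: np.ndarray


def compute_site_stats(counts: PoolAlleleCounts) -> SiteStats:
    """Vectorized per-site F_ST components and per-pool diversity."""
    nat = counts.class_indices("native_saline")
    inv = counts.class_indices("invasive_freshwater")
    if len(nat) == 0 or len(inv) == 0:
        raise ValueError("need at least one pool per habitat class")
    d = counts.depths.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(d > 0, counts.alt_counts / np.maximum(d, 1), np.nan)
        pi = np.where(d >= 2, (d / np.maximum(d - 1, 1)) * 2.0 * p * (1.0 - p), 0.0)

    n_snps = counts.n_snps
    fst_num = np.zeros(n_snps)
    fst_den = np.zeros(n_snps)
    for i in nat:
        for j in inv:
            p1, p2 = p[:, i], p[:, j]
            d1, d2 = d[:, i], d[:, j]
            valid = (d1 >= 2) & (d2 >= 2)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / np.maximum(d1 - 1, 1)
                - p2 * (1 - p2) / np.maximum(d2 - 1, 1)
            )
            contrib = valid & (den > 0)
            fst_num += np.where(contrib, num, 0.0)
            fst_den += np.where(contrib, den, 0.0)
    return SiteStats(
        sites=counts.sites,
        fst_num=fst_num,
        fst_den=fst_den,
        pi=pi,
        depths=counts.depths,
        native_idx=nat,
        invasive_idx=inv,
    )


def window_starts(length: int, window: int, step: int) -> np.ndarray:
    """Half-open tiling: one window per start in 0, step, 2*step, ... < length,
    the last truncated at the chromosome end."""
    return np.arange(0, length, step, dtype=np.int64)


def window_scan(
    site_stats: SiteStats,
    layout: GenomeLayout,
    window: int = 10_000,
    step: int = 5_000,
) -> pd.DataFrame:
    """Sliding-window F_ST, per-class theta-pi, and log2 diversity ratio.

    Windows with no SNPs are emitted with NaN statistics (excluded from any
    downstream quantile ranking); flags start out False.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    pi_nat_site = site_stats.pi[:, site_stats.native_idx].mean(axis=1)
    pi_inv_site = site_stats.pi[:, site_stats.invasive_idx].mean(axis=1)

    rows = []
    for chrom, length in layout.chromosomes:
        mask = (site_stats.sites["chrom"] == chrom).to_numpy()
        pos = site_stats.sites["pos"].to_numpy()[mask]
        num = np.concatenate([[0.0], np.cumsum(site_stats.fst_num[mask])])
        den = np.concatenate([[0.0], np.cumsum(site_stats.fst_den[mask])])
        pn = np.concatenate([[0.0], np.cumsum(pi_nat_site[mask])])
        pv = np.concatenate([[0.0], np.cumsum(pi_inv_site[mask])])

        starts = window_starts(length, window, step)
        ends = np.minimum(starts + window, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        n_snps = hi - lo
        wlen = (ends - starts).astype(float)

        w_num = num[hi] - num[lo]
        w_den = den[hi] - den[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(w_den > 0, w_num / np.where(w_den > 0, w_den, 1.0), 0.0)
        pi_native = (pn[hi] - pn[lo]) / wlen
        pi_invasive = (pv[hi] - pv[lo]) / wlen
        log2_ratio = np.log2((pi_invasive + LOG2_EPS) / (pi_native + LOG2_EPS))

        empty = n_snps == 0
        fst = np.where(empty, np.nan, fst)
        pi_native = np.where(empty, np.nan, pi_native)
        pi_invasive = np.where(empty, np.nan, pi_invasive)
        log2_ratio = np.where(empty, np.nan, log2_ratio)

        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_snps": n_snps.astype(np.int64),
                    "fst": fst,
                    "pi_native": pi_native,
                    "pi_invasive": pi_invasive,
                    "log2_ratio": log2_ratio,
                    "flag_top5": False,
                    "flag_top1": False,
                    "flag_bf": False,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True) if rows else None
    if table is None:
        from .core import empty_window_table

        return empty_window_table()
    return table[WINDOW_COLUMNS]
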