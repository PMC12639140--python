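"""Empirical-null enrichment of outlier windows at chromosomal fusion sites.

The background distribution of selection signatures is approximated by
randomly sampling a large number of fixed-length intervals (1 Mb and 2 Mb
by default) along each chromosome and counting flagged windows in each. An
interval centered on a fusion site is then scored against that chromosome's
background: the one-sided empirical p is (1 + #{background >= observed}) /
(1 + N), floored at 1/(N + 1), and a site is called significant when its
count reaches the upper 5% quantile of the background. Set-level tests
compare all fusion-site counts on a chromosome (or genome-wide, with
chromosomes weighted by length) against the background sample via
two-sample KS and Cramér-von Mises tests.

Window membership in an interval is by window midpoint, which prevents
double counting across the half-overlapping sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FusionSite, GenomeLayout, TestResult
from .stats import cramer_von_mises_two, empirical_quantile, ks_two_sample

MEASURE_FLAGS = {"top5": "flag_top5", "top1": "flag_top1", "bf": "flag_bf"}


@dataclass
class BackgroundDist:
    """Empirical distribution of flagged-window counts in random intervals."""

    chrom: str
    interval_length: int
    counts: np.ndarray
    n: int
    seed: int


@dataclass
class EnrichmentResult:
    site_label: str
    measure: str
    interval_length: int
    observed_count: int
    p_emp: float
    significant: bool
    quantile95: float

    def as_dict(self) -> dict:
        return {
            "site": self.site_label,
            "measure": self.measure,
            "interval_length": self.interval_length,
            "observed": self.observed_count,
            "p_emp": self.p_emp,
            "significant": self.significant,
            "quantile95": self.quantile95,
        }


def _flag_midpoints(table: pd.DataFrame, measure: str, chrom: str) -> np.ndarray:
    """Sorted midpoints of flagged windows on one chromosome."""
    col = MEASURE_FLAGS[measure]
    sel = table[(table["chrom"] == chrom) & table[col]]
    mids = ((sel["start"] + sel["end"]) // 2).to_numpy(dtype=np.int64)
    return np.sort(mids)


def count_outliers_in_interval(
    table: pd.DataFrame, measure: str, chrom: str, start: int, end: int
) -> int:
    """Flagged windows with midpoint in [start, end)."""
    mids = _flag_midpoints(table, measure, chrom)
    return int(
        np.searchsorted(mids, end, side="left")
        - np.searchsorted(mids, start, side="left")
    )


def sample_background(
    table: pd.DataFrame,
    measure: str,
    layout: GenomeLayout,
    chrom: str,
    interval_length: int,
    n: int = 1_000_000,
    seed: int = 0,
) -> BackgroundDist:
    """Counts of flagged windows in ``n`` uniformly placed intervals.

    Interval starts are drawn uniformly (with replacement) from
    [0, chromosome length - interval_length]; overlap with fusion-site
    intervals is not excluded.
    """
    length = layout.chrom_lengths[chrom]
    if length <= interval_length:
        raise ValueError(
            f"chromosome {chrom!r} ({length} bp) not longer than the "
            f"{interval_length} bp interval"
        )
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, length - interval_length + 1, size=n)
    mids = _flag_midpoints(table, measure, chrom)
    counts = (
        np.searchsorted(mids, starts + interval_length, side="left")
        - np.searchsorted(mids, starts, side="left")
    )
    return BackgroundDist(chrom, interval_length, counts.astype(np.int64), n, seed)


def site_interval(site: FusionSite, interval_length: int, chrom_length: int
                  ) -> tuple[int, int]:
    """Interval of the given length centered on the fusion site, shifted to
    stay within the chromosome."""
    start = site.position - interval_length // 2
    start = max(0, min(start, chrom_length - interval_length))
    return start, start + interval_length


def site_enrichment(
    site: FusionSite,
    table: pd.DataFrame,
    measure: str,
    background: BackgroundDist,
    layout: GenomeLayout,
) -> EnrichmentResult:
    """Score one fusion site against its chromosome's background."""
    if site.chrom != background.chrom:
        raise ValueError("site and background are on different chromosomes")
    start, end = site_interval(site, background.interval_length,
                               layout.chrom_lengths[site.chrom])
    observed = count_outliers_in_interval(table, measure, site.chrom, start, end)
    k = int((background.counts >= observed).sum())
    p_emp = (1 + k) / (1 + background.n)
    q95 = empirical_quantile(background.counts, 0.95)
    return EnrichmentResult(
        site_label=site.label,
        measure=measure,
        interval_length=background.interval_length,
        observed_count=observed,
        p_emp=float(p_emp),
        significant=bool(observed >= q95),
        quantile95=float(q95),
    )


def site_set_test(
    site_counts, background: BackgroundDist, seed: int = 0,
    cvm_permutations: int = 10_000,
) -> tuple[TestResult, TestResult]:
    """KS and Cramér-von Mises tests of all site counts on one chromosome
    against the background count sample (enrichment read as a shift of the
    site-count sample toward high counts)."""
    x = np.asarray(site_counts, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one site count")
    y = background.counts.astype(float)
    return (
        ks_two_sample(x, y),
        cramer_von_mises_two(x, y, seed=seed, n_permutations=cvm_permutations),
    )


def pooled_background(
    backgrounds: dict[str, BackgroundDist],
    layout: GenomeLayout,
    n: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Genome-wide background: resample counts, drawing each from chromosome
    c with probability length_c / total length."""
    chroms = sorted(backgrounds)
    lengths = layout.chrom_lengths
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    if n is None:
        n = max(b.n for b in backgrounds.values())
    rng = np.random.default_rng(seed)
    which = rng.choice(len(chroms), size=n, p=weights)
    pooled = np.empty(n, dtype=np.int64)
    for i, c in enumerate(chroms):
        mask = which == i
        k = int(mask.sum())
        if k:
            pooled[mask] = rng.choice(backgrounds[c].counts, size=k, replace=True)
    return pooled


def genomewide_test(
    backgrounds: dict[str, BackgroundDist],
    table: pd.DataFrame,
    measure: str,
    layout: GenomeLayout,
    n: int | None = None,
    seed: int = 0,
    cvm_permutations: int = 10_000,
) -> tuple[TestResult, TestResult]:
    """All fusion sites combined vs the length-weighted pooled background."""
    with_sites = {c for c in backgrounds if layout.sites_on(c)}
    if len(with_sites) < 2:
        raise ValueError("genome-wide test needs sites on >= 2 chromosomes")
    counts = []
    for chrom, bg in backgrounds.items():
        for site in layout.sites_on(chrom):
            start, end = site_interval(site, bg.interval_length,
                                       layout.chrom_lengths[chrom])
            counts.append(
                count_outliers_in_interval(table, measure, chrom, start, end)
            )
    pooled = pooled_background(backgrounds, layout, n=n, seed=seed)
    x = np.asarray(counts, dtype=float)
    return (
        ks_two_sample(x, pooled),
        cramer_von_mises_two(x, pooled, seed=seed,
                             n_permutations=cvm_permutations),
    )


def enrichment_scan(
    table: pd.DataFrame,
    layout: GenomeLayout,
    measures: tuple[str, ...] = ("top5", "top1", "bf"),
    interval_lengths: tuple[int, ...] = (1_000_000, 2_000_000),
    n: int = 1_000_000,
    seed: int = 0,
    cvm_permutations: int = 10_000,
) -> tuple[pd.DataFrame, dict]:
    """Full per-site scan plus per-chromosome and genome-wide set tests.

    Returns (per-site results DataFrame, nested dict of set-test results).
    One independent background per (chromosome, measure, interval length),
    seeded deterministically from ``seed``.
    """
    rows = []
    set_tests: dict = {}
    ss = np.random.SeedSequence(seed)
    for li, interval_length in enumerate(interval_lengths):
        for mi, measure in enumerate(measures):
            backgrounds: dict[str, BackgroundDist] = {}
            for ci, (chrom, length) in enumerate(layout.chromosomes):
                if length <= interval_length:
                    continue
                sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                bg = sample_background(
                    table, measure, layout, chrom, interval_length, n=n, seed=sub
                )
                backgrounds[chrom] = bg
                sites = layout.sites_on(chrom)
                if not sites:
                    continue
                site_counts = []
                for site in sites:
                    res = site_enrichment(site, table, measure, bg, layout)
                    rows.append(res.as_dict())
                    site_counts.append(res.observed_count)
                ks, cm = site_set_test(site_counts, bg, seed=sub,
                                       cvm_permutations=cvm_permutations)
                set_tests[f"{chrom}|{measure}|{interval_length}"] = {
                    "ks": ks.as_dict(), "cm": cm.as_dict(),
                }
            if sum(bool(layout.sites_on(c)) for c in backgrounds) >= 2:
                sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                ks, cm = genomewide_test(
                    backgrounds, table, measure, layout, seed=sub,
                    cvm_permutations=cvm_permutations,
                )
                set_tests[f"genome|{measure}|{interval_length}"] = {
                    "ks": ks.as_dict(), "cm": cm.as_dict(),
                }
    return pd.DataFrame(rows), set_tests
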