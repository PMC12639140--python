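"""Quantile-intersection outlier calling and environmental association.

A window carries a selection signature when it falls simultaneously in the
top tail of F_ST and the bottom tail of the log2 invasive/native diversity
ratio; an optional second layer additionally requires at least one SNP in
the window whose allele frequencies are strongly associated with salinity
(Bayes factor above a threshold).

The faithful association path imports externally computed per-SNP Bayes
factors. A built-in surrogate score is provided so the pipeline runs end to
end without external MCMC: the Pearson correlation between across-pool
standardized allele frequencies and standardized salinity, converted to a
pseudo-Bayes factor via exp(delta-BIC / 2) for the one-covariate linear
model against the intercept model. Surrogate scores are labelled
``source="surrogate"`` everywhere and are not equivalent to an
auxiliary-model Bayes factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PoolAlleleCounts
from .stats import empirical_quantile


def call_quantile_outliers(table: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Flag windows in BOTH the top-q F_ST tail and bottom-q log2-ratio tail.

    Thresholds are genome-wide type-7 quantiles over windows with at least
    one SNP; ties at the threshold are included. ``q=0.05`` populates
    ``flag_top5``, ``q=0.01`` populates ``flag_top1``; other q values return
    the flag as a separate column ``flag_q``.
    """
    out = table.copy()
    ranked = out["n_snps"] >= 1
    if ranked.sum() == 0:
        flag = pd.Series(False, index=out.index)
    else:
        fst = out.loc[ranked, "fst"]
        ratio = out.loc[ranked, "log2_ratio"]
        fst_thr = empirical_quantile(fst.to_numpy(), 1.0 - q)
        ratio_thr = empirical_quantile(ratio.to_numpy(), q)
        flag = pd.Series(False, index=out.index)
        flag.loc[ranked] = (fst >= fst_thr) & (ratio <= ratio_thr)
    if q == 0.05:
        out["flag_top5"] = flag
    elif q == 0.01:
        out["flag_top1"] = flag
    else:
        out["flag_q"] = flag
    return out


def standardize_frequencies(
    counts: PoolAlleleCounts,
) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale each SNP's across-pool alt frequencies to mean 0, sd 1.

    Returns (standardized (n_kept, n_pools) matrix, boolean keep mask over
    the input SNPs); SNPs with zero across-pool variance are dropped from
    association scoring.
    """
    if counts.n_pools < 2:
        raise ValueError("standardization needs at least 2 pools")
    f = counts.alt_freqs
    mean = np.nanmean(f, axis=1, keepdims=True)
    sd = np.nanstd(f, axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    std = np.where(keep[:, None], (f - mean) / np.where(keep[:, None], sd, 1.0), np.nan)
    return std[keep], keep


def _pseudo_bf(r2: np.ndarray, n: int) -> np.ndarray:
    """exp(delta-BIC / 2) for the slope-vs-intercept linear model comparison.

    delta-BIC = n * ln(RSS0 / RSS1) - ln(n) = -n * ln(1 - R^2) - ln(n);
    equals 1/sqrt(n) (< 1) when R^2 = 0.
    """
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    dbic = -n * np.log1p(-r2) - np.log(n)
    return np.exp(dbic / 2.0)


def salinity_association(
    counts: PoolAlleleCounts,
    mode: str = "surrogate",
    bf_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP salinity-association scores.

    ``mode="import"`` passes through externally computed Bayes factors
    (columns chrom, pos, bf). ``mode="surrogate"`` scores each SNP by the
    Pearson correlation r between standardized across-pool allele frequency
    and standardized salinity, with a pseudo-Bayes factor from the BIC model
    comparison; requires at least 4 pools. Returns a DataFrame with columns
    chrom, pos, bf, r (NaN for imports), source.
    """
    if mode == "import":
        if bf_table is None:
            raise ValueError("import mode requires a bf_table")
        out = bf_table[["chrom", "pos", "bf"]].copy()
        out["r"] = np.nan
        out["source"] = "imported"
        return out
    if mode != "surrogate":
        raise ValueError(f"unknown association mode {mode!r}")
    if counts.n_pools < 4:
        raise ValueError("surrogate association needs at least 4 pools")
    std, keep = standardize_frequencies(counts)
    sal = counts.salinities()
    sal_sd = sal.std(ddof=1)
    if sal_sd == 0:
        raise ValueError("salinity covariate is constant across pools")
    sal_std = (sal - sal.mean()) / sal_sd
    n = counts.n_pools
    # Pearson r between standardized vectors: mean of products * n/(n-1)
    r = std @ sal_std / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    bf = _pseudo_bf(r**2, n)
    out = counts.sites.loc[keep, ["chrom", "pos"]].reset_index(drop=True)
    out["bf"] = bf
    out["r"] = r
    out["source"] = "surrogate"
    return out


def call_bf_outliers(
    table: pd.DataFrame,
    scores: pd.DataFrame,
    bf_threshold: float = 10.0,
) -> pd.DataFrame:
    """Set ``flag_bf`` on windows that are top-5% outliers AND contain at
    least one SNP with BF strictly above ``bf_threshold``."""
    out = table.copy()
    hits = scores.loc[scores["bf"] > bf_threshold, ["chrom", "pos"]]
    flag = np.zeros(len(out), dtype=bool)
    for chrom, grp in hits.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        sel = (out["chrom"] == chrom).to_numpy()
        lo = np.searchsorted(pos, out.loc[sel, "start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, out.loc[sel, "end"].to_numpy(), side="left")
        flag[sel] = hi > lo
    out["flag_bf"] = flag & out["flag_top5"].to_numpy()
    return out
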