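"""Composite linkage disequilibrium, distance-binned decay profiles, and the
fusion-region vs background paired comparison.

LD between two SNPs is the squared Pearson correlation of diploid dosage
vectors (Rogers-Huff composite LD), which needs no phasing and is the
natural choice for small panels of unphased individuals. Profiles average
r^2 at exact integer base-pair distances; the paired regional test compares
two profiles at shared distances only, with df = (#shared distances) - 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import TestResult
from .stats import paired_t

MIN_DIST = 20
MAX_DIST = 300_000


def pairwise_r2(
    genotypes: np.ndarray,
    positions: np.ndarray,
    max_dist: int = MAX_DIST,
    min_dist: int = MIN_DIST,
    min_complete: int = 4,
) -> pd.DataFrame:
    """Composite r^2 for all SNP pairs within [min_dist, max_dist].

    ``genotypes`` is an (individuals x SNPs) dosage matrix in {0, 1, 2} with
    NaN for missing calls; ``positions`` are base-pair coordinates on one
    chromosome, sorted ascending. Pairs with fewer than ``min_complete``
    pairwise-complete individuals, or zero dosage variance at either SNP
    over those individuals, are skipped. Returns a DataFrame with columns
    i, j (SNP indices), dist, r2.
    """
    g = np.asarray(genotypes, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    if g.ndim != 2 or g.shape[1] != len(pos):
        raise ValueError("genotypes must be (individuals x SNPs)")
    if not (np.diff(pos) >= 0).all():
        raise ValueError("positions must be sorted ascending")
    n_snps = g.shape[1]
    has_missing = np.isnan(g).any()

    out_i, out_j, out_d, out_r2 = [], [], [], []
    if not has_missing:
        # complete data: center once, use vectorized dot products per anchor
        gc = g - g.mean(axis=0)
        ss = (gc**2).sum(axis=0)
        for i in range(n_snps):
            j_hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            j_lo = np.searchsorted(pos, pos[i] + min_dist, side="left")
            if j_lo >= j_hi:
                continue
            cols = np.arange(j_lo, j_hi)
            if ss[i] == 0:
                continue
            cov = gc[:, i] @ gc[:, cols]
            valid = ss[cols] > 0
            r2 = np.zeros(len(cols))
            r2[valid] = (cov[valid] ** 2) / (ss[i] * ss[cols][valid])
            keep = valid & (g.shape[0] >= min_complete)
            out_i.extend([i] * int(keep.sum()))
            out_j.extend(cols[keep].tolist())
            out_d.extend((pos[cols[keep]] - pos[i]).tolist())
            out_r2.extend(r2[keep].tolist())
    else:
        for i in range(n_snps):
            j_hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            j_lo = np.searchsorted(pos, pos[i] + min_dist, side="left")
            for j in range(j_lo, j_hi):
                both = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
                if both.sum() < min_complete:
                    continue
                x, y = g[both, i], g[both, j]
                vx, vy = x.var(), y.var()
                if vx == 0 or vy == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                out_i.append(i)
                out_j.append(j)
                out_d.append(int(pos[j] - pos[i]))
                out_r2.append(float(r * r))
    return pd.DataFrame(
        {"i": np.array(out_i, dtype=np.int64),
         "j": np.array(out_j, dtype=np.int64),
         "dist": np.array(out_d, dtype=np.int64),
         "r2": np.array(out_r2, dtype=float)}
    )


def ld_profile(
    pairs: pd.DataFrame,
    positions: np.ndarray | None = None,
    region_mask: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Mean r^2 per exact integer distance.

    With a ``region_mask`` (list of half-open (start, end) intervals), only
    pairs whose *both* SNP positions fall inside the mask are kept;
    ``positions`` must then be supplied to resolve SNP indices. Distances
    with zero pairs are absent from the output. Returns columns dist,
    mean_r2, n_pairs.
    """
    sel = pairs
    if region_mask is not None:
        if positions is None:
            raise ValueError("region_mask requires positions")
        pos = np.asarray(positions, dtype=np.int64)
        in_mask = np.zeros(len(pos), dtype=bool)
        for start, end in region_mask:
            in_mask |= (pos >= start) & (pos < end)
        keep = in_mask[pairs["i"].to_numpy()] & in_mask[pairs["j"].to_numpy()]
        sel = pairs.loc[keep]
    if len(sel) == 0:
        return pd.DataFrame({"dist": pd.Series(dtype=np.int64),
                             "mean_r2": pd.Series(dtype=float),
                             "n_pairs": pd.Series(dtype=np.int64)})
    grp = sel.groupby("dist")["r2"]
    out = grp.mean().rename("mean_r2").reset_index()
    out["n_pairs"] = grp.size().to_numpy()
    return out


def paired_region_test(profile_a: pd.DataFrame, profile_b: pd.DataFrame
                       ) -> TestResult:
    """Paired t-test of mean r^2 at distances shared by both profiles.

    df equals the number of shared distances minus one, exactly.
    """
    merged = profile_a.merge(profile_b, on="dist", suffixes=("_a", "_b"))
    if len(merged) < 2:
        raise ValueError("paired_region_test needs >= 2 shared distances")
    return paired_t(merged["mean_r2_a"].to_numpy(),
                    merged["mean_r2_b"].to_numpy())
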