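import numpy as np
import pandas as pd
import pytest

from fusescan.core import FusionSite, GenomeLayout, Pool, PoolAlleleCounts


@pytest.fixture
def layout():
    """Two 5 Mb chromosomes, two fusion sites each (first is the centromere)."""
    return GenomeLayout(
        chromosomes=[("chr1", 5_000_000), ("chr2", 5_000_000)],
        fusion_sites=[
            FusionSite("chr1", 1_500_000, "Chr1#1", True),
            FusionSite("chr1", 3_500_000, "Chr1#2", False),
            FusionSite("chr2", 1_500_000, "Chr2#1", True),
            FusionSite("chr2", 3_500_000, "Chr2#2", False),
        ],
    )


@pytest.fixture
def pools():
    return [
        Pool("nat1", "native_saline", 25.0),
        Pool("nat2", "native_saline", 30.0),
        Pool("inv1", "invasive_freshwater", 0.2),
        Pool("inv2", "invasive_freshwater", 0.5),
    ]


def make_counts(pools, chrom="chr1", positions=(100, 200, 300),
                ref=None, alt=None):
    """Small PoolAlleleCounts with explicit count matrices."""
    n = len(positions)
    k = len(pools)
    if ref is None:
        ref = np.full((n, k), 20)
    if alt is None:
        alt = np.full((n, k), 10)
    sites = pd.DataFrame({"chrom": chrom, "pos": np.array(positions)})
    return PoolAlleleCounts(sites, np.asarray(ref), np.asarray(alt), pools)


def flag_table(chrom_lengths, flagged_mids, window=10_000, step=5_000):
    """Window table with flag_top5 set on windows whose midpoint is listed.

    ``flagged_mids`` maps chromosome name -> set of flagged window midpoints.
    """
    rows = []
    for chrom, length in chrom_lengths:
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        mids = (starts + ends) // 2
        flags = np.isin(mids, list(flagged_mids.get(chrom, [])))
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_snps": 5, "fst": 0.1, "pi_native": 0.01, "pi_invasive": 0.01,
            "log2_ratio": 0.0, "flag_top5": flags, "flag_top1": False,
            "flag_bf": False,
        }))
    return pd.concat(rows, ignore_index=True)


def random_flag_table(chrom_lengths, density, rng, window=10_000, step=5_000):
    """Window table with flag_top5 drawn i.i.d. Bernoulli(density)."""
    rows = []
    for chrom, length in chrom_lengths:
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        flags = rng.random(len(starts)) < density
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_snps": 5, "fst": 0.1, "pi_native": 0.01, "pi_invasive": 0.01,
            "log2_ratio": 0.0, "flag_top5": flags, "flag_top1": False,
            "flag_bf": False,
        }))
    return pd.concat(rows, ignore_index=True)
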