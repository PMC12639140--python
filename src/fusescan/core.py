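"""Shared domain types for the fusion-site selection-signature pipeline.

All coordinates are 0-based, half-open throughout the package. BED input is
native; GFF3 is converted on read. Strand is ignored everywhere: allele
counts and gene positions are strand-free in this analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HABITAT_CLASSES = ("native_saline", "invasive_freshwater")

#: Column order of the window table, shared by the scanner, the outlier
#: caller and the TSV reader/writer.
WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps", "fst",
    "pi_native", "pi_invasive", "log2_ratio",
    "flag_top5", "flag_top1", "flag_bf",
]


class ValidationError(ValueError):
    """Raised when an input record violates a coordinate or count invariant."""


@dataclass(frozen=True)
class FusionSite:
    chrom: str
    position: int
    label: str
    is_centromere: bool = False


@dataclass
class GenomeLayout:
    """Chromosome lengths plus fusion-site (and centromere) coordinates.

    Fusion sites are point coordinates (the junction of two ancestral
    chromosomes); centromeres are fusion sites carrying ``is_centromere``.
    """

    chromosomes: list[tuple[str, int]]
    fusion_sites: list[FusionSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")
        lengths = dict(self.chromosomes)
        labels = [s.label for s in self.fusion_sites]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate fusion-site labels in layout")
        for site in self.fusion_sites:
            if site.chrom not in lengths:
                raise ValidationError(
                    f"fusion site {site.label!r} on unknown chromosome {site.chrom!r}"
                )
            if not 0 <= site.position < lengths[site.chrom]:
                raise ValidationError(
                    f"fusion site {site.label!r} at {site.chrom}:{site.position} "
                    f"outside [0, {lengths[site.chrom]})"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def sites_on(self, chrom: str) -> list[FusionSite]:
        return [s for s in self.fusion_sites if s.chrom == chrom]


@dataclass(frozen=True)
class Pool:
    """One pooled population sample."""

    name: str
    habitat_class: str  # native_saline | invasive_freshwater
    salinity: float  # PSU at time of collection

    def __post_init__(self) -> None:
        if self.habitat_class not in HABITAT_CLASSES:
            raise ValidationError(
                f"pool {self.name!r}: unknown habitat class {self.habitat_class!r}"
            )


@dataclass
class PoolAlleleCounts:
    """Per-SNP, per-pool biallelic read counts from pooled sequencing.

    ``ref_counts`` and ``alt_counts`` are (n_snps, n_pools) integer arrays;
    ``sites`` is a DataFrame with columns chrom, pos (0-based).
    """

    sites: pd.DataFrame
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    pools: list[Pool]

    def __post_init__(self) -> None:
        n = len(self.sites)
        k = len(self.pools)
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if self.ref_counts.shape != (n, k) or self.alt_counts.shape != (n, k):
            raise ValidationError(
                f"count matrices must be ({n}, {k}); got "
                f"{self.ref_counts.shape} and {self.alt_counts.shape}"
            )
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValidationError("negative allele counts")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValidationError(
                    f"positions not strictly increasing on {chrom!r}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def depths(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    @property
    def alt_freqs(self) -> np.ndarray:
        """Alt-allele frequency per SNP per pool (NaN where depth is 0)."""
        d = self.depths
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.alt_counts / np.maximum(d, 1), np.nan)

    def class_indices(self, habitat_class: str) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.pools) if p.habitat_class == habitat_class],
            dtype=int,
        )

    def salinities(self) -> np.ndarray:
        return np.array([p.salinity for p in self.pools], dtype=float)

    def take(self, mask: np.ndarray) -> "PoolAlleleCounts":
        """Row subset preserving pool metadata."""
        return PoolAlleleCounts(
            sites=self.sites.loc[mask].reset_index(drop=True),
            ref_counts=self.ref_counts[mask],
            alt_counts=self.alt_counts[mask],
            pools=self.pools,
        )


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    set_label: str = "other"  # selected25 | family36 | ion253 | other

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"gene {self.gene_id!r}: start must be < end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test (t, U, KS D, CM T, paired t)."""

    statistic: float
    p: float
    method: str
    df: float | None = None
    alternative: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "df": None if self.df is None else float(self.df),
            "p": float(self.p),
            "alternative": self.alternative,
            "method": self.method,
        }


def empty_window_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "n_snps": pd.Series(dtype=np.int64),
            "fst": pd.Series(dtype=float),
            "pi_native": pd.Series(dtype=float),
            "pi_invasive": pd.Series(dtype=float),
            "log2_ratio": pd.Series(dtype=float),
            "flag_top5": pd.Series(dtype=bool),
            "flag_top1": pd.Series(dtype=bool),
            "flag_bf": pd.Series(dtype=bool),
        }
    )
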