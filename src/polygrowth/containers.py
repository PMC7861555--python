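"""Core in-memory containers shared across the pipeline.

Genotypes are biallelic SNP dosage codes for inbred lines: 0/1/2 copies of
the alternate allele, with ``-1`` marking a missing call.  Selfing lines are
effectively haploid, so codes are normally 0 or 2; heterozygous calls (1)
are tolerated everywhere and counted as allele frequency 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with a physical marker map.

    Attributes
    ----------
    codes
        ``(n_lines, n_markers)`` int8 array with values in {0, 1, 2, -1}.
    chrom, pos
        Marker map; positions are 1-based bp, sorted within chromosome.
    line_ids
        Accession identifiers, one per row.
    regions
        Optional region label per line (e.g. ``"Spain"``).
    """

    codes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    line_ids: np.ndarray
    regions: np.ndarray | None = None
    marker_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.line_ids = np.asarray(self.line_ids)
        if self.regions is not None:
            self.regions = np.asarray(self.regions)
        if self.marker_ids is None:
            self.marker_ids = np.array(
                [f"{c}_{p}" for c, p in zip(self.chrom, self.pos)]
            )
        else:
            self.marker_ids = np.asarray(self.marker_ids)
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        if self.codes.shape != (len(self.line_ids), len(self.pos)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.pos)} markers"
            )

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing calls."""
        codes = self.codes.astype(float)
        codes[self.missing_mask()] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(codes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def dosage_imputed(self) -> np.ndarray:
        """Float dosage matrix with missing calls mean-imputed per marker."""
        out = self.codes.astype(float)
        miss = self.missing_mask()
        out[miss] = np.nan
        col_mean = np.nanmean(np.where(miss, np.nan, out), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(miss)
        out[idx] = col_mean[idx[1]]
        return out

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            codes=self.codes[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            marker_ids=self.marker_ids[index],
        )

    def take_lines(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            codes=self.codes[index, :],
            line_ids=self.line_ids[index],
            regions=None if self.regions is None else self.regions[index],
        )

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "chrom": self.chrom, "pos": self.pos}
        )


@dataclass
class DiameterSeries:
    """One plant's rosette-diameter time course with its design covariates."""

    plant_id: str
    genotype_id: str
    regime: str  # "HL" or "LL"
    block: int
    tray: int
    row: int
    col: int
    days: np.ndarray
    diameters: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if len(self.days) != len(self.diameters):
            raise ValueError("days and diameters must be the same length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.diameters < 0):
            raise ValueError("diameters must be non-negative")


@dataclass
class GrowthParameters:
    """Three-parameter logistic fit: d(t) = fs / (1 + exp(-slope*(t - t50)))."""

    fs: float
    slope: float
    t50: float
    sse: float = np.nan
    n_points: int = 0
    converged: bool = True

    @property
    def inflection_slope(self) -> float:
        """Derivative of the curve at t50 (cm/day): slope * fs / 4."""
        return self.slope * self.fs / 4.0


def check_regions(regions: Sequence, min_per_region: int = 2) -> np.ndarray:
    regions = np.asarray(regions)
    labels, counts = np.unique(regions, return_counts=True)
    if len(labels) < 2:
        raise ValueError("at least two regions are required")
    if counts.min() < min_per_region:
        raise ValueError(
            f"every region needs >= {min_per_region} members; "
            f"got {dict(zip(labels, counts))}"
        )
    return regions
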