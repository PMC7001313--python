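"""Droplet digital PCR quantification of the K27M variant allele frequency.

A duplexed ddPCR well reads every droplet on two fluorescence channels: FAM
(mutant probe) and HEX (wild-type probe).  Droplets are gated by fixed
amplitude thresholds into four quadrants; the VAF is the ratio of
FAM-single-positive droplets to all single-positive droplets.  Assay
linearity is checked on a dilution series of mutant/wild-type plasmid
mixtures by ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DropletCounts",
    "DropletWell",
    "DilutionSeries",
    "classify_droplets",
    "vaf_from_counts",
    "poisson_corrected_vaf",
    "linearity",
    "DEFAULT_FAM_THRESHOLD",
    "DEFAULT_HEX_THRESHOLD",
]

# Fixed gating thresholds on the two fluorescence channels.
DEFAULT_FAM_THRESHOLD = 2400.0
DEFAULT_HEX_THRESHOLD = 1700.0


@dataclass(frozen=True)
class DropletCounts:
    """Quadrant counts of a gated well."""

    fam_only: int
    hex_only: int
    double_pos: int
    double_neg: int

    def __post_init__(self) -> None:
        for name in ("fam_only", "hex_only", "double_pos", "double_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.fam_only + self.hex_only + self.double_pos + self.double_neg


@dataclass
class DropletWell:
    """One well: raw amplitudes and/or gated counts plus the thresholds."""

    counts: DropletCounts
    fam_threshold: float = DEFAULT_FAM_THRESHOLD
    hex_threshold: float = DEFAULT_HEX_THRESHOLD
    amplitudes: np.ndarray | None = None  # shape (n, 2): fam, hex


@dataclass(frozen=True)
class DilutionSeries:
    """Expected/measured VAF pairs from a plasmid mixture series."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("a dilution series needs at least 3 points")
        expected = [e for e, _ in self.points]
        if len(set(expected)) != len(expected):
            raise ValueError("expected VAF values must be distinct")


def classify_droplets(
    amplitudes: Iterable[Sequence[float]] | np.ndarray,
    fam_threshold: float = DEFAULT_FAM_THRESHOLD,
    hex_threshold: float = DEFAULT_HEX_THRESHOLD,
) -> DropletCounts:
    """Gate droplets into quadrants by strict per-channel thresholds.

    A droplet is positive on a channel when its amplitude strictly exceeds
    the threshold (droplets sitting exactly on a threshold are negative).
    """
    amps = np.asarray(list(amplitudes) if not isinstance(amplitudes, np.ndarray) else amplitudes, dtype=float)
    if amps.size == 0:
        raise ValueError("no droplets to classify")
    if amps.ndim != 2 or amps.shape[1] != 2:
        raise ValueError("amplitudes must be (n, 2): fam, hex per droplet")
    if not np.isfinite(amps).all():
        raise ValueError("non-finite droplet amplitude")
    fam_pos = amps[:, 0] > fam_threshold
    hex_pos = amps[:, 1] > hex_threshold
    return DropletCounts(
        fam_only=int(np.sum(fam_pos & ~hex_pos)),
        hex_only=int(np.sum(~fam_pos & hex_pos)),
        double_pos=int(np.sum(fam_pos & hex_pos)),
        double_neg=int(np.sum(~fam_pos & ~hex_pos)),
    )


def vaf_from_counts(counts: DropletCounts) -> float:
    """VAF = FAM-single-positive / (FAM-single-positive + HEX-single-positive).

    Double-positive droplets contain both templates and are excluded from
    the ratio; double-negative droplets are empty.
    """
    informative = counts.fam_only + counts.hex_only
    if informative == 0:
        raise ValueError("no informative (single-positive) droplets")
    return counts.fam_only / informative


def poisson_corrected_vaf(counts: DropletCounts) -> float:
    """Occupancy-corrected VAF from per-channel negative fractions.

    Estimates mean template molecules per droplet on each channel as
    ``-ln(negative fraction)`` and ratios the concentrations.  Not the
    default estimator (the raw dot ratio is), but removes the small bias
    the dot ratio acquires at high droplet occupancy.
    """
    total = counts.total
    if total == 0:
        raise ValueError("empty well")
    fam_neg = (counts.hex_only + counts.double_neg) / total
    hex_neg = (counts.fam_only + counts.double_neg) / total
    if fam_neg <= 0 or hex_neg <= 0:
        raise ValueError("a channel is saturated; occupancy correction undefined")
    lam_mut = -math.log(fam_neg)
    lam_wild = -math.log(hex_neg)
    if lam_mut + lam_wild == 0:
        raise ValueError("no template detected on either channel")
    return lam_mut / (lam_mut + lam_wild)


def linearity(series: DilutionSeries) -> tuple[float, float, float]:
    """OLS of measured on expected VAF: returns (slope, intercept, r_squared)."""
    expected = np.array([e for e, _ in series.points], dtype=float)
    measured = np.array([m for _, m in series.points], dtype=float)
    if np.ptp(expected) == 0:
        raise ValueError("degenerate series: expected VAF has no variance")
    if np.ptp(measured) == 0:
        raise ValueError("degenerate series: measured VAF is constant")
    fit = stats.linregress(expected, measured)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
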