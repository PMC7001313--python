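"""Purity-mixture allelic models for mutant allele specific imbalance (MASI).

A tumor specimen is modeled as a two-component mixture: a single tumor clone
carrying an :class:`AllelicConfiguration` at the locus of interest (here the
*H3F3A* K27M site on 1q), and admixed normal cells that contribute two
wild-type copies, one per parental haplotype.  Under a tumor-cell fraction
(purity) ``p`` the expected variant allele frequency (VAF) of the somatic
mutation and the expected major-allele B-allele frequency (BAF) of germline
heterozygous SNPs on the same segment have the closed forms

    VAF(p) = p*M / (p*N + 2*(1 - p))
    BAF(p) = (p*a + (1 - p)) / (p*N + 2*(1 - p))

where ``N`` is the tumor total copy number, ``M`` the number of copies
carrying the mutation and ``a`` the copy number of the major haplotype.
Inverting the VAF relation yields a purity back-calculation used to validate
a selected configuration against an orthogonal purity estimate (IHC).

Model selection follows a two-stage screen: candidate total copy numbers are
enumerated from the WGS segment mean, all haplotype splits and mutation
phasings are generated, the configurations whose expected BAF best matches
the observed mirrored-BAF upper band are shortlisted, and among those the
configuration whose expected VAF best matches the ddPCR VAF is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "MutantPhase",
    "AllelicConfiguration",
    "PurityEstimate",
    "Observations",
    "ModelFit",
    "InfeasibleModelError",
    "expected_vaf",
    "expected_major_baf",
    "purity_from_vaf",
    "enumerate_total_cn_candidates",
    "enumerate_configs",
    "select_model",
    "validate_purity",
    "to_percent",
]

#: Copies of the locus contributed by each admixed normal cell (diploid,
#: one wild-type copy per haplotype).
NORMAL_COPIES = 2


class MutantPhase(str, Enum):
    """Which parental haplotype carries the somatic mutation."""

    MAJOR = "major"
    MINOR = "minor"


class InfeasibleModelError(ValueError):
    """No purity in [0, 1] can produce the observed VAF under the model."""


@dataclass(frozen=True, order=True)
class AllelicConfiguration:
    """Tumor-clone genotype at a locus.

    ``major_copies`` and ``minor_copies`` are the copy numbers of the two
    parental haplotypes (major >= minor); ``mutant_on`` phases the somatic
    mutation onto one haplotype.  All copies of that haplotype are assumed
    to carry the mutation (a single mutational event before the copy-number
    change), so ``mutant_copies`` is the full haplotype copy number.
    """

    total_cn: int
    major_copies: int
    minor_copies: int
    mutant_on: MutantPhase = MutantPhase.MAJOR

    def __post_init__(self) -> None:
        if self.total_cn < 1:
            raise ValueError(f"total_cn must be >= 1, got {self.total_cn}")
        if self.minor_copies < 0 or self.major_copies < self.minor_copies:
            raise ValueError(
                f"need major_copies >= minor_copies >= 0, got "
                f"{self.major_copies}:{self.minor_copies}"
            )
        if self.major_copies + self.minor_copies != self.total_cn:
            raise ValueError("haplotype copies must sum to total_cn")
        if self.mutant_copies == 0:
            raise ValueError("mutation must reside on a retained haplotype")

    @property
    def mutant_copies(self) -> int:
        if self.mutant_on is MutantPhase.MAJOR:
            return self.major_copies
        return self.minor_copies

    @property
    def wild_copies(self) -> int:
        return self.total_cn - self.mutant_copies

    @property
    def is_masi(self) -> bool:
        """Mutant allele specific imbalance: mutant gained and/or wild lost."""
        return self.mutant_copies > self.wild_copies or self.wild_copies == 0

    def label(self) -> str:
        return (
            f"{self.mutant_copies} mutant / {self.wild_copies} wild-type "
            f"(total {self.total_cn}, split {self.major_copies}:"
            f"{self.minor_copies}, mutant on {self.mutant_on.value})"
        )


@dataclass(frozen=True)
class PurityEstimate:
    """Tumor-cell fraction with the measurement it came from."""

    fraction: float
    source: str = "ihc_counts"  # "ihc_counts" | "vaf_backcalc"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"purity must be in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class Observations:
    """Per-case observations feeding model selection.

    ``observed_vaf`` comes from ddPCR, ``observed_baf_upper`` is the median
    of the mirrored-BAF upper band over the locus segment, ``mean_segment_cn``
    the WGS segment mean copy number (may be None when candidate totals are
    supplied directly), and ``tumor_content`` the IHC purity.
    """

    observed_vaf: float
    observed_baf_upper: float
    tumor_content: PurityEstimate
    mean_segment_cn: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.observed_vaf <= 1.0:
            raise ValueError("observed_vaf must be in [0, 1]")
        if not 0.5 <= self.observed_baf_upper <= 1.0:
            raise ValueError("observed_baf_upper must be in [0.5, 1]")
        if self.mean_segment_cn is not None and self.mean_segment_cn <= 0:
            raise ValueError("mean_segment_cn must be > 0")


@dataclass
class ModelFit:
    """One candidate configuration scored against the observations."""

    config: AllelicConfiguration
    expected_baf: float
    expected_vaf: float
    baf_distance: float
    vaf_distance: float
    baf_shortlisted: bool = False
    selected: bool = False
    backcalc_purity: PurityEstimate | None = None


def to_percent(fraction: float, ndigits: int = 1) -> float:
    """Fraction -> percent, rounded half-up to ``ndigits`` decimals.

    Reports are compared at one-decimal percent precision; round-half-up
    (not banker's rounding) matches conventional manual rounding.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(fraction * 100.0)).quantize(quantum, rounding=ROUND_HALF_UP))


def _denominator(purity: float, total_cn: int) -> float:
    return purity * total_cn + NORMAL_COPIES * (1.0 - purity)


def expected_vaf(purity: float, config: AllelicConfiguration) -> float:
    """Expected bulk VAF of the somatic mutation at tumor fraction ``purity``.

    v = p*M / (p*N + 2*(1-p)): mutant copies come only from tumor cells,
    normal cells dilute with two wild-type copies.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    return purity * config.mutant_copies / _denominator(purity, config.total_cn)


def expected_major_baf(purity: float, config: AllelicConfiguration) -> float:
    """Expected major-haplotype allele frequency of a germline het SNP.

    B = (p*a + (1-p)) / (p*N + 2*(1-p)): normal cells contribute one copy of
    each haplotype.  Equals 0.5 for balanced splits at any purity.  The SNP
    is assumed to sit on the same segment as the mutation, so its haplotype
    copy numbers are those of the configuration.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    return (purity * config.major_copies + (1.0 - purity)) / _denominator(
        purity, config.total_cn
    )


def purity_from_vaf(vaf: float, config: AllelicConfiguration) -> PurityEstimate:
    """Back-calculate tumor purity from an observed VAF under ``config``.

    Algebraic inverse of :func:`expected_vaf`:

        p = 2*v / (M + 2*v - v*N)

    Raises :class:`InfeasibleModelError` when no purity in (0, 1] yields the
    observed VAF — i.e. the configuration cannot explain the measurement.
    """
    if not 0.0 < vaf < 1.0:
        raise ValueError(f"vaf must be in (0, 1), got {vaf}")
    m = config.mutant_copies
    n = config.total_cn
    denom = m + 2.0 * vaf - vaf * n
    if denom <= 0.0:
        raise InfeasibleModelError(
            f"{config.label()} cannot produce VAF {vaf:.4f} at any purity"
        )
    p = 2.0 * vaf / denom
    if p > 1.0 + 1e-12:
        raise InfeasibleModelError(
            f"{config.label()} would require purity {p:.4f} > 1 at VAF {vaf:.4f}"
        )
    return PurityEstimate(fraction=min(p, 1.0), source="vaf_backcalc")


def enumerate_total_cn_candidates(mean_segment_cn: float) -> set[int]:
    """Candidate integral total copy numbers from a WGS segment mean.

    The first candidate is the integer nearest the segment mean; the second
    is one step further from two (one more copy when the mean exceeds two,
    one fewer when below), because admixed diploid normal cells pull the
    apparent copy number of an altered segment toward two.  A mean of
    exactly two yields {2, 3}; exact halves round away from two; candidates
    below one are dropped (a mean far below one still proposes {1}).
    """
    if not math.isfinite(mean_segment_cn) or mean_segment_cn <= 0:
        raise ValueError(f"mean_segment_cn must be finite and > 0, got {mean_segment_cn}")
    floor = math.floor(mean_segment_cn)
    frac = mean_segment_cn - floor
    if frac == 0.5:
        nearest = floor + 1 if mean_segment_cn > 2 else floor
    elif frac > 0.5:
        nearest = floor + 1
    else:
        nearest = floor
    if mean_segment_cn > 2:
        cands = {nearest, nearest + 1}
    elif mean_segment_cn < 2:
        cands = {nearest, nearest - 1}
    else:
        cands = {2, 3}
    cands = {c for c in cands if c >= 1}
    return cands or {1}


def enumerate_configs(total_cns: Iterable[int]) -> list[AllelicConfiguration]:
    """All valid allelic configurations for the given total copy numbers.

    For each N, every haplotype split (a, b) with a >= b >= 0 and a + b = N,
    crossed with the mutation phased on either haplotype.  Configurations
    without a mutant copy are excluded (the mutation is present in the
    tumor); for balanced splits the two phasings are indistinguishable and
    only the major-phased one is kept.
    """
    configs: list[AllelicConfiguration] = []
    for n in sorted(set(total_cns)):
        if n < 1:
            raise ValueError(f"total copy number must be >= 1, got {n}")
        for major in range(n, (n + 1) // 2 - 1, -1):
            minor = n - major
            for phase in (MutantPhase.MAJOR, MutantPhase.MINOR):
                if phase is MutantPhase.MINOR and (minor == major or minor == 0):
                    continue
                configs.append(
                    AllelicConfiguration(
                        total_cn=n, major_copies=major, minor_copies=minor, mutant_on=phase
                    )
                )
    return configs


def _config_sort_key(config: AllelicConfiguration) -> tuple[int, int]:
    # Tie-break convention: parsimony first (smaller total), then the more
    # imbalanced explanation (larger mutant copy number).
    return (config.total_cn, -config.mutant_copies)


def select_model(
    obs: Observations,
    configs: Sequence[AllelicConfiguration],
    shortlist_size: int = 2,
) -> list[ModelFit]:
    """Two-stage selection of the most appropriate allelic configuration.

    Stage 1 (BAF screen): every configuration is scored at the IHC tumor
    content; the ``shortlist_size`` *distinct* expected-BAF values closest
    to the observed mirrored-BAF upper band are shortlisted.  Mutation
    phasings of one split share a BAF value and advance together, competing
    only at stage 2.

    Stage 2 (VAF decision): among shortlisted configurations, the one whose
    expected VAF is closest to the ddPCR VAF is selected and its purity
    back-calculated from the observed VAF.

    Returns every scored :class:`ModelFit`, selected model first, the rest
    ordered by BAF distance.  Raises if ``configs`` is empty or no
    shortlisted configuration can produce the observed VAF at any purity.
    """
    if not configs:
        raise ValueError("no candidate configurations supplied")
    p = obs.tumor_content.fraction
    fits = []
    for config in configs:
        e_baf = expected_major_baf(p, config)
        e_vaf = expected_vaf(p, config)
        fits.append(
            ModelFit(
                config=config,
                expected_baf=e_baf,
                expected_vaf=e_vaf,
                baf_distance=abs(e_baf - obs.observed_baf_upper),
                vaf_distance=abs(e_vaf - obs.observed_vaf),
            )
        )

    # Stage 1: shortlist on distinct BAF values.
    groups: dict[float, list[ModelFit]] = {}
    for fit in fits:
        groups.setdefault(round(fit.expected_baf, 9), []).append(fit)
    ordered_groups = sorted(
        groups.values(),
        key=lambda grp: (
            grp[0].baf_distance,
            min(_config_sort_key(f.config) for f in grp),
        ),
    )
    for grp in ordered_groups[:shortlist_size]:
        for fit in grp:
            fit.baf_shortlisted = True

    shortlisted = [f for f in fits if f.baf_shortlisted]
    if not shortlisted:
        raise ValueError("empty shortlist")

    def _feasible(fit: ModelFit) -> bool:
        try:
            purity_from_vaf(obs.observed_vaf, fit.config)
        except InfeasibleModelError:
            return False
        return True

    if not any(_feasible(f) for f in shortlisted):
        raise InfeasibleModelError(
            "no shortlisted configuration can produce the observed VAF "
            f"{obs.observed_vaf:.4f} at any purity"
        )

    # Stage 2: decide on VAF distance.
    winner = min(
        shortlisted, key=lambda f: (f.vaf_distance, _config_sort_key(f.config))
    )
    winner.selected = True
    try:
        winner.backcalc_purity = purity_from_vaf(obs.observed_vaf, winner.config)
    except InfeasibleModelError:
        winner.backcalc_purity = None

    fits.sort(
        key=lambda f: (
            not f.selected,
            f.baf_distance,
            f.vaf_distance,
            _config_sort_key(f.config),
        )
    )
    return fits


def validate_purity(
    fit: ModelFit, ihc_purity: PurityEstimate, tolerance: float = 0.05
) -> bool:
    """Does the back-calculated purity agree with the IHC purity?

    Absolute comparison on the [0, 1] scale.  The default tolerance 0.05
    accommodates the counting error of IHC-based purity at typical field
    sizes.
    """
    if fit.backcalc_purity is None:
        raise ValueError("model fit has no back-calculated purity")
    return abs(fit.backcalc_purity.fraction - ihc_purity.fraction) <= tolerance
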