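"""Synthetic case and cohort generation with known ground truth.

Emulates the statistical structure of every measured input so the whole
pipeline can be exercised and validated without patient data:

* binned WGS depth: gamma-Poisson (negative-binomial) counts around
  ``genome mean x mixed copy number / 2`` at 33x mean coverage;
* heterozygous common-SNP allele counts: binomial at the purity-mixed
  major-haplotype frequency, with a random phase per SNP (~1 het SNP per
  1.5 kb);
* ddPCR droplets: Poisson template loading per droplet and channel at the
  mixture VAF, read out as quadrant counts (and optionally as two-channel
  amplitudes in well-separated clusters);
* IHC fields: binomial cell counts at the true purity and marker levels,
  log-normal per-cell intensity ratios.

Each synthetic genome is a single chromosome (default 50 Mb in 10-kb bins)
carrying one altered segment that contains the mutation locus; the rest is
diploid-balanced.  All draws come from one seeded generator, so a bundle is
reproducible from its truth record alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .models import (
    AllelicConfiguration,
    MutantPhase,
    expected_major_baf,
    expected_vaf,
)

__all__ = [
    "SyntheticTruth",
    "CaseBundle",
    "simulate_well",
    "simulate_case",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic case."""

    config: AllelicConfiguration
    purity: float
    seed: int
    # genome layout
    chrom: str = "chr1"
    genome_length: int = 50_000_000
    bin_width: int = 10_000
    event_start: int = 25_000_000
    event_end: int = 35_000_000
    locus_pos: int = 30_000_000
    # sequencing
    mean_coverage: float = 33.0
    depth_dispersion: float = 0.1
    snp_spacing: int = 1_500
    # ddPCR
    n_droplets: int = 20_000
    droplet_occupancy: float = 0.25
    # IHC
    n_fields: int = 4
    cells_per_field: int = 1_000
    ki67: float = 0.3
    h3k27me3: float = 0.3
    rel_intensity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if not (0 <= self.event_start < self.event_end <= self.genome_length):
            raise ValueError("event interval must lie inside the genome")
        if not (self.event_start < self.locus_pos <= self.event_end):
            raise ValueError("locus must lie inside the altered segment")

    @property
    def true_vaf(self) -> float:
        return expected_vaf(self.purity, self.config)

    @property
    def true_baf_upper(self) -> float:
        return expected_major_baf(self.purity, self.config)

    def manifest(self) -> dict:
        d = asdict(self)
        d["config"]["mutant_on"] = self.config.mutant_on.value
        d["true_vaf"] = self.true_vaf
        d["true_baf_upper"] = self.true_baf_upper
        return d


@dataclass
class CaseBundle:
    """The flat-file views of one simulated case, as in-memory tables."""

    truth: SyntheticTruth
    coverage: pd.DataFrame  # chrom, start, depth
    snps: pd.DataFrame  # chrom, pos, ref_count, alt_count, pop_af
    droplet_counts: pd.DataFrame  # fam_only, hex_only, double_pos, double_neg
    amplitudes: pd.DataFrame  # fam, hex per droplet
    ihc_fields: pd.DataFrame  # field_id + marker counts
    ihc_cells: pd.DataFrame  # field_id, cell_id, k27m_intensity, h4_intensity


def _mixed_cn(truth: SyntheticTruth, starts: np.ndarray) -> np.ndarray:
    """Bulk copy number per bin: tumor CN in the event, 2 elsewhere, purity-mixed."""
    tumor_cn = np.full(starts.shape, 2.0)
    in_event = (starts >= truth.event_start) & (starts < truth.event_end)
    tumor_cn[in_event] = truth.config.total_cn
    return truth.purity * tumor_cn + 2.0 * (1.0 - truth.purity)


def _simulate_coverage(truth: SyntheticTruth, rng: np.random.Generator) -> pd.DataFrame:
    starts = np.arange(0, truth.genome_length, truth.bin_width)
    mean_depth = truth.mean_coverage * _mixed_cn(truth, starts) / 2.0
    if truth.depth_dispersion > 0:
        # gamma-Poisson: var = m + d * m^2
        shape = 1.0 / truth.depth_dispersion
        lam = rng.gamma(shape, mean_depth / shape)
    else:
        lam = mean_depth
    depth = rng.poisson(lam).astype(float)
    return pd.DataFrame({"chrom": truth.chrom, "start": starts, "depth": depth})


def _simulate_snps(truth: SyntheticTruth, rng: np.random.Generator) -> pd.DataFrame:
    n_snps = truth.genome_length // truth.snp_spacing
    pos = np.unique(rng.integers(0, truth.genome_length, size=n_snps)) + 1
    n_snps = pos.size
    in_event = (pos - 1 >= truth.event_start) & (pos - 1 < truth.event_end)
    major_baf = np.where(in_event, truth.true_baf_upper, 0.5)
    # random phase: the alt allele sits on the major haplotype for half the SNPs
    alt_freq = np.where(rng.random(n_snps) < 0.5, major_baf, 1.0 - major_baf)
    local_cn = _mixed_cn(truth, pos - 1)
    depth = rng.poisson(truth.mean_coverage * local_cn / 2.0)
    keep = depth > 0
    alt = rng.binomial(depth[keep], alt_freq[keep])
    pop_af = rng.uniform(0.05, 0.5, size=int(keep.sum()))
    return pd.DataFrame(
        {
            "chrom": truth.chrom,
            "pos": pos[keep],
            "ref_count": depth[keep] - alt,
            "alt_count": alt,
            "pop_af": pop_af,
        }
    )


# Amplitude cluster means/SDs per channel: (negative, positive).
_FAM_CLUSTERS = ((1000.0, 200.0), (4500.0, 300.0))
_HEX_CLUSTERS = ((800.0, 150.0), (3200.0, 250.0))


def simulate_well(
    vaf: float,
    n_droplets: int = 20_000,
    occupancy: float = 0.25,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One ddPCR well at molecular VAF ``vaf`` under Poisson template loading.

    Each droplet receives Poisson(occupancy * vaf) mutant and
    Poisson(occupancy * (1 - vaf)) wild-type templates; a channel is
    positive when at least one template of its kind is present.  Returns
    (quadrant-count table with one row, per-droplet amplitude table) with
    amplitudes drawn from well-separated positive/negative clusters around
    the default gating thresholds.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mut = rng.poisson(occupancy * vaf, size=n_droplets)
    wild = rng.poisson(occupancy * (1.0 - vaf), size=n_droplets)
    fam_pos = mut > 0
    hex_pos = wild > 0
    counts = pd.DataFrame(
        {
            "fam_only": [int(np.sum(fam_pos & ~hex_pos))],
            "hex_only": [int(np.sum(~fam_pos & hex_pos))],
            "double_pos": [int(np.sum(fam_pos & hex_pos))],
            "double_neg": [int(np.sum(~fam_pos & ~hex_pos))],
        }
    )
    fam_amp = np.where(
        fam_pos,
        rng.normal(*_FAM_CLUSTERS[1], size=n_droplets),
        rng.normal(*_FAM_CLUSTERS[0], size=n_droplets),
    )
    hex_amp = np.where(
        hex_pos,
        rng.normal(*_HEX_CLUSTERS[1], size=n_droplets),
        rng.normal(*_HEX_CLUSTERS[0], size=n_droplets),
    )
    amplitudes = pd.DataFrame({"fam": fam_amp, "hex": hex_amp})
    return counts, amplitudes


def _simulate_droplets(
    truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    return simulate_well(
        truth.true_vaf,
        n_droplets=truth.n_droplets,
        occupancy=truth.droplet_occupancy,
        rng=rng,
    )


def _simulate_ihc(
    truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    cell_rows = []
    for f in range(truth.n_fields):
        dapi = truth.cells_per_field
        k27m = int(rng.binomial(dapi, truth.purity))
        ki67 = int(rng.binomial(k27m, truth.ki67)) if k27m else 0
        h4 = dapi  # H4 stains all nucleated cells
        me3 = int(rng.binomial(h4, truth.h3k27me3))
        rows.append(
            {
                "field_id": f,
                "k27m_pos": k27m,
                "dapi_pos": dapi,
                "ki67_pos": ki67,
                "h3k27me3_pos": me3,
                "h4_pos": h4,
            }
        )
        n_cells = min(k27m, 50)  # intensities measured on a subset of tumor cells
        h4_int = rng.lognormal(np.log(100.0), 0.2, size=n_cells)
        # per-cell ratio log-normal around the true median ratio
        ratio = truth.rel_intensity * rng.lognormal(0.0, 0.15, size=n_cells)
        for c in range(n_cells):
            cell_rows.append(
                {
                    "field_id": f,
                    "cell_id": c,
                    "k27m_intensity": ratio[c] * h4_int[c],
                    "h4_intensity": h4_int[c],
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(cell_rows)


def simulate_case(truth: SyntheticTruth) -> CaseBundle:
    """Draw one complete synthetic case from its truth record."""
    rng = np.random.default_rng(truth.seed)
    coverage = _simulate_coverage(truth, rng)
    snps = _simulate_snps(truth, rng)
    counts, amplitudes = _simulate_droplets(truth, rng)
    fields, cells = _simulate_ihc(truth, rng)
    return CaseBundle(
        truth=truth,
        coverage=coverage,
        snps=snps,
        droplet_counts=counts,
        amplitudes=amplitudes,
        ihc_fields=fields,
        ihc_cells=cells,
    )


# Imbalanced configurations a MASI case may carry (gain of the mutant
# haplotype and/or loss of the wild-type one), drawn uniformly.
_MASI_CONFIGS = (
    AllelicConfiguration(3, 3, 0, MutantPhase.MAJOR),
    AllelicConfiguration(2, 2, 0, MutantPhase.MAJOR),
    AllelicConfiguration(1, 1, 0, MutantPhase.MAJOR),
    AllelicConfiguration(3, 2, 1, MutantPhase.MAJOR),
)
_HET_CONFIG = AllelicConfiguration(2, 1, 1, MutantPhase.MAJOR)


def simulate_cohort(
    n_cases: int = 15,
    masi_fraction: float = 4 / 15,
    hazard_ratio: float = 3.5,
    median_survival_lower: float = 18.0,
    marker_shift: float = 1.0,
    follow_up: float = 60.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate a cohort of case records with survival and marker levels.

    MASI cases carry an imbalanced allelic configuration (so their true VAF
    exceeds 0.5 at realistic purity); the rest are heterozygous diploid.
    Survival is exponential, with the MASI hazard ``hazard_ratio`` times the
    lower-VAF hazard (median ``median_survival_lower`` months), censored
    administratively at ``follow_up`` months.  ``marker_shift`` scales the
    group difference in Ki-67 and relative K27M intensity (0 = null).

    Returns (cohort table, truth manifests).  Times are in months; the VAF
    column holds the ddPCR-measured value on the fraction scale.
    """
    if n_cases < 2:
        raise ValueError("a cohort needs at least 2 cases")
    rng = np.random.default_rng(seed)
    n_masi = int(round(masi_fraction * n_cases))
    rows = []
    manifests = []
    lam_lower = np.log(2.0) / median_survival_lower
    for i in range(n_cases):
        is_masi = i < n_masi
        if is_masi:
            config = _MASI_CONFIGS[rng.integers(len(_MASI_CONFIGS))]
            # above 0.7 even the mildest imbalance (2:1) yields VAF > 0.5
            purity = rng.uniform(0.7, 0.99)
            ki67 = 0.30 + 0.15 * marker_shift
            rel_int = 1.0 + 0.8 * marker_shift
            me3 = max(0.05, 0.30 - 0.15 * marker_shift)
        else:
            config = _HET_CONFIG
            purity = rng.uniform(0.4, 0.95)
            ki67, rel_int, me3 = 0.30, 1.0, 0.30
        truth = SyntheticTruth(
            config=config,
            purity=purity,
            seed=int(rng.integers(2**31)),
            ki67=ki67,
            rel_intensity=rel_int,
            h3k27me3=me3,
        )
        case_rng = np.random.default_rng(truth.seed)
        # ddPCR measurement of the VAF: Poisson loading, raw dot ratio
        lam = truth.droplet_occupancy
        v = truth.true_vaf
        mut = case_rng.poisson(lam * v, size=truth.n_droplets)
        wild = case_rng.poisson(lam * (1 - v), size=truth.n_droplets)
        fam_only = int(np.sum((mut > 0) & (wild == 0)))
        hex_only = int(np.sum((mut == 0) & (wild > 0)))
        vaf = fam_only / max(fam_only + hex_only, 1)
        hazard = lam_lower * (hazard_ratio if is_masi else 1.0)
        t_event = case_rng.exponential(1.0 / hazard)
        os_months = min(t_event, follow_up)
        os_event = int(t_event <= follow_up)
        t_prog = case_rng.exponential(1.0 / (hazard * 1.5))
        pfs_months = min(t_prog, follow_up)
        pfs_event = int(t_prog <= follow_up)
        ki67_obs = case_rng.binomial(400, truth.ki67) / 400
        me3_obs = case_rng.binomial(400, truth.h3k27me3) / 400
        int_obs = float(
            np.median(truth.rel_intensity * case_rng.lognormal(0, 0.15, size=100))
        )
        rows.append(
            {
                "case_id": i + 1,
                "vaf": vaf,
                "masi_confirmed": config.is_masi,
                "ki67": ki67_obs,
                "h3k27me3": me3_obs,
                "rel_intensity": int_obs,
                "os_months": os_months,
                "os_event": os_event,
                "pfs_months": pfs_months,
                "pfs_event": pfs_event,
            }
        )
        manifests.append(truth.manifest())
    return pd.DataFrame(rows), manifests
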