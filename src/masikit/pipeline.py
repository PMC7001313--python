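"""End-to-end orchestration: per-case model selection and cohort statistics.

A :class:`RunConfig` carries every tunable parameter; reports embed the
serialized configuration and seed so a run can be reproduced exactly.
Stages are composable — a case can enter at the raw-table level (droplet
amplitudes, binned coverage, SNP counts, IHC fields) or directly at the
observation level (VAF, upper-band BAF, tumor content, candidate totals).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ddpcr, ihc, wgs
from .io import fits_to_frame
from .models import (
    Observations,
    PurityEstimate,
    enumerate_configs,
    enumerate_total_cn_candidates,
    select_model,
    to_percent,
    validate_purity,
)

__all__ = ["RunConfig", "run_case", "run_cohort"]

logger = logging.getLogger("masikit")


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults."""

    fam_threshold: float = ddpcr.DEFAULT_FAM_THRESHOLD
    hex_threshold: float = ddpcr.DEFAULT_HEX_THRESHOLD
    locus_chrom: str = "chr1"
    locus_pos: int = 30_000_000
    bin_width: int = 10_000
    baf_window: int = 3
    baf_band_quantile: float = 0.9
    min_pop_af: float = 0.05
    cbs_alpha: float = 0.01
    cbs_min_width: int = 3
    cbs_n_perm: int = 1000
    shortlist_size: int = 2
    vaf_cutoff: float = 0.5
    validation_tolerance: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _derive_observations(
    config: RunConfig,
    coverage: pd.DataFrame | None,
    snps: pd.DataFrame | None,
    amplitudes: pd.DataFrame | None,
    droplet_counts: pd.DataFrame | None,
    ihc_fields: pd.DataFrame | None,
) -> Observations:
    if amplitudes is not None:
        counts = ddpcr.classify_droplets(
            amplitudes[["fam", "hex"]].to_numpy(),
            fam_threshold=config.fam_threshold,
            hex_threshold=config.hex_threshold,
        )
    elif droplet_counts is not None:
        row = droplet_counts.iloc[0]
        counts = ddpcr.DropletCounts(
            fam_only=int(row["fam_only"]),
            hex_only=int(row["hex_only"]),
            double_pos=int(row["double_pos"]),
            double_neg=int(row["double_neg"]),
        )
    else:
        raise ValueError("need droplet amplitudes or counts to measure the VAF")
    vaf = ddpcr.vaf_from_counts(counts)
    logger.info("ddPCR VAF %.4f from %d informative droplets",
                vaf, counts.fam_only + counts.hex_only)

    if coverage is None or snps is None:
        raise ValueError("need binned coverage and SNP counts for the WGS signals")
    cn = wgs.cn_ratio(coverage)
    segments = wgs.segment_cn(
        cn,
        alpha=config.cbs_alpha,
        min_width=config.cbs_min_width,
        n_perm=config.cbs_n_perm,
        seed=config.seed,
    )
    baf = wgs.baf_track(
        snps,
        bin_width=config.bin_width,
        window=config.baf_window,
        min_pop_af=config.min_pop_af,
    )
    mean_cn, baf_upper = wgs.locus_observation(
        segments, baf, config.locus_chrom, config.locus_pos,
        band_quantile=config.baf_band_quantile,
    )
    logger.info("locus segment: mean CN %.3f, upper-band BAF %.4f", mean_cn, baf_upper)

    if ihc_fields is None:
        raise ValueError("need IHC field counts for the tumor content")
    purity = ihc.tumor_content(ihc_fields)
    logger.info("IHC tumor content %.4f", purity.fraction)
    return Observations(
        observed_vaf=vaf,
        observed_baf_upper=baf_upper,
        tumor_content=purity,
        mean_segment_cn=mean_cn,
    )


def run_case(
    config: RunConfig,
    observations: Observations | None = None,
    candidate_totals: list[int] | None = None,
    coverage: pd.DataFrame | None = None,
    snps: pd.DataFrame | None = None,
    amplitudes: pd.DataFrame | None = None,
    droplet_counts: pd.DataFrame | None = None,
    ihc_fields: pd.DataFrame | None = None,
    case_id: str = "case",
) -> dict:
    """Select the most appropriate allelic configuration for one case.

    Either pass ``observations`` (optionally with explicit
    ``candidate_totals``) or the raw tables the observations are derived
    from.  Returns a JSON-serializable report with every scored model.
    """
    if observations is None:
        observations = _derive_observations(
            config, coverage, snps, amplitudes, droplet_counts, ihc_fields
        )
    if candidate_totals is None:
        if observations.mean_segment_cn is None:
            raise ValueError("need candidate totals or a mean segment copy number")
        candidate_totals = sorted(
            enumerate_total_cn_candidates(observations.mean_segment_cn)
        )
    logger.info("candidate total copy numbers: %s", candidate_totals)
    configs = enumerate_configs(candidate_totals)
    fits = select_model(observations, configs, shortlist_size=config.shortlist_size)
    selected = fits[0]
    validated = None
    if selected.backcalc_purity is not None:
        validated = validate_purity(
            selected, observations.tumor_content, config.validation_tolerance
        )
    logger.info(
        "selected %s; back-calculated purity %s; validated=%s",
        selected.config.label(),
        "absent" if selected.backcalc_purity is None
        else f"{selected.backcalc_purity.fraction:.4f}",
        validated,
    )
    table = fits_to_frame(fits, tolerance_validated=validated)
    return {
        "case_id": case_id,
        "config_digest": config.digest(),
        "seed": config.seed,
        "observations": {
            "vaf_pct": to_percent(observations.observed_vaf),
            "baf_upper_pct": to_percent(observations.observed_baf_upper),
            "tumor_content_pct": to_percent(observations.tumor_content.fraction),
            "mean_segment_cn": observations.mean_segment_cn,
            "candidate_totals": candidate_totals,
        },
        "selected": {
            "label": selected.config.label(),
            "total_cn": selected.config.total_cn,
            "major": selected.config.major_copies,
            "minor": selected.config.minor_copies,
            "mutant_on": selected.config.mutant_on.value,
            "mutant_copies": selected.config.mutant_copies,
            "wild_copies": selected.config.wild_copies,
            "is_masi": selected.config.is_masi,
            "expected_baf_pct": to_percent(selected.expected_baf),
            "expected_vaf_pct": to_percent(selected.expected_vaf),
            "backcalc_purity_pct": (
                to_percent(selected.backcalc_purity.fraction)
                if selected.backcalc_purity is not None
                else None
            ),
            "validated": validated,
        },
        "models": table.to_dict(orient="records"),
    }


def run_cohort(config: RunConfig, cases: pd.DataFrame) -> dict:
    """Group a cohort by the VAF cutoff and compare markers and survival.

    Marker columns (ki67, h3k27me3, rel_intensity) and survival columns
    (os_months/os_event, pfs_months/pfs_event) are each optional; the
    report contains whichever comparisons the table supports.
    """
    from . import cohort as cohort_stats

    if len(cases) < 2:
        raise ValueError("a cohort needs at least 2 cases")
    grouped, counts = cohort_stats.classify_masi(cases, vaf_cutoff=config.vaf_cutoff)
    high = grouped[grouped["vaf_group"] == "high"]
    lower = grouped[grouped["vaf_group"] == "lower"]
    report: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_cases": len(cases),
        "vaf_cutoff": config.vaf_cutoff,
        "counts": counts,
    }
    markers = {}
    for col in ("ki67", "h3k27me3", "rel_intensity"):
        if col in grouped.columns:
            a = high[col].dropna()
            b = lower[col].dropna()
            if len(a) and len(b):
                stat, p = cohort_stats.compare_groups(a, b)
                markers[col] = {
                    "statistic": stat,
                    "p_value": p,
                    "p_value_2dp": round(p, 2),
                    "n_high": len(a),
                    "n_lower": len(b),
                }
    report["markers"] = markers
    survival = {}
    for endpoint in ("os", "pfs"):
        tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
        if tcol in grouped.columns and ecol in grouped.columns:
            if len(high) and len(lower):
                curves, chi2, p = cohort_stats.km_logrank(
                    high[tcol], high[ecol], lower[tcol], lower[ecol]
                )
                survival[endpoint] = {
                    "chi_square": chi2,
                    "p_value": p,
                    "p_value_2dp": round(p, 2),
                }
    report["survival"] = survival
    return report
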