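"""Flat-file dialects and packaged fixtures.

All tables are plain TSV/CSV (coverage: chrom/start/depth; SNPs:
chrom/pos/ref_count/alt_count/pop_af; droplet amplitudes: fam,hex per row;
IHC fields and cells; cohort records).  Two fixtures ship with the package:
the published per-case VAF/intensity table of the 15-case cohort, and the
observation sets of the four high-VAF cases that were worked through the
structure-model selection.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .models import ModelFit, Observations, PurityEstimate, to_percent

__all__ = [
    "read_coverage",
    "read_snps",
    "read_snps_vcf",
    "read_amplitudes",
    "read_droplet_counts",
    "read_ihc_fields",
    "read_ihc_cells",
    "read_cohort",
    "read_observations",
    "fits_to_frame",
    "load_cohort_table",
    "load_printed_cases",
]


def read_coverage(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_snps(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_snps_vcf(path: str | Path, af_tag: str = "AF") -> pd.DataFrame:
    """Optional VCF ingestion: map records with AD genotype fields to SNP rows.

    Requires pysam (not a hard dependency).  The first sample's allelic
    depths supply ref/alt counts; the INFO ``af_tag`` supplies the
    population allele frequency (0 when absent).
    """
    import pysam  # local import: optional dependency

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                continue
            sample = rec.samples[list(rec.samples)[0]]
            ad = sample.get("AD")
            if ad is None or len(ad) < 2:
                continue
            af = rec.info.get(af_tag, 0.0)
            if isinstance(af, (tuple, list)):
                af = af[0] if af else 0.0
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref_count": int(ad[0]),
                    "alt_count": int(ad[1]),
                    "pop_af": float(af or 0.0),
                }
            )
    return pd.DataFrame(rows)


def read_amplitudes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)  # CSV: fam,hex per droplet (reader-export-like)


def read_droplet_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ihc_fields(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ihc_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_observations(path: str | Path) -> tuple[Observations, list[int] | None]:
    """One case's observations from a JSON block (fractions throughout).

    Keys: vaf, baf_upper, tumor_content, and either mean_cn or
    candidate_totals.  Returns (observations, candidate totals or None).
    """
    payload = json.loads(Path(path).read_text())
    return _observations_from_dict(payload)


def _observations_from_dict(d: dict) -> tuple[Observations, list[int] | None]:
    obs = Observations(
        observed_vaf=float(d["vaf"]),
        observed_baf_upper=float(d["baf_upper"]),
        tumor_content=PurityEstimate(float(d["tumor_content"]), source="ihc_counts"),
        mean_segment_cn=float(d["mean_cn"]) if d.get("mean_cn") is not None else None,
    )
    totals = d.get("candidate_totals")
    return obs, [int(t) for t in totals] if totals is not None else None


def fits_to_frame(fits: list[ModelFit], tolerance_validated: bool | None = None) -> pd.DataFrame:
    """Scored model list as a report table (percent columns at one decimal)."""
    rows = []
    for fit in fits:
        c = fit.config
        rows.append(
            {
                "total_cn": c.total_cn,
                "major": c.major_copies,
                "minor": c.minor_copies,
                "mutant_on": c.mutant_on.value,
                "mutant_copies": c.mutant_copies,
                "wild_copies": c.wild_copies,
                "expected_baf_pct": to_percent(fit.expected_baf),
                "expected_vaf_pct": to_percent(fit.expected_vaf),
                "baf_dist": round(fit.baf_distance, 6),
                "vaf_dist": round(fit.vaf_distance, 6),
                "shortlisted": fit.baf_shortlisted,
                "selected": fit.selected,
                "backcalc_purity_pct": (
                    to_percent(fit.backcalc_purity.fraction)
                    if fit.backcalc_purity is not None
                    else None
                ),
            }
        )
    frame = pd.DataFrame(rows)
    if tolerance_validated is not None:
        frame["validated"] = frame["selected"] & tolerance_validated
    return frame


def load_cohort_table() -> pd.DataFrame:
    """The published 15-case cohort: VAF (%) and relative K27M intensity.

    Adds a ``vaf`` column on the fraction scale for the grouping rule.
    """
    with resources.files("masikit.data").joinpath("cohort_table.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    table["vaf"] = table["vaf_percent"] / 100.0
    return table


def load_printed_cases() -> dict[str, tuple[Observations, list[int] | None]]:
    """Observation sets of the four worked high-VAF cases, keyed by case id."""
    with resources.files("masikit.data").joinpath("printed_cases.json").open() as fh:
        payload = json.load(fh)
    return {case_id: _observations_from_dict(d) for case_id, d in payload.items()}
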