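"""Locus-level observations from whole-genome and targeted sequencing tables.

Inputs are flat tables, not alignments: 10-kb binned read depths, per-SNP
allele counts with population allele frequencies, and annotated variant
tables.  This module turns them into the quantities the allelic model
consumes: a segmented copy-number profile, a mirrored B-allele-frequency
track, and the (mean segment CN, upper-band BAF) pair at the mutation locus.

Coordinates: coverage bins and segments are 0-based half-open; SNP positions
are 1-based (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "cn_ratio",
    "segment_cn",
    "baf_track",
    "locus_observation",
    "filter_variants",
    "SEX_CHROMS",
]

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def cn_ratio(
    bins: pd.DataFrame,
    diploid_scale: bool = True,
    exclude_chroms: frozenset[str] = SEX_CHROMS,
) -> pd.DataFrame:
    """Per-bin copy number from binned depth relative to the genome mean.

    The genome mean is computed over autosomal bins only.  With
    ``diploid_scale`` the ratio is doubled so a typical bin reads ~2 copies.
    Zero-depth bins yield ratio 0 and are flagged in a ``zero_depth`` column
    rather than dropped.
    """
    required = {"chrom", "start", "depth"}
    if not required.issubset(bins.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    autosomal = ~bins["chrom"].isin(exclude_chroms)
    mean_depth = bins.loc[autosomal, "depth"].mean()
    if not mean_depth > 0:
        raise ValueError("genome-wide mean depth is zero")
    out = bins.copy()
    scale = 2.0 if diploid_scale else 1.0
    out["cn"] = out["depth"] / mean_depth * scale
    out["zero_depth"] = out["depth"] == 0
    return out


def _max_abs_t(values: np.ndarray, min_width: int) -> tuple[int, float] | None:
    """Best split of 1-D ``values`` by the two-sample pooled t statistic.

    Returns (left size, |t|) of the maximizing split, or None when the
    series is too short to split with ``min_width`` bins on both sides.
    """
    n = values.shape[-1]
    if n < 2 * min_width:
        return None
    x = np.atleast_2d(values)
    cs = np.cumsum(x, axis=1)
    css = np.cumsum(x * x, axis=1)
    k = np.arange(min_width, n - min_width + 1)
    left_sum = cs[:, k - 1]
    right_sum = cs[:, -1:] - left_sum
    left_n = k
    right_n = n - k
    left_mean = left_sum / left_n
    right_mean = right_sum / right_n
    ss_left = css[:, k - 1] - left_sum**2 / left_n
    ss_right = (css[:, -1:] - css[:, k - 1]) - right_sum**2 / right_n
    pooled = (ss_left + ss_right) / max(n - 2, 1)
    se = np.sqrt(np.maximum(pooled, 1e-300) * (1.0 / left_n + 1.0 / right_n))
    t = np.abs((left_mean - right_mean) / se)
    if values.ndim == 1:
        idx = int(np.argmax(t[0]))
        return int(k[idx]), float(t[0, idx])
    return t  # type: ignore[return-value]  # (B, len(k)) matrix for callers that batch


def _split_is_significant(
    values: np.ndarray,
    observed_t: float,
    min_width: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation test: does any split beat the observed |t| often?

    Permutations run in chunks with early stopping: once enough exceedances
    have accumulated that the final p-value cannot fall below ``alpha``, the
    split is rejected without drawing the remaining permutations.
    """
    n = values.shape[0]
    reject_at = alpha * (n_perm + 1) - 1  # count that pins p >= alpha
    exceed = 0
    done = 0
    chunk = max(min(n_perm, 100_000 // max(n, 1), 200), 10)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(values, (b, n)), axis=1)
        t_matrix = _max_abs_t(perms, min_width)
        exceed += int(np.sum(np.max(t_matrix, axis=1) >= observed_t))
        done += b
        if exceed >= reject_at:
            return False
    p = (1 + exceed) / (n_perm + 1)
    return p < alpha


def _segment_one(
    values: np.ndarray,
    min_width: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> list[int]:
    """Recursive binary segmentation; returns sorted internal breakpoints."""
    best = _max_abs_t(values, min_width)
    if best is None:
        return []
    split, t_obs = best
    if not _split_is_significant(values, t_obs, min_width, alpha, n_perm, rng):
        return []
    left = _segment_one(values[:split], min_width, alpha, n_perm, rng)
    right = _segment_one(values[split:], min_width, alpha, n_perm, rng)
    return left + [split] + [split + b for b in right]


def segment_cn(
    bins: pd.DataFrame,
    alpha: float = 0.01,
    min_width: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment the per-bin copy-number signal into constant-mean pieces.

    Recursive binary splitting on the two-sample t statistic; a split is
    accepted when its permutation p-value falls below ``alpha``.  Bins are
    processed per chromosome in positional order; the output partitions the
    input and per-segment means are recomputed from member bins.

    Returns a BED-like frame: chrom, start, end, mean_cn, n_bins.
    """
    required = {"chrom", "start", "cn"}
    if not required.issubset(bins.columns):
        raise ValueError(f"binned CN table needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    bin_width = None
    for chrom, grp in bins.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        values = grp["cn"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        if len(values) < min_width:
            raise ValueError(
                f"{chrom}: {len(values)} bins < min segment width {min_width}"
            )
        if bin_width is None:
            bin_width = int(np.diff(starts).min()) if len(starts) > 1 else 1
        breaks = [0] + _segment_one(values, min_width, alpha, n_perm, rng) + [len(values)]
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[lo]),
                    "end": int(starts[hi - 1]) + bin_width,
                    "mean_cn": float(values[lo:hi].mean()),
                    "n_bins": hi - lo,
                }
            )
    return pd.DataFrame(rows)


def baf_track(
    snps: pd.DataFrame,
    bin_width: int = 10_000,
    window: int = 3,
    min_pop_af: float = 0.05,
) -> pd.DataFrame:
    """Mirrored B-allele-frequency track from per-SNP allele counts.

    Common SNPs (population allele frequency strictly above ``min_pop_af``)
    are assigned to ``bin_width`` regions; the per-region mismatch ratio
    alt/(ref+alt) is summarized by its median, smoothed by a centered moving
    average over ``window`` sequential occupied regions (truncated at track
    ends), and mirrored about 0.5 into upper and lower bands.

    Because each SNP's mismatch ratio reflects an arbitrary phase (the
    alternate allele sits on either haplotype), regions mixing phases pull
    the unfolded medians toward 0.5 and the mirrored bands with them.  The
    frame therefore also carries a ``band`` column — the same median/moving
    average chain applied to per-SNP ratios folded about 0.5 — which is the
    phase-free estimate of the major-haplotype frequency used when a band
    level must be read off numerically.

    Returns a frame: chrom, start, median, moving_avg, upper, lower, band.
    """
    required = {"chrom", "pos", "ref_count", "alt_count", "pop_af"}
    if not required.issubset(snps.columns):
        raise ValueError(f"SNP table needs columns {sorted(required)}")
    common = snps[snps["pop_af"] > min_pop_af].copy()
    if common.empty:
        raise ValueError("no SNPs pass the population-frequency filter")
    depth = common["ref_count"] + common["alt_count"]
    if (depth <= 0).any():
        raise ValueError("SNP with zero allele counts")
    common["ratio"] = common["alt_count"] / depth
    common["folded"] = np.maximum(common["ratio"], 1.0 - common["ratio"])
    common["start"] = (common["pos"] - 1) // bin_width * bin_width
    rows = []
    for chrom, grp in common.groupby("chrom", sort=False):
        medians = grp.groupby("start")["ratio"].median().sort_index()
        folded = grp.groupby("start")["folded"].median().sort_index()
        if len(medians) < window:
            raise ValueError(
                f"{chrom}: {len(medians)} occupied regions < window {window}"
            )
        moving = medians.rolling(window, center=True, min_periods=1).mean()
        band = folded.rolling(window, center=True, min_periods=1).mean()
        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "start": medians.index.to_numpy(),
                "median": medians.to_numpy(),
                "moving_avg": moving.to_numpy(),
                "band": band.to_numpy(),
            }
        )
        rows.append(frame)
    out = pd.concat(rows, ignore_index=True)
    out["upper"] = np.maximum(out["moving_avg"], 1.0 - out["moving_avg"])
    out["lower"] = 1.0 - out["upper"]
    return out[["chrom", "start", "median", "moving_avg", "upper", "lower", "band"]]


def locus_observation(
    segments: pd.DataFrame,
    baf: pd.DataFrame,
    chrom: str,
    pos: int,
    band_quantile: float = 0.9,
) -> tuple[float, float]:
    """(mean segment CN, upper-band BAF) at a 1-based locus position.

    The locus must fall inside exactly one segment.  The band level is read
    from the phase-free ``band`` column of the BAF track (falling back to
    the mirrored ``upper`` column for tracks that lack it) as a high
    quantile (default 0.9) over the segment rather than the median: an
    allelic imbalance confined to part of a long copy-neutral segment would
    otherwise be averaged away by the segment's balanced remainder.
    """
    hit = segments[
        (segments["chrom"] == chrom)
        & (segments["start"] <= pos - 1)
        & (segments["end"] > pos - 1)
    ]
    if len(hit) == 0:
        raise ValueError(f"locus {chrom}:{pos} not covered by any segment")
    if len(hit) > 1:
        raise ValueError(f"locus {chrom}:{pos} covered by {len(hit)} segments")
    seg = hit.iloc[0]
    in_seg = baf[
        (baf["chrom"] == chrom)
        & (baf["start"] >= seg["start"])
        & (baf["start"] < seg["end"])
    ]
    if in_seg.empty:
        raise ValueError(f"no BAF regions inside the locus segment {chrom}:{pos}")
    column = "band" if "band" in in_seg.columns else "upper"
    return float(seg["mean_cn"]), float(in_seg[column].quantile(band_quantile))


EXCLUDED_EFFECTS = frozenset({"synonymous", "unknown"})


def filter_variants(
    variants: pd.DataFrame,
    pop_af_columns: Sequence[str] | None = None,
    min_variant_reads: int = 10,
    min_vaf: float = 0.05,
    common_af: float = 0.01,
) -> pd.DataFrame:
    """Adopt variants from an annotated targeted-capture table.

    Keeps variants with variant reads strictly above ``min_variant_reads``
    and VAF at least ``min_vaf``; then excludes synonymous / ambiguously
    annotated ("unknown") calls and common polymorphisms — population
    allele frequency of at least ``common_af`` in any annotation database
    column, or dbSNP membership.  Missing annotation values count as zero.
    """
    required = {"variant_reads", "vaf", "effect"}
    if not required.issubset(variants.columns):
        raise ValueError(f"variant table needs columns {sorted(required)}")
    if pop_af_columns is None:
        pop_af_columns = [
            c for c in variants.columns if c.endswith("_af") and c != "vaf"
        ]
    keep = (variants["variant_reads"] > min_variant_reads) & (
        variants["vaf"] >= min_vaf
    )
    out = variants[keep].copy()
    effect = out["effect"].str.lower()
    out = out[~effect.isin(EXCLUDED_EFFECTS)]
    if pop_af_columns:
        afs = out[list(pop_af_columns)].fillna(0.0)
        out = out[~(afs >= common_af).any(axis=1)]
    if "dbsnp_member" in out.columns:
        out = out[~out["dbsnp_member"].fillna(False).astype(bool)]
    return out.reset_index(drop=True)
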