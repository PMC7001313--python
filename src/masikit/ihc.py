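"""Immunofluorescence-derived quantities from per-field cell counts.

Four microscope fields are counted per case.  Tumor content is the fraction
of H3 K27M-positive nuclei among DAPI-positive nuclei; the Ki-67 index is
Ki-67-positive over K27M-positive cells; the H3K27me3 fraction is
H3K27me3-positive over histone-H4-positive cells.  The relative H3 K27M
intensity is the per-tumor-cell ratio of K27M to H4 fluorescence,
median-aggregated within and then across fields.

Count fractions are averaged across fields (mean); intensity ratios use the
median, which is how the per-case intensity is tabulated.  Both aggregations
are configurable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import PurityEstimate

__all__ = [
    "tumor_content",
    "ki67_fraction",
    "h3k27me3_fraction",
    "relative_k27m_intensity",
    "EXPECTED_FIELDS",
]

EXPECTED_FIELDS = 4


def _check_fields(fields: pd.DataFrame, columns: set[str]) -> None:
    if not columns.issubset(fields.columns):
        raise ValueError(f"field table needs columns {sorted(columns)}")
    if len(fields) != EXPECTED_FIELDS:
        warnings.warn(
            f"expected {EXPECTED_FIELDS} fields per case, got {len(fields)}",
            stacklevel=3,
        )


def _count_fraction(
    fields: pd.DataFrame, numerator: str, denominator: str, agg: str
) -> float:
    _check_fields(fields, {numerator, denominator})
    den = fields[denominator]
    if (den <= 0).any():
        raise ValueError(f"zero {denominator} count in a field")
    num = fields[numerator]
    if (num > den).any():
        raise ValueError(f"{numerator} exceeds {denominator} in a field")
    ratios = num / den
    return float(ratios.agg(agg))


def tumor_content(fields: pd.DataFrame, agg: str = "mean") -> PurityEstimate:
    """Tumor purity: K27M-positive / DAPI-positive nuclei, per field, aggregated."""
    frac = _count_fraction(fields, "k27m_pos", "dapi_pos", agg)
    return PurityEstimate(fraction=frac, source="ihc_counts")


def ki67_fraction(fields: pd.DataFrame, agg: str = "mean") -> float:
    """Proliferation index: Ki-67-positive / K27M-positive cells."""
    return _count_fraction(fields, "ki67_pos", "k27m_pos", agg)


def h3k27me3_fraction(fields: pd.DataFrame, agg: str = "mean") -> float:
    """H3K27me3-positive / histone-H4-positive cells."""
    return _count_fraction(fields, "h3k27me3_pos", "h4_pos", agg)


def relative_k27m_intensity(cells: pd.DataFrame, agg: str = "median") -> float:
    """Per-tumor-cell K27M / H4 fluorescence ratio, aggregated per field then across.

    ``cells`` has one row per tumor cell: field_id, k27m_intensity,
    h4_intensity.  H4 is the denominator (internal loading control) and must
    be positive in every used cell.  The ratio is invariant under a joint
    rescaling of both channels.
    """
    required = {"field_id", "k27m_intensity", "h4_intensity"}
    if not required.issubset(cells.columns):
        raise ValueError(f"cell table needs columns {sorted(required)}")
    if cells.empty:
        raise ValueError("no tumor cells with intensity measurements")
    if (cells["h4_intensity"] <= 0).any():
        raise ValueError("zero H4 intensity in a used cell")
    per_cell = cells["k27m_intensity"] / cells["h4_intensity"]
    per_field = per_cell.groupby(cells["field_id"]).agg(agg)
    return float(per_field.agg(agg))
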