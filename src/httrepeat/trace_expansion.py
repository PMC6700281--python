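"""Somatic-expansion scoring from capillary fragment-analysis peak tables.

Bulk PCR fragment sizing of the *HTT* CAG repeat produces, per sample, a
main peak at the inherited expanded allele plus stutter peaks to its left
and — in individuals with high somatic mosaicism — peaks to its right
corresponding to somatically expanded repeats.  The per-sample "peak
proportional sum" is the summed height of right-of-main peaks divided by
the main-peak height.

Pipeline: per-plate linear calibration of fragment size (bp) to CAG units
using the called main peaks, a 500 bp / 50 RFU peak filter, nearest-integer
CAG assignment with larger-height collision resolution, and summation of
peaks strictly right of the main allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy import stats

__all__ = [
    "PEAK_COLUMNS",
    "PlateCalibration",
    "ExpansionIndex",
    "main_peaks",
    "fit_plate_calibration",
    "assign_peak_cag",
    "filter_peaks",
    "resolve_collisions",
    "peak_proportional_sum",
    "score_samples",
    "rank_top_quartile",
]

#: Column layout of a peak table (GeneMapper-style export).
PEAK_COLUMNS = ["sample", "plate", "called_cag", "size_bp", "height_rfu", "area", "scan"]


@dataclass(frozen=True)
class PlateCalibration:
    """Least-squares size->CAG calibration for one plate."""

    intercept: float   # CAG units
    slope: float       # CAG per bp
    n_points: int
    residual_sd: float

    def cag_of(self, size_bp: float) -> float:
        return self.intercept + self.slope * size_bp


@dataclass(frozen=True)
class ExpansionIndex:
    """Per-sample somatic-expansion index."""

    sample: str
    main_cag: int
    peak_proportional_sum: float
    n_expansion_peaks: int


def main_peaks(records: pd.DataFrame) -> pd.DataFrame:
    """The main (highest) peak of each sample: the bulk PCR product at the
    inherited expanded allele."""
    idx = records.groupby("sample")["height_rfu"].idxmax()
    return records.loc[idx]


def fit_plate_calibration(records: pd.DataFrame) -> PlateCalibration:
    """OLS of called CAG allele on main-peak size for one plate.

    ``records`` must contain main peaks only (one per sample on the plate).
    """
    sizes = records["size_bp"].to_numpy(dtype=float)
    cags = records["called_cag"].to_numpy(dtype=float)
    if len(sizes) < 2 or len(set(sizes.tolist())) < 2:
        raise ValueError(
            "plate calibration requires >= 2 main peaks with distinct sizes"
        )
    fit = stats.linregress(sizes, cags)
    resid = cags - (fit.intercept + fit.slope * sizes)
    return PlateCalibration(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        n_points=len(sizes),
        residual_sd=float(resid.std(ddof=1)) if len(sizes) > 2 else 0.0,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def assign_peak_cag(size_bp: float, cal: PlateCalibration) -> int:
    """Transform a fragment size to an integer CAG length (nearest integer,
    halves away from zero)."""
    return _round_half_away(cal.cag_of(size_bp))


def filter_peaks(
    records: pd.DataFrame, max_size: float = 500.0, min_height: float = 50.0
) -> pd.DataFrame:
    """Keep peaks with size <= 500 bp and height >= 50 RFU (boundaries kept)."""
    keep = (records["size_bp"] <= max_size) & (records["height_rfu"] >= min_height)
    return records[keep]


def resolve_collisions(records: pd.DataFrame) -> pd.DataFrame:
    """Within a sample, when several peaks map to the same CAG length keep
    the one with the larger height."""
    idx = records.groupby(["sample", "assigned_cag"])["height_rfu"].idxmax()
    return records.loc[idx]


def peak_proportional_sum(sample_records: pd.DataFrame) -> Optional[ExpansionIndex]:
    """Sum of height proportions of peaks strictly right of the main allele.

    Peaks at or left of the main CAG are excluded (left-of-main products are
    dominated by PCR stutter artifacts).  Returns ``None`` when the sample
    has no main peak surviving the filters.
    """
    if sample_records.empty:
        return None
    main = sample_records.loc[sample_records["height_rfu"].idxmax()]
    main_height = float(main["height_rfu"])
    if main_height <= 0:
        return None
    main_cag = int(main["assigned_cag"])
    right = sample_records[sample_records["assigned_cag"] > main_cag]
    value = float(right["height_rfu"].sum()) / main_height
    return ExpansionIndex(
        sample=str(main["sample"]),
        main_cag=main_cag,
        peak_proportional_sum=value,
        n_expansion_peaks=len(right),
    )


def score_samples(
    records: pd.DataFrame, max_size: float = 500.0, min_height: float = 50.0
) -> pd.DataFrame:
    """Full scoring pipeline over a multi-plate peak table.

    Returns a DataFrame with columns sample, plate, main_cag,
    peak_proportional_sum, n_expansion_peaks.  Samples without a usable main
    peak are skipped.
    """
    out = []
    for plate, plate_records in records.groupby("plate"):
        cal = fit_plate_calibration(main_peaks(plate_records))
        kept = filter_peaks(plate_records, max_size=max_size, min_height=min_height).copy()
        if kept.empty:
            continue
        kept["assigned_cag"] = [
            assign_peak_cag(s, cal) for s in kept["size_bp"].to_numpy(dtype=float)
        ]
        kept = resolve_collisions(kept)
        for sample, sample_records in kept.groupby("sample"):
            idx = peak_proportional_sum(sample_records)
            if idx is None:
                continue
            out.append(
                {
                    "sample": idx.sample,
                    "plate": plate,
                    "main_cag": idx.main_cag,
                    "peak_proportional_sum": idx.peak_proportional_sum,
                    "n_expansion_peaks": idx.n_expansion_peaks,
                }
            )
    return pd.DataFrame(out, columns=["sample", "plate", "main_cag",
                                      "peak_proportional_sum", "n_expansion_peaks"])


def rank_top_quartile(scores: pd.DataFrame) -> pd.Index:
    """Sample ids of the top quartile by peak proportional sum.

    Descending sort; the top quartile has floor(n/4) samples; boundary ties
    are broken by sample id so the split is stable.
    """
    n = len(scores)
    if n < 4:
        raise ValueError("quartile ranking requires at least 4 samples")
    ranked = scores.sort_values(
        ["peak_proportional_sum", "sample"], ascending=[False, True]
    )
    return pd.Index(ranked["sample"].iloc[: n // 4])
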