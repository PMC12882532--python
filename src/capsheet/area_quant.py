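"""Per-aggregate adaptive-threshold area measurement and group comparison.

Each segmented aggregate region is thresholded independently at

    T = (max − min) − κ·σ

computed from that region's own pixel values (κ defaults to 1.5, σ is the
population standard deviation). Pixels pass when their min-shifted value
(value − region minimum) is at least T, which makes the rule invariant to a
constant intensity offset; the passing count converts to nm² through the
pixel size. Condition groups are compared with pairwise Wilcoxon rank-sum
tests under Benjamini–Hochberg correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import AREA_TABLE_COLUMNS, LabelMask, Micrograph
from .stats_compare import bh_adjust, stars, wilcoxon_rank_sum

__all__ = ["ThresholdParams", "AggregateAreaRecord", "GroupComparisonResult",
           "region_threshold", "measure_aggregate_area", "measure_all",
           "compare_area_groups"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdParams:
    """Adaptive-threshold settings.

    ``kappa`` multiplies the region standard deviation; ``invert`` negates
    intensities first, for dark-aggregate (bright-field) images.
    """

    kappa: float = 1.5
    invert: bool = False

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass(frozen=True)
class AggregateAreaRecord:
    aggregate_id: int
    condition: str
    region_pixel_count: int
    threshold: float
    above_threshold_pixels: int
    area_nm2: float


def region_threshold(region_values, params: ThresholdParams = ThresholdParams()
                     ) -> float:
    """Adaptive threshold T = (max − min) − κ·σ of a region's intensities.

    σ is the population standard deviation. T may be negative (all pixels
    then pass) and is zero for a constant region.
    """
    values = np.asarray(region_values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty region")
    if params.invert:
        values = -values
    return float((values.max() - values.min()) - params.kappa * values.std())


def measure_aggregate_area(image: Micrograph, mask: LabelMask, aggregate_id: int,
                           params: ThresholdParams = ThresholdParams(),
                           condition: str = "") -> AggregateAreaRecord:
    """Measure one aggregate's above-threshold area in nm².

    Statistics are computed over the masked region only; a pixel counts when
    its min-shifted value meets the threshold (ties pass). All passing pixels
    in the region are counted regardless of connectivity.
    """
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    sel = mask.labels == aggregate_id
    count = int(sel.sum())
    if aggregate_id <= 0 or count == 0:
        raise KeyError(f"aggregate id {aggregate_id} not present in mask")
    values = image.values[sel]
    if params.invert:
        values = -values
    t = float((values.max() - values.min()) - params.kappa * values.std())
    if values.max() == values.min():
        log.warning("aggregate %d: uniform region, threshold degenerates to 0 "
                    "and every pixel counts", aggregate_id)
    passing = int(np.count_nonzero(values - values.min() >= t))
    area = passing * (image.pixel_size / 10.0) ** 2
    return AggregateAreaRecord(aggregate_id=int(aggregate_id),
                               condition=condition,
                               region_pixel_count=count, threshold=t,
                               above_threshold_pixels=passing, area_nm2=area)


def measure_all(image: Micrograph, mask: LabelMask,
                params: ThresholdParams = ThresholdParams(),
                condition: str = "") -> pd.DataFrame:
    """Measure every labelled aggregate, one independent threshold each.

    Returns an area table (DataFrame) with one row per distinct positive
    label; an empty mask yields an empty table with a warning.
    """
    ids = mask.ids
    if ids.size == 0:
        log.warning("mask contains no labelled aggregates; empty area table")
    records = [measure_aggregate_area(image, mask, int(i), params, condition)
               for i in ids]
    return pd.DataFrame([r.__dict__ for r in records], columns=AREA_TABLE_COLUMNS)


@dataclass(frozen=True)
class GroupComparisonResult:
    """All pairwise condition comparisons plus per-condition summaries.

    ``pairs`` has columns condition_a, condition_b, raw_p, adjusted_p, stars;
    ``summary`` has per-condition n, median and interquartile range (nm²).
    """

    pairs: pd.DataFrame
    summary: pd.DataFrame


def compare_area_groups(table: pd.DataFrame) -> GroupComparisonResult:
    """Compare aggregate areas across conditions.

    Requires at least two conditions with at least two records each. Raw
    two-sided Wilcoxon rank-sum p-values over all condition pairs are
    Benjamini–Hochberg adjusted across the full set of pairs and labelled
    with significance stars (* p<0.05, ** p<0.01, *** p<0.001).
    """
    if "condition" not in table.columns or "area_nm2" not in table.columns:
        raise ValueError("area table needs 'condition' and 'area_nm2' columns")
    groups = {c: g["area_nm2"].to_numpy() for c, g in table.groupby("condition",
                                                                    sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least two conditions to compare")
    for c, v in groups.items():
        if v.size < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 records")

    pairs = list(itertools.combinations(sorted(groups), 2))
    raw = [wilcoxon_rank_sum(groups[a], groups[b]).p_two_sided for a, b in pairs]
    adj = bh_adjust(raw)
    pair_df = pd.DataFrame({
        "condition_a": [a for a, _ in pairs],
        "condition_b": [b for _, b in pairs],
        "raw_p": raw,
        "adjusted_p": adj,
        "stars": [stars(p) for p in adj],
    })
    summary = pd.DataFrame({
        "condition": sorted(groups),
        "n": [groups[c].size for c in sorted(groups)],
        "median_nm2": [float(np.median(groups[c])) for c in sorted(groups)],
        "iqr_lo_nm2": [float(np.percentile(groups[c], 25)) for c in sorted(groups)],
        "iqr_hi_nm2": [float(np.percentile(groups[c], 75)) for c in sorted(groups)],
    })
    return GroupComparisonResult(pairs=pair_df, summary=summary)
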