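"""Dense/dilute partition statistics for condensate-forming cells.

Central quantity: the *condensate fraction* — the share of a cell's total
(background-subtracted) fluorescence residing in the dense phase,

    fraction = Area_dense * (MeanI_dense - MeanI_dilute) / TotalIntegratedDensity,

where the dense-phase mean is taken over the condensate mask, the dilute mean
over the rest of the cell, and the denominator is the background-subtracted
integrated density over the whole cell mask.  Comparing the fraction before
and after a disruption treatment gives the percent disruption efficiency,

    efficiency% = 100 * (Fraction_pre - Fraction_post) / Fraction_pre.

All statistics here are invariant to adding a constant to every pixel (with a
matched background estimate) and to positive rescaling of the
background-subtracted intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .errors import UndefinedStatisticError
from .segment import SegmentationResult

logger = logging.getLogger(__name__)


@dataclass
class PartitionMeasurement:
    """Per-frame decomposition of cell fluorescence into dense and dilute phases.

    All intensity fields are background-subtracted.  ``mean_dense`` is NaN
    (and flagged) when the condensate mask is empty; the fraction is then 0.
    """

    area_dense: int
    mean_dense: float
    mean_dilute: float
    total_integrated_density: float
    fraction_in_condensate: float
    flags: List[str] = field(default_factory=list)


@dataclass
class DisruptionResult:
    """Pre/post condensate fractions and the derived disruption efficiency for one cell."""

    fraction_pre: float
    fraction_post: float
    efficiency_percent: float
    dense_dilute_ratio: float
    flags: List[str] = field(default_factory=list)


def estimate_background(
    frame: np.ndarray,
    cell_mask: np.ndarray,
    dilate_px: int = 2,
) -> float:
    """Mean intensity over pixels outside the (dilated) cell mask.

    The cell mask is dilated by ``dilate_px`` before exclusion so dim cell
    fringes do not contaminate the background estimate.

    Raises
    ------
    UndefinedStatisticError
        If no pixels remain outside the cell; pass an explicit background
        value to the downstream statistics instead.
    """
    frame = np.asarray(frame, dtype=np.float64)
    mask = np.asarray(cell_mask, dtype=bool)
    if dilate_px > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate_px)
    outside = ~mask
    if not outside.any():
        raise UndefinedStatisticError(
            "cell mask (after dilation) covers the entire frame; "
            "supply an explicit background value"
        )
    return float(frame[outside].mean())


def partition_stats(
    frame: np.ndarray,
    seg: SegmentationResult,
    background: float = 0.0,
) -> PartitionMeasurement:
    """Compute the dense/dilute partition of one background-subtracted frame.

    Raises
    ------
    UndefinedStatisticError
        If the cell mask is empty or the total background-subtracted
        integrated density is nonpositive (the fraction denominator).
    """
    frame = np.asarray(frame, dtype=np.float64)
    cell = seg.cell_mask
    cond = seg.condensate_mask
    if not cell.any():
        raise UndefinedStatisticError("empty cell mask: partition undefined")
    if background < 0:
        raise ValueError("background must be >= 0")

    corrected = frame - background
    total = float(corrected[cell].sum())
    if total <= 0:
        raise UndefinedStatisticError(
            f"total background-subtracted integrated density is {total:g} <= 0; "
            "fraction undefined"
        )

    area = int(cond.sum())
    flags: List[str] = []
    if area == 0:
        mean_dense = float("nan")
        mean_dilute = float(corrected[cell].mean())
        fraction = 0.0
        flags.append("empty condensate mask: mean_dense undefined, fraction set to 0")
    else:
        mean_dense = float(corrected[cond].mean())
        dilute_px = cell & ~cond
        if dilute_px.any():
            mean_dilute = float(corrected[dilute_px].mean())
        else:
            mean_dilute = 0.0
            flags.append("condensate mask covers entire cell: mean_dilute set to 0")
        fraction = area * (mean_dense - mean_dilute) / total

    logger.info("partition: area_dense=%d mean_dense=%g mean_dilute=%g total=%g "
                "fraction=%g (background=%g)", area, mean_dense, mean_dilute,
                total, fraction, background)
    return PartitionMeasurement(
        area_dense=area,
        mean_dense=mean_dense,
        mean_dilute=mean_dilute,
        total_integrated_density=total,
        fraction_in_condensate=float(fraction),
        flags=flags,
    )


def disruption_efficiency(
    pre: PartitionMeasurement,
    post: PartitionMeasurement,
) -> DisruptionResult:
    """Percent disruption efficiency from pre- and post-treatment partitions.

    ``efficiency = 100 * (fraction_pre - fraction_post) / fraction_pre``.
    Negative efficiencies (condensate growth) are reported and flagged, not
    clipped.  The dense/dilute mean-intensity ratio is taken from the
    pre-treatment measurement.

    Raises
    ------
    UndefinedStatisticError
        If ``fraction_pre <= 0``.
    """
    f_pre = pre.fraction_in_condensate
    f_post = post.fraction_in_condensate
    if f_pre <= 0:
        raise UndefinedStatisticError(
            f"fraction_pre = {f_pre:g} <= 0: disruption efficiency undefined"
        )
    efficiency = 100.0 * (f_pre - f_post) / f_pre
    flags: List[str] = []
    if efficiency < 0:
        flags.append("negative efficiency: condensate grew after treatment")
    if pre.mean_dilute > 0 and np.isfinite(pre.mean_dense):
        ratio = pre.mean_dense / pre.mean_dilute
    else:
        ratio = float("nan")
        flags.append("dense/dilute ratio undefined for pre measurement")
    return DisruptionResult(
        fraction_pre=f_pre,
        fraction_post=f_post,
        efficiency_percent=float(efficiency),
        dense_dilute_ratio=float(ratio),
        flags=flags,
    )


def condensate_intensity_ratio(
    frame: np.ndarray,
    seg: SegmentationResult,
    background: float = 0.0,
) -> float:
    """Integrated intensity within condensates over total cell integrated density.

    Both numerator and denominator are background-subtracted; with the
    condensate mask a subset of the cell mask and nonnegative corrected
    intensities, the ratio lies in [0, 1].  For multi-cell merged fields the
    cell mask covers all cells, giving the field-level aggregate.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not seg.cell_mask.any():
        raise UndefinedStatisticError("empty cell mask: ratio undefined")
    corrected = frame - background
    total = float(corrected[seg.cell_mask].sum())
    if total <= 0:
        raise UndefinedStatisticError(
            f"total background-subtracted intensity is {total:g} <= 0; ratio undefined"
        )
    within = float(corrected[seg.condensate_mask].sum())
    return within / total


def efficiency_ratio_correlation(
    results: Sequence[DisruptionResult],
) -> Tuple[float, float, float]:
    """Least-squares line of efficiency against the dense/dilute ratio.

    Returns ``(slope, intercept, pearson_r)``.  Cells with higher dense-phase
    enrichment resist disruption, so a negative slope is the expected
    signature.

    Raises
    ------
    UndefinedStatisticError
        For fewer than 3 finite points or zero variance in the ratio.
    """
    pts = [
        (r.dense_dilute_ratio, r.efficiency_percent)
        for r in results
        if np.isfinite(r.dense_dilute_ratio) and np.isfinite(r.efficiency_percent)
    ]
    if len(pts) < 3:
        raise UndefinedStatisticError(
            f"need >= 3 results with finite values, got {len(pts)}"
        )
    x, y = np.array(pts).T
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("zero variance in dense/dilute ratio")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def uptake_percent(
    transfected_intensities: Sequence[float],
    untransfected_intensities: Sequence[float],
    background: float = 0.0,
) -> float:
    """Cargo-uptake signal in transfected cells as percent of untransfected cells.

    ``100 * mean(transfected - background) / mean(untransfected - background)``.
    Used e.g. for transferrin uptake read-outs of clathrin-mediated
    endocytosis.

    Raises
    ------
    UndefinedStatisticError
        If either list is empty or the untransfected mean does not exceed the
        background.
    """
    t = np.asarray(transfected_intensities, dtype=np.float64)
    u = np.asarray(untransfected_intensities, dtype=np.float64)
    if t.size == 0 or u.size == 0:
        raise UndefinedStatisticError("both intensity lists must be nonempty")
    denom = u.mean() - background
    if denom <= 0:
        raise UndefinedStatisticError(
            f"untransfected mean ({u.mean():g}) does not exceed background "
            f"({background:g})"
        )
    return float(100.0 * (t.mean() - background) / denom)
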