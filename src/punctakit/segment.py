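"""Condensate and cell segmentation by histogram thresholding.

The segmentation mirrors a standard ImageJ workflow on confocal timelapses of
phase-separating proteins: Z-stacks are reduced by maximal projection, the
dense phase (condensates) is isolated with a histogram threshold (Otsu's
between-class-variance criterion or Kapur's maximum-entropy criterion), and
the cell footprint with the Mean auto-threshold.  Histograms use 256 bins
spanning the per-image ``[min, max]`` range, thresholds are bin edges, masks
use the strictly-greater-than convention, and ties between equally good
thresholds break toward the lower one.  Because thresholds are
histogram-relative, masks are invariant to affine intensity rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import DegenerateHistogramError
from .stack import ImageStack

logger = logging.getLogger(__name__)

CONDENSATE_METHODS = ("otsu", "maxentropy", "mean")
CELL_METHODS = ("mean", "otsu", "maxentropy")

#: Default minimum object size (pixels) used to suppress single-pixel shot noise.
DEFAULT_MIN_OBJECT_PX = 4


@dataclass
class SegmentationResult:
    """Masks and thresholds for one frame.

    ``condensate_mask`` is a subset of ``cell_mask`` pixelwise; both are
    boolean arrays with the frame's (Y, X) shape.
    """

    condensate_mask: np.ndarray
    cell_mask: np.ndarray
    threshold_value: float
    cell_threshold_value: float
    method: str
    cell_method: str
    min_object_px: int
    warnings: List[str] = field(default_factory=list)

    @property
    def empty_cell(self) -> bool:
        return not bool(self.cell_mask.any())


def max_project(stack: ImageStack) -> ImageStack:
    """Maximal Z-projection: per-pixel maximum across the Z planes of each frame.

    Single-plane input (no Z axis) is returned unchanged.
    """
    if not stack.has_z:
        return stack
    if stack.pixels.shape[1] < 1:
        raise ValueError("stack has an empty Z axis")
    projected = stack.pixels.max(axis=1)
    return ImageStack(projected, stack.times_s, stack.channel_role, dict(stack.meta))


def _histogram(image: np.ndarray, n_bins: int):
    """Counts and edges of an n_bins histogram over the image's [min, max]."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise DegenerateHistogramError(
            f"constant image (all pixels = {lo}): histogram threshold undefined"
        )
    counts, edges = np.histogram(image.ravel(), bins=n_bins, range=(lo, hi))
    return counts.astype(np.float64), edges


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the bin edge maximizing between-class variance.

    Candidate threshold k places bins ``<= k`` in the background class and
    bins ``> k`` in the foreground; the returned value is the edge between
    them, so the mask convention is ``pixels > threshold``.  Ties break
    toward the lower threshold.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant.
    """
    counts, edges = _histogram(image, n_bins)
    total = counts.sum()
    p = counts / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    # cumulative weight and mean for the background class after each bin
    w0 = np.cumsum(p)[:-1]
    mu_cum = np.cumsum(p * centers)
    mu_total = mu_cum[-1]
    mu0_sum = mu_cum[:-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.full(n_bins - 1, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu0_sum / w0
        mu1 = (mu_total - mu0_sum) / w1
        vb = w0 * w1 * (mu0 - mu1) ** 2
    var_between[valid] = vb[valid]
    k = int(np.argmax(var_between))  # argmax returns the first (lowest) maximizer
    return float(edges[k + 1])


def maxentropy_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Kapur's maximum-entropy threshold.

    Maximizes the sum of the Shannon entropies of the background and
    foreground histogram classes; candidates leaving either class empty are
    skipped.  Same edge/tie conventions as :func:`otsu_threshold`.
    """
    counts, edges = _histogram(image, n_bins)
    p = counts / counts.sum()
    P0 = np.cumsum(p)[:-1]
    c0 = np.cumsum(counts)[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S = np.cumsum(plogp)
    S0 = S[:-1]
    S_total = S[-1]
    valid = (c0 > 0) & (c0 < counts.sum())
    objective = np.full(n_bins - 1, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_back = np.log(P0) - S0 / P0
        h_fore = np.log1p(-P0) - (S_total - S0) / (1.0 - P0)
        obj = h_back + h_fore
    objective[valid] = obj[valid]
    k = int(np.argmax(objective))
    return float(edges[k + 1])


def mean_threshold(image: np.ndarray) -> float:
    """Arithmetic-mean threshold (ImageJ "Mean" auto-threshold convention)."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    return float(image.mean())


_THRESHOLD_FUNCS = {
    "otsu": otsu_threshold,
    "maxentropy": maxentropy_threshold,
    "mean": mean_threshold,
}


def threshold(image: np.ndarray, method: str, n_bins: int = 256) -> float:
    """Dispatch to one of the named threshold methods."""
    if method not in _THRESHOLD_FUNCS:
        raise ValueError(f"unknown threshold method {method!r}; expected one of "
                         f"{tuple(_THRESHOLD_FUNCS)}")
    if method == "mean":
        return mean_threshold(image)
    return _THRESHOLD_FUNCS[method](image, n_bins)


def _remove_small_objects(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than min_px pixels."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def make_masks(
    frame: np.ndarray,
    condensate_method: str = "otsu",
    cell_method: str = "mean",
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
    condensate_threshold: Optional[float] = None,
    cell_threshold: Optional[float] = None,
    subregion_mask: Optional[np.ndarray] = None,
) -> SegmentationResult:
    """Segment one frame into a cell mask and a condensate mask.

    The cell mask is ``frame > cell_threshold``, morphologically closed and
    hole-filled.  The condensate mask is ``frame > condensate_threshold``
    restricted to the cell mask, with connected objects smaller than
    ``min_object_px`` removed.  Precomputed threshold values (e.g. from a
    reference frame of a timelapse) override the per-frame computation.
    ``subregion_mask`` (e.g. a nucleus or cytosol mask) further restricts the
    condensate mask when given.

    An empty cell mask is flagged in ``result.warnings``, not raised.
    """
    frame = np.asarray(frame, dtype=np.float64)
    warnings: List[str] = []

    t_cell = cell_threshold if cell_threshold is not None else threshold(frame, cell_method)
    cell_mask = frame > t_cell
    if cell_mask.any():
        cell_mask = morphology.closing(cell_mask, morphology.disk(2)).astype(bool)
        cell_mask = ndimage.binary_fill_holes(cell_mask)
    else:
        warnings.append(f"empty cell mask at cell threshold {t_cell:g}")

    t_cond = (condensate_threshold if condensate_threshold is not None
              else threshold(frame, condensate_method))
    condensate_mask = (frame > t_cond) & cell_mask
    if subregion_mask is not None:
        condensate_mask &= np.asarray(subregion_mask, dtype=bool)
    if min_object_px > 1:
        condensate_mask = _remove_small_objects(condensate_mask, min_object_px)
    if not condensate_mask.any():
        warnings.append(f"empty condensate mask at threshold {t_cond:g}")

    logger.info("segment: cell threshold=%g (%s), condensate threshold=%g (%s), "
                "min_object_px=%d", t_cell, cell_method, t_cond, condensate_method,
                min_object_px)
    return SegmentationResult(
        condensate_mask=condensate_mask,
        cell_mask=cell_mask,
        threshold_value=float(t_cond),
        cell_threshold_value=float(t_cell),
        method=condensate_method,
        cell_method=cell_method,
        min_object_px=min_object_px,
        warnings=warnings,
    )


def segment_stack(
    stack: ImageStack,
    condensate_method: str = "otsu",
    cell_method: str = "mean",
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
    reference_frame: Optional[int] = 0,
    subregion_mask: Optional[np.ndarray] = None,
    freeze_mask: bool = False,
) -> List[SegmentationResult]:
    """Segment every frame of a (projected) timelapse.

    With ``reference_frame`` set (the default: frame 0, i.e. the
    pre-treatment image) the condensate threshold is computed once on that
    frame and held fixed across the movie — per-frame re-thresholding of a
    dissolving movie would hallucinate foreground after dissolution.  Pass
    ``reference_frame=None`` to re-threshold each frame independently.

    ``freeze_mask=True`` additionally holds the reference frame's condensate
    *mask* fixed for the whole movie.  This is the right choice for kinetics
    timecourses: the signal inside a fixed dense-phase region tracks the
    dissolution kinetics directly, whereas a per-frame mask shrinks as
    condensates dim past the threshold and steepens the apparent decay.
    """
    if stack.has_z:
        stack = max_project(stack)
    fixed_t: Optional[float] = None
    if reference_frame is not None:
        if not (0 <= reference_frame < stack.n_frames):
            raise ValueError(f"reference_frame {reference_frame} outside stack")
        fixed_t = threshold(stack.frame(reference_frame), condensate_method)
    elif freeze_mask:
        raise ValueError("freeze_mask requires a reference_frame")
    results = [
        make_masks(
            stack.frame(i),
            condensate_method=condensate_method,
            cell_method=cell_method,
            min_object_px=min_object_px,
            condensate_threshold=fixed_t,
            subregion_mask=subregion_mask,
        )
        for i in range(stack.n_frames)
    ]
    if freeze_mask:
        ref_mask = results[reference_frame].condensate_mask
        for res in results:
            res.condensate_mask = ref_mask & res.cell_mask
    return results
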