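"""FRAP (fluorescence recovery after photobleaching) trace normalization.

The bleached-region integrated density is first divided by the background-free
total cell integrated density at every frame — this ratio cancels global
acquisition photobleaching, which dims region and cell alike.  The ratio trace
r(t) is then mapped to [0, 1]:

    normalized(t) = (r(t) - r(bleach)) / (mean_prebleach(r) - r(bleach)),

so the bleach time point sits at 0 and the pre-bleach average at 1.  Values
outside [0, 1] (noise overshoot) are left unclipped; the expectation stays in
[0, 1].  The long-time plateau of the normalized curve estimates the mobile
fraction of the bleached species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .errors import UndefinedStatisticError
from .kinetics import KineticFit, Timecourse, fit_exponential
from .stack import ImageStack

logger = logging.getLogger(__name__)

#: Photobleaching pulses are typically calibrated to remove 60-85% of the
#: original signal; depths outside this band are flagged, not rejected.
BLEACH_DEPTH_BAND = (0.60, 0.85)


@dataclass
class FRAPTrace:
    """Raw and normalized photobleaching-recovery traces for one bleach event."""

    times_s: np.ndarray
    raw_bleach_integrated: np.ndarray
    raw_total_integrated: np.ndarray
    bleach_index: int
    normalized: Optional[np.ndarray] = None
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.raw_bleach_integrated = np.asarray(self.raw_bleach_integrated, dtype=np.float64)
        self.raw_total_integrated = np.asarray(self.raw_total_integrated, dtype=np.float64)
        n = len(self.times_s)
        if len(self.raw_bleach_integrated) != n or len(self.raw_total_integrated) != n:
            raise ValueError("trace arrays must have equal length")
        if not 0 < self.bleach_index < n:
            raise ValueError(
                f"bleach_index {self.bleach_index} needs at least one pre-bleach "
                f"frame and must lie within the {n}-frame trace"
            )

    @property
    def bleach_time_s(self) -> float:
        return float(self.times_s[self.bleach_index])


def measure_frap_trace(
    stack: ImageStack,
    bleach_region: np.ndarray,
    cell_mask: np.ndarray,
    bleach_index: int,
    background: float = 0.0,
) -> FRAPTrace:
    """Extract raw bleach-region and whole-cell integrated densities from a movie.

    The bleached region is a fixed mask drawn at the bleach frame and held
    constant.  Both integrals are background-subtracted ("background free").
    """
    region = np.asarray(bleach_region, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty bleach region")
    if (region & ~cell).any():
        raise ValueError("bleach region extends outside the cell mask")
    corrected = stack.pixels - background
    raw_bleach = corrected[:, region].sum(axis=1)
    raw_total = corrected[:, cell].sum(axis=1)
    return FRAPTrace(stack.times_s.copy(), raw_bleach, raw_total, bleach_index)


def normalize_frap(trace: FRAPTrace) -> FRAPTrace:
    """Normalize a raw FRAP trace to the [0, 1] convention described above.

    Raises
    ------
    UndefinedStatisticError
        If any total integrated density is nonpositive, or the pre-bleach mean
        ratio equals the bleach-point ratio (no bleaching occurred).
    """
    if np.any(trace.raw_total_integrated <= 0):
        raise UndefinedStatisticError(
            "total integrated density must be > 0 at every frame"
        )
    r = trace.raw_bleach_integrated / trace.raw_total_integrated
    r_pre = float(r[: trace.bleach_index].mean())
    r0 = float(r[trace.bleach_index])
    denom = r_pre - r0
    if denom == 0:
        raise UndefinedStatisticError(
            "pre-bleach mean ratio equals the bleach-point ratio: no bleaching occurred"
        )
    normalized = (r - r0) / denom

    flags = list(trace.flags)
    depth = bleach_depth(trace)
    if not BLEACH_DEPTH_BAND[0] <= depth <= BLEACH_DEPTH_BAND[1]:
        flags.append(
            f"bleach depth {depth:.2f} outside calibration band "
            f"{BLEACH_DEPTH_BAND[0]:.2f}-{BLEACH_DEPTH_BAND[1]:.2f}"
        )
    logger.info("frap normalize: r_pre=%g r_bleach=%g depth=%.3f", r_pre, r0, depth)
    return replace(trace, normalized=normalized, flags=flags)


def bleach_depth(trace: FRAPTrace) -> float:
    """Fraction of the pre-bleach region ratio removed by the bleach pulse."""
    r = trace.raw_bleach_integrated / trace.raw_total_integrated
    r_pre = float(r[: trace.bleach_index].mean())
    if r_pre == 0:
        raise UndefinedStatisticError("pre-bleach ratio is zero")
    return 1.0 - float(r[trace.bleach_index]) / r_pre


def recovery_at(trace: FRAPTrace, elapsed_s: float) -> float:
    """Normalized recovery at ``bleach_time + elapsed_s`` (linear interpolation).

    Raises
    ------
    ValueError
        If the requested time lies outside the post-bleach span of the trace.
    """
    if trace.normalized is None:
        raise ValueError("trace must be normalized first (see normalize_frap)")
    if elapsed_s < 0:
        raise ValueError("elapsed_s must be >= 0")
    target = trace.bleach_time_s + elapsed_s
    if target > trace.times_s[-1]:
        raise ValueError(
            f"elapsed_s {elapsed_s:g} reaches {target:g} s, beyond the trace end "
            f"({trace.times_s[-1]:g} s)"
        )
    post_t = trace.times_s[trace.bleach_index:]
    post_v = trace.normalized[trace.bleach_index:]
    return float(np.interp(target, post_t, post_v))


def fit_recovery(trace: FRAPTrace) -> KineticFit:
    """Single-exponential fit of the post-bleach normalized curve (convenience).

    Fits ``n(t) = m - m * exp(-(t - t_bleach)/tau)``; the fitted base is the
    plateau, i.e. the mobile-fraction estimate, and tau the exchange time.
    This summary goes beyond plain normalized-curve read-outs and is provided
    for convenience on top of the exponential fitter.
    """
    if trace.normalized is None:
        raise ValueError("trace must be normalized first (see normalize_frap)")
    tc = Timecourse(
        trace.times_s[trace.bleach_index:],
        trace.normalized[trace.bleach_index:],
        onset_s=trace.bleach_time_s,
    )
    return fit_exponential(tc, t_start_s=trace.bleach_time_s)
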