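"""Dissolution/formation kinetics: timecourse extraction and tau fitting.

Condensate signal per frame (the condensate fraction, or the
condensate-integrated intensity) is fitted to one of two models:

    sigmoid:      v(t) = base + amplitude / (1 + exp((t - t_half) / tau))
    exponential:  v(t) = base + amplitude * exp(-(t - t_start) / tau)

``tau`` is the characteristic time in both.  The sigmoid is the logistic with
tau as the exponential rate parameter (midpoint slope = -amplitude/(4 tau));
users comparing against e.g. 10-90% rise-time conventions can convert via
t_10-90 = 2 ln(9) tau.  For dissolution after a treatment added at
``onset_s``, frames before onset are included in sigmoid fits (they pin the
upper plateau) but excluded from exponential fits, which model only the
post-treatment decay.

Fits are bounded least squares (tau > 0), relative tolerance 1e-8, at most
1000 residual evaluations; non-convergence and degenerate inputs are reported
via ``converged=False``, never as a fabricated tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError
from .quantify import PartitionMeasurement, partition_stats
from .segment import SegmentationResult
from .stack import ImageStack

logger = logging.getLogger(__name__)


@dataclass
class Timecourse:
    """Condensate signal as a function of acquisition time."""

    times_s: np.ndarray
    values: np.ndarray
    onset_s: float = 0.0
    observable: str = "fraction"  # or "integrated_intensity"
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times_s and values must be 1-D arrays of equal length")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")


@dataclass
class KineticFit:
    """Result of a sigmoid or exponential kinetics fit."""

    model: str
    base: float
    amplitude: float
    t_half_s: float  # sigmoid midpoint, or the exponential origin t_start_s
    tau_s: float
    r_squared: float
    converged: bool
    param_uncertainties: Dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def t_start_s(self) -> float:
        return self.t_half_s


def condensate_timecourse(
    stack: ImageStack,
    segs: Sequence[SegmentationResult],
    backgrounds: Sequence[float],
    onset_s: float = 0.0,
    observable: str = "fraction",
) -> Timecourse:
    """Per-frame condensate signal from a segmented movie.

    ``observable`` selects the condensate fraction or the background-subtracted
    condensate-integrated intensity.  Frames with empty condensate masks yield
    0 (flagged), not missing values.
    """
    if stack.n_frames < 3:
        raise FitError(f"need >= 3 frames for a timecourse, got {stack.n_frames}")
    if len(segs) != stack.n_frames or len(backgrounds) != stack.n_frames:
        raise ValueError("one segmentation and one background per frame required")
    if observable not in ("fraction", "integrated_intensity"):
        raise ValueError(f"unknown observable {observable!r}")

    values = np.empty(stack.n_frames)
    flags: List[str] = []
    n_empty = 0
    for i in range(stack.n_frames):
        pm = partition_stats(stack.frame(i), segs[i], backgrounds[i])
        if pm.area_dense == 0:
            n_empty += 1
        if observable == "fraction":
            values[i] = pm.fraction_in_condensate
        else:
            corrected = stack.frame(i) - backgrounds[i]
            values[i] = float(corrected[segs[i].condensate_mask].sum())
    if n_empty == stack.n_frames:
        flags.append("all frames have empty condensate masks")
    elif n_empty:
        flags.append(f"{n_empty} frame(s) with empty condensate masks (value 0)")
    return Timecourse(stack.times_s.copy(), values, onset_s=onset_s,
                      observable=observable, flags=flags)


def _no_fit(model: str, message: str) -> KineticFit:
    return KineticFit(model=model, base=float("nan"), amplitude=float("nan"),
                      t_half_s=float("nan"), tau_s=float("nan"),
                      r_squared=float("nan"), converged=False, message=message)


def _crossing_time(t: np.ndarray, v: np.ndarray, level: float) -> Optional[float]:
    """First time v crosses `level` (either direction), linearly interpolated."""
    above = v >= level
    for i in range(len(v) - 1):
        if above[i] != above[i + 1] and v[i + 1] != v[i]:
            frac = (level - v[i]) / (v[i + 1] - v[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def _finish_fit(model: str, names: Tuple[str, ...], res, t, v,
                predict) -> KineticFit:
    """Assemble a KineticFit with r² and covariance-based standard errors."""
    params = res.x
    fitted = predict(t, *params)
    ss_res = float(np.sum((v - fitted) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    uncertainties: Dict[str, float] = {}
    dof = len(v) - len(params)
    if dof > 0:
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * (ss_res / dof)
            ses = np.sqrt(np.clip(np.diag(cov), 0, None))
            uncertainties = {n: float(s) for n, s in zip(names, ses)}
        except np.linalg.LinAlgError:
            pass

    converged = bool(res.success) and params[-1] > 0
    fit = KineticFit(
        model=model,
        base=float(params[0]),
        amplitude=float(params[1]),
        t_half_s=float(params[2]),
        tau_s=float(params[3]),
        r_squared=r2,
        converged=converged,
        param_uncertainties=uncertainties,
        message=res.message if not converged else "",
    )
    logger.info("%s fit: base=%g amplitude=%g %s=%g tau_s=%g r2=%g converged=%s",
                model, fit.base, fit.amplitude, names[2], fit.t_half_s,
                fit.tau_s, r2, converged)
    return fit


def _sigmoid(t, base, amplitude, t_half, tau):
    return base + amplitude / (1.0 + np.exp((t - t_half) / tau))


def fit_sigmoid(tc: Timecourse, init: Optional[Sequence[float]] = None) -> KineticFit:
    """Fit the logistic dissolution model and extract the characteristic time tau.

    Initialization (unless ``init`` = (base, amplitude, t_half, tau) is given):
    base and amplitude from the series extremes, t_half from the half-crossing
    time, tau from the 25-75% crossing span divided by 2 ln 3.

    Returns a non-converged :class:`KineticFit` (never raises) on degenerate
    series; raises only on fewer than 6 points.
    """
    t, v = tc.times_s, tc.values
    if len(t) < 6:
        raise FitError(f"sigmoid fit needs >= 6 points, got {len(t)}")
    if np.ptp(v) == 0:
        return _no_fit("sigmoid", "degenerate series: zero variance")

    if init is not None:
        x0 = np.asarray(init, dtype=np.float64)
    else:
        vmin, vmax = float(v.min()), float(v.max())
        amp0 = vmax - vmin
        mid = _crossing_time(t, v, vmin + 0.5 * amp0)
        t_half0 = mid if mid is not None else float(t.mean())
        lo = _crossing_time(t, v, vmin + 0.25 * amp0)
        hi = _crossing_time(t, v, vmin + 0.75 * amp0)
        if lo is not None and hi is not None and lo != hi:
            tau0 = abs(hi - lo) / (2.0 * np.log(3.0))
        else:
            tau0 = float(np.ptp(t)) / 8.0
        x0 = np.array([vmin, amp0, t_half0, max(tau0, 1e-6)])
        logger.info("sigmoid init: base=%g amplitude=%g t_half=%g tau=%g", *x0)

    span = float(np.ptp(t))
    bounds = ([-np.inf, -np.inf, t[0] - span, 1e-9],
              [np.inf, np.inf, t[-1] + span, np.inf])
    x0 = np.clip(x0, bounds[0], bounds[1])
    res = least_squares(lambda p: _sigmoid(t, *p) - v, x0, bounds=bounds,
                        xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=1000)
    return _finish_fit("sigmoid", ("base", "amplitude", "t_half_s", "tau_s"),
                       res, t, v, _sigmoid)


def _exponential(t, base, amplitude, t_start, tau):
    return base + amplitude * np.exp(-(t - t_start) / tau)


def fit_exponential(tc: Timecourse, t_start_s: Optional[float] = None) -> KineticFit:
    """Fit a single-exponential decay to the post-treatment points.

    Only points at ``t >= t_start_s`` (default: the timecourse onset) enter
    the fit; ``t_start_s`` is held fixed as the exponential origin, so the
    free parameters are base, amplitude and tau.
    """
    if t_start_s is None:
        t_start_s = tc.onset_s
    keep = tc.times_s >= t_start_s
    t, v = tc.times_s[keep], tc.values[keep]
    if len(t) < 4:
        raise FitError(f"exponential fit needs >= 4 points at t >= {t_start_s:g}, "
                       f"got {len(t)}")
    if np.ptp(v) == 0:
        return _no_fit("exponential", "degenerate series: zero variance")

    tail = float(v[-max(3, len(v) // 10):].mean())
    amp0 = float(v[0]) - tail
    level = tail + amp0 / np.e
    t_e = _crossing_time(t, v, level)
    tau0 = (t_e - t_start_s) if (t_e is not None and t_e > t_start_s) else float(np.ptp(t)) / 3.0
    x0 = np.array([tail, amp0, max(tau0, 1e-6)])
    logger.info("exponential init: base=%g amplitude=%g tau=%g (t_start=%g)",
                x0[0], x0[1], x0[2], t_start_s)

    def resid(p):
        return _exponential(t, p[0], p[1], t_start_s, p[2]) - v

    bounds = ([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf])
    res = least_squares(resid, np.clip(x0, bounds[0], bounds[1]), bounds=bounds,
                        xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=1000)

    # reshape result into the 4-parameter layout with t_start fixed
    class _Res:
        pass

    full = _Res()
    full.x = np.array([res.x[0], res.x[1], t_start_s, res.x[2]])
    full.success = res.success
    full.message = res.message
    # jacobian columns for (base, amplitude, tau); t_start column omitted
    full.jac = res.jac

    fitted_params = full.x
    fitted = _exponential(t, *fitted_params)
    ss_res = float(np.sum((v - fitted) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    uncertainties: Dict[str, float] = {}
    dof = len(v) - 3
    if dof > 0:
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac) * (ss_res / dof)
            ses = np.sqrt(np.clip(np.diag(cov), 0, None))
            uncertainties = {n: float(s)
                             for n, s in zip(("base", "amplitude", "tau_s"), ses)}
        except np.linalg.LinAlgError:
            pass
    converged = bool(res.success) and res.x[2] > 0
    fit = KineticFit(
        model="exponential",
        base=float(res.x[0]),
        amplitude=float(res.x[1]),
        t_half_s=float(t_start_s),
        tau_s=float(res.x[2]),
        r_squared=r2,
        converged=converged,
        param_uncertainties=uncertainties,
        message=res.message if not converged else "",
    )
    logger.info("exponential fit: base=%g amplitude=%g tau_s=%g r2=%g converged=%s",
                fit.base, fit.amplitude, fit.tau_s, r2, converged)
    return fit


def compare_taus(fit_a: KineticFit, fit_b: KineticFit) -> Tuple[float, float]:
    """Fold change tau_a / tau_b with first-order propagated uncertainty.

    Raises
    ------
    FitError
        If either fit did not converge.
    """
    if not (fit_a.converged and fit_b.converged):
        raise FitError("both fits must have converged to compare taus")
    fold = fit_a.tau_s / fit_b.tau_s
    sa = fit_a.param_uncertainties.get("tau_s", 0.0)
    sb = fit_b.param_uncertainties.get("tau_s", 0.0)
    sd = abs(fold) * np.sqrt((sa / fit_a.tau_s) ** 2 + (sb / fit_b.tau_s) ** 2)
    return float(fold), float(sd)
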