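"""Synthetic condensate timelapse generator with exact ground truth.

Scenes emulate a single cell imaged by fluorescence timelapse microscopy: an
elliptical cell footprint over a dark background, containing bright circular
condensates (the dense phase, partition coefficient P > 1) in a dilute
cytosolic pool.  During simulated disruption the dense-phase *excess*
intensity decays with sigmoid or exponential kinetics from the treatment
onset, and the lost integrated intensity is redistributed uniformly into the
dilute pool, so the total expected photon count per frame is conserved
exactly.  Photon shot noise (Poisson, with gain) and Gaussian read noise are
applied last; with noise disabled, frames equal their expectations.

Droplets are rendered as anti-aliased discs (area-weighted edge pixels) so
sub-pixel edges stress segmentation the way real condensates do.

Seeding: one master seed; droplet geometry and each frame's noise use fixed
derived streams, so changing the frame count never reshuffles earlier frames,
and identical config + seed reproduces bit-identical stacks.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, PlacementError
from .frap import FRAPTrace
from .stack import ImageStack

logger = logging.getLogger(__name__)

KINETICS_MODELS = ("sigmoid_decay", "exponential_decay", "constant", "sigmoid_growth")
DECAY_MODELS = ("sigmoid_decay", "exponential_decay")

#: Sigmoid midpoint sits this many taus after onset, so the pre-onset plateau
#: is flat to ~5% before normalization (exactly flat after it).
SIGMOID_MIDPOINT_TAUS = 3.0

#: Excess fraction below which a dissolving droplet no longer counts as dense
#: phase in the ground-truth mask.
MASK_EXTINCTION_FRACTION = 0.01


@dataclass
class SimulationConfig:
    """Parameters of one synthetic scene.

    Intensity levels are expected photons/pixel at t = 0; the partition
    coefficient is the dense/dilute expected-intensity ratio (> 1 for
    condensate-forming scenes).  ``noise_gain = 0`` disables shot noise and
    ``read_noise_sd = 0`` disables read noise; with both 0 the rendered stack
    equals its expectation.  Defaults describe a condensate-disruption
    experiment in the regime of fast scaffold dissolution: tau ~30 s (typical
    fitted taus fall in 25-45 s), treatment at t = 60 s, 2 s frame interval,
    and a dense phase ~6x over a 40 photon/px dilute pool, which puts the
    dense-pixel shot-noise SNR above 10.
    """

    image_shape: Tuple[int, int] = (128, 128)
    n_frames: int = 90
    frame_interval_s: float = 2.0
    cell_center_yx: Optional[Tuple[float, float]] = None  # default: image center
    cell_semi_axes_yx: Optional[Tuple[float, float]] = None  # default: 0.4 * shape
    nucleus_center_yx: Optional[Tuple[float, float]] = None
    nucleus_semi_axes_yx: Optional[Tuple[float, float]] = None
    n_droplets: int = 8
    droplet_radius_px: Tuple[float, float] = (3.0, 8.0)
    dilute_level: float = 40.0
    partition_coefficient: float = 6.0
    dense_level: Optional[float] = None  # overrides dilute * partition
    background_level: float = 10.0
    kinetics_model: str = "sigmoid_decay"
    tau_s: float = 30.0
    onset_s: float = 60.0
    noise_gain: float = 1.0
    read_noise_sd: float = 2.0
    seed: int = 0
    nuclear_droplet_fraction: float = 0.0
    dissolution_mode: str = "excess_decay"  # or "shrink"
    acquisition_bleach_tau_s: Optional[float] = None  # global photobleaching, off

    def __post_init__(self) -> None:
        if self.kinetics_model not in KINETICS_MODELS:
            raise ConfigError(f"kinetics_model must be one of {KINETICS_MODELS}, "
                              f"got {self.kinetics_model!r}")
        if self.tau_s <= 0:
            raise ConfigError(f"tau_s must be > 0, got {self.tau_s}")
        if self.onset_s < 0:
            raise ConfigError("onset_s must be >= 0")
        for name in ("dilute_level", "background_level", "noise_gain", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.dense_level is not None and self.dense_level < 0:
            raise ConfigError("dense_level must be >= 0")
        if self.n_droplets > 0 and self.excess_level() <= 0:
            raise ConfigError("dense phase must be brighter than dilute for "
                              "scenes with droplets (partition_coefficient > 1, "
                              "or dense_level > dilute_level)")
        if not 0 <= self.nuclear_droplet_fraction <= 1:
            raise ConfigError("nuclear_droplet_fraction must be in [0, 1]")
        if self.dissolution_mode not in ("excess_decay", "shrink"):
            raise ConfigError(f"unknown dissolution_mode {self.dissolution_mode!r}")
        rmin, rmax = self.droplet_radius_px
        if rmin <= 0 or rmax < rmin:
            raise ConfigError("droplet_radius_px must satisfy 0 < min <= max")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be > 0")
        if (self.nucleus_center_yx is None) != (self.nucleus_semi_axes_yx is None):
            raise ConfigError("nucleus center and semi-axes must be given together")
        if self.nuclear_droplet_fraction > 0 and self.nucleus_center_yx is None:
            raise ConfigError("nuclear droplets require a nucleus ellipse")

    @property
    def noise_enabled(self) -> bool:
        return self.noise_gain > 0 or self.read_noise_sd > 0

    def excess_level(self) -> float:
        """Dense-phase expected intensity above the dilute pool at t = 0."""
        if self.dense_level is not None:
            return self.dense_level - self.dilute_level
        return self.dilute_level * (self.partition_coefficient - 1.0)

    def true_partition(self) -> float:
        dense = self.dilute_level + self.excess_level()
        if self.dilute_level == 0:
            return float("inf") if dense > 0 else 1.0
        return dense / self.dilute_level

    def resolved_cell(self) -> Tuple[Tuple[float, float], Tuple[float, float]]:
        ny, nx = self.image_shape
        center = self.cell_center_yx or ((ny - 1) / 2.0, (nx - 1) / 2.0)
        axes = self.cell_semi_axes_yx or (0.4 * ny, 0.4 * nx)
        return tuple(center), tuple(axes)

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        fields_ = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - fields_
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("image_shape", "cell_center_yx", "cell_semi_axes_yx",
                    "nucleus_center_yx", "nucleus_semi_axes_yx", "droplet_radius_px"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class Droplet:
    center_yx: Tuple[float, float]
    radius_px: float
    in_nucleus: bool = False


@dataclass
class GroundTruth:
    """Simulator-side record of the true scene, for parameter-recovery tests."""

    true_condensate_mask: np.ndarray  # (T, Y, X) bool
    true_cell_mask: np.ndarray  # (Y, X) bool
    true_fraction: np.ndarray  # (T,)
    true_tau_s: float
    true_partition_coefficient: float
    seed: int
    true_efficiency_percent: Optional[float] = None
    true_nucleus_mask: Optional[np.ndarray] = None
    droplets: List[Droplet] = field(default_factory=list)
    droplet_coverage: Optional[np.ndarray] = None  # (Y, X) area fractions at t=0
    times_s: Optional[np.ndarray] = None
    # FRAP-specific truth
    bleach_region: Optional[np.ndarray] = None
    bleach_index: Optional[int] = None
    true_mobile_fraction: Optional[float] = None
    true_exchange_tau_s: Optional[float] = None
    true_trace: Optional[FRAPTrace] = None
    # endpoint-pair truth
    true_intensity_ratio_a: Optional[float] = None
    true_intensity_ratio_b: Optional[float] = None


# ----------------------------------------------------------------- geometry

def _ellipse_mask(shape, center_yx, semi_axes_yx) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = center_yx
    ay, ax = semi_axes_yx
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _disc_coverage(shape, center_yx, radius_px) -> np.ndarray:
    """Anti-aliased disc: per-pixel coverage approximated by a linear edge ramp."""
    cov = np.zeros(shape)
    cy, cx = center_yx
    r = radius_px
    y0, y1 = int(max(0, np.floor(cy - r - 1))), int(min(shape[0], np.ceil(cy + r + 2)))
    x0, x1 = int(max(0, np.floor(cx - r - 1))), int(min(shape[1], np.ceil(cx + r + 2)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    cov[y0:y1, x0:x1] = np.clip(r + 0.5 - dist, 0.0, 1.0)
    return cov


def _inside_ellipse_with_margin(center_yx, ellipse, margin) -> bool:
    (cy, cx), (ay, ax) = ellipse
    ay_m, ax_m = ay - margin, ax - margin
    if ay_m <= 0 or ax_m <= 0:
        return False
    y, x = center_yx
    return ((y - cy) / ay_m) ** 2 + ((x - cx) / ax_m) ** 2 <= 1.0


def place_droplets(config: SimulationConfig, max_tries: int = 200) -> List[Droplet]:
    """Sample non-overlapping droplets fully inside the cell (and optionally nucleus).

    Raises
    ------
    PlacementError
        If a droplet cannot be placed after ``max_tries`` rejection-sampling
        attempts (cell too crowded or radii too large).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    cell = config.resolved_cell()
    nucleus = None
    if config.nucleus_center_yx is not None:
        nucleus = (tuple(config.nucleus_center_yx), tuple(config.nucleus_semi_axes_yx))
    n_nuclear = int(round(config.nuclear_droplet_fraction * config.n_droplets))

    droplets: List[Droplet] = []
    rmin, rmax = config.droplet_radius_px
    (cy, cx), (ay, ax) = cell
    for i in range(config.n_droplets):
        in_nucleus = i < n_nuclear
        target = nucleus if in_nucleus else cell
        for attempt in range(max_tries):
            r = rng.uniform(rmin, rmax)
            y = rng.uniform(cy - ay, cy + ay)
            x = rng.uniform(cx - ax, cx + ax)
            if not _inside_ellipse_with_margin((y, x), target, r + 1.0):
                continue
            if not in_nucleus and nucleus is not None and _inside_ellipse_with_margin(
                    (y, x), nucleus, -(r + 1.0)):
                continue  # cytosolic droplet landed in the nucleus
            if any(np.hypot(y - d.center_yx[0], x - d.center_yx[1])
                   < r + d.radius_px + 1.0 for d in droplets):
                continue
            droplets.append(Droplet((y, x), r, in_nucleus))
            break
        else:
            raise PlacementError(
                f"could not place droplet {i + 1}/{config.n_droplets} inside the "
                f"{'nucleus' if in_nucleus else 'cell'} after {max_tries} tries"
            )
    return droplets


# ----------------------------------------------------------------- kinetics

def kinetics_factor(t, model: str, tau_s: float, onset_s: float):
    """Fraction of the initial dense-phase excess remaining at time t.

    constant: 1.  exponential_decay: 1 before onset, exp(-(t-onset)/tau)
    after.  sigmoid_decay: the pure logistic 1/(1 + exp((t - t_half)/tau))
    with midpoint t_half = onset + 3 tau, so the factor is within 5% of 1 at
    onset and the rendered timecourse is exactly the logistic that the
    kinetics fitter assumes.  sigmoid_growth: the mirrored rising logistic.
    Decay factors are non-increasing in t, growth non-decreasing.
    """
    t = np.asarray(t, dtype=np.float64)
    if model == "constant":
        return np.ones_like(t)
    if model == "exponential_decay":
        return np.where(t <= onset_s, 1.0, np.exp(-(np.maximum(t, onset_s) - onset_s) / tau_s))
    t_half = onset_s + SIGMOID_MIDPOINT_TAUS * tau_s
    if model == "sigmoid_decay":
        return 1.0 / (1.0 + np.exp((t - t_half) / tau_s))
    if model == "sigmoid_growth":
        return 1.0 / (1.0 + np.exp(-(t - t_half) / tau_s))
    raise ConfigError(f"unknown kinetics model {model!r}")


def true_fraction_closed_form(config: SimulationConfig, t, area_droplet: float,
                              area_cell: float):
    """Closed-form expected condensate fraction at time t.

    fraction(t) = E0 * f(t) * A_drop / (D0 * A_cell + E0 * A_drop) with
    E0 = dilute_level * (P - 1) the initial excess, f the kinetics factor.
    """
    excess0 = config.excess_level()
    f = kinetics_factor(t, config.kinetics_model, config.tau_s, config.onset_s)
    total = config.dilute_level * area_cell + excess0 * area_droplet
    return excess0 * f * area_droplet / total


# ----------------------------------------------------------------- rendering

def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1, frame_index]))


def _apply_noise(expected: np.ndarray, config: SimulationConfig,
                 frame_index: int) -> np.ndarray:
    if not config.noise_enabled:
        return expected
    rng = _frame_rng(config.seed, frame_index)
    out = expected
    if config.noise_gain > 0:
        out = rng.poisson(expected / config.noise_gain).astype(np.float64) * config.noise_gain
    if config.read_noise_sd > 0:
        out = out + rng.normal(0.0, config.read_noise_sd, size=expected.shape)
    return np.maximum(out, 0.0)


def _scene_geometry(config: SimulationConfig):
    cell_center, cell_axes = config.resolved_cell()
    cell_mask = _ellipse_mask(config.image_shape, cell_center, cell_axes)
    nucleus_mask = None
    if config.nucleus_center_yx is not None:
        nucleus_mask = _ellipse_mask(config.image_shape, config.nucleus_center_yx,
                                     config.nucleus_semi_axes_yx)
    droplets = place_droplets(config)
    coverage = np.zeros(config.image_shape)
    for d in droplets:
        coverage += _disc_coverage(config.image_shape, d.center_yx, d.radius_px)
    coverage = np.clip(coverage, 0.0, 1.0)
    return cell_mask, nucleus_mask, droplets, coverage


def simulate_dissolution_movie(config: SimulationConfig) -> Tuple[ImageStack, GroundTruth]:
    """Render a condensate-disruption timelapse with exact ground truth.

    The dense-phase excess decays per ``config.kinetics_model`` from
    ``onset_s`` with time constant ``tau_s``; the lost integrated intensity
    reappears uniformly in the dilute pool inside the cell, so the total
    expected photon count is constant across frames.  Growth models are also
    accepted (the "dissolution" is then a formation timecourse).
    """
    cell_mask, nucleus_mask, droplets, coverage = _scene_geometry(config)
    times = config.times_s()
    f = kinetics_factor(times, config.kinetics_model, config.tau_s, config.onset_s)

    excess0 = config.excess_level()
    area_cell = float(cell_mask.sum())
    area_drop0 = float(coverage.sum())
    total_excess0 = excess0 * area_drop0

    frames = np.empty((config.n_frames,) + tuple(config.image_shape))
    masks = np.empty((config.n_frames,) + tuple(config.image_shape), dtype=bool)
    fractions = np.empty(config.n_frames)
    denom = config.dilute_level * area_cell + total_excess0

    for i, (t, fi) in enumerate(zip(times, f)):
        if config.dissolution_mode == "shrink" and config.kinetics_model != "constant":
            # dense area shrinks so integrated excess tracks f (radius ~ sqrt(f))
            cov_t = np.zeros(config.image_shape)
            for d in droplets:
                r_t = d.radius_px * np.sqrt(fi)
                if r_t > 0.05:
                    cov_t += _disc_coverage(config.image_shape, d.center_yx, r_t)
            cov_t = np.clip(cov_t, 0.0, 1.0)
            dense_excess = excess0 * cov_t
        else:
            cov_t = coverage
            dense_excess = excess0 * fi * coverage
        excess_integral = float(dense_excess.sum())
        dilute_t = config.dilute_level + (total_excess0 - excess_integral) / area_cell
        fluor = cell_mask * dilute_t + dense_excess
        if config.acquisition_bleach_tau_s is not None:
            fluor = fluor * np.exp(-t / config.acquisition_bleach_tau_s)
        expected = config.background_level + fluor
        frames[i] = _apply_noise(expected, config, i)
        alive = (excess_integral / total_excess0 > MASK_EXTINCTION_FRACTION
                 if total_excess0 > 0 else False)
        masks[i] = (cov_t >= 0.5) & alive
        fractions[i] = excess_integral / denom if denom > 0 else 0.0

    efficiency = None
    if fractions[0] > 0:
        efficiency = 100.0 * (fractions[0] - fractions[-1]) / fractions[0]

    stack = ImageStack(frames, times, "scaffold",
                       meta={"simulated": True, "seed": config.seed,
                             "kinetics_model": config.kinetics_model})
    truth = GroundTruth(
        true_condensate_mask=masks,
        true_cell_mask=cell_mask,
        true_fraction=fractions,
        true_tau_s=config.tau_s,
        true_partition_coefficient=config.true_partition(),
        seed=config.seed,
        true_efficiency_percent=efficiency,
        true_nucleus_mask=nucleus_mask,
        droplets=droplets,
        droplet_coverage=coverage,
        times_s=times,
    )
    logger.info("simulated dissolution movie: %d frames, %d droplets, "
                "fraction[0]=%.4f", config.n_frames, len(droplets), fractions[0])
    return stack, truth


def default_bleach_region(config: SimulationConfig,
                          droplets: Sequence[Droplet]) -> np.ndarray:
    """Disc mask one pixel inside the largest droplet (the typical bleach spot)."""
    biggest = max(droplets, key=lambda d: d.radius_px)
    cov = _disc_coverage(config.image_shape, biggest.center_yx,
                         max(biggest.radius_px - 1.0, 1.0))
    return cov >= 0.999


def simulate_frap_movie(
    config: SimulationConfig,
    bleach_frame: int,
    bleach_region: Optional[np.ndarray] = None,
    bleach_depth: float = 0.7,
    mobile_fraction: float = 0.5,
    exchange_tau_s: float = 30.0,
) -> Tuple[ImageStack, GroundTruth]:
    """Render a photobleaching-recovery movie on a static condensate scene.

    At ``bleach_frame`` the expected signal inside ``bleach_region`` (default:
    a spot inside the largest droplet) drops by ``bleach_depth``.  The region
    then relaxes toward the post-bleach cell-average concentration with time
    constant ``exchange_tau_s``; only ``mobile_fraction`` of the species
    exchanges.  The recovered signal is drawn from the rest of the cell
    (conservative exchange), so the post-bleach total stays constant and the
    normalized FRAP plateau equals the mobile fraction exactly.
    """
    if not 0 <= bleach_depth <= 1:
        raise ConfigError("bleach_depth must be in [0, 1]")
    if not 0 <= mobile_fraction <= 1:
        raise ConfigError("mobile_fraction must be in [0, 1]")
    if exchange_tau_s <= 0:
        raise ConfigError("exchange_tau_s must be > 0")
    cfg = replace(config, kinetics_model="constant")
    cell_mask, nucleus_mask, droplets, coverage = _scene_geometry(cfg)
    if not 0 < bleach_frame < cfg.n_frames:
        raise ConfigError(f"bleach_frame {bleach_frame} must leave at least one "
                          f"pre-bleach frame within the {cfg.n_frames}-frame movie")
    if bleach_region is None:
        bleach_region = default_bleach_region(cfg, droplets)
    region = np.asarray(bleach_region, dtype=bool)
    if (region & ~cell_mask).any():
        raise ConfigError("bleach_region extends outside the cell footprint")
    if not region.any():
        raise ConfigError("bleach_region is empty")

    excess0 = cfg.excess_level()
    base_fluor = cell_mask * cfg.dilute_level + excess0 * coverage
    times = cfg.times_s()
    t_bleach = times[bleach_frame]

    B = float(base_fluor[region].sum())  # region integrated, pre-bleach
    T = float(base_fluor[cell_mask].sum())  # whole-cell integrated
    T_post = T - bleach_depth * B
    # full exchange returns the region to the cell-average concentration of
    # the diminished fluorescent pool, not to its absolute pre-bleach count
    eq_region = base_fluor * (T_post / T)
    rest = cell_mask & ~region
    area_rest = float(rest.sum())

    frames = np.empty((cfg.n_frames,) + tuple(cfg.image_shape))
    true_bleach = np.empty(cfg.n_frames)
    true_total = np.empty(cfg.n_frames)
    for i, t in enumerate(times):
        fluor = base_fluor.copy()
        if i >= bleach_frame:
            bleached = base_fluor * (1.0 - bleach_depth)
            recov = mobile_fraction * (1.0 - np.exp(-(t - t_bleach) / exchange_tau_s))
            region_now = bleached + recov * (eq_region - bleached)
            gained = float((region_now - bleached)[region].sum())
            fluor[region] = region_now[region]
            fluor[rest] -= gained / area_rest
        if cfg.acquisition_bleach_tau_s is not None:
            fluor = fluor * np.exp(-t / cfg.acquisition_bleach_tau_s)
        true_bleach[i] = float(fluor[region].sum())
        true_total[i] = float(fluor[cell_mask].sum())
        frames[i] = _apply_noise(cfg.background_level + fluor, cfg, i)

    stack = ImageStack(frames, times, "scaffold",
                       meta={"simulated": True, "seed": cfg.seed, "frap": True})
    area_drop = float(coverage.sum())
    fraction0 = (excess0 * area_drop / T) if T > 0 else 0.0
    truth = GroundTruth(
        true_condensate_mask=np.broadcast_to(coverage >= 0.5,
                                             frames.shape).copy(),
        true_cell_mask=cell_mask,
        true_fraction=np.full(cfg.n_frames, fraction0),
        true_tau_s=exchange_tau_s,
        true_partition_coefficient=cfg.true_partition(),
        seed=cfg.seed,
        true_nucleus_mask=nucleus_mask,
        droplets=droplets,
        droplet_coverage=coverage,
        times_s=times,
        bleach_region=region,
        bleach_index=bleach_frame,
        true_mobile_fraction=mobile_fraction,
        true_exchange_tau_s=exchange_tau_s,
        true_trace=FRAPTrace(times, true_bleach, true_total, bleach_frame),
    )
    return stack, truth


def matched_blocked_config(config: SimulationConfig) -> SimulationConfig:
    """Blocked-counterpart config: no droplets, dilute level raised so the
    total expected cell fluorescence matches the condensate-forming scene."""
    cell_mask, _, _, coverage = _scene_geometry(config)
    excess0 = config.excess_level()
    area_cell = float(cell_mask.sum())
    total = config.dilute_level * area_cell + excess0 * float(coverage.sum())
    return replace(config, n_droplets=0, partition_coefficient=1.0,
                   dilute_level=total / area_cell, kinetics_model="constant",
                   n_frames=1)


def simulate_blocking_endpoint(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
) -> Tuple[ImageStack, ImageStack, GroundTruth]:
    """Matched pair of single-frame endpoint scenes (e.g. untreated vs blocked).

    Both configs must share the cell geometry; they should share the total
    expected cell fluorescence (see :func:`matched_blocked_config`).  Ground
    truth carries each scene's condensate intensity ratio — the integrated
    expected intensity over the droplet support divided by the whole-cell
    integrated expected intensity (background-free).
    """
    if (config_a.image_shape != config_b.image_shape
            or config_a.resolved_cell() != config_b.resolved_cell()):
        raise ConfigError("endpoint pair must share image shape and cell geometry")

    ratios = []
    stacks = []
    cell_mask = None
    for cfg in (config_a, config_b):
        cfg1 = replace(cfg, n_frames=1, kinetics_model="constant")
        stack, truth = simulate_dissolution_movie(cfg1) if cfg1.n_droplets > 0 \
            else _render_dropletless(cfg1)
        cell_mask = truth.true_cell_mask
        excess0 = cfg1.excess_level()
        cov = truth.droplet_coverage
        fluor = cell_mask * cfg1.dilute_level + excess0 * cov
        total = float(fluor[cell_mask].sum())
        support = cov > 0
        ratios.append(float(fluor[support].sum()) / total if total > 0 else 0.0)
        stacks.append(stack)

    truth = GroundTruth(
        true_condensate_mask=np.zeros((1,) + tuple(config_a.image_shape), dtype=bool),
        true_cell_mask=cell_mask,
        true_fraction=np.zeros(1),
        true_tau_s=config_a.tau_s,
        true_partition_coefficient=config_a.partition_coefficient,
        seed=config_a.seed,
        true_intensity_ratio_a=ratios[0],
        true_intensity_ratio_b=ratios[1],
    )
    return stacks[0], stacks[1], truth


def _render_dropletless(config: SimulationConfig) -> Tuple[ImageStack, GroundTruth]:
    """Single-cell scene with no droplets (blocked condensate formation)."""
    cell_center, cell_axes = config.resolved_cell()
    cell_mask = _ellipse_mask(config.image_shape, cell_center, cell_axes)
    times = config.times_s()
    frames = np.empty((config.n_frames,) + tuple(config.image_shape))
    for i, t in enumerate(times):
        fluor = cell_mask * config.dilute_level
        if config.acquisition_bleach_tau_s is not None:
            fluor = fluor * np.exp(-t / config.acquisition_bleach_tau_s)
        frames[i] = _apply_noise(config.background_level + fluor, config, i)
    stack = ImageStack(frames, times, "scaffold",
                       meta={"simulated": True, "seed": config.seed})
    truth = GroundTruth(
        true_condensate_mask=np.zeros(frames.shape, dtype=bool),
        true_cell_mask=cell_mask,
        true_fraction=np.zeros(config.n_frames),
        true_tau_s=config.tau_s,
        true_partition_coefficient=1.0,
        seed=config.seed,
        droplet_coverage=np.zeros(config.image_shape),
        times_s=times,
    )
    return stack, truth
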