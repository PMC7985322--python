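"""End-to-end runs: simulate/load -> segment -> quantify -> kinetics/FRAP.

A :class:`RunConfig` fully determines a run; every setting is echoed into the
output manifest and all randomness flows from the single seed, so re-running
an identical config reproduces numerically identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import frap as frap_mod
from . import io as pio
from .errors import ConfigError
from .kinetics import KineticFit, condensate_timecourse, fit_exponential, fit_sigmoid
from .quantify import disruption_efficiency, estimate_background, partition_stats
from .segment import DEFAULT_MIN_OBJECT_PX, max_project, segment_stack
from .simulate import SimulationConfig, simulate_dissolution_movie, simulate_frap_movie
from .stack import ImageStack

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one reproducible pipeline run."""

    out_dir: str = "punctakit_run"
    seed: int = 0
    # input: either a simulation config or a TIFF path
    simulation: Optional[SimulationConfig] = None
    input_path: Optional[str] = None
    frame_interval_s: Optional[float] = None
    n_z: Optional[int] = None
    # segmentation
    condensate_method: str = "otsu"
    cell_method: str = "mean"
    min_object_px: int = DEFAULT_MIN_OBJECT_PX
    reference_frame: Optional[int] = 0
    freeze_mask: bool = True
    # quantification
    pre_frame: Optional[int] = None  # default: last frame at/before onset
    post_frame: Optional[int] = None  # default: last frame
    background: Union[str, float] = "auto"
    # kinetics
    fit_model: str = "sigmoid"  # sigmoid | exponential | none
    onset_s: Optional[float] = None
    observable: str = "fraction"
    # frap (only for frap runs)
    bleach_frame: Optional[int] = None
    bleach_depth: float = 0.7
    mobile_fraction: float = 0.5
    exchange_tau_s: float = 30.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_path is None):
            raise ConfigError("exactly one of simulation / input_path must be set")
        if self.fit_model not in ("sigmoid", "exponential", "none"):
            raise ConfigError(f"unknown fit_model {self.fit_model!r}")
        if isinstance(self.background, str) and self.background != "auto":
            raise ConfigError("background must be 'auto' or a number")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        fields_ = set(cls.__dataclass_fields__)
        unknown = set(data) - fields_
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        data = dict(data)
        if isinstance(data.get("simulation"), dict):
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        return cls(**data)


@dataclass
class RunManifest:
    """Record of a completed run: provenance, outputs, and headline numbers."""

    tool_version: str
    config: dict
    config_hash: str
    input_checksums: dict = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    started_at: str = ""
    finished_at: str = ""
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _resolve_stack(config: RunConfig):
    """Input stage: simulate a movie or read one from disk."""
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
        stack, truth = simulate_dissolution_movie(sim)
        return stack, truth, sim, {}
    stack = pio.read_stack(config.input_path,
                           frame_interval_s=config.frame_interval_s,
                           n_z=config.n_z)
    checksums = {config.input_path: pio.sha256_file(config.input_path)}
    return stack, None, None, checksums


def _backgrounds(config: RunConfig, stack: ImageStack, segs) -> List[float]:
    if config.background == "auto":
        return [estimate_background(stack.frame(i), segs[i].cell_mask)
                for i in range(stack.n_frames)]
    return [float(config.background)] * stack.n_frames


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute simulate/load -> segment -> quantify -> fit and write all outputs.

    Writes per-frame masks (TIFF), the partition table, the disruption result,
    the kinetic fit table, and a fit-overlay plot into ``config.out_dir``,
    plus a JSON manifest listing them.  Any stage failure propagates with the
    stage named in the log.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outputs: List[str] = []

    logger.info("stage: input")
    stack, truth, sim, checksums = _resolve_stack(config)
    if stack.has_z:
        stack = max_project(stack)

    onset = config.onset_s
    if onset is None:
        onset = sim.onset_s if sim is not None else 0.0

    logger.info("stage: segment")
    segs = segment_stack(stack, config.condensate_method, config.cell_method,
                         config.min_object_px, config.reference_frame,
                         freeze_mask=config.freeze_mask)
    mask_path = out / "condensate_masks.tif"
    pio.write_mask(mask_path, np.stack([s.condensate_mask for s in segs]))
    outputs.append(str(mask_path))
    cell_path = out / "cell_mask.tif"
    pio.write_mask(cell_path, segs[0].cell_mask)
    outputs.append(str(cell_path))

    logger.info("stage: quantify")
    backgrounds = _backgrounds(config, stack, segs)
    measurements = [partition_stats(stack.frame(i), segs[i], backgrounds[i])
                    for i in range(stack.n_frames)]
    table = pd.DataFrame({
        "frame": np.arange(stack.n_frames),
        "time_s": stack.times_s,
        "area_dense_px": [m.area_dense for m in measurements],
        "mean_dense": [m.mean_dense for m in measurements],
        "mean_dilute": [m.mean_dilute for m in measurements],
        "total_integrated_density": [m.total_integrated_density for m in measurements],
        "fraction_in_condensate": [m.fraction_in_condensate for m in measurements],
        "background": backgrounds,
        "threshold": [s.threshold_value for s in segs],
        "method": [s.method for s in segs],
        "seed": config.seed,
    })
    partition_path = pio.write_table(out / "partition.csv", table)
    outputs.append(str(partition_path))

    pre = config.pre_frame
    if pre is None:
        at_onset = np.nonzero(stack.times_s <= onset)[0]
        pre = int(at_onset[-1]) if len(at_onset) else 0
    post = config.post_frame if config.post_frame is not None else stack.n_frames - 1
    disruption = disruption_efficiency(measurements[pre], measurements[post])
    dis_table = pd.DataFrame([{
        "pre_frame": pre, "post_frame": post,
        "fraction_pre": disruption.fraction_pre,
        "fraction_post": disruption.fraction_post,
        "efficiency_percent": disruption.efficiency_percent,
        "dense_dilute_ratio": disruption.dense_dilute_ratio,
        "flags": ";".join(disruption.flags),
    }])
    dis_path = pio.write_table(out / "disruption.csv", dis_table)
    outputs.append(str(dis_path))

    summary = {
        "fraction_pre": disruption.fraction_pre,
        "fraction_post": disruption.fraction_post,
        "efficiency_percent": disruption.efficiency_percent,
    }
    if truth is not None and truth.true_efficiency_percent is not None:
        summary["true_efficiency_percent"] = truth.true_efficiency_percent

    fit: Optional[KineticFit] = None
    if config.fit_model != "none":
        logger.info("stage: kinetics")
        tc = condensate_timecourse(stack, segs, backgrounds, onset_s=onset,
                                   observable=config.observable)
        tc_path = pio.write_table(out / "timecourse.csv",
                                  pd.DataFrame({"time_s": tc.times_s,
                                                "value": tc.values}))
        outputs.append(str(tc_path))
        fit = (fit_sigmoid(tc) if config.fit_model == "sigmoid"
               else fit_exponential(tc, t_start_s=onset))
        fit_table = pd.DataFrame([{
            "model": fit.model, "base": fit.base, "amplitude": fit.amplitude,
            "t_half_s": fit.t_half_s, "tau_s": fit.tau_s,
            "r_squared": fit.r_squared, "converged": fit.converged,
            **{f"se_{k}": v for k, v in fit.param_uncertainties.items()},
        }])
        fit_path = pio.write_table(out / "kinetic_fit.csv", fit_table)
        outputs.append(str(fit_path))
        plot_path = out / "fit_overlay.png"
        _plot_fit(tc, fit, plot_path)
        outputs.append(str(plot_path))
        summary["tau_s"] = fit.tau_s
        summary["fit_converged"] = fit.converged
        if truth is not None:
            summary["true_tau_s"] = truth.true_tau_s

    run_config_dict = config.to_dict()
    manifest = RunManifest(
        tool_version=_version,
        config=run_config_dict,
        config_hash=pio.config_hash(run_config_dict),
        input_checksums=checksums,
        outputs=outputs,
        started_at=started,
        finished_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
        summary=summary,
    )
    pio.write_manifest(out / "manifest.json", manifest.to_dict())
    logger.info("run complete: %s", summary)
    return manifest


def run_frap_pipeline(config: RunConfig) -> RunManifest:
    """Simulate a FRAP movie, extract and normalize the trace, fit the recovery."""
    if config.simulation is None or config.bleach_frame is None:
        raise ConfigError("FRAP runs need a simulation config and bleach_frame")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    sim = config.simulation
    if sim.seed != config.seed:
        sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
    stack, truth = simulate_frap_movie(
        sim, config.bleach_frame, bleach_depth=config.bleach_depth,
        mobile_fraction=config.mobile_fraction,
        exchange_tau_s=config.exchange_tau_s)

    background = (float(config.background)
                  if config.background != "auto" else sim.background_level)
    trace = frap_mod.measure_frap_trace(stack, truth.bleach_region,
                                        truth.true_cell_mask,
                                        config.bleach_frame, background)
    trace = frap_mod.normalize_frap(trace)
    table = pd.DataFrame({
        "time_s": trace.times_s,
        "raw_bleach_integrated": trace.raw_bleach_integrated,
        "raw_total_integrated": trace.raw_total_integrated,
        "normalized": trace.normalized,
    })
    trace_path = pio.write_table(out / "frap_trace.csv", table)
    fit = frap_mod.fit_recovery(trace)
    summary = {
        "bleach_depth_measured": frap_mod.bleach_depth(trace),
        "mobile_fraction_estimate": fit.base if fit.converged else float("nan"),
        "exchange_tau_s_estimate": fit.tau_s if fit.converged else float("nan"),
        "true_mobile_fraction": truth.true_mobile_fraction,
    }
    run_config_dict = config.to_dict()
    manifest = RunManifest(
        tool_version=_version,
        config=run_config_dict,
        config_hash=pio.config_hash(run_config_dict),
        outputs=[str(trace_path)],
        started_at=started,
        finished_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
        summary=summary,
    )
    pio.write_manifest(out / "manifest.json", manifest.to_dict())
    return manifest


def _plot_fit(tc, fit: KineticFit, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(tc.times_s, tc.values, "o", ms=3, label="data")
    if fit.converged:
        tt = np.linspace(tc.times_s[0], tc.times_s[-1], 300)
        if fit.model == "sigmoid":
            vv = fit.base + fit.amplitude / (1 + np.exp((tt - fit.t_half_s) / fit.tau_s))
        else:
            tt = tt[tt >= fit.t_start_s]
            vv = fit.base + fit.amplitude * np.exp(-(tt - fit.t_start_s) / fit.tau_s)
        ax.plot(tt, vv, "-", label=f"{fit.model} fit, tau = {fit.tau_s:.1f} s")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(tc.observable)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
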