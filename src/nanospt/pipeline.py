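"""End-to-end orchestration: simulate → detect → track → quantify → dynamics.

A run is fully described by a :class:`RunConfig` (serialisable, strict —
unknown keys are refused).  Every output file is prefixed with the
12-character hash of the resolved configuration, and a run record embeds
the resolved configuration and package version, so any artefact can be
traced to the exact run that produced it.  Runs are deterministic under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import chemotaxis as chemo
from . import detect as det
from . import diffusion as diff
from . import intensity as inten
from . import io as nio
from . import simulate as sim

logger = logging.getLogger("nanospt")


@dataclass
class DetectionParams:
    psf_sigma_px: float = 1.0
    snr_min: float = 4.0


@dataclass
class LinkingParams:
    max_disp_px: Optional[float] = None  # None: derived from D_max = 0.2 μm²/s
    max_gap: int = 2


@dataclass
class IntensityParams:
    window_frames: int = 20
    background_quantile: float = 0.80
    truncate_at_step: bool = True
    calibration_particles: int = 2000


@dataclass
class DiffusionParams:
    min_track_len: int = 20
    # conservative default covering the dimmest particles; None estimates
    # it from the MSD-fit intercepts instead
    loc_noise_sd_um: Optional[float] = 0.03
    threshold_n_sim: int = 2000
    threshold_percentile: float = 99.0
    d_immobile_um2_s: Optional[float] = None  # overrides the calibrated threshold


@dataclass
class ChemotaxisParams:
    enabled: bool = False
    n_cells: int = 100
    n_steps: int = 80
    step_um: float = 5.0
    bias: float = 0.3


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "nanospt_run"
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    intensity: IntensityParams = field(default_factory=IntensityParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    chemotaxis: ChemotaxisParams = field(default_factory=ChemotaxisParams)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs: dict[str, Any] = {}
        blocks = {"detection": DetectionParams, "linking": LinkingParams,
                  "intensity": IntensityParams, "diffusion": DiffusionParams,
                  "chemotaxis": ChemotaxisParams}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for name, block_cls in blocks.items():
            if name in data:
                block = data.pop(name)
                names = {f.name for f in dataclasses.fields(block_cls)}
                bad = set(block) - names
                if bad:
                    raise ValueError(
                        f"unknown keys in '{name}' block: {sorted(bad)}")
                kwargs[name] = block_cls(**block)
        if "simulation" in data:
            simblock = data.pop("simulation")
            names = {f.name for f in dataclasses.fields(sim.SimulationConfig)}
            bad = set(simblock) - names
            if bad:
                raise ValueError(f"unknown keys in 'simulation' block: {sorted(bad)}")
            kwargs["simulation"] = simblock
        kwargs.update(data)
        return cls(**kwargs)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation_config())
        d["simulation"]["stoichiometry_pmf"] = {
            str(k): v for k, v in d["simulation"]["stoichiometry_pmf"].items()}
        return d

    def simulation_config(self) -> sim.SimulationConfig:
        block = dict(self.simulation)
        if "stoichiometry_pmf" in block:
            block["stoichiometry_pmf"] = {
                int(k): float(v) for k, v in block["stoichiometry_pmf"].items()}
        block.setdefault("seed", self.seed)
        return sim.SimulationConfig(**block)


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s: FAILED after %.2fs", name, dt)
                raise RuntimeError(f"pipeline stage '{name}' failed") from exc
            report.setdefault("stage_seconds", {})[name] = round(dt, 3)
            logger.info("stage %s: done in %.2fs", name, dt)
    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    cfg = config
    resolved = cfg.resolved()
    # the hash identifies the analysis, not where it is written
    chash = nio.config_hash({k: v for k, v in resolved.items() if k != "out_dir"})
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = out / f"{chash}"
    report: dict[str, Any] = {"config_hash": chash, "version": __version__}

    simcfg = cfg.simulation_config()
    with _stage(report, "simulate"):
        stack, gt = sim.simulate_receptor_movie(simcfg)
        nio.write_stack(stack, f"{prefix}_stack.tif")
        gt.particles.to_csv(f"{prefix}_ground_truth_particles.csv", index=False)
        report["n_true_particles"] = gt.n_particles

    with _stage(report, "calibrate"):
        calcfg = dataclasses.replace(
            sim.monomer_config(simcfg),
            n_particles=cfg.intensity.calibration_particles,
            seed=cfg.seed + 1)
        cal_tracks, _ = sim.simulate_trajectories(calcfg)
        calibration, bleach = inten.calibrate_monomer(
            cal_tracks, simcfg.frame_interval_s,
            window_frames=cfg.intensity.window_frames)
        window_ok = inten.check_window_vs_bleaching(
            cfg.intensity.window_frames, bleach)
        report["calibration"] = {
            "mu_mono_au": calibration.mu_mono,
            "sigma_mono_au": calibration.sigma_mono,
            "n_particles": calibration.n_particles,
            "tau0_s": bleach.tau0_s,
            "tau0_frames": bleach.tau0_frames,
            "window_frames_ok": window_ok,
        }

    with _stage(report, "detect_track"):
        max_disp = cfg.linking.max_disp_px or det.default_max_disp_px(
            simcfg.pixel_size_um, simcfg.frame_interval_s)
        detections = det.detect_stack(stack, cfg.detection.psf_sigma_px,
                                      cfg.detection.snr_min)
        tracks = det.link_tracks(detections, max_disp_px=max_disp,
                                 max_gap=cfg.linking.max_gap)
        nio.write_tracks(tracks, f"{prefix}_tracks.csv")
        report["n_detections"] = int(len(detections))
        report["n_tracks"] = int(tracks["track_id"].nunique()) if len(tracks) else 0

    with _stage(report, "background"):
        mask = inten.segment_cell(stack)
        background = inten.estimate_background(
            stack, mask, detections, q=cfg.intensity.background_quantile)
        report["background_k0_mean_au"] = float(np.mean(background.k0))

    with _stage(report, "quantify"):
        traces = inten.extract_traces(tracks, stack, background,
                                      psf_sigma_px=cfg.detection.psf_sigma_px)
        particles = inten.summarize_particles(
            traces, calibration, window_frames=cfg.intensity.window_frames,
            truncate_at_step=cfg.intensity.truncate_at_step)
        particles.to_csv(f"{prefix}_particles.csv", index=False)
        group = inten.classify_aggregation(particles) if len(particles) else None
        report["stoichiometry"] = (
            dataclasses.asdict(group) if group else {"n_particles": 0})

    with _stage(report, "dynamics"):
        estimates = diff.analyze_tracks(
            tracks, simcfg.pixel_size_um, simcfg.frame_interval_s,
            min_track_len=cfg.diffusion.min_track_len)
        if cfg.diffusion.d_immobile_um2_s is not None:
            d_imm = cfg.diffusion.d_immobile_um2_s
        else:
            loc_sd = cfg.diffusion.loc_noise_sd_um
            if loc_sd is None:
                loc_sd = diff.estimate_loc_noise(estimates) if len(estimates) else 0.03
            report["loc_noise_sd_um"] = loc_sd
            d_imm = diff.immobile_threshold(
                loc_sd, simcfg.frame_interval_s,
                n_sim=cfg.diffusion.threshold_n_sim,
                n_frames=max(cfg.diffusion.min_track_len,
                             int(estimates["n_frames"].median()) if len(estimates) else 100),
                seed=cfg.seed + 2,
                percentile=cfg.diffusion.threshold_percentile)
        classified = (diff.classify_mobility(estimates, d_imm)
                      if len(estimates) else estimates)
        classified.to_csv(f"{prefix}_diffusion.csv", index=False)
        report["mobility"] = (
            diff.group_mobility_summary(classified) if len(classified)
            else {"n_tracks": 0})
        report["mobility"]["d_immobile_um2_s"] = d_imm

    if cfg.chemotaxis.enabled:
        with _stage(report, "chemotaxis"):
            cells, _ = sim.simulate_cell_tracks(
                cfg.chemotaxis.n_cells, cfg.chemotaxis.n_steps,
                cfg.chemotaxis.step_um, cfg.chemotaxis.bias,
                seed=cfg.seed + 3)
            nio.write_cell_tracks(cells, f"{prefix}_cell_tracks.csv")
            chemo.reorigin_tracks(cells).to_csv(
                f"{prefix}_spider_coords.csv", index=False)
            report["chemotaxis"] = chemo.group_chemotaxis_summary(cells)

    record = {"config": resolved, "report": report}
    Path(f"{prefix}_run_record.json").write_text(json.dumps(record, indent=2))
    Path(f"{prefix}_report.txt").write_text(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Human-readable run summary."""
    lines = [f"nanospt {report.get('version', '?')} run {report.get('config_hash', '?')}"]
    cal = report.get("calibration", {})
    if cal:
        lines.append(
            f"  monomer reference: {cal['mu_mono_au']:.1f} ± "
            f"{cal['sigma_mono_au']:.1f} a.u. (n={cal['n_particles']}); "
            f"tau0 = {cal['tau0_s']:.2f} s = {cal['tau0_frames']:.1f} frames; "
            f"window ok: {cal['window_frames_ok']}")
    sto = report.get("stoichiometry", {})
    if sto.get("n_particles"):
        lines.append(
            f"  particles: {sto['n_particles']}; "
            f"mono+dimer {sto['pct_mono_dimer']:.1f}% / "
            f"nanocluster {sto['pct_nanocluster']:.1f}%; "
            f"MSI {sto['msi_au']:.0f} a.u.")
    mob = report.get("mobility", {})
    if mob.get("n_tracks"):
        lines.append(
            f"  mobility: {mob['pct_mobile']:.1f}% mobile / "
            f"{mob['pct_immobile']:.1f}% immobile; median mobile D1-4 = "
            f"{mob['median_d_mobile_um2_s']:.4f} um2/s "
            f"(threshold {mob['d_immobile_um2_s']:.5f})")
    che = report.get("chemotaxis", {})
    if che:
        lines.append(
            f"  chemotaxis: n={che['n_cells']} cells, FMI_x "
            f"{che['fmi_x_mean']:.3f} ± {che['fmi_x_sd']:.3f}, straightness "
            f"{che['straightness_mean']:.3f} ± {che['straightness_sd']:.3f}")
    return "\n".join(lines) + "\n"


def compare_conditions(d_a, d_b, counts_a: dict, counts_b: dict) -> dict:
    """Paper-style statistics between two conditions.

    ``d_a``/``d_b``: D1-4 samples (mobile tracks) → two-tailed Mann-Whitney.
    ``counts_a``/``counts_b``: categorical counts with identical keys (e.g.
    mobile/immobile or mono_dimer/nanocluster) → chi-square.
    """
    from . import stats as gstats

    mw = gstats.mann_whitney_two_tailed(d_a, d_b)
    keys = sorted(counts_a)
    if sorted(counts_b) != keys:
        raise ValueError("count categories differ between conditions")
    table = [[counts_a[k] for k in keys], [counts_b[k] for k in keys]]
    chi = gstats.chi_square_contingency(table)
    return {
        "d14_mann_whitney": dataclasses.asdict(mw),
        "categorical_chi_square": dataclasses.asdict(chi),
        "categories": keys,
    }
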