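"""End-to-end demo pipeline: simulate -> detect -> invert -> track -> register.

One seeded configuration drives three stages over synthetic data: a
zero-stress calibration phantom (fixes the SBR normalization reference), a
two-region tumor scene (detection, stress inversion, CPD registration,
region statistics), and a longitudinal series (linking and loading-rate
statistics).  Outputs are CSV tables, a resolved copy of the configuration,
and a plain-text report; identical config and seed reproduce identical
files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .calibration import DEFAULT_MODEL, estimate_stress
from .errors import MechanomapError, ValidationError
from .mrsignal import detect_particles, filter_aggregates, normalize_signal
from .registration import PointCloud, assign_regions, region_stats, register_cpd, transform_points
from .synthetic import (
    NoiseSpec,
    generate_calibration_phantom,
    generate_tumor_timeseries,
    generate_two_region_scene,
)
from .tracking import classify_loading, link_particles, trajectories_to_frame, trajectory_stress

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (defaults fill every field)."""

    seed: int = 0
    output_dir: str = "pipeline_out"
    run_phantom: bool = True
    run_two_region: bool = True
    run_timeseries: bool = True
    # synthetic scene sizes
    phantom_particles: int = 30
    two_region_sensors_per_region: int = 20
    timeseries_particles: int = 15
    timeseries_sessions: tuple = (0.0, 3.0, 6.0, 9.0)
    timeseries_growth_rate: float = 0.02
    timeseries_aggregate_fraction: float = 0.1
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    # detection / exclusion thresholds
    min_contrast: float = 0.02
    min_separation_mm: float = 0.9
    sbr_max: float = 2.5
    area_max_px: int = 9
    aggregate_rule: str = "or"
    # registration
    cpd_w: float = 0.1
    cpd_beta_mm: float = 2.0
    cpd_lambda: float = 3.0
    cpd_tol: float = 1e-5
    cpd_max_iter: int = 100
    sampling_radius_mm: float = 0.3
    # tracking
    rate_threshold_kPa_per_day: float = 5.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build a config from a (YAML) mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            noise_known = {f.name for f in dataclasses.fields(NoiseSpec)}
            bad = set(d["noise"]) - noise_known
            if bad:
                raise ValidationError(f"unknown noise keys: {sorted(bad)}")
            d["noise"] = NoiseSpec(**d["noise"])
        if "timeseries_sessions" in d:
            d["timeseries_sessions"] = tuple(d["timeseries_sessions"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timeseries_sessions"] = list(self.timeseries_sessions)
        return d


@dataclass
class PipelineReport:
    seed: int
    output_dir: str
    stages: dict = field(default_factory=dict)
    report_path: str = ""

    def lines(self) -> list[str]:
        out = [f"mechanomap pipeline report (seed={self.seed})"]
        for name, info in self.stages.items():
            kv = " ".join(f"{k}={v}" for k, v in info.items())
            out.append(f"stage {name}: {kv}")
        return out


def _fmt(x: float, nd: int = 6) -> str:
    return f"{x:.{nd}g}"


def run_pipeline(config: PipelineConfig, output_dir=None) -> PipelineReport:
    """Execute the configured stages and write tables, config, and report."""
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    report = PipelineReport(seed=config.seed, output_dir=str(outdir))
    model = DEFAULT_MODEL
    reference_sbr0 = config.noise.sbr0  # design value; refined by the phantom

    detect_kw = dict(
        min_contrast=config.min_contrast,
        min_separation=config.min_separation_mm,
        sbr_max=config.sbr_max,
        area_max_px=config.area_max_px,
    )

    # ---------------- stage 1: calibration phantom ----------------------
    if config.run_phantom:
        try:
            volume, scene = generate_calibration_phantom(
                config.phantom_particles, 0.0, noise=config.noise,
                seed=int(seeds[0]),
            )
            dets = detect_particles(volume, **detect_kw)
            retained, excluded = filter_aggregates(
                dets, sbr_max=config.sbr_max, area_max_px=config.area_max_px,
                combine=config.aggregate_rule,
            )
            if retained:
                reference_sbr0 = float(np.mean([d.sbr for d in retained]))
            mio.write_detections_csv(retained, outdir / "phantom_detections.csv",
                                     session_time=0.0)
            report.stages["phantom"] = {
                "status": "complete",
                "particles": scene.n_particles,
                "detections": len(dets),
                "excluded": len(excluded),
                "reference_sbr0": _fmt(reference_sbr0),
                "seed": int(seeds[0]),
            }
        except Exception as exc:
            raise MechanomapError(
                f"stage 'phantom' failed ({outdir / 'phantom_detections.csv'}): {exc}"
            ) from exc

    model = model.with_reference(reference_sbr0)

    # ---------------- stage 2: two-region tumor -------------------------
    if config.run_two_region:
        try:
            tr = generate_two_region_scene(
                config.two_region_sensors_per_region, noise=config.noise,
                seed=int(seeds[1]),
            )
            dets = detect_particles(tr.mr_volume, **detect_kw)
            retained, excluded = filter_aggregates(
                dets, sbr_max=config.sbr_max, area_max_px=config.area_max_px,
                combine=config.aggregate_rule,
            )
            for det in retained:
                det.normalized_signal = normalize_signal(det.sbr, reference_sbr0, model)
                det.stress_kPa, det.stress_in_range = estimate_stress(
                    model, det.normalized_signal
                )
            result = register_cpd(
                tr.registration.source, tr.registration.target, mode="nonrigid",
                w=config.cpd_w, beta=config.cpd_beta_mm, lam=config.cpd_lambda,
                tol=config.cpd_tol, max_iter=config.cpd_max_iter,
            )
            sensor_cloud = PointCloud(
                np.array([d.position_mm for d in retained]), frame_label="mr"
            )
            registered = transform_points(result, sensor_cloud)
            assignments = assign_regions(
                registered, tr.registration.labels,
                sampling_radius=config.sampling_radius_mm,
            )
            stresses = np.array([d.stress_kPa for d in retained])
            stats = region_stats(assignments, stresses)
            mio.write_detections_csv(retained, outdir / "two_region_detections.csv",
                                     session_time=0.0)
            stats.to_csv(outdir / "region_stats.csv")
            report.stages["two_region"] = {
                "status": "complete",
                "sensors": tr.scene.n_particles,
                "detections": len(dets),
                "retained": len(retained),
                "excluded": len(excluded),
                "cpd_converged": result.converged,
                "cpd_sigma2": _fmt(result.final_sigma2),
                "mean_negative_kPa": _fmt(stats.loc["vimentin_negative", "mean_kPa"]),
                "mean_positive_kPa": _fmt(stats.loc["vimentin_positive", "mean_kPa"]),
                "seed": int(seeds[1]),
            }
        except Exception as exc:
            raise MechanomapError(
                f"stage 'two_region' failed ({outdir / 'region_stats.csv'}): {exc}"
            ) from exc

    # ---------------- stage 3: longitudinal tracking --------------------
    if config.run_timeseries:
        try:
            n = config.timeseries_particles
            sessions = np.asarray(config.timeseries_sessions, dtype=float)
            rng = np.random.default_rng(int(seeds[2]))
            peaks = rng.uniform(3.0, 10.0, size=n)
            frac = (sessions - sessions[0]) / (sessions[-1] - sessions[0])
            stresses = 0.5 + np.outer(peaks - 0.5, frac)
            volumes, scene = generate_tumor_timeseries(
                n, sessions, stresses,
                growth_rate=config.timeseries_growth_rate,
                aggregate_fraction=config.timeseries_aggregate_fraction,
                noise=config.noise, seed=int(seeds[2]),
            )
            per_session = []
            n_excluded_first = 0
            n_det_total = 0
            for s, vol in enumerate(volumes):
                dets = detect_particles(vol, **detect_kw)
                retained, excluded = filter_aggregates(
                    dets, sbr_max=config.sbr_max, area_max_px=config.area_max_px,
                    combine=config.aggregate_rule,
                )
                if s == 0:
                    n_excluded_first = len(excluded)
                n_det_total += len(dets)
                per_session.append(retained)
            trajectories = link_particles(per_session, sessions,
                                          growth_correction=True)
            for traj in trajectories:
                trajectory_stress(traj, model)
            frame = trajectories_to_frame(trajectories)
            frame.to_csv(outdir / "trajectories.csv", index=False)
            full = [t for t in trajectories if len(t) == len(sessions)]
            classes = [
                classify_loading(t, config.rate_threshold_kPa_per_day) for t in full
            ]
            report.stages["timeseries"] = {
                "status": "complete",
                "particles": n,
                "true_aggregates": int(scene.aggregate_flags.sum()),
                "detections_total": n_det_total,
                "excluded_first_session": n_excluded_first,
                "trajectories": len(trajectories),
                "full_length": len(full),
                "acute": classes.count("acute"),
                "seed": int(seeds[2]),
            }
        except Exception as exc:
            raise MechanomapError(
                f"stage 'timeseries' failed ({outdir / 'trajectories.csv'}): {exc}"
            ) from exc

    resolved = config.to_dict()
    resolved["noise"] = dataclasses.asdict(config.noise)
    mio.dump_yaml(resolved, outdir / "resolved_config.yaml")
    report.report_path = str(outdir / "report.txt")
    with open(report.report_path, "w") as fh:
        fh.write("\n".join(report.lines()) + "\n")
    return report
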