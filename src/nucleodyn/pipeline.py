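"""End-to-end orchestration of the analysis on synthetic or user data.

A single validated :class:`RunConfig` drives the stage chain

    generate/ingest → density classification → tracking/MSD →
    spatial statistics → model prediction → comparison report

with explicit seeds for every random stage and a :class:`RunReport` listing
(and checksumming) every output file, so identical configs give
byte-identical outputs.  The functions here are the orchestration surface
of the package; the per-stage APIs live in their own modules and the
``examples/`` scripts show them individually.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import density, io, model, spatial, synth, tracking
from .types import NuclearMask

__all__ = ["RunConfig", "RunReport", "run_pipeline", "summarize_condition"]


class VolumeStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: tuple[int, int, int] = (20, 56, 56)
    voxel_size: tuple[float, float, float] = (250.0, 110.0, 110.0)
    class_means: tuple[float, ...] = (100, 200, 300, 400, 500, 600, 700)
    class_sds: tuple[float, ...] = (12.0,) * 7
    smoothing_scale: float = 1.5
    seed: int = 0


class TrackStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_traj: int = 2100
    n_frames: int = 20
    dt: float = 0.02            # s; 20 ms frame interval
    max_lag: float = 0.5        # s; nucleosome lag cap
    loc_error_xy: float = 25.0  # nm
    loc_error_z: float = 140.0  # nm
    min_traj: int = 250
    min_r2: float = 0.95
    physical_2d: bool = False   # divide log-log intercept by 4 when True
    seed: int = 0
    # per-class (D, alpha): defaults decrease D with density, constant alpha
    per_class_motion: dict[int, tuple[float, float]] = Field(
        default_factory=lambda: {
            k: (0.018 - 0.002 * (k - 1), 0.7) for k in range(1, 8)})


class DensityStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    K: int = 7
    beta: float = 0.7
    n_init: int = 5
    trim_cdc1: bool = True
    periphery_cutoff_nm: float = 500.0
    seed: int = 0


class SpatialStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    n_molecules: int = 4000
    d_f_true: float = 2.7
    region_nm: tuple[tuple[float, float], ...] = (
        (0.0, 1000.0), (0.0, 2000.0), (0.0, 2000.0))
    blink_mean: float = 4.0
    r_max_nm: float = 600.0
    n_random_factor: int = 5
    tag_fraction: float = 0.044     # HaloTag-H2B : endogenous H2B
    expressing_fraction: float = 1.0
    seed: int = 0


class ModelStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    alpha_halo: float = 0.8
    alpha_halo_sd: float = 0.05
    D_halo: float = 0.5         # µm²/s^α, log-log intercept convention
    n_mc: int = 2000
    seed: int = 0


class RunConfig(BaseModel):
    """Validated end-to-end run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    schema_version: int = 1
    out_dir: str = "nucleodyn_run"
    volume: VolumeStageConfig = Field(default_factory=VolumeStageConfig)
    track: TrackStageConfig = Field(default_factory=TrackStageConfig)
    density: DensityStageConfig = Field(default_factory=DensityStageConfig)
    spatial: SpatialStageConfig = Field(default_factory=SpatialStageConfig)
    model_stage: ModelStageConfig = Field(default_factory=ModelStageConfig)


class RunReport(BaseModel):
    """Stage outputs, parameter echo, and provenance of one run."""

    model_config = ConfigDict(extra="forbid")
    config: RunConfig
    outputs: dict[str, str] = {}        # name -> path
    checksums: dict[str, str] = {}      # name -> sha256
    warnings: list[str] = []
    wall_time_s: float = 0.0
    software: str = "nucleodyn 0.1.0"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the stage chain on a synthetic scene and write all outputs.

    Stages run in dependency order; the report lists every file written with
    its checksum.  Reruns with an identical config reproduce identical
    files.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg)

    # --- generate ---------------------------------------------------------
    vol_gt = synth.VolumeGroundTruth(
        shape=cfg.volume.shape, voxel_size=cfg.volume.voxel_size,
        class_means=cfg.volume.class_means, class_sds=cfg.volume.class_sds,
        smoothing_scale=cfg.volume.smoothing_scale, seed=cfg.volume.seed)
    traj_gt = synth.TrajectoryGroundTruth(
        n_traj=cfg.track.n_traj, n_frames=cfg.track.n_frames, dt=cfg.track.dt,
        loc_error_xy=cfg.track.loc_error_xy, loc_error_z=cfg.track.loc_error_z,
        seed=cfg.track.seed)
    scene = synth.simulate_correlated_scene(
        vol_gt, cfg.track.per_class_motion, traj_gt)
    io.write_volume(scene.volume, out / "volume.tif")
    io.write_localizations(scene.locs, out / "trajectories.csv")

    # --- density classification ------------------------------------------
    mask = NuclearMask(scene.true_labels.labels > 0,
                       voxel_size=cfg.volume.voxel_size, provenance="synthetic")
    intens = scene.volume.data[mask.data]
    fit = density.fit_mixture(intens, cfg.density.K,
                              n_init=cfg.density.n_init, seed=cfg.density.seed)
    cdc = density.classify_mrf(scene.volume, mask, fit, beta=cfg.density.beta)
    if cfg.density.trim_cdc1:
        cdc = density.trim_edge_cdc1(cdc, mask)
    io.write_cdc(cdc, out / "cdc.tif")

    # --- tracking / MSD ---------------------------------------------------
    labels = tracking.assign_cdc(scene.locs, cdc)
    curves = tracking.compute_msd(scene.locs, dt=cfg.track.dt,
                                  max_lag=cfg.track.max_lag, labels=labels)
    fits = []
    for lab, curve in sorted(curves.items(), key=lambda kv: str(kv[0])):
        try:
            fits.append(tracking.fit_power_law(
                curve, min_r2=cfg.track.min_r2,
                physical_2d=cfg.track.physical_2d))
        except ValueError as e:
            report.warnings.append(f"fit skipped for class {lab}: {e}")
    kept = tracking.filter_fits(fits, min_traj=cfg.track.min_traj,
                                min_r2=cfg.track.min_r2)
    fits_df = pd.DataFrame([{
        "cdc": f.label, "D_app": f.D_app, "alpha": f.alpha, "r2": f.r2,
        "n_traj": f.n_traj, "retained": f in kept} for f in fits])
    fits_df.to_csv(out / "fits.csv", index=False)

    # --- spatial statistics ----------------------------------------------
    estimates = {}
    if cfg.spatial.enabled:
        cloud_gt = synth.CloudGroundTruth(
            n_molecules=cfg.spatial.n_molecules, d_f_true=cfg.spatial.d_f_true,
            region=cfg.spatial.region_nm, blink_mean=cfg.spatial.blink_mean,
            seed=cfg.spatial.seed)
        cloud = synth.simulate_fractal_cloud(cloud_gt)
        region = spatial.BoxRegion(cfg.spatial.region_nm)
        pc = spatial.pair_correlation(
            cloud, region,
            bins=spatial.default_bins(r_max=cfg.spatial.r_max_nm),
            n_random_factor=cfg.spatial.n_random_factor,
            seed=cfg.spatial.seed + 1)
        frac = spatial.fit_fractal_dimension(pc)
        n_blinks = spatial.estimate_blinks(cloud)
        box_um3 = np.prod([(hi - lo) / 1e3 for lo, hi in cfg.spatial.region_nm])
        rho_loc = len(cloud) / box_um3
        rho = spatial.corrected_nucleosome_density(
            rho_loc, n_blinks, cfg.spatial.tag_fraction,
            cfg.spatial.expressing_fraction)
        try:
            dom = spatial.estimate_domain_size(pc)
            R2_um2 = model.nm2_to_um2(dom.R2_nm2)
        except ValueError as e:
            report.warnings.append(f"domain size: {e}")
            R2_um2 = model.nm2_to_um2(200.0 ** 2)
        estimates = {"d_f": frac.d_f, "gamma": frac.gamma, "fit_r2": frac.r2,
                     "n_blinks": n_blinks, "rho_loc_um3": rho_loc,
                     "rho_corrected_um3": rho, "R2_um2": R2_um2}
        gr_df = pd.DataFrame({"r_nm": pc.r, "G": pc.G, "DD": pc.DD, "RR": pc.RR})
        gr_df.to_csv(out / "gr.csv", index=False)
        io.write_json(estimates, out / "spatial_estimates.json")

    # --- model ------------------------------------------------------------
    if cfg.model_stage.enabled and estimates:
        classes = sorted({int(f.label) for f in kept
                          if isinstance(f.label, (int, np.integer))})
        inputs = model.ModelInputs(
            alpha_halo=cfg.model_stage.alpha_halo,
            alpha_halo_sd=cfg.model_stage.alpha_halo_sd,
            D_halo=cfg.model_stage.D_halo,
            d_f={k: estimates["d_f"] for k in classes},
            d_f_sd={k: 0.05 for k in classes},
            rho_um3={k: estimates["rho_corrected_um3"] for k in classes},
            R2_um2={k: estimates["R2_um2"] for k in classes},
        )
        if classes:
            pred = model.propagate_errors(inputs, n_mc=cfg.model_stage.n_mc,
                                          seed=cfg.model_stage.seed)
            interior = [f for f in kept
                        if isinstance(f.label, (int, np.integer))]
            for f in interior:
                f.region = "interior"
            comp = model.compare_model_experiment(pred, interior)
            comp.to_csv(out / "model_comparison.csv", index=False)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "report.json":
            report.outputs[p.name] = str(p)
            report.checksums[p.name] = _sha256(p)
    report.wall_time_s = time.time() - t0
    report_path = out / "report.json"
    report.outputs["report.json"] = str(report_path)
    report_path.write_text(report.model_dump_json(indent=2))
    return report


def summarize_condition(
    groups: dict[str, list[pd.DataFrame]],
) -> pd.DataFrame:
    """Descriptive per-condition summary of per-class fit tables.

    ``groups`` maps a condition name to the list of per-run fit tables
    (as written by :func:`run_pipeline` to ``fits.csv``).  Returns a
    long-format table of (condition, cdc) group means and standard
    deviations of D and α, plus the rank correlation of mean D with class.
    No hypothesis testing is performed.
    """
    from scipy.stats import spearmanr

    rows = []
    expected_cdcs = None
    for cond, tables in groups.items():
        if not tables:
            raise ValueError(f"empty group {cond!r}")
        cat = pd.concat(tables, ignore_index=True)
        cat = cat[pd.to_numeric(cat["cdc"], errors="coerce").notna()]
        cat["cdc"] = cat["cdc"].astype(int)
        cdcs = sorted(cat["cdc"].unique())
        if expected_cdcs is None:
            expected_cdcs = cdcs
        elif cdcs != expected_cdcs:
            raise ValueError(
                f"group {cond!r} has classes {cdcs}, expected {expected_cdcs}")
        g = cat.groupby("cdc")
        mean_d = g["D_app"].mean()
        rho = spearmanr(mean_d.index, mean_d.values).statistic if len(mean_d) > 2 else np.nan
        for cdc, sub in g:
            rows.append({
                "condition": cond, "cdc": cdc,
                "D_mean": sub["D_app"].mean(), "D_sd": sub["D_app"].std(ddof=0),
                "alpha_mean": sub["alpha"].mean(),
                "alpha_sd": sub["alpha"].std(ddof=0),
                "n_runs": len(sub), "spearman_D_vs_cdc": rho,
            })
    return pd.DataFrame(rows)
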