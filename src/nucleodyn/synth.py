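"""Synthetic generators for every input the analysis pipeline consumes.

Three generators emulate the three raw data modalities:

* :func:`simulate_fbm_trajectories` — 3D fractional-Brownian-motion paths of
  chromatin-bound particles with prescribed apparent diffusion coefficient
  ``D`` and anomalous exponent ``α`` (lateral ensemble MSD follows
  ``MSD(τ) = D·τ^α`` in µm², the same convention the fitting module uses),
  plus Gaussian localization error;
* :func:`simulate_fractal_cloud` — blinking SMLM point clouds with a tunable
  fractal dimension built from a lognormal intensity field with exact
  power-law pair correlation, a Gaussian axial detection envelope, and
  Poisson blink counts;
* :func:`simulate_chromatin_volume` — chromatin intensity volumes drawn from
  a K-component Gaussian intensity mixture over a spatially smoothed latent
  class field inside an ellipsoidal nuclear mask.

:func:`simulate_correlated_scene` combines them into an end-to-end scene with
full ground truth, for closed-loop recovery tests of the whole pipeline.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import CDCMap, IntensityVolume, LOC_COLUMNS

__all__ = [
    "TrajectoryGroundTruth",
    "CloudGroundTruth",
    "VolumeGroundTruth",
    "SceneBundle",
    "simulate_fbm_trajectories",
    "simulate_fractal_cloud",
    "simulate_chromatin_volume",
    "simulate_correlated_scene",
]


# ---------------------------------------------------------------------------
# Ground-truth parameter bundles
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryGroundTruth:
    """Parameters of a synthetic tracking experiment.

    Defaults mirror the acquisition this package targets: 20 ms frames,
    25 frames per z-slice, ~25 nm lateral / ~140 nm axial precision, and
    nucleosome-like subdiffusion (D = 0.01 µm²/s^α, α = 0.8).
    """

    n_traj: int = 2000
    n_frames: int = 25
    dt: float = 0.02          # s
    D_true: float = 0.01      # µm²/s^α, apparent (log-log intercept) convention
    alpha_true: float = 0.8
    loc_error_xy: float = 25.0   # nm, per axis
    loc_error_z: float = 140.0   # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.D_true < 0:
            raise ValueError("D_true must be >= 0")
        if not (0 < self.alpha_true <= 2):
            raise ValueError("alpha_true must lie in (0, 2]")
        if self.loc_error_xy < 0 or self.loc_error_z < 0:
            raise ValueError("localization errors must be >= 0")
        if self.n_traj < 1 or self.n_frames < 2:
            raise ValueError("need n_traj >= 1 and n_frames >= 2")


@dataclass
class CloudGroundTruth:
    """Parameters of a synthetic SMLM nucleosome map.

    ``region`` is an axis-aligned box ``((zmin, zmax), (ymin, ymax),
    (xmin, xmax))`` in nm.  ``axial_sigma`` is the Gaussian z-detection
    envelope (localizations away from the focal plane are detected less
    efficiently); ``None`` disables the envelope.  ``corr_length_nm`` is the
    upper cutoff of the fractal scaling (the chromatin-domain scale: G(r)
    flattens to 1 beyond it) and ``grid_nm`` the lower cutoff.
    """

    n_molecules: int = 20000
    d_f_true: float = 2.7
    region: tuple[tuple[float, float], ...] = (
        (0.0, 1500.0), (0.0, 2000.0), (0.0, 2000.0))
    blink_mean: float = 4.0
    blink_radius: float = 20.0   # nm
    axial_sigma: float | None = None
    loc_error_xy: float = 18.0   # nm
    loc_error_z: float = 80.0    # nm
    grid_nm: float = 20.0        # intensity-field cell size (lower cutoff)
    corr_length_nm: float = 300.0  # fractal scaling upper cutoff / domain scale
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.d_f_true <= 3):
            raise ValueError(
                f"d_f_true={self.d_f_true} infeasible; the generator supports "
                "fractal dimensions in (0, 3]")
        for lo, hi in self.region:
            if hi <= lo:
                raise ValueError("region must have positive extent on all axes")
        if self.blink_mean < 1:
            raise ValueError("blink_mean must be >= 1")
        if self.axial_sigma is not None and self.axial_sigma <= 0:
            raise ValueError("axial_sigma must be positive or None")
        if self.grid_nm <= 0 or self.corr_length_nm <= self.grid_nm:
            raise ValueError("need corr_length_nm > grid_nm > 0")


@dataclass
class VolumeGroundTruth:
    """Parameters of a synthetic chromatin intensity volume."""

    shape: tuple[int, int, int] = (24, 64, 64)        # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (250.0, 110.0, 110.0)
    class_means: tuple[float, ...] = (100, 200, 300, 400, 500, 600, 700)
    class_sds: tuple[float, ...] = (12.0,) * 7
    smoothing_scale: float = 1.5      # voxels, latent-field correlation length
    nucleus: tuple[float, float, float] | None = None  # ellipsoid semi-axes, voxels
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_means) != len(self.class_sds):
            raise ValueError("class_means and class_sds must match in length")
        if len(self.class_means) < 1:
            raise ValueError("K must be >= 1")
        means = np.asarray(self.class_means, dtype=float)
        if np.any(np.diff(means) <= 0):
            raise ValueError("class_means must be strictly increasing")
        if self.nucleus is None:
            self.nucleus = tuple(0.42 * s for s in self.shape)
        for semi, extent in zip(self.nucleus, self.shape):
            if 2 * semi > extent:
                raise ValueError("nuclear ellipsoid exceeds the voxel grid")

    @property
    def K(self) -> int:
        return len(self.class_means)


# ---------------------------------------------------------------------------
# fBm trajectories
# ---------------------------------------------------------------------------

def _fbm_sampler(n_steps: int, dt: float, hurst: float) -> np.ndarray:
    """Square root of the fBm position covariance on the grid dt..n_steps*dt.

    Uses an eigendecomposition of the exact fBm covariance
    ``C_ij = (t_i^{2H} + t_j^{2H} − |t_i − t_j|^{2H}) / 2`` (unit diffusivity)
    so that sampled paths have exactly the prescribed second moments; the
    eigen route also handles the singular ballistic limit H = 1.
    """
    t = dt * np.arange(1, n_steps + 1)
    two_h = 2.0 * hurst
    cov = 0.5 * (t[:, None] ** two_h + t[None, :] ** two_h
                 - np.abs(t[:, None] - t[None, :]) ** two_h)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_fbm_trajectories(
    gt: TrajectoryGroundTruth,
    origins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate 3D fBm trajectories with localization noise.

    Each axis is an independent fBm with Hurst index ``α/2`` scaled so the
    ensemble *lateral* (x–y) MSD at lag τ equals ``D_true·τ^α`` µm², i.e. the
    exact curve the power-law fitting convention expects.  The axial path
    carries the same per-axis variance; axial anisotropy of real data enters
    through the larger axial localization error.

    Parameters
    ----------
    gt:
        Generator parameters (validated on construction).
    origins:
        Optional ``(n_traj, 3)`` array of (z, y, x) starting points in nm;
        defaults to the origin for every trajectory.

    Returns
    -------
    pandas.DataFrame
        Localization table (columns :data:`nucleodyn.types.LOC_COLUMNS`) with
        one row per (trajectory, frame).
    """
    rng = np.random.default_rng(gt.seed)
    n_pts = gt.n_frames - 1
    # per-axis lateral MSD is D/2 (two lateral axes sum to D); nm² units
    sigma2_nm = gt.D_true * 1e6 / 2.0
    if gt.D_true > 0:
        root = math.sqrt(sigma2_nm) * _fbm_sampler(n_pts, gt.dt, gt.alpha_true / 2.0)
    else:
        root = np.zeros((n_pts, n_pts))

    if origins is None:
        origins = np.zeros((gt.n_traj, 3))
    origins = np.asarray(origins, dtype=float)

    # paths[axis] has shape (n_traj, n_frames)
    paths = np.zeros((3, gt.n_traj, gt.n_frames))
    for ax in range(3):
        z = rng.standard_normal((gt.n_traj, n_pts))
        paths[ax][:, 1:] = z @ root.T
    noise_sd = np.array([gt.loc_error_z, gt.loc_error_xy, gt.loc_error_xy])
    for ax in range(3):
        paths[ax] += origins[:, ax][:, None]
        if noise_sd[ax] > 0:
            paths[ax] += rng.normal(0.0, noise_sd[ax], paths[ax].shape)

    ids = np.repeat(np.arange(gt.n_traj), gt.n_frames)
    frames = np.tile(np.arange(gt.n_frames), gt.n_traj)
    return pd.DataFrame({
        "id": ids,
        "frame": frames,
        "x_nm": paths[2].ravel(),
        "y_nm": paths[1].ravel(),
        "z_nm": paths[0].ravel(),
        "sigma_xy_nm": gt.loc_error_xy,
        "sigma_z_nm": gt.loc_error_z,
    })


# ---------------------------------------------------------------------------
# Fractal point clouds
# ---------------------------------------------------------------------------

def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def fractal_intensity_field(
    rng: np.random.Generator,
    gamma: float,
    shape: tuple[int, int, int],
    cell_nm: float,
    corr_length_nm: float,
) -> np.ndarray:
    """Lognormal intensity field with exact power-law pair correlation.

    A Gaussian field ``Z`` with logarithmic covariance
    ``C(r) = γ·ln(L/r)`` for ``r < L`` (zero beyond) is synthesized
    spectrally on a periodic grid; the exponentiated intensity
    ``λ = exp(Z)`` then has two-point function
    ``E[λ(x)λ(y)]/E[λ]² = exp(C(r)) = (L/r)^γ`` — a pure power law between
    the grid scale and ``L``.  This makes the fractal exponent of the
    generated clouds exact by construction rather than an asymptotic limit
    of a hierarchical cascade.
    """
    axes = [np.minimum(np.arange(s), s - np.arange(s)) * cell_nm for s in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    r = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    C = gamma * np.log(corr_length_nm / np.maximum(r, cell_nm))
    C[r >= corr_length_nm] = 0.0
    lam = np.clip(np.fft.fftn(C).real, 0.0, None)  # circulant eigenvalues
    w = rng.standard_normal(shape)
    Z = np.fft.irfftn(
        np.sqrt(lam[:, :, : shape[2] // 2 + 1]) * np.fft.rfftn(w),
        s=shape, axes=(0, 1, 2))
    return np.exp(Z)


def simulate_fractal_cloud(gt: CloudGroundTruth) -> pd.DataFrame:
    """Simulate a blinking SMLM point cloud with fractal dimension ``d_f_true``.

    Molecule positions are drawn from a lognormal intensity field whose
    pair correlation is exactly ``(L/r)^γ`` with ``γ = 3 − d_f_true``
    between ``grid_nm`` and ``corr_length_nm`` (see
    :func:`fractal_intensity_field`); ``d_f_true = 3`` reduces to a uniform
    distribution.  Each molecule emits ``Poisson(blink_mean)`` localizations
    (molecules with zero detections are dropped) scattered uniformly within
    ``blink_radius``; localizations are then thinned in z by the Gaussian
    envelope and perturbed by localization error.

    Returns a localization table whose ``id`` column is the molecule id.
    """
    rng = np.random.default_rng(gt.seed)
    lows = np.array([lo for lo, _ in gt.region])
    highs = np.array([hi for _, hi in gt.region])
    extent = highs - lows

    if gt.d_f_true >= 3.0 - 1e-9:
        mols = lows + extent * rng.random((gt.n_molecules, 3))
    else:
        a = gt.grid_nm
        shape = tuple(int(math.ceil(e / a)) for e in extent)
        field_ = fractal_intensity_field(
            rng, 3.0 - gt.d_f_true, shape, a, gt.corr_length_nm)
        p = (field_ / field_.sum()).ravel()
        counts = rng.multinomial(gt.n_molecules, p)
        idx = np.repeat(np.arange(p.size), counts)
        ijk = np.column_stack(np.unravel_index(idx, shape))
        mols = lows + (ijk + rng.random((gt.n_molecules, 3))) * a
        np.minimum(mols, highs, out=mols)  # last partial cells

    # blinks: Poisson counts, zero-detection molecules dropped
    counts = rng.poisson(gt.blink_mean, gt.n_molecules)
    detected = counts > 0
    mols, counts = mols[detected], counts[detected]
    mol_ids = np.repeat(np.arange(len(mols)), counts)
    locs = np.repeat(mols, counts, axis=0)
    locs = locs + _uniform_in_ball(rng, len(locs), gt.blink_radius)

    if gt.axial_sigma is not None:
        zc = 0.5 * (lows[0] + highs[0])
        accept = rng.random(len(locs)) < np.exp(
            -((locs[:, 0] - zc) ** 2) / (2.0 * gt.axial_sigma ** 2))
        locs, mol_ids = locs[accept], mol_ids[accept]

    noise = np.column_stack([
        rng.normal(0.0, gt.loc_error_z, len(locs)) if gt.loc_error_z > 0 else np.zeros(len(locs)),
        rng.normal(0.0, gt.loc_error_xy, len(locs)) if gt.loc_error_xy > 0 else np.zeros(len(locs)),
        rng.normal(0.0, gt.loc_error_xy, len(locs)) if gt.loc_error_xy > 0 else np.zeros(len(locs)),
    ])
    locs = locs + noise

    return pd.DataFrame({
        "id": mol_ids,
        "frame": np.arange(len(locs)),
        "x_nm": locs[:, 2],
        "y_nm": locs[:, 1],
        "z_nm": locs[:, 0],
        "sigma_xy_nm": gt.loc_error_xy,
        "sigma_z_nm": gt.loc_error_z,
    })


# ---------------------------------------------------------------------------
# Chromatin volumes
# ---------------------------------------------------------------------------

def simulate_chromatin_volume(
    gt: VolumeGroundTruth,
) -> tuple[IntensityVolume, np.ndarray]:
    """Simulate a chromatin intensity volume with known class labels.

    A white-noise field is smoothed with a Gaussian of ``smoothing_scale``
    voxels and quantile-partitioned into K spatially correlated latent
    classes of equal prevalence inside the nuclear ellipsoid; each voxel's
    intensity is then drawn from its class Gaussian.  Voxels outside the
    ellipsoid are zero.

    Returns the volume and the true label grid (0 = background, 1..K).
    """
    rng = np.random.default_rng(gt.seed)
    zc, yc, xc = [(s - 1) / 2.0 for s in gt.shape]
    zz, yy, xx = np.ogrid[:gt.shape[0], :gt.shape[1], :gt.shape[2]]
    az, ay, ax = gt.nucleus
    inside = ((zz - zc) / az) ** 2 + ((yy - yc) / ay) ** 2 + ((xx - xc) / ax) ** 2 <= 1.0

    field_ = ndimage.gaussian_filter(rng.standard_normal(gt.shape), gt.smoothing_scale)
    labels = np.zeros(gt.shape, dtype=np.int32)
    vals = field_[inside]
    edges = np.quantile(vals, np.linspace(0, 1, gt.K + 1)[1:-1])
    labels[inside] = np.searchsorted(edges, vals) + 1

    intensity = np.zeros(gt.shape)
    means = np.asarray(gt.class_means, dtype=float)
    sds = np.asarray(gt.class_sds, dtype=float)
    for k in range(1, gt.K + 1):
        m = labels == k
        intensity[m] = rng.normal(means[k - 1], sds[k - 1], int(m.sum()))
    np.clip(intensity, 0.0, None, out=intensity)

    vol = IntensityVolume(intensity, voxel_size=gt.voxel_size)
    return vol, labels


# ---------------------------------------------------------------------------
# Correlated end-to-end scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneBundle:
    """A fully ground-truthed synthetic scene: volume + trajectories."""

    volume: IntensityVolume
    true_labels: CDCMap
    locs: pd.DataFrame
    traj_class: pd.Series          # trajectory id -> true class at seed voxel
    traj_origin_voxel: np.ndarray  # (n_traj, 3) integer (z, y, x)
    volume_gt: VolumeGroundTruth
    traj_gt: TrajectoryGroundTruth
    per_class_motion: dict = field(default_factory=dict)


def simulate_correlated_scene(
    volume_gt: VolumeGroundTruth,
    per_class_motion: dict[int, tuple[float, float]],
    traj_gt: TrajectoryGroundTruth,
) -> SceneBundle:
    """Simulate a chromatin volume plus trajectories whose motion follows
    the density class of their seeding voxel.

    ``per_class_motion`` maps class label (1..K) to ``(D, α)``; every class
    must be covered.  Trajectories are seeded at uniformly chosen foreground
    voxels (centre of the voxel) and generated with their class's motion
    parameters; all ground truth is returned for end-to-end recovery tests.
    """
    for k in range(1, volume_gt.K + 1):
        if k not in per_class_motion:
            raise ValueError(f"per_class_motion missing class {k}")

    vol, labels = simulate_chromatin_volume(volume_gt)
    rng = np.random.default_rng(traj_gt.seed + 1)
    fg = np.argwhere(labels > 0)
    seeds_idx = rng.integers(0, len(fg), traj_gt.n_traj)
    seed_vox = fg[seeds_idx]
    seed_class = labels[seed_vox[:, 0], seed_vox[:, 1], seed_vox[:, 2]]
    voxel = np.asarray(volume_gt.voxel_size)
    origins_nm = seed_vox * voxel  # paired with divide-and-round CDC lookup

    tables = []
    for k in range(1, volume_gt.K + 1):
        sel = seed_class == k
        n_k = int(sel.sum())
        if n_k == 0:
            continue
        D_k, a_k = per_class_motion[k]
        gt_k = TrajectoryGroundTruth(
            n_traj=n_k, n_frames=traj_gt.n_frames, dt=traj_gt.dt,
            D_true=D_k, alpha_true=a_k,
            loc_error_xy=traj_gt.loc_error_xy, loc_error_z=traj_gt.loc_error_z,
            seed=traj_gt.seed + 1000 + k)
        tab = simulate_fbm_trajectories(gt_k, origins=origins_nm[sel])
        ids = np.flatnonzero(sel)
        tab["id"] = np.repeat(ids, traj_gt.n_frames)
        tables.append(tab)
    locs = pd.concat(tables, ignore_index=True)

    return SceneBundle(
        volume=vol,
        true_labels=CDCMap(labels, K=volume_gt.K, voxel_size=volume_gt.voxel_size,
                           provenance="truth"),
        locs=locs,
        traj_class=pd.Series(seed_class, index=np.arange(traj_gt.n_traj)),
        traj_origin_voxel=seed_vox,
        volume_gt=volume_gt,
        traj_gt=traj_gt,
        per_class_motion=dict(per_class_motion),
    )
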