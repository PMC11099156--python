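"""Trajectory building and per-class anomalous-diffusion analysis.

The chain implemented here: link localization streams into trajectories
(400 nm / 2-frame gap rule, no merging or splitting), merge SMLM blinks,
assign each localization or displacement to a chromatin density class,
compute per-class ensemble lateral MSDs, fit the anomalous-diffusion power
law ``log MSD = log D + α log τ`` by ordinary least squares, and apply the
inclusion filters (≥250 trajectories, fit r² ≥ 0.95).

Unit boundary: localization coordinates are nm; MSDs and the fitted ``D``
are in µm² and µm²·s^−α.  ``D`` is the *apparent* coefficient — the
exponential of the log-log intercept, with no geometric factor; pass
``physical_2d=True`` to :func:`fit_power_law` to divide by 4 for the
2D-physical convention ``MSD = 4 D τ^α``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .types import CDCMap, validate_localizations

__all__ = [
    "MSDCurve",
    "PowerLawFit",
    "AnisotropySummary",
    "link_trajectories",
    "merge_blinks",
    "assign_cdc",
    "compute_msd",
    "fit_power_law",
    "radius_of_gyration",
    "angular_anisotropy",
    "filter_fits",
]

NM2_PER_UM2 = 1e6


@dataclass
class MSDCurve:
    """Ensemble MSD for one label (a CDC, a region tag, or whole-cell)."""

    lags: np.ndarray       # seconds, strictly increasing
    msd: np.ndarray        # µm²
    n_pairs: np.ndarray    # displacement pairs per lag
    label: object = "whole-cell"
    n_traj: int = 0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class PowerLawFit:
    """Fitted anomalous-diffusion parameters for one label."""

    D_app: float           # µm²/s^α
    alpha: float
    r2: float
    n_traj: int
    label: object = "whole-cell"
    region: str = "whole-cell"
    excluded: bool = False


@dataclass
class AnisotropySummary:
    """Forward/backward displacement-angle counts for one label."""

    label: object
    n_forward: int
    n_backward: int

    @property
    def log2_fold_change(self) -> float:
        """log2(forward/backward); NaN when either count is zero."""
        if self.n_forward == 0 or self.n_backward == 0:
            return float("nan")
        return float(np.log2(self.n_forward / self.n_backward))


# ---------------------------------------------------------------------------
# Linking and blink merging
# ---------------------------------------------------------------------------

def link_trajectories(
    locs: pd.DataFrame,
    max_disp: float = 400.0,
    max_gap: int = 2,
) -> pd.DataFrame:
    """Link localizations into trajectories frame by frame.

    Assignment between open trajectory ends and the next frame's detections
    is globally optimal per frame pair (Hungarian algorithm on lateral
    distance), with links above ``max_disp`` nm forbidden; trajectory ends
    stay open across gaps of up to ``max_gap`` frames.  Trajectories never
    merge or split.

    Returns a copy of the table with a fresh ``id`` column; single-detection
    trajectories are retained (filter downstream if unwanted).
    """
    locs = validate_localizations(locs).sort_values("frame", kind="stable")
    coords = locs[["x_nm", "y_nm"]].to_numpy(dtype=float)
    frames = locs["frame"].to_numpy()
    idx = np.arange(len(locs))

    BIG = 1e12
    next_id = 0
    track_of = np.full(len(locs), -1, dtype=int)
    # open track ends: (track id, row index of last detection, last frame)
    open_ends: list[tuple[int, int, int]] = []

    for f in np.unique(frames):
        rows = idx[frames == f]
        open_ends = [e for e in open_ends if f - e[2] <= max_gap]
        assigned: set[int] = set()
        if open_ends and len(rows):
            ends_xy = coords[[e[1] for e in open_ends]]
            det_xy = coords[rows]
            d = np.linalg.norm(ends_xy[:, None, :] - det_xy[None, :, :], axis=2)
            cost = np.where(d <= max_disp, d, BIG)
            ri, ci = linear_sum_assignment(cost)
            matched_ends: set[int] = set()
            for r, c in zip(ri, ci):
                if cost[r, c] < BIG:
                    tid = open_ends[r][0]
                    track_of[rows[c]] = tid
                    open_ends[r] = (tid, int(rows[c]), int(f))
                    assigned.add(c)
                    matched_ends.add(r)
        for c, r in enumerate(rows):
            if c in assigned:
                continue
            track_of[r] = next_id
            open_ends.append((next_id, int(r), int(f)))
            next_id += 1

    out = locs.copy()
    out["id"] = track_of
    return out.sort_values(["id", "frame"], kind="stable").reset_index(drop=True)


def merge_blinks(
    locs: pd.DataFrame,
    radius: float = 100.0,
    max_frame_gap: int = 2,
) -> pd.DataFrame:
    """Collapse temporally contiguous localization bursts of one emitter.

    Localizations within ``radius`` nm (3D) of an open burst whose last
    detection is at most ``max_frame_gap`` frames earlier (a gap of less
    than two missing frames, per the merging rule) are merged; each burst
    becomes a single output localization at the mean position, stamped with
    the burst's first frame.
    """
    locs = validate_localizations(locs).sort_values("frame", kind="stable")
    xyz = locs[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    frames = locs["frame"].to_numpy()

    burst_of = np.full(len(locs), -1, dtype=int)
    open_bursts: list[tuple[int, int, np.ndarray]] = []  # (burst id, last frame, last pos)
    nb = 0
    for i in range(len(locs)):
        f = frames[i]
        open_bursts = [b for b in open_bursts if f - b[1] <= max_frame_gap]
        best, best_d = -1, radius
        for j, (bid, _, pos) in enumerate(open_bursts):
            d = float(np.linalg.norm(xyz[i] - pos))
            if d <= best_d:
                best, best_d = j, d
        if best >= 0:
            bid = open_bursts[best][0]
            burst_of[i] = bid
            open_bursts[best] = (bid, int(f), xyz[i])
        else:
            burst_of[i] = nb
            open_bursts.append((nb, int(f), xyz[i]))
            nb += 1

    tmp = locs.copy()
    tmp["_burst"] = burst_of
    agg = tmp.groupby("_burst", sort=True).agg(
        id=("id", "first"),
        frame=("frame", "min"),
        x_nm=("x_nm", "mean"),
        y_nm=("y_nm", "mean"),
        z_nm=("z_nm", "mean"),
        sigma_xy_nm=("sigma_xy_nm", "mean"),
        sigma_z_nm=("sigma_z_nm", "mean"),
    ).reset_index(drop=True)
    return agg


# ---------------------------------------------------------------------------
# CDC assignment
# ---------------------------------------------------------------------------

def assign_cdc(
    locs: pd.DataFrame,
    cdc: CDCMap,
    voxel_size: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Label each localization with the density class of its voxel.

    The voxel index is the coordinate divided by the voxel size and rounded
    to the nearest integer; out-of-grid localizations get label 0
    (background) and are excluded downstream.
    """
    validate_localizations(locs)
    vz, vy, vx = voxel_size if voxel_size is not None else cdc.voxel_size
    iz = np.rint(locs["z_nm"].to_numpy() / vz).astype(int)
    iy = np.rint(locs["y_nm"].to_numpy() / vy).astype(int)
    ix = np.rint(locs["x_nm"].to_numpy() / vx).astype(int)
    nz, ny, nx = cdc.shape
    ok = (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
    out = np.zeros(len(locs), dtype=np.int32)
    out[ok] = cdc.labels[iz[ok], iy[ok], ix[ok]]
    return out


# ---------------------------------------------------------------------------
# MSD and power-law fitting
# ---------------------------------------------------------------------------

def compute_msd(
    locs: pd.DataFrame,
    dt: float = 0.02,
    max_lag: float = 0.5,
    labels: np.ndarray | None = None,
    subtract_localization_error: bool = True,
) -> dict[object, MSDCurve]:
    """Ensemble lateral MSD per label from a trajectory table.

    Squared x–y displacements over all within-trajectory localization pairs
    up to ``max_lag`` seconds are averaged per lag; each displacement is
    assigned to the label of its *final* localization, and curves are pooled
    across all trajectories sharing a label.  With
    ``subtract_localization_error`` the static-error offset
    ``2·(σ_xy,i² + σ_xy,j²)`` is removed from each pair using the table's
    per-localization precision columns, which debiases the curve when the
    precision floor is comparable to the smallest displacements.

    ``labels=None`` computes a single whole-cell curve.
    """
    if max_lag < dt:
        raise ValueError("max_lag must be >= dt")
    locs = validate_localizations(locs)
    max_steps = int(round(max_lag / dt))

    frames = locs["frame"].to_numpy()
    ids = locs["id"].to_numpy()
    x = locs["x_nm"].to_numpy() / 1e3  # µm
    y = locs["y_nm"].to_numpy() / 1e3
    sig2 = (locs["sigma_xy_nm"].to_numpy() / 1e3) ** 2
    if labels is None:
        labels = np.full(len(locs), "whole-cell", dtype=object)
    labels = np.asarray(labels)

    order = np.lexsort((frames, ids))
    frames, ids, x, y, sig2, labels = (a[order] for a in (frames, ids, x, y, sig2, labels))

    codes, uniques = pd.factorize(labels)
    n_lab = len(uniques)
    sums = np.zeros((n_lab, max_steps + 1))
    cnts = np.zeros((n_lab, max_steps + 1), dtype=np.int64)
    traj_sets: list[set] = [set() for _ in range(n_lab)]

    starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    bounds = np.r_[starts, len(ids)]
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        n = b1 - b0
        if n < 2:
            continue
        ii, jj = np.triu_indices(n, k=1)
        steps = frames[b0 + jj] - frames[b0 + ii]
        keep = (steps >= 1) & (steps <= max_steps)
        if not np.any(keep):
            continue
        ii, jj, steps = ii[keep], jj[keep], steps[keep]
        d2 = (x[b0 + jj] - x[b0 + ii]) ** 2 + (y[b0 + jj] - y[b0 + ii]) ** 2
        if subtract_localization_error:
            d2 = d2 - 2.0 * (sig2[b0 + jj] + sig2[b0 + ii])
        # a displacement inherits the label of its final localization
        code = codes[b0 + jj]
        np.add.at(sums, (code, steps), d2)
        np.add.at(cnts, (code, steps), 1)
        for c in np.unique(code):
            traj_sets[c].add(ids[b0])

    out: dict[object, MSDCurve] = {}
    for c, lab in enumerate(uniques):
        if isinstance(lab, (int, np.integer)) and lab == 0:
            continue  # background / out of grid
        steps = np.flatnonzero(cnts[c])
        if len(steps) == 0:
            continue
        out[lab] = MSDCurve(
            lags=steps * dt,
            msd=sums[c][steps] / cnts[c][steps],
            n_pairs=cnts[c][steps],
            label=lab,
            n_traj=len(traj_sets[c]),
        )
    return out


def fit_power_law(
    msd: MSDCurve,
    min_r2: float = 0.95,
    physical_2d: bool = False,
) -> PowerLawFit:
    """Fit ``log MSD = log D + α log τ`` by ordinary least squares.

    ``α`` is the slope and ``D`` the exponential of the intercept (apparent
    coefficient); with ``physical_2d`` the intercept is divided by 4 to
    report the 2D-physical coefficient of ``MSD = 4 D τ^α``.  Fits with
    r² < ``min_r2`` are returned flagged ``excluded`` (not dropped here —
    see :func:`filter_fits`).
    """
    if len(msd.lags) < 3:
        raise ValueError("need at least 3 lags to fit")
    if np.any(msd.msd <= 0):
        raise ValueError("MSD values must be positive for a log-log fit")
    lx = np.log(msd.lags)
    ly = np.log(msd.msd)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = intercept + slope * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot
    D = float(np.exp(intercept))
    if physical_2d:
        D /= 4.0
    return PowerLawFit(
        D_app=D, alpha=float(slope), r2=float(r2),
        n_traj=msd.n_traj, label=msd.label,
        excluded=bool(r2 < min_r2),
    )


# ---------------------------------------------------------------------------
# Geometry summaries
# ---------------------------------------------------------------------------

def radius_of_gyration(
    locs: pd.DataFrame,
    labels: np.ndarray | None = None,
) -> dict[object, float]:
    """Per-label radius of gyration (nm) of trajectory-centred positions.

    Each trajectory's XY positions are centred on the trajectory mean; the
    centred points are then partitioned by the label of the original
    localization, and Rg per label is the RMS distance from the origin of
    that label's points.
    """
    locs = validate_localizations(locs)
    if labels is None:
        labels = np.full(len(locs), "whole-cell", dtype=object)
    labels = np.asarray(labels)
    xy = locs[["x_nm", "y_nm"]].to_numpy(dtype=float)
    ids = locs["id"].to_numpy()

    centred = xy - pd.DataFrame(xy).groupby(ids).transform("mean").to_numpy()
    r2 = np.einsum("ij,ij->i", centred, centred)

    out: dict[object, float] = {}
    for lab in pd.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        out[lab] = float(np.sqrt(r2[sel].mean()))
    return out


def angular_anisotropy(
    locs: pd.DataFrame,
    labels: np.ndarray | None = None,
    window_deg: float = 30.0,
) -> dict[object, AnisotropySummary]:
    """Forward/backward counts of consecutive-displacement angles per label.

    For every triple of consecutive localizations the XY angle between the
    two displacement vectors is taken in (−180°, 180°]; the triple is labeled
    by the class of the middle point.  ``|angle| ≤ window`` counts forward,
    ``|angle| ≥ 180 − window`` backward (closed windows: −30..30 forward,
    150..210 backward at the default).
    """
    locs = validate_localizations(locs)
    if labels is None:
        labels = np.full(len(locs), "whole-cell", dtype=object)
    labels = np.asarray(labels)
    order = np.lexsort((locs["frame"].to_numpy(), locs["id"].to_numpy()))
    ids = locs["id"].to_numpy()[order]
    xy = locs[["x_nm", "y_nm"]].to_numpy(dtype=float)[order]
    labs = labels[order]

    fwd: dict[object, int] = {}
    bwd: dict[object, int] = {}
    same = (ids[2:] == ids[1:-1]) & (ids[1:-1] == ids[:-2])
    v1 = xy[1:-1] - xy[:-2]
    v2 = xy[2:] - xy[1:-1]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = np.einsum("ij,ij->i", v1, v2)
    ang = np.degrees(np.arctan2(cross, dot))
    mid_lab = labs[1:-1]
    for a, lab, ok in zip(ang, mid_lab, same):
        if not ok or lab == 0:
            continue
        if abs(a) <= window_deg:
            fwd[lab] = fwd.get(lab, 0) + 1
            bwd.setdefault(lab, 0)
        elif abs(a) >= 180.0 - window_deg:
            bwd[lab] = bwd.get(lab, 0) + 1
            fwd.setdefault(lab, 0)
    return {
        lab: AnisotropySummary(label=lab, n_forward=fwd.get(lab, 0),
                               n_backward=bwd.get(lab, 0))
        for lab in set(fwd) | set(bwd)
    }


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

def filter_fits(
    fits: list[PowerLawFit],
    min_traj: int = 250,
    min_r2: float = 0.95,
) -> list[PowerLawFit]:
    """Drop fits below the trajectory-count or goodness-of-fit thresholds."""
    return [f for f in fits if f.n_traj >= min_traj and f.r2 >= min_r2]


def subsample_trajectories(
    locs: pd.DataFrame,
    labels: np.ndarray,
    fixed_n: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Subsample to exactly ``fixed_n`` trajectories per label (seeded).

    A trajectory belongs to a label if any of its localizations carries it;
    labels smaller than ``fixed_n`` trajectories are dropped entirely, so
    every retained label contributes the same number of trajectories — the
    fixed-count control for class-imbalance artifacts.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    keep_rows = np.zeros(len(locs), dtype=bool)
    ids = locs["id"].to_numpy()
    for lab in pd.unique(labels):
        if lab == 0:
            continue
        lab_ids = np.unique(ids[labels == lab])
        if len(lab_ids) < fixed_n:
            continue
        chosen = rng.choice(lab_ids, size=fixed_n, replace=False)
        keep_rows |= np.isin(ids, chosen) & (labels == lab)
    return locs.loc[keep_rows].copy(), labels[keep_rows]
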