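"""Spatial statistics of SMLM nucleosome localizations.

The central quantity is the normalized 3D pair-correlation function

    G(r) = (N_R / N) · (DD(r) / RR(r)),

where DD(r) and RR(r) are the average numbers of pairs per object at
separation r in the data and in a matched random reference of N_R points
drawn uniformly in the same region (and thinned axially by the measured
z-detection envelope).  Because the reference occupies the same masked
region, G is edge-corrected by construction, and G ≡ 1 for complete spatial
randomness.  Fractal organization shows up as a power-law decay
``G(r) ∝ r^−γ`` whose exponent gives the fractal dimension ``d_f = 3 − γ``.

The module also provides the two-regime hinge fit used for whole-cell G(r)
curves, per-class localization densities, the blink-corrected nucleosome
density, and the chromatin-domain size read off where the log-log slope of
G(r) flattens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .types import CDCMap, validate_localizations

__all__ = [
    "BoxRegion",
    "MaskRegion",
    "AxialBiasModel",
    "PairCorrelation",
    "FractalEstimate",
    "HingeFit",
    "DensityEstimate",
    "DomainSize",
    "default_bins",
    "fit_axial_bias",
    "pair_correlation",
    "fit_fractal_dimension",
    "fit_two_regime_hinge",
    "localization_density",
    "estimate_blinks",
    "corrected_nucleosome_density",
    "estimate_domain_size",
]


def default_bins(r_min: float = 30.0, r_max: float = 1200.0, width: float = 10.0) -> np.ndarray:
    """Default G(r) bin edges: 10 nm bins from the ~30 nm precision floor."""
    return np.arange(r_min, r_max + width, width)


# ---------------------------------------------------------------------------
# Sampling regions for the random reference
# ---------------------------------------------------------------------------

class BoxRegion:
    """Axis-aligned box ((zmin, zmax), (ymin, ymax), (xmin, xmax)) in nm."""

    def __init__(self, bounds: tuple[tuple[float, float], ...]):
        self.bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
        for lo, hi in self.bounds:
            if hi <= lo:
                raise ValueError("region must have positive extent")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lows = np.array([lo for lo, _ in self.bounds])
        highs = np.array([hi for _, hi in self.bounds])
        return lows + (highs - lows) * rng.random((n, 3))

    @property
    def z_range(self) -> tuple[float, float]:
        return self.bounds[0]


class MaskRegion:
    """The voxel support of a label set — e.g. one CDC's voxels.

    Random points are drawn by picking a support voxel uniformly and then a
    uniform position within it, which confines the reference to the same
    masked region as the data (the edge correction of the normalization).
    """

    def __init__(self, support: np.ndarray, voxel_size: tuple[float, float, float]):
        self.voxels = np.argwhere(np.asarray(support, dtype=bool))
        if len(self.voxels) == 0:
            raise ValueError("empty region support")
        self.voxel_size = np.asarray(voxel_size, dtype=float)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        pick = rng.integers(0, len(self.voxels), n)
        # divide-and-round voxel convention: voxel i spans (i−½, i+½)·voxel
        return (self.voxels[pick] - 0.5 + rng.random((n, 3))) * self.voxel_size

    @property
    def z_range(self) -> tuple[float, float]:
        zmin = (self.voxels[:, 0].min() - 0.5) * self.voxel_size[0]
        zmax = (self.voxels[:, 0].max() + 0.5) * self.voxel_size[0]
        return float(zmin), float(zmax)


# ---------------------------------------------------------------------------
# Axial detection bias
# ---------------------------------------------------------------------------

@dataclass
class AxialBiasModel:
    """Gaussian z-detection envelope fitted to the localization z-histogram.

    ``sigma=None`` denotes the uniform (no-bias) fallback.
    """

    center: float | None
    sigma: float | None
    r2: float = float("nan")

    def acceptance(self, z: np.ndarray) -> np.ndarray:
        """Thinning probability (max-normalized) for reference points."""
        if self.sigma is None:
            return np.ones_like(np.asarray(z, dtype=float))
        return np.exp(-((np.asarray(z, dtype=float) - self.center) ** 2)
                      / (2.0 * self.sigma ** 2))


def fit_axial_bias(locs: pd.DataFrame, bin_width: float = 100.0) -> AxialBiasModel:
    """Fit a Gaussian to the z-histogram of localization counts.

    The fitted envelope is used to thin the random reference so it suffers
    the same axial sampling bias as the data.  A flat histogram falls back
    to the uniform model with a warning; fully degenerate input (all z
    identical) raises.
    """
    locs = validate_localizations(locs)
    if len(locs) < 100:
        raise ValueError("need at least 100 localizations to fit the z envelope")
    z = locs["z_nm"].to_numpy(dtype=float)
    if np.ptp(z) == 0:
        raise ValueError("all z identical: axial histogram degenerate")
    edges = np.arange(z.min(), z.max() + bin_width, bin_width)
    if len(edges) < 4:
        warnings.warn("too few z-planes for a Gaussian fit; using uniform reference")
        return AxialBiasModel(center=None, sigma=None)
    counts, edges = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(zz, a, mu, sd):
        return a * np.exp(-((zz - mu) ** 2) / (2.0 * sd ** 2))

    try:
        p0 = (counts.max(), centers[np.argmax(counts)], np.ptp(z) / 4)
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=5000)
        pred = gauss(centers, *popt)
        ss_tot = float(np.sum((counts - counts.mean()) ** 2))
        if ss_tot == 0:
            raise RuntimeError("flat histogram")
        r2 = 1.0 - float(np.sum((counts - pred) ** 2)) / ss_tot
        if r2 < 0.2 or popt[2] <= 0 or not np.isfinite(popt).all():
            raise RuntimeError("poor Gaussian fit")
    except RuntimeError:
        warnings.warn("z-envelope Gaussian fit failed; using uniform reference")
        return AxialBiasModel(center=None, sigma=None)
    return AxialBiasModel(center=float(popt[1]), sigma=abs(float(popt[2])), r2=r2)


# ---------------------------------------------------------------------------
# Pair correlation
# ---------------------------------------------------------------------------

@dataclass
class PairCorrelation:
    """Binned G(r) with its pair counts and matched random reference.

    ``RR`` is the summed raw pair count over the reference realizations and
    ``rr_per_pair`` the realization-averaged per-ordered-pair count that G
    is normalized by.
    """

    r: np.ndarray            # bin centers, nm
    G: np.ndarray
    DD: np.ndarray           # raw data-data pair counts per bin
    RR: np.ndarray           # summed reference pair counts per bin
    N: int
    N_R: int                 # total reference points over all realizations
    rr_per_pair: np.ndarray | None = None
    label: object = "whole-cell"
    data_points: np.ndarray | None = None
    reference_points: list[np.ndarray] | None = None


def _pair_counts(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    tree = cKDTree(points)
    return tree.count_neighbors(tree, edges, cumulative=False)[1:].astype(float)


def pair_correlation(
    locs: pd.DataFrame,
    region: BoxRegion | MaskRegion,
    bins: np.ndarray | None = None,
    bias: AxialBiasModel | None = None,
    n_random_factor: int = 10,
    seed: int = 0,
    label: object = "whole-cell",
    keep_points: bool = False,
) -> PairCorrelation:
    """Normalized 3D pair-correlation function with a matched reference.

    With per-object pair averages ``DD(r)/N`` and ``RR(r)/N_R`` the
    normalization reads ``G = (N_R/N)·(DD/N)/(RR/N_R) =
    (DD/N²)/(RR/N_R²)``, which makes G independent of both the data count
    and the reference size.  The reference matches the data density (one
    realization of N points uniform in ``region``, thinned axially by
    ``bias``); ``n_random_factor`` independent realizations are averaged to
    suppress reference shot noise — pair counting cost grows linearly in
    the factor this way rather than quadratically in one enlarged set.
    """
    locs = validate_localizations(locs)
    if len(locs) < 2:
        raise ValueError("need at least 2 localizations")
    if bins is None:
        bins = default_bins()
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be strictly increasing")

    data = locs[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    N = len(data)

    DD = _pair_counts(data, bins)
    RR_sum = np.zeros(len(bins) - 1)
    rr_norms = []
    refs = []
    for _ in range(max(1, n_random_factor)):
        ref = region.sample(rng, N)
        if bias is not None and bias.sigma is not None:
            ref = ref[rng.random(len(ref)) < bias.acceptance(ref[:, 0])]
        if len(ref) < 2:
            continue
        counts = _pair_counts(ref, bins)
        RR_sum += counts
        rr_norms.append(counts / (len(ref) ** 2))
        refs.append(ref)
    if not rr_norms:
        raise ValueError("reference collapsed to fewer than 2 points")
    rr_per_pair = np.mean(rr_norms, axis=0)
    N_R = int(sum(len(r_) for r_ in refs))

    with np.errstate(divide="ignore", invalid="ignore"):
        G = (DD / N ** 2) / rr_per_pair
    G[rr_per_pair == 0] = np.nan
    return PairCorrelation(
        r=0.5 * (bins[:-1] + bins[1:]), G=G, DD=DD, RR=RR_sum, N=N, N_R=N_R,
        rr_per_pair=rr_per_pair, label=label,
        data_points=data if keep_points else None,
        reference_points=refs if keep_points else None,
    )


# ---------------------------------------------------------------------------
# Fractal-dimension fits
# ---------------------------------------------------------------------------

@dataclass
class FractalEstimate:
    """Power-law fit of G(r) and the implied fractal dimension d_f = 3 − γ."""

    gamma: float
    d_f: float
    r_min: float
    r_max: float
    r2: float
    label: object = "whole-cell"

    @property
    def retained(self) -> bool:
        """Inclusion rule: fits with r² < 0.95 are excluded downstream."""
        return self.r2 >= 0.95


def _loglog_fit(r: np.ndarray, g: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of log G on log r; returns (slope, intercept, r2, ssr)."""
    lx, ly = np.log(r), np.log(g)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = intercept + slope * lx
    ssr = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if (ss_tot == 0 and ssr <= 1e-24) else 1.0 - ssr / ss_tot
    return float(slope), float(intercept), float(r2), ssr


def fit_fractal_dimension(
    pc: PairCorrelation,
    r_min: float = 35.0,
    r2_floor: float = 0.98,
    min_bins: int = 3,
) -> FractalEstimate:
    """Estimate γ and d_f from the power-law regime of G(r).

    A log-log regression starts at ``r_min`` (the localization-precision
    floor) over the smallest admissible window and the upper bound grows bin
    by bin until the fit r² drops below ``r2_floor``; the last fit at or
    above the floor is reported.  ``d_f = 3 − γ``.
    """
    ok = (pc.r >= r_min) & np.isfinite(pc.G) & (pc.G > 0)
    r, g = pc.r[ok], pc.G[ok]
    if len(r) < min_bins:
        raise ValueError("fewer than 3 usable bins above r_min")
    best = None
    for upper in range(min_bins, len(r) + 1):
        slope, _, r2, _ = _loglog_fit(r[:upper], g[:upper])
        if best is None:
            best = (slope, r2, upper)
        if r2 < r2_floor and upper > min_bins:
            break
        if r2 >= r2_floor or upper == min_bins:
            best = (slope, r2, upper)
    slope, r2, upper = best
    gamma = -slope
    return FractalEstimate(
        gamma=gamma, d_f=3.0 - gamma,
        r_min=float(r[0]), r_max=float(r[upper - 1]), r2=r2, label=pc.label,
    )


@dataclass
class HingeFit:
    """Two-segment log-log fit of whole-cell G(r) with an optimal breakpoint."""

    hinge_r: float
    lower: FractalEstimate
    upper: FractalEstimate
    combined_ssr: float
    degenerate: bool = False


def fit_two_regime_hinge(
    pc: PairCorrelation,
    r_lo: float = 75.0,
    r_hi: float = 505.0,
    min_bins: int = 3,
) -> HingeFit:
    """Find the breakpoint separating the two scaling regimes of G(r).

    For every candidate hinge r* in [r_lo, r_hi] two log-log regressions are
    fitted — [r_lo, r*] and [r*, r_hi] — and the hinge minimizing the
    combined summed squared residuals is selected; per-regime fractal
    dimensions come from the segment slopes.  If the SSR profile is flat
    (single-slope curve) the fit is flagged degenerate.
    """
    ok = (pc.r >= r_lo) & (pc.r <= r_hi) & np.isfinite(pc.G) & (pc.G > 0)
    r, g = pc.r[ok], pc.G[ok]
    if len(r) < 2 * min_bins:
        raise ValueError("hinge window outside data support or too few bins")
    results = []
    for i in range(min_bins - 1, len(r) - min_bins + 1):
        lo_s, _, lo_r2, lo_ssr = _loglog_fit(r[:i + 1], g[:i + 1])
        hi_s, _, hi_r2, hi_ssr = _loglog_fit(r[i:], g[i:])
        results.append((lo_ssr + hi_ssr, i, lo_s, lo_r2, hi_s, hi_r2))
    ssrs = np.array([x[0] for x in results])
    best = results[int(np.argmin(ssrs))]
    _, i, lo_s, lo_r2, hi_s, hi_r2 = best
    degenerate = bool(np.ptp(ssrs) <= 1e-10 * (1.0 + ssrs.max()))
    lower = FractalEstimate(gamma=-lo_s, d_f=3.0 + lo_s, r_min=float(r[0]),
                            r_max=float(r[i]), r2=lo_r2, label=pc.label)
    upper = FractalEstimate(gamma=-hi_s, d_f=3.0 + hi_s, r_min=float(r[i]),
                            r_max=float(r[-1]), r2=hi_r2, label=pc.label)
    return HingeFit(hinge_r=float(r[i]), lower=lower, upper=upper,
                    combined_ssr=float(best[0]), degenerate=degenerate)


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def localization_density(
    locs: pd.DataFrame,
    cdc: CDCMap,
) -> dict[int, float]:
    """Localizations per µm³ for each density class.

    Count of localizations assigned to the class divided by the class volume
    (voxel count × voxel volume).  Empty classes get NaN (flagged via a
    warning) rather than a silent zero.
    """
    from .tracking import assign_cdc

    labels = assign_cdc(locs, cdc)
    out: dict[int, float] = {}
    for k in range(1, cdc.K + 1):
        n_vox = int(np.count_nonzero(cdc.labels == k))
        if n_vox == 0:
            warnings.warn(f"class {k} has no voxels; density undefined")
            out[k] = float("nan")
            continue
        out[k] = float(np.count_nonzero(labels == k) / (n_vox * _voxel_um3(cdc)))
    return out


def _voxel_um3(cdc: CDCMap) -> float:
    vz, vy, vx = cdc.voxel_size
    return vz * vy * vx * 1e-9


def estimate_blinks(
    locs: pd.DataFrame,
    eps: float = 100.0,
    min_samples: int = 1,
) -> float:
    """Mean localizations per dye molecule from density-based clustering.

    DBSCAN (radius ``eps`` nm, ``min_samples`` = 1 so isolated localizations
    form singleton clusters) groups the merged SMLM stream into per-molecule
    clusters; the blink count N_blinks is the mean cluster size.
    """
    locs = validate_localizations(locs)
    if len(locs) == 0:
        raise ValueError("no localizations to cluster")
    xyz = locs[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    lab = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(xyz)
    lab = lab[lab >= 0]
    if len(lab) == 0:
        raise ValueError("no clusters found")
    _, sizes = np.unique(lab, return_counts=True)
    return float(sizes.mean())


@dataclass
class DensityEstimate:
    """Blink- and labeling-corrected nucleosome density for one class."""

    rho_loc: float            # localizations / µm³
    n_blinks: float
    tag_fraction: float       # HaloTag-H2B : endogenous H2B (western blot)
    expressing_fraction: float
    label: object = "whole-cell"

    @property
    def rho_corrected(self) -> float:
        return corrected_nucleosome_density(
            self.rho_loc, self.n_blinks, self.tag_fraction, self.expressing_fraction)


def corrected_nucleosome_density(
    rho_loc: float,
    n_blinks: float,
    tag_fraction: float,
    expressing_fraction: float = 1.0,
) -> float:
    """Corrected nucleosome density ⟨ρ⟩ = ρ_loc/(N_blinks·tag·expressing).

    Raw localization density over-counts molecules by the mean blink number
    and under-counts nucleosomes by the tagged fraction of H2B and the
    fraction of cells expressing the tag; all three corrections are exact
    multiplicative factors.
    """
    for name, v in (("rho_loc", rho_loc), ("n_blinks", n_blinks),
                    ("tag_fraction", tag_fraction),
                    ("expressing_fraction", expressing_fraction)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return rho_loc / n_blinks / tag_fraction / expressing_fraction


# ---------------------------------------------------------------------------
# Domain size
# ---------------------------------------------------------------------------

@dataclass
class DomainSize:
    """Chromatin-domain size from where the G(r) log-log slope flattens."""

    r_detect: float      # nm
    R2_nm2: float        # ⟨R²⟩ = r_detect², nm²
    label: object = "whole-cell"


def estimate_domain_size(
    pc: PairCorrelation,
    slope_tol: float = 0.05,
    smooth_window: int = 7,
) -> DomainSize:
    """Smallest r where the smoothed log-log slope of G(r) flattens.

    The log-log curve is smoothed with a Savitzky–Golay filter before
    differentiating; the first bin where ``|d log G / d log r| < slope_tol``
    is the detected domain radius and ⟨R²⟩ is its square.  A curve whose
    slope never flattens raises with the maximum-r diagnostic.
    """
    ok = np.isfinite(pc.G) & (pc.G > 0)
    r, g = pc.r[ok], pc.G[ok]
    if len(r) < smooth_window:
        raise ValueError("too few bins for slope estimation")
    lx, ly = np.log(r), np.log(g)
    win = min(smooth_window, len(r))
    if win % 2 == 0:
        win -= 1
    ly_s = savgol_filter(ly, window_length=max(win, 3), polyorder=2)
    # consecutive-bin slope of the smoothed curve; report the left edge of
    # the first flat pair so a sharp flattening is located within one bin
    slope = np.diff(ly_s) / np.diff(lx)
    flat = np.flatnonzero(np.abs(slope) < slope_tol)
    if len(flat) == 0:
        raise ValueError(
            f"G(r) slope never flattens below {slope_tol} up to r={r[-1]:.0f} nm")
    r_det = float(r[flat[0]])
    return DomainSize(r_detect=r_det, R2_nm2=r_det ** 2, label=pc.label)
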