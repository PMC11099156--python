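"""Chromatin density classification (CDC) of nuclear volumes.

Every nuclear voxel of a deconvolved chromatin volume is assigned to one of
K density classes (CDC1 sparsest … CDCK densest, K = 7 by default) by
fitting a Gaussian intensity mixture with EM and regularizing the voxel
labeling spatially with a 26-neighbour Potts Markov random field solved by
iterated conditional modes (ICM).  The module also produces the scrambled
control maps (randomly transformed composites that preserve the intensity
marginal but destroy spatial correspondence), the 500 nm periphery/interior
partition, and per-class voxel proportions.

The MRF labeling is a reimplementation of the published
maximum-likelihood/MRF approach this analysis family delegates to an
external package; the neighborhood order and coupling strength of the
original are unpublished, so both are explicit parameters here and
equivalence to the original estimator is not claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .types import CDCMap, DistanceMap, IntensityVolume, NuclearMask, RegionPartition

__all__ = [
    "MixtureFit",
    "fit_mixture",
    "fit_mixture_select_k",
    "zscore_criteria",
    "classify_mrf",
    "trim_edge_cdc1",
    "scramble_cdc",
    "partition_periphery",
    "cdc_proportions",
]


@dataclass
class MixtureFit:
    """A K-component Gaussian intensity mixture with selection criteria."""

    K: int
    weights: np.ndarray
    means: np.ndarray       # sorted ascending; class k (1-based) = means[k-1]
    sds: np.ndarray
    log_likelihood: float
    aic: float
    bic: float
    converged: bool = True

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior class probabilities, shape (n, K)."""
        x = np.asarray(x, dtype=float)[:, None]
        log_pdf = (
            -0.5 * ((x - self.means[None, :]) / self.sds[None, :]) ** 2
            - np.log(self.sds[None, :])
            + np.log(self.weights[None, :])
        )
        log_pdf -= log_pdf.max(axis=1, keepdims=True)
        p = np.exp(log_pdf)
        return p / p.sum(axis=1, keepdims=True)

    def log_component_likelihood(self, x: np.ndarray) -> np.ndarray:
        """Per-class Gaussian log likelihood (no weights), shape (n, K)."""
        x = np.asarray(x, dtype=float)[:, None]
        return (
            -0.5 * ((x - self.means[None, :]) / self.sds[None, :]) ** 2
            - np.log(self.sds[None, :])
            - 0.5 * np.log(2 * np.pi)
        )


def fit_mixture(
    intensities: np.ndarray,
    K: int,
    n_init: int = 10,
    seed: int = 0,
    max_iter: int = 300,
) -> MixtureFit:
    """EM fit of a K-component Gaussian mixture to 1D intensities.

    Initialization uses k-means with ``n_init`` restarts (best likelihood
    kept) and a fixed seed for reproducibility.  Classes are reported sorted
    by mean.  Zero-variance data are degenerate and rejected.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if len(x) < 2 * K:
        raise ValueError("too few intensities for the requested K")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance intensities: mixture fit degenerate")
    gm = GaussianMixture(
        n_components=K, covariance_type="full", n_init=n_init,
        random_state=seed, max_iter=max_iter, reg_covar=1e-6,
    ).fit(x[:, None])
    if not gm.converged_:
        warnings.warn(f"EM did not converge for K={K}")
    order = np.argsort(gm.means_.ravel())
    ll = float(gm.score(x[:, None]) * len(x))
    return MixtureFit(
        K=K,
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        log_likelihood=ll,
        aic=float(gm.aic(x[:, None])),
        bic=float(gm.bic(x[:, None])),
        converged=bool(gm.converged_),
    )


def fit_mixture_select_k(
    intensities: np.ndarray,
    k_range: range | list[int] = range(1, 11),
    criterion: str = "bic",
    n_init: int = 10,
    seed: int = 0,
) -> tuple[dict[int, MixtureFit], int]:
    """Fit mixtures over ``k_range`` and select K by AIC or BIC.

    ``intensities`` should be the masked, deconvolved, non-zero voxel values
    flattened to 1D.  Returns all fits plus the selected K.  When pooling
    across cells, normalize each cell's criteria with
    :func:`zscore_criteria` before averaging and selecting.
    """
    fits = {k: fit_mixture(intensities, k, n_init=n_init, seed=seed) for k in k_range}
    key = (lambda k: fits[k].bic) if criterion == "bic" else (lambda k: fits[k].aic)
    best = min(fits, key=key)
    return fits, best


def zscore_criteria(values: np.ndarray) -> np.ndarray:
    """Z-score normalize one cell's criterion values across its K sweep."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def classify_mrf(
    vol: IntensityVolume,
    mask: NuclearMask,
    fit: MixtureFit,
    beta: float = 0.7,
    max_sweeps: int = 10,
) -> CDCMap:
    """MRF-regularized density-class labeling of masked voxels.

    Energy per voxel v with label k:
    ``−log N(I_v | µ_k, σ_k) − β · #{26-neighbours of v with label k}``;
    ICM sweeps from the per-voxel posterior-argmax initialization until the
    labeling is stable.  ``beta = 0`` reduces exactly to the posterior
    argmax of the mixture.  Labels are ordered by class mean (CDC1 = lowest
    intensity).  The default coupling is calibrated so well-separated
    phantoms misclassify < 1% of voxels.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if vol.shape != mask.shape:
        raise ValueError("volume and mask must share a shape")
    m = mask.data
    vals = vol.data[m]
    K = fit.K

    post = fit.responsibilities(vals)
    labels_flat = np.argmax(post, axis=1) + 1
    labels = np.zeros(vol.shape, dtype=np.int32)
    labels[m] = labels_flat

    if beta > 0 and K > 1:
        loglik = np.zeros(vol.shape + (K,))
        loglik[m] = fit.log_component_likelihood(vals)
        kernel = np.ones((3, 3, 3))
        kernel[1, 1, 1] = 0.0
        for _ in range(max_sweeps):
            energy = np.empty(vol.shape + (K,))
            for k in range(K):
                nbr = ndimage.convolve((labels == k + 1).astype(float), kernel,
                                       mode="constant", cval=0.0)
                energy[..., k] = -loglik[..., k] - beta * nbr
            new_labels = np.zeros_like(labels)
            new_labels[m] = np.argmin(energy[m], axis=1) + 1
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels

    return CDCMap(labels, K=K, voxel_size=vol.voxel_size, provenance="real")


def trim_edge_cdc1(cdc: CDCMap, mask: NuclearMask) -> CDCMap:
    """Remove CDC1 voxels closer than 5 voxels to the nuclear-mask edge.

    Compensates for the diffraction roll-off in intensity at the nuclear
    boundary, which otherwise inflates the sparsest class there.  Distance is
    Euclidean in voxel units; only CDC1 is affected.
    """
    if cdc.shape != mask.shape:
        raise ValueError("cdc and mask must share a shape")
    dist_vox = ndimage.distance_transform_edt(mask.data)
    labels = cdc.labels.copy()
    labels[(labels == 1) & (dist_vox < 5)] = 0
    return CDCMap(labels, K=cdc.K, voxel_size=cdc.voxel_size, provenance=cdc.provenance)


def scramble_cdc(
    vol: IntensityVolume,
    mask: NuclearMask,
    fit: MixtureFit,
    beta: float = 0.7,
    n_iter: int = 10,
    seed: int = 0,
    max_rotation_deg: float = 360.0,
) -> CDCMap:
    """Scrambled-control density map from randomly transformed copies.

    The deconvolved volume is iteratively rotated about z and translated in
    all three axes (translations up to half the field); at each iteration
    only voxels not already occupied by non-zero values are filled, building
    a composite that preserves the gross morphology and intensity marginal
    while destroying spatial correspondence with the real map.  The
    composite is clipped to the original mask and classified with the
    standard MRF pipeline; a warning reports coverage if the composite fails
    to cover the mask.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    composite = np.zeros_like(vol.data)
    nz, ny, nx = vol.shape
    for _ in range(n_iter):
        angle = rng.uniform(0.0, max_rotation_deg)
        shift = (
            rng.integers(-nz // 2, nz // 2 + 1),
            rng.integers(-ny // 2, ny // 2 + 1),
            rng.integers(-nx // 2, nx // 2 + 1),
        )
        t = ndimage.rotate(vol.data, angle, axes=(1, 2), reshape=False, order=0)
        t = ndimage.shift(t, shift, order=0, mode="constant", cval=0.0)
        fill = (composite == 0) & (t > 0)
        composite[fill] = t[fill]
    composite[~mask.data] = 0.0
    covered = np.count_nonzero(composite[mask.data]) / max(1, int(mask.data.sum()))
    if covered < 1.0:
        warnings.warn(f"scramble composite covers {covered:.1%} of the mask")
    out = classify_mrf(IntensityVolume(composite, voxel_size=vol.voxel_size),
                       mask, fit, beta=beta)
    out.provenance = "scrambled"
    return out


def partition_periphery(
    cdc: CDCMap,
    dist: DistanceMap,
    cutoff: float = 500.0,
) -> RegionPartition:
    """Split the nuclear foreground at ``cutoff`` nm from the mask edge.

    Periphery = foreground voxels with edge distance ≤ cutoff; interior =
    the rest.  Apply the returned boolean grids to a CDCMap's labels to get
    per-region maps.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cdc.shape != dist.data.shape:
        raise ValueError("cdc and distance map must share a shape")
    fg = dist.data > 0
    periphery = fg & (dist.data <= cutoff)
    interior = fg & (dist.data > cutoff)
    return RegionPartition(periphery=periphery, interior=interior, cutoff_nm=cutoff)


def cdc_proportions(cdc: CDCMap) -> np.ndarray:
    """Fractions of foreground voxels per class 1..K (sums to 1)."""
    fg = cdc.labels > 0
    if not np.any(fg):
        raise ValueError("empty foreground")
    counts = np.bincount(cdc.labels[fg], minlength=cdc.K + 1)[1:]
    return counts / counts.sum()
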