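# Methods

This note documents the models, estimators, parameter choices and known
limitations of `nucleodyn`, in the order data flows through the package.

## Synthetic data: what it emulates, and what it does not

The generators in `nucleodyn.synth` stand in for three data modalities:
live-cell 3D single-molecule tracking of chromatin-bound particles,
fixed-cell SMLM point clouds of nucleosomes, and diffraction-limited
chromatin intensity volumes. Their defaults mirror the acquisition they
emulate: 20 ms frame interval, 25 frames per slice, ~25 nm lateral and
~140 nm axial tracking precision, ~18/80 nm SMLM precision, 110×110×250 nm
live-cell voxels, and 110 nm isotropic SMLM histogram bins. All generators
are bit-reproducible under a fixed seed.

**Trajectories.** Each axis is an exact fractional Brownian motion with
Hurst index α/2, sampled by eigendecomposition of the exact fBm covariance
(sharp recovery tests need exact second moments; the eigen route also
handles the singular ballistic limit α = 2). The per-axis variance is
scaled so the ensemble *lateral* MSD is exactly `D·τ^α` in µm² — the same
convention the fitting stage uses. The axial path carries the same per-axis
variance; the axial anisotropy of real data enters through the larger
axial localization error, which is added as independent Gaussian noise per
localization (homoscedastic: the depth-dependence of precision in real
data is not modeled).

**Fractal clouds.** Molecule positions are drawn from a lognormal
intensity field `λ = exp(Z)` where `Z` is a Gaussian field with
logarithmic covariance `C(r) = γ·ln(L/r)` for `r < L` (synthesized
spectrally on a periodic grid). Then `E[λ(x)λ(y)]/E[λ]² = exp(C) =
(L/r)^γ` — the pair correlation is a *pure power law by construction*
between the grid scale (default 20 nm) and the correlation length `L`
(default 300 nm, playing the role of the chromatin-domain scale at which
G(r) flattens to 1). The target dimension enters as `γ = 3 − d_f`;
`d_f = 3` reduces to a uniform distribution. This construction was chosen
over a Soneira–Peebles-style hierarchical cascade after oracle validation:
the cascade's finite-level exponent is strongly pre-asymptotic in the
35–500 nm measurement window (errors up to ±0.5 in d_f, non-monotone in
the length ratio), whereas the lognormal field recovers d_f within ±0.05
on 3-cloud means across d_f ∈ [2, 3]. Two caveats are inherent to the
lognormal construction: correlations flatten below the grid scale and
above `L`, so fits must live inside that window; and single-realization
estimates at strong clustering (γ ≈ 1) scatter by roughly ±0.1 because
the heavy-tailed field self-averages slowly — analyses therefore average
over several clouds, as a real study averages over cells.

Blinking is modeled as a Poisson number of localizations per molecule
(mean `blink_mean`; molecules with zero detections are dropped, so the
realized per-molecule mean is the zero-truncated value), scattered
uniformly within `blink_radius`; no photophysics (dark-state kinetics,
frame-split bursts) is modeled. The axial detection envelope thins
localizations with Gaussian acceptance in z, matching how the random
reference is thinned in the G(r) estimator.

**Volumes.** A white-noise field smoothed at `smoothing_scale` (1.5
voxels) is quantile-partitioned into K equal-prevalence, spatially
correlated latent classes inside an ellipsoidal nucleus; intensities are
class-conditional Gaussians (default means 100…700, SD 12 — ≈8 SD
separation). Real chromatin volumes have unequal class prevalences,
intensity gradients and PSF anisotropy that this phantom does not attempt;
passing segmentation tests therefore demonstrates estimator correctness at
honest separations, not performance on marginal real data.

**Correlated scenes** seed each trajectory at a random foreground voxel
(origin at `voxel_index × voxel_size`, so the divide-and-round CDC lookup
maps it back to its voxel) and give it the (D, α) of that voxel's true
class. Trajectories are short relative to voxels, so class mixing along a
trajectory is minor but present — as in real data, where it is handled by
the final-localization assignment rule.

## Volume processing

Dark-current subtraction clamps negatives at zero. Channel registration is
integer-voxel phase cross-correlation; the returned tuple is the
displacement of the moving volume relative to the reference and
`apply_shift` undoes it. Nuclear masking is Otsu/multi-Otsu thresholding,
morphological opening, hole filling, small-object removal, then keeping
the largest connected component. Richardson–Lucy deconvolution (default
20 iterations) mirrors the volume across z on both faces before iterating
and crops back afterwards; x/y are reflect-padded by one PSF half-width
(the axial treatment matters most because the axial PSF extent is
comparable to the stack depth). No regularization or background term is
used. The distance-to-edge map is a Euclidean distance transform with
anisotropic voxel sampling, in nm. The radial power spectrum bins squared
FFT magnitudes into unit-width radial-frequency annuli starting at radius
0.5, weights each bin by its annulus area and normalizes by the maximum
(so the output peaks at exactly 1 and is invariant to intensity
rescaling).

## Density classification

Voxel intensities (masked, deconvolved, non-zero, flattened) are fitted
with a K-component Gaussian mixture (EM via scikit-learn, k-means
initialization, 10 restarts, fixed seed); AIC/BIC select K, with per-cell
z-score normalization of the criteria before pooling across cells. K
defaults to 7. Labeling minimizes, per voxel, the energy
`−log N(I | µ_k, σ_k) − β · #{26-neighbours with label k}` by ICM from the
posterior-argmax initialization; `β = 0` reduces exactly to posterior
argmax. The default coupling β = 0.7 was calibrated on phantoms at the
default class separation to keep misclassification below 1% while still
removing isolated discordant voxels. The published analysis this
reimplements delegates to an external MRF package whose neighbourhood
order and coupling are unpublished; equivalence to that estimator is not
claimed, and both knobs are exposed. After labeling, CDC1 voxels with
voxel-metric (Euclidean) edge distance < 5 are removed — the diffraction
roll-off at the nuclear rim otherwise inflates the sparsest class.

Scrambled controls iteratively rotate the volume about z (rotations about
x/y would move mass out of the thin axial extent) and translate it in all
three axes by up to half the field, compositing only into voxels not
already occupied, clipping to the original mask, and classifying with the
standard pipeline. This preserves the intensity marginal (and hence class
proportions) while reducing voxelwise agreement with the real map to
chance.

## Trajectory analysis

Linking enforces a 400 nm maximum lateral displacement, a 2-frame maximum
gap, and no merging or splitting; frame-to-frame correspondence is the
globally optimal assignment (Hungarian) on lateral distance — a
reproducible, dependency-free stand-in for the original tracker's cost
model with the same hard constraints. SMLM blink merging collapses
localizations within 100 nm and less than 2 frames apart into their mean.

MSD is lateral (x–y) only, over all within-trajectory pairs up to a lag
cap (500 ms for nucleosomes, 125 ms for the inert tracer), pooled per
label; a displacement inherits the CDC of its final localization.
**Static-error subtraction:** at the default acquisition the precision
floor (4σ² ≈ 2500 nm² for σ = 25 nm) exceeds the true lag-1 MSD
(~440 nm²), so the estimator subtracts the per-pair offset
`2(σ_i² + σ_j²)` using the table's per-localization precisions (on by
default, switchable). Without it, no log-log fit can recover (D, α) at
these conditions. Fits are ordinary least squares of log MSD on log τ; `D`
is the exponential of the intercept (apparent coefficient). A
`physical_2d` flag divides by 4 for the `MSD = 4Dτ^α` convention; all
internal comparisons use the intercept convention consistently. Fits with
r² < 0.95 or fewer than 250 trajectories are excluded; a seeded
fixed-count subsampler provides the equal-n control. Anisotropy classifies
the XY angle between consecutive displacements as forward (|θ| ≤ 30°) or
backward (|θ| ≥ 150°), closed windows, labeled by the middle point's CDC;
a zero backward count yields NaN fold change, never a pseudocount.

## Spatial statistics

G(r) uses raw pair counts with the per-object normalization
`G = (DD/N²)/(RR/N_R²)`, which is independent of both the data count and
reference size. The reference matches the data density — one realization
of N uniform points in the same region (box or the voxel support of a
CDC, which makes the estimator edge-corrected by construction), axially
thinned by the fitted Gaussian z-envelope. `n_random_factor` (default 10)
independent realizations are averaged; this cuts reference shot noise
linearly in cost, whereas one enlarged reference would cost quadratically
in pair counting. Default bins are 10 nm wide from 30 nm (the precision
floor) to 1200 nm; analyses of the synthetic clouds fit below the
generator's correlation length (bins to ~250 nm).

The fractal fit regresses log G on log r from 35 nm, growing the upper
bound bin by bin until r² drops below 0.98, and reports d_f = 3 − γ;
estimates with r² < 0.95 are flagged excluded. The whole-cell hinge fit
scans every candidate breakpoint in [75, 505] nm, fits the two segments,
and minimizes combined SSR; a flat SSR profile (single slope) is flagged
degenerate. Localization density is count/volume per CDC (NaN for empty
classes). Blink number is the mean DBSCAN cluster size (eps and minPts
configurable; eps must exceed the 3D burst spread and stay below molecule
spacing — defaults 100 nm, 1). The domain size is the first radius where
the consecutive-bin slope of the Savitzky–Golay-smoothed (window 7,
order 2) log-log curve falls below `slope_tol` = 0.05; the squared radius
is ⟨R²⟩.

## The fractal-Rouse map

The model treats nucleosomes as monomers of a Rouse polymer arranged with
fractal dimension d_f in a viscoelastic medium probed by an inert tracer.
Implementation notes: the constants A, B, C are evaluated in closed form
(validated against 30-digit symbolic evaluation); the valid domain is
d_f ∈ (1, 3] — below that sin(π/d_f) changes sign — and chromatin
estimates (2.1–2.9) sit comfortably inside. Units are µm throughout;
nm²→µm² conversion of ⟨R²⟩ is explicit. `D_halo` defaults to the same
intercept convention as the fits (recorded in prediction metadata).
Error propagation samples (α_halo, d_f) from independent truncated
Gaussians (default 10⁴ draws, seeded); the delta method is provided as a
cross-check but is not the default because D_nuc is strongly nonlinear in
d_f at realistic uncertainties. Model-experiment comparison accepts
interior-region fits only: at the nuclear periphery lamina tethering
violates the monodisperse-polymer assumption, so periphery fits are
rejected rather than silently compared.

## Problem sizes and determinism

The test suite and the acceptance script run study-scale but desk-sized
problems: 2,000 trajectories × 25 frames for diffusion recovery, 20,000
points per cloud (3 clouds per d_f target), 20,000-point CSR nulls,
20×56×56-voxel volumes, and 20-seed repetition for selection/sign-rate
statistics. These sizes were chosen so each statistic's Monte-Carlo error
is well below the tolerance it is compared against. Every random stage
takes an explicit seed; identical configurations produce byte-identical
outputs.

## Known limitations

* Localization noise is homoscedastic; depth-dependent precision is not
  modeled.
* The cloud generator's fractal scaling lives strictly between its grid
  scale and correlation length; fits outside that window measure the
  cutoffs, not d_f.
* The MRF classifier is a reimplementation with explicit (neighbourhood,
  β) choices, not a port of the unpublished original.
* The linker is optimal per frame pair, not over whole tracks; at the
  densities tested this makes no measurable difference, but very dense
  streams could differ from a global tracker.
* No camera/optics simulation: localization error is injected directly,
  and rendered volumes are histogram-convolutions with a supplied PSF.
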