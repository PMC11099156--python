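# nucleodyn

Correlative analysis of single-nucleosome dynamics and the local chromatin
environment, as a tested, reusable Python library.

## The scientific problem

In live-cell light-sheet experiments, single nucleosomes (HaloTag-H2B) are
tracked in 3D at 20 ms per frame while the surrounding chromatin density is
imaged simultaneously at diffraction-limited resolution. Complementary
fixed-cell super-resolution (SMLM) imaging maps nucleosome positions to
~20 nm. Three questions connect these data: how does nucleosome mobility
depend on local chromatin density, how does nucleosome *packing* (its
fractal organization) change with density, and can a polymer model with no
free parameters predict the motion from the packing?

`nucleodyn` implements the full analysis chain:

* **Chromatin density classification (CDC)** — nuclear voxels of the
  deconvolved chromatin volume are assigned to K classes (default 7, CDC1
  sparsest … CDC7 densest) by a Gaussian intensity mixture fitted with EM
  and a 26-neighbour Potts Markov random field solved by iterated
  conditional modes, with AIC/BIC class-count selection, a 500 nm
  periphery/interior partition, and scrambled-map controls.
* **Anomalous-diffusion analysis** — trajectories are linked (400 nm /
  2-frame gap rule, Hungarian assignment, no merging or splitting), each
  displacement inherits the CDC of its final localization, and per-class
  ensemble lateral MSDs are fitted to

  ```
  log MSD(τ) = log D + α · log τ
  ```

  with the inclusion filters r² ≥ 0.95 and ≥ 250 trajectories. Radius of
  gyration and forward/backward displacement anisotropy are computed per
  class.
* **Fractal spatial statistics** — the normalized 3D pair correlation

  ```
  G(r) = (N_R / N) · DD(r) / RR(r)
  ```

  against a matched random reference (confined to the same region and
  thinned by the fitted Gaussian axial-detection envelope), power-law fits
  G(r) ∝ r^(−γ) giving the fractal dimension d_f = 3 − γ, the two-regime
  hinge fit over 75–505 nm, per-CDC localization densities, and the
  blink-corrected nucleosome density
  ρ = ρ_loc / (N_blinks · tag fraction · expressing fraction).
* **Fractal-Rouse model** — the analytical map from measured (α_halo,
  D_halo, d_f, ρ, ⟨R²⟩) to predicted nucleosome dynamics,

  ```
  α_nuc = 2·α_halo / (2 + d_f)
  D_nuc = C · (3 D_free / ((4π/3)·ρ))^(2/(2+d_f)) · ⟨R²⟩^((d_f−3)/(d_f+2))
  ```

  with D_free = D_halo/5 and C a closed-form function of Γ functions of
  (d_f, α_halo); uncertainties propagate by Monte Carlo with a delta-method
  cross-check.
* **Synthetic data** — exact-covariance fractional-Brownian-motion
  trajectories, blinking SMLM clouds with an exactly power-law pair
  correlation, K-class chromatin volumes, and fully correlated end-to-end
  scenes with ground truth, so every stage is testable without the (multi-TB,
  undeposited) raw imaging data.

## Worked example

```sh
$ python examples/01_anomalous_diffusion.py
true:   alpha = 0.800, D = 0.0100 um^2/s^a
fitted: alpha = 0.809, D = 0.0100 um^2/s^a, r^2 = 0.9995
```

2,000 synthetic nucleosome trajectories at the experiment's noise level
(25 nm lateral / 140 nm axial precision) are fitted back to within 0.01 in
the anomalous exponent and 1% in the apparent coefficient — the
localization-error offset is subtracted per displacement pair, which is
what makes the sub-precision motion recoverable.

```sh
$ python examples/05_end_to_end_scene.py
class  D_true   D_fitted  n_traj
CDC1   0.0180   0.0177   643
...
CDC7   0.0060   0.0059   631
Spearman rank correlation of fitted D vs class: -1.00
```

A correlated scene whose trajectories slow down with the density class of
their seeding voxel is pushed through the *entire* pipeline (mixture fit →
MRF labeling → CDC assignment → per-class MSD fits); the fitted
coefficients recover the monotone density/mobility relationship exactly in
rank. The other examples cover density classification with the scrambled
control (`02`), pair-correlation/fractal/blink analysis (`03`), and the
parameter-free model prediction (`04`).

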