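"""Classify nuclear voxels into chromatin density classes (CDCs).

Simulates a chromatin intensity volume with 7 latent classes inside an
ellipsoidal nucleus, selects the class count by BIC, labels voxels with the
MRF-regularized mixture classifier, trims diffraction-artifact CDC1 voxels
at the nuclear edge, and builds the scrambled control.
"""

import numpy as np

from nucleodyn import density, synth
from nucleodyn.types import NuclearMask

gt = synth.VolumeGroundTruth(shape=(20, 56, 56), seed=11)
vol, truth = synth.simulate_chromatin_volume(gt)
mask = NuclearMask(truth > 0, voxel_size=gt.voxel_size, provenance="synthetic")
intens = vol.data[mask.data]

fits, best_k = density.fit_mixture_select_k(intens, range(1, 11), n_init=3, seed=0)
print(f"BIC selects K = {best_k} classes (true K = {gt.K})")

cdc = density.classify_mrf(vol, mask, fits[best_k], beta=0.7)
agree = (cdc.labels[mask.data] == truth[mask.data]).mean()
print(f"voxel label agreement with ground truth: {100 * agree:.2f}%")

trimmed = density.trim_edge_cdc1(cdc, mask)
removed = int((cdc.labels == 1).sum() - (trimmed.labels == 1).sum())
print(f"edge trim removed {removed} CDC1 voxels within 5 voxels of the edge")

scr = density.scramble_cdc(vol, mask, fits[best_k], beta=0.7, n_iter=10, seed=1)
tv = 0.5 * np.abs(density.cdc_proportions(cdc) - density.cdc_proportions(scr)).sum()
chance = (scr.labels[mask.data] == cdc.labels[mask.data]).mean()
print(f"scrambled control: class-proportion TV distance {tv:.3f} "
      f"(marginals preserved), voxel agreement {100 * chance:.1f}% "
      f"(~chance = {100 / best_k:.1f}%)")
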