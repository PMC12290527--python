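"""End-to-end desk-scale VASO experiment: simulate, reconstruct, analyze.

Runs a shortened version of the default experiment (2 task blocks instead
of 10, 16x16x8 matrix) through the full pipeline and prints the functional
results: the BOLD-corrected VASO activation amplitude, the gray-vs-white
specificity (ROC area), and the laminar activation profile.
"""

import warnings

import numpy as np

from spiralvaso import RunConfig, run_all

cfg = RunConfig.from_dict({
    "seed": 3,
    "phantom": {"matrix": [16, 16, 8], "n_coils": 3, "n_layers": 3},
    "trajectory": {"res_xy": 12.0, "r_xy": 1.5, "n_kz": 8, "dwell": 4.0},
    "timing": {"n_partitions": 8},
    "paradigm": {"n_blocks": 2},
    "recon": {"max_iter": 8, "n_segments": 2},
})
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = run_all(cfg, out_dir="scratch/example_run")

ph = res.phantom
roi = ph.roi_mask
print(f"volumes reconstructed: {len(res.vaso_series)} VASO + "
      f"{len(res.bold_series)} BOLD")
print(f"mean VASO z in the activated ribbon: {res.z_vaso[roi].mean():.2f}")
print(f"mean VASO z outside it:              "
      f"{res.z_vaso[~roi & ph.mask].mean():.2f}")
print(f"GM-vs-WM relative-specificity AUC:   {res.roc.auc:.3f}")
print("layer profile (mean z, deep -> superficial):",
      np.round(res.layer_z, 2).tolist())
print(f"whole-slab VASO tSNR: {res.tsnr_vaso[ph.mask].mean():.1f}")
# The blood-nulled contrast deflects downward during activity; after
# dynamic division the GLM (with sign -1) localizes the response to the
# stimulated ribbon sector, peaking in the middle cortical layers where
# the generator placed the microvascular CBV response.
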