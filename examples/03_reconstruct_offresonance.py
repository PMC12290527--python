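"""Off-resonance-corrected CG-SENSE versus a field-blind reconstruction.

A weak-gradient spiral stretches the 16x16 readout to ~53 ms, so the B0
inhomogeneity of the phantom (smooth field plus a susceptibility focus)
blurs the image exactly as it would in the full-resolution acquisition.
The time-segmented operator with the estimated field map removes the blur.
"""

import numpy as np

from spiralvaso import (DEFAULT_ECHO_TIMES, PhantomConfig, ReconConfig,
                        SpiralParams, build_phantom, design_vd_spiral,
                        estimate_fieldmap, estimate_sensitivities,
                        simulate_megre, slow_encode, solve)
from spiralvaso.recon import EncodingOperator

plane = design_vd_spiral(SpiralParams(fov_xy=192, res_xy=12.0, alpha=1.6,
                                      r_xy=1.0, g_max=0.36, sr_max=1.5,
                                      dwell=40.0))
print(f"stretched readout: {plane.readout_duration*1e3:.1f} ms")

ph = build_phantom((16, 16, 8), seed=17,
                   config=PhantomConfig(n_coils=3, n_layers=3,
                                        b0_amplitude=40.0, n_foci=1,
                                        focus_amplitude=60.0))
img_true = ph.m0[:, :, :1].astype(complex)
sens = ph.coil_sens[:, :, :, :1]
data = slow_encode(img_true, sens, plane, te=0.0024,
                   f0=ph.b0_map[:, :, :1])

megre = simulate_megre(ph, DEFAULT_ECHO_TIMES)
fmap = estimate_fieldmap(megre, DEFAULT_ECHO_TIMES, n_echoes_used=3)
sens_est = estimate_sensitivities(megre[0])

cfg = ReconConfig(beta=0.0, max_iter=15)
corrected_op = EncodingOperator(plane, sens_est.c[:, :, :, :1],
                                fieldmap=fmap.f0[:, :, :1], n_segments=24,
                                te=0.0024)
blind_op = EncodingOperator(plane, sens_est.c[:, :, :, :1], te=0.0024)
img_corr, _ = solve(data, corrected_op, cfg)
img_blind, _ = solve(data, blind_op, cfg)

ref = np.abs(img_true)
for name, img in (("field-blind", img_blind), ("corrected", img_corr)):
    nrmse = np.linalg.norm(np.abs(img) - ref) / np.linalg.norm(ref)
    print(f"{name:12s} NRMSE vs ground truth: {100*nrmse:.1f}%")
# The corrected reconstruction recovers the phantom to a few percent while
# the blind one keeps the off-resonance blurring of the long spiral readout.
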