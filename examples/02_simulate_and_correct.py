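"""Simulate a short functional run with scanner imperfections and undo them.

A 16x16x8 brain-slab phantom is scanned with a stack-of-spirals readout
while a 2 Hz/min frequency drift, an eddy-current compensation phase and a
zeroth-order k0 excursion corrupt the raw data. The corrections (EC phase
removal, k0 demodulation, repetition DORK from the FID navigators) restore
the clean k-space volumes.
"""

import numpy as np

from spiralvaso import (Paradigm, PerturbationSpec, PhantomConfig,
                        SequenceTiming, SpiralParams, acquire_run,
                        build_phantom, design_vd_spiral, dork_correct,
                        k0_demodulate, make_k0_trace, remove_ec_phase,
                        stack_spirals)

plane = design_vd_spiral(SpiralParams(fov_xy=192, res_xy=12.0, r_xy=1.5,
                                      dwell=4.0))
traj = stack_spirals(plane, 8, 24.0)
ph = build_phantom((16, 16, 8), seed=1,
                   config=PhantomConfig(n_coils=3, n_layers=3, cbv_delta=0.0))
timing = SequenceTiming(n_partitions=8, tr_effective=30.0)
paradigm = Paradigm(2, 2, 2, tr_effective=30.0)

pert = PerturbationSpec(drift_hz_per_min=2.0, ec_coeffs=[(0.3, 0.008)],
                        k0_phase=make_k0_trace(traj.n_samples, 4e-6, 0.2,
                                               seed=7))
dirty = acquire_run(ph, timing, paradigm, traj, perturb=pert,
                    noise_sigma=0.0, seed=2, bold_amplitude=0.0)
clean = acquire_run(ph, timing, paradigm, traj, noise_sigma=0.0, seed=2,
                    bold_amplitude=0.0)

step1 = [remove_ec_phase(kd, pert.ec_phase(traj.t)) for kd in dirty]
step2 = [k0_demodulate(kd, pert.k0_phase) for kd in step1]
corrected, dork = dork_correct(step2)

before = max(np.abs(np.angle(d.samples * np.conj(c.samples))).max()
             for d, c in zip(dirty, clean))
after = max(np.abs(np.angle(d.samples * np.conj(c.samples))).max()
            for d, c in zip(corrected, clean))
print(f"worst residual sample phase before corrections: {before:.3f} rad")
print(f"worst residual sample phase after corrections:  {after:.2e} rad")
print("per-volume DORK estimates (Hz):",
      np.round(dork.offsets_hz, 4).tolist())
# The DORK offsets track the injected 2 Hz/min drift at each volume's scan
# time; after all three corrections the raw data match the unperturbed
# acquisition to numerical precision.
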