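"""Design the protocol spiral readout and audit its gradient waveform.

Builds the single-shot variable-density spiral of the 0.8 mm laminar-fMRI
protocol (FOV 192 mm, alpha 1.6, r_xy 3, Gmax 35 mT/m, SRmax 155 T/m/s),
stacks it over 24 kz partitions, and checks the gradient spectrum against
the scanner's mechanical-resonance bands (550 +- 50 Hz, 1100 +- 150 Hz).
"""

import numpy as np

from spiralvaso import (SpiralParams, design_vd_spiral, gradient_spectrum,
                        stack_spirals)

params = SpiralParams(fov_xy=192, res_xy=0.8, alpha=1.6, r_xy=3,
                      g_max=35, sr_max=155, dwell=2.0)
plane = design_vd_spiral(params)
traj = stack_spirals(plane, 24, 24.0, order="linear")

g = plane.g
slew = np.abs(np.diff(g[:, :2], axis=0)) / plane.grad_raster * 1e-3
print(f"readout duration: {plane.readout_duration*1e3:.2f} ms "
      f"({plane.n_samples} samples at {params.dwell:.0f} us dwell)")
print(f"peak gradient:    {np.abs(g).max():.2f} mT/m (limit {params.g_max})")
print(f"peak slew rate:   {slew.max():.1f} T/m/s (limit {params.sr_max})")
print(f"kz partitions:    {traj.n_readouts}, order {traj.kz_order[:6]}...")

rep = gradient_spectrum(plane, bands=[(550.0, 100.0), (1100.0, 300.0)])
print(f"spectral peak:    {rep.peak_freq:.0f} Hz")
for (c, w), frac in zip(rep.bands, rep.band_fractions):
    print(f"energy in {c:.0f}+-{w/2:.0f} Hz band: {100*frac:.2f}%")

# The readout sweeps k-space center-out in one shot; the peak gradient and
# slew sit at their limits (time-optimal traversal), and only a small
# fraction of the acoustic energy falls into the forbidden bands.
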