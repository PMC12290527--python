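"""Point-spread-function comparison: spiral vs EPI under T2* decay.

Simulates a centered point source along the protocol spiral (single shot,
~47 ms) and the matched 3D-EPI echo train (1.02 ms echo spacing, GRAPPA 3,
6/8 partial Fourier), both with exp(-t / 25 ms) signal decay, and measures
the effective in-plane resolution from the density-compensated adjoint
reconstruction.
"""

from spiralvaso import (EpiParams, SpiralParams, design_epi, design_vd_spiral,
                        simulate_psf)

spiral = design_vd_spiral(SpiralParams(fov_xy=192, res_xy=0.8, alpha=1.6,
                                       r_xy=3, g_max=35, sr_max=155,
                                       dwell=2.0))
spiral_full = design_vd_spiral(SpiralParams(fov_xy=192, res_xy=0.8, alpha=1.6,
                                            r_xy=1.0, g_max=35, sr_max=155,
                                            dwell=2.0))
epi = design_epi(EpiParams())
epi_full = design_epi(EpiParams(grappa=1, partial_fourier=1.0))

r_sp = simulate_psf(spiral, 25e-3, 240, reference_traj=spiral_full)
r_ep = simulate_psf(epi, 25e-3, 240, reference_traj=epi_full)

for name, r in (("spiral", r_sp), ("EPI", r_ep)):
    print(f"{name:6s}: FWHM x/y = {r.fwhm_x:.3f}/{r.fwhm_y:.3f} px, "
          f"effective resolution = {r.effective_resolution:.3f} mm "
          f"(nominal {r.nominal_res:.1f} mm)")
pct = 100 * (r_sp.effective_resolution / r_ep.effective_resolution - 1)
print(f"spiral vs EPI effective-resolution difference: {pct:+.1f}%")
# T2* decay apodizes the spiral isotropically (both axes broaden alike),
# while the EPI echo train blurs only the phase-encode axis; the zero-filled
# partial-Fourier model used here makes that axis broad enough that the x/y
# averaged penalty of the spiral comes out slightly negative.
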