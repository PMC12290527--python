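"""Encoding operator, density compensation, solvers, and PSF simulation."""

import copy

import numpy as np
import pytest

from spiralvaso import (EpiParams, PhantomConfig, ReconConfig, SpiralParams,
                        build_phantom, density_compensation, design_epi,
                        design_vd_spiral, simulate_psf, slow_encode, solve,
                        stack_spirals)
from spiralvaso.recon import EncodingOperator, segment_weights


@pytest.fixture(scope="module")
def offres_problem(slow_spiral_plane):
    """16x16 single-plane problem with |f0| <= 100 Hz over a ~53 ms readout
    and the exact slow-DFT data as oracle."""
    rng = np.random.default_rng(21)
    n = 16
    sens = rng.standard_normal((3, n, n, 1)) + 1j * rng.standard_normal((3, n, n, 1))
    img = rng.standard_normal((n, n, 1)) + 1j * rng.standard_normal((n, n, 1))
    f0 = rng.uniform(-100.0, 100.0, (n, n, 1))
    exact = slow_encode(img, sens, slow_spiral_plane, te=0.0024, f0=f0)
    return img, sens, f0, exact


class TestOperator:
    def test_no_fieldmap_equals_plain_sense_nufft(self, spiral_plane_small):
        rng = np.random.default_rng(2)
        n = 16
        sens = rng.standard_normal((2, n, n, 1)) + 0j
        img = rng.standard_normal((n, n, 1)) + 0j
        op = EncodingOperator(spiral_plane_small, sens)
        manual = np.stack([
            op.nufft.forward((sens[c, :, :, 0] * img[:, :, 0]))
            for c in range(2)])[:, None, :]
        assert np.allclose(op.forward(img), manual, atol=1e-10)

    def test_adjoint_inner_product(self, slow_spiral_plane):
        rng = np.random.default_rng(3)
        n = 16
        sens = rng.standard_normal((3, n, n, 1)) + 1j * rng.standard_normal((3, n, n, 1))
        f0 = rng.uniform(-100, 100, (n, n, 1))
        op = EncodingOperator(slow_spiral_plane, sens, fieldmap=f0,
                              n_segments=8, te=0.0024)
        x = rng.standard_normal(op.shape) + 1j * rng.standard_normal(op.shape)
        y = rng.standard_normal((3, 1, slow_spiral_plane.n_samples)) \
            + 1j * rng.standard_normal((3, 1, slow_spiral_plane.n_samples))
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_segmentation_error_monotone_and_small_at_24(
            self, slow_spiral_plane, offres_problem):
        img, sens, f0, exact = offres_problem
        errs = []
        for L in (1, 4, 8, 24):
            op = EncodingOperator(slow_spiral_plane, sens, fieldmap=f0,
                                  n_segments=L, te=0.0024)
            s = op.forward(img)
            errs.append(np.linalg.norm(s - exact) / np.linalg.norm(exact))
        assert all(b < a for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-2

    def test_hanning_interpolator_also_converges(self, slow_spiral_plane,
                                                 offres_problem):
        img, sens, f0, exact = offres_problem
        errs = []
        for L in (8, 24, 48):
            op = EncodingOperator(slow_spiral_plane, sens, fieldmap=f0,
                                  n_segments=L, te=0.0024,
                                  interpolator="hanning")
            errs.append(np.linalg.norm(op.forward(img) - exact)
                        / np.linalg.norm(exact))
        assert all(b < a for a, b in zip(errs, errs[1:]))

    def test_weight_rows_sum_to_one(self, slow_spiral_plane):
        rng = np.random.default_rng(5)
        sens = np.ones((1, 16, 16, 1), complex)
        f0 = rng.uniform(-80, 80, (16, 16, 1))
        for interp in ("ls", "hanning"):
            op = EncodingOperator(slow_spiral_plane, sens, fieldmap=f0,
                                  n_segments=12, te=0.0024, interpolator=interp)
            assert np.abs(op.weights.sum(axis=0) - 1.0).max() < 1e-6

    def test_hanning_weights_partition_of_unity(self):
        t = np.linspace(0.0, 0.05, 401)
        centers = np.linspace(0.0, 0.05, 9)
        w = segment_weights(t, centers)
        assert np.abs(w.sum(axis=0) - 1.0).max() < 1e-12

    def test_invalid_segments_and_grids(self, spiral_plane_small):
        sens = np.ones((1, 16, 16, 1), complex)
        with pytest.raises(ValueError):
            EncodingOperator(spiral_plane_small, sens, n_segments=0)
        with pytest.raises(ValueError):
            EncodingOperator(spiral_plane_small, sens,
                             fieldmap=np.zeros((8, 8, 1)))


class TestDensityCompensation:
    def test_cartesian_uniform(self):
        traj = design_epi(EpiParams(fov_xy=192, res_xy=12.0, grappa=1,
                                    partial_fourier=1.0))
        w = density_compensation(traj)
        assert np.allclose(w, w[0])

    def test_spiral_weights_grow_with_radius(self, spiral_plane_small):
        """Uniform-density region: Pipe-Menon weights follow the |k| ramp."""
        p = SpiralParams(fov_xy=192, res_xy=12.0, alpha=1.0, r_xy=1.0,
                         dwell=4.0)
        traj = design_vd_spiral(p)
        w = density_compensation(traj, "pipe_menon")
        r = np.hypot(*traj.k[0, :, :2].T)
        bins = np.linspace(0, r.max(), 8)
        prof = [w[(r >= a) & (r < b)].mean() for a, b in zip(bins, bins[1:])]
        assert all(b > a for a, b in zip(prof[1:-1], prof[2:]))

    def test_voronoi_positive_and_radial(self, spiral_plane_small):
        p = SpiralParams(fov_xy=192, res_xy=12.0, alpha=1.0, r_xy=1.0,
                         dwell=4.0)
        traj = design_vd_spiral(p)
        w = density_compensation(traj, "voronoi")
        assert np.all(w > 0)
        r = np.hypot(*traj.k[0, :, :2].T)
        inner = w[r < 0.3 * r.max()].mean()
        outer = w[(r > 0.6 * r.max()) & (r < 0.9 * r.max())].mean()
        assert outer > inner

    def test_repeated_points_rejected_by_voronoi(self, spiral_plane_small):
        traj = copy.deepcopy(spiral_plane_small)
        traj.k[0, 1] = traj.k[0, 0]
        with pytest.raises(ValueError):
            density_compensation(traj, "voronoi")


class TestSolve:
    def test_zero_data_gives_zero_image(self, spiral_plane_small):
        sens = np.ones((1, 16, 16, 1), complex)
        op = EncodingOperator(spiral_plane_small, sens)
        img, _ = solve(np.zeros((1, 1, spiral_plane_small.n_samples)), op,
                       ReconConfig(beta=0.0, max_iter=5))
        assert np.abs(img).max() == 0.0

    def test_inverse_crime_recovery_under_1pct(self):
        """Noiseless fully sampled Cartesian acquisition, beta=0, data from
        the exact slow encoder: NRMSE < 1%."""
        cfg = PhantomConfig(n_coils=4, n_layers=3, b0_amplitude=0.0,
                            n_foci=0, focus_amplitude=0.0)
        ph = build_phantom((16, 16, 8), seed=13, config=cfg)
        plane = design_epi(EpiParams(fov_xy=192, res_xy=12.0, grappa=1,
                                     partial_fourier=1.0))
        traj = stack_spirals(plane, 8, 24.0)
        data = slow_encode(ph.m0.astype(complex), ph.coil_sens, traj)
        op = EncodingOperator(traj, ph.coil_sens)
        img, _ = solve(data, op, ReconConfig(beta=0.0, max_iter=20, tol=1e-10))
        nrmse = np.linalg.norm(np.abs(img) - ph.m0) / np.linalg.norm(ph.m0)
        assert nrmse < 0.01

    def test_admm_l1_approaches_cg_at_small_beta(self, phantom_small):
        """On a well-posed (fully sampled) problem the two objectives share
        a unique minimizer as beta -> 0."""
        ph = phantom_small
        plane = design_epi(EpiParams(fov_xy=192, res_xy=12.0, grappa=1,
                                     partial_fourier=1.0))
        sens = ph.coil_sens[:, :, :, :1]
        img_t = ph.m0[:, :, :1].astype(complex)
        data = slow_encode(img_t, sens, plane)
        op = EncodingOperator(plane, sens)
        cg_img, _ = solve(data, op, ReconConfig(solver="cg_sense", beta=0.0,
                                                max_iter=30, tol=1e-12))
        admm_img, _ = solve(data, op, ReconConfig(
            solver="admm_l1", beta=1e-8, admm_rho=1.0, max_iter=12,
            admm_inner_iter=10, tol=1e-12))
        nrmse = np.linalg.norm(admm_img - cg_img) / np.linalg.norm(cg_img)
        assert nrmse < 1e-3

    def test_cg_objective_monotone(self, spiral_plane_small, phantom_small):
        ph = phantom_small
        sens = ph.coil_sens[:, :, :, :1]
        data = slow_encode(ph.m0[:, :, :1].astype(complex), sens,
                           spiral_plane_small)
        op = EncodingOperator(spiral_plane_small, sens)
        _, log = solve(data, op, ReconConfig(beta=1e-6, max_iter=12))
        assert all(b <= a + 1e-12 * abs(a)
                   for a, b in zip(log.objective, log.objective[1:]))

    def test_offresonance_correction_beats_uncorrected(self, slow_spiral_plane):
        """Same data, same solver: the field-aware operator reconstructs
        the phantom better than the blind one."""
        cfg = PhantomConfig(n_coils=3, n_layers=3, b0_amplitude=40.0,
                            n_foci=1, focus_amplitude=60.0)
        ph = build_phantom((16, 16, 8), seed=17, config=cfg)
        sens = ph.coil_sens[:, :, :, :1]
        img_t = ph.m0[:, :, :1].astype(complex)
        f0 = ph.b0_map[:, :, :1]
        data = slow_encode(img_t, sens, slow_spiral_plane, te=0.0024, f0=f0)
        corr_op = EncodingOperator(slow_spiral_plane, sens, fieldmap=f0,
                                   n_segments=24, te=0.0024)
        blind_op = EncodingOperator(slow_spiral_plane, sens, te=0.0024)
        cfg_r = ReconConfig(beta=0.0, max_iter=15, tol=1e-10)
        img_c, _ = solve(data, corr_op, cfg_r)
        img_b, _ = solve(data, blind_op, cfg_r)
        ref = np.abs(img_t)
        err_c = np.linalg.norm(np.abs(img_c) - ref) / np.linalg.norm(ref)
        err_b = np.linalg.norm(np.abs(img_b) - ref) / np.linalg.norm(ref)
        assert err_c < err_b

    def test_nonfinite_data_rejected(self, spiral_plane_small):
        sens = np.ones((1, 16, 16, 1), complex)
        op = EncodingOperator(spiral_plane_small, sens)
        bad = np.full((1, 1, spiral_plane_small.n_samples), np.nan + 0j)
        with pytest.raises(ValueError):
            solve(bad, op)


class TestPsf:
    def test_self_reference_no_decay_ratio_is_one(self, spiral_plane_small):
        rep = simulate_psf(spiral_plane_small, None, 64)
        assert rep.ratio_vs_nominal == pytest.approx(1.0, abs=1e-9)

    def test_cartesian_full_psf_near_sinc_width(self):
        traj = design_epi(EpiParams(fov_xy=192, res_xy=12.0, grappa=1,
                                    partial_fourier=1.0))
        rep = simulate_psf(traj, None, 64)
        assert rep.fwhm_x == pytest.approx(1.2067, rel=0.10)
        assert rep.fwhm_y == pytest.approx(1.2067, rel=0.10)

    def test_spiral_full_psf_near_airy_width(self):
        """Disk k-space coverage: the density-compensated point response is
        the Airy pattern, FWHM ~1.41 px at Nyquist."""
        p = SpiralParams(fov_xy=192, res_xy=12.0, alpha=1.0, r_xy=1.0,
                         dwell=4.0)
        rep = simulate_psf(design_vd_spiral(p), None, 64)
        assert 0.5 * (rep.fwhm_x + rep.fwhm_y) == pytest.approx(1.41, rel=0.10)

    def test_fwhm_monotone_in_decay(self, spiral_plane_small):
        widths = [0.5 * (r.fwhm_x + r.fwhm_y) for r in
                  (simulate_psf(spiral_plane_small, t, 64)
                   for t in (None, 0.025, 0.010))]
        assert widths[0] <= widths[1] <= widths[2]

    def test_peak_at_center(self, spiral_plane_small):
        rep = simulate_psf(spiral_plane_small, 0.025, 64)
        peak = np.unravel_index(np.argmax(np.abs(rep.psf)), rep.psf.shape)
        assert peak == (32, 32)
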