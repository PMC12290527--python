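"""VASO fMRI analysis chain: BOCO, filtering, tSNR, GLM, layers, ROC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spiralvaso import (Paradigm, SequenceTiming, VasoSeries, boco_correct,
                        build_paradigm, glm_activation, layer_profile,
                        roc_specificity, t1w_cvarinv, temporal_highpass,
                        tsnr, vaso_signal_timeseries)
from spiralvaso.analysis import cluster_threshold, effective_tsnr


def make_series(par, vaso, bold, tr=2.0, offset=1.0):
    t_v = np.arange(len(vaso)) * tr
    return VasoSeries(vaso=vaso, bold=bold, tr_effective=tr, paradigm=par,
                      t_vaso=t_v, t_bold=t_v + offset)


class TestBoco:
    def test_unit_bold_is_pure_upsampling(self):
        par = Paradigm(2, 4, 4, 2.0)
        rng = np.random.default_rng(0)
        vaso = rng.uniform(1, 2, (par.n_volumes, 4, 4, 2))
        ser = make_series(par, vaso, np.ones_like(vaso))
        out = boco_correct(ser)
        assert len(out.vaso) == 2 * par.n_volumes
        # at the original VASO acquisition times the series is unchanged
        orig = out.vaso[::2]
        assert np.allclose(orig, vaso)

    def test_shared_multiplicative_contamination_removed(self):
        """Known v(t) * b(t) with the same b in the BOLD series: the
        division recovers v(t) within interpolation error."""
        par = Paradigm(4, 4, 4, 2.0)
        nt = par.n_volumes
        box = par.boxcar()
        shape = (nt, 3, 3, 2)
        v_clean = (1.0 - 0.03 * box)[:, None, None, None] * np.ones(shape[1:])
        b = (1.0 + 0.05 * box)[:, None, None, None] * np.ones(shape[1:])
        ser = make_series(par, v_clean * b, b)
        out = boco_correct(ser)
        target = np.repeat(v_clean, 2, axis=0)[:out.vaso.shape[0]]
        # interior volumes (edges feel one-sided interpolation)
        nrmse = np.linalg.norm(out.vaso[2:-2] - target[2:-2]) \
            / np.linalg.norm(target[2:-2])
        assert nrmse < 0.01

    @settings(max_examples=10, deadline=None)
    @given(amp=st.floats(0.01, 0.2), seed=st.integers(0, 100))
    def test_block_contamination_exact_between_transitions(self, amp, seed):
        """Piecewise-constant shared contamination cancels exactly except
        at the block transitions, where linear interpolation of the
        step is the only residual."""
        par = Paradigm(4, 4, 4, 2.0)
        nt = par.n_volumes
        box = par.boxcar()
        b1 = 1.0 + amp * box
        v = 1.0 - 0.02 * box
        vaso = (v * b1)[:, None, None, None] * np.ones((nt, 2, 2, 1))
        bold = b1[:, None, None, None] * np.ones((nt, 2, 2, 1))
        out = boco_correct(make_series(par, vaso, bold))
        target = np.repeat(v, 2)[:len(out.vaso)]
        err = np.abs(out.vaso[:, 0, 0, 0] - target)
        bad = {2 * i + d for i in np.where(np.diff(box) != 0)[0]
               for d in range(4)}
        ok = [i for i in range(2, len(err) - 2) if i not in bad]
        assert err[ok].max() < 1e-12

    def test_sine_contamination_error_shrinks_with_frequency(self):
        """Interpolation residual of smooth contamination decreases as the
        contamination slows relative to the sampling."""
        par = Paradigm(4, 4, 4, 2.0)
        nt = par.n_volumes
        t = np.arange(nt)
        errs = []
        for freq in (4, 2, 1):
            b1 = 1.0 + 0.1 * np.sin(2 * np.pi * freq * t / nt)
            v = 1.0 - 0.02 * par.boxcar()
            vaso = (v * b1)[:, None, None, None] * np.ones((nt, 2, 2, 1))
            bold = b1[:, None, None, None] * np.ones((nt, 2, 2, 1))
            out = boco_correct(make_series(par, vaso, bold))
            target = np.repeat(v, 2)[:len(out.vaso)]
            errs.append(np.abs(out.vaso[2:-2, 0, 0, 0] - target[2:-2]).max())
        assert errs[0] > errs[1] > errs[2]

    def test_negative_deflection_preserved(self, phantom_default):
        ph = phantom_default
        timing = SequenceTiming(n_partitions=8)
        par = build_paradigm("spiral", 2)
        vaso, bold, t_v, t_b = vaso_signal_timeseries(ph, timing, par,
                                                      bold_amplitude=0.02)
        ser = VasoSeries(vaso=vaso, bold=bold, tr_effective=par.tr_effective,
                         paradigm=par, t_vaso=t_v, t_bold=t_b)
        out = boco_correct(ser)
        box_up = np.repeat(par.boxcar(), 2)[:len(out.vaso)].astype(bool)
        core = ph.cbv_delta > 0
        act = out.vaso[box_up][:, core].mean()
        rest = out.vaso[~box_up][:, core].mean()
        assert act < rest

    def test_empty_series_rejected(self):
        par = Paradigm(0, 4, 4, 2.0)
        ser = make_series(par, np.zeros((0, 2, 2, 1)), np.zeros((0, 2, 2, 1)))
        with pytest.raises(ValueError):
            boco_correct(ser)


class TestHighpass:
    def test_constant_series_unchanged(self):
        x = np.full((64, 2, 2, 1), 3.7)
        out = temporal_highpass(x, 16.0, tr=2.0)
        assert np.abs(out - 3.7).max() < 1e-10

    def test_infinite_cutoff_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((32, 2, 2, 1))
        assert np.abs(temporal_highpass(x, np.inf) - x).max() < 1e-10

    def test_removes_drift_keeps_block(self):
        par = Paradigm(10, 8, 8, 2.0)
        nt = par.n_volumes
        t = np.arange(nt)
        bc = par.boxcar() - par.boxcar().mean()
        drift = 0.01 * t
        x = (1 + 0.05 * bc + drift)[:, None, None, None] * np.ones((nt, 1, 1, 1))
        block_cycle_s = 16 * 2.0
        out = temporal_highpass(x, block_cycle_s, tr=2.0)[:, 0, 0, 0]
        assert abs(np.corrcoef(out, drift)[0, 1]) < 0.05
        retained = (out - out.mean()) @ bc / (bc @ bc) / 0.05
        assert retained > 0.9

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            temporal_highpass(np.zeros((8, 1, 1, 1)), 0.0)


class TestTsnr:
    def test_matches_mean_over_std(self):
        rng = np.random.default_rng(4)
        mu, sigma = 5.0, 0.5
        x = mu + sigma * rng.standard_normal((160, 12, 12, 1))
        ts = tsnr(x, detrend=True)
        assert np.abs(ts.mean() - mu / sigma) / (mu / sigma) < 0.05

    def test_zero_series_is_zero(self):
        assert np.all(tsnr(np.zeros((8, 2, 2, 1))) == 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        x = 3 + rng.standard_normal((40, 3, 3, 1))
        assert np.allclose(tsnr(10 * x), tsnr(x))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            tsnr(np.zeros((2, 2, 2, 1)))

    def test_effective_tsnr_scales_with_voxel_volume(self):
        ts = np.full((4, 4, 1), 30.0)
        out = effective_tsnr(ts, effective_resolution=1.0, nominal_resolution=0.8)
        assert np.allclose(out, 30.0 / (1.0 / 0.8) ** 2)


class TestCvarinv:
    def test_two_level_closed_form(self):
        a, b = 2.0, 1.0
        v = np.tile(np.array([a, b] * 8)[:, None, None, None], (1, 2, 2, 1))
        out = t1w_cvarinv(v[:8], v[8:])
        assert np.allclose(out, (a + b) / abs(a - b))

    def test_zero_variance_masked(self):
        v = np.ones((8, 2, 2, 1))
        assert np.all(t1w_cvarinv(v, v) == 0.0)

    def test_monotone_in_level_difference(self):
        outs = []
        for d in (0.5, 1.0, 2.0):
            v = np.tile(np.array([2.0 + d, 2.0 - d] * 8)[:, None, None, None],
                        (1, 1, 1, 1))
            outs.append(t1w_cvarinv(v[:8], v[8:])[0, 0, 0])
        assert outs[0] > outs[1] > outs[2]


class TestGlm:
    def test_matches_closed_form_ols_oracle(self):
        par = Paradigm(5, 8, 8, 2.0)
        nt = par.n_volumes
        rng = np.random.default_rng(6)
        t = np.arange(nt, dtype=float)
        y = 2 + 0.3 * par.boxcar() + 0.01 * t
        Y = y[:, None, None, None] + 0.1 * rng.standard_normal((nt, 4, 4, 1))
        res = glm_activation(Y, par)
        X = np.column_stack([par.boxcar() - par.boxcar().mean(),
                             np.ones(nt), t - t.mean()])
        bet = np.linalg.inv(X.T @ X) @ X.T @ Y.reshape(nt, -1)
        resid = Y.reshape(nt, -1) - X @ bet
        s2 = (resid**2).sum(0) / (nt - 3)
        t_or = bet[0] / np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0])
        assert np.abs(res.tmap.ravel() - t_or).max() < 1e-10

    def test_null_suprathreshold_fraction_calibrated(self):
        """Pure noise at z threshold 2.4: suprathreshold fraction before
        clustering matches the normal tail within a binomial interval."""
        par = Paradigm(5, 8, 8, 2.0)
        rng = np.random.default_rng(7)
        n_vox = 40 * 40 * 6
        Y = rng.standard_normal((par.n_volumes, 40, 40, 6))
        res = glm_activation(Y, par, min_cluster=1)
        frac = (res.zmap >= 2.4).mean()
        p = stats.norm.sf(2.4)
        ci = 4 * np.sqrt(p * (1 - p) / n_vox)
        assert abs(frac - p) < ci

    def test_vaso_contrast_sign_flips_z(self, phantom_default):
        ph = phantom_default
        timing = SequenceTiming(n_partitions=8)
        par = build_paradigm("spiral", 2)
        vaso, _, _, _ = vaso_signal_timeseries(ph, timing, par,
                                               bold_amplitude=0.0)
        rng = np.random.default_rng(8)
        noisy = vaso + 1e-4 * rng.standard_normal(vaso.shape)
        res = glm_activation(noisy, par, contrast_sign=-1.0)
        assert res.zmap[ph.roi_mask].mean() > 2.0

    def test_rank_deficient_design_rejected(self):
        par = Paradigm(1, 0, 8, 2.0)  # boxcar constant -> collinear
        with pytest.raises(ValueError):
            glm_activation(np.zeros((8, 2, 2, 1)), par)

    def test_cluster_minimum_extent(self):
        z = np.zeros((8, 8, 2))
        z[0, 0, 0] = 5.0            # isolated voxel
        z[4:6, 4:6, :] = 5.0        # 8-voxel block
        labels, active = cluster_threshold(z, 2.4, min_cluster=5)
        assert not active[0, 0, 0]
        assert active[4, 4, 0]


class TestLayers:
    def test_constant_map_gives_constant_profile(self, phantom_default):
        ph = phantom_default
        prof = layer_profile(np.ones(ph.shape), ph.layer_index,
                             ph.config.n_layers)
        assert np.allclose(prof, 1.0)

    def test_linear_gradient_recovered(self, phantom_default):
        ph = phantom_default
        z = np.where(ph.layer_index >= 0, ph.layer_index.astype(float), 0.0)
        prof = layer_profile(z, ph.layer_index, ph.config.n_layers)
        assert np.allclose(prof, np.arange(ph.config.n_layers))

    def test_generator_places_vaso_mid_and_bold_superficial(
            self, phantom_default):
        """CBV response peaks mid-ribbon; BOLD weighting peaks at the
        superficial layers."""
        ph = phantom_default
        L = ph.config.n_layers
        layers_in_roi = np.where(ph.sector_mask, ph.layer_index, -1)
        v_prof = layer_profile(ph.cbv_delta, layers_in_roi, L)
        b_prof = layer_profile(ph.bold_weight, layers_in_roi, L)
        assert np.argmax(v_prof) == L // 2
        assert np.argmax(b_prof) == L - 1

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            layer_profile(np.zeros((4, 4, 1)), -np.ones((4, 4, 1), int), 3)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        z = np.zeros((10, 10, 2))
        gm = np.zeros_like(z, bool)
        wm = np.zeros_like(z, bool)
        gm[:5], wm[5:] = True, True
        z[gm] = 8.0
        roc = roc_specificity(z, gm, wm, min_cluster=1)
        assert roc.auc > 0.99

    def test_exchangeable_null_auc_half(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal((25, 20, 20))  # 10^4 voxels
        gm = np.zeros_like(z, bool)
        wm = np.zeros_like(z, bool)
        gm[:12], wm[13:] = True, True
        roc = roc_specificity(z, gm, wm, min_cluster=1)
        assert abs(roc.auc - 0.5) < 0.05

    def test_fractions_monotone_in_threshold(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal((10, 10, 4)) + 1.0
        gm = np.zeros_like(z, bool)
        wm = np.zeros_like(z, bool)
        gm[:5], wm[5:] = True, True
        roc = roc_specificity(z, gm, wm, min_cluster=1)
        assert np.all(np.diff(roc.tp_fraction) <= 1e-12)
        assert np.all(np.diff(roc.fp_fraction) <= 1e-12)

    def test_empty_mask_rejected(self):
        z = np.zeros((4, 4, 1))
        with pytest.raises(ValueError):
            roc_specificity(z, np.zeros_like(z, bool), np.ones_like(z, bool))
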