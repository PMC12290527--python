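"""Forward simulation of the multi-coil off-resonance signal model.

Synthesizes k-space data s_gamma(t) from a phantom along a trajectory,
including T2* decay during the readout, per-voxel off-resonance, additive
complex Gaussian noise, FID navigator samples, and injectable global
phase perturbations (scanner frequency drift, eddy-current compensation
phase, zeroth-order k0 field excursions).

Two paths are available: a brute-force discrete sum with the exact
per-sample off-resonance/decay phase (the oracle; use only at small
matrix sizes) and a fast path through the same time-segmented
SENSE-NUFFT operator used for reconstruction, run at a higher segment
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Paradigm, PhantomState, SequenceTiming, vaso_signal_timeseries
from .recon import EncodingOperator
from .trajectory import Trajectory3D


@dataclass
class PerturbationSpec:
    """Global phase perturbations injected into the raw data.

    drift_hz_per_min: linear scanner frequency drift; the instantaneous
        offset Df(v) = rate * scan_time(v)/60 multiplies every sample of
        volume v by exp(-i 2 pi Df (TE + t)).
    ec_coeffs: eddy-current compensation phase as a sum of exponentially
        decaying terms [(amplitude_rad, tau_s), ...] evaluated on the
        readout time axis.
    k0_phase: explicit per-sample zeroth-order phase trace (rad), or None.
    """

    drift_hz_per_min: float = 0.0
    ec_coeffs: list[tuple[float, float]] = field(default_factory=list)
    k0_phase: np.ndarray | None = None

    def ec_phase(self, t: np.ndarray) -> np.ndarray:
        phi = np.zeros_like(t)
        for amp, tau in self.ec_coeffs:
            phi += amp * np.exp(-t / tau)
        return phi


def make_k0_trace(n_samples: int, dwell: float, amplitude: float = 0.1,
                  seed: int = 0) -> np.ndarray:
    """Smooth synthetic k0 phase trace (rad): low-pass filtered random walk
    emulating zeroth-order field excursions during the readout."""
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal(n_samples)
    walk = np.cumsum(steps)
    kernel = np.hanning(max(n_samples // 16, 8))
    kernel /= kernel.sum()
    smooth = np.convolve(walk, kernel, mode="same")
    smooth -= smooth[0]
    peak = np.abs(smooth).max() or 1.0
    return amplitude * smooth / peak


@dataclass
class KspaceData:
    """Multi-coil raw data of one volume: (n_coils, n_kz, n_samples)."""

    samples: np.ndarray
    traj: Trajectory3D
    navigators: np.ndarray | None = None   # (n_coils, n_nav)
    nav_times: np.ndarray | None = None    # s since excitation
    meta: dict = field(default_factory=dict)
    noise_sigma: float = 0.0

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]

    def copy_with(self, samples: np.ndarray) -> "KspaceData":
        return KspaceData(samples=samples, traj=self.traj,
                          navigators=self.navigators, nav_times=self.nav_times,
                          meta=dict(self.meta), noise_sigma=self.noise_sigma)


def slow_encode(image: np.ndarray, sens: np.ndarray, traj: Trajectory3D,
                te: float = 0.0, f0: np.ndarray | None = None,
                t2star: np.ndarray | None = None,
                chunk: int = 512) -> np.ndarray:
    """Exact discrete evaluation of the signal model (brute-force DFT).

    s[c, p, j] = sum_r sens[c, r] image[r] exp(-i 2 pi k_j(p) . r)
                 exp(-i 2 pi f0(r) (te + t_j)) exp(-(te + t_j)/t2star(r))

    Voxel positions are in units of the reconstruction pixel, centered.
    Intended for small problems as the oracle of the fast path.
    """
    nc = sens.shape[0]
    nx, ny, nz = image.shape
    if sens.shape[1:] != image.shape:
        raise ValueError("sensitivity/image dimension mismatch")
    xs = np.arange(nx) - nx // 2
    ys = np.arange(ny) - ny // 2
    zs = np.arange(nz) - nz // 2
    xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")
    pos = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1).astype(float)
    t_abs = te + traj.t
    rate = np.zeros(nx * ny * nz, complex)
    if f0 is not None:
        rate += 2j * np.pi * f0.ravel()
    if t2star is not None:
        rate += 1.0 / np.maximum(t2star.ravel(), 1e-6)
    weighted = np.stack([(sens[c] * image).ravel() for c in range(nc)], axis=1)

    res = traj.res
    out = np.zeros((nc, traj.n_readouts, traj.n_samples), complex)
    for p in range(traj.n_readouts):
        kn = traj.k[p] * np.array([res[0], res[1], res[2]])  # cycles/pixel
        for j0 in range(0, traj.n_samples, chunk):
            sl = slice(j0, min(j0 + chunk, traj.n_samples))
            phase = np.exp(-2j * np.pi * (kn[sl] @ pos.T))
            phase = phase * np.exp(-np.outer(t_abs[sl], rate))
            out[:, p, sl] = (phase @ weighted).T
    return out


def _navigator_signal(image: np.ndarray, sens: np.ndarray, nav_times: np.ndarray,
                      f0: np.ndarray | None, t2star: np.ndarray | None
                      ) -> np.ndarray:
    """FID navigator samples: k = 0 readout before the spiral gradient."""
    rate = np.zeros(image.shape, complex)
    if f0 is not None:
        rate += 2j * np.pi * f0
    if t2star is not None:
        rate += 1.0 / np.maximum(t2star, 1e-6)
    decay = np.exp(-np.multiply.outer(nav_times, rate))  # (n_nav, ...)
    weighted = sens * image[None]
    return np.einsum("cxyz,nxyz->cn", weighted, decay)


def encode(ph: PhantomState, image: np.ndarray, traj: Trajectory3D,
           te: float = 0.0024, perturb: PerturbationSpec | None = None,
           noise_sigma: float = 0.0, seed: int = 0, method: str = "fast",
           n_segments: int = 32, n_nav: int = 8,
           drift_hz: float = 0.0,
           operator: EncodingOperator | None = None) -> KspaceData:
    """Synthesize one k-space volume from a ground-truth image.

    ``method`` selects the fast time-segmented path or the exact slow DFT.
    ``drift_hz`` is the instantaneous global frequency offset of this
    volume (driven by the scan clock in :func:`acquire_run`).
    """
    perturb = perturb or PerturbationSpec()
    if image.shape != ph.shape:
        raise ValueError("image does not match phantom matrix")
    if method == "fast":
        op = operator or EncodingOperator(
            traj, ph.coil_sens, fieldmap=ph.b0_map, n_segments=n_segments,
            te=te, t2star=ph.t2star)
        s = op.forward(image.astype(complex))
    elif method == "exact":
        s = slow_encode(image.astype(complex), ph.coil_sens, traj, te=te,
                        f0=ph.b0_map, t2star=ph.t2star)
    else:
        raise ValueError(f"unknown encode method {method!r}")

    dwell = traj.t[1] - traj.t[0] if traj.n_samples > 1 else 2e-6
    nav_times = te + np.arange(n_nav) * dwell
    nav = _navigator_signal(image.astype(complex), ph.coil_sens, nav_times,
                            ph.b0_map, ph.t2star)

    t_abs = te + traj.t
    phase = np.zeros(traj.n_samples)
    if perturb.ec_coeffs:
        phase = phase - perturb.ec_phase(traj.t)
    if perturb.k0_phase is not None:
        if len(perturb.k0_phase) != traj.n_samples:
            raise ValueError("k0 phase trace length mismatch")
        phase = phase - perturb.k0_phase
    if drift_hz != 0.0:
        phase = phase - 2 * np.pi * drift_hz * t_abs
        nav = nav * np.exp(-2j * np.pi * drift_hz * nav_times)[None, :]
    if np.any(phase):
        s = s * np.exp(1j * phase)[None, None, :]

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = s + noise_sigma * (rng.standard_normal(s.shape)
                               + 1j * rng.standard_normal(s.shape))
        nav = nav + noise_sigma * (rng.standard_normal(nav.shape)
                                   + 1j * rng.standard_normal(nav.shape))
    return KspaceData(
        samples=s, traj=traj, navigators=nav, nav_times=nav_times,
        meta={"te": te, "drift_hz": drift_hz}, noise_sigma=noise_sigma)


def acquire_run(ph: PhantomState, timing: SequenceTiming, paradigm: Paradigm,
                traj: Trajectory3D, perturb: PerturbationSpec | None = None,
                noise_sigma: float | None = None, seed: int = 0,
                bold_amplitude: float = 0.02, method: str = "fast",
                n_segments: int = 32) -> list[KspaceData]:
    """Simulate a full functional run: per paradigm volume one VASO and one
    BOLD k-space volume, interleaved in acquisition order.

    The per-volume scan clock drives the drift phase; a relative
    ``noise_sigma`` of None selects 2% of the RMS of the first VASO
    volume's samples. Deterministic under ``seed``.
    """
    perturb = perturb or PerturbationSpec()
    vaso, bold, t_vaso, t_bold = vaso_signal_timeseries(
        ph, timing, paradigm, bold_amplitude=bold_amplitude)
    te_b = timing.te_bold if timing.te_bold is not None else timing.te
    op_v = op_b = None
    if method == "fast":
        op_v = EncodingOperator(traj, ph.coil_sens, fieldmap=ph.b0_map,
                                n_segments=n_segments, te=timing.te,
                                t2star=ph.t2star)
        op_b = op_v if te_b == timing.te else EncodingOperator(
            traj, ph.coil_sens, fieldmap=ph.b0_map, n_segments=n_segments,
            te=te_b, t2star=ph.t2star)

    if noise_sigma is None:
        ref = encode(ph, vaso[0], traj, te=timing.te, method=method,
                     n_segments=n_segments, operator=op_v)
        noise_sigma = 0.02 * float(np.sqrt(np.mean(np.abs(ref.samples) ** 2)))

    ss = np.random.SeedSequence([int(seed), 2])
    child = ss.generate_state(2 * paradigm.n_volumes)
    run: list[KspaceData] = []
    for v in range(paradigm.n_volumes):
        for tag, img, t_acq, te, op in (
                ("vaso", vaso[v], t_vaso[v], timing.te, op_v),
                ("bold", bold[v], t_bold[v], te_b, op_b)):
            drift = perturb.drift_hz_per_min * (t_acq / 60.0)
            kd = encode(ph, img, traj, te=te, perturb=perturb,
                        noise_sigma=noise_sigma,
                        seed=int(child[2 * v + (tag == "bold")]),
                        method=method, n_segments=n_segments, drift_hz=drift,
                        operator=op)
            kd.meta.update(volume_index=v, contrast=tag, scan_time=float(t_acq))
            run.append(kd)
    return run
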