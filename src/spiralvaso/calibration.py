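"""B0 field map and coil sensitivity estimation from multi-echo GRE data.

A low-resolution multi-echo gradient-echo calibration scan (simulated in
the image domain from the phantom, or supplied externally) yields:

* the off-resonance map f0(r) in Hz, from a magnitude-weighted
  least-squares fit of the temporally unwrapped phase evolution across
  the first echoes, with an optional quadratic spatial smoothness penalty
  solved by conjugate gradients;
* coil sensitivity maps, by dividing each coil image by the
  sum-of-squares combination and smoothing (``ratio_smooth``). ESPIRiT is
  accepted as a method name for API compatibility but no eigenvector
  backend ships with this package.

Low-resolution maps are brought to the reconstruction grid by zero-filled
Fourier interpolation, mirroring the matched-geometry calibration
protocol.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse.linalg import LinearOperator, cg

from .phantom import PhantomState

#: echo times (s) of the calibration protocol; the first three are used
#: for field mapping by default.
DEFAULT_ECHO_TIMES = (2.72e-3, 6.31e-3, 12e-3, 25e-3, 32e-3)


def simulate_megre(ph: PhantomState, echo_times=DEFAULT_ECHO_TIMES,
                   noise_sigma: float = 0.0, seed: int = 0,
                   downsample: int = 1) -> np.ndarray:
    """Multi-echo GRE calibration volumes, (n_echoes, n_coils, nx, ny, nz).

    Image-domain simulation: I_n = c * m0 * exp(i 2 pi f0 TE_n)
    * exp(-TE_n / T2*), optionally Fourier-truncated to a ``downsample``x
    lower resolution (matched low-res protocol) and with complex noise.
    """
    echo_times = np.asarray(echo_times, float)
    imgs = []
    for te in echo_times:
        w = ph.m0 * np.exp(2j * np.pi * ph.b0_map * te) \
            * np.exp(-te / np.maximum(ph.t2star, 1e-6))
        imgs.append(ph.coil_sens * w[None])
    out = np.stack(imgs)  # (ne, nc, nx, ny, nz)
    if downsample > 1:
        out = fourier_downsample(out, downsample)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + noise_sigma * (rng.standard_normal(out.shape)
                                   + 1j * rng.standard_normal(out.shape))
    return out


def _centered_fft2(x):
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(-3, -2)),
                                       axes=(-3, -2)), axes=(-3, -2))


def _centered_ifft2(x):
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x, axes=(-3, -2)),
                                        axes=(-3, -2)), axes=(-3, -2))


def fourier_downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    """Crop the in-plane k-space center (axes -3, -2), keeping nz."""
    nx, ny = vol.shape[-3], vol.shape[-2]
    mx, my = nx // factor, ny // factor
    X = _centered_fft2(vol)
    x0, y0 = (nx - mx) // 2, (ny - my) // 2
    Xc = X[..., x0:x0 + mx, y0:y0 + my, :]
    return _centered_ifft2(Xc) / (nx * ny) * (mx * my)


def fourier_upsample(vol: np.ndarray, shape_xy: tuple[int, int]) -> np.ndarray:
    """Zero-filled Fourier interpolation of the in-plane axes (-3, -2)."""
    nx, ny = vol.shape[-3], vol.shape[-2]
    mx, my = shape_xy
    X = _centered_fft2(vol)
    out = np.zeros(vol.shape[:-3] + (mx, my, vol.shape[-1]), complex)
    x0, y0 = (mx - nx) // 2, (my - ny) // 2
    out[..., x0:x0 + nx, y0:y0 + ny, :] = X
    return _centered_ifft2(out) / (nx * ny) * (mx * my)


class FieldMap:
    """Off-resonance map in Hz with support mask and aliasing flags."""

    def __init__(self, f0: np.ndarray, mask: np.ndarray,
                 echo_times_used: np.ndarray, aliased: np.ndarray | None = None):
        self.f0 = f0
        self.mask = mask
        self.echo_times_used = echo_times_used
        self.aliased = aliased if aliased is not None else np.zeros_like(mask)

    def to_grid(self, shape_xy: tuple[int, int]) -> "FieldMap":
        if self.f0.shape[:2] == tuple(shape_xy):
            return self
        f0 = fourier_upsample(self.f0.astype(complex), shape_xy).real
        mask = fourier_upsample(self.mask.astype(complex), shape_xy).real > 0.5
        f0 = np.where(mask, f0, 0.0)
        return FieldMap(f0, mask, self.echo_times_used)


class SensitivityMaps:
    """Complex coil maps, sum-of-squares normalized inside the mask."""

    def __init__(self, c: np.ndarray, mask: np.ndarray):
        self.c = c
        self.mask = mask

    @property
    def n_coils(self) -> int:
        return self.c.shape[0]

    def to_grid(self, shape_xy: tuple[int, int]) -> "SensitivityMaps":
        if self.c.shape[1:3] == tuple(shape_xy):
            return self
        c = fourier_upsample(self.c, shape_xy)
        mask = fourier_upsample(self.mask.astype(complex), shape_xy).real > 0.5
        sos = np.sqrt((np.abs(c) ** 2).sum(axis=0))
        c = np.where(mask[None], c / np.maximum(sos[None], 1e-12), c)
        return SensitivityMaps(c, mask)


def estimate_fieldmap(megre: np.ndarray, echo_times, n_echoes_used: int = 3,
                      smoothing_reg: float = 0.0,
                      mask_threshold: float = 0.10) -> FieldMap:
    """Magnitude-weighted least-squares field map from multi-echo phase.

    ``megre``: (n_echoes, n_coils, nx, ny, nz) complex. Coil-combined
    inter-echo phase differences are temporally unwrapped assuming
    |f0| < 1/(2 min dTE); the weighted LS slope of phase vs TE gives f0.
    ``smoothing_reg`` > 0 adds a quadratic spatial-Laplacian penalty,
    solved with conjugate gradients on (W + lambda L^T L) f = W f_wls.
    """
    echo_times = np.asarray(echo_times, float)
    if megre.ndim != 5:
        raise ValueError("megre must be (n_echoes, n_coils, nx, ny, nz)")
    if len(echo_times) != megre.shape[0]:
        raise ValueError("echo_times length mismatch")
    if n_echoes_used < 2:
        raise ValueError("need at least 2 echoes")
    ne = int(n_echoes_used)
    echo_times = echo_times[:ne]
    if np.any(np.diff(echo_times) <= 0):
        raise ValueError("echo times must be strictly increasing")
    data = megre[:ne]

    mag1 = np.sqrt((np.abs(data[0]) ** 2).sum(axis=0))
    mask = mag1 > mask_threshold * mag1.max()

    # coil-combined phase differences between successive echoes
    dtes = np.diff(echo_times)
    shape = data.shape[2:]
    phi = np.zeros((ne,) + shape)
    weights = np.zeros((ne - 1,) + shape)
    for n in range(ne - 1):
        inner = (data[n + 1] * np.conj(data[n])).sum(axis=0)
        dphi = np.angle(inner)  # wrapped to (-pi, pi]: |f0| < 1/(2 dTE)
        phi[n + 1] = phi[n] + dphi
        weights[n] = np.abs(inner)

    # weighted LS slope of phi vs TE per voxel (intercept included)
    w = np.concatenate([weights[:1], weights], axis=0)  # echo weights
    te = echo_times[:, None, None, None]
    sw = w.sum(axis=0)
    sw = np.where(sw > 0, sw, 1.0)
    te_bar = (w * te).sum(axis=0) / sw
    phi_bar = (w * phi).sum(axis=0) / sw
    cov = (w * (te - te_bar) * (phi - phi_bar)).sum(axis=0)
    var = (w * (te - te_bar) ** 2).sum(axis=0)
    slope = np.where(var > 0, cov / np.maximum(var, 1e-30), 0.0)
    f0 = slope / (2 * np.pi)
    f0 = np.where(mask, f0, 0.0)

    nyq = 1.0 / (2.0 * dtes.min())
    aliased = mask & (np.abs(f0) > nyq)

    if smoothing_reg > 0:
        f0 = _smooth_penalized(f0, sw * mask, smoothing_reg)
        f0 = np.where(mask, f0, 0.0)
    return FieldMap(f0, mask, echo_times, aliased)


def _laplacian3(x):
    out = -6.0 * x
    for ax in range(3):
        out += np.roll(x, 1, axis=ax) + np.roll(x, -1, axis=ax)
    return out


def _smooth_penalized(f_wls, w, lam, max_iter=100):
    """Solve (W + lam L^T L) f = W f_wls with CG."""
    shape = f_wls.shape
    wflat = w.ravel()

    def matvec(v):
        vol = v.reshape(shape)
        return (wflat * v) + lam * _laplacian3(_laplacian3(vol)).ravel()

    A = LinearOperator((f_wls.size,) * 2, matvec=matvec, dtype=float)
    b = (w * f_wls).ravel()
    sol, _ = cg(A, b, x0=f_wls.ravel(), maxiter=max_iter, rtol=1e-8)
    return sol.reshape(shape)


def estimate_sensitivities(calib: np.ndarray, method: str = "ratio_smooth",
                           smooth_sigma: float = 1.0,
                           mask_threshold: float = 0.10) -> SensitivityMaps:
    """Coil sensitivity maps from a fully sampled calibration volume.

    ``calib``: (n_coils, nx, ny, nz) complex (e.g. the first GRE echo).
    ``ratio_smooth`` divides each coil image by the sum-of-squares
    combination, smooths the ratio, and renormalizes to unit SoS inside
    the mask.
    """
    if method == "espirit":
        raise ValueError(
            "no ESPIRiT eigen-decomposition backend is available in this "
            "package; use method='ratio_smooth'")
    if method != "ratio_smooth":
        raise ValueError(f"unknown sensitivity method {method!r}")
    calib = np.asarray(calib, complex)
    sos = np.sqrt((np.abs(calib) ** 2).sum(axis=0))
    if sos.max() == 0:
        raise ValueError("all-zero calibration data")
    mask = sos > mask_threshold * sos.max()
    ratio = calib / np.maximum(sos[None], 1e-12 * sos.max())
    sm = np.empty_like(ratio)
    for c in range(ratio.shape[0]):
        sm[c] = gaussian_filter(ratio[c].real, smooth_sigma) \
            + 1j * gaussian_filter(ratio[c].imag, smooth_sigma)
    sos2 = np.sqrt((np.abs(sm) ** 2).sum(axis=0))
    c = np.where(mask[None], sm / np.maximum(sos2[None], 1e-12), 0.0)
    return SensitivityMaps(c, mask)
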