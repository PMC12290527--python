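"""Kaiser-Bessel gridding NUFFT for 2D non-Cartesian sampling.

The operator evaluates s_j = sum_r m(r) exp(-i 2 pi k_j . r) for arbitrary
sample locations k_j, with r on a centered Cartesian grid, via an
oversampled FFT and sparse Kaiser-Bessel interpolation. The interpolation
is stored as an explicit scipy.sparse matrix, so the adjoint is the exact
conjugate transpose and the forward/adjoint pair passes inner-product
tests to machine-level accuracy of the kernel approximation (~1e-6 with
oversampling 2 and kernel width 6).

A dense slow DFT (``slow_dft`` / ``slow_dft_adjoint``) is provided as the
brute-force oracle for small problems.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import i0


def _kb_beta(width: int, os: float) -> float:
    # Beatty et al. choice of the Kaiser-Bessel shape parameter
    return np.pi * np.sqrt((width / os) ** 2 * (os - 0.5) ** 2 - 0.8)


def _kb_kernel(d: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel on grid-index offsets d, support |d| <= width/2."""
    x = 2.0 * d / width
    inside = np.abs(x) <= 1.0
    val = np.zeros_like(d, dtype=float)
    val[inside] = i0(beta * np.sqrt(1.0 - x[inside] ** 2))
    return val


class PlaneNufft:
    """2D NUFFT between an (nx, ny) image and arbitrary k-space samples.

    Parameters
    ----------
    k_norm : (n_samples, 2) array
        Sample locations in normalized units (cycles per pixel,
        k_cycles_per_m * pixel_size), in [-0.5, 0.5).
    shape : (nx, ny)
        Image matrix.
    os : float
        Grid oversampling factor.
    width : int
        Interpolation kernel width in oversampled-grid units.
    """

    def __init__(self, k_norm: np.ndarray, shape: tuple[int, int],
                 os: float = 2.0, width: int = 6):
        k_norm = np.asarray(k_norm, float)
        if k_norm.ndim != 2 or k_norm.shape[1] != 2:
            raise ValueError("k_norm must have shape (n_samples, 2)")
        if np.any(np.abs(k_norm) > 0.5 + 1e-9):
            raise ValueError("normalized k-space samples must lie in [-0.5, 0.5]")
        self.shape = tuple(shape)
        self.n_samples = k_norm.shape[0]
        self.os = os
        self.width = int(width)
        self.grid = tuple(int(np.ceil(os * n / 2) * 2) for n in shape)
        beta = _kb_beta(self.width, os)
        self._beta = beta
        self._interp = self._build_interp(k_norm, beta)
        self._interp_H = self._interp.conjugate().transpose().tocsr()
        self._deapod = self._build_deapod(beta)
        # centered DFT via plain fft: fold the fftshift/ifftshift pairs into
        # (a) a checkerboard sign on the padded image (absorbed into the
        # deapodization patch) and (b) a per-grid-point sign on the
        # interpolation matrix columns
        Gx, Gy = self.grid
        cbg = np.outer((-1.0) ** np.arange(Gx), (-1.0) ** np.arange(Gy))
        self._interp = self._interp.multiply(cbg.ravel()[None, :]).tocsr()
        self._interp_H = self._interp.conjugate().transpose().tocsr()
        nx, ny = self.shape
        x0, y0 = (Gx - nx) // 2, (Gy - ny) // 2
        cb_img = np.outer((-1.0) ** (np.arange(nx) + x0),
                          (-1.0) ** (np.arange(ny) + y0))
        self._deapod_fft = self._deapod * cb_img * (-1.0) ** (Gx // 2 + Gy // 2)
        self._pad_offset = (x0, y0)

    # -- construction -----------------------------------------------------
    def _build_interp(self, k_norm, beta):
        Gx, Gy = self.grid
        w = self.width
        half = w / 2.0
        # fractional grid position of each sample (centered convention)
        px = k_norm[:, 0] * Gx + Gx / 2.0
        py = k_norm[:, 1] * Gy + Gy / 2.0
        offs = np.arange(-int(np.ceil(half)) + 1, int(np.ceil(half)) + 1)
        ix = np.floor(px)[:, None] + offs[None, :]
        iy = np.floor(py)[:, None] + offs[None, :]
        wx = _kb_kernel(ix - px[:, None], w, beta)
        wy = _kb_kernel(iy - py[:, None], w, beta)
        ix = np.mod(ix.astype(int), Gx)
        iy = np.mod(iy.astype(int), Gy)
        n_off = len(offs)
        rows = np.repeat(np.arange(self.n_samples), n_off * n_off)
        cols = (ix[:, :, None] * Gy + iy[:, None, :]).reshape(-1)
        vals = (wx[:, :, None] * wy[:, None, :]).reshape(-1)
        keep = vals != 0.0
        mat = sp.csr_matrix(
            (vals[keep], (rows[keep], cols[keep])),
            shape=(self.n_samples, Gx * Gy),
        )
        return mat

    def _ft_kernel_1d(self, n, G, beta):
        """Numerical Fourier transform of the KB kernel at image positions
        (centered), used for deapodization."""
        w = self.width
        d = np.linspace(-w / 2, w / 2, 4001)
        c = _kb_kernel(d, w, beta)
        x = (np.arange(n) - n // 2) / G  # cycles per grid index
        ph = np.exp(-2j * np.pi * x[:, None] * d[None, :])
        return np.real(np.trapezoid(ph * c[None, :], d, axis=1))

    def _build_deapod(self, beta):
        nx, ny = self.shape
        Gx, Gy = self.grid
        fx = self._ft_kernel_1d(nx, Gx, beta)
        fy = self._ft_kernel_1d(ny, Gy, beta)
        return 1.0 / np.outer(fx, fy)

    # -- application ------------------------------------------------------
    def forward(self, img: np.ndarray) -> np.ndarray:
        """Image(s) (..., nx, ny) -> samples (..., n_samples)."""
        img = np.asarray(img)
        batch = img.shape[:-2]
        nx, ny = self.shape
        Gx, Gy = self.grid
        x0, y0 = self._pad_offset
        pad = np.zeros(batch + (Gx, Gy), dtype=complex)
        pad[..., x0:x0 + nx, y0:y0 + ny] = img * self._deapod_fft
        X = np.fft.fft2(pad, axes=(-2, -1))
        flat = X.reshape(-1, Gx * Gy)
        out = self._interp @ np.ascontiguousarray(flat.T)
        return np.ascontiguousarray(out.T).reshape(batch + (self.n_samples,))

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward`: samples (..., n) -> image."""
        samples = np.asarray(samples, complex)
        batch = samples.shape[:-1]
        nx, ny = self.shape
        Gx, Gy = self.grid
        flat = samples.reshape(-1, self.n_samples)
        X = self._interp_H @ np.ascontiguousarray(flat.T)
        X = np.ascontiguousarray(X.T).reshape(batch + (Gx, Gy))
        x = np.fft.ifft2(X, axes=(-2, -1)) * (Gx * Gy)
        x0, y0 = self._pad_offset
        crop = x[..., x0:x0 + nx, y0:y0 + ny]
        return crop * self._deapod_fft

    def interp_only(self, weights: np.ndarray) -> np.ndarray:
        """Kernel convolution C C^H w on the sample cloud (Pipe-Menon)."""
        return self._interp @ (self._interp_H @ weights)


def slow_dft(img: np.ndarray, k_norm: np.ndarray) -> np.ndarray:
    """Brute-force s_j = sum_r m(r) exp(-i 2 pi k_j . r), r centered."""
    nx, ny = img.shape[-2:]
    x = np.arange(nx) - nx // 2
    y = np.arange(ny) - ny // 2
    xx, yy = np.meshgrid(x, y, indexing="ij")
    phase = np.exp(
        -2j * np.pi * (k_norm[:, 0, None] * xx.ravel()[None, :]
                       + k_norm[:, 1, None] * yy.ravel()[None, :])
    )
    if img.ndim == 2:
        return phase @ img.ravel()
    flat = img.reshape(-1, nx * ny)
    return (phase @ flat.T).T.reshape(img.shape[:-2] + (len(k_norm),))


def slow_dft_adjoint(samples: np.ndarray, k_norm: np.ndarray,
                     shape: tuple[int, int]) -> np.ndarray:
    nx, ny = shape
    x = np.arange(nx) - nx // 2
    y = np.arange(ny) - ny // 2
    xx, yy = np.meshgrid(x, y, indexing="ij")
    phase = np.exp(
        2j * np.pi * (k_norm[:, 0, None] * xx.ravel()[None, :]
                      + k_norm[:, 1, None] * yy.ravel()[None, :])
    )
    return (phase.T @ samples).reshape(nx, ny)
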