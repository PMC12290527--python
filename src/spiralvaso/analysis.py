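"""Functional analysis of interleaved VASO/BOLD time series.

Implements the downstream chain for blood-volume fMRI: temporal
upsampling and dynamic-division BOLD correction (the blood-nulled and
BOLD-weighted volumes share proton-density, T2* and bias weighting, so
dividing the upsampled series removes the multiplicative BOLD
contamination), Gaussian-running-line high-pass filtering, tSNR and the
T1-weighted inverse-coefficient-of-variation image, GLM activation maps
with cluster thresholding, laminar profiles, and gray-vs-white-matter ROC
curves quantifying relative spatial specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .phantom import Paradigm


@dataclass
class VasoSeries:
    """Paired 4D magnitude series, (n_volumes, nx, ny, nz) each."""

    vaso: np.ndarray
    bold: np.ndarray
    tr_effective: float
    paradigm: Paradigm
    t_vaso: np.ndarray | None = None
    t_bold: np.ndarray | None = None
    upsampled: bool = False

    def __post_init__(self):
        if self.vaso.shape != self.bold.shape:
            raise ValueError("VASO and BOLD series must have the same shape")
        if self.t_vaso is None:
            self.t_vaso = np.arange(len(self.vaso)) * self.tr_effective
        if self.t_bold is None:
            self.t_bold = self.t_vaso + 0.5 * self.tr_effective


def boco_correct(series: VasoSeries, eps: float = 1e-6) -> VasoSeries:
    """Dynamic-division BOLD correction after 2x temporal upsampling.

    Both series are linearly interpolated onto the union of the VASO and
    BOLD acquisition times (doubling the volume count); the corrected
    VASO is the voxelwise ratio VASO/BOLD with the divisor floored at
    ``eps`` times its maximum.
    """
    if len(series.vaso) == 0:
        raise ValueError("empty series")
    t_union = np.sort(np.concatenate([series.t_vaso, series.t_bold]))
    v_up = _interp_series(series.vaso, series.t_vaso, t_union)
    b_up = _interp_series(series.bold, series.t_bold, t_union)
    floor = eps * b_up.max()
    corrected = v_up / np.maximum(b_up, floor)
    boxcar = series.paradigm.boxcar()
    up_par = Paradigm(series.paradigm.n_blocks, 2 * series.paradigm.trs_rest,
                      2 * series.paradigm.trs_active,
                      series.paradigm.tr_effective / 2)
    return VasoSeries(vaso=corrected, bold=b_up,
                      tr_effective=series.tr_effective / 2, paradigm=up_par,
                      t_vaso=t_union, t_bold=t_union, upsampled=True)


def _interp_series(series: np.ndarray, t: np.ndarray, t_new: np.ndarray):
    flat = series.reshape(len(series), -1)
    out = np.empty((len(t_new), flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_new, t, flat[:, j])
    return out.reshape((len(t_new),) + series.shape[1:])


def temporal_highpass(series: np.ndarray, cutoff_fwhm: float,
                      tr: float = 1.0) -> np.ndarray:
    """Gaussian-weighted running-line high-pass filter (mean preserving).

    At each time point a linear trend is fitted with Gaussian weights of
    the given FWHM (seconds, converted with ``tr``) and subtracted; the
    temporal mean is re-added. cutoff_fwhm = inf returns the input.
    """
    if cutoff_fwhm <= 0:
        raise ValueError("cutoff_fwhm must be positive")
    nt = len(series)
    if not np.isfinite(cutoff_fwhm):
        return series.copy()
    sigma = cutoff_fwhm / tr / (2 * np.sqrt(2 * np.log(2)))
    t = np.arange(nt, dtype=float)
    w = np.exp(-0.5 * ((t[:, None] - t[None, :]) / sigma) ** 2)  # (t0, t)
    sw = w.sum(axis=1)
    st = w @ t
    stt = w @ (t * t)
    flat = series.reshape(nt, -1)
    sy = w @ flat
    sty = w @ (t[:, None] * flat)
    denom = sw * stt - st**2
    denom = np.where(np.abs(denom) > 1e-12, denom, 1.0)
    slope = (sw[:, None] * sty - st[:, None] * sy) / denom[:, None]
    intercept = (sy - slope * st[:, None]) / sw[:, None]
    trend = intercept + slope * t[:, None]
    out = flat - trend + flat.mean(axis=0, keepdims=True)
    return out.reshape(series.shape)


def tsnr(series: np.ndarray, detrend: bool = True) -> np.ndarray:
    """Voxelwise temporal mean / temporal std (optionally after removing a
    linear trend); zero where the std vanishes."""
    if len(series) < 3:
        raise ValueError("tsnr needs at least 3 volumes")
    flat = series.reshape(len(series), -1).astype(float)
    mean = flat.mean(axis=0)
    resid = flat - mean
    if detrend:
        t = np.arange(len(series), dtype=float)
        t = t - t.mean()
        slope = (t @ resid) / (t @ t)
        resid = resid - t[:, None] * slope[None, :]
    std = resid.std(axis=0)
    out = np.where(std > 0, mean / np.where(std > 0, std, 1.0), 0.0)
    return out.reshape(series.shape[1:])


def effective_tsnr(tsnr_map: np.ndarray, effective_resolution: float,
                   nominal_resolution: float) -> np.ndarray:
    """tSNR per effective-resolution element: divides by the in-plane
    voxel-volume ratio implied by the PSF broadening."""
    ratio = (effective_resolution / nominal_resolution) ** 2
    return tsnr_map / ratio


def t1w_cvarinv(vaso: np.ndarray, bold: np.ndarray) -> np.ndarray:
    """T1-weighted image: inverse coefficient of variation (mean/std,
    population convention) over the concatenated VASO+BOLD series; voxels
    with zero variance are masked to zero."""
    cat = np.concatenate([vaso, bold], axis=0)
    mean = cat.mean(axis=0)
    std = cat.std(axis=0)  # ddof=0
    return np.where(std > 0, mean / np.where(std > 0, std, 1.0), 0.0)


@dataclass
class ActivationResult:
    zmap: np.ndarray
    tmap: np.ndarray
    beta: np.ndarray
    clusters: np.ndarray          # labeled components of suprathreshold voxels
    active_mask: np.ndarray
    threshold: float
    min_cluster: int
    dof: int


def glm_activation(series: np.ndarray, paradigm: Paradigm,
                   contrast_sign: float = 1.0, include_drift: bool = True,
                   z_threshold: float = 2.4, min_cluster: int = 5,
                   design: np.ndarray | None = None) -> ActivationResult:
    """Ordinary-least-squares GLM with a boxcar regressor.

    Design: [boxcar, intercept, linear drift (optional)]. The t statistic
    of the boxcar is converted to a z score through the Student-t CDF and
    multiplied by ``contrast_sign`` (use -1 for the negative VASO
    response). Clusters are 6-connected components of |z| >= threshold in
    the signed (sign-adjusted) map; components smaller than
    ``min_cluster`` voxels are discarded.
    """
    nt = len(series)
    box = design if design is not None else paradigm.boxcar()
    if len(box) != nt:
        raise ValueError("design length does not match series length")
    cols = [box - box.mean(), np.ones(nt)]
    if include_drift:
        t = np.arange(nt, dtype=float)
        cols.append(t - t.mean())
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    flat = series.reshape(nt, -1).astype(float)
    beta, _, _, _ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    dof = nt - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / max(dof, 1)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 1e-300))
    tstat = beta[0] / se
    # normal-approximation z through the exact t CDF (symmetric tails)
    z = stats.norm.isf(stats.t.sf(np.abs(tstat), dof)) * np.sign(tstat)
    z = np.clip(np.nan_to_num(z), -40, 40)
    zmap = (contrast_sign * z).reshape(series.shape[1:])
    tmap = tstat.reshape(series.shape[1:])
    clusters, active = cluster_threshold(zmap, z_threshold, min_cluster)
    return ActivationResult(zmap=zmap, tmap=tmap,
                            beta=beta[0].reshape(series.shape[1:]),
                            clusters=clusters, active_mask=active,
                            threshold=z_threshold, min_cluster=min_cluster,
                            dof=dof)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def cluster_threshold(zmap: np.ndarray, threshold: float,
                      min_cluster: int) -> tuple[np.ndarray, np.ndarray]:
    """Face-connected (6-connectivity) components of z >= threshold with a
    minimum cluster extent. Returns (labels, surviving mask)."""
    supra = zmap >= threshold
    labels, n = ndimage.label(supra, structure=_STRUCT6)
    if n == 0:
        return labels, supra
    counts = np.bincount(labels.ravel())
    keep = counts >= min_cluster
    keep[0] = False
    active = keep[labels]
    labels = np.where(active, labels, 0)
    return labels, active


def layer_profile(zmap: np.ndarray, layer_index: np.ndarray,
                  n_layers: int) -> np.ndarray:
    """Mean z per cortical layer (NaN for empty layers)."""
    if not np.any(layer_index >= 0):
        raise ValueError("no ROI voxels: layer_index is empty")
    prof = np.full(n_layers, np.nan)
    for l in range(n_layers):
        sel = layer_index == l
        if np.any(sel):
            prof[l] = zmap[sel].mean()
    return prof


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tp_fraction: np.ndarray
    fp_fraction: np.ndarray
    auc: float


def roc_specificity(zmap: np.ndarray, gm_mask: np.ndarray, wm_mask: np.ndarray,
                    thresholds: np.ndarray | None = None,
                    min_cluster: int = 5) -> RocCurve:
    """Relative-specificity ROC: fraction of suprathreshold voxels (after
    cluster thresholding) in gray matter (true positives) vs white matter
    (false positives) over a range of z thresholds; AUC by trapezoid over
    the false-positive axis, with the curve closed at (0,0) and (1,1)."""
    if not gm_mask.any() or not wm_mask.any():
        raise ValueError("empty GM or WM mask")
    if thresholds is None:
        thresholds = np.linspace(-8.0, 12.0, 101)
    thresholds = np.asarray(thresholds, float)
    tp = np.empty(len(thresholds))
    fp = np.empty(len(thresholds))
    n_gm = gm_mask.sum()
    n_wm = wm_mask.sum()
    for i, th in enumerate(thresholds):
        _, active = cluster_threshold(zmap, th, min_cluster)
        tp[i] = active[gm_mask].sum() / n_gm
        fp[i] = active[wm_mask].sum() / n_wm
    order = np.argsort(fp)
    fpo = np.concatenate([[0.0], fp[order], [1.0]])
    tpo = np.concatenate([[0.0], tp[order], [1.0]])
    auc = float(np.trapezoid(tpo, fpo))
    return RocCurve(thresholds=thresholds, tp_fraction=tp, fp_fraction=fp,
                    auc=auc)
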