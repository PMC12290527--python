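"""Digital brain-slab phantom and VASO/BOLD ground-truth signal model.

The phantom is a cylindrical slab with a CSF rim, a cortical gray-matter
ribbon subdivided into layers, and a white-matter core. It carries proton
density, T1, T2*, a smooth B0 field with optional susceptibility foci,
resting blood-volume fractions, and analytic complex coil sensitivities.
It is the ground truth against which trajectory, reconstruction and
analysis code is tested.

The VASO signal model: an adiabatic inversion (ideal rotation with
efficiency ``inv_eff``) precedes each blood-nulled volume; at the chosen
inversion time TI1 the blood longitudinal magnetization crosses zero, so
the voxel signal is m0 * (1 - CBV) * f_tissue, where f_tissue is the
steady-state inversion-recovery factor of tissue. Activation increases
CBV by a fractional amount, producing the characteristic negative VASO
response -cbv_rest * cbv_delta / (1 - cbv_rest). A BOLD-weighted volume
acquired right after the VASO one shares the multiplicative BOLD factor,
which is what the downstream dynamic-division correction removes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

LABELS = {"background": 0, "csf": 1, "gm": 2, "wm": 3}


@dataclass
class PhantomConfig:
    """Generator knobs; defaults emulate a 7T laminar-fMRI protocol slab."""

    n_layers: int = 7
    n_coils: int = 8
    # tissue parameters (s) — field-strength-typical assumptions, overridable
    t1_gm: float = 1.9
    t1_wm: float = 1.2
    t1_csf: float = 4.3
    t1_blood: float = 2.1
    t2s_gm: float = 0.025
    t2s_wm: float = 0.022
    t2s_csf: float = 0.06
    m0_gm: float = 0.8
    m0_wm: float = 0.65
    m0_csf: float = 1.0
    # blood volume
    cbv_rest_gm: float = 0.05
    cbv_rest_wm: float = 0.01
    cbv_delta: float = 0.6  # fractional CBV increase at activation peak
    # activation geometry: angular sector of the ribbon that responds
    roi_half_angle_deg: float = 60.0
    # B0 field: peak of the smooth polynomial component (Hz) and foci
    b0_amplitude: float = 30.0
    n_foci: int = 2
    focus_amplitude: float = 60.0
    focus_sigma_vox: float = 2.5
    # BOLD weighting toward superficial layers / CSF (draining veins)
    bold_superficial_weight: float = 1.0


@dataclass
class PhantomState:
    """Voxelwise ground truth for the simulated acquisition."""

    labels: np.ndarray          # int, (nx, ny, nz)
    layer_index: np.ndarray     # int, -1 outside the ribbon
    m0: np.ndarray
    t1: np.ndarray
    t2star: np.ndarray
    b0_map: np.ndarray          # Hz
    cbv_rest: np.ndarray
    cbv_delta: np.ndarray       # fractional increase during activity
    bold_weight: np.ndarray     # relative BOLD amplitude map (1 = nominal)
    sector_mask: np.ndarray     # stimulated angular sector (all tissues)
    coil_sens: np.ndarray       # complex, (n_coils, nx, ny, nz)
    t1_blood: float
    config: PhantomConfig
    seed: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels != LABELS["background"]

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels == LABELS["gm"]

    @property
    def wm_mask(self) -> np.ndarray:
        return self.labels == LABELS["wm"]

    @property
    def roi_mask(self) -> np.ndarray:
        return self.cbv_delta > 0


def build_phantom(matrix: tuple[int, int, int], seed: int = 0,
                  config: PhantomConfig | None = None) -> PhantomState:
    """Generate the deterministic brain-slab phantom.

    ``matrix`` = (nx, ny, nz), each >= 8. The in-plane geometry is an
    ellipse: CSF rim outside, a gray-matter ribbon of ``n_layers`` layers
    (layer 0 deepest, adjacent to WM), and a WM core.
    """
    cfg = config or PhantomConfig()
    nx, ny, nz = matrix
    if min(nx, ny, nz) < 8:
        raise ValueError("matrix must be at least 8 in every dimension")
    rng = np.random.default_rng(seed)

    x = (np.arange(nx) - nx / 2 + 0.5) / (nx / 2)
    y = (np.arange(ny) - ny / 2 + 0.5) / (ny / 2)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rho = np.sqrt((xx / 0.95) ** 2 + (yy / 0.8) ** 2)  # elliptical radius
    theta = np.arctan2(yy, xx)

    # radial shells: WM core | GM ribbon | CSF rim | background
    r_wm, r_gm, r_csf = 0.55, 0.82, 1.0
    labels2d = np.zeros((nx, ny), dtype=np.int8)
    labels2d[rho < r_csf] = LABELS["csf"]
    labels2d[rho < r_gm] = LABELS["gm"]
    labels2d[rho < r_wm] = LABELS["wm"]

    layer2d = np.full((nx, ny), -1, dtype=np.int16)
    in_ribbon = labels2d == LABELS["gm"]
    depth = (rho - r_wm) / (r_gm - r_wm)  # 0 at WM boundary, 1 at CSF
    idx = np.clip((depth * cfg.n_layers).astype(int), 0, cfg.n_layers - 1)
    layer2d[in_ribbon] = idx[in_ribbon]
    if any((layer2d == l).sum() == 0 for l in range(cfg.n_layers)):
        raise ValueError("matrix too small to contain the layered ribbon")

    labels = np.repeat(labels2d[:, :, None], nz, axis=2)
    layer_index = np.repeat(layer2d[:, :, None], nz, axis=2)

    def fill(gm, wm, csf):
        out = np.zeros(matrix)
        out[labels == LABELS["gm"]] = gm
        out[labels == LABELS["wm"]] = wm
        out[labels == LABELS["csf"]] = csf
        return out

    m0 = fill(cfg.m0_gm, cfg.m0_wm, cfg.m0_csf)
    t1 = fill(cfg.t1_gm, cfg.t1_wm, cfg.t1_csf)
    t2star = fill(cfg.t2s_gm, cfg.t2s_wm, cfg.t2s_csf)
    t2star[t2star == 0] = cfg.t2s_csf  # background: value irrelevant (m0=0)

    # smooth low-order polynomial B0 + local susceptibility foci
    coeffs = rng.uniform(-1.0, 1.0, size=6)
    zz = (np.arange(nz) - nz / 2 + 0.5) / (nz / 2)
    poly = (coeffs[0] * xx + coeffs[1] * yy + coeffs[2] * xx * yy
            + coeffs[3] * (xx**2 - 0.5) + coeffs[4] * (yy**2 - 0.5))
    b0 = np.repeat(poly[:, :, None], nz, axis=2) + coeffs[5] * 0.3 * zz[None, None, :]
    peak = np.abs(b0).max()
    b0 = b0 / peak * cfg.b0_amplitude if peak > 0 else b0
    for _ in range(cfg.n_foci):
        ang = rng.uniform(0, 2 * np.pi)
        fx = 0.9 * r_gm * np.cos(ang) * 0.95
        fy = 0.9 * r_gm * np.sin(ang) * 0.8
        amp = rng.choice([-1.0, 1.0]) * cfg.focus_amplitude
        sx = cfg.focus_sigma_vox / (nx / 2)
        d2 = ((xx - fx) ** 2 + (yy - fy) ** 2) / (2 * sx**2)
        b0 += amp * np.exp(-np.minimum(d2, 50.0))[:, :, None]
    if cfg.b0_amplitude == 0 and cfg.focus_amplitude == 0:
        b0[:] = 0.0
    b0[labels == 0] = 0.0

    cbv_rest = fill(cfg.cbv_rest_gm, cfg.cbv_rest_wm, 0.0)

    # activated ROI: angular sector of the ribbon; CBV response peaks
    # mid-ribbon (microvasculature), BOLD weighting grows superficially
    sector = np.abs(np.degrees(theta)) < cfg.roi_half_angle_deg
    sector3d = np.repeat(sector[:, :, None], nz, axis=2)
    cbv_delta = np.zeros(matrix)
    in_roi = sector3d & (layer_index >= 0)
    mid = (cfg.n_layers - 1) / 2.0
    layer_f = layer_index.astype(float)
    bump = 0.5 + 0.5 * np.exp(-((layer_f - mid) ** 2) / (2 * (cfg.n_layers / 4.0) ** 2))
    cbv_delta[in_roi] = cfg.cbv_delta * bump[in_roi]

    bold_weight = np.zeros(matrix)
    sup = 0.4 + 0.6 * (layer_f + 1) / cfg.n_layers  # ramps to superficial
    bold_weight[in_roi] = (1 - cfg.bold_superficial_weight) + \
        cfg.bold_superficial_weight * sup[in_roi]
    csf_roi = sector3d & (labels == LABELS["csf"])
    bold_weight[csf_roi] = 1.0 + 0.2 * cfg.bold_superficial_weight

    coil_sens = _analytic_coils(matrix, cfg.n_coils)

    return PhantomState(
        labels=labels, layer_index=layer_index, m0=m0, t1=t1, t2star=t2star,
        b0_map=b0, cbv_rest=cbv_rest, cbv_delta=cbv_delta,
        bold_weight=bold_weight, sector_mask=sector3d, coil_sens=coil_sens,
        t1_blood=cfg.t1_blood, config=cfg, seed=seed,
    )


def _analytic_coils(matrix, n_coils) -> np.ndarray:
    """Smooth complex sensitivities: Gaussian amplitude lobes placed on a
    circle around the object with slowly varying phase ramps, normalized
    to unit sum-of-squares (the convention SENSE reconstruction assumes,
    so reconstructed magnitudes compare directly to m0)."""
    nx, ny, nz = matrix
    x = (np.arange(nx) - nx / 2 + 0.5) / (nx / 2)
    y = (np.arange(ny) - ny / 2 + 0.5) / (ny / 2)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    sens = np.zeros((n_coils, nx, ny, nz), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cx, cy = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        amp = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 0.8**2))
        phase = np.pi * (0.3 * (xx * np.cos(ang) + yy * np.sin(ang)) + 0.2 * c / n_coils)
        sens[c] = (amp * np.exp(1j * phase))[:, :, None]
    if n_coils == 1:
        sens[:] = 1.0
    sos = np.sqrt((np.abs(sens) ** 2).sum(axis=0))
    return sens / sos[None]


# -- acquisition timing and paradigm ---------------------------------------

@dataclass(frozen=True)
class Paradigm:
    """Block paradigm: n_blocks x (trs_rest rest + trs_active active)."""

    n_blocks: int
    trs_rest: int
    trs_active: int
    tr_effective: float = 3.948  # s per VASO+BOLD pair

    @property
    def n_volumes(self) -> int:
        return self.n_blocks * (self.trs_rest + self.trs_active)

    def boxcar(self) -> np.ndarray:
        """Activity indicator per volume index."""
        one = np.concatenate([np.zeros(self.trs_rest), np.ones(self.trs_active)])
        return np.tile(one, self.n_blocks)


def build_paradigm(readout: str = "spiral", n_blocks: int = 10,
                   tr_effective: float | None = None) -> Paradigm:
    """Paradigm per readout arm: spiral blocks are 8 rest + 8 active TRs,
    EPI blocks 7 + 7 (matched ~30 s block durations at the two TRs)."""
    if n_blocks < 0:
        raise ValueError("n_blocks must be >= 0")
    if readout == "spiral":
        rest, active, tr = 8, 8, 3.948
    elif readout == "epi":
        rest, active, tr = 7, 7, 4.239
    else:
        raise ValueError(f"unknown readout {readout!r}")
    return Paradigm(n_blocks, rest, active, tr_effective or tr)


@dataclass(frozen=True)
class SequenceTiming:
    """Volume/partition timing of the SS-SI-VASO acquisition (seconds)."""

    n_partitions: int = 24
    tr_partition: float = 0.062
    ti1: float | None = None        # inversion -> blood-null (center partition)
    inversion_lead: float = 0.600   # inversion -> first VASO excitation
    te: float = 0.0024
    te_bold: float | None = None    # TE of the BOLD volume (defaults to te)
    inversion_efficiency: float = 0.95
    flip_angle: float = 26.0
    tr_effective: float = 3.948     # period of one VASO+BOLD pair

    def __post_init__(self):
        if not (0 < self.inversion_efficiency <= 1):
            raise ValueError("inversion_efficiency must be in (0, 1]")

    @property
    def tr_volume(self) -> float:
        return self.n_partitions * self.tr_partition


def timing_from_config(config: dict) -> SequenceTiming:
    """Build SequenceTiming, checking tr_volume = n_partitions * tr_partition."""
    cfg = dict(config)
    n_part = int(cfg.pop("n_partitions"))
    tr_part = cfg.pop("tr_partition", None)
    tr_vol = cfg.pop("tr_volume", None)
    if tr_part is None and tr_vol is None:
        raise ValueError("need tr_partition or tr_volume")
    if tr_part is None:
        tr_part = tr_vol / n_part
    elif tr_vol is not None and abs(tr_vol - n_part * tr_part) > 1e-3:
        raise ValueError(
            f"inconsistent timing: {n_part} x {tr_part} s != tr_volume {tr_vol} s")
    return SequenceTiming(n_partitions=n_part, tr_partition=tr_part, **cfg)


# -- steady-state inversion-recovery signal model ---------------------------

def _steady_state_pre_inversion(t1: np.ndarray | float, period: float,
                                eff: float) -> np.ndarray | float:
    """Longitudinal magnetization (units of M0) just before each inversion,
    for ideal instantaneous inversion with efficiency ``eff`` repeated
    every ``period`` seconds."""
    t1 = np.maximum(np.asarray(t1, float), 1e-6)  # background voxels carry t1=0
    e = np.exp(-period / t1)
    return (1.0 - e) / (1.0 + eff * e)


def blood_null_ti(t1_blood: float, timing: SequenceTiming) -> float:
    """TI at which steady-state blood magnetization crosses zero."""
    m_pre = _steady_state_pre_inversion(t1_blood, timing.tr_effective,
                                        timing.inversion_efficiency)
    return float(t1_blood * np.log(1.0 + timing.inversion_efficiency * m_pre))


def inversion_recovery_factor(t1, ti, timing: SequenceTiming):
    """Mz(TI)/M0 in the inversion steady state."""
    eff = timing.inversion_efficiency
    t1 = np.maximum(np.asarray(t1, float), 1e-6)
    m_pre = _steady_state_pre_inversion(t1, timing.tr_effective, eff)
    return 1.0 - (1.0 + eff * m_pre) * np.exp(-ti / t1)


def vaso_signal_timeseries(
    ph: PhantomState,
    timing: SequenceTiming,
    paradigm: Paradigm,
    bold_amplitude: float = 0.02,
    te_bold_ref: float = 0.0235,
):
    """Ground-truth VASO and BOLD magnitude series.

    Returns ``(vaso, bold, t_vaso, t_bold)`` with series shaped
    (n_volumes, nx, ny, nz). The BOLD factor 1 + a(r) * active(v) is
    shared multiplicatively by both volumes of a pair (same readout, same
    TE), which is the structure the dynamic-division correction exploits;
    its amplitude scales linearly with TE relative to ``te_bold_ref``.
    """
    ti1 = timing.ti1 if timing.ti1 is not None else blood_null_ti(ph.t1_blood, timing)
    if ti1 <= timing.inversion_lead:
        raise ValueError("ti1 must exceed the inversion lead time")
    blood_mz = float(inversion_recovery_factor(ph.t1_blood, ti1, timing))
    if abs(blood_mz) > 0.01:
        warnings.warn(
            f"configured TI1={ti1:.3f}s misses the blood null: residual "
            f"blood Mz = {blood_mz:+.3f} M0", stacklevel=2)

    f_tissue = inversion_recovery_factor(ph.t1, ti1, timing)
    f_tissue[~ph.mask] = 0.0
    boxcar = paradigm.boxcar()
    n_vol = paradigm.n_volumes
    te = timing.te
    te_b = timing.te_bold if timing.te_bold is not None else te
    bold_gain_vaso = bold_amplitude * (te / te_bold_ref) * ph.bold_weight
    bold_gain_bold = bold_amplitude * (te_b / te_bold_ref) * ph.bold_weight

    shape = (n_vol,) + ph.shape
    vaso = np.empty(shape)
    bold = np.empty(shape)
    for v in range(n_vol):
        act = boxcar[v]
        cbv = ph.cbv_rest * (1.0 + ph.cbv_delta * act)
        clean = ph.m0 * (1.0 - cbv) * f_tissue + ph.m0 * cbv * blood_mz
        vaso[v] = clean * (1.0 + bold_gain_vaso * act)
        bold[v] = ph.m0 * (1.0 + bold_gain_bold * act)
    t_pair = paradigm.tr_effective
    t_vaso = np.arange(n_vol) * t_pair
    t_bold = t_vaso + timing.tr_volume
    return vaso, bold, t_vaso, t_bold
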