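"""Gradient-limited k-space trajectory design.

Designs single-shot variable-density spiral-out readouts by time-optimal
reparameterization of a geometric spiral under gradient-amplitude and
slew-rate constraints, stacks them along kz for 3D stack-of-spirals
acquisitions, builds matched Cartesian EPI line trajectories (used for
point-spread-function comparison and the gradient acoustic audit only),
and computes gradient waveform spectra against mechanical-resonance bands.

Units: k-space in cycles/m, gradients in mT/m, slew in T/m/s, time in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Gyromagnetic ratio of 1H, Hz/T (gamma-bar).
GAMMA = 42.5774688e6

#: Gradient raster interval (s) on which waveforms are returned.
GRAD_RASTER = 10e-6


@dataclass(frozen=True)
class SpiralParams:
    """Variable-density spiral design parameters.

    fov_xy, res_xy in mm; g_max in mT/m; sr_max in T/m/s; dwell in µs.
    ``alpha`` is the variable-density exponent (1 = uniform Archimedean);
    ``r_xy`` the in-plane undersampling factor reached at the k-space edge.
    """

    fov_xy: float = 192.0
    res_xy: float = 0.8
    alpha: float = 1.6
    r_xy: float = 3.0
    g_max: float = 35.0
    sr_max: float = 155.0
    dwell: float = 2.0
    n_interleaves: int = 1

    def __post_init__(self) -> None:
        if self.fov_xy <= 0 or self.res_xy <= 0:
            raise ValueError("fov_xy and res_xy must be positive")
        if self.alpha < 1:
            raise ValueError("variable-density exponent alpha must be >= 1")
        if self.r_xy < 1:
            raise ValueError("in-plane undersampling r_xy must be >= 1")
        if self.g_max <= 0 or self.sr_max <= 0 or self.dwell <= 0:
            raise ValueError("g_max, sr_max and dwell must be positive")
        if self.n_interleaves < 1:
            raise ValueError("n_interleaves must be >= 1")

    @property
    def k_max(self) -> float:
        """Edge of k-space, cycles/m."""
        return 1.0 / (2.0 * self.res_xy * 1e-3)

    @property
    def matrix(self) -> int:
        return int(round(self.fov_xy / self.res_xy))

    @property
    def n_turns(self) -> float:
        """Revolutions of the geometric spiral, N / (2 r_xy) per interleaf."""
        return self.matrix / (2.0 * self.r_xy * self.n_interleaves)


@dataclass(frozen=True)
class EpiParams:
    """Cartesian EPI readout parameters (PSF/spectrum comparison arm)."""

    fov_xy: float = 192.0
    res_xy: float = 0.8
    echo_spacing: float = 1.02  # ms
    grappa: int = 3
    partial_fourier: float = 6.0 / 8.0

    def __post_init__(self) -> None:
        if self.echo_spacing <= 0:
            raise ValueError("echo_spacing must be positive")
        if self.grappa < 1:
            raise ValueError("grappa must be >= 1")
        if not (0.5 < self.partial_fourier <= 1.0):
            raise ValueError("partial_fourier must be in (0.5, 1]")

    @property
    def matrix(self) -> int:
        return int(round(self.fov_xy / self.res_xy))

    @property
    def k_max(self) -> float:
        return 1.0 / (2.0 * self.res_xy * 1e-3)


@dataclass
class Trajectory3D:
    """Time-stamped k-space sample locations plus gradient waveforms.

    ``k`` has shape (n_readouts, n_samples, 3) in cycles/m; ``t`` is the
    shared per-sample time since excitation (s). ``g`` holds the in-plane
    gradient waveform (n_grad, 3) in mT/m on the ``grad_raster`` raster.
    """

    k: np.ndarray
    t: np.ndarray
    g: np.ndarray
    grad_raster: float
    kz_order: list[int]
    readout_duration: float
    fov: tuple[float, float, float]  # m
    res: tuple[float, float, float]  # m
    kind: str = "spiral"  # "spiral" | "cartesian"
    meta: dict = field(default_factory=dict)

    @property
    def n_readouts(self) -> int:
        return self.k.shape[0]

    @property
    def n_samples(self) -> int:
        return self.k.shape[1]

    @property
    def is_plane(self) -> bool:
        return self.n_readouts == 1 and np.allclose(self.k[..., 2], 0.0)

    @property
    def k_max_xy(self) -> float:
        return 1.0 / (2.0 * self.res[0])


def _geometric_spiral(params: SpiralParams, n_tau: int = 60000):
    """Geometric curve k(tau) = k_max tau^alpha e^{i 2 pi n tau} and its
    arc length / curvature on a dense tau grid."""
    tau = np.linspace(0.0, 1.0, n_tau)
    kmax = params.k_max
    n = params.n_turns
    phi = 2.0 * np.pi * n * tau
    r = kmax * tau**params.alpha
    kx = r * np.cos(phi)
    ky = r * np.sin(phi)

    # analytic first/second derivatives wrt tau (avoids FD noise at tau=0)
    a = params.alpha
    w = 2.0 * np.pi * n
    with np.errstate(divide="ignore", invalid="ignore"):
        rp = kmax * a * tau ** (a - 1.0)
        rpp = kmax * a * (a - 1.0) * tau ** (a - 2.0)
    rp = np.nan_to_num(rp, posinf=0.0)
    rpp = np.nan_to_num(rpp, posinf=0.0)
    if a == 1.0:
        rp[:] = kmax
        rpp[:] = 0.0
    c, s = np.cos(phi), np.sin(phi)
    dkx = rp * c - r * w * s
    dky = rp * s + r * w * c
    d2kx = rpp * c - 2 * rp * w * s - r * w**2 * c
    d2ky = rpp * s + 2 * rp * w * c - r * w**2 * s

    speed = np.hypot(dkx, dky)  # |dk/dtau|
    cross = dkx * d2ky - dky * d2kx
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = np.abs(cross) / speed**3
    curvature = np.nan_to_num(curvature, nan=0.0, posinf=0.0)
    s_arc = np.concatenate(
        [[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(tau))]
    )
    return tau, kx, ky, s_arc, curvature


def _time_optimal_speed(s_arc, curvature, g_max_T, sr_max):
    """Forward-backward sweep for the maximal feasible speed profile v(s).

    v is |dk/dt| in cycles/m/s; gradient limit v <= gamma*g_max and the
    slew limit splits between tangential and centripetal acceleration:
    sqrt(v_dot^2 + (kappa v^2)^2) <= gamma*sr_max.
    """
    a_max = GAMMA * sr_max  # (cycles/m)/s^2
    v_grad = GAMMA * g_max_T
    with np.errstate(divide="ignore"):
        v_curv = np.sqrt(a_max / np.maximum(curvature, 1e-30))
    v_lim = np.minimum(v_grad, v_curv)
    if not np.any(v_lim > 0):
        raise ValueError("infeasible gradient constraints: zero speed limit")

    ds = np.diff(s_arc)
    n = len(s_arc)
    v = np.zeros(n)
    # forward sweep (acceleration limit)
    for i in range(n - 1):
        a_t2 = a_max**2 - (curvature[i] * v[i] ** 2) ** 2
        a_t = np.sqrt(max(a_t2, 0.0))
        v[i + 1] = min(v_lim[i + 1], np.sqrt(v[i] ** 2 + 2 * a_t * ds[i]))
    # backward sweep (deceleration limit keeps the profile attainable)
    for i in range(n - 1, 0, -1):
        a_t2 = a_max**2 - (curvature[i] * v[i] ** 2) ** 2
        a_t = np.sqrt(max(a_t2, 0.0))
        v[i - 1] = min(v[i - 1], np.sqrt(v[i] ** 2 + 2 * a_t * ds[i - 1]))
    if v[1] <= 0:
        raise ValueError("infeasible constraints: trajectory cannot start")
    return v


def design_vd_spiral(params: SpiralParams, n_tau: int = 60000) -> Trajectory3D:
    """Design a time-optimal single-shot variable-density spiral-out readout.

    The geometric curve is k(tau) = k_max tau^alpha exp(i 2 pi n_turns tau)
    with n_turns = N/(2 r_xy): radial density is Nyquist at the center and
    relaxes outward following ``alpha``. The curve is traversed at the
    fastest speed compatible with ``g_max`` and ``sr_max`` (arc-length
    forward/backward sweep), then sampled on the ADC dwell.
    """
    tau, kx, ky, s_arc, curvature = _geometric_spiral(params, n_tau)
    v = _time_optimal_speed(s_arc, curvature, params.g_max * 1e-3, params.sr_max)

    # time along the curve: t(s) = integral ds / v  (midpoint rule)
    v_mid = 0.5 * (v[1:] + v[:-1])
    dt = np.diff(s_arc) / np.maximum(v_mid, 1e-12)
    t_of_s = np.concatenate([[0.0], np.cumsum(dt)])
    duration = float(t_of_s[-1])

    dwell_s = params.dwell * 1e-6
    n_samp = int(np.floor(duration / dwell_s)) + 1
    t_samp = np.arange(n_samp) * dwell_s
    tau_samp = np.interp(t_samp, t_of_s, tau)
    kmax = params.k_max
    phi = 2.0 * np.pi * params.n_turns * tau_samp
    r = kmax * tau_samp**params.alpha
    k = np.zeros((1, n_samp, 3))
    k[0, :, 0] = r * np.cos(phi)
    k[0, :, 1] = r * np.sin(phi)

    # gradient waveform on the raster: g = (dk/dt)/gamma
    n_grad = int(np.floor(duration / GRAD_RASTER)) + 1
    t_grad = np.arange(n_grad) * GRAD_RASTER
    tau_g = np.interp(t_grad, t_of_s, tau)
    phig = 2.0 * np.pi * params.n_turns * tau_g
    rg = kmax * tau_g**params.alpha
    kxg = rg * np.cos(phig)
    kyg = rg * np.sin(phig)
    # midpoint (forward-difference) gradient samples: cumulative integration
    # of g reproduces k at the raster nodes exactly
    g = np.zeros((n_grad - 1, 3))
    g[:, 0] = np.diff(kxg) / GRAD_RASTER / GAMMA * 1e3  # mT/m
    g[:, 1] = np.diff(kyg) / GRAD_RASTER / GAMMA * 1e3

    return Trajectory3D(
        k=k,
        t=t_samp,
        g=g,
        grad_raster=GRAD_RASTER,
        kz_order=[0],
        readout_duration=duration,
        fov=(params.fov_xy * 1e-3,) * 2 + (params.fov_xy * 1e-3,),
        res=(params.res_xy * 1e-3,) * 2 + (params.res_xy * 1e-3,),
        kind="spiral",
        meta={"params": params},
    )


def stack_spirals(
    plane: Trajectory3D,
    n_kz: int,
    fov_z: float,
    order: str = "linear",
    rotation: float = 0.0,
) -> Trajectory3D:
    """Replicate an in-plane trajectory at n_kz partitions along kz.

    Partition index p gets kz = (p - n_kz//2) / fov_z (fov_z in mm);
    ``order`` selects the acquisition ordering of partition indices and
    ``rotation`` an optional per-partition in-plane rotation increment
    (radians; e.g. the golden angle).
    """
    if n_kz < 1:
        raise ValueError("n_kz must be >= 1")
    if not plane.is_plane:
        raise ValueError("stack_spirals expects a single-plane (kz == 0) input")
    fov_z_m = fov_z * 1e-3
    dkz = 1.0 / fov_z_m
    k = np.repeat(plane.k, n_kz, axis=0).astype(float)
    for p in range(n_kz):
        kz = (p - n_kz // 2) * dkz
        if rotation != 0.0:
            ang = rotation * p
            c, s = np.cos(ang), np.sin(ang)
            kx = plane.k[0, :, 0] * c - plane.k[0, :, 1] * s
            ky = plane.k[0, :, 0] * s + plane.k[0, :, 1] * c
            k[p, :, 0] = kx
            k[p, :, 1] = ky
        k[p, :, 2] = kz
    if order == "linear":
        kz_order = list(range(n_kz))
    elif order == "centric":
        kz_order = sorted(range(n_kz), key=lambda p: (abs(p - n_kz // 2), p))
    else:
        raise ValueError(f"unknown kz ordering {order!r}")
    res_z = fov_z_m / n_kz
    return Trajectory3D(
        k=k,
        t=plane.t.copy(),
        g=plane.g.copy(),
        grad_raster=plane.grad_raster,
        kz_order=kz_order,
        readout_duration=plane.readout_duration,
        fov=plane.fov[:2] + (fov_z_m,),
        res=plane.res[:2] + (res_z,),
        kind=plane.kind,
        meta=dict(plane.meta, n_kz=n_kz, kz_rotation=rotation),
    )


def design_epi(params: EpiParams, t2star_ref: float | None = None) -> Trajectory3D:
    """Build a Cartesian EPI line trajectory (phase encode along y).

    Partial Fourier omits early (most negative) ky lines; GRAPPA keeps
    every ``grappa``-th of the remaining lines (unsampled lines are simply
    absent and zero-filled by the adjoint downstream — no k-space
    interpolation kernel is applied). Every sample on a line shares the
    line's echo time offset j * echo_spacing.
    """
    n = params.matrix
    fov_m = params.fov_xy * 1e-3
    dk = 1.0 / fov_m
    first_line = n - int(round(params.partial_fourier * n))
    lines = np.arange(first_line, n, params.grappa)
    es = params.echo_spacing * 1e-3

    kx_line = (np.arange(n) - n // 2) * dk
    n_samp = len(lines) * n
    k = np.zeros((1, n_samp, 3))
    t = np.zeros(n_samp)
    for j, line in enumerate(lines):
        sl = slice(j * n, (j + 1) * n)
        # serpentine readout direction, as in an actual echo train
        k[0, sl, 0] = kx_line if j % 2 == 0 else kx_line[::-1]
        k[0, sl, 1] = (line - n // 2) * dk
        t[sl] = j * es

    g = _epi_gradient_waveform(params)
    return Trajectory3D(
        k=k,
        t=t,
        g=g,
        grad_raster=GRAD_RASTER,
        kz_order=[0],
        readout_duration=float(len(lines) * es),
        fov=(fov_m, fov_m, fov_m),
        res=(params.res_xy * 1e-3,) * 3,
        kind="cartesian",
        meta={
            "params": params,
            "lines": lines,
            "t2star_ref": t2star_ref,
            "n_lines": len(lines),
        },
    )


def _epi_gradient_waveform(params: EpiParams) -> np.ndarray:
    """Trapezoidal alternating readout-gradient train on the raster
    (serves the acoustic-spectrum audit; amplitude from the line traverse
    2*k_max over ~80% of the echo spacing, 10% ramps each side)."""
    es = params.echo_spacing * 1e-3
    n_per_echo = max(int(round(es / GRAD_RASTER)), 4)
    ramp = max(n_per_echo // 10, 1)
    flat = n_per_echo - 2 * ramp
    area = 2.0 * params.k_max / GAMMA  # T/m * s per line
    g_flat = area / ((flat + ramp) * GRAD_RASTER)
    one = np.concatenate(
        [
            np.linspace(0, g_flat, ramp, endpoint=False),
            np.full(flat, g_flat),
            np.linspace(g_flat, 0, ramp, endpoint=False),
        ]
    )
    n_lines = len(
        np.arange(
            params.matrix - int(round(params.partial_fourier * params.matrix)),
            params.matrix,
            params.grappa,
        )
    )
    wave = np.concatenate([one * (-1) ** j for j in range(n_lines)])
    g = np.zeros((len(wave), 3))
    g[:, 0] = wave * 1e3  # mT/m
    return g


@dataclass
class SpectrumReport:
    """Gradient-waveform spectrum audited against forbidden bands."""

    freqs: np.ndarray
    power: np.ndarray  # (n_axes, n_freq) one-sided spectral density
    band_fractions: list[float]
    peak_freq: float
    bands: list[tuple[float, float]]


def gradient_spectrum(
    traj: Trajectory3D, bands: list[tuple[float, float]] | None = None
) -> SpectrumReport:
    """Magnitude spectrum of the gradient waveforms and the fraction of
    total spectral energy inside each (center, width) forbidden band."""
    g = traj.g
    if g is None or g.size == 0:
        raise ValueError("trajectory carries no gradient waveform")
    bands = bands or []
    dt = traj.grad_raster
    nt = g.shape[0]
    spec = np.fft.rfft(g, axis=0)
    freqs = np.fft.rfftfreq(nt, dt)
    # one-sided power density normalized for Parseval:
    # sum(power * df) == sum(|g|^2 * dt) per axis
    power = np.abs(spec.T) ** 2 * dt**2
    if nt % 2 == 0:
        power[:, 1:-1] *= 2.0
    else:
        power[:, 1:] *= 2.0
    total = power.sum()
    fractions = []
    for center, width in bands:
        in_band = np.abs(freqs - center) <= width / 2.0
        fractions.append(float(power[:, in_band].sum() / total) if total > 0 else 0.0)
    tot_axis = power.sum(axis=0)
    peak = float(freqs[np.argmax(tot_axis)])
    return SpectrumReport(
        freqs=freqs, power=power, band_fractions=fractions, peak_freq=peak, bands=bands
    )


def integrate_gradients(traj: Trajectory3D) -> np.ndarray:
    """Cumulative integral of the gradient waveform, cycles/m on the raster
    (consistency check against ``k``)."""
    return np.cumsum(traj.g * 1e-3, axis=0) * traj.grad_raster * GAMMA
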