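"""Pre-reconstruction raw-data corrections.

Three zeroth-order phase corrections are applied to the spiral raw data,
in this order: removal of the (known) eddy-current compensation phase,
demodulation of the measured k0 phase trace, and repetition-DORK — a
per-volume global frequency offset estimated from the FID navigator phase
against the first volume of the run and removed as a phase ramp over
(TE + t). All three are pure per-sample phase multiplications and
preserve sample magnitudes exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward import KspaceData


def remove_ec_phase(data: KspaceData, ec_phase: np.ndarray) -> KspaceData:
    """Multiply samples by exp(+i ec_phase) (undo the injected -ec_phase).

    Not idempotent: applying the removal twice adds the phase twice.
    """
    ec_phase = np.asarray(ec_phase, float)
    if len(ec_phase) != data.samples.shape[-1]:
        raise ValueError("eddy-current phase trace length mismatch")
    return data.copy_with(data.samples * np.exp(1j * ec_phase)[None, None, :])


def k0_demodulate(data: KspaceData, k0_phase: np.ndarray) -> KspaceData:
    """Demodulate the measured zeroth-order k0 phase from the raw data."""
    k0_phase = np.asarray(k0_phase, float)
    if len(k0_phase) != data.samples.shape[-1]:
        raise ValueError("k0 phase trace length mismatch")
    return data.copy_with(data.samples * np.exp(1j * k0_phase)[None, None, :])


@dataclass
class DorkState:
    """Per-volume repetition-DORK estimates."""

    reference_phase: np.ndarray                 # rad per (coil, nav sample)
    offsets_rad: list[float] = field(default_factory=list)
    offsets_hz: list[float] = field(default_factory=list)

    def as_table(self) -> "np.ndarray":
        return np.column_stack([np.arange(len(self.offsets_rad)),
                                self.offsets_rad, self.offsets_hz])


def dork_correct(run: list[KspaceData], snr_threshold: float = 3.0
                 ) -> tuple[list[KspaceData], DorkState]:
    """Repetition-DORK: remove per-volume global frequency offsets.

    The phase offset of volume v is the angle of the magnitude-weighted
    inner product sum_{c,n} nav_v[c,n] * conj(nav_ref[c,n]) (robust to
    per-coil phase offsets); the equivalent frequency f_v = dphi /
    (2 pi mean(t_nav)) is removed from all samples of the volume as
    exp(+i 2 pi f_v (TE + t)). The first volume is the reference
    (offset 0 by construction).
    """
    if not run:
        raise ValueError("empty run")
    for kd in run:
        if kd.navigators is None:
            raise ValueError("volume without navigators: DORK needs FID samples")
    ref = run[0]
    t_nav_mean = float(np.mean(ref.nav_times))
    state = DorkState(reference_phase=np.angle(ref.navigators))
    noise = max(ref.noise_sigma, 1e-30)
    # the blood-nulled and BOLD-weighted volumes have different image
    # content, hence different intrinsic navigator phase: each contrast is
    # referenced to its own first volume of the scan
    refs: dict = {}
    out: list[KspaceData] = []
    prev = 0.0
    for v, kd in enumerate(run):
        tag = kd.meta.get("contrast", "")
        nav_ref = refs.setdefault(tag, kd.navigators)
        inner = np.sum(kd.navigators * np.conj(nav_ref))
        nav_mag = np.sqrt(np.mean(np.abs(kd.navigators) ** 2))
        if nav_mag / noise < snr_threshold and kd.noise_sigma > 0:
            warnings.warn(f"navigator SNR below threshold in volume {v}; "
                          "offset set to 0", stacklevel=2)
            dphi = 0.0
        else:
            # drift phase enters as exp(-i 2 pi f t), so the accumulated
            # navigator phase is -2 pi f t_nav; negate to report drift in Hz
            dphi = -float(np.angle(inner))
        if v > 0 and abs(dphi - prev) > np.pi / 2:
            warnings.warn(
                f"navigator phase jump > pi/2 between volumes {v-1} and {v}: "
                "possible phase wrap", stacklevel=2)
        prev = dphi
        f_v = dphi / (2 * np.pi * t_nav_mean)
        te = kd.meta.get("te", 0.0)
        t_abs = te + kd.traj.t
        corr = kd.copy_with(kd.samples * np.exp(2j * np.pi * f_v * t_abs)[None, None, :])
        corr.navigators = kd.navigators * np.exp(2j * np.pi * f_v * kd.nav_times)[None, :]
        corr.meta["dork_hz"] = f_v
        state.offsets_rad.append(dphi)
        state.offsets_hz.append(f_v)
        out.append(corr)
    return out, state
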