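"""Readers/writers and run configuration.

Raw k-space data travel in an ISMRMRD-convention HDF5 container written
directly with h5py: one group per acquisition holding the complex
samples, the attached trajectory, navigator samples and metadata
(scan counter, contrast label, volume index, TE), plus a shared
trajectory group (k, g, t, kz order, design parameters). Image volumes
and series are written as NIfTI with an affine encoding the field of
view at the magnet isocenter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np
import yaml

from .forward import KspaceData
from .trajectory import Trajectory3D


# -- raw container ----------------------------------------------------------

def write_trajectory_group(parent, traj: Trajectory3D) -> None:
    tg = parent.create_group("trajectory")
    tg.create_dataset("k", data=traj.k)
    tg.create_dataset("g", data=traj.g)
    tg.create_dataset("t", data=traj.t)
    tg.create_dataset("kz_order", data=np.asarray(traj.kz_order))
    tg.attrs["grad_raster"] = traj.grad_raster
    tg.attrs["readout_duration"] = traj.readout_duration
    tg.attrs["fov"] = traj.fov
    tg.attrs["res"] = traj.res
    tg.attrs["kind"] = traj.kind


def read_trajectory_group(tg) -> Trajectory3D:
    return Trajectory3D(
        k=tg["k"][()], t=tg["t"][()], g=tg["g"][()],
        grad_raster=float(tg.attrs["grad_raster"]),
        kz_order=[int(x) for x in tg["kz_order"][()]],
        readout_duration=float(tg.attrs["readout_duration"]),
        fov=tuple(tg.attrs["fov"]), res=tuple(tg.attrs["res"]),
        kind=str(tg.attrs["kind"]),
    )


def write_trajectory(path, traj: Trajectory3D) -> None:
    """Standalone trajectory container (design-traj CLI output)."""
    with h5py.File(path, "w") as f:
        write_trajectory_group(f, traj)


def read_trajectory(path) -> Trajectory3D:
    with h5py.File(path, "r") as f:
        if "trajectory" not in f:
            raise ValueError("malformed container: missing group 'trajectory'")
        return read_trajectory_group(f["trajectory"])


def write_raw(path, run: list[KspaceData],
              extras: dict[str, np.ndarray] | None = None) -> None:
    """Write a list of k-space volumes to an MRD-style HDF5 container.

    ``extras`` stores known per-sample correction traces (e.g. the
    eddy-current compensation phase and the measured k0 trace) alongside
    the data, mirroring how they arrive from simulation/field camera.
    """
    if not run:
        raise ValueError("empty run")
    traj = run[0].traj
    with h5py.File(path, "w") as f:
        g = f.create_group("dataset")
        write_trajectory_group(g, traj)
        if extras:
            xg = g.create_group("extras")
            for name, arr in extras.items():
                xg.create_dataset(name, data=np.asarray(arr))
        ag = g.create_group("acquisitions")
        for i, kd in enumerate(run):
            a = ag.create_group(f"{i:06d}")
            a.create_dataset("data", data=kd.samples.astype(np.complex128))
            if kd.navigators is not None:
                a.create_dataset("navigators", data=kd.navigators)
                a.create_dataset("nav_times", data=kd.nav_times)
            a.attrs["scan_counter"] = i
            a.attrs["noise_sigma"] = kd.noise_sigma
            a.attrs["meta"] = json.dumps(kd.meta)


def read_raw(path, with_extras: bool = False):
    """Read an MRD-style container back; round-trips samples bit-exactly."""
    with h5py.File(path, "r") as f:
        if "dataset" not in f:
            raise ValueError("malformed container: missing group 'dataset'")
        g = f["dataset"]
        missing = [k for k in ("trajectory", "acquisitions") if k not in g]
        if missing:
            raise ValueError(f"malformed container: missing {missing}")
        traj = read_trajectory_group(g["trajectory"])
        extras = {}
        if "extras" in g:
            extras = {name: g["extras"][name][()] for name in g["extras"]}
        run = []
        for name in sorted(g["acquisitions"]):
            a = g["acquisitions"][name]
            kd = KspaceData(
                samples=a["data"][()], traj=traj,
                navigators=a["navigators"][()] if "navigators" in a else None,
                nav_times=a["nav_times"][()] if "nav_times" in a else None,
                meta=json.loads(a.attrs["meta"]),
                noise_sigma=float(a.attrs["noise_sigma"]),
            )
            kd.meta["scan_counter"] = int(a.attrs["scan_counter"])
            run.append(kd)
    if with_extras:
        return run, extras
    return run


# -- NIfTI ------------------------------------------------------------------

def nifti_affine(fov: tuple[float, float, float],
                 shape: tuple[int, int, int]) -> np.ndarray:
    """RAS affine with isocenter at the matrix center; units mm."""
    vox = [f * 1e3 / n for f, n in zip(fov, shape)]
    aff = np.diag(vox + [1.0])
    for i in range(3):
        aff[i, 3] = -vox[i] * (shape[i] // 2)
    return aff


def write_nifti(path, vol: np.ndarray, fov: tuple[float, float, float]) -> None:
    """Write a 3D volume or 4D series (time last) as float32 NIfTI."""
    data = np.asarray(vol)
    if data.ndim == 4:
        # internal convention is (t, x, y, z); NIfTI wants time last
        data = np.moveaxis(data, 0, -1)
    shape3 = data.shape[:3]
    img = nib.Nifti1Image(np.abs(data).astype(np.float32),
                          nifti_affine(fov, shape3))
    img.header.set_qform(nifti_affine(fov, shape3), code=1)
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    return data, img.affine


# -- run configuration ------------------------------------------------------

@dataclass
class PhantomSection:
    matrix: tuple[int, int, int] = (32, 32, 8)
    n_coils: int = 6
    n_layers: int = 5
    b0_amplitude: float = 30.0
    n_foci: int = 2
    focus_amplitude: float = 60.0
    cbv_rest_gm: float = 0.05
    cbv_delta: float = 0.6
    bold_amplitude: float = 0.02


@dataclass
class TrajectorySection:
    fov_xy: float = 192.0
    res_xy: float = 6.0
    alpha: float = 1.6
    r_xy: float = 2.0
    g_max: float = 35.0
    sr_max: float = 155.0
    dwell: float = 4.0
    n_kz: int = 8
    fov_z: float = 24.0
    kz_order: str = "linear"


@dataclass
class TimingSection:
    n_partitions: int = 8
    tr_partition: float = 0.062
    te: float = 0.0024
    inversion_efficiency: float = 0.95
    tr_effective: float = 3.948


@dataclass
class ParadigmSection:
    readout: str = "spiral"
    n_blocks: int = 10


@dataclass
class PerturbationsSection:
    drift_hz_per_min: float = 1.0
    ec_amp_rad: float = 0.2
    ec_tau_s: float = 0.01
    k0_amp_rad: float = 0.1
    noise_rel: float = 0.02


@dataclass
class ReconSection:
    solver: str = "cg_sense"
    beta: float | None = 0.0    # None -> data-scaled heuristic
    max_iter: int = 10
    n_segments: int = 4         # short desk-scale readout; 24 for 52 ms
    dcf: str = "pipe_menon"
    calib_echoes: int = 3


@dataclass
class AnalysisSection:
    z_threshold: float = 2.4
    min_cluster: int = 5
    highpass_blocks: float = 1.0   # filter FWHM in units of one block cycle
    drop_first_slices: int = 0


@dataclass
class RunConfig:
    """Structured configuration of an end-to-end simulated experiment."""

    seed: int = 0
    phantom: PhantomSection = field(default_factory=PhantomSection)
    trajectory: TrajectorySection = field(default_factory=TrajectorySection)
    timing: TimingSection = field(default_factory=TimingSection)
    paradigm: ParadigmSection = field(default_factory=ParadigmSection)
    perturbations: PerturbationsSection = field(default_factory=PerturbationsSection)
    recon: ReconSection = field(default_factory=ReconSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)

    SECTIONS = {
        "phantom": PhantomSection, "trajectory": TrajectorySection,
        "timing": TimingSection, "paradigm": ParadigmSection,
        "perturbations": PerturbationsSection, "recon": ReconSection,
        "analysis": AnalysisSection,
    }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        kwargs = {}
        if "seed" in doc:
            kwargs["seed"] = int(doc.pop("seed"))
        for name, typ in cls.SECTIONS.items():
            sec = doc.pop(name, {}) or {}
            valid = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sec) - valid
            if unknown:
                raise ValueError(
                    f"unknown config key(s) in [{name}]: {sorted(unknown)}")
            if "matrix" in sec:
                sec["matrix"] = tuple(sec["matrix"])
            kwargs[name] = typ(**sec)
        if doc:
            raise ValueError(f"unknown config section(s): {sorted(doc)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def set_override(self, dotted: str, value: str) -> None:
        """Apply a 'section.key=value' style override (CLI)."""
        section, key = dotted.split(".", 1)
        if section == "seed":
            raise ValueError("use the top-level seed key")
        target = getattr(self, section)
        if not hasattr(target, key):
            raise ValueError(f"unknown config key {dotted!r}")
        current = getattr(target, key)
        if isinstance(current, bool):
            value = value.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            value = int(value)
        elif isinstance(current, float) or current is None:
            value = float(value)
        elif isinstance(current, tuple):
            value = tuple(int(v) for v in value.split(","))
        setattr(target, key, value)

    def content_hash(self) -> str:
        doc = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: SeedSequence([seed, stage index])."""
    stages = ["phantom", "acquire", "calibration", "recon", "analysis"]
    idx = stages.index(stage)
    return int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0]
               % (2**31 - 1))
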