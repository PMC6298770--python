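"""File formats: NIfTI volumes, BIDS-style event tables, motion text,
respiration and hypnogram TSVs, EEG with JSON sidecar, YAML config."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .glm import RespirationTrace

__all__ = [
    "save_volume",
    "load_volume",
    "write_events",
    "read_events",
    "write_motion",
    "read_motion",
    "write_respiration",
    "read_respiration",
    "write_hypnogram",
    "read_hypnogram",
    "write_eeg",
    "read_eeg",
    "PipelineConfig",
    "load_config",
    "save_config",
]


def save_volume(path, data: np.ndarray, voxel_size_mm: float = 2.0) -> None:
    """Write a 3D or 4D array as NIfTI-1 with an isotropic diagonal affine.

    4D inputs with a single volume keep their 4th axis.
    """
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI-1 volume; returns (data, affine)."""
    try:
        img = nib.load(str(path))
    except (nib.filebasedimages.ImageFileError, FileNotFoundError) as err:
        raise ValueError(f"not a readable NIfTI file: {path}") from err
    return np.asarray(img.dataobj), img.affine


def write_events(path, events: pd.DataFrame) -> None:
    events[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_motion(path, motion6: np.ndarray) -> None:
    np.savetxt(path, np.asarray(motion6, dtype=float), fmt="%.8f")


def read_motion(path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion file must have 6 columns")
    return motion


def write_respiration(path, trace: RespirationTrace) -> None:
    t = np.arange(trace.samples.size) / trace.fs
    pd.DataFrame({"time_s": t, "amplitude": trace.samples}).to_csv(path, sep="\t", index=False)


def read_respiration(path) -> RespirationTrace:
    frame = pd.read_csv(path, sep="\t")
    t = frame["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return RespirationTrace(frame["amplitude"].to_numpy(), float(round(fs, 6)))


def write_hypnogram(path, hypnogram: pd.DataFrame) -> None:
    hypnogram[["epoch_start_s", "stage"]].to_csv(path, sep="\t", index=False)


def read_hypnogram(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"stage": str})
    return frame


def write_eeg(path, samples: np.ndarray, fs: float, channel: str = "Fpz") -> None:
    """Single-channel EEG as TSV plus a JSON sidecar with fs and channel."""
    path = Path(path)
    pd.DataFrame({channel: np.asarray(samples, dtype=float)}).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"fs": fs, "channel": channel}))


def read_eeg(path) -> tuple[np.ndarray, float, str]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    frame = pd.read_csv(path, sep="\t")
    return frame[meta["channel"]].to_numpy(), float(meta["fs"]), meta["channel"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, serialised to every output sidecar."""

    seed: int = 0
    n_subjects: int = 18
    dims: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 2.0
    tr_s: float = 2.5
    n_wake_runs: int = 12
    sphere_radius_vox: float = 3.7
    min_sphere_voxels: int = 10
    subject_smoothing_fwhm_mm: float = 2.0
    group_smoothing_fwhm_mm: float = 6.0
    sensitivity_alpha: float = 0.001
    n_permutations: int = 2000
    n_blocks_per_odor: int = 15
    rho_range: tuple[float, float] = (0.0, 0.8)
    behavior_coupling: tuple[float, float] = (0.02, 0.30)
    wake_noise_sd: float = 1.0
    sleep_pattern_sd: float = 1.0
    sleep_noise_sd: float = 1.0
    behavior_noise_sd: float = 0.04
    fd_spike_threshold_factor: float = 0.9  # times the voxel size, in mm
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "n_subjects",
            "voxel_size_mm",
            "tr_s",
            "n_wake_runs",
            "sphere_radius_vox",
            "min_sphere_voxels",
            "sensitivity_alpha",
            "n_permutations",
            "n_blocks_per_odor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.dims = tuple(int(d) for d in self.dims)
        self.rho_range = tuple(float(x) for x in self.rho_range)
        self.behavior_coupling = tuple(float(x) for x in self.behavior_coupling)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
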