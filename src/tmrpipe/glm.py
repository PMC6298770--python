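"""First-level GLM machinery for wake and sleep fMRI sessions.

Builds blocked and finite-impulse-response (FIR) design matrices, the
extended nuisance set used for the long sleep scan (24 motion regressors,
volume-quality indices, respiration), and estimates voxelwise betas by
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

__all__ = [
    "DesignMatrix",
    "NuisanceSet",
    "RespirationTrace",
    "canonical_hrf",
    "build_block_design",
    "build_fir_design",
    "build_nuisance_matrix",
    "align_onsets_to_inhalation",
    "trim_sleep_volumes",
    "FirstLevelGLM",
    "fit_glm",
    "smooth_volume",
]

_OVERSAMPLE = 16  # temporal oversampling used when convolving boxcars


@dataclass
class RespirationTrace:
    """Single-channel breathing trace in arbitrary units."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class DesignMatrix:
    """Volumes x regressors matrix with named columns.

    ``task_columns`` lists the regressors of interest; everything else
    (the constant, any appended nuisance) is absorbed at fit time.
    """

    values: np.ndarray
    column_names: list[str]
    tr: float
    frame_times: np.ndarray
    task_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("values shape does not match column names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite entries")
        if self.column_names.count("constant") != 1:
            raise ValueError("design matrix must contain exactly one constant column")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names, index=self.frame_times)


@dataclass
class NuisanceSet:
    """Nuisance regressors for one scan session.

    motion24 expands the six realignment parameters into values, squares,
    backward differences and squared differences.  quality4 carries the
    even-odd slice intensity difference, the across-slice variance, and
    their differences.  Spike columns are one-hot indicators for volumes
    whose framewise displacement exceeds the configured threshold.
    """

    motion24: np.ndarray
    quality4: np.ndarray
    respiration: np.ndarray
    spike_columns: np.ndarray

    def __post_init__(self) -> None:
        if self.motion24.shape[1] != 24:
            raise ValueError("motion24 must have exactly 24 columns")
        if self.quality4.shape[1] != 4:
            raise ValueError("quality4 must have exactly 4 columns")
        if self.spike_columns.size:
            col_sums = self.spike_columns.sum(axis=0)
            if not (np.all(np.isin(self.spike_columns, (0.0, 1.0))) and np.all(col_sums == 1)):
                raise ValueError("spike columns must be one-hot")

    @property
    def matrix(self) -> np.ndarray:
        parts = [self.motion24, self.quality4, self.respiration.reshape(-1, 1)]
        if self.spike_columns.size:
            parts.append(self.spike_columns)
        return np.hstack(parts)

    @property
    def column_names(self) -> list[str]:
        names = [f"motion_{i}" for i in range(24)]
        names += ["slice_evenodd", "slice_var", "slice_evenodd_diff", "slice_var_diff"]
        names += ["respiration"]
        names += [f"spike_{i}" for i in range(self.spike_columns.shape[1] if self.spike_columns.size else 0)]
        return names


def canonical_hrf(tr: float, oversampling: int = _OVERSAMPLE, length: float = 32.0) -> np.ndarray:
    """Double-gamma haemodynamic response sampled at ``tr / oversampling``.

    Response peak at 6 s, undershoot at 16 s with ratio 1/6, peak-normalised
    to 1.  Returned at the oversampled grid used internally for convolution;
    pass ``oversampling=1`` for a TR-resolution kernel.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    dt = tr / oversampling
    t = np.arange(0, length, dt)
    h = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    return h / h.max()


def _convolved_boxcar(onsets: np.ndarray, durations: np.ndarray, n_volumes: int, tr: float) -> np.ndarray:
    """HRF-convolved boxcar sampled at frame times, unit peak."""
    dt = tr / _OVERSAMPLE
    n_hires = n_volumes * _OVERSAMPLE
    box = np.zeros(n_hires)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        box[i0 : min(i1, n_hires)] = 1.0
    kernel = canonical_hrf(tr)
    conv = np.convolve(box, kernel)[:n_hires]
    col = conv[:: _OVERSAMPLE]
    peak = np.abs(col).max()
    return col / peak if peak > 0 else col


def build_block_design(events: pd.DataFrame, n_volumes: int, tr: float) -> DesignMatrix:
    """One HRF-convolved boxcar column per condition, plus a constant.

    ``events`` needs columns onset, duration, trial_type (BIDS naming).
    Columns are ordered by sorted condition label; each task column is
    normalised to unit peak after convolution.
    """
    frame_times = np.arange(n_volumes) * tr
    events = events.copy()
    if len(events):
        if (events["onset"] < 0).any() or (events["duration"] <= 0).any():
            raise ValueError("onsets must be >= 0 and durations > 0")
        if (events["onset"] + events["duration"] > n_volumes * tr).any():
            raise ValueError("event extends past the end of the scan")
    conditions = sorted(events["trial_type"].unique()) if len(events) else []
    cols, names = [], []
    for cond in conditions:
        sel = events[events["trial_type"] == cond]
        cols.append(_convolved_boxcar(sel["onset"].to_numpy(), sel["duration"].to_numpy(), n_volumes, tr))
        names.append(str(cond))
    cols.append(np.ones(n_volumes))
    names.append("constant")
    return DesignMatrix(np.column_stack(cols), names, tr, frame_times, task_columns=list(map(str, conditions)))


def build_fir_design(
    odor_onsets: dict[str, np.ndarray],
    n_volumes: int,
    tr: float = 2.5,
    n_pre: int = 3,
    n_post: int = 6,
) -> DesignMatrix:
    """FIR stick design: one regressor per odor per peri-onset volume.

    Offsets run from ``-n_pre`` to ``+n_post`` volumes around each onset
    (10 sticks per odor at the defaults, spanning a 25 s window at
    TR = 2.5 s).  Sticks that would fall before volume 0 or past the end
    of the scan are dropped (clamped).
    """
    frame_times = np.arange(n_volumes) * tr
    offsets = np.arange(-n_pre, n_post + 1)
    cols, names = [], []
    for odor in sorted(odor_onsets):
        onset_vols = np.round(np.asarray(odor_onsets[odor], dtype=float) / tr).astype(int)
        if np.any(onset_vols >= n_volumes) or np.any(onset_vols < 0):
            raise ValueError("onset outside the scan")
        for off in offsets:
            col = np.zeros(n_volumes)
            rows = onset_vols + off
            rows = rows[(rows >= 0) & (rows < n_volumes)]
            col[rows] = 1.0
            cols.append(col)
            names.append(f"{odor}_t{off:+d}")
    task = list(names)
    cols.append(np.ones(n_volumes))
    names.append("constant")
    return DesignMatrix(np.column_stack(cols), names, tr, frame_times, task_columns=task)


def _backward_diff(x: np.ndarray) -> np.ndarray:
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def framewise_displacement(motion6: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style FD: summed absolute backward differences, rotations
    (columns 3-5, radians) projected onto a sphere of 50 mm radius."""
    d = _backward_diff(motion6)
    d[:, 3:] *= rotation_radius_mm
    return np.abs(d).sum(axis=1)


def build_nuisance_matrix(
    motion6: np.ndarray,
    volumes_4d: np.ndarray | None,
    respiration: RespirationTrace | None,
    tr: float,
    fd_spike_threshold: float | None = None,
) -> NuisanceSet:
    """Assemble the extended sleep-scan nuisance set.

    Parameters
    ----------
    motion6:
        Realignment parameters, one row per volume, 6 columns
        (3 translations mm, 3 rotations rad).
    volumes_4d:
        Spatial data (x, y, z, t) from which the slice-quality indices are
        computed (slices taken along the third axis).  ``None`` yields zero
        quality columns.
    respiration:
        Breathing trace; averaged within each TR window.  ``None`` yields a
        zero column.
    fd_spike_threshold:
        Framewise-displacement cutoff (mm) above which a volume receives a
        one-hot spike regressor.  ``None`` disables spike detection.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion parameters must have exactly 6 columns")
    n_vol = motion6.shape[0]

    dm = _backward_diff(motion6)
    motion24 = np.hstack([motion6, motion6**2, dm, dm**2])

    if volumes_4d is not None:
        if volumes_4d.shape[3] != n_vol:
            raise ValueError("volume count does not match motion parameters")
        slice_means = volumes_4d.mean(axis=(0, 1))  # (n_slices, n_vol)
        even_odd = slice_means[::2].mean(axis=0) - slice_means[1::2].mean(axis=0)
        slice_var = slice_means.var(axis=0)
        quality4 = np.column_stack(
            [even_odd, slice_var, _backward_diff(even_odd), _backward_diff(slice_var)]
        )
    else:
        quality4 = np.zeros((n_vol, 4))

    if respiration is not None:
        samples_per_tr = respiration.fs * tr
        resp = np.array(
            [
                respiration.samples[int(round(i * samples_per_tr)) : int(round((i + 1) * samples_per_tr))].mean()
                if int(round(i * samples_per_tr)) < respiration.samples.size
                else 0.0
                for i in range(n_vol)
            ]
        )
    else:
        resp = np.zeros(n_vol)

    if fd_spike_threshold is not None:
        fd = framewise_displacement(motion6)
        spikes = np.flatnonzero(fd > fd_spike_threshold)
        spike_cols = np.zeros((n_vol, spikes.size))
        spike_cols[spikes, np.arange(spikes.size)] = 1.0
    else:
        spike_cols = np.zeros((n_vol, 0))

    return NuisanceSet(motion24, quality4, resp, spike_cols)


def align_onsets_to_inhalation(
    trigger_times: np.ndarray,
    respiration: RespirationTrace,
    max_shift: float = 16.0,
    smooth_s: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift each odor trigger forward to the next inhalation onset.

    Inhalation onset is the first sample at or after the trigger where the
    smoothed derivative of the breathing trace crosses from <= 0 to > 0
    (rising slope).  Onsets are never moved backward; if no inhalation is
    found within ``max_shift`` seconds the trigger is kept and flagged.

    Returns (adjusted_times, flags) where flags marks unadjusted triggers.
    """
    trigger_times = np.asarray(trigger_times, dtype=float)
    if trigger_times.size and trigger_times.max() > respiration.duration:
        raise ValueError("respiration trace does not cover all triggers")
    smoothed = ndimage.gaussian_filter1d(respiration.samples, sigma=smooth_s * respiration.fs)
    deriv = np.gradient(smoothed)
    rising = (deriv[1:] > 0) & (deriv[:-1] <= 0)

    adjusted = trigger_times.copy()
    flags = np.zeros(trigger_times.size, dtype=bool)
    for i, t in enumerate(trigger_times):
        start = int(np.ceil(t * respiration.fs))
        stop = min(int((t + max_shift) * respiration.fs), rising.size)
        if start < rising.size and deriv[start] > 0 and (start == 0 or deriv[start - 1] <= 0):
            continue  # trigger already sits on an inhalation onset
        hits = np.flatnonzero(rising[start:stop])
        if hits.size:
            adjusted[i] = (start + hits[0] + 1) / respiration.fs
        else:
            flags[i] = True
    return adjusted, flags


def trim_sleep_volumes(n_volumes: int, first_onset_vol: int, last_offset_vol: int) -> tuple[int, int]:
    """Retained volume range for the sleep scan.

    Keeps everything between the first odor onset and the last odor offset
    plus six volumes of padding on either side, clamped to the scan.
    Returns an inclusive (start, stop) index pair.
    """
    if not 0 <= first_onset_vol <= last_offset_vol < max(n_volumes, 1):
        if not 0 <= first_onset_vol <= last_offset_vol:
            raise ValueError("invalid onset/offset volume order")
    start = max(first_onset_vol - 6, 0)
    stop = min(last_offset_vol + 6, n_volumes - 1)
    return start, stop


class RankDeficientDesignError(np.linalg.LinAlgError):
    """Raised when the combined design + nuisance matrix is rank deficient."""


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(names)) if i >= rank or diag[i] <= tol]
        raise RankDeficientDesignError(f"design matrix is rank deficient; collinear columns: {sorted(set(bad))}")


class FirstLevelGLM(BaseEstimator):
    """Ordinary least squares fit of a voxelwise GLM.

    No prewhitening is applied: inference in this pipeline happens at the
    group level, where subject-level serial correlation only costs
    efficiency, not validity.

    Parameters
    ----------
    data format:
        ``fit(Y, design, nuisance)`` with Y of shape (n_volumes, n_voxels).

    Attributes
    ----------
    betas_ : ndarray (n_task_columns, n_voxels)
        Coefficients for the design's task columns only.
    task_columns_ : list of str
    residual_variance_ : ndarray (n_voxels,)
        Unbiased residual variance estimate.
    """

    def fit(self, Y: np.ndarray, design: DesignMatrix, nuisance: NuisanceSet | np.ndarray | None = None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2:
            raise ValueError("Y must be (n_volumes, n_voxels)")
        if Y.shape[0] != design.n_volumes:
            raise ValueError("design rows must match the number of retained volumes")
        X = design.values
        names = list(design.column_names)
        if nuisance is not None:
            N = nuisance.matrix if isinstance(nuisance, NuisanceSet) else np.asarray(nuisance, dtype=float)
            nuis_names = (
                nuisance.column_names
                if isinstance(nuisance, NuisanceSet)
                else [f"nuisance_{i}" for i in range(N.shape[1])]
            )
            # all-zero nuisance columns (e.g. no spikes detected, constant
            # motion derivatives) carry no information; drop them silently
            keep = np.flatnonzero(np.any(N != 0, axis=0))
            X = np.hstack([X, N[:, keep]])
            names += [nuis_names[i] for i in keep]
        _check_full_rank(X, names)
        coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        dof = max(Y.shape[0] - X.shape[1], 1)
        task_idx = [names.index(c) for c in design.task_columns]
        self.design_columns_ = names
        self.task_columns_ = list(design.task_columns)
        self.betas_ = coef[task_idx]
        self.all_betas_ = coef
        self.residual_variance_ = (resid**2).sum(axis=0) / dof
        self.residuals_ = resid
        return self


def fit_glm(
    Y: np.ndarray,
    design: DesignMatrix,
    nuisance: NuisanceSet | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper around :class:`FirstLevelGLM`.

    Returns (task betas, residual variance).
    """
    model = FirstLevelGLM().fit(Y, design, nuisance)
    return model.betas_, model.residual_variance_


def smooth_volume(volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing; ``fwhm_mm=0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_mm / voxel_size_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_vox)
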