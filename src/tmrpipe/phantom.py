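"""Synthetic phantom brains with known ground truth.

Generates everything the analysis pipeline consumes: a labeled voxel
grid, wake-session category beta patterns, a sleep session in which odor
cues evoke a mixture of cued-template signal (strength rho) and noise,
behavioral recall whose cued benefit is linear in rho, and an EEG trace
with odor-on/off blocks.  Every quantity a downstream stage estimates is
therefore known exactly, which makes the whole pipeline testable by
parameter recovery.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import RespirationTrace, _convolved_boxcar

__all__ = [
    "PhantomSpace",
    "GroundTruth",
    "OdorSchedule",
    "SleepSession",
    "SleepDesign",
    "make_phantom_space",
    "make_category_templates",
    "counterbalanced_pairs",
    "make_ground_truth",
    "simulate_wake_runs",
    "make_odor_schedule",
    "simulate_sleep_session",
    "simulate_sleep_patterns",
    "simulate_behavior",
    "simulate_recall_tables",
    "simulate_eeg_and_hypnogram",
    "InsufficientCueingWarning",
]

N_CATEGORIES = 4
SIGNAL_REGIONS = ("vmpfc_like", "fusiform_like", "hippocampus_like")

# -- default study conditions (fixed once; see docs/methods.md) -------------
DEFAULT_DIMS = (20, 20, 20)
DEFAULT_VOXEL_SIZE = 2.0  # mm
DEFAULT_N_RUNS = 12
DEFAULT_WAKE_NOISE_SD = 1.0
DEFAULT_TEMPLATE_AMPLITUDE = 1.0
DEFAULT_SLEEP_PATTERN_SD = 1.0
DEFAULT_SLEEP_NOISE_SD = 1.0
DEFAULT_BEHAVIOR_NOISE_SD = 0.04
DEFAULT_COUPLING = (0.02, 0.30)  # benefit fraction = a + b * mean(rho) + noise
DEFAULT_RHO_RANGE = (0.0, 0.8)
DEFAULT_P_PRETEST = 0.73
DEFAULT_BASE_RETENTION = 0.775
MIN_BLOCKS_PER_ODOR = 14
EEG_CUEING_START_S = 840.0  # first odor block in the EEG/hypnogram frame


class InsufficientCueingWarning(UserWarning):
    """Fewer than the minimum number of cue presentations for an odor."""


@dataclass
class PhantomSpace:
    """Labeled voxel grid shared by all synthetic subjects.

    region_labels maps a name to a 3D boolean array; regions are pairwise
    disjoint and lie inside the ellipsoidal brain mask.
    """

    dims: tuple[int, int, int]
    voxel_size: float
    brain_mask: np.ndarray
    region_labels: dict[str, np.ndarray]

    @property
    def n_voxels(self) -> int:
        return int(self.brain_mask.sum())

    def region_indices(self, name: str) -> np.ndarray:
        """Indices of a region's voxels into the in-mask voxel vector."""
        vec_index = -np.ones(self.brain_mask.shape, dtype=int)
        vec_index[self.brain_mask] = np.arange(self.n_voxels)
        idx = vec_index[self.region_labels[name]]
        return idx[idx >= 0]

    def to_volume(self, vector: np.ndarray) -> np.ndarray:
        """Embed an in-mask voxel vector into the 3D (or 4D) grid."""
        vector = np.asarray(vector)
        out = np.zeros(vector.shape[:-1] + self.brain_mask.shape, dtype=vector.dtype)
        out[..., self.brain_mask] = vector
        return out

    def to_4d(self, timeseries: np.ndarray) -> np.ndarray:
        """(n_volumes, n_voxels) -> (x, y, z, n_volumes)."""
        vol = self.to_volume(timeseries)  # (n_volumes, x, y, z)
        return np.moveaxis(vol, 0, -1)


def make_phantom_space(
    dims: tuple[int, int, int] = DEFAULT_DIMS,
    seed: int = 0,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
) -> PhantomSpace:
    """Ellipsoidal brain mask with four disjoint labeled regions.

    Region centers sit at fixed fractional positions of the grid with a
    +-1 voxel seeded jitter; voxels already claimed by an earlier region
    are never reassigned, so regions are disjoint by construction.
    """
    dims = tuple(int(d) for d in dims)
    if any(d < 12 for d in dims):
        raise ValueError("each dimension must be >= 12 to host a searchlight sphere")
    rng = np.random.default_rng(seed)
    grid = np.indices(dims).astype(float)
    center = (np.array(dims) - 1) / 2.0
    semi = np.array(dims) / 2.0 - 1.0
    dist2 = sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    brain_mask = dist2 <= 1.0

    radius = max(2, min(dims) // 7)
    fractions = {
        "vmpfc_like": (0.50, 0.75, 0.35),
        "fusiform_like": (0.35, 0.25, 0.35),
        "hippocampus_like": (0.65, 0.45, 0.40),
        "control": (0.50, 0.50, 0.70),
    }
    claimed = np.zeros(dims, dtype=bool)
    labels: dict[str, np.ndarray] = {}
    for name, frac in fractions.items():
        c = np.array([f * d for f, d in zip(frac, dims)]) + rng.integers(-1, 2, size=3)
        d2 = sum((grid[i] - c[i]) ** 2 for i in range(3))
        region = (d2 <= radius**2) & brain_mask & ~claimed
        if not region.any():
            raise ValueError(f"region {name} is empty; dims too small")
        labels[name] = region
        claimed |= region
    return PhantomSpace(dims, float(voxel_size), brain_mask, labels)


def make_category_templates(
    space: PhantomSpace,
    amplitude: float = DEFAULT_TEMPLATE_AMPLITUDE,
    seed: int = 0,
) -> np.ndarray:
    """Generating category patterns: iid Gaussian values of the given
    amplitude inside the signal regions, zero in control and unlabeled
    voxels.  Shape (4, n_voxels)."""
    rng = np.random.default_rng(seed)
    templates = np.zeros((N_CATEGORIES, space.n_voxels))
    for name in SIGNAL_REGIONS:
        idx = space.region_indices(name)
        templates[:, idx] = rng.normal(0.0, amplitude, size=(N_CATEGORIES, idx.size))
    return templates


def counterbalanced_pairs(n_subjects: int) -> list[tuple[int, int]]:
    """Assign each subject 2 of the 4 categories to cue, cycling through the
    six possible pairs so each pair is used floor(n/6) or ceil(n/6) times."""
    pairs = list(itertools.combinations(range(N_CATEGORIES), 2))
    return [pairs[i % len(pairs)] for i in range(n_subjects)]


@dataclass
class GroundTruth:
    """Generating parameters for one synthetic group."""

    n_subjects: int = 18
    cued_categories: list[tuple[int, int]] = field(default_factory=list)
    rho: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    behavior_coupling: tuple[float, float] = DEFAULT_COUPLING
    wake_noise_sd: float = DEFAULT_WAKE_NOISE_SD
    sleep_pattern_sd: float = DEFAULT_SLEEP_PATTERN_SD
    sleep_noise_sd: float = DEFAULT_SLEEP_NOISE_SD
    behavior_noise_sd: float = DEFAULT_BEHAVIOR_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cued_categories) != self.n_subjects:
            raise ValueError("one cued pair per subject required")
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (self.n_subjects, 2):
            raise ValueError("rho must be (n_subjects, 2)")
        if not np.all(np.isfinite(self.rho)) or (self.rho < 0).any():
            raise ValueError("rho must be finite and >= 0")

    @property
    def mean_rho(self) -> np.ndarray:
        return self.rho.mean(axis=1)


def make_ground_truth(
    n_subjects: int = 18,
    rho_range: tuple[float, float] = DEFAULT_RHO_RANGE,
    behavior_coupling: tuple[float, float] = DEFAULT_COUPLING,
    seed: int = 0,
    **noise_overrides,
) -> GroundTruth:
    """Draw per-subject reactivation strengths and counterbalance cueing."""
    rng = np.random.default_rng(seed)
    rho = rng.uniform(rho_range[0], rho_range[1], size=(n_subjects, 2))
    return GroundTruth(
        n_subjects=n_subjects,
        cued_categories=counterbalanced_pairs(n_subjects),
        rho=rho,
        behavior_coupling=behavior_coupling,
        seed=seed,
        **noise_overrides,
    )


def simulate_wake_runs(
    space: PhantomSpace,
    templates: np.ndarray,
    n_runs: int = DEFAULT_N_RUNS,
    noise_sd: float = DEFAULT_WAKE_NOISE_SD,
    seed: int = 0,
) -> np.ndarray:
    """Run-wise wake beta patterns: template + iid Gaussian noise.

    Returns (4 categories, n_runs, n_voxels).  Templates are zero in the
    control region, so it carries pure noise by construction.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.shape != (N_CATEGORIES, space.n_voxels):
        raise ValueError("templates do not match the phantom space")
    if n_runs < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out analysis")
    rng = np.random.default_rng(seed)
    runs = np.broadcast_to(templates[:, None, :], (N_CATEGORIES, n_runs, space.n_voxels)).copy()
    if noise_sd > 0:
        runs += rng.normal(0.0, noise_sd, size=runs.shape)
    return runs


@dataclass
class OdorSchedule:
    """Non-overlapping 16 s odor-on blocks with odor labels."""

    onsets: np.ndarray
    odors: list[str]
    block_duration: float = 16.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        order = np.argsort(self.onsets)
        self.onsets = self.onsets[order]
        self.odors = [self.odors[i] for i in order]
        if np.any(np.diff(self.onsets) < 2 * self.block_duration - 1e-9):
            raise ValueError("blocks must alternate on/off with >= one block-length gap")

    @property
    def span(self) -> float:
        return float(self.onsets[-1] + self.block_duration) if self.onsets.size else 0.0

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for o in self.odors:
            out[o] = out.get(o, 0) + 1
        return out

    def to_events(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset": self.onsets, "duration": self.block_duration, "trial_type": self.odors}
        )


def make_odor_schedule(
    n_blocks_per_odor: int = 15,
    start_s: float = 30.0,
    odors: tuple[str, str] = ("odor_1", "odor_2"),
    block_duration: float = 16.0,
) -> OdorSchedule:
    """Alternating 16 s on / 16 s off blocks, the two odors interleaved."""
    onsets, labels = [], []
    t = start_s
    for _ in range(n_blocks_per_odor):
        for odor in odors:
            onsets.append(t)
            labels.append(odor)
            t += 2 * block_duration  # on block + off block
    return OdorSchedule(np.array(onsets), labels, block_duration)


@dataclass
class SleepDesign:
    """Acquisition parameters for the synthetic sleep scan."""

    tr: float = 2.5
    n_blocks_per_odor: int = 15
    block_duration: float = 16.0
    start_s: float = 30.0
    tail_s: float = 30.0
    drift_amplitude: float = 0.5


@dataclass
class SleepSession:
    """One subject's synthetic sleep scan and its auxiliary recordings."""

    bold: np.ndarray  # (n_volumes, n_voxels)
    events: pd.DataFrame
    schedule: OdorSchedule
    respiration: RespirationTrace
    motion: np.ndarray  # (n_volumes, 6)
    tr: float
    cued: tuple[int, int]
    insufficient_blocks: bool = False

    @property
    def n_volumes(self) -> int:
        return self.bold.shape[0]


def _simulate_respiration(duration: float, fs: float = 25.0, seed: int = 0) -> RespirationTrace:
    """Sinusoid-like breathing at ~0.25 Hz with slow phase jitter.

    Inhalation onsets (positive-derivative zero crossings) are therefore
    jittered relative to any fixed trigger grid.
    """
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    phase_noise = np.cumsum(rng.normal(0.0, 0.02, size=n))
    samples = np.sin(2 * np.pi * 0.25 * t + phase_noise) + rng.normal(0.0, 0.02, size=n)
    return RespirationTrace(samples, fs)


def _simulate_motion(n_volumes: int, voxel_size: float, seed: int = 0) -> np.ndarray:
    """Bounded random walk: translations within +-1 voxel, small rotations."""
    rng = np.random.default_rng(seed)
    bounds = np.array([voxel_size] * 3 + [0.02] * 3)
    steps = rng.normal(0.0, 1.0, size=(n_volumes, 6)) * (bounds / 50.0)
    walk = np.cumsum(steps, axis=0)
    return np.clip(walk, -bounds, bounds)


def simulate_sleep_patterns(
    space: PhantomSpace,
    templates: np.ndarray,
    cued: tuple[int, int],
    rho: np.ndarray,
    pattern_sd: float = DEFAULT_SLEEP_PATTERN_SD,
    seed: int = 0,
) -> np.ndarray:
    """Odor-evoked spatial patterns at the beta level (no BOLD synthesis).

    pattern_o = rho_o * template(cued_o) + (1 - rho_o) * noise.  This is
    the generating pattern the sleep GLM recovers; reduced-scale studies
    (e.g. null-calibration batteries) use it directly.
    """
    rng = np.random.default_rng(seed)
    rho = np.asarray(rho, dtype=float)
    patterns = np.empty((2, space.n_voxels))
    for o in range(2):
        noise = rng.normal(0.0, pattern_sd, size=space.n_voxels)
        patterns[o] = rho[o] * templates[cued[o]] + (1.0 - rho[o]) * noise
    return patterns


def simulate_sleep_session(
    space: PhantomSpace,
    templates: np.ndarray,
    cued: tuple[int, int],
    rho: np.ndarray,
    design: SleepDesign | None = None,
    pattern_sd: float = DEFAULT_SLEEP_PATTERN_SD,
    noise_sd: float = DEFAULT_SLEEP_NOISE_SD,
    seed: int = 0,
) -> SleepSession:
    """Full BOLD synthesis of the cueing scan.

    BOLD = HRF-convolved odor boxcars x spatial patterns + slow drift +
    iid Gaussian noise.  Also produces the odor event table, a breathing
    trace, and bounded-random-walk motion parameters.
    """
    if design is None:
        design = SleepDesign()
    if design.n_blocks_per_odor < MIN_BLOCKS_PER_ODOR:
        warnings.warn(
            f"fewer than {MIN_BLOCKS_PER_ODOR} blocks per odor violates the inclusion criterion",
            InsufficientCueingWarning,
        )
    rng = np.random.default_rng(seed)
    schedule = make_odor_schedule(design.n_blocks_per_odor, design.start_s, block_duration=design.block_duration)
    duration = schedule.span + design.tail_s
    n_volumes = int(np.ceil(duration / design.tr))
    events = schedule.to_events()

    patterns = simulate_sleep_patterns(
        space, templates, cued, rho, pattern_sd, seed=rng.integers(2**31)
    )
    bold = np.zeros((n_volumes, space.n_voxels))
    for o, odor in enumerate(sorted(set(schedule.odors))):
        sel = events[events["trial_type"] == odor]
        reg = _convolved_boxcar(sel["onset"].to_numpy(), sel["duration"].to_numpy(), n_volumes, design.tr)
        bold += np.outer(reg, patterns[o])

    t = np.arange(n_volumes) * design.tr
    drift_shape = (t / t[-1] - 0.5) + np.cos(2 * np.pi * t / 300.0)
    bold += np.outer(drift_shape * design.drift_amplitude, rng.normal(0.0, 1.0, size=space.n_voxels))
    if noise_sd > 0:
        bold += rng.normal(0.0, noise_sd, size=bold.shape)

    respiration = _simulate_respiration(duration, seed=int(rng.integers(2**31)))
    motion = _simulate_motion(n_volumes, space.voxel_size, seed=int(rng.integers(2**31)))
    counts = schedule.counts()
    return SleepSession(
        bold=bold,
        events=events,
        schedule=schedule,
        respiration=respiration,
        motion=motion,
        tr=design.tr,
        cued=tuple(cued),
        insufficient_blocks=any(c < MIN_BLOCKS_PER_ODOR for c in counts.values()),
    )


# -- behavior ---------------------------------------------------------------

def _grid_keys(n_items_per_category: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced correct grid cells: two objects per category per cell."""
    cells = np.repeat(np.arange(1, 17), n_items_per_category // 16 if n_items_per_category >= 16 else 1)
    if cells.size < n_items_per_category:
        cells = np.concatenate([cells, rng.integers(1, 17, size=n_items_per_category - cells.size)])
    return rng.permutation(cells[:n_items_per_category])


def simulate_recall_tables(
    cued: tuple[int, int],
    mean_rho: float,
    coupling: tuple[float, float] = DEFAULT_COUPLING,
    noise_sd: float = DEFAULT_BEHAVIOR_NOISE_SD,
    p_pretest: float = DEFAULT_P_PRETEST,
    base_retention: float = DEFAULT_BASE_RETENTION,
    n_items_per_category: int = 32,
    rt_log_shift_cued: float = 0.04,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Object-level recall tables for one subject, one DataFrame per phase.

    Posttest retention for cued categories is base + a + b * mean(rho) +
    noise; non-cued categories get base + noise.  With b = 0 the benefit is
    independent of rho.  RTs are lognormal; cued objects respond slower in
    the interference phase (memory-competition effect).
    """
    a, b = coupling
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("coupling parameters must be finite")
    rng = np.random.default_rng(seed)
    rows: dict[str, list] = {p: [] for p in ("pretest", "interference", "posttest", "followup")}
    for cat in range(N_CATEGORIES):
        is_cued = cat in cued
        retention = base_retention + (a + b * mean_rho if is_cued else 0.0) + rng.normal(0.0, noise_sd)
        retention = float(np.clip(retention, 0.0, 1.2))
        keys = _grid_keys(n_items_per_category, rng)
        p_post = np.clip(p_pretest * retention, 0.0, 0.98)
        phase_p = {
            "pretest": p_pretest,
            "interference": 0.41,
            "posttest": p_post,
            "followup": 0.38,
        }
        for item in range(n_items_per_category):
            obj = cat * n_items_per_category + item
            for phase, p in phase_p.items():
                correct = bool(rng.random() < p)
                chosen = int(keys[item]) if correct else int(rng.choice([c for c in range(1, 17) if c != keys[item]]))
                log_rt = rng.normal(0.0, 0.3)
                if phase == "interference" and is_cued:
                    log_rt += rt_log_shift_cued
                rows[phase].append(
                    dict(
                        object=obj,
                        category=cat,
                        cued=is_cued,
                        phase=phase,
                        key_cell=int(keys[item]),
                        chosen_cell=chosen,
                        correct=correct,
                        rt=float(np.exp(log_rt)),
                    )
                )
    return {phase: pd.DataFrame(r) for phase, r in rows.items()}


def simulate_behavior(
    ground_truth: GroundTruth,
    n_items_per_category: int = 32,
    seed: int = 0,
) -> list[dict[str, pd.DataFrame]]:
    """Recall tables for every subject of a synthetic group."""
    out = []
    for s in range(ground_truth.n_subjects):
        out.append(
            simulate_recall_tables(
                ground_truth.cued_categories[s],
                float(ground_truth.mean_rho[s]),
                coupling=ground_truth.behavior_coupling,
                noise_sd=ground_truth.behavior_noise_sd,
                n_items_per_category=n_items_per_category,
                seed=seed * 100003 + s,
            )
        )
    return out


# -- EEG and hypnogram ------------------------------------------------------

def _one_over_f_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n)
    return out / out.std()


def simulate_eeg_and_hypnogram(
    duration_min: float = 75.0,
    schedule: OdorSchedule | None = None,
    effect: float | None = None,
    fs: float = 100.0,
    amplitude_uv: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Frontal-channel EEG (1/f-like noise, microvolts) plus a hypnogram.

    Under ``effect=None`` the generating spectrum is identical during
    odor-on and odor-off periods.  ``effect=x`` multiplies 1-4 Hz power by
    x during odor-on blocks (an arousal-like confound used for power
    analyses).  The scripted hypnogram guarantees at least 2 min of
    continuous stage 2 before the first odor block and approximates a
    typical cueing-nap architecture (~10 min wake, ~8.5 min stage 1,
    ~26.5 min stage 2, ~30 min stage 3 over a 75 min recording).
    """
    if schedule is None:
        schedule = make_odor_schedule(n_blocks_per_odor=15, start_s=EEG_CUEING_START_S)
    duration = duration_min * 60.0
    if schedule.span > duration:
        raise ValueError("odor schedule extends past the recording")
    first_onset = float(schedule.onsets[0])
    if first_onset < 150.0:
        raise ValueError("first odor block must allow 2 min of prior stage 2 sleep")

    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    eeg = _one_over_f_noise(n, rng) * amplitude_uv
    if effect is not None and effect != 1.0:
        # band-limited 1-4 Hz component added during odor-on samples only
        extra = _one_over_f_noise(n, rng, exponent=0.0)
        spec = np.fft.rfft(extra)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        spec[(f < 1.0) | (f > 4.0)] = 0.0
        band = np.fft.irfft(spec, n=n)
        band /= band.std()
        base_delta = _band_rms(eeg, fs, 1.0, 4.0)
        gain = np.sqrt(max(effect - 1.0, 0.0)) * base_delta
        on = np.zeros(n, dtype=bool)
        for onset in schedule.onsets:
            on[int(onset * fs) : int((onset + schedule.block_duration) * fs)] = True
        eeg = eeg + gain * band * on

    # scripted hypnogram: W -> N1 -> N2 (>= 4 min before cueing) -> N3 ->
    # N2 -> N1 -> W; boundaries track the first odor onset so the 2 min
    # continuous-stage-2 gate always holds
    epochs = np.arange(0, duration, 30.0)
    stage1_start = max(first_onset - 510.0, 0.0)
    stage2_start = max(first_onset - 240.0, 60.0)
    deep_start = first_onset + 240.0
    deep_end = min(deep_start + 1800.0, duration - 510.0)
    stages = []
    for t0 in epochs:
        if t0 < stage1_start:
            stages.append("W")
        elif t0 < stage2_start:
            stages.append("1")
        elif t0 < deep_start:
            stages.append("2")
        elif t0 < deep_end:
            stages.append("3")
        elif t0 < duration - 510.0:
            stages.append("2")
        elif t0 < duration - 270.0:
            stages.append("1")
        else:
            stages.append("W")
    hypnogram = pd.DataFrame({"epoch_start_s": epochs, "stage": stages})
    return eeg, hypnogram


def _band_rms(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> float:
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, d=1.0 / fs)
    band = spec.copy()
    band[(f < f_lo) | (f > f_hi)] = 0.0
    return float(np.fft.irfft(band, n=x.size).std())
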