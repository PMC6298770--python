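"""Sleep EEG spectral contrasts, stage summaries and cueing gates.

Power spectral density is estimated per 16 s block with Welch's method
(4 s Hann segments, 50% overlap, one-sided density scaling) and averaged
onto a 0.5 Hz grid between 0.5 and 20 Hz.  The odor-on versus odor-off
contrast is a two-factor (condition x frequency) repeated-measures ANOVA
whose interaction term asks whether odor delivery changed the spectrum —
a check that cueing did not provoke arousal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import TestResult
from .phantom import OdorSchedule

__all__ = [
    "welch_psd",
    "PSD_FREQS",
    "condition_block_psd",
    "condition_psd_contrast",
    "sleep_stage_summary",
    "CueingEligibility",
    "cueing_gates",
]

PSD_FREQS = np.arange(0.5, 20.0 + 1e-9, 0.5)  # 40 bins
STAGES = ("W", "1", "2", "3", "R")
SLEEP_STAGES = ("1", "2", "3", "R")


def welch_psd(
    trace: np.ndarray,
    fs: float,
    seg_len_s: float = 4.0,
    overlap: float = 0.5,
    band_grid: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of one EEG trace.

    Hann-windowed averaged periodogram with one-sided density scaling
    (units uV^2/Hz for a microvolt input).  With ``band_grid=True`` the
    native 0.25 Hz resolution is aggregated onto the 0.5 Hz grid between
    0.5 and 20 Hz by band-averaging; otherwise the native grid is
    returned.
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(seg_len_s * fs))
    if trace.size < nperseg:
        raise ValueError("trace shorter than one Welch segment")
    freqs, pxx = signal.welch(
        trace, fs=fs, window="hann", nperseg=nperseg, noverlap=int(round(nperseg * overlap)), detrend="constant"
    )
    if not band_grid:
        return freqs, pxx
    power = np.empty(PSD_FREQS.size)
    for i, fc in enumerate(PSD_FREQS):
        sel = (freqs > fc - 0.25) & (freqs <= fc + 0.25)
        power[i] = pxx[sel].mean()
    return PSD_FREQS.copy(), power


def condition_block_psd(
    trace: np.ndarray,
    fs: float,
    schedule: OdorSchedule,
) -> np.ndarray:
    """Per-condition mean PSD for one subject: (2, 40) for (on, off).

    Odor-on blocks come from the schedule; each odor-off block is the
    16 s window immediately following an on block.
    """
    n = trace.size
    on_psds, off_psds = [], []
    block = schedule.block_duration
    for onset in schedule.onsets:
        i0, i1 = int(onset * fs), int((onset + block) * fs)
        j0, j1 = i1, int((onset + 2 * block) * fs)
        if j1 > n:
            continue
        on_psds.append(welch_psd(trace[i0:i1], fs)[1])
        off_psds.append(welch_psd(trace[j0:j1], fs)[1])
    if len(on_psds) < 5 or len(off_psds) < 5:
        raise ValueError("need at least 5 odor-on and 5 odor-off blocks")
    return np.stack([np.mean(on_psds, axis=0), np.mean(off_psds, axis=0)])


def condition_psd_contrast(
    subject_psds: np.ndarray,
    condition_names: tuple[str, str] = ("odor_on", "odor_off"),
) -> tuple[pd.DataFrame, TestResult]:
    """Group-level condition x frequency repeated-measures ANOVA.

    subject_psds: (n_subjects, 2 conditions, 40 frequency bins).  Returns
    the tidy PSD table and the interaction test.  The classical univariate
    interaction df is (c-1)(f-1) over (c-1)(f-1)(n-1); the
    Greenhouse-Geisser corrected p accompanies it.
    """
    import pingouin as pg

    psds = np.asarray(subject_psds, dtype=float)
    if psds.ndim != 3 or psds.shape[1] != 2 or psds.shape[2] != PSD_FREQS.size:
        raise ValueError("expected (n_subjects, 2, 40) PSD array")
    n = psds.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for s in range(n):
        for ci, cond in enumerate(condition_names):
            for fi, freq in enumerate(PSD_FREQS):
                rows.append(dict(subject=s, condition=cond, frequency=freq, power=psds[s, ci, fi]))
    table = pd.DataFrame(rows)
    aov = pg.rm_anova(data=table, dv="power", within=["condition", "frequency"], subject="subject", detailed=True)
    inter = aov[aov["Source"].str.contains(r"\*")].iloc[0]
    c, f = 2, PSD_FREQS.size
    result = TestResult(
        name="psd_condition_by_frequency",
        statistic=float(inter["F"]),
        df=float((c - 1) * (f - 1)),
        tails=2,
        p=float(inter["p_GG_corr"]),
        extra={
            "df_error_classical": float((c - 1) * (f - 1) * (n - 1)),
            "p_uncorrected": float(inter["p_unc"]),
            "gg_epsilon": float(inter["eps"]),
        },
    )
    return table, result


def sleep_stage_summary(hypnogram: pd.DataFrame) -> pd.DataFrame:
    """Minutes and percentages per stage from a 30 s epoch hypnogram.

    Percentages are of total recording time (wake + sleep); total sleep
    time pools stages 1, 2, 3 and REM.
    """
    if hypnogram.empty:
        raise ValueError("empty hypnogram")
    unknown = set(hypnogram["stage"].astype(str)) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    epoch_min = 0.5
    counts = hypnogram["stage"].astype(str).value_counts()
    total_min = float(len(hypnogram) * epoch_min)
    rows = []
    for stage in STAGES:
        minutes = float(counts.get(stage, 0) * epoch_min)
        rows.append(dict(stage=stage, minutes=minutes, percent=100.0 * minutes / total_min))
    tst = float(sum(counts.get(s, 0) for s in SLEEP_STAGES) * epoch_min)
    rows.append(dict(stage="total_sleep", minutes=tst, percent=100.0 * tst / total_min))
    rows.append(dict(stage="total", minutes=total_min, percent=100.0))
    return pd.DataFrame(rows)


@dataclass
class CueingEligibility:
    """Protocol gates for the odor-cueing session."""

    first_block_eligible: bool
    odor_counts: dict[str, int]
    min_count_met: bool
    button_press: bool
    included: bool


def _stage_at(hypnogram: pd.DataFrame, t: float) -> str:
    idx = np.searchsorted(hypnogram["epoch_start_s"].to_numpy(), t, side="right") - 1
    idx = max(idx, 0)
    return str(hypnogram["stage"].iloc[idx])


def cueing_gates(
    hypnogram: pd.DataFrame,
    schedule: OdorSchedule,
    button_presses: np.ndarray | list | tuple = (),
) -> CueingEligibility:
    """Apply the cueing-protocol gates and the subject inclusion rule.

    The first odor block may only start after at least 120 s of continuous
    stage 2 (or deeper) sleep.  A subject is included iff every odor was
    presented at least 14 times and no odor-perception button press
    occurred during the nap.
    """
    if schedule.span > hypnogram["epoch_start_s"].iloc[-1] + 30.0:
        raise ValueError("odor schedule extends past the hypnogram")
    first = float(schedule.onsets[0])
    window = np.arange(first - 120.0, first + 1e-9, 30.0)
    eligible = all(_stage_at(hypnogram, max(t, 0.0)) in ("2", "3") for t in window) and first >= 120.0
    counts = schedule.counts()
    min_met = all(c >= 14 for c in counts.values())
    pressed = len(button_presses) > 0
    return CueingEligibility(
        first_block_eligible=bool(eligible),
        odor_counts=counts,
        min_count_met=bool(min_met),
        button_press=pressed,
        included=bool(min_met and not pressed),
    )
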