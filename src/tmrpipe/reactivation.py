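"""Within-sleep memory reactivation: templates, indices and group models.

The reactivation index measures how much an odor-evoked sleep pattern
resembles the wake template of its cued category beyond the non-cued
templates, in Fisher-Z units:

    index = mean over the two odors of
            [ atanh r(sleep_o, template_cued(o))
              - mean_{c not cued(o)} atanh r(sleep_o, template_c) ]

Group-level inference correlates per-voxel indices with the behavioral
cued memory benefit across subjects, with family-wise error control by
max-statistic permutation within an explicit mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .searchlight import (
    DegenerateCorrelationWarning,
    SphereSpec,
    StatMap,
    fisher_z,
    run_searchlight,
)

__all__ = [
    "build_category_templates",
    "reactivation_from_correlations",
    "reactivation_index",
    "cued_only_index",
    "roi_reactivation",
    "reactivation_searchlight",
    "fisher_ci",
    "GroupResult",
    "GroupCorrelation",
    "GroupOneSample",
    "group_covariate_correlation",
    "main_effect_reactivation",
    "univariate_odor_activation",
    "fir_timecourse_correlation",
]


def build_category_templates(wake_patterns: np.ndarray) -> np.ndarray:
    """Wake category templates: run-averaged, condition-mean-centred.

    wake_patterns: (n_categories, n_runs, n_voxels) beta patterns from the
    initial learning session.  Returns (n_categories, n_voxels); the four
    template values sum to zero at every voxel.
    """
    wake_patterns = np.asarray(wake_patterns, dtype=float)
    if wake_patterns.ndim != 3 or wake_patterns.shape[0] < 2:
        raise ValueError("expected (n_categories, n_runs, n_voxels) with all categories present")
    mean = wake_patterns.mean(axis=1)
    return mean - mean.mean(axis=0, keepdims=True)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 (with a warning) for zero-variance inputs."""
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        warnings.warn("zero-variance pattern; correlation scored as 0", DegenerateCorrelationWarning)
        return 0.0
    return float(ac @ bc / (na * nb))


def reactivation_from_correlations(r_cued: float, r_noncued: np.ndarray) -> float:
    """Fisher-Z reactivation index for one odor from raw correlations."""
    return float(fisher_z(r_cued) - np.mean(fisher_z(np.asarray(r_noncued, dtype=float))))


def reactivation_index(
    sleep_patterns: np.ndarray,
    templates: np.ndarray,
    cued: tuple[int, int],
) -> float:
    """Cued-versus-non-cued reactivation index, averaged over the two odors.

    sleep_patterns: (2, n_voxels) odor-evoked beta patterns (no condition
    mean is removed here: with two odors, centring would create a pair of
    anticorrelated vectors).  templates: (4, n_voxels) wake templates.
    cued: the template index each odor cues; the two must differ.
    """
    sleep_patterns = np.asarray(sleep_patterns, dtype=float)
    templates = np.asarray(templates, dtype=float)
    if sleep_patterns.shape[0] != 2:
        raise ValueError("expected two odor-evoked sleep patterns")
    if cued[0] == cued[1]:
        raise ValueError("the two odors must cue distinct categories")
    vals = []
    for o in range(2):
        rs = np.array([_corr(sleep_patterns[o], templates[c]) for c in range(templates.shape[0])])
        noncued = [c for c in range(templates.shape[0]) if c != cued[o]]
        vals.append(reactivation_from_correlations(rs[cued[o]], rs[noncued]))
    return float(np.mean(vals))


def cued_only_index(
    sleep_patterns: np.ndarray,
    templates: np.ndarray,
    cued: tuple[int, int],
) -> float:
    """Reactivation limited to the two cued categories: each odor's pattern
    is compared against its own cued template versus the other odor's cued
    template, ignoring the non-cued templates entirely."""
    sleep_patterns = np.asarray(sleep_patterns, dtype=float)
    templates = np.asarray(templates, dtype=float)
    if cued[0] == cued[1]:
        raise ValueError("the two odors must cue distinct categories")
    vals = []
    for o, other in ((0, 1), (1, 0)):
        r_own = _corr(sleep_patterns[o], templates[cued[o]])
        r_other = _corr(sleep_patterns[o], templates[cued[other]])
        vals.append(float(fisher_z(r_own) - fisher_z(r_other)))
    return float(np.mean(vals))


def roi_reactivation(
    sleep_patterns: np.ndarray,
    templates: np.ndarray,
    cued: tuple[int, int],
    roi_voxels: np.ndarray,
) -> float:
    """Reactivation index computed once over an anatomical ROI (indices into
    the voxel axis) instead of searchlight spheres."""
    roi_voxels = np.asarray(roi_voxels)
    if roi_voxels.size == 0:
        raise ValueError("empty ROI")
    return reactivation_index(
        np.asarray(sleep_patterns)[..., roi_voxels],
        np.asarray(templates)[..., roi_voxels],
        cued,
    )


def reactivation_searchlight(
    sleep_patterns: np.ndarray,
    wake_patterns: np.ndarray,
    cued: tuple[int, int],
    mask: np.ndarray,
    sphere: SphereSpec | None = None,
    index: str = "full",
) -> StatMap:
    """Per-sphere reactivation map for one subject.

    Templates are built per sphere from the wake beta patterns (the
    construction is voxelwise, so this equals restricting globally built
    templates to the sphere).  ``index`` selects the comparison set:
    "full" (cued vs the three non-cued templates) or "cued_only".
    """
    templates = build_category_templates(wake_patterns)
    if index == "full":
        fn = lambda sub: reactivation_index(sub[0], sub[1], cued)  # noqa: E731
    elif index == "cued_only":
        fn = lambda sub: cued_only_index(sub[0], sub[1], cued)  # noqa: E731
    else:
        raise ValueError("index must be 'full' or 'cued_only'")
    return run_searchlight((np.asarray(sleep_patterns), templates), mask, sphere, fn)


def _sphere_kernel(sphere: SphereSpec) -> np.ndarray:
    r = int(np.floor(sphere.radius_vox))
    kernel = np.zeros((2 * r + 1,) * 3)
    kernel[tuple((sphere.offsets + r).T)] = 1.0
    return kernel


def _sphere_sum(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(volume, kernel, mode="constant", cval=0.0)


def reactivation_map_fast(
    sleep_patterns: np.ndarray,
    templates: np.ndarray,
    cued: tuple[int, int],
    mask: np.ndarray,
    sphere: SphereSpec | None = None,
) -> StatMap:
    """Searchlight reactivation map via sphere-kernel convolutions.

    Computes, for every center at once, the per-sphere Pearson
    correlations between each sleep pattern and each template from local
    sums (sum x, sum x^2, sum xy over the in-mask sphere), then assembles
    the same index as :func:`reactivation_index`.  Numerically equivalent
    to the per-center searchlight loop, but orders of magnitude faster —
    used by the pipeline and by large simulation batteries.

    ``templates`` here are taken as given (pass the output of
    :func:`build_category_templates`).
    """
    if sphere is None:
        sphere = SphereSpec()
    mask = np.asarray(mask, dtype=bool)
    kernel = _sphere_kernel(sphere)
    sleep_patterns = np.asarray(sleep_patterns, dtype=float)
    templates = np.asarray(templates, dtype=float)
    if cued[0] == cued[1]:
        raise ValueError("the two odors must cue distinct categories")

    def vol(vec: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape)
        out[mask] = vec
        return out

    n = _sphere_sum(mask.astype(float), kernel)
    valid = mask & (n >= sphere.min_voxels)
    n_safe = np.where(n > 0, n, 1.0)

    s_vols = [vol(sleep_patterns[o]) for o in range(2)]
    t_vols = [vol(templates[c]) for c in range(templates.shape[0])]
    sx = [_sphere_sum(v, kernel) for v in s_vols]
    sxx = [_sphere_sum(v * v, kernel) for v in s_vols]
    tx = [_sphere_sum(v, kernel) for v in t_vols]
    txx = [_sphere_sum(v * v, kernel) for v in t_vols]

    z = np.zeros((2, templates.shape[0]) + mask.shape)
    for o in range(2):
        var_s = sxx[o] - sx[o] ** 2 / n_safe
        for c in range(templates.shape[0]):
            sxy = _sphere_sum(s_vols[o] * t_vols[c], kernel)
            cov = sxy - sx[o] * tx[c] / n_safe
            var_t = txx[c] - tx[c] ** 2 / n_safe
            denom = np.sqrt(np.maximum(var_s, 0.0) * np.maximum(var_t, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
            z[o, c] = fisher_z(r)

    values = np.zeros(mask.shape)
    for o in range(2):
        noncued = [c for c in range(templates.shape[0]) if c != cued[o]]
        values += z[o, cued[o]] - z[o, noncued].mean(axis=0)
    values /= 2.0
    values[~valid] = 0.0
    return StatMap(values, valid)


def fisher_ci(r: float, n: int, level: float = 0.90) -> tuple[float, float]:
    """Fisher-Z confidence interval for a Pearson correlation."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - (1 - level) / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


@dataclass
class GroupResult:
    """Group-level voxelwise statistics with permutation FWE at the peak."""

    stat_map: np.ndarray  # t values at valid voxels, NaN elsewhere
    r_map: np.ndarray | None  # correlation map (covariate analyses only)
    peak_index: tuple
    peak_stat: float
    peak_r: float | None
    p_uncorrected: float
    p_fwe: float
    n_permutations: int
    n_subjects: int
    mask: np.ndarray


def _as_subject_matrix(maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(n_subjects, ...) spatial stack -> (n_subjects, n_mask_voxels)."""
    maps = np.asarray(maps, dtype=float)
    return maps.reshape(maps.shape[0], -1)[:, np.asarray(mask, dtype=bool).ravel()]


class GroupCorrelation(BaseEstimator):
    """Across-subject correlation of voxel maps with a covariate.

    One-tailed (positive) Pearson correlation at each voxel inside an
    explicit mask; the peak t is corrected for family-wise error by
    max-statistic permutation of the covariate across subjects.

    Attributes (after ``fit``) mirror :class:`GroupResult`, which is also
    available as ``result_``.
    """

    def __init__(self, n_permutations: int = 10000, seed: int | None = 0):
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, maps: np.ndarray, covariate: np.ndarray, mask: np.ndarray):
        covariate = np.asarray(covariate, dtype=float)
        n = covariate.size
        if n < 4:
            raise ValueError("need at least 4 subjects")
        if np.ptp(covariate) == 0:
            raise ValueError("constant covariate")
        mask = np.asarray(mask, dtype=bool)
        M = _as_subject_matrix(maps, mask)
        if M.shape[0] != n:
            raise ValueError("one map per subject required")

        Mc = M - M.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(Mc, axis=0)
        norms[norms == 0] = 1.0
        Mu = Mc / norms

        def unit(v: np.ndarray) -> np.ndarray:
            vc = v - v.mean()
            return vc / np.linalg.norm(vc)

        bu = unit(covariate)
        r = bu @ Mu
        t = self._r_to_t(r, n)
        peak_flat = int(np.argmax(t))
        obs_peak_t = float(t[peak_flat])

        rng = np.random.default_rng(self.seed)
        null_max = np.empty(self.n_permutations)
        for i in range(self.n_permutations):
            null_max[i] = (unit(rng.permutation(covariate)) @ Mu).max()
        null_max_t = self._r_to_t(null_max, n)
        p_fwe = (1.0 + np.sum(null_max_t >= obs_peak_t)) / (self.n_permutations + 1.0)

        self.r_ = r
        self.t_ = t
        mask_flat_index = np.flatnonzero(mask.ravel())[peak_flat]
        peak_index = np.unravel_index(mask_flat_index, mask.shape)
        t_map = np.full(mask.shape, np.nan)
        t_map[mask] = t
        r_map = np.full(mask.shape, np.nan)
        r_map[mask] = r
        self.result_ = GroupResult(
            stat_map=t_map,
            r_map=r_map,
            peak_index=tuple(int(i) for i in peak_index),
            peak_stat=obs_peak_t,
            peak_r=float(r[peak_flat]),
            p_uncorrected=float(stats.t.sf(obs_peak_t, df=n - 2)),
            p_fwe=float(p_fwe),
            n_permutations=self.n_permutations,
            n_subjects=n,
            mask=mask,
        )
        return self

    @staticmethod
    def _r_to_t(r: np.ndarray, n: int) -> np.ndarray:
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        return r * np.sqrt((n - 2) / (1.0 - r**2))


class GroupOneSample(BaseEstimator):
    """One-sample, one-tailed group t test with sign-flip permutation FWE.

    Used for the main effect of reactivation (mean index > 0) and for the
    univariate odor-activation contrast.  Under the null the subject maps
    are symmetric about zero, so random sign flips generate the
    max-statistic null distribution.
    """

    def __init__(self, n_permutations: int = 10000, seed: int | None = 0):
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, maps: np.ndarray, mask: np.ndarray):
        mask = np.asarray(mask, dtype=bool)
        M = _as_subject_matrix(maps, mask)
        n = M.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")

        sumsq = (M**2).sum(axis=0)

        def tmap(signed_sum: np.ndarray) -> np.ndarray:
            mean = signed_sum / n
            var = (sumsq - n * mean**2) / (n - 1)
            sd = np.sqrt(np.maximum(var, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
            return t

        t = tmap(M.sum(axis=0))
        peak_flat = int(np.argmax(t))
        obs_peak_t = float(t[peak_flat])

        rng = np.random.default_rng(self.seed)
        null_max = np.empty(self.n_permutations)
        for i in range(self.n_permutations):
            signs = rng.choice((-1.0, 1.0), size=n)
            null_max[i] = tmap(signs @ M).max()
        p_fwe = (1.0 + np.sum(null_max >= obs_peak_t)) / (self.n_permutations + 1.0)

        self.t_ = t
        mask_flat_index = np.flatnonzero(mask.ravel())[peak_flat]
        peak_index = np.unravel_index(mask_flat_index, mask.shape)
        t_map = np.full(mask.shape, np.nan)
        t_map[mask] = t
        self.result_ = GroupResult(
            stat_map=t_map,
            r_map=None,
            peak_index=tuple(int(i) for i in peak_index),
            peak_stat=obs_peak_t,
            peak_r=None,
            p_uncorrected=float(stats.t.sf(obs_peak_t, df=n - 1)),
            p_fwe=float(p_fwe),
            n_permutations=self.n_permutations,
            n_subjects=n,
            mask=mask,
        )
        return self


def group_covariate_correlation(
    subject_maps: np.ndarray,
    benefits: np.ndarray,
    explicit_mask: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = 0,
) -> GroupResult:
    """Functional wrapper: correlate subject reactivation maps with cued
    memory benefit inside the explicit (learning-derived) mask."""
    return GroupCorrelation(n_permutations=n_perm, seed=seed).fit(subject_maps, benefits, explicit_mask).result_


def main_effect_reactivation(
    subject_maps: np.ndarray,
    explicit_mask: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = 0,
) -> GroupResult:
    """Main effect of odor cueing on reactivation (mean index > 0),
    without the behavioral covariate."""
    return GroupOneSample(n_permutations=n_perm, seed=seed).fit(subject_maps, explicit_mask).result_


def univariate_odor_activation(
    subject_contrasts: np.ndarray,
    roi_mask: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = 0,
) -> GroupResult:
    """Group test of odor-onset activation with small-volume FWE inside an
    anatomical ROI (sign-flip permutation of subject contrast maps)."""
    return GroupOneSample(n_permutations=n_perm, seed=seed).fit(subject_contrasts, roi_mask).result_


def fir_timecourse_correlation(
    timepoint_maps: np.ndarray,
    benefits: np.ndarray,
    cluster_voxels: np.ndarray,
    level: float = 0.90,
) -> list[tuple[float, tuple[float, float]]]:
    """Time-resolved brain-behavior correlation.

    timepoint_maps: (n_timepoints, n_subjects, n_voxels) reactivation maps
    from the FIR model.  For each time point the map is averaged over the
    cluster voxels and correlated with the cued memory benefit; the
    confidence interval comes from :func:`fisher_ci`.
    """
    timepoint_maps = np.asarray(timepoint_maps, dtype=float)
    cluster_voxels = np.asarray(cluster_voxels)
    if cluster_voxels.size == 0:
        raise ValueError("empty cluster")
    benefits = np.asarray(benefits, dtype=float)
    n = benefits.size
    out = []
    for tp in range(timepoint_maps.shape[0]):
        vals = timepoint_maps[tp][:, cluster_voxels].mean(axis=1)
        r = float(np.corrcoef(vals, benefits)[0, 1])
        out.append((r, fisher_ci(r, n, level)))
    return out
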