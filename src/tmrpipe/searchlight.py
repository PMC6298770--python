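"""Correlation-based searchlight pattern analysis.

At every voxel of a brain mask, patterns from a small sphere of
neighbouring voxels are extracted and scored with a leave-one-run-out
correlation statistic: within-category train/test correlations are
compared against the average of between-category correlations, after
Fisher-Z transformation.  A positive statistic means the sphere carries
category information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "SphereSpec",
    "StatMap",
    "sphere_offsets",
    "fisher_z",
    "discrimination_from_correlations",
    "discrimination_statistic",
    "per_category_discrimination",
    "run_searchlight",
    "CorrelationSearchlight",
    "group_sensitivity_mask",
]

ATANH_CLIP = 1.0 - 1e-7


class DegenerateCorrelationWarning(RuntimeWarning):
    """A zero-variance pattern forced a correlation to be scored as 0."""


def sphere_offsets(radius_vox: float) -> np.ndarray:
    """Integer offsets within a sphere, in lexicographic order.

    All (dx, dy, dz) with dx^2 + dy^2 + dz^2 <= radius^2.  The default
    searchlight radius of 3.7 voxels yields 203 offsets.
    """
    if radius_vox < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius_vox))
    grid = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(grid, grid, grid, indexing="ij")
    offs = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    keep = (offs**2).sum(axis=1) <= radius_vox**2
    return offs[keep]  # meshgrid('ij') + ravel is already lexicographic


@dataclass
class SphereSpec:
    """Searchlight sphere geometry and the validity rule at mask edges."""

    radius_vox: float = 3.7
    min_voxels: int = 10
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.offsets = sphere_offsets(self.radius_vox)


@dataclass
class StatMap:
    """Per-voxel statistic with a validity mask (sphere underfilled -> invalid)."""

    values: np.ndarray
    valid: np.ndarray

    def masked(self) -> np.ndarray:
        out = np.full(self.values.shape, np.nan)
        out[self.valid] = self.values[self.valid]
        return out


def fisher_z(r: np.ndarray | float, clip: float = ATANH_CLIP) -> np.ndarray | float:
    """atanh with clipping so exact +-1 correlations stay finite."""
    return np.arctanh(np.clip(r, -clip, clip))


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between all row pairs of a (m, v) and b (k, v).

    Zero-variance rows produce r = 0 with a warning.
    """
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean(axis=-1, keepdims=True)
    na = np.linalg.norm(ac, axis=-1)
    nb = np.linalg.norm(bc, axis=-1)
    degenerate = (na == 0).any() or (nb == 0).any()
    if degenerate:
        warnings.warn("zero-variance pattern; correlation scored as 0", DegenerateCorrelationWarning)
    na = np.where(na == 0, 1.0, na)
    nb = np.where(nb == 0, 1.0, nb)
    return (ac @ bc.T) / np.outer(na, nb)


def discrimination_from_correlations(r_matrix: np.ndarray) -> float:
    """Aggregate a (folds, cond, cond) or (cond, cond) train-x-test
    correlation matrix into the discrimination statistic.

    Rows index training condition, columns the test condition.  Each entry
    is Fisher-Z transformed; the statistic is the mean within-condition Z
    (diagonal) minus the mean between-condition Z (off-diagonal), averaged
    over folds.
    """
    z = fisher_z(np.asarray(r_matrix, dtype=float))
    if z.ndim == 2:
        z = z[None]
    c = z.shape[-1]
    diag = z[:, np.arange(c), np.arange(c)]
    within = diag.mean(axis=-1)
    between = (z.sum(axis=(-2, -1)) - diag.sum(axis=-1)) / (c * (c - 1))
    return float((within - between).mean())


def _fold_z_matrices(patterns: np.ndarray) -> np.ndarray:
    """Fisher-Z train-x-test correlation matrices, one per held-out run.

    patterns: (n_conditions, n_runs, n_voxels).  For fold r, training
    patterns are the mean of the other runs per condition; the condition
    mean is removed from training and test sets separately before
    correlating.  Returns (n_runs, cond_train, cond_test).
    """
    patterns = np.asarray(patterns, dtype=float)
    c, n_runs, _ = patterns.shape
    if n_runs < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    total = patterns.sum(axis=1)
    zs = np.empty((n_runs, c, c))
    for r in range(n_runs):
        test = patterns[:, r, :]
        train = (total - test) / (n_runs - 1)
        train = train - train.mean(axis=0, keepdims=True)
        test = test - test.mean(axis=0, keepdims=True)
        zs[r] = fisher_z(_corr_rows(train, test))
    return zs


def discrimination_statistic(patterns: np.ndarray) -> float:
    """Leave-one-run-out category discrimination score for one sphere.

    Mean over folds of [mean within-category Z - mean between-category Z].
    Zero when the four conditions carry identical patterns; positive when
    patterns are more similar within than between categories.
    """
    z = _fold_z_matrices(patterns)
    c = z.shape[-1]
    diag = z[:, np.arange(c), np.arange(c)]
    within = diag.mean(axis=-1)
    between = (z.sum(axis=(-2, -1)) - diag.sum(axis=-1)) / (c * (c - 1))
    return float((within - between).mean())


def per_category_discrimination(patterns: np.ndarray) -> np.ndarray:
    """Category-wise discrimination: for category c, within-Z minus the mean
    Z of training c against the incongruent test patterns.

    The mean of the four values equals :func:`discrimination_statistic`.
    """
    z = _fold_z_matrices(patterns)
    c = z.shape[-1]
    diag = z[:, np.arange(c), np.arange(c)]
    between = (z.sum(axis=-1) - diag) / (c - 1)
    return (diag - between).mean(axis=0)


def _neighbor_table(mask: np.ndarray, offsets: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """For each in-mask voxel, indices (into the mask vector) of its
    in-mask sphere neighbours."""
    mask = np.asarray(mask, dtype=bool)
    coords = np.array(np.nonzero(mask)).T  # (n_mask, 3)
    vec_index = -np.ones(mask.shape, dtype=int)
    vec_index[mask] = np.arange(coords.shape[0])
    dims = np.array(mask.shape)
    neighbors = []
    for center in coords:
        pts = center + offsets
        ok = np.all((pts >= 0) & (pts < dims), axis=1)
        pts = pts[ok]
        idx = vec_index[pts[:, 0], pts[:, 1], pts[:, 2]]
        neighbors.append(idx[idx >= 0])
    return coords, neighbors


def run_searchlight(
    data: np.ndarray | Sequence[np.ndarray],
    mask: np.ndarray,
    sphere: SphereSpec | None = None,
    stat_fn: Callable = discrimination_statistic,
    centers: np.ndarray | None = None,
) -> StatMap:
    """Evaluate ``stat_fn`` on the sphere around every valid mask voxel.

    ``data`` is an array (or tuple of arrays) whose last axis indexes the
    in-mask voxels, in the order given by ``np.nonzero(mask)``.  For each
    center whose sphere contains at least ``sphere.min_voxels`` in-mask
    voxels, ``stat_fn`` receives the data restricted to those voxels.
    ``centers`` (boolean, same shape as mask) optionally restricts which
    voxels are evaluated as sphere centers; neighbourhoods still draw from
    the full mask.
    """
    if sphere is None:
        sphere = SphereSpec()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    single = isinstance(data, np.ndarray)
    arrays = (data,) if single else tuple(np.asarray(a) for a in data)
    n_mask = int(mask.sum())
    for a in arrays:
        if a.shape[-1] != n_mask:
            raise ValueError("data last axis must match the number of mask voxels")

    coords, neighbors = _neighbor_table(mask, sphere.offsets)
    values = np.zeros(mask.shape)
    valid = np.zeros(mask.shape, dtype=bool)
    centers = None if centers is None else np.asarray(centers, dtype=bool)
    for center, nbr in zip(coords, neighbors):
        if centers is not None and not centers[tuple(center)]:
            continue
        if nbr.size < sphere.min_voxels:
            continue
        sub = arrays[0][..., nbr] if single else tuple(a[..., nbr] for a in arrays)
        values[tuple(center)] = stat_fn(sub)
        valid[tuple(center)] = True
    return StatMap(values, valid)


class CorrelationSearchlight(BaseEstimator):
    """Sphere-based category-discrimination mapping as an estimator.

    Parameters
    ----------
    radius_vox : float
        Searchlight sphere radius in voxels.
    min_voxels : int
        Minimum in-mask sphere size for a center to be scored.
    per_category : bool
        If True, fit stores four per-category maps instead of one pooled map.

    Attributes
    ----------
    stat_map_ : StatMap (pooled) or list of StatMap (per category)
    """

    def __init__(self, radius_vox: float = 3.7, min_voxels: int = 10, per_category: bool = False):
        self.radius_vox = radius_vox
        self.min_voxels = min_voxels
        self.per_category = per_category

    def fit(self, patterns: np.ndarray, mask: np.ndarray):
        """patterns: (n_conditions, n_runs, n_mask_voxels)."""
        sphere = SphereSpec(self.radius_vox, self.min_voxels)
        if self.per_category:
            n_cat = patterns.shape[0]
            maps = [np.zeros(mask.shape) for _ in range(n_cat)]
            coords, neighbors = _neighbor_table(np.asarray(mask, dtype=bool), sphere.offsets)
            valid = np.zeros(mask.shape, dtype=bool)
            for center, nbr in zip(coords, neighbors):
                if nbr.size < sphere.min_voxels:
                    continue
                vals = per_category_discrimination(patterns[..., nbr])
                for k in range(n_cat):
                    maps[k][tuple(center)] = vals[k]
                valid[tuple(center)] = True
            self.stat_map_ = [StatMap(m, valid.copy()) for m in maps]
            self.valid_mask_ = valid
        else:
            result = run_searchlight(patterns, mask, sphere, discrimination_statistic)
            self.stat_map_ = result
            self.valid_mask_ = result.valid
        self.n_centers_ = int(self.valid_mask_.sum())
        return self


def group_sensitivity_mask(subject_maps: np.ndarray, alpha: float = 0.001) -> np.ndarray:
    """Voxels with group-level category information.

    One-sample, one-tailed t test across subjects against zero at every
    voxel; the mask keeps voxels with uncorrected p < alpha.  Input maps
    are expected already smoothed per the pipeline configuration.
    ``subject_maps``: (n_subjects, ...) array; NaN marks invalid voxels.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    finite = np.all(np.isfinite(maps), axis=0)
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    n = maps.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = stats.t.sf(t, df=n - 1)
    out = finite & (p < alpha)
    # degenerate all-zero voxels (t = 0/0) carry no information
    out &= sd > 0
    return out
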