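"""Seed-based psychophysiological interaction (PPI) analysis.

Tests whether coupling between a limbic seed region and target voxels is
stronger during odor presentation than at baseline.  The physiological
factor is the mean BOLD series of a small sphere around a peak voxel;
the psychological factor is the HRF-convolved odor boxcar; their
elementwise product (both factors centred) is the interaction regressor.
No hemodynamic deconvolution of the seed is applied — the product is
taken at the BOLD level, a known simplification of generalized PPI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .behavior import TestResult
from .glm import DesignMatrix, FirstLevelGLM, NuisanceSet, _convolved_boxcar
from .searchlight import sphere_offsets

__all__ = [
    "extract_seed_series",
    "ppi_design",
    "PPIModel",
    "ppi_group_test",
]


def seed_sphere_indices(
    peak_ijk: tuple[int, int, int],
    radius_mm: float,
    voxel_size_mm: float,
    mask: np.ndarray,
) -> np.ndarray:
    """Indices (into the in-mask voxel vector) of the seed sphere."""
    mask = np.asarray(mask, dtype=bool)
    offs = sphere_offsets(radius_mm / voxel_size_mm)
    pts = np.asarray(peak_ijk) + offs
    dims = np.array(mask.shape)
    ok = np.all((pts >= 0) & (pts < dims), axis=1)
    pts = pts[ok]
    vec_index = -np.ones(mask.shape, dtype=int)
    vec_index[mask] = np.arange(int(mask.sum()))
    idx = vec_index[pts[:, 0], pts[:, 1], pts[:, 2]]
    idx = idx[idx >= 0]
    if idx.size == 0:
        raise ValueError("seed sphere does not intersect the mask")
    return idx


def extract_seed_series(
    bold: np.ndarray,
    peak_ijk: tuple[int, int, int],
    radius_mm: float,
    voxel_size_mm: float,
    mask: np.ndarray,
) -> np.ndarray:
    """Demeaned mean BOLD time course over the seed sphere.

    ``bold``: (n_volumes, n_mask_voxels) with voxels ordered as
    ``np.nonzero(mask)``.  A radius smaller than half a voxel reduces to
    the single peak voxel.
    """
    idx = seed_sphere_indices(peak_ijk, radius_mm, voxel_size_mm, mask)
    series = np.asarray(bold, dtype=float)[:, idx].mean(axis=1)
    return series - series.mean()


def ppi_design(
    seed: np.ndarray,
    odor_events: pd.DataFrame,
    n_volumes: int,
    tr: float,
) -> DesignMatrix:
    """PPI design: physiological, psychological and interaction columns.

    The psychological column is the HRF-convolved boxcar over all odor
    blocks (pooled), mean-centred; the interaction is the elementwise
    product of the demeaned seed and the centred psychological column.
    Both main effects are included so the interaction coefficient is
    identified.
    """
    seed = np.asarray(seed, dtype=float)
    if seed.size != n_volumes:
        raise ValueError("seed length must match the scan")
    if np.ptp(seed) == 0:
        raise ValueError("degenerate constant seed")
    seed = seed - seed.mean()
    psych = _convolved_boxcar(
        odor_events["onset"].to_numpy(), odor_events["duration"].to_numpy(), n_volumes, tr
    )
    psych = psych - psych.mean()
    interaction = seed * psych
    values = np.column_stack([seed, psych, interaction, np.ones(n_volumes)])
    return DesignMatrix(
        values,
        ["seed", "psych", "interaction", "constant"],
        tr,
        np.arange(n_volumes) * tr,
        task_columns=["seed", "psych", "interaction"],
    )


class PPIModel(BaseEstimator):
    """Voxelwise PPI regression for one subject.

    ``fit`` estimates, at every target voxel, the coefficient of the
    seed-by-odor interaction with both main effects (and any nuisance)
    in the model.

    Attributes
    ----------
    interaction_betas_ : ndarray (n_voxels,)
    seed_betas_, psych_betas_ : ndarray (n_voxels,)
    """

    def fit(
        self,
        bold: np.ndarray,
        seed: np.ndarray,
        odor_events: pd.DataFrame,
        tr: float,
        nuisance: NuisanceSet | np.ndarray | None = None,
    ):
        bold = np.asarray(bold, dtype=float)
        design = ppi_design(seed, odor_events, bold.shape[0], tr)
        glm = FirstLevelGLM().fit(bold, design, nuisance)
        by_name = dict(zip(glm.task_columns_, glm.betas_))
        self.design_columns_ = glm.design_columns_
        self.seed_betas_ = by_name["seed"]
        self.psych_betas_ = by_name["psych"]
        self.interaction_betas_ = by_name["interaction"]
        return self

    def cluster_mean(self, cluster_voxels: np.ndarray) -> float:
        """Mean interaction coefficient over a target cluster."""
        cluster_voxels = np.asarray(cluster_voxels)
        if cluster_voxels.size == 0:
            raise ValueError("empty cluster")
        return float(self.interaction_betas_[cluster_voxels].mean())


def ppi_group_test(cluster_betas: np.ndarray) -> TestResult:
    """One-sample, one-tailed t test of cluster-mean coupling against zero."""
    betas = np.asarray(cluster_betas, dtype=float)
    n = betas.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.ptp(betas) == 0:  # degenerate constant sample
        if betas[0] == 0:
            return TestResult("ppi_one_sample_t", 0.0, n - 1, 1, 0.5)
        return TestResult("ppi_one_sample_t", np.sign(betas[0]) * np.inf, n - 1, 1, 0.0 if betas[0] > 0 else 1.0)
    res = stats.ttest_1samp(betas, 0.0, alternative="greater")
    return TestResult("ppi_one_sample_t", float(res.statistic), n - 1, 1, float(res.pvalue))
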