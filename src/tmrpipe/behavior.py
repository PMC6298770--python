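"""Behavioral scoring and statistics for the cued-memory paradigm.

Recall is scored on a 16-cell spatial grid (chance 6.25%).  The quantity
of interest is the cued memory benefit: posttest retention, expressed as
a percentage of the pretest baseline, for cued minus non-cued
categories.  Group statistics follow the paradigm's conventions:
one-tailed Wilcoxon signed-rank and exact binomial tests for the cueing
effect, a two-tailed paired t test on log reaction times, and
within-subject (Cousineau-Morey) standard errors for plotting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CuedBenefit",
    "TestResult",
    "score_recall_and_benefit",
    "wilcoxon_one_tailed",
    "exact_binomial_one_tailed",
    "paired_log_rt_test",
    "select_odor_set",
    "within_subject_sem",
    "simulate_association_learning",
    "write_test_results",
    "CHANCE_LEVEL_PCT",
]

CHANCE_LEVEL_PCT = 100.0 / 16.0  # 16 grid cells
RETENTION_CAP = 200.0


@dataclass
class CuedBenefit:
    """Per-subject retention summary (percentage points)."""

    retention_cued: float
    retention_noncued: float
    benefit: float
    flagged: bool = False


@dataclass
class TestResult:
    """A single statistical test in tidy form."""

    name: str
    statistic: float
    df: float | None
    tails: int
    p: float
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _category_counts(table: pd.DataFrame) -> pd.Series:
    return table.groupby("category")["correct"].sum()


def score_recall_and_benefit(
    recall_pre: pd.DataFrame,
    recall_post: pd.DataFrame,
    cued_categories: tuple[int, int] | list[int],
    item_conditional: bool = False,
) -> CuedBenefit:
    """Cued memory benefit from pre/post recall tables.

    Retention per cueing condition is 100 * (posttest correct count) /
    (pretest correct count), pooled over that condition's two categories;
    benefit = cued retention - non-cued retention.  Retention is capped at
    200%.  A zero pretest count leaves retention undefined and flags the
    subject.

    With ``item_conditional=True`` retention is instead the percentage of
    pretest-correct objects that remain correct at posttest.
    """
    cued = set(int(c) for c in cued_categories)
    categories = set(recall_pre["category"].unique())
    if len(cued) != 2 or not cued <= categories or len(categories) != 4:
        raise ValueError("cued categories must be 2 of the 4 present categories")
    if set(recall_pre["object"]) != set(recall_post["object"]):
        raise ValueError("pre and post tables must cover the same objects")

    def retention(cats: set[int]) -> tuple[float, bool]:
        pre = recall_pre[recall_pre["category"].isin(cats)]
        post = recall_post[recall_post["category"].isin(cats)]
        if item_conditional:
            correct_pre = set(pre.loc[pre["correct"], "object"])
            if not correct_pre:
                return np.nan, True
            kept = post[post["object"].isin(correct_pre) & post["correct"]]
            return min(100.0 * len(kept) / len(correct_pre), RETENTION_CAP), False
        n_pre = int(pre["correct"].sum())
        n_post = int(post["correct"].sum())
        if n_pre == 0:
            return np.nan, True
        return min(100.0 * n_post / n_pre, RETENTION_CAP), False

    noncued = categories - cued
    ret_c, flag_c = retention(cued)
    ret_n, flag_n = retention(noncued)
    flagged = flag_c or flag_n
    benefit = ret_c - ret_n if not flagged else np.nan
    return CuedBenefit(ret_c, ret_n, benefit, flagged)


def wilcoxon_one_tailed(differences: np.ndarray) -> TestResult:
    """One-tailed Wilcoxon signed-rank test (positive differences expected).

    Normal approximation without continuity correction, average ranks for
    ties, zero differences dropped.  For 18 strictly positive differences
    Z = 85.5 / sqrt(527.25) ~= 3.72.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size < 5:
        raise ValueError("need at least 5 non-zero differences")
    res = stats.wilcoxon(d, alternative="greater", correction=False, method="approx")
    return TestResult("wilcoxon_signed_rank", float(res.zstatistic), None, 1, float(res.pvalue))


def exact_binomial_one_tailed(k: int, n: int) -> TestResult:
    """Exact one-tailed binomial tail probability under p = 1/2.

    p = sum_{j=k}^{n} C(n, j) / 2^n.  For 15 of 18 subjects this is
    988/262144 ~= 0.00377.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    res = stats.binomtest(k, n, p=0.5, alternative="greater")
    return TestResult("binomial", float(k), None, 1, float(res.pvalue))


def paired_log_rt_test(
    rt_cued: list[np.ndarray],
    rt_noncued: list[np.ndarray],
) -> TestResult:
    """Two-tailed paired t test on log-transformed reaction times.

    Trial RTs are log transformed and averaged within subject and
    condition; the paired t has n - 1 degrees of freedom.  A degenerate
    zero-variance difference with a non-zero mean returns p = 0, flagged.
    """
    if len(rt_cued) != len(rt_noncued):
        raise ValueError("one RT vector per subject per condition required")
    means_c, means_n = [], []
    for c, n in zip(rt_cued, rt_noncued):
        c, n = np.asarray(c, dtype=float), np.asarray(n, dtype=float)
        if c.size == 0 or n.size == 0:
            raise ValueError("each subject needs at least one RT per condition")
        means_c.append(np.log(c).mean())
        means_n.append(np.log(n).mean())
    diff = np.asarray(means_c) - np.asarray(means_n)
    n_subj = diff.size
    if np.allclose(diff.std(ddof=0), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return TestResult("paired_t_log_rt", 0.0, n_subj - 1, 2, 1.0)
        return TestResult("paired_t_log_rt", np.inf, n_subj - 1, 2, 0.0, extra={"degenerate": True})
    res = stats.ttest_rel(means_c, means_n)
    return TestResult("paired_t_log_rt", float(res.statistic), n_subj - 1, 2, float(res.pvalue))


def select_odor_set(ratings: pd.DataFrame) -> tuple[tuple[int, ...], float]:
    """Choose the 4 of 8 odors with the lowest total pairwise similarity.

    ``ratings`` has columns odor_a, odor_b, rating with exactly two rows
    per unordered pair (28 pairs, 56 rows).  The pair score is the mean of
    its two ratings; each of the 70 four-odor subsets is scored by the sum
    of its six pair scores and the argmin is returned, ties broken by the
    lexicographically smallest subset.
    """
    pairs: dict[frozenset, list[float]] = {}
    for _, row in ratings.iterrows():
        key = frozenset((int(row["odor_a"]), int(row["odor_b"])))
        pairs.setdefault(key, []).append(float(row["rating"]))
    odors = sorted({o for key in pairs for o in key})
    if len(odors) != 8:
        raise ValueError("exactly 8 odors must be rated")
    expected = {frozenset(p) for p in itertools.combinations(odors, 2)}
    if set(pairs) != expected or any(len(v) != 2 for v in pairs.values()):
        raise ValueError("all 28 pairs must be rated exactly twice")
    score = {key: float(np.mean(v)) for key, v in pairs.items()}

    best_subset, best_total = None, np.inf
    for subset in itertools.combinations(odors, 4):  # already lexicographic
        total = sum(score[frozenset(p)] for p in itertools.combinations(subset, 2))
        if total < best_total - 1e-12:
            best_subset, best_total = subset, total
    return best_subset, best_total


def within_subject_sem(values: np.ndarray) -> np.ndarray:
    """Cousineau-Morey within-subject SEM per condition.

    Each subject's mean is removed (and the grand mean restored) before
    computing the per-condition SEM, then scaled by the Morey factor
    sqrt(c / (c - 1)).  Shape (n_subjects, n_conditions) -> (n_conditions,).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    n, c = values.shape
    normalized = values - values.mean(axis=1, keepdims=True) + values.mean()
    morey = np.sqrt(c / (c - 1.0))
    return normalized.std(axis=0, ddof=1) / np.sqrt(n) * morey


def simulate_association_learning(
    p_correct: float = 1.0,
    n_pairs: int = 4,
    criterion: int = 16,
    seed: int = 0,
    max_trials: int = 100000,
) -> int:
    """Trials needed to learn the odor-category associations to criterion.

    Pairs are presented cyclically; the task ends when every pair has been
    answered correctly ``criterion`` times.  An errorless learner finishes
    in exactly ``criterion * n_pairs`` trials (64 at the defaults).
    """
    rng = np.random.default_rng(seed)
    hits = np.zeros(n_pairs, dtype=int)
    trials = 0
    while np.any(hits < criterion):
        pair = trials % n_pairs
        if hits[pair] < criterion and rng.random() < p_correct:
            hits[pair] += 1
        trials += 1
        if trials > max_trials:
            raise RuntimeError("learning did not converge")
    return trials


def write_test_results(results: list[TestResult], path) -> pd.DataFrame:
    """Emit statistics as a tidy CSV (test, statistic, df, tails, p)."""
    frame = pd.DataFrame(
        [dict(test=r.name, statistic=r.statistic, df=r.df, tails=r.tails, p=r.p) for r in results]
    )
    frame.to_csv(path, index=False)
    return frame
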