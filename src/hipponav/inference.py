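"""Circular-shift permutation inference for cross-validated AUCs.

Chance-level calibration uses surrogate label sequences built by
circularly rotating the windowed speed trace relative to the (fixed)
neural features, then re-deriving labels and re-running the full
cross-validated decoder.  Rotation — rather than shuffling — preserves
the temporal autocorrelation of both the features and the behaviour, so
the null reflects only the broken alignment between them.  Family-wise
error across a set of tasks is controlled with the permutation maxT
rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .decode import crossval_auc
from .labeling import (
    LabeledDataset,
    PairwiseTask,
    discretize_bins,
    extreme_decile_labels,
    pairwise_tasks,
)
from .preprocess import FeatureTable

__all__ = [
    "NullDistribution",
    "SignificanceReport",
    "shift_speed_sequence",
    "shift_null_distribution",
    "pvalue_from_null",
    "maxt_adjust",
    "significance_report",
    "speed_gap_correlation",
    "decile_task_aucs",
    "pairwise_task_aucs",
]

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_MIN_SHIFT = 20  # windows (10 s at the default 0.5-s hop)
DEFAULT_ALPHA = 0.05


@dataclass
class NullDistribution:
    """Permutation AUCs: one row per circular shift, one column per task."""

    null_aucs: np.ndarray  # (n_perm, n_tasks)
    shifts: np.ndarray  # (n_perm,) offsets in windows
    task_names: list[str]
    seed: int

    @property
    def n_perm(self) -> int:
        return self.null_aucs.shape[0]


@dataclass
class SignificanceReport:
    """Observed AUCs with raw and maxT-adjusted permutation p-values."""

    task_names: list[str]
    observed_auc: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray  # bool, p_adjusted < alpha
    alpha: float = DEFAULT_ALPHA
    n_perm: int = 0
    two_sided: bool = False
    extras: dict = field(default_factory=dict)


def shift_speed_sequence(table: FeatureTable, offset: int) -> FeatureTable:
    """Circularly rotate the window-level speeds; features stay fixed.

    Row i of the output carries the speed of row (i - offset) mod N, so
    labels re-derived from the rotated speeds are misaligned with the
    neural features while keeping their run-length structure.
    """
    n = table.n_windows
    if not 0 < offset < n:
        raise ValueError(f"offset must lie in (0, {n}), got {offset}")
    return table.with_speed(np.roll(table.speed, offset))


def decile_task_aucs(
    table: FeatureTable, fraction: float = 0.10, k: int = 10, cv_seed: int = 0,
    folds: str = "stratified",
) -> tuple[list[str], np.ndarray, list[LabeledDataset]]:
    """Observed decile-task AUC as a one-task family."""
    ds = extreme_decile_labels(table, fraction=fraction)
    res = crossval_auc(ds, k=k, seed=cv_seed, folds=folds)
    return ["slow_vs_fast_decile"], np.array([res.auc]), [ds]


def pairwise_task_aucs(
    table: FeatureTable,
    bin_width: float = 10.0,
    v_max: float = 50.0,
    k: int = 10,
    cv_seed: int = 0,
    folds: str = "stratified",
) -> tuple[list[PairwiseTask], np.ndarray]:
    """Observed AUCs for all pairwise speed-bin tasks."""
    binned = discretize_bins(table, bin_width=bin_width, v_max=v_max)
    tasks = pairwise_tasks(binned, bin_width=bin_width)
    aucs = np.array(
        [crossval_auc(ds, k=k, seed=cv_seed, folds=folds).auc
         for _, ds in tasks]
    )
    return [t for t, _ in tasks], aucs


def shift_null_distribution(
    table: FeatureTable,
    scheme: str,
    n_perm: int = DEFAULT_N_PERM,
    min_shift: int = DEFAULT_MIN_SHIFT,
    seed: int = 0,
    fraction: float = 0.10,
    bin_width: float = 10.0,
    v_max: float = 50.0,
    k: int = 10,
    cv_seed: int = 0,
    folds: str = "stratified",
) -> NullDistribution:
    """Null AUC distribution from ``n_perm`` circular speed shifts.

    Offsets are drawn uniformly from {min_shift, ..., N - min_shift};
    the same offset is applied to every task within one permutation, and
    the same cross-validation fold seed is reused throughout so that the
    null reflects label-shift variability only.  ``scheme`` selects the
    label derivation: "decile" (one task) or "bins" (all pairwise tasks).
    """
    n = table.n_windows
    if n <= 2 * min_shift:
        raise ValueError(
            f"session too short: {n} windows but min_shift={min_shift} "
            f"requires N > {2 * min_shift}"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme == "decile":
        task_names, _, _ = decile_task_aucs(table, fraction, k, cv_seed, folds)
    elif scheme == "bins":
        tasks, _ = pairwise_task_aucs(table, bin_width, v_max, k, cv_seed,
                                      folds)
        task_names = [t.name for t in tasks]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_perm, endpoint=True)
    null = np.empty((n_perm, len(task_names)))
    for i, off in enumerate(shifts):
        shifted = shift_speed_sequence(table, int(off))
        if scheme == "decile":
            _, aucs, _ = decile_task_aucs(shifted, fraction, k, cv_seed, folds)
        else:
            perm_tasks, aucs = pairwise_task_aucs(
                shifted, bin_width, v_max, k, cv_seed, folds
            )
            if [t.name for t in perm_tasks] != task_names:
                raise RuntimeError(
                    "task family changed under a circular shift; this "
                    "should be impossible since shifts preserve bin counts"
                )
        null[i] = aucs
    return NullDistribution(
        null_aucs=null, shifts=shifts, task_names=task_names, seed=seed
    )


def pvalue_from_null(observed: float, null_aucs: np.ndarray) -> float:
    """One-sided add-one permutation p-value: (1 + #{null >= obs})/(1 + B)."""
    null_aucs = np.asarray(null_aucs, dtype=float)
    if null_aucs.size == 0:
        raise ValueError("empty null distribution")
    b = null_aucs.size
    return float(1 + np.sum(null_aucs >= observed)) / (1 + b)


def maxt_adjust(observed: np.ndarray, null_aucs: np.ndarray) -> np.ndarray:
    """Family-wise adjusted p-values from the permutation maxima.

    For each permutation the maximum AUC across tasks is taken; task j's
    adjusted p-value is the add-one tail probability of that maximum
    exceeding the observed AUC of task j.
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    null_aucs = np.atleast_2d(np.asarray(null_aucs, dtype=float))
    if null_aucs.shape[1] != len(observed):
        raise ValueError(
            f"null has {null_aucs.shape[1]} task columns but "
            f"{len(observed)} observed values were given"
        )
    m = null_aucs.max(axis=1)
    b = len(m)
    return np.array(
        [(1 + np.sum(m >= obs)) / (1 + b) for obs in observed]
    )


def significance_report(
    observed: np.ndarray,
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
    two_sided: bool = False,
) -> SignificanceReport:
    """Raw and maxT-adjusted permutation p-values for a task family.

    The default test is one-sided (above-chance decoding).  With
    ``two_sided=True`` the literal outside-the-95%-band rule is applied:
    below-chance deviations are assessed against the permutation minima
    (min-T) and the smaller tail probability is doubled.
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    nulls = np.atleast_2d(null.null_aucs)
    if nulls.shape[1] != len(observed):
        raise ValueError("observed/task column mismatch")
    p_raw = np.array(
        [pvalue_from_null(obs, nulls[:, j]) for j, obs in enumerate(observed)]
    )
    p_adj = maxt_adjust(observed, nulls)
    if two_sided:
        b = nulls.shape[0]
        p_raw_lo = np.array(
            [(1 + np.sum(nulls[:, j] <= obs)) / (1 + b)
             for j, obs in enumerate(observed)]
        )
        mins = nulls.min(axis=1)
        p_adj_lo = np.array(
            [(1 + np.sum(mins <= obs)) / (1 + b) for obs in observed]
        )
        p_raw = np.minimum(2.0 * np.minimum(p_raw, p_raw_lo), 1.0)
        p_adj = np.minimum(2.0 * np.minimum(p_adj, p_adj_lo), 1.0)
    return SignificanceReport(
        task_names=list(null.task_names),
        observed_auc=observed,
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=p_adj < alpha,
        alpha=alpha,
        n_perm=nulls.shape[0],
        two_sided=two_sided,
    )


def speed_gap_correlation(
    tasks: list[PairwiseTask], aucs: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between pairwise speed gap and decoding AUC.

    Returns (r, p) with the two-sided p-value from the t transform at
    n_tasks - 2 degrees of freedom.
    """
    gaps = np.array([t.gap for t in tasks], dtype=float)
    aucs = np.asarray(aucs, dtype=float)
    if len(gaps) < 3:
        raise ValueError("need at least 3 tasks for a correlation")
    if np.ptp(gaps) == 0 or np.ptp(aucs) == 0:
        raise ValueError("zero variance in gaps or AUCs")
    res = stats.pearsonr(gaps, aucs)
    return float(res.statistic), float(res.pvalue)
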