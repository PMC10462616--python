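"""Shrinkage-regularized LDA, cross-validation and ROC/AUC evaluation.

The classifier is a two-class linear discriminant whose pooled
within-class covariance is shrunk toward a scaled identity target,
nu * I with nu = trace(S)/p, by the analytic Ledoit-Wolf weight: the
intensity minimising expected Frobenius loss is estimated in closed form
from the class-centered samples, so there is no hyperparameter search.
AUC follows the Mann-Whitney convention (ties count one half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .labeling import LabeledDataset

__all__ = [
    "LdaModel",
    "DecodingResult",
    "ledoit_wolf_shrinkage",
    "fit_shrinkage_lda",
    "decision_scores",
    "roc_auc",
    "crossval_auc",
]

log = logging.getLogger(__name__)


@dataclass
class LdaModel:
    """Fitted two-class shrinkage LDA."""

    mu0: np.ndarray
    mu1: np.ndarray
    sigma_hat: np.ndarray
    lam: float  # shrinkage weight in [0, 1]
    w: np.ndarray  # sigma_hat^{-1} (mu1 - mu0)
    b: float  # threshold, w . (mu0 + mu1)/2 (equal priors)


@dataclass
class DecodingResult:
    """Pooled out-of-fold decoding performance."""

    auc: float
    roc_points: np.ndarray  # (m, 2) of (FPR, TPR), (0,0) -> (1,1)
    scores: np.ndarray  # out-of-fold decision values, dataset row order
    fold_assignment: np.ndarray  # fold id per dataset row
    seed: int
    k: int


def ledoit_wolf_shrinkage(z: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Analytic shrinkage intensity for centered samples ``z`` (n x p).

    Returns ``(lambda, S, nu)`` where ``S = z'z / n`` is the sample
    covariance of the (already centered) rows, ``nu = trace(S)/p`` the
    identity-target scale, and ``lambda`` the closed-form intensity
    min(b^2, d^2)/d^2 with
        d^2 = ||S - nu*I||_F^2
        b^2 = (1/n^2) * sum_i ||z_i z_i' - S||_F^2   (clipped at d^2).
    """
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    S = z.T @ z / n
    nu = float(np.trace(S)) / p
    diff = S - nu * np.eye(p)
    d2 = float(np.sum(diff * diff))
    if d2 <= 0.0:
        return 0.0, S, nu
    # sum_i ||z_i z_i' - S||^2 = sum_i (z_i.z_i)^2 - n ||S||^2
    sq_norms = np.einsum("ij,ij->i", z, z)
    frob_S = float(np.sum(S * S))
    b2 = (float(np.sum(sq_norms**2)) - n * frob_S) / n**2
    lam = min(max(b2, 0.0), d2) / d2
    return float(np.clip(lam, 0.0, 1.0)), S, nu


def fit_shrinkage_lda(X: np.ndarray, y: np.ndarray) -> LdaModel:
    """Fit the shrinkage LDA on binary labels (0/1)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    idx0 = y == classes[0]
    idx1 = y == classes[1]
    if idx0.sum() < 2 or idx1.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    mu0 = X[idx0].mean(axis=0)
    mu1 = X[idx1].mean(axis=0)
    z = X.copy()
    z[idx0] -= mu0
    z[idx1] -= mu1
    lam, S, nu = ledoit_wolf_shrinkage(z)
    p = X.shape[1]
    sigma_hat = (1.0 - lam) * S + lam * nu * np.eye(p)
    try:
        w = np.linalg.solve(sigma_hat, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular (lambda = 0 on degenerate "
            "data); consider a positive shrinkage floor"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError(
            "non-finite discriminant weights; covariance effectively "
            "singular — consider a positive shrinkage floor"
        )
    b = float(w @ (mu0 + mu1) / 2.0)
    return LdaModel(mu0=mu0, mu1=mu1, sigma_hat=sigma_hat, lam=lam, w=w, b=b)


def decision_scores(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Linear read-out ``w . x - b``; higher means class 1."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.w):
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"dimension {len(model.w)}"
        )
    return X @ model.w - model.b


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC (Mann-Whitney, ties count 1/2) and the ROC curve.

    The curve is produced by sweeping a threshold over the unique scores
    (tied scores grouped), giving points from (0, 0) to (1, 1) whose
    trapezoidal area equals the returned AUC exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(scores)
    auc = (float(ranks[pos].sum()) - n1 * (n1 + 1) / 2.0) / (n0 * n1)

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = pos[order].astype(int)
    # indices where a run of tied scores ends
    ends = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.concatenate([ends, [len(s_sorted) - 1]])
    tp = np.cumsum(y_sorted)[ends] / n1
    fp = np.cumsum(1 - y_sorted)[ends] / n0
    roc = np.column_stack(
        [np.concatenate([[0.0], fp]), np.concatenate([[0.0], tp])]
    )
    return auc, roc


def _stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded-shuffle stratified fold ids, balanced within each class."""
    fold = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = np.arange(len(idx)) % k
    return fold


def _contiguous_folds(order: np.ndarray, k: int) -> np.ndarray:
    """Fold ids by temporally contiguous blocks along ``order``."""
    n = len(order)
    fold = np.empty(n, dtype=int)
    fold[order] = (np.arange(n) * k) // n
    return fold


def crossval_auc(
    dataset: LabeledDataset, k: int = 10, seed: int = 0,
    folds: str = "stratified",
) -> DecodingResult:
    """Stratified k-fold cross-validated AUC with pooled out-of-fold scores.

    By default folds are assigned by a seeded shuffle within each class;
    each sample is scored exactly once by a model that never saw it.  If
    the smaller class has fewer than ``k`` samples, ``k`` is reduced to
    that size with a warning.

    ``folds="contiguous"`` assigns temporally contiguous blocks (by
    window index) instead.  This choice is material: interleaved random
    folds let temporally autocorrelated features leak between train and
    test windows, which inflates absolute AUCs; block folds suppress the
    leakage.  The permutation null in :mod:`hipponav.inference` re-runs
    whichever policy is used, so significance testing stays calibrated
    under either.
    """
    X = np.asarray(dataset.features, dtype=float)
    y = np.asarray(dataset.labels)
    counts = np.unique(y, return_counts=True)[1]
    if len(counts) != 2 or counts.min() < 2:
        raise ValueError("need two classes with at least 2 samples each")
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        log.warning("reducing folds from %d to %d (smallest class size)", k, k_eff)
    rng = np.random.default_rng(seed)
    if folds == "stratified":
        fold = _stratified_folds(y, k_eff, rng)
    elif folds == "contiguous":
        fold = _contiguous_folds(np.argsort(dataset.window_index, kind="stable"),
                                 k_eff)
        for f in range(k_eff):
            train_y = y[fold != f]
            vals, cnts = np.unique(train_y, return_counts=True)
            if len(vals) != 2 or cnts.min() < 2:
                raise ValueError(
                    "contiguous folds leave a training split without two "
                    "populated classes; use fewer folds or stratified folds"
                )
    else:
        raise ValueError(f"unknown fold policy {folds!r}")
    y01 = (y == np.unique(y)[1]).astype(int)
    scores = np.empty(len(y), dtype=float)
    for f in range(k_eff):
        test = fold == f
        model = fit_shrinkage_lda(X[~test], y01[~test])
        scores[test] = decision_scores(model, X[test])
    auc, roc = roc_auc(scores, y01)
    return DecodingResult(
        auc=auc, roc_points=roc, scores=scores, fold_assignment=fold,
        seed=seed, k=k_eff,
    )
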