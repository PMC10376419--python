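"""Logistic disease-risk estimation on latent factor scores.

Training uses stratified k-fold cross-validation with SMOTE class balancing
applied inside each training fold only (synthetic minority points are
interpolations between minority nearest neighbors — never derived from
test-fold samples), maximum-likelihood logistic regression, and empirical
ROC/AUC evaluation of the pooled out-of-fold predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .exceptions import DomainError, ResamplingError

logger = logging.getLogger(__name__)


def smote(minority: np.ndarray, k: int, target_size: int,
          seed: int = 0) -> np.ndarray:
    """Synthetic minority oversampling.

    Each synthetic point is x + u (nn_j(x) - x) with u ~ Uniform(0, 1) and
    nn_j a random one of x's k nearest minority neighbors (Euclidean,
    excluding x itself). Returns the (target_size - len(minority)) new points.
    """
    minority = np.atleast_2d(np.asarray(minority, dtype=float))
    m = minority.shape[0]
    if m < 2:
        raise ResamplingError("SMOTE needs a minority class of >= 2 points")
    k = min(k, m - 1)
    if k < 1:
        raise ResamplingError("SMOTE needs k >= 1 neighbor")
    n_new = target_size - m
    if n_new <= 0:
        return np.empty((0, minority.shape[1]))
    d = np.linalg.norm(minority[:, None, :] - minority[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :k]  # (m, k)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, m, n_new)
    neigh = nn[base, rng.integers(0, k, n_new)]
    u = rng.uniform(0.0, 1.0, n_new)[:, None]
    return minority[base] + u * (minority[neigh] - minority[base])


def _smote_balance(X: np.ndarray, y: np.ndarray, k: int, seed: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() == counts.max():
        return X, y
    minor = classes[np.argmin(counts)]
    target = counts.max()
    synth = smote(X[y == minor], k, target, seed=seed)
    if len(synth) == 0:
        return X, y
    return (np.vstack([X, synth]),
            np.concatenate([y, np.full(len(synth), minor, dtype=y.dtype)]))


@dataclass
class RiskModel:
    coefficients: dict[str, float]       # intercept + one per latent score
    folds: list[dict]                    # per-fold train/test sample ids
    seed: int
    separation_flagged: bool = False
    per_fold_auc: list[float] = field(default_factory=list)


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # bounded iterations under separation
        model.fit(X, y)
    return model


def fit_cv(scores: pd.DataFrame, outcome, n_folds: int = 10, seed: int = 0,
           smote_k: int = 5) -> tuple[RiskModel, np.ndarray]:
    """SMOTE-balanced stratified k-fold logistic regression.

    Returns the final model (refit on the fully balanced data) and the
    out-of-fold predicted case probabilities, in sample order. The fold
    count shrinks to the minority class size when needed so every fold keeps
    both classes.
    """
    X = scores.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=int)
    ids = list(scores.index)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise DomainError("outcome must have exactly two classes")
    eff_folds = min(n_folds, int(counts.min()))
    if eff_folds < n_folds:
        logger.warning("reducing folds from %d to %d to keep both classes per fold",
                       n_folds, eff_folds)
    if eff_folds < 2:
        raise DomainError("minority class too small for cross-validation")

    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    folds, per_fold_auc = [], []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        k_eff = min(smote_k, max(int(np.bincount(y[tr]).min()) - 1, 1))
        Xb, yb = _smote_balance(X[tr], y[tr], k_eff, seed=seed * 1000 + f)
        model = _fit_logistic(Xb, yb)
        oof[te] = model.predict_proba(X[te])[:, 1]
        folds.append({"fold": f, "train": [ids[i] for i in tr],
                      "test": [ids[i] for i in te]})
        if len(np.unique(y[te])) == 2:
            per_fold_auc.append(roc_auc(oof[te], y[te]).auc)

    k_eff = min(smote_k, max(int(counts.min()) - 1, 1))
    Xb, yb = _smote_balance(X, y, k_eff, seed=seed * 1000 + eff_folds)
    final = _fit_logistic(Xb, yb)
    coefs = {"intercept": float(final.intercept_[0])}
    coefs.update({c: float(v) for c, v in zip(scores.columns, final.coef_[0])})
    flagged = max(abs(v) for v in coefs.values()) > 25.0
    if flagged:
        logger.warning("possible complete separation: very large coefficients")
    model = RiskModel(coefs, folds, seed, flagged, per_fold_auc)
    return model, oof


def roc_auc(predicted, outcome) -> RocResult:
    """Empirical ROC over all thresholds; trapezoid AUC (= tie-corrected
    Mann-Whitney statistic of the predicted scores)."""
    y = np.asarray(outcome, dtype=int)
    s = np.asarray(predicted, dtype=float)
    if len(np.unique(y)) != 2:
        raise DomainError("both outcome classes must be present")
    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(thr, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def plot_roc(roc: RocResult, path, label: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, label=f"{label} AUC = {roc.auc:.2f}".strip())
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
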