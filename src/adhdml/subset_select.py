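"""Optimal feature-subset selection by external cross-validation.

The number of top-ranked features to keep is chosen by 10-fold
cross-validation that is *external* to the feature ranking: within each
fold, features are ranked by mSVM-RFE on the training nine-tenths only,
an RBF-kernel SVM is tuned and trained on the top-k features for each
candidate k, and accuracy is measured on the held-out tenth. Averaging
across folds gives an accuracy-vs-k curve whose maximum picks k*; because
the held-out samples never inform ranking, scaling or tuning, the curve is
an unbiased estimate of generalization accuracy.

Hyperparameters (soft-margin penalty C and RBF kernel width gamma) are
tuned by internal stratified 10-fold grid search on a log2-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .rfe import RfeConfig, msvm_rfe_rank

__all__ = [
    "SvmHyperparams",
    "CvCurve",
    "SubsetSelectConfig",
    "default_k_grid",
    "FULL_C_GRID",
    "FULL_GAMMA_GRID",
    "COARSE_C_GRID",
    "COARSE_GAMMA_GRID",
    "tune_rbf_svm",
    "external_cv_curve",
    "select_optimal_k",
]

# Full tuning grid: C in 2^-5..2^15, kernel width in 2^-15..2^3, log2-spaced.
FULL_C_GRID = tuple(2.0**e for e in range(-5, 16))
FULL_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4))
# Coarse subgrid (log2 step 4) used inside the nested external-CV loop,
# where the grid search runs once per (fold, k).
COARSE_C_GRID = tuple(2.0**e for e in range(-5, 16, 4))
COARSE_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 4))


@dataclass(frozen=True)
class SvmHyperparams:
    """Tuned RBF-SVM hyperparameters (both positive, from the search grid)."""

    C: float
    rbf_width: float

    def make_svc(self) -> SVC:
        return SVC(kernel="rbf", C=self.C, gamma=self.rbf_width)


@dataclass
class CvCurve:
    """Externally cross-validated accuracy as a function of top-k features."""

    k_values: list[int]
    mean_accuracy: list[float]
    fold_accuracy: np.ndarray  # n_folds x n_k
    best_k: int
    expected_accuracy: float

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"k": self.k_values, "mean_accuracy": self.mean_accuracy}
        )
        for f in range(self.fold_accuracy.shape[0]):
            df[f"fold{f}_accuracy"] = self.fold_accuracy[f]
        return df


@dataclass
class SubsetSelectConfig:
    """Parameters of external-CV subset selection."""

    n_folds: int = 10
    k_grid: tuple[int, ...] | None = None
    rfe: RfeConfig = field(default_factory=RfeConfig)
    c_grid: tuple[float, ...] = COARSE_C_GRID
    gamma_grid: tuple[float, ...] = COARSE_GAMMA_GRID
    inner_folds: int = 10
    balanced: bool = False
    seed: int = 0


def default_k_grid(n_features: int) -> tuple[int, ...]:
    """Approximately geometric ladder of candidate subset sizes.

    1, 2, 5, 10, 25, 50, 100, 250, ... capped at the feature count.
    """
    ladder = [1, 2, 5, 10, 25, 50, 100, 250, 500, 1000, 2500, 5000, 10000,
              25000, 50000, 100000]
    grid = [k for k in ladder if k < n_features]
    grid.append(n_features)
    return tuple(grid)


def _score(y_true, y_pred, balanced: bool) -> float:
    if balanced:
        return float(balanced_accuracy_score(y_true, y_pred))
    return float(accuracy_score(y_true, y_pred))


def tune_rbf_svm(
    X,
    y,
    c_grid: tuple[float, ...] = FULL_C_GRID,
    gamma_grid: tuple[float, ...] = FULL_GAMMA_GRID,
    n_folds: int = 10,
    seed: int = 0,
    balanced: bool = False,
) -> tuple[SvmHyperparams, float]:
    """Grid-search RBF-SVM hyperparameters by internal stratified k-fold CV.

    Returns the best (C, kernel width) pair and its internal CV accuracy;
    ties resolve to the smaller C, then the smaller width. Features are
    standardized inside each training fold.
    """
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y)
    n_folds = min(n_folds, int(np.bincount(pd.factorize(y)[0]).min()))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = (None, -np.inf)
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            preds = np.empty(len(y), dtype=object)
            for tr, te in splits:
                clf = make_pipeline(
                    StandardScaler(), SVC(kernel="rbf", C=C, gamma=gamma)
                )
                clf.fit(X[tr], y[tr])
                preds[te] = clf.predict(X[te])
            acc = _score(y, preds, balanced)
            if acc > best[1] + 1e-12:  # strict improvement: ties keep smaller C, gamma
                best = (SvmHyperparams(C=C, rbf_width=gamma), acc)
    return best


def external_cv_curve(X, y, cfg: SubsetSelectConfig | None = None) -> CvCurve:
    """Accuracy-vs-k curve from ranking-external stratified 10-fold CV.

    Per fold: mSVM-RFE ranks features on the training rows only; for every
    k in the grid an RBF-SVM is tuned (internal CV on the training rows)
    and scored on the held-out rows. No information flows from a held-out
    fold into ranking, standardization or tuning.
    """
    cfg = cfg or SubsetSelectConfig()
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y)
    if len(y) < 20:
        raise ValueError("need at least 20 observations for 10-fold selection")
    k_grid = cfg.k_grid or default_k_grid(Xa.shape[1])
    k_grid = tuple(min(k, Xa.shape[1]) for k in k_grid)
    k_grid = tuple(dict.fromkeys(k_grid))  # dedupe after truncation, keep order
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    name_to_col = {n: j for j, n in enumerate(names)}
    fold_acc = np.zeros((cfg.n_folds, len(k_grid)))
    for f, (tr, te) in enumerate(skf.split(Xa, y)):
        fold_rfe = RfeConfig(
            C=cfg.rfe.C,
            n_subsamples=cfg.rfe.n_subsamples,
            subsample_fraction=cfg.rfe.subsample_fraction,
            drop_half_threshold=cfg.rfe.drop_half_threshold,
            seed=cfg.rfe.seed + f,
        )
        ranked = msvm_rfe_rank(
            pd.DataFrame(Xa[tr], columns=names), y[tr], fold_rfe
        )
        for ki, k in enumerate(k_grid):
            cols = [name_to_col[n] for n in ranked.top(k)]
            hp, _ = tune_rbf_svm(
                Xa[np.ix_(tr, cols)], y[tr],
                c_grid=cfg.c_grid, gamma_grid=cfg.gamma_grid,
                n_folds=cfg.inner_folds, seed=cfg.seed + f,
                balanced=cfg.balanced,
            )
            clf = make_pipeline(StandardScaler(), hp.make_svc())
            clf.fit(Xa[np.ix_(tr, cols)], y[tr])
            fold_acc[f, ki] = _score(
                y[te], clf.predict(Xa[np.ix_(te, cols)]), cfg.balanced
            )
    mean_acc = fold_acc.mean(axis=0)
    best_idx = int(np.argmax(mean_acc))  # first argmax: ties -> smallest k
    return CvCurve(
        k_values=list(k_grid),
        mean_accuracy=mean_acc.tolist(),
        fold_accuracy=fold_acc,
        best_k=int(k_grid[best_idx]),
        expected_accuracy=float(mean_acc[best_idx]),
    )


def select_optimal_k(curve: CvCurve) -> int:
    """k attaining the maximum mean hold-out accuracy (ties: smallest k)."""
    if not curve.k_values:
        raise ValueError("empty curve")
    best_idx = int(np.argmax(curve.mean_accuracy))
    return int(curve.k_values[best_idx])
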