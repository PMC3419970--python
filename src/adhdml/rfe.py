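"""Linear SVM recursive feature elimination with multi-subsample stabilization.

Features are ranked by backward elimination: on each pass a soft-margin
linear SVM is fitted to the surviving (standardized) features and the
feature(s) with the smallest weight-based criterion are removed, never to
be reconsidered. Two refinements are applied for scale and stability:

* an accelerated schedule that drops half of the surviving features per
  pass while more than ``drop_half_threshold`` (default 5000) remain, then
  switches to one-by-one elimination for accurate top rankings;
* multiple-subsample (mSVM-RFE) stabilization: per pass, several linear
  SVMs are fitted to stratified subsamples and each feature's criterion is
  the mean of its squared weight across subsamples divided by the standard
  deviation of that squared weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "RfeConfig",
    "RankedFeatureList",
    "linear_svm_weights",
    "svm_rfe_rank",
    "msvm_rfe_rank",
]


@dataclass
class RfeConfig:
    """Parameters of the (m)SVM-RFE ranking run."""

    C: float = 1.0
    n_subsamples: int = 10
    subsample_fraction: float = 0.9
    drop_half_threshold: int = 5000
    seed: int = 0

    def validate(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")


@dataclass
class RankedFeatureList:
    """Ranked feature names (rank 1 = most useful) with the elimination log.

    ``elimination_log`` records, per pass, the features removed on that
    pass; the ranking is the reverse of elimination order.
    """

    features: list[str]
    elimination_log: list[list[str]] = field(default_factory=list)

    def top(self, k: int) -> list[str]:
        return self.features[:k]

    def rank_of(self, name: str) -> int:
        return self.features.index(name) + 1


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"f{j}" for j in range(X.shape[1])]


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    if counts.min() < 2:
        raise ValueError("need at least 2 observations per class")
    return y


def linear_svm_weights(X, y, C: float = 1.0) -> np.ndarray:
    """Weight vector of a soft-margin linear SVM on standardized features.

    Features are standardized to mean 0, sd 1 on the rows passed in (and
    only those rows), so weight magnitudes are commensurate across
    features.
    """
    X, _ = _as_matrix(X)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    y = _check_labels(y)
    clf = SVC(kernel="linear", C=C)
    clf.fit(_standardize(X), y)
    return clf.coef_.ravel()


def _stratified_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a class-stratified subsample without replacement.

    Guarantees at least 2 rows per class so the SVM fit is well-posed.
    """
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        n_take = max(2, int(round(fraction * len(members))))
        n_take = min(n_take, len(members))
        idx.append(rng.choice(members, size=n_take, replace=False))
    return np.sort(np.concatenate(idx))


def _pass_criterion(
    X: np.ndarray, y: np.ndarray, cfg: RfeConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-feature usefulness criterion for one elimination pass."""
    if cfg.n_subsamples == 1 and cfg.subsample_fraction == 1.0:
        w = linear_svm_weights(X, y, C=cfg.C)
        return w**2
    w2 = np.empty((cfg.n_subsamples, X.shape[1]))
    for s in range(cfg.n_subsamples):
        idx = _stratified_subsample(y, cfg.subsample_fraction, rng)
        w = linear_svm_weights(X[idx], y[idx], C=cfg.C)
        w2[s] = w**2
    mean = w2.mean(axis=0)
    sd = w2.std(axis=0)
    return mean / (sd + 1e-12)


def _rfe(X, y, cfg: RfeConfig, multiple: bool) -> RankedFeatureList:
    cfg.validate()
    X, names = _as_matrix(X)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    y = _check_labels(y)
    rng = np.random.default_rng(cfg.seed)

    surviving = list(range(X.shape[1]))
    eliminated: list[int] = []
    log: list[list[str]] = []
    single_cfg = RfeConfig(
        C=cfg.C, n_subsamples=1, subsample_fraction=1.0,
        drop_half_threshold=cfg.drop_half_threshold, seed=cfg.seed,
    )
    pass_cfg = cfg if multiple else single_cfg
    while len(surviving) > 1:
        crit = _pass_criterion(X[:, surviving], y, pass_cfg, rng)
        # stable argsort: ties broken by original column order (surviving is
        # kept in ascending original-index order)
        order = np.argsort(crit, kind="stable")
        n_drop = len(surviving) // 2 if len(surviving) > cfg.drop_half_threshold else 1
        drop_local = order[:n_drop]
        dropped = [surviving[i] for i in drop_local]  # ascending criterion
        eliminated.extend(dropped)
        log.append([names[i] for i in dropped])
        drop_set = set(drop_local.tolist())
        surviving = [s for k, s in enumerate(surviving) if k not in drop_set]
    eliminated.extend(surviving)
    log.append([names[i] for i in surviving])
    ranked = [names[i] for i in reversed(eliminated)]
    return RankedFeatureList(features=ranked, elimination_log=log)


def svm_rfe_rank(X, y, cfg: RfeConfig | None = None) -> RankedFeatureList:
    """Single-fit SVM-RFE ranking (criterion: squared linear-SVM weight)."""
    return _rfe(X, y, cfg or RfeConfig(), multiple=False)


def msvm_rfe_rank(X, y, cfg: RfeConfig | None = None) -> RankedFeatureList:
    """Multiple-subsample SVM-RFE ranking.

    Per pass, ``cfg.n_subsamples`` linear SVMs are fitted on stratified
    subsamples of fraction ``cfg.subsample_fraction``; the elimination
    criterion is mean(w^2)/sd(w^2) per feature. With one subsample at
    fraction 1 this reduces exactly to :func:`svm_rfe_rank`. Deterministic
    given ``cfg.seed``.
    """
    return _rfe(X, y, cfg or RfeConfig(), multiple=True)
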