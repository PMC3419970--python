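"""Per-site, per-modality RBF-SVM classifiers and cross-site alignment.

Each study site gets its own classifier per feature modality, trained on
all of that site's labeled subjects using only the top-k* ranked features,
standardized by the site's own training statistics. Sites lacking labeled
training data are handled by cross-site mean alignment: feature means are
aligned on the typically-developing subgroup when labels are available
(preserving the class contrast exactly), or on all subjects together when
they are not, after which an across-site classifier applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .rfe import RankedFeatureList
from .subset_select import SvmHyperparams

__all__ = [
    "TrainedSiteModel",
    "train_site_model",
    "predict",
    "align_sites_by_td",
    "align_sites_unlabeled",
]


@dataclass
class TrainedSiteModel:
    """Fitted site + modality classifier.

    Predicts only from its selected features; refuses input missing any of
    them unless median imputation is enabled at predict time.
    """

    site: str
    modality: str
    features: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    hyperparams: SvmHyperparams
    classifier: SVC
    class_priors: dict[str, float]
    subtype_priors: dict[str, float] = field(default_factory=dict)
    feature_medians: np.ndarray | None = None

    def transform(self, X: pd.DataFrame, impute: bool = False) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing and not impute:
            raise ValueError(
                f"missing feature column(s) for {self.site}/{self.modality}: "
                + ", ".join(missing)
            )
        cols = {}
        for j, f in enumerate(self.features):
            if f in X.columns:
                col = X[f].to_numpy(dtype=float)
                if impute and np.isnan(col).any():
                    col = np.where(np.isnan(col), self.feature_medians[j], col)
            else:
                col = np.full(len(X), self.feature_medians[j])
            cols[f] = col
        mat = np.column_stack([cols[f] for f in self.features])
        return (mat - self.scaler_mean) / self.scaler_sd


def train_site_model(
    X_site: pd.DataFrame,
    y_site,
    ranked: RankedFeatureList | list[str],
    k_star: int,
    hyperparams: SvmHyperparams,
    site: str = "",
    modality: str = "",
    subtype_counts: dict[str, int] | None = None,
) -> TrainedSiteModel:
    """Fit the final site model on all labeled site rows.

    Uses the top ``k_star`` ranked features, standardized by the site's own
    training mean/sd. A single-class site cannot be fitted here and is
    directed to the cross-site alignment path.
    """
    y = np.asarray(y_site)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(
            f"site {site!r} has a single training class; use cross-site "
            "alignment (align_sites_by_td / align_sites_unlabeled) instead"
        )
    feats = ranked.top(k_star) if isinstance(ranked, RankedFeatureList) else list(ranked)[:k_star]
    missing = [f for f in feats if f not in X_site.columns]
    if missing:
        raise ValueError("training matrix lacks selected feature(s): " + ", ".join(missing))
    mat = X_site[feats].to_numpy(dtype=float)
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    clf = hyperparams.make_svc()
    clf.fit((mat - mu) / sd, y)
    priors = {str(c): float(n) / len(y) for c, n in zip(classes, counts)}
    total_sub = sum((subtype_counts or {}).values())
    sub_priors = {
        k: v / total_sub for k, v in (subtype_counts or {}).items()
    } if total_sub else {}
    return TrainedSiteModel(
        site=site,
        modality=modality,
        features=feats,
        scaler_mean=mu,
        scaler_sd=sd,
        hyperparams=hyperparams,
        classifier=clf,
        class_priors=priors,
        subtype_priors=sub_priors,
        feature_medians=np.median(mat, axis=0),
    )


def predict(model: TrainedSiteModel, X_new: pd.DataFrame, impute: bool = False) -> np.ndarray:
    """Predict 2-class labels for new rows; deterministic.

    Raises a named error for any missing selected feature column unless
    ``impute`` is set, in which case the site-training median fills in.
    """
    return model.classifier.predict(model.transform(X_new, impute=impute))


# ---------------------------------------------------------------------------
# Cross-site alignment


def _check_aligned_columns(mats: dict[str, pd.DataFrame]) -> list[str]:
    cols = None
    for site, X in mats.items():
        if cols is None:
            cols = list(X.columns)
        elif list(X.columns) != cols:
            raise ValueError(f"site {site!r} has mismatched feature columns")
    return cols or []


def align_sites_by_td(
    mats: dict[str, pd.DataFrame], labels: dict[str, np.ndarray]
) -> dict[str, pd.DataFrame]:
    """Align site feature means on the typically-developing subgroup.

    For every feature and site, the site's TD mean is subtracted and the
    pooled (across-site) TD mean added, so after adjustment each site's TD
    mean equals the pooled TD mean exactly while within-site class
    contrasts are untouched (a pure shift). Sites need >= 2 TD subjects;
    a site with no TD rows belongs on :func:`align_sites_unlabeled`.
    """
    _check_aligned_columns(mats)
    td_rows = []
    for site, X in mats.items():
        is_td = np.asarray(labels[site]) == "TD"
        if is_td.sum() < 2:
            raise ValueError(
                f"site {site!r} has fewer than 2 TD subjects; use "
                "align_sites_unlabeled"
            )
        td_rows.append(X.loc[is_td])
    pooled_td_mean = pd.concat(td_rows).mean(axis=0)
    out = {}
    for site, X in mats.items():
        is_td = np.asarray(labels[site]) == "TD"
        site_td_mean = X.loc[is_td].mean(axis=0)
        out[site] = X - site_td_mean + pooled_td_mean
    return out


def align_sites_unlabeled(mats: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Align site feature means on all subjects together.

    The cruder adjustment for sites whose class labels are unknown: each
    site's grand mean is replaced by the pooled grand mean. With a single
    site the round trip is the identity.
    """
    _check_aligned_columns(mats)
    for site, X in mats.items():
        if len(X) < 2:
            raise ValueError(f"site {site!r} needs >= 2 subjects to align")
    pooled_mean = pd.concat(list(mats.values())).mean(axis=0)
    return {site: X - X.mean(axis=0) + pooled_mean for site, X in mats.items()}
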