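"""Modality voting, subtype assignment, scoring and prevalence statistics.

Modality-level 2-class predictions are combined by simple majority vote
(ties default to TD, the majority training class). Subjects voted ADHD are
assigned a subtype from the site-specific pretest probabilities: the modal
subtype among that site's ADHD training subjects. Predictions are scored
with the competition-style metrics: 3-class accuracy, 2-class sensitivity
and specificity, subtype accuracy among correctly detected ADHD, and a
point total (1 point for a correct TD, 1 for a correct ADHD with correct
subtype, half a point for a correct ADHD with wrong subtype).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "PredictionSet",
    "ScoreReport",
    "DEFAULT_POINT_SCHEME",
    "majority_vote",
    "assign_subtype",
    "combine_votes",
    "score_predictions",
    "prevalence_stats",
    "round_half_away",
]

DEFAULT_POINT_SCHEME = {
    "correct_td": 1.0,
    "correct_adhd_correct_subtype": 1.0,
    "correct_adhd_wrong_subtype": 0.5,
    "incorrect": 0.0,
}


@dataclass
class PredictionSet:
    """Per-subject votes and final 2-/3-class labels.

    ``table`` columns: subject_id, site, one ``vote_<modality>`` column per
    contributing model, ``final_2class`` (TD/ADHD) and ``final_3class``
    (TD, ADHD-C or ADHD-I; subtype present iff the 2-class label is ADHD).
    """

    table: pd.DataFrame


@dataclass
class ScoreReport:
    accuracy_3class: float
    sensitivity: float
    specificity: float
    subtype_accuracy: float
    points: float
    max_points: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy_3class": self.accuracy_3class,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "subtype_accuracy": self.subtype_accuracy,
            "points": self.points,
            "max_points": self.max_points,
        }


def majority_vote(votes, tie_label: str = "TD") -> str:
    """Modal label of a non-empty vote list; ties resolve to ``tie_label``.

    The TD default reflects the emphasis on correct TD diagnoses in a
    majority-TD sample. Permutation-invariant in the vote list.
    """
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote set")
    labels, counts = np.unique(votes, return_counts=True)
    top = counts.max()
    winners = set(labels[counts == top])
    if len(winners) > 1:
        return tie_label
    return str(winners.pop())


def assign_subtype(
    site: str, training_phenotypes: pd.DataFrame, subtypes=("ADHD-C", "ADHD-I")
) -> str:
    """Modal ADHD subtype among a site's ADHD training subjects.

    Falls back to the pooled modal subtype when the site has no ADHD
    training subjects; ties resolve to ADHD-C (the overall more prevalent
    subtype).
    """
    pheno = training_phenotypes
    adhd = pheno[pheno["dx"].isin(subtypes)]
    site_adhd = adhd[adhd["site"] == site]
    pool = site_adhd if len(site_adhd) else adhd
    if not len(pool):
        raise ValueError("no ADHD training subjects to derive a subtype from")
    counts = pool["dx"].value_counts()
    top = counts.max()
    winners = set(counts[counts == top].index)
    return "ADHD-C" if "ADHD-C" in winners else counts.idxmax()


def combine_votes(
    votes: pd.DataFrame,
    training_phenotypes: pd.DataFrame,
    tie_label: str = "TD",
) -> PredictionSet:
    """Vote across modality predictions and attach subtypes.

    ``votes`` has columns subject_id, site, and one ``vote_*`` column per
    modality holding TD/ADHD labels.
    """
    vote_cols = [c for c in votes.columns if c.startswith("vote_")]
    if not vote_cols:
        raise ValueError("no vote_* columns present")
    table = votes.copy()
    table["final_2class"] = [
        majority_vote([row[c] for c in vote_cols], tie_label=tie_label)
        for _, row in votes.iterrows()
    ]
    table["final_3class"] = [
        assign_subtype(row["site"], training_phenotypes)
        if row["final_2class"] != "TD"
        else "TD"
        for _, row in table.iterrows()
    ]
    return PredictionSet(table=table)


def score_predictions(
    pred: PredictionSet | pd.DataFrame,
    truth: pd.DataFrame,
    point_scheme: dict[str, float] | None = None,
) -> ScoreReport:
    """Score 3-class predictions against true labels.

    ``truth`` has columns subject_id and dx (TD / ADHD-C / ADHD-I);
    sensitivity and specificity are computed on the 2-class collapse, and
    subtype accuracy among true-ADHD subjects predicted ADHD.
    """
    scheme = point_scheme or DEFAULT_POINT_SCHEME
    table = pred.table if isinstance(pred, PredictionSet) else pred
    merged = table.merge(truth[["subject_id", "dx"]], on="subject_id", how="outer",
                         indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", "subject_id"].tolist()
        raise ValueError(f"prediction/truth subject mismatch: {bad}")
    pred3 = merged["final_3class"].to_numpy()
    true3 = merged["dx"].to_numpy()
    pred_adhd = merged["final_2class"].to_numpy() != "TD"
    true_adhd = true3 != "TD"

    n = len(merged)
    acc3 = float((pred3 == true3).mean())
    sens = float(pred_adhd[true_adhd].mean()) if true_adhd.any() else np.nan
    spec = float((~pred_adhd[~true_adhd]).mean()) if (~true_adhd).any() else np.nan
    detected = true_adhd & pred_adhd
    subtype_acc = (
        float((pred3[detected] == true3[detected]).mean()) if detected.any() else np.nan
    )
    points = 0.0
    for p3, t3, pa, ta in zip(pred3, true3, pred_adhd, true_adhd):
        if not ta and not pa:
            points += scheme["correct_td"]
        elif ta and pa:
            points += (
                scheme["correct_adhd_correct_subtype"]
                if p3 == t3
                else scheme["correct_adhd_wrong_subtype"]
            )
        else:
            points += scheme["incorrect"]
    return ScoreReport(
        accuracy_3class=acc3,
        sensitivity=sens,
        specificity=spec,
        subtype_accuracy=subtype_acc,
        points=points,
        max_points=float(n),
    )


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (285/776 -> 37%, 58/218 -> 27%)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def prevalence_stats(
    pheno: pd.DataFrame,
    by: str = "overall",
    include_subtypes: tuple[str, ...] = ("ADHD-C", "ADHD-H", "ADHD-I"),
    exclude_sites: tuple[str, ...] = (),
    decimals: int = 0,
) -> pd.DataFrame:
    """ADHD prevalence (percent) and subtype ratios by stratum.

    ``by`` is one of overall / site / gender. Subjects whose diagnosis is
    not TD and not in ``include_subtypes`` are excluded entirely (dropping
    e.g. the hyperactive-impulsive subtype changes both numerator and
    denominator, matching the two published counting conventions).
    Percentages are rounded half away from zero.
    """
    if not len(pheno):
        raise ValueError("empty phenotype table")
    df = pheno[~pheno["site"].isin(exclude_sites)].copy()
    df = df[(df["dx"] == "TD") | df["dx"].isin(include_subtypes)]
    if by == "overall":
        groups = {"overall": df}
    elif by in ("site", "gender"):
        groups = {str(k): g for k, g in df.groupby(by)}
    else:
        raise ValueError("by must be overall, site or gender")
    rows = []
    for name, g in groups.items():
        n = len(g)
        n_adhd = int((g["dx"] != "TD").sum())
        n_c = int((g["dx"] == "ADHD-C").sum())
        n_i = int((g["dx"] == "ADHD-I").sum())
        if n_c and n_i:
            frac = Fraction(n_c, n_i)
            ratio = f"{frac.numerator}:{frac.denominator}"
        else:
            ratio = f"{n_c}:{n_i}"
        rows.append(
            {
                "stratum": name,
                "n": n,
                "n_adhd": n_adhd,
                "prevalence_pct": round_half_away(100.0 * n_adhd / n, decimals)
                if n
                else np.nan,
                "subtype_ratio_c_to_i": ratio,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")
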