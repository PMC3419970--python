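import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhdml import ensemble as en


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes, expected",
        [
            (["ADHD", "ADHD", "TD"], "ADHD"),
            (["ADHD", "TD"], "TD"),  # tie rule favors TD
            (["ADHD"], "ADHD"),
            (["TD", "TD", "ADHD"], "TD"),
        ],
    )
    def test_modal_label(self, votes, expected):
        assert en.majority_vote(votes) == expected

    def test_configurable_tie_label(self):
        assert en.majority_vote(["ADHD", "TD"], tie_label="ADHD") == "ADHD"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            en.majority_vote([])

    @given(st.lists(st.sampled_from(["TD", "ADHD"]), min_size=1, max_size=9),
           st.randoms(use_true_random=False))
    @settings(deadline=None, max_examples=50)
    def test_permutation_invariance(self, votes, rnd):
        shuffled = list(votes)
        rnd.shuffle(shuffled)
        assert en.majority_vote(votes) == en.majority_vote(shuffled)


class TestAssignSubtype:
    @pytest.fixture()
    def train_pheno(self, adhd200_phenotypes):
        return adhd200_phenotypes

    def test_combined_heavy_site(self, train_pheno):
        # 18 combined vs 1 inattentive at the NI-like site
        assert en.assign_subtype("NI", train_pheno) == "ADHD-C"

    def test_inattentive_heavy_site(self, train_pheno):
        # 29 combined vs 49 inattentive at the Peking-like site
        assert en.assign_subtype("Peking", train_pheno) == "ADHD-I"

    def test_no_adhd_site_pooled_fallback(self, train_pheno):
        # TD-only site falls back to the pooled modal subtype (combined:
        # 163 vs 111 overall)
        assert en.assign_subtype("Pitt", train_pheno) == "ADHD-C"

    def test_tie_resolves_to_combined(self):
        pheno = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "site": ["X", "X"],
                "dx": ["ADHD-C", "ADHD-I"],
            }
        )
        assert en.assign_subtype("X", pheno) == "ADHD-C"


def make_predictions(rows):
    table = pd.DataFrame(
        rows, columns=["subject_id", "site", "final_2class", "final_3class"]
    )
    return en.PredictionSet(table=table)


class TestScoring:
    def test_all_correct_full_points(self):
        n = 195
        truth = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "dx": ["TD"] * 100 + ["ADHD-C"] * 50 + ["ADHD-I"] * 45,
            }
        )
        pred = make_predictions(
            [
                (f"s{i}", "X", "TD" if d == "TD" else "ADHD", d)
                for i, d in enumerate(truth["dx"])
            ]
        )
        rep = en.score_predictions(pred, truth)
        assert rep.points == 195
        assert rep.accuracy_3class == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.subtype_accuracy == 1.0

    def test_all_td_prediction_no_information(self):
        truth = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(20)],
                "dx": ["TD"] * 11 + ["ADHD-C"] * 9,
            }
        )
        pred = make_predictions(
            [(f"s{i}", "X", "TD", "TD") for i in range(20)]
        )
        rep = en.score_predictions(pred, truth)
        assert rep.accuracy_3class == pytest.approx(11 / 20)
        assert rep.specificity == 1.0
        assert rep.sensitivity == 0.0

    def test_half_points_for_wrong_subtype(self):
        # enumeration oracle on a 10-subject worked fixture with 2
        # wrong-subtype cases: 6*1 + 2*1 + 2*0.5 = 9.0
        truth = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(10)],
                "dx": ["TD"] * 6 + ["ADHD-C"] * 2 + ["ADHD-I"] * 2,
            }
        )
        rows = []
        for i, d in enumerate(truth["dx"]):
            if d == "TD":
                rows.append((f"s{i}", "X", "TD", "TD"))
            elif d == "ADHD-C":
                rows.append((f"s{i}", "X", "ADHD", "ADHD-C"))
            else:
                rows.append((f"s{i}", "X", "ADHD", "ADHD-C"))  # wrong subtype
        rep = en.score_predictions(make_predictions(rows), truth)
        assert rep.points == pytest.approx(9.0)
        assert rep.subtype_accuracy == pytest.approx(0.5)

    def test_consistency_identity(self):
        rng = np.random.default_rng(0)
        truth = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(50)],
                "dx": rng.choice(["TD", "ADHD-C", "ADHD-I"], 50),
            }
        )
        rows = [
            (
                f"s{i}",
                "X",
                rng.choice(["TD", "ADHD"]),
                "TD",
            )
            for i in range(50)
        ]
        rows = [
            (sid, site, p2, p2 if p2 == "TD" else "ADHD-C")
            for sid, site, p2, _ in rows
        ]
        rep = en.score_predictions(make_predictions(rows), truth)
        n_adhd = (truth["dx"] != "TD").sum()
        n_td = (truth["dx"] == "TD").sum()
        n_correct2 = rep.sensitivity * n_adhd + rep.specificity * n_td
        assert n_correct2 == pytest.approx(round(n_correct2))

    def test_subject_mismatch_rejected(self):
        truth = pd.DataFrame({"subject_id": ["a"], "dx": ["TD"]})
        pred = make_predictions([("b", "X", "TD", "TD")])
        with pytest.raises(ValueError):
            en.score_predictions(pred, truth)


class TestPrevalence:
    def test_overall_37_percent(self, adhd200_phenotypes):
        out = en.prevalence_stats(adhd200_phenotypes)
        assert out.loc["overall", "prevalence_pct"] == 37.0

    def test_excluding_td_only_sites_46_percent(self, adhd200_phenotypes):
        out = en.prevalence_stats(
            adhd200_phenotypes, exclude_sites=("Pitt", "WashU")
        )
        assert out.loc["overall", "prevalence_pct"] == 46.0

    def test_gender_gap(self, adhd200_phenotypes):
        out = en.prevalence_stats(
            adhd200_phenotypes, by="gender",
            exclude_sites=("Pitt", "WashU"),
            include_subtypes=("ADHD-C", "ADHD-I"),
        )
        assert out.loc["F", "prevalence_pct"] == 27.0
        assert out.loc["M", "prevalence_pct"] == 54.0

    def test_site_extremes_and_subtype_ratios(self, adhd200_phenotypes):
        out = en.prevalence_stats(
            adhd200_phenotypes, by="site", include_subtypes=("ADHD-C", "ADHD-I")
        )
        assert out.loc["NYU", "prevalence_pct"] == 55.0
        assert out.loc["NI", "subtype_ratio_c_to_i"] == "18:1"

    def test_kki_both_counting_conventions(self, adhd200_phenotypes):
        with_h = en.prevalence_stats(adhd200_phenotypes, by="site")
        without_h = en.prevalence_stats(
            adhd200_phenotypes, by="site", include_subtypes=("ADHD-C", "ADHD-I")
        )
        assert with_h.loc["KKI", "prevalence_pct"] == 27.0
        assert without_h.loc["KKI", "prevalence_pct"] == 26.0

    def test_all_td_zero(self):
        pheno = pd.DataFrame(
            {"subject_id": ["a", "b"], "site": ["X", "X"], "dx": ["TD", "TD"],
             "gender": ["F", "M"]}
        )
        out = en.prevalence_stats(pheno)
        assert out.loc["overall", "prevalence_pct"] == 0.0

    def test_rounding_half_away_from_zero(self):
        assert en.round_half_away(100 * 285 / 776) == 37.0
        assert en.round_half_away(100 * 58 / 218) == 27.0
        assert en.round_half_away(100 * 7 / 52, 1) == 13.5
        assert en.round_half_away(0.5) == 1.0
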