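"""Splitting, stage training, ROC cut-offs, and the sequential decision tree."""

import numpy as np
import pandas as pd
import pytest

from octriage.cascade import (
    STAGES,
    FittedTest,
    StageClassifier,
    TriageCascade,
    evaluate_cascade,
    roc_cutoff,
    run_cascade,
    site_score,
    split_train_cv,
)
from octriage.exceptions import (
    AlignmentError,
    ConfigurationError,
    CutoffError,
    DomainError,
    StratificationError,
    TrainingError,
)


class TestSplitTrainCv:
    def test_seven_three_split_of_ten_sites(self):
        labels = pd.Series([True] * 5 + [False] * 5, index=[f"s{i}" for i in range(10)])
        train, cv = split_train_cv(labels, 0.7, seed=0)
        assert len(train) == 7 and len(cv) == 3

    def test_no_site_leaks_across_sides(self):
        labels = pd.Series([True] * 6 + [False] * 8, index=[f"s{i}" for i in range(14)])
        train, cv = split_train_cv(labels, 0.7, seed=3)
        assert not set(train) & set(cv)
        assert set(train) | set(cv) == set(labels.index)

    def test_deterministic_under_seed(self):
        labels = pd.Series([True] * 5 + [False] * 5, index=[f"s{i}" for i in range(10)])
        assert split_train_cv(labels, 0.7, 9) == split_train_cv(labels, 0.7, 9)

    def test_small_stratum_raises(self):
        labels = pd.Series([True] * 9 + [False], index=[f"s{i}" for i in range(10)])
        with pytest.raises(StratificationError):
            split_train_cv(labels, 0.7, 0)


# linearly separable 2-D toy set
TOY_X = np.array([[0.0, 0.0], [0.2, 0.1], [1.0, 1.0], [0.9, 1.2]])
TOY_Y = np.array([0, 0, 1, 1])


class TestStageClassifier:
    def test_separable_toy_set_trains_to_perfect_accuracy(self):
        clf = StageClassifier().fit(TOY_X, TOY_Y)
        assert np.array_equal(clf.predict(TOY_X), TOY_Y)

    def test_label_swap_negates_decisions(self):
        d = StageClassifier().fit(TOY_X, TOY_Y).decision_function(TOY_X)
        d_swapped = StageClassifier().fit(TOY_X, 1 - TOY_Y).decision_function(TOY_X)
        assert np.all(np.sign(d) == -np.sign(d_swapped))

    def test_single_class_input_rejected(self):
        with pytest.raises(TrainingError):
            StageClassifier().fit(TOY_X, np.zeros(4))


class TestSiteScore:
    @pytest.mark.parametrize(
        "values,expected", [([1.0, -1.0], 0.0), ([0.2, 0.4, 0.6], 0.4)]
    )
    def test_mean(self, values, expected):
        assert site_score(values) == pytest.approx(expected)

    def test_symmetric_mirror_pairs_average_like_frames(self):
        frames = [0.3, -0.1, 0.5]
        duplicated = [v + d for v in frames for d in (+0.02, -0.02)]
        assert site_score(duplicated) == pytest.approx(site_score(frames))

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            site_score([])


class TestRocCutoff:
    def test_perfect_separation_gives_midpoint(self):
        cut = roc_cutoff(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert 0.2 < cut < 0.8
        assert cut == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(50))
    def test_youden_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.random(n) < 0.4
        scores = rng.normal(labels.astype(float), 1.0)
        cut = roc_cutoff(scores, labels)

        def j_at(t):
            called = scores >= t
            return (called & labels).sum() / labels.sum() + (
                (~called & ~labels).sum() / (~labels).sum()
            ) - 1

        best = max(j_at(t) for t in np.concatenate([scores - 1e-9, scores + 1e-9, [-np.inf, np.inf]]))
        assert j_at(cut) == pytest.approx(best, abs=1e-12)

    def test_single_class_labels_raise(self):
        with pytest.raises(CutoffError):
            roc_cutoff(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_identical_scores_raise(self):
        with pytest.raises(CutoffError):
            roc_cutoff(np.full(6, 0.5), np.array([0, 1, 0, 1, 0, 1]))


def _toy_cascade():
    """Hand-fitted cascade: stages threshold single feature coordinates."""

    class OneFeature:
        def __init__(self, idx, sign=1.0):
            self.idx, self.sign = idx, sign

        def decision_function(self, X):
            return self.sign * np.asarray(X)[:, self.idx]

    tests = {}
    for k, stage in enumerate(STAGES):
        tests[stage] = FittedTest(
            stage=stage, classifier=OneFeature(k), cutoff=0.5,
            n_train_sites=0, n_cv_sites=0,
        )
    return tests


def _toy_table(rows):
    recs = []
    for site, (f0, f1, f2) in rows.items():
        recs.append({"site_id": site, "f000": f0, "f001": f1, "f002": f2})
    return pd.DataFrame(recs)


class TestRunCascade:
    def test_positive_test1_short_circuits(self):
        table = _toy_table({"a": (1.0, 9.0, 9.0)})
        (pred,) = run_cascade(_toy_cascade(), table)
        assert pred.final_label == "refer_biopsy_oscc"
        assert "test2_dysplasia_vs_rest" not in pred.stage_calls
        assert "test3_hgd_vs_lgd" not in pred.stage_calls

    def test_all_negative_routes_to_monitoring(self):
        (pred,) = run_cascade(_toy_cascade(), _toy_table({"a": (0.0, 0.0, 0.0)}))
        assert pred.final_label == "routine_monitoring"

    def test_matches_manual_tree_replay(self):
        rng = np.random.default_rng(0)
        rows = {f"s{i}": tuple(rng.normal(0.5, 0.5, 3)) for i in range(40)}
        preds = {p.site_id: p.final_label for p in run_cascade(_toy_cascade(), _toy_table(rows))}
        for site, (f0, f1, f2) in rows.items():
            if f0 >= 0.5:
                expected = "refer_biopsy_oscc"
            elif f1 < 0.5:
                expected = "routine_monitoring"
            elif f2 >= 0.5:
                expected = "refer_biopsy_hgd"
            else:
                expected = "surveillance_lgd"
            assert preds[site] == expected

    def test_missing_stage_is_configuration_error(self):
        tests = _toy_cascade()
        del tests["test3_hgd_vs_lgd"]
        with pytest.raises(ConfigurationError):
            run_cascade(tests, _toy_table({"a": (0, 0, 0)}))


class TestEvaluateCascade:
    def _run(self, rows, truth):
        preds = run_cascade(_toy_cascade(), _toy_table(rows))
        return preds, evaluate_cascade(preds, pd.Series(truth))

    def test_perfect_classifier_scores_100(self):
        rows = {
            "o1": (1.0, 0, 0), "o2": (1.0, 0, 0),
            "h1": (0.0, 1.0, 1.0), "m1": (0.0, 1.0, 0.0),
            "n1": (0.0, 0.0, 0.0), "n2": (0.0, 0.0, 0.0),
        }
        truth = {
            "o1": "oscc", "o2": "oscc", "h1": "severe_dysplasia",
            "m1": "mild_dysplasia", "n1": "normal", "n2": "benign",
        }
        _, ev = self._run(rows, truth)
        for counts in ev.combined.values():
            assert counts["FN"] == 0 and counts["FP"] == 0

    def test_counts_conserve_reached_population(self):
        rng = np.random.default_rng(1)
        diagnoses = ["oscc", "mild_dysplasia", "moderate_dysplasia", "normal", "benign"]
        rows, truth = {}, {}
        for i in range(30):
            rows[f"s{i}"] = tuple(rng.normal(0.4, 0.4, 3))
            truth[f"s{i}"] = diagnoses[i % len(diagnoses)]
        preds, ev = self._run(rows, truth)
        for stage, (_pos, population) in STAGES.items():
            reached = sum(
                1
                for p in preds
                if stage in p.stage_calls and truth[p.site_id] in population
            )
            c = ev.per_stage[stage]
            assert c["TP"] + c["FP"] + c["TN"] + c["FN"] == reached

    def test_combined_sensitivity_dominates_stage_one(self):
        rng = np.random.default_rng(2)
        rows, truth = {}, {}
        for i in range(40):
            rows[f"s{i}"] = tuple(rng.normal(0.5, 0.6, 3))
            truth[f"s{i}"] = "oscc" if i % 3 == 0 else "normal"
        preds, ev = self._run(rows, truth)
        s1 = ev.per_stage["test1_oscc_vs_rest"]
        comb = ev.combined["oscc"]
        sens_1 = s1["TP"] / (s1["TP"] + s1["FN"])
        sens_c = comb["TP"] / (comb["TP"] + comb["FN"])
        assert sens_c >= sens_1

    def test_site_mismatch_raises(self):
        preds = run_cascade(_toy_cascade(), _toy_table({"a": (0, 0, 0)}))
        with pytest.raises(AlignmentError):
            evaluate_cascade(preds, pd.Series({"b": "normal"}))

    def test_raising_test1_cutoff_never_adds_referrals(self):
        rng = np.random.default_rng(3)
        rows = {f"s{i}": tuple(rng.normal(0.5, 0.5, 3)) for i in range(50)}
        table = _toy_table(rows)
        counts = []
        for cut in np.linspace(-0.5, 1.5, 10):
            tests = _toy_cascade()
            tests["test1_oscc_vs_rest"].cutoff = cut
            preds = run_cascade(tests, table)
            counts.append(sum(p.final_label == "refer_biopsy_oscc" for p in preds))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFittedCascadeOnCohort:
    """End-to-end training on the small synthetic cohort."""

    @pytest.fixture(scope="class")
    def fitted(self, small_features):
        return TriageCascade(seed=0).fit(small_features)

    def test_no_site_straddles_any_stage_split(self, fitted, small_features):
        for stage, t in fitted.tests_.items():
            assert t.n_train_sites > 0 and t.n_cv_sites > 0

    def test_stage1_separates_cohort_well(self, fitted, small_features):
        preds = fitted.predict(small_features)
        truth = (
            small_features.groupby("site_id")["diagnosis"].first()
        )
        ev = evaluate_cascade(preds, truth.loc[[p.site_id for p in preds]])
        c = ev.per_stage["test1_oscc_vs_rest"]
        acc = (c["TP"] + c["TN"]) / max(sum(c.values()), 1)
        assert acc >= 0.8
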