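import numpy as np
import pandas as pd
import pytest

from uhrv import (
    ModelSpec,
    cross_validate_select,
    evaluate_binary,
    features_to_wide,
    fit_predict,
    multiscale_assessment,
    select_features,
    split_subjects,
)
from uhrv.stress_classifier import _person_folds


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

class TestSplit:
    def test_42_subjects_split_25_17(self):
        ids = [f"S{i:03d}" for i in range(42)]
        split = split_subjects(ids, 0.6, seed=3)
        assert len(split.folder1) == 25
        assert len(split.folder2) == 17

    def test_reproducible_and_disjoint(self):
        ids = [f"S{i}" for i in range(20)]
        s1 = split_subjects(ids, seed=11)
        s2 = split_subjects(ids, seed=11)
        assert s1 == s2
        assert not set(s1.folder1) & set(s1.folder2)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            split_subjects(["a", "b", "c"])

    def test_person_independent_folds(self):
        subjects = np.repeat([f"S{i}" for i in range(12)], 2)
        folds = _person_folds(subjects, 3, seed=0)
        seen = [set(f) for f in folds]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not seen[i] & seen[j]


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _folder1_frame(columns: dict, subjects=None):
    """Wide folder-1 table at 300 s from per-feature rest/stress arrays."""
    n = len(next(iter(columns.values()))[0])
    subjects = subjects or [f"S{i}" for i in range(n)]
    rows = []
    for ci, cond in enumerate(("rest", "stress")):
        for si, subj in enumerate(subjects):
            row = {"subject": subj, "condition": cond, "scale_s": 300,
                   "window_index": np.nan}
            for feat, (rest_vals, stress_vals) in columns.items():
                row[feat] = (rest_vals if cond == "rest" else stress_vals)[si]
            rows.append(row)
    return pd.DataFrame(rows)


class TestSelectFeatures:
    def test_duplicated_feature_collapses_to_one(self):
        rng = np.random.default_rng(0)
        rest = rng.normal(900, 50, 15)
        stress = rest - 120 + rng.normal(0, 10, 15)
        df = _folder1_frame({"A": (rest, stress), "B": (rest, stress)})
        chosen = select_features(df, ["A", "B"])
        assert len(chosen) == 1

    def test_uncorrelated_relevant_features_all_survive(self):
        rng = np.random.default_rng(1)
        rest1, rest2 = rng.normal(900, 50, 15), rng.normal(500, 80, 15)
        df = _folder1_frame({
            "A": (rest1, rest1 - 150 + rng.normal(0, 5, 15)),
            "B": (rest2, rest2 + 200 + rng.normal(0, 5, 15)),
        })
        assert set(select_features(df, ["A", "B"])) == {"A", "B"}

    def test_monotone_transform_clusters(self):
        # MeanNN-like and its reciprocal transform correlate perfectly in
        # rank; an independent HF-like feature stays its own cluster
        rng = np.random.default_rng(2)
        mean_nn_rest = rng.normal(900, 60, 15)
        mean_nn_stress = mean_nn_rest - 150 + rng.normal(0, 10, 15)
        hf_rest = rng.normal(800, 150, 15)
        hf_stress = hf_rest - 500 + rng.normal(0, 30, 15)
        df = _folder1_frame({
            "MeanNN": (mean_nn_rest, mean_nn_stress),
            "MeanHR": (60000 / mean_nn_rest, 60000 / mean_nn_stress),
            "HF": (hf_rest, hf_stress),
        })
        chosen = select_features(df, ["MeanNN", "MeanHR", "HF"])
        assert len(chosen) == 2
        assert "HF" in chosen
        assert len({"MeanNN", "MeanHR"} & set(chosen)) == 1

    def test_no_relevant_features_errors(self):
        rng = np.random.default_rng(3)
        rest = rng.normal(900, 50, 12)
        df = _folder1_frame({"A": (rest, rest + rng.normal(0, 50, 12))})
        with pytest.raises(ValueError):
            select_features(df, ["A"], alpha=1e-6)


# ---------------------------------------------------------------------------
# model fitting and metrics
# ---------------------------------------------------------------------------

def _separable_data(n_subj=18, seed=0):
    rng = np.random.default_rng(seed)
    X, y, groups = [], [], []
    for i in range(n_subj):
        for cond in (0, 1):
            X.append([cond * 4 + rng.normal(0, 0.5),
                      -cond * 3 + rng.normal(0, 0.5)])
            y.append(cond)
            groups.append(f"S{i}")
    return np.array(X), np.array(y), np.array(groups)


class TestFitPredict:
    def test_knn1_identical_point_scores_one(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.1, 0.0], [0.9, 1.0]])
        y = np.array([0, 1, 0, 1])
        spec = ModelSpec("knn", (("k", 1),))
        scores, labels = fit_predict(spec, X, y, np.array([[1.0, 1.0]]))
        assert scores[0] == 1.0 and labels[0] == 1

    def test_lda_boundary_on_symmetric_gaussians(self):
        rng = np.random.default_rng(4)
        delta, sigma = 2.0, 1.0
        X_tr = np.r_[rng.normal(0, sigma, (400, 1)),
                     rng.normal(delta, sigma, (400, 1))]
        y_tr = np.r_[np.zeros(400), np.ones(400)].astype(int)
        X_te = np.r_[rng.normal(0, sigma, (2000, 1)),
                     rng.normal(delta, sigma, (2000, 1))]
        y_te = np.r_[np.zeros(2000), np.ones(2000)].astype(int)
        _, labels = fit_predict(ModelSpec("lda"), X_tr, y_tr, X_te)
        err = np.mean(labels != y_te)
        from scipy.stats import norm
        bayes = norm.cdf(-delta / (2 * sigma))
        assert err == pytest.approx(bayes, abs=0.03)

    def test_non_finite_feature_rejected_by_harness(self):
        from uhrv.stress_classifier import _xy
        df = pd.DataFrame({
            "subject": ["a", "b"], "condition": ["rest", "stress"],
            "scale_s": [300, 300], "window_index": [np.nan, np.nan],
            "F": [1.0, np.nan],
        })
        with pytest.raises(ValueError, match="non-finite"):
            _xy(df, ["F"])


class TestEvaluateBinary:
    def test_perfect_scores(self):
        truth = np.array([0, 0, 1, 1])
        m = evaluate_binary([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], truth)
        assert (m.sensitivity, m.specificity, m.accuracy, m.auc) == (1, 1, 1, 1)

    def test_inverted_scores_auc_zero(self):
        truth = np.array([0, 0, 1, 1])
        m = evaluate_binary([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], truth)
        assert m.auc == 0.0

    def test_two_by_two_table(self):
        # TP=15, FN=2, TN=17, FP=0
        truth = np.r_[np.ones(17), np.zeros(17)].astype(int)
        labels = np.r_[np.ones(15), np.zeros(2), np.zeros(17)].astype(int)
        scores = labels.astype(float)
        m = evaluate_binary(scores, labels, truth)
        assert m.sensitivity == pytest.approx(15 / 17, abs=5e-4)
        assert m.specificity == 1.0
        assert m.accuracy == pytest.approx(32 / 34, abs=5e-4)

    def test_single_class_truth_errors(self):
        with pytest.raises(ValueError):
            evaluate_binary([0.5, 0.6], [1, 1], [1, 1])

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, 40)
        truth[:2] = [0, 1]
        scores = rng.normal(size=40) + truth
        m1 = evaluate_binary(scores, (scores > 0.5).astype(int), truth)
        m2 = evaluate_binary(np.exp(3 * scores), (scores > 0.5).astype(int), truth)
        assert m1.auc == pytest.approx(m2.auc, abs=1e-12)


class TestCrossValidateSelect:
    def test_single_model_grid_returned(self):
        X, y, g = _separable_data()
        spec, _ = cross_validate_select(X, y, g, grid=[ModelSpec("lda")])
        assert spec == ModelSpec("lda")

    def test_separable_data_high_auc(self):
        X, y, g = _separable_data()
        _, auc = cross_validate_select(
            X, y, g, grid=[ModelSpec("lda"), ModelSpec("knn", (("k", 3),))]
        )
        assert auc >= 0.95

    def test_same_seed_same_selection(self):
        X, y, g = _separable_data(seed=6)
        s1 = cross_validate_select(X, y, g, seed=2)
        s2 = cross_validate_select(X, y, g, seed=2)
        assert s1 == s2


# ---------------------------------------------------------------------------
# multiscale assessment on the synthetic cohort
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def wide(small_cohort_features):
    return features_to_wide(small_cohort_features)


class TestHarnessOnCohort:

    def test_identical_test_features_reproduce_benchmark_metrics(self, wide):
        split = split_subjects(wide["subject"].unique(), seed=1)
        feats = ["MeanNN", "StdHR", "HF"]
        res = multiscale_assessment(
            ModelSpec("knn", (("k", 3),)), wide, split, feats, scales=(300, 300)
        )
        assert res["per_scale"][300] == res["per_scale"][300]

    def test_metrics_stable_across_scales(self, wide):
        split = split_subjects(wide["subject"].unique(), seed=1)
        feats = ["MeanNN", "StdHR", "HF"]
        res = multiscale_assessment(
            ModelSpec("lda"), wide, split, feats, scales=(300, 180, 120, 60)
        )
        accs = [m.accuracy for m in res["per_scale"].values()]
        assert len(accs) == 4
        # programmed contrast survives shortening: spread <= 10 points
        assert max(accs) - min(accs) <= 0.10 + 1e-9

    def test_consecutive_windows_summarised(self, wide):
        split = split_subjects(wide["subject"].unique(), seed=1)
        res = multiscale_assessment(
            ModelSpec("lda"), wide, split, ["MeanNN", "StdHR", "HF"],
            scales=(300,), consecutive_scale=60,
        )
        assert len(res["consecutive"]) == 5
        assert set(res["consecutive_summary"]) == {
            "sensitivity", "specificity", "accuracy", "auc"
        }

    def test_no_leakage_from_folder2(self, wide):
        """Permuting folder-2 condition labels never changes training outputs."""
        split = split_subjects(wide["subject"].unique(), seed=1)
        folder1 = wide[wide["subject"].isin(split.folder1)]

        def train_outputs(w):
            chosen = select_features(
                w[w["subject"].isin(split.folder1)],
                ["MeanNN", "StdNN", "MeanHR", "StdHR", "HF", "SD2"],
            )
            from uhrv.stress_classifier import _select_rows, _xy
            X, y, g = _xy(_select_rows(w, split.folder1, 300), chosen)
            spec, auc = cross_validate_select(
                X, y, g, grid=[ModelSpec("lda"), ModelSpec("knn", (("k", 3),))],
                seed=0,
            )
            return chosen, spec, auc

        base = train_outputs(wide)
        permuted = wide.copy()
        rng = np.random.default_rng(9)
        mask = permuted["subject"].isin(split.folder2)
        permuted.loc[mask, "condition"] = rng.permutation(
            permuted.loc[mask, "condition"].values
        )
        assert train_outputs(permuted) == base
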