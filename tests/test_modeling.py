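"""Patient-level splitting, balanced resampling, tuning, paired bootstrap, BCa."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seasonri.modeling import (ModelSpec, balanced_resample, bca_interval,
                               evaluate_pair, split_by_patient, tune_and_fit)


class ScoreModel:
    """Stand-in classifier scoring rows by a fixed score vector or function."""

    def __init__(self, scores):
        self.scores = scores

    def predict_proba(self, X):
        s = self.scores(X) if callable(self.scores) else np.asarray(self.scores, float)
        return np.column_stack([1 - s, s])


def admissions_frame(n_patients=10, adm_per_patient=1):
    rows = []
    k = 0
    for p in range(n_patients):
        for _ in range(adm_per_patient):
            rows.append({"admission_id": f"A{k}", "patient_id": f"P{p}"})
            k += 1
    return pd.DataFrame(rows)


class TestSplitByPatient:
    def test_seventy_thirty_split_of_ten_patients(self):
        adm = admissions_frame(10)
        dev, test = split_by_patient(adm, dev_frac=0.7, seed=0)
        assert len(dev) == 7 and len(test) == 3

    def test_same_seed_same_split(self):
        adm = admissions_frame(25, 3)
        a = split_by_patient(adm, seed=4)
        b = split_by_patient(adm, seed=4)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_patients_never_straddle(self):
        adm = admissions_frame(8, 5)
        dev, test = split_by_patient(adm, seed=1)
        dev_pats = set(adm.set_index("admission_id").loc[dev, "patient_id"])
        test_pats = set(adm.set_index("admission_id").loc[test, "patient_id"])
        assert not dev_pats & test_pats
        # every admission of a patient is on one side
        for p in dev_pats:
            ids = adm.loc[adm["patient_id"] == p, "admission_id"]
            assert all(i in dev for i in ids)


class TestBalancedResample:
    def test_minority_oversampled_to_majority(self):
        y = np.array([1] * 10 + [0] * 90)
        idx = balanced_resample(y, seed=0)
        assert len(idx) == 180
        assert (y[idx] == 1).sum() == 90 and (y[idx] == 0).sum() == 90

    def test_balanced_input_passes_through(self):
        y = np.array([0, 1] * 25)
        idx = balanced_resample(y, seed=0)
        assert len(idx) == 50
        assert sorted(idx) == list(range(50))

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            balanced_resample(np.zeros(10), seed=0)

    def test_deterministic_under_seed(self):
        y = np.array([1] * 5 + [0] * 45)
        assert np.array_equal(balanced_resample(y, seed=3), balanced_resample(y, seed=3))


class TestTuneAndFit:
    def linearly_separable(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] > 0).astype(int)
        groups = np.arange(n) // 5
        return X, y, groups

    def test_single_config_is_selected(self):
        X, y, g = self.linearly_separable()
        spec = ModelSpec("decision_tree", distributions={"max_depth": [3]}, n_search=1, cv_folds=3)
        model, log = tune_and_fit(spec, X, y, g, seed=0)
        assert len(log) == 1
        assert model.get_params()["max_depth"] == 3

    def test_best_f1_config_wins(self):
        X, y, g = self.linearly_separable()
        # depth-1 stump on feature 0 is perfect; a stump forced off-feature is not
        spec = ModelSpec("decision_tree",
                         distributions={"max_depth": [1, 8], "min_samples_leaf": [1]},
                         n_search=2, cv_folds=3)
        model, log = tune_and_fit(spec, X, y, g, seed=0)
        best = log.loc[log["mean_f1"].idxmax()]
        assert model.get_params()["max_depth"] == best["params"]["max_depth"]

    def test_separable_data_reaches_high_f1(self):
        X, y, g = self.linearly_separable()
        spec = ModelSpec("decision_tree", distributions={"max_depth": [4]}, n_search=1, cv_folds=3)
        _, log = tune_and_fit(spec, X, y, g, seed=0)
        assert log["mean_f1"].max() >= 0.95

    def test_single_class_dev_set_is_error(self):
        X, y, g = self.linearly_separable()
        with pytest.raises(ValueError, match="both classes"):
            tune_and_fit(ModelSpec("decision_tree"), X, np.zeros_like(y), g, seed=0)


class TestEvaluatePair:
    def test_identical_models_give_zero_differences(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        scores = rng.random(200)
        m = ScoreModel(scores)
        res = evaluate_pair(m, m, np.zeros((200, 1)), np.zeros((200, 1)), y,
                            n_boots=100, bca_boots=500, seed=1)
        assert np.all(res.auroc_diffs == 0.0)
        assert res.verdict == "no_difference"
        assert res.bca_ci == (0.0, 0.0)

    def test_perfect_vs_random_classifier(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 100)
        perfect = ScoreModel(y.astype(float))
        random_m = ScoreModel(rng.random(200))
        res = evaluate_pair(random_m, perfect, np.zeros((200, 1)), np.zeros((200, 1)), y,
                            n_boots=200, bca_boots=1000, seed=2)
        assert res.auroc_v2 == 1.0
        assert abs(res.auroc_v1 - 0.5) < 0.15
        assert np.all(res.auroc_diffs > 0)
        assert abs(np.mean(res.auroc_diffs) - 0.5) < 0.15
        assert res.verdict == "v2_better"

    def test_boot_count_and_point_inside_percentile_ci(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 300)
        m1 = ScoreModel(rng.random(300) + 0.3 * y)
        m2 = ScoreModel(rng.random(300) + 0.4 * y)
        res = evaluate_pair(m1, m2, np.zeros((300, 1)), np.zeros((300, 1)), y,
                            n_boots=150, bca_boots=500, seed=3)
        assert len(res.auroc_diffs) == 150
        lo, hi = res.auroc_ci_v1
        assert lo <= res.auroc_v1 <= hi

    def test_rare_positive_labels_still_yield_full_boot_count(self):
        y = np.array([1] * 3 + [0] * 97)  # single-class resamples likely; redrawn
        s = np.random.default_rng(0).random(100)
        m = ScoreModel(s)
        res = evaluate_pair(m, m, np.zeros((100, 1)), np.zeros((100, 1)), y,
                            n_boots=100, bca_boots=200, seed=5)
        assert len(res.auroc_diffs) == 100

    def test_pairing_is_index_based_not_sequential(self):
        # resample b depends only on (seed, b): computing a subset first
        # changes nothing
        from seasonri.modeling import _boot_indices
        a = [_boot_indices(50, seed=9, b=b) for b in range(10)]
        b_rev = [_boot_indices(50, seed=9, b=b) for b in reversed(range(10))][::-1]
        assert all(np.array_equal(x, y) for x, y in zip(a, b_rev))

    def test_single_class_test_set_is_error(self):
        m = ScoreModel(np.zeros(10))
        with pytest.raises(ValueError):
            evaluate_pair(m, m, np.zeros((10, 1)), np.zeros((10, 1)), np.zeros(10),
                          n_boots=10, bca_boots=100, seed=0)


class TestBCaInterval:
    def test_degenerate_all_equal(self):
        assert bca_interval(np.zeros(100)) == (0.0, 0.0)
        assert bca_interval(np.full(50, 3.5)) == (3.5, 3.5)

    def test_symmetric_sample_matches_percentile_interval(self, rng):
        x = rng.standard_normal(1000)
        lo, hi = bca_interval(x, n_outer_boots=4000, seed=1)
        idx = np.random.default_rng(1).integers(0, 1000, size=(4000, 1000))
        boot_means = x[idx].mean(axis=1)
        plo, phi = np.percentile(boot_means, [2.5, 97.5])
        assert abs(lo - plo) < 0.02 and abs(hi - phi) < 0.02

    def test_shifted_sample_excludes_zero(self, rng):
        x = rng.normal(5.0, 1.0, size=1000)
        lo, hi = bca_interval(x, n_outer_boots=2000, seed=2)
        assert lo > 0
        assert abs((lo + hi) / 2 - 5.0) < 0.1

    def test_against_scipy_reference(self, rng):
        # independent oracle: scipy's BCa implementation on a skewed sample
        x = rng.exponential(2.0, size=400)
        lo, hi = bca_interval(x, n_outer_boots=8000, seed=3)
        ref = stats.bootstrap((x,), np.mean, n_resamples=8000, method="BCa",
                              confidence_level=0.95, random_state=np.random.default_rng(3))
        assert lo == pytest.approx(ref.confidence_interval.low, abs=0.05)
        assert hi == pytest.approx(ref.confidence_interval.high, abs=0.05)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            bca_interval(np.array([]))
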