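"""Classifier training and paired-bootstrap comparison of encoding versions.

Four pluggable scikit-learn families (adaBoost, decision tree, neural net,
random forest) are tuned by random search (<= 40 configurations, 5-fold
patient-grouped CV, balanced case/control resampling of training folds, F1
selection at the 0.5 threshold), refit on the development set, and compared
on the test set: the same admission resamples feed both versions, giving a
paired distribution of AUROC/AUPRC differences whose mean is interval-
estimated by a bias-corrected and accelerated (BCa) bootstrap.  A version-2
gain is declared only when the BCa interval excludes 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import GroupKFold, ParameterSampler
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

FAMILIES = ("adaboost", "decision_tree", "neural_net", "random_forest")

#: random-search spaces per family; modest grids over the knobs that matter
#: (tree depth/count, learning rate, hidden sizes, regularization)
DEFAULT_DISTRIBUTIONS: dict[str, dict[str, list]] = {
    "adaboost": {
        "n_estimators": [25, 50, 100, 200],
        "learning_rate": [0.05, 0.1, 0.5, 1.0],
    },
    "decision_tree": {
        "max_depth": [2, 3, 4, 6, 8, 12, None],
        "min_samples_leaf": [1, 5, 20, 50],
        "criterion": ["gini", "entropy"],
    },
    "neural_net": {
        "hidden_layer_sizes": [(8,), (16,), (32,), (32, 16)],
        "alpha": [1e-4, 1e-3, 1e-2],
        "learning_rate_init": [1e-3, 1e-2],
    },
    "random_forest": {
        "n_estimators": [50, 100, 200],
        "max_depth": [3, 5, 10, None],
        "min_samples_leaf": [1, 5, 20],
        "max_features": ["sqrt", None],
    },
}


@dataclass
class ModelSpec:
    """One classifier family plus its search budget."""

    family: str
    distributions: dict[str, list] = field(default_factory=dict)
    n_search: int = 40
    cv_folds: int = 5

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; options: {FAMILIES}")
        if self.n_search < 1:
            raise ValueError("n_search must be >= 1")
        if not self.distributions:
            self.distributions = DEFAULT_DISTRIBUTIONS[self.family]

    def estimator(self, params: dict, seed: int):
        if self.family == "adaboost":
            return AdaBoostClassifier(random_state=seed, **params)
        if self.family == "decision_tree":
            return DecisionTreeClassifier(random_state=seed, **params)
        if self.family == "neural_net":
            return MLPClassifier(random_state=seed, max_iter=300, **params)
        return RandomForestClassifier(random_state=seed, **params)


def split_by_patient(admissions: pd.DataFrame, dev_frac: float = 0.7,
                     seed: int = 0) -> tuple[pd.Index, pd.Index]:
    """Patient-level 70/30 split; every admission of a patient lands on one side.

    Returns (dev admission_ids, test admission_ids).
    """
    patients = np.sort(admissions["patient_id"].unique())
    if patients.size < 2:
        raise ValueError("need >= 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(patients)
    n_dev = int(round(dev_frac * patients.size))
    dev_patients = set(perm[:n_dev])
    in_dev = admissions["patient_id"].isin(dev_patients).to_numpy()
    ids = admissions["admission_id"]
    dev_ids, test_ids = pd.Index(ids[in_dev]), pd.Index(ids[~in_dev])
    assert not set(admissions.loc[in_dev, "patient_id"]) & set(admissions.loc[~in_dev, "patient_id"])
    return dev_ids, test_ids


def balanced_resample(labels: np.ndarray, seed: int) -> np.ndarray:
    """Equal-count case/control index multiset.

    The majority class is kept as-is; the minority class is resampled with
    replacement up to the majority count.  Deterministic under ``seed``.
    """
    y = np.asarray(labels).astype(int)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(f"balanced_resample requires both classes; got {pos.size} cases, {neg.size} controls")
    rng = np.random.default_rng(seed)
    if pos.size == neg.size:
        return np.concatenate([pos, neg])
    minority, majority = (pos, neg) if pos.size < neg.size else (neg, pos)
    boosted = rng.choice(minority, size=majority.size, replace=True)
    return np.concatenate([majority, boosted])


def _f1_at_half(model, X, y) -> float:
    prob = model.predict_proba(X)[:, 1]
    return f1_score(y, (prob >= 0.5).astype(int), zero_division=0.0)


def tune_and_fit(spec: ModelSpec, X_dev: np.ndarray, y_dev: np.ndarray,
                 groups: np.ndarray, seed: int) -> tuple[object, pd.DataFrame]:
    """Random search + patient-grouped CV + balanced training resampling.

    Each sampled configuration is scored by mean F1 (0.5 threshold) over
    ``cv_folds`` GroupKFold folds, balancing only the training folds; the
    best configuration (ties -> earliest sampled) is refit on the balanced
    full development set.  Returns (fitted model, search log).
    """
    X_dev = np.asarray(X_dev, float)
    y_dev = np.asarray(y_dev, int)
    if len(np.unique(y_dev)) < 2:
        raise ValueError("development set must contain both classes")
    sampler = ParameterSampler(spec.distributions, n_iter=spec.n_search, random_state=seed)
    n_folds = min(spec.cv_folds, len(np.unique(groups)))
    cv = GroupKFold(n_splits=n_folds)
    log = []
    best_idx, best_score, best_params = -1, -np.inf, None
    for i, params in enumerate(sampler):
        scores = []
        try:
            for k, (tr, va) in enumerate(cv.split(X_dev, y_dev, groups)):
                if len(np.unique(y_dev[tr])) < 2 or len(np.unique(y_dev[va])) < 2:
                    continue
                idx = tr[balanced_resample(y_dev[tr], seed=seed * 10007 + i * 101 + k)]
                model = spec.estimator(params, seed=seed)
                model.fit(X_dev[idx], y_dev[idx])
                scores.append(_f1_at_half(model, X_dev[va], y_dev[va]))
        except Exception as exc:  # a configuration failing to converge is logged, not fatal
            log.append({"config": i, "params": params, "mean_f1": np.nan, "error": str(exc)})
            continue
        mean_f1 = float(np.mean(scores)) if scores else np.nan
        log.append({"config": i, "params": params, "mean_f1": mean_f1, "error": ""})
        if np.isfinite(mean_f1) and mean_f1 > best_score:
            best_idx, best_score, best_params = i, mean_f1, params
    log_df = pd.DataFrame(log)
    if best_params is None:
        raise RuntimeError(f"no {spec.family} configuration converged; search log:\n{log_df}")
    idx = balanced_resample(y_dev, seed=seed * 10007 + 999983)
    final = spec.estimator(best_params, seed=seed)
    final.fit(X_dev[idx], y_dev[idx])
    logger.info("tune_and_fit[%s]: config %d selected, dev CV F1=%.3f", spec.family, best_idx, best_score)
    return final, log_df


# ---------------------------------------------------------------------------
# paired bootstrap comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Version-2 minus version-1 performance for one outcome x family."""

    outcome: str
    family: str
    auroc_v1: float
    auroc_v2: float
    auprc_v1: float
    auprc_v2: float
    auroc_ci_v1: tuple[float, float]
    auroc_ci_v2: tuple[float, float]
    auprc_ci_v1: tuple[float, float]
    auprc_ci_v2: tuple[float, float]
    auroc_diffs: np.ndarray = field(repr=False, default=None)
    auprc_diffs: np.ndarray = field(repr=False, default=None)
    bca_ci: tuple[float, float] = (np.nan, np.nan)
    bca_ci_auprc: tuple[float, float] = (np.nan, np.nan)
    median_diff: float = np.nan
    median_diff_auprc: float = np.nan
    verdict: str = "no_difference"

    def to_row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k not in ("auroc_diffs", "auprc_diffs")}
        return d


def _boot_indices(n: int, seed: int, b: int) -> np.ndarray:
    """Indexed (not sequential) resample b, so execution order is irrelevant."""
    rng = np.random.default_rng([seed, b])
    return rng.integers(0, n, size=n)


def evaluate_pair(model_v1, model_v2, X1_test, X2_test, y_test,
                  outcome: str = "", family: str = "",
                  n_boots: int = 1000, bca_boots: int = 10000,
                  level: float = 0.95, seed: int = 0) -> ComparisonResult:
    """Paired-bootstrap AUROC/AUPRC comparison of the two encoding versions.

    Boot ``b`` resamples the same test admissions for both versions, so each
    difference isolates the encoding change from sampling noise.  Resamples
    containing a single class are redrawn (the count stays ``n_boots``).
    Verdict: v2_better / v1_better when the BCa interval of the mean AUROC
    difference excludes 0, else no_difference.
    """
    y = np.asarray(y_test).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("test labels must contain both classes")
    s1 = model_v1.predict_proba(np.asarray(X1_test, float))[:, 1]
    s2 = model_v2.predict_proba(np.asarray(X2_test, float))[:, 1]
    n = y.size

    auroc_v1, auroc_v2 = roc_auc_score(y, s1), roc_auc_score(y, s2)
    auprc_v1, auprc_v2 = average_precision_score(y, s1), average_precision_score(y, s2)

    m1 = np.empty((n_boots, 2))  # auroc, auprc for v1
    m2 = np.empty((n_boots, 2))
    n_redrawn = 0
    for b in range(n_boots):
        attempt = 0
        while True:
            rng = np.random.default_rng([seed, b, attempt])
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
            attempt += 1
            n_redrawn += 1
        yb = y[idx]
        m1[b] = roc_auc_score(yb, s1[idx]), average_precision_score(yb, s1[idx])
        m2[b] = roc_auc_score(yb, s2[idx]), average_precision_score(yb, s2[idx])
    if n_redrawn:
        logger.info("evaluate_pair: redrew %d single-class resamples", n_redrawn)

    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    auroc_diffs = m2[:, 0] - m1[:, 0]
    auprc_diffs = m2[:, 1] - m1[:, 1]
    bca = bca_interval(auroc_diffs, n_outer_boots=bca_boots, level=level, seed=seed)
    bca_pr = bca_interval(auprc_diffs, n_outer_boots=bca_boots, level=level, seed=seed + 1)
    if bca[0] > 0:
        verdict = "v2_better"
    elif bca[1] < 0:
        verdict = "v1_better"
    else:
        verdict = "no_difference"
    return ComparisonResult(
        outcome=outcome, family=family,
        auroc_v1=float(auroc_v1), auroc_v2=float(auroc_v2),
        auprc_v1=float(auprc_v1), auprc_v2=float(auprc_v2),
        auroc_ci_v1=tuple(np.percentile(m1[:, 0], [lo_q, hi_q])),
        auroc_ci_v2=tuple(np.percentile(m2[:, 0], [lo_q, hi_q])),
        auprc_ci_v1=tuple(np.percentile(m1[:, 1], [lo_q, hi_q])),
        auprc_ci_v2=tuple(np.percentile(m2[:, 1], [lo_q, hi_q])),
        auroc_diffs=auroc_diffs, auprc_diffs=auprc_diffs,
        bca_ci=bca, bca_ci_auprc=bca_pr,
        median_diff=float(np.median(auroc_diffs)),
        median_diff_auprc=float(np.median(auprc_diffs)),
        verdict=verdict,
    )


def bca_interval(sample, n_outer_boots: int = 10000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for the mean of ``sample``.

    z0 (bias correction) is the normal quantile of the fraction of outer-boot
    means below the observed mean; a (acceleration) comes from the jackknife
    skewness of the mean.  A degenerate all-equal sample returns (c, c); for
    symmetric samples z0 ~ 0 and a ~ 0, and BCa reduces to the percentile
    interval.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    obs = float(x.mean())
    if np.ptp(x) == 0.0:
        return (obs, obs)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_outer_boots, x.size))
    boot_means = x[idx].mean(axis=1)

    prop = (np.count_nonzero(boot_means < obs)
            + 0.5 * np.count_nonzero(boot_means == obs)) / n_outer_boots
    prop = min(max(prop, 1.0 / (2 * n_outer_boots)), 1.0 - 1.0 / (2 * n_outer_boots))
    z0 = ndtri(prop)

    # jackknife acceleration
    jack = (x.sum() - x) / (x.size - 1)
    d = jack.mean() - jack
    denom = 6.0 * (d ** 2).sum() ** 1.5
    a = float((d ** 3).sum() / denom) if denom > 0 else 0.0

    alpha = 1.0 - level
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = ndtri(q)
        adj = ndtr(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        out.append(float(np.quantile(boot_means, min(max(adj, 0.0), 1.0))))
    return (out[0], out[1])


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
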