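"""Permutation-sampling Shapley attributions and level-wise ANOVA.

Feature contributions to the model score are approximated by iterating
through permutations of the input features: walking a random ordering, each
feature's value is switched from a background row's value to the explained
row's value and the change in model output is credited to that feature.
Averaged over all orderings and the full background this is exactly the
Shapley value; Monte-Carlo sampling of (ordering, background row) pairs
gives the estimator used at scale.  Summaries follow the usual conventions:
mean absolute attribution per feature (optionally scaled to [0, 1] within an
outcome), and a one-way ANOVA of attributions grouped by the feature's
pre-standardization level (-1/0/+1) with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ShapMatrix:
    """Per-row, per-feature attributions plus the background base value."""

    values: pd.DataFrame      # rows x features, model-output units
    base_value: float         # expected model output over the background

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


def _scores(predict_fn, X: np.ndarray) -> np.ndarray:
    out = np.asarray(predict_fn(X), dtype=float)
    if out.ndim == 2:  # predict_proba-style output: positive-class column
        out = out[:, -1]
    return out


def permutation_shap(predict_fn, rows: pd.DataFrame, background: pd.DataFrame,
                     n_permutations: int = 50, seed: int = 0,
                     exhaustive: bool = False) -> ShapMatrix:
    """Monte-Carlo (or exhaustive) permutation Shapley attributions.

    Parameters
    ----------
    predict_fn
        score function; given an (n, d) array returns n scores (an (n, 2)
        probability matrix is reduced to its positive-class column).
    rows
        rows to explain (standardized features, as seen by the model).
    background
        reference rows defining the "feature absent" distribution.
    n_permutations
        sampled (ordering, background row) pairs per explained row; ignored
        when ``exhaustive`` is set.
    exhaustive
        enumerate all d! orderings against every background row — exact
        Shapley values; only sensible for a handful of features.

    Local accuracy: per row, attributions sum to score(row) - base_value
    (exactly under ``exhaustive``, in expectation under sampling).
    """
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    X = rows.to_numpy(float)
    B = background.to_numpy(float)
    n, d = X.shape
    base_value = float(_scores(predict_fn, B).mean())

    if exhaustive:
        orderings = [np.array(p) for p in permutations(range(d))]
        pairs = [(o, b) for o in orderings for b in range(len(B))]
    else:
        rng = np.random.default_rng(seed)
        pairs = [(rng.permutation(d), int(rng.integers(0, len(B)))) for _ in range(n_permutations)]

    phi = np.zeros((n, d))
    for order, b in pairs:
        # states: background row with successively more features switched in;
        # evaluate all d+1 prefixes for all rows in one model call
        states = np.tile(B[b], (n * (d + 1), 1))
        for k, feat in enumerate(order):
            block = slice(n * (k + 1), n * (d + 1))
            states.reshape(d + 1, n, d)[k + 1:, :, feat] = X[:, feat]
        scores = _scores(predict_fn, states).reshape(d + 1, n)
        deltas = np.diff(scores, axis=0)  # (d, n): contribution of order[k]
        for k, feat in enumerate(order):
            phi[:, feat] += deltas[k]
    phi /= len(pairs)
    return ShapMatrix(values=pd.DataFrame(phi, index=rows.index, columns=rows.columns),
                      base_value=base_value)


def exact_shapley(predict_fn, rows: pd.DataFrame, background: pd.DataFrame) -> ShapMatrix:
    """Exact Shapley values via exhaustive permutation enumeration."""
    return permutation_shap(predict_fn, rows, background, exhaustive=True)


def mean_abs_shap(shap: ShapMatrix, scaled: bool = False) -> pd.Series:
    """Mean |attribution| per feature across all explained rows.

    ``scaled=True`` divides by the per-outcome maximum, so values rank the
    features within one outcome on [0, 1].
    """
    if shap.values.empty:
        raise ValueError("empty attribution matrix")
    out = shap.values.abs().mean(axis=0)
    if scaled:
        top = out.max()
        if top > 0:
            out = out / top
    return out


@dataclass
class LevelTest:
    """One-way ANOVA of a feature's attributions across its input levels."""

    feature: str
    levels: list
    group_sizes: list[int]
    f_stat: float
    p: float
    p_bonferroni: float
    significant: bool
    tested: bool
    reason: str = ""


def anova_by_level(shap: ShapMatrix, raw_features: pd.DataFrame,
                   alpha: float = 0.05, min_per_level: int = 2) -> list[LevelTest]:
    """Per feature, compare attribution distributions across -1/0/+1 levels.

    Grouping uses the pre-standardization level of the feature.  Bonferroni
    correction multiplies p by the number of features actually tested for
    this outcome.  Features with fewer than two populated levels are
    reported as untested rather than dropped.
    """
    raw = raw_features.loc[shap.values.index]
    prelim = []
    for feat in shap.features:
        levels = sorted(raw[feat].unique())
        groups = [shap.values.loc[raw[feat] == lv, feat].to_numpy() for lv in levels]
        keep = [(lv, g) for lv, g in zip(levels, groups) if g.size >= min_per_level]
        if len(keep) < 2:
            prelim.append(LevelTest(feat, [lv for lv, _ in keep], [g.size for _, g in keep],
                                    np.nan, np.nan, np.nan, False, tested=False,
                                    reason="fewer than 2 levels with enough rows"))
            continue
        arrays = [g for _, g in keep]
        if all(np.ptp(g) == 0 for g in arrays) and np.ptp(np.concatenate(arrays)) == 0:
            f_stat, p = 0.0, 1.0  # identical constant attributions across levels
        else:
            f_stat, p = stats.f_oneway(*arrays)
            if not np.isfinite(p):
                f_stat, p = 0.0, 1.0
        prelim.append(LevelTest(feat, [lv for lv, _ in keep], [g.size for _, g in keep],
                                float(f_stat), float(p), np.nan, False, tested=True))
    n_tested = sum(t.tested for t in prelim)
    for t in prelim:
        if t.tested:
            t.p_bonferroni = min(1.0, t.p * n_tested)
            t.significant = t.p_bonferroni < alpha
    return prelim


def level_tests_to_frame(tests: list[LevelTest]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in tests])
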