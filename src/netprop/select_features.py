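"""Random-forest Gini-importance ranking and key-feature intersection.

Each cohort ranks the panel genes by mean decrease in Gini impurity from
a random forest classifying case vs control on the panel-gene expression
submatrix.  The top quarter (by importance, ceiling cardinality) is kept
per cohort and the per-cohort survivors are intersected to give the key
biomarkers.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .net_io import ExpressionStudy, GeneSet

logger = logging.getLogger("netprop.select_features")

__all__ = [
    "GiniImportanceSelector",
    "tune_tree_count",
    "rank_rf_importance",
    "retain_top_fraction",
    "intersect_key_features",
]


def _panel_design(study: ExpressionStudy, genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [g for g in genes if g not in study.matrix.index]
    if missing:
        raise ValueError(f"{study.cohort_id}: panel genes absent from study: {missing}")
    X = study.matrix.loc[genes].to_numpy(dtype=float).T  # samples x genes
    y = (study.labels == "case").to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"{study.cohort_id}: labels contain a single class")
    return X, y


class GiniImportanceSelector(BaseEstimator):
    """Select the highest-Gini-importance fraction of features.

    A sklearn-style estimator: ``fit(X, y)`` trains a
    ``RandomForestClassifier`` (``max_features='sqrt'``, unlimited depth,
    the randomForest-package defaults) and records per-feature mean
    decrease in Gini impurity in ``importances_``; ``selected_mask_``
    marks the ``ceil(fraction * p)`` most important features, boundary
    ties broken by feature name (lexicographic) via ``feature_names``.
    """

    def __init__(self, n_trees: int = 100, fraction: float = 0.25,
                 random_state: int = 0, feature_names: list[str] | None = None):
        self.n_trees = n_trees
        self.fraction = fraction
        self.random_state = random_state
        self.feature_names = feature_names

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt",
            random_state=self.random_state,
        )
        forest.fit(X, y)
        self.forest_ = forest
        self.importances_ = forest.feature_importances_
        names = self.feature_names or [f"f{i}" for i in range(X.shape[1])]
        order = sorted(range(X.shape[1]), key=lambda i: (-self.importances_[i], names[i]))
        n_keep = math.ceil(self.fraction * X.shape[1])
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[order[:n_keep]] = True
        self.selected_mask_ = mask
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_mask_")
        return np.asarray(X)[:, self.selected_mask_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "selected_mask_")
        return self.selected_mask_


def tune_tree_count(
    study: ExpressionStudy, panel: pd.DataFrame, grid: list[int], rng_seed: int = 0
) -> int:
    """Grid value minimising out-of-bag error; ties go to the smaller count."""
    if not grid or any(g < 1 for g in grid):
        raise ValueError("grid must be non-empty with all values >= 1")
    X, y = _panel_design(study, list(panel["symbol"]))
    best_n, best_err = None, np.inf
    for n_trees in sorted(grid):
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", oob_score=True,
            random_state=rng_seed,
        )
        with warnings.catch_warnings():
            # few trees leave some samples without OOB predictions
            warnings.simplefilter("ignore", UserWarning)
            forest.fit(X, y)
            err = 1.0 - forest.oob_score_
        if err < best_err:
            best_n, best_err = n_trees, err
    logger.info("%s: best tree count %d (OOB error %.3f)", study.cohort_id,
                best_n, best_err)
    return best_n


def rank_rf_importance(
    study: ExpressionStudy, panel: pd.DataFrame, n_trees: int, rng_seed: int = 0
) -> pd.DataFrame:
    """Mean-decrease-Gini importance of each panel gene in one cohort."""
    genes = list(panel["symbol"])
    X, y = _panel_design(study, genes)
    sel = GiniImportanceSelector(n_trees=n_trees, random_state=rng_seed,
                                 feature_names=genes).fit(X, y)
    table = pd.DataFrame(
        {"gene": genes, "mean_decrease_gini": sel.importances_}
    ).sort_values(["mean_decrease_gini", "gene"], ascending=[False, True])
    table.attrs["cohort_id"] = study.cohort_id
    table.attrs["n_trees"] = n_trees
    return table.reset_index(drop=True)


def retain_top_fraction(imp: pd.DataFrame, fraction: float = 0.25) -> GeneSet:
    """The ceil(fraction * n) highest-importance genes; ties lexicographic."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    ordered = imp.sort_values(["mean_decrease_gini", "gene"],
                              ascending=[False, True])
    n_keep = math.ceil(fraction * len(ordered))
    kept = ordered["gene"].head(n_keep)
    return GeneSet.from_iterable(
        f"top{fraction:g}_{imp.attrs.get('cohort_id', 'cohort')}", kept
    )


def intersect_key_features(a: GeneSet, b: GeneSet) -> GeneSet:
    """Lexicographically ordered intersection of two cohorts' retained sets."""
    common = a.members & b.members
    if not common:
        logger.warning("key-feature intersection of %s and %s is empty", a.name, b.name)
    return GeneSet(name=f"{a.name}&{b.name}", members=frozenset(common))
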