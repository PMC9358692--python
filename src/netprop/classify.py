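"""Median binarization, neural-network classification, and ROC analysis.

Biomarker expression is first converted to a 0/1 matrix: for an
up-regulated biomarker a sample scores 1 when its value is equal to or
greater than that biomarker's median across all samples of the cohort;
for a down-regulated biomarker the rule is reversed (1 when at or below
the median).  Each cohort is binarized against its own medians, including
held-out test cohorts.  The binary matrix feeds a feed-forward network
with one hidden layer of logistic units and a logistic output; the
network's output probability is the multifactor score for ROC analysis.
AUC uses the tie-corrected rank (Mann-Whitney) formulation and its 95%
confidence interval comes from DeLong's variance estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .net_io import ExpressionStudy

logger = logging.getLogger("netprop.classify")

__all__ = [
    "BinaryMatrix",
    "RocResult",
    "MedianBinarizer",
    "BinaryPatternClassifier",
    "binarize_by_median",
    "fit_nn_classifier",
    "evaluate_roc",
    "delong_auc_ci",
]


@dataclass
class BinaryMatrix:
    """0/1 biomarker x sample matrix plus the medians and directions used."""

    values: pd.DataFrame  # biomarkers x samples, values in {0, 1}
    medians: pd.Series
    directions: pd.Series  # 'up' or 'down' per biomarker


class MedianBinarizer(BaseEstimator, TransformerMixin):
    """Direction-aware median thresholding of biomarker expression.

    sklearn transformer over ``X`` of shape ``(n_samples, n_biomarkers)``.
    ``directions`` is a sequence of 'up'/'down' per biomarker; 'up'
    features map to 1 at or above the fitted median, 'down' features to 1
    at or below it.  Fit on the cohort being binarized — the median rule
    is per-dataset, so a test cohort gets its own fit.
    """

    def __init__(self, directions: list[str] | None = None):
        self.directions = directions

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.medians_ = np.median(X, axis=0)
        dirs = self.directions or ["up"] * X.shape[1]
        if len(dirs) != X.shape[1]:
            raise ValueError("one direction per biomarker required")
        if set(dirs) - {"up", "down"}:
            raise ValueError("directions must be 'up' or 'down'")
        self.directions_ = np.asarray(dirs)
        return self

    def transform(self, X):
        check_is_fitted(self, "medians_")
        X = np.asarray(X, dtype=float)
        up = self.directions_ == "up"
        out = np.where(up[None, :], X >= self.medians_[None, :],
                       X <= self.medians_[None, :])
        return out.astype(int)


def binarize_by_median(study: ExpressionStudy, panel: pd.DataFrame) -> BinaryMatrix:
    """Binarize a study's panel-gene expression against its own medians."""
    genes = list(panel["symbol"])
    missing = [g for g in genes if g not in study.matrix.index]
    if missing:
        raise ValueError(f"{study.cohort_id}: panel genes absent: {missing}")
    directions = list(panel["direction"])
    X = study.matrix.loc[genes].to_numpy(dtype=float).T  # samples x biomarkers
    binarizer = MedianBinarizer(directions=directions).fit(X)
    values = pd.DataFrame(binarizer.transform(X).T, index=genes,
                          columns=study.matrix.columns)
    return BinaryMatrix(
        values=values,
        medians=pd.Series(binarizer.medians_, index=genes),
        directions=pd.Series(directions, index=genes),
    )


class BinaryPatternClassifier(ClassifierMixin, BaseEstimator):
    """One-hidden-layer logistic network over binary biomarker patterns.

    Thin sklearn estimator around :class:`MLPClassifier` with a single
    hidden layer (default width 5) of logistic units and a logistic
    output, trained by L-BFGS with a fixed iteration cap.  Exposes
    ``converged_`` so non-convergence is visible rather than fatal.
    """

    def __init__(self, hidden: int = 5, random_state: int = 0, max_iter: int = 2000):
        self.hidden = hidden
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        mlp = MLPClassifier(
            hidden_layer_sizes=(self.hidden,),
            activation="logistic",
            solver="lbfgs",
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            mlp.fit(np.asarray(X, dtype=float), y)
        self.converged_ = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        if not self.converged_:
            logger.warning("network did not converge in %d iterations; "
                           "best weights kept", self.max_iter)
        self.mlp_ = mlp
        self.classes_ = mlp.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict_proba(np.asarray(X, dtype=float))

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive ('case') class for each sample."""
        proba = self.predict_proba(X)
        pos = list(self.classes_).index(1) if 1 in self.classes_ else 1
        return proba[:, pos]


def fit_nn_classifier(
    bin_matrix: BinaryMatrix, labels: pd.Series, hidden: int = 5, rng_seed: int = 0
) -> BinaryPatternClassifier:
    """Train the logistic-unit network on a binarized cohort."""
    X = bin_matrix.values.to_numpy(dtype=float).T  # samples x biomarkers
    y = (labels.loc[bin_matrix.values.columns] == "case").astype(int).to_numpy()
    return BinaryPatternClassifier(hidden=hidden, random_state=rng_seed).fit(X, y)


@dataclass
class RocResult:
    """AUC with a 95% DeLong confidence interval and class counts."""

    auc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0):
            raise ValueError(
                f"invalid ROC result: auc={self.auc}, ci=({self.ci_low}, {self.ci_high})"
            )


def delong_auc_ci(
    scores: np.ndarray, y: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """Tie-corrected AUC and DeLong confidence interval.

    ``y`` is 0/1 with 1 = case.  The AUC is the mean placement value
    (identical to the Mann-Whitney statistic with the 1/2 tie
    correction); the CI is normal-theory on the DeLong variance, clipped
    to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required for ROC analysis")
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    if var <= 0:
        return auc, auc, auc
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def evaluate_roc(
    model: BinaryPatternClassifier, bin_matrix: BinaryMatrix, labels: pd.Series
) -> RocResult:
    """Score a binarized cohort with the network and report AUC + 95% CI."""
    X = bin_matrix.values.to_numpy(dtype=float).T
    y = (labels.loc[bin_matrix.values.columns] == "case").astype(int).to_numpy()
    scores = model.decision_scores(X)
    if np.allclose(scores, scores[0]):
        logger.warning("all scores identical; AUC undefined, reporting 0.5")
        return RocResult(auc=0.5, ci_low=0.5, ci_high=0.5,
                         n_case=int(y.sum()), n_control=int((1 - y).sum()))
    auc, lo, hi = delong_auc_ci(scores, y)
    return RocResult(auc=float(auc), ci_low=float(lo), ci_high=float(hi),
                     n_case=int(y.sum()), n_control=int((1 - y).sum()))
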