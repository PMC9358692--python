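"""Signature-based immune-cell deconvolution and correlation reporting.

Each bulk sample is regressed on a cell-type signature matrix with a
linear-kernel nu-support-vector regression: sample and signature columns
are z-scored over shared genes, the fit is repeated for several values of
``nu`` and the one with the lowest reconstruction RMSE wins, negative
coefficients are clipped to zero and the rest renormalised to mixture
fractions summing to one.  Per-sample significance comes from a shared
permutation null: gene-shuffled samples are deconvolved the same way and
a sample's p-value is the fraction of null fits whose reconstruction
correlation reaches its observed one.  Mixtures are assumed to be on
linear (non-log) scale, matching the convention of signature-based
deconvolution; a log2 input can be anti-logged by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from sklearn.svm import NuSVR
from sklearn.utils.validation import check_is_fitted

from .net_io import ExpressionStudy

logger = logging.getLogger("netprop.deconvolve")

__all__ = [
    "SignatureDeconvolver",
    "deconvolve_mixture",
    "filter_significant_samples",
    "correlate_features",
    "correlation_band",
]

DEFAULT_NUS = (0.25, 0.5, 0.75)

# interpretation bands for |coefficient|
_BANDS = (
    (0.70, "strong"),
    (0.50, "moderate"),
    (0.30, "weak-moderate"),
    (0.0, "weak"),
)


def correlation_band(coefficient: float) -> str:
    """Label |r|: >0.70 strong, 0.50-0.70 moderate, 0.30-0.50 weak-moderate,
    <0.30 weak.  Boundary values fall into the stronger band."""
    r = abs(coefficient)
    if r > 0.70:
        return "strong"
    if r >= 0.50:
        return "moderate"
    if r >= 0.30:
        return "weak-moderate"
    return "weak"


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _fit_sample(X: np.ndarray, y: np.ndarray, nus) -> tuple[np.ndarray, float, float]:
    """Best-of-nus linear nu-SVR fit; returns (raw weights, rmse, corr)."""
    best = None
    for nu in nus:
        svr = NuSVR(kernel="linear", nu=nu, C=1.0)
        svr.fit(X, y)
        recon = svr.predict(X)
        rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
        corr = float(np.corrcoef(recon, y)[0, 1]) if recon.std() > 0 else 0.0
        if best is None or rmse < best[1]:
            best = (svr.coef_.ravel().copy(), rmse, corr)
    return best


class SignatureDeconvolver(BaseEstimator):
    """nu-SVR deconvolution of bulk samples against a cell-type signature.

    ``fit(signature)`` stores the reference (genes x cell types
    DataFrame); ``transform(mixture)`` returns per-sample fractions.  The
    estimator is transform-shaped rather than predictive: the "model" is
    the signature itself.
    """

    def __init__(self, nus: tuple[float, ...] = DEFAULT_NUS,
                 n_perm: int = 100, random_state: int = 0):
        self.nus = nus
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, signature: pd.DataFrame, y=None):
        if signature.index.duplicated().any():
            raise ValueError("signature contains duplicate genes")
        if signature.shape[1] < 2:
            raise ValueError("signature needs >= 2 cell types")
        if any(not 0.0 < nu < 1.0 for nu in self.nus):
            raise ValueError("all nu values must lie in (0, 1)")
        self.signature_ = signature
        return self

    def transform(self, mixture: pd.DataFrame) -> pd.DataFrame:
        """Deconvolve a genes x samples matrix into a FractionTable.

        Returns samples x (cell types + p_value, rmse, corr); fractions
        are non-negative and sum to one per sample.
        """
        check_is_fitted(self, "signature_")
        sig = self.signature_
        shared = mixture.index.intersection(sig.index)
        if len(shared) < 2:
            raise ValueError(
                f"only {len(shared)} genes shared between mixture and signature"
            )
        logger.info("deconvolving %d samples on %d shared genes, %d cell types",
                    mixture.shape[1], len(shared), sig.shape[1])
        X = np.apply_along_axis(_zscore, 0, sig.loc[shared].to_numpy(dtype=float))
        rng = np.random.default_rng(self.random_state)

        rows = {}
        corrs = {}
        for sample in mixture.columns:
            y = _zscore(mixture.loc[shared, sample].to_numpy(dtype=float))
            w, rmse, corr = _fit_sample(X, y, self.nus)
            w = np.clip(w, 0.0, None)
            total = w.sum()
            if total <= 0:
                logger.warning("%s: all coefficients non-positive; uniform fractions",
                               sample)
                fractions = np.full(len(w), 1.0 / len(w))
            else:
                fractions = w / total
            rows[sample] = np.concatenate([fractions, [rmse, corr]])
            corrs[sample] = corr

        # shared permutation null: gene-shuffled samples, same fitting path
        null_corrs = np.empty(self.n_perm)
        samples = list(mixture.columns)
        for b in range(self.n_perm):
            src = mixture.loc[shared, samples[b % len(samples)]].to_numpy(dtype=float)
            y_perm = _zscore(rng.permutation(src))
            _, _, null_corrs[b] = _fit_sample(X, y_perm, self.nus)

        table = pd.DataFrame.from_dict(
            rows, orient="index", columns=list(sig.columns) + ["rmse", "corr"]
        )
        table["p_value"] = [
            float(np.mean(null_corrs >= corrs[s])) for s in table.index
        ]
        table.index.name = "sample"
        return table

    def fit_transform(self, signature: pd.DataFrame, mixture: pd.DataFrame | None = None,
                      **kwargs) -> pd.DataFrame:
        if mixture is None:
            raise ValueError("fit_transform requires both signature and mixture")
        return self.fit(signature).transform(mixture)


def deconvolve_mixture(
    mixture: ExpressionStudy | pd.DataFrame,
    signature: pd.DataFrame,
    nus: tuple[float, ...] = DEFAULT_NUS,
    n_perm: int = 100,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Functional wrapper over :class:`SignatureDeconvolver`."""
    matrix = mixture.matrix if isinstance(mixture, ExpressionStudy) else mixture
    dec = SignatureDeconvolver(nus=nus, n_perm=n_perm, random_state=rng_seed)
    return dec.fit(signature).transform(matrix)


def filter_significant_samples(ft: pd.DataFrame, p_cutoff: float = 0.05) -> pd.DataFrame:
    """Keep samples with deconvolution ``p_value < p_cutoff`` (strict)."""
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must be in (0, 1]")
    kept = ft[ft["p_value"] < p_cutoff]
    logger.info("retained %d of %d samples at p < %g", len(kept), len(ft), p_cutoff)
    if kept.empty:
        logger.warning("no sample passed the deconvolution significance filter")
    return kept


def correlate_features(
    x: pd.DataFrame, y: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Pairwise correlations between the columns of two sample-aligned frames.

    Returns one row per (feature_a, feature_b) pair with the coefficient,
    two-sided p-value, and the interpretation band.  Zero-variance
    features yield NaN coefficients flagged ``undefined``.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown method {method!r}")
    common = x.index.intersection(y.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired observations")
    x, y = x.loc[common], y.loc[common]
    corr_fn = scipy.stats.pearsonr if method == "pearson" else scipy.stats.spearmanr
    rows = []
    for fa in x.columns:
        va = x[fa].to_numpy(dtype=float)
        for fb in y.columns:
            vb = y[fb].to_numpy(dtype=float)
            if va.std() == 0 or vb.std() == 0:
                rows.append((fa, fb, np.nan, np.nan, "undefined"))
                continue
            res = corr_fn(va, vb)
            coef, pval = float(res.statistic), float(res.pvalue)
            rows.append((fa, fb, coef, pval, correlation_band(coef)))
    return pd.DataFrame(
        rows, columns=["feature_a", "feature_b", "coefficient", "p_value", "band"]
    )
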