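"""Quantile normalisation, differential expression, and panel assembly.

Differential expression is case-vs-control on log2-scale values: the
effect is log2FC = mean(case) - mean(control), tested by a two-sided
Welch t-test with Benjamini-Hochberg adjustment across genes.  A gene is
flagged when ``adjusted_p < adj_p_cutoff`` and ``|log2FC| >=
log2(fc_cutoff)``.  The biomarker panel is the direction-concordant
intersection of two cohorts' flagged genes with the propagation catalog.
"""

from __future__ import annotations

import logging
from dataclasses import replace as _dc_replace

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.stats.multitest import multipletests

from .net_io import ExpressionStudy

logger = logging.getLogger("netprop.diffexpr")

__all__ = [
    "QuantileNormalizer",
    "quantile_normalize",
    "differential_expression",
    "derive_biomarker_panel",
]


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map every sample onto a common (mean-of-sorted-columns) distribution.

    Follows the sklearn transformer contract with samples as rows and
    genes as features, i.e. ``X`` of shape ``(n_samples, n_genes)`` —
    note this is the transpose of the genes x samples expression table.
    ``fit`` stores the reference distribution (per-rank mean over the
    fitted samples); ``transform`` replaces each sample's values by the
    reference values at their ranks, assigning tied entries the mean of
    the tied ranks' reference values.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        ref = self.reference_
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            row = X[i]
            # average rank handles ties: equal values get the mean of the
            # reference values their tied ranks would receive
            ranks = scipy.stats.rankdata(row, method="average")
            out[i] = np.interp(ranks, np.arange(1, len(ref) + 1), ref)
        return out


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Quantile-normalise the samples of a study against each other."""
    values = study.matrix.to_numpy(dtype=float).T  # samples x genes
    normed = QuantileNormalizer().fit_transform(values)
    matrix = pd.DataFrame(normed.T, index=study.matrix.index,
                          columns=study.matrix.columns)
    return _dc_replace(study, matrix=matrix)


def differential_expression(
    study: ExpressionStudy, adj_p_cutoff: float = 0.05, fc_cutoff: float = 1.2
) -> pd.DataFrame:
    """Welch t-test per gene with BH adjustment; full table with DEG flags.

    Returns a DataFrame indexed by gene with columns ``log2_fold_change``,
    ``p_value``, ``adjusted_p``, ``direction`` and ``is_deg``.  Genes with
    zero variance in both groups get p = 1 (logged).
    """
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must exceed 1")
    case = study.case_matrix().to_numpy(dtype=float)
    control = study.control_matrix().to_numpy(dtype=float)
    lfc = case.mean(axis=1) - control.mean(axis=1)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant genes trigger a precision warning; they are caught
        # below and assigned p = 1
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = scipy.stats.ttest_ind(case, control, axis=1, equal_var=False)
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        logger.info("%d genes with zero variance in both groups, p set to 1",
                    int(degenerate.sum()))
        pvals = np.where(degenerate, 1.0, pvals)
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": pvals,
            "adjusted_p": adj,
            "direction": np.where(lfc > 0, "up", "down"),
        },
        index=pd.Index(study.gene_ids, name="gene"),
    )
    table["is_deg"] = (table["adjusted_p"] < adj_p_cutoff) & (
        table["log2_fold_change"].abs() >= np.log2(fc_cutoff)
    )
    logger.info("%s: %d DEGs of %d genes (adj p < %g, FC >= %g)", study.cohort_id,
                int(table["is_deg"].sum()), len(table), adj_p_cutoff, fc_cutoff)
    return table


def derive_biomarker_panel(
    deg_a: pd.DataFrame, deg_b: pd.DataFrame, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Intersect two cohorts' DEGs with the catalog, requiring concordance.

    Panel genes must be flagged in both cohorts, carry the same direction
    in both, and appear in the catalog.  Returns a DataFrame with columns
    ``symbol``, ``direction``, ``origin``; discordant genes are logged.
    """
    flagged_a = deg_a[deg_a["is_deg"]]
    flagged_b = deg_b[deg_b["is_deg"]]
    common = flagged_a.index.intersection(flagged_b.index)
    origin = dict(zip(catalog["symbol"], catalog["origin"]))
    rows, discordant = [], []
    for gene in common:
        if gene not in origin:
            continue
        da, db = flagged_a.loc[gene, "direction"], flagged_b.loc[gene, "direction"]
        if da != db:
            discordant.append(gene)
            continue
        rows.append((gene, da, origin[gene]))
    if discordant:
        logger.info("%d genes discordant between cohorts, excluded: %s",
                    len(discordant), sorted(discordant)[:10])
    panel = pd.DataFrame(rows, columns=["symbol", "direction", "origin"])
    panel = panel.sort_values("symbol").reset_index(drop=True)
    if panel.empty:
        logger.warning("biomarker panel is empty")
    return panel
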