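"""Hypergeometric over-representation analysis against user term sets.

For a query set of n genes drawn from a universe of N, a term covering K
universe genes with k of them in the query gets the upper-tail
hypergeometric p-value P(X >= k).  Benjamini-Hochberg adjustment is
applied across terms; selection mirrors the raw-p < cutoff convention,
with the adjusted value reported alongside.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .net_io import GeneSet

logger = logging.getLogger("netprop.enrichment")

__all__ = ["overrepresentation"]


def overrepresentation(
    genes: GeneSet,
    annotation: Mapping[str, GeneSet],
    universe: GeneSet,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Test each annotation term for enrichment in the query set.

    Query genes outside the universe are dropped with a warning; term
    genes are restricted to the universe.  Returns a DataFrame sorted by
    p-value with columns term, k, n, K, N, p_value, adjusted_p,
    significant, genes.
    """
    if not annotation:
        raise ValueError("annotation mapping is empty")
    query = genes.members & universe.members
    dropped = genes.members - universe.members
    if dropped:
        logger.warning("%d query genes outside the universe dropped: %s",
                       len(dropped), sorted(dropped)[:10])
    if not query:
        raise ValueError("no query gene lies in the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for term in sorted(annotation):
        term_genes = annotation[term].members & universe.members
        K = len(term_genes)
        overlap = sorted(term_genes & query)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, k, n, K, N, p, ",".join(overlap)))
    table = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p_value", "genes"]
    )
    _, adj, _, _ = multipletests(table["p_value"], method="fdr_bh")
    table["adjusted_p"] = adj
    table["significant"] = table["p_value"] < p_cutoff
    table = table.sort_values(["p_value", "term"]).reset_index(drop=True)
    return table[["term", "k", "n", "K", "N", "p_value", "adjusted_p",
                  "significant", "genes"]]
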