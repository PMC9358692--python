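"""Network construction, random walk with restart, and permutation FDR.

The propagation stage scores every protein in a high-confidence PPI
network by its proximity to a set of validated seed genes.  The walker
update is

    P(t+1) = (1 - alpha) * M @ P(t) + alpha * P(0)

where ``M`` is the column-normalised (column-stochastic) adjacency of the
network, ``alpha`` the restart probability, and ``P(0)`` the uniform
distribution over seed nodes.  Iteration stops when the L1 change falls
below ``tol``.  Candidates above a probability threshold are screened by
an empirical permutation FDR: random seed sets of the same size are
propagated and, for each candidate, the FDR is the fraction of random
sets that score it strictly higher than the real seeds did.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .net_io import EdgeTable, GeneSet, IdMap

logger = logging.getLogger("netprop.propagation")

__all__ = [
    "Network",
    "TransitionMatrix",
    "RwrConfig",
    "build_network",
    "column_normalize",
    "make_seed_vector",
    "run_rwr",
    "select_candidates",
    "permutation_fdr",
    "assemble_catalog",
]


@dataclass
class Network:
    """An undirected, unweighted network with a fixed lexicographic node order."""

    nodes: list[str]
    adjacency: sp.csr_matrix
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=0)).ravel()


@dataclass
class TransitionMatrix:
    """Column-stochastic propagation operator of a :class:`Network`.

    ``matrix[i, j] = A[i, j] / degree(j)``; columns of isolated nodes are
    zero and flagged in ``zero_columns``.
    """

    matrix: sp.csr_matrix
    zero_columns: np.ndarray  # boolean mask over node indices

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RwrConfig:
    """Walker settings: restart probability, convergence, candidate cutoff."""

    alpha: float = 0.3
    tol: float = 1e-6
    max_iter: int = 1000
    candidate_threshold: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.candidate_threshold <= 0:
            raise ValueError("candidate_threshold must be positive")


def build_network(edges: EdgeTable, min_score: int = 899) -> Network:
    """Keep edges with ``combined_score > min_score`` (strict) and build G.

    Nodes are exactly the endpoints of retained edges, ordered
    lexicographically for reproducibility.
    """
    if not 1 <= min_score <= 999:
        raise ValueError(f"min_score must be in [1, 999], got {min_score}")
    kept = edges[edges["combined_score"] > min_score]
    if kept.empty:
        raise ValueError(f"no edges with combined_score > {min_score}")
    nodes = sorted(set(kept["protein_a"]) | set(kept["protein_b"]))
    index = {n: i for i, n in enumerate(nodes)}
    ia = kept["protein_a"].map(index).to_numpy()
    ib = kept["protein_b"].map(index).to_numpy()
    n = len(nodes)
    data = np.ones(len(kept), dtype=float)
    adj = sp.coo_matrix((data, (ia, ib)), shape=(n, n))
    adj = adj + adj.T
    adj.data[:] = 1.0  # binary adjacency
    net = Network(nodes=nodes, adjacency=adj.tocsr())
    logger.info("network: %d nodes, %d edges (score > %d)", net.n_nodes,
                net.n_edges, min_score)
    return net


def column_normalize(net: Network) -> TransitionMatrix:
    """Normalise each adjacency column by the node degree."""
    deg = net.degrees()
    zero = deg == 0
    inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, deg))
    matrix = (net.adjacency @ sp.diags(inv)).tocsr()
    if zero.any():
        logger.warning("%d isolated nodes produce zero columns", int(zero.sum()))
    return TransitionMatrix(matrix=matrix, zero_columns=zero)


def make_seed_vector(net: Network, seeds: GeneSet) -> np.ndarray:
    """Uniform restart vector over the seeds that map into the network."""
    mapped = [g for g in sorted(seeds.members) if g in net.index]
    unmapped = sorted(seeds.members - set(mapped))
    if not mapped:
        raise ValueError("no seed gene maps into the network")
    if unmapped:
        logger.warning("%d seeds not in network, ignored: %s", len(unmapped), unmapped)
    p0 = np.zeros(net.n_nodes)
    for g in mapped:
        p0[net.index[g]] = 1.0 / len(mapped)
    return p0


def run_rwr(
    M: TransitionMatrix, p0: np.ndarray, cfg: RwrConfig | None = None
) -> np.ndarray:
    """Iterate the restart walk to its stationary distribution.

    Returns the converged probability vector; if ``max_iter`` is reached
    first a warning is logged and the last iterate is returned.
    """
    cfg = cfg or RwrConfig()
    if p0.shape[0] != M.n_nodes:
        raise ValueError("seed vector length does not match network size")
    p = p0.copy()
    A = M.matrix
    for it in range(cfg.max_iter):
        p_next = (1.0 - cfg.alpha) * (A @ p) + cfg.alpha * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < cfg.tol:
            logger.debug("RWR converged after %d iterations (L1 delta %.2e)", it + 1, delta)
            return p
    logger.warning("RWR did not converge within %d iterations (L1 delta %.2e)",
                   cfg.max_iter, delta)
    return p


def rwr_closed_form(M: TransitionMatrix, p0: np.ndarray, alpha: float) -> np.ndarray:
    """Direct linear solve of the stationary equation; small graphs only."""
    n = M.n_nodes
    lhs = np.eye(n) - (1.0 - alpha) * M.matrix.toarray()
    return alpha * np.linalg.solve(lhs, p0)


def _run_rwr_batch(
    M: TransitionMatrix, P0: np.ndarray, cfg: RwrConfig
) -> np.ndarray:
    """Vectorised RWR over the columns of P0 (one walk per column)."""
    P = P0.copy()
    A = M.matrix
    active = np.ones(P.shape[1], dtype=bool)
    for _ in range(cfg.max_iter):
        P_next = (1.0 - cfg.alpha) * (A @ P) + cfg.alpha * P0
        deltas = np.abs(P_next - P).sum(axis=0)
        P = P_next
        active = deltas >= cfg.tol
        if not active.any():
            break
    return P


def select_candidates(
    p: np.ndarray, net: Network, seeds: GeneSet, threshold: float = 1e-4
) -> pd.DataFrame:
    """Non-seed nodes scoring strictly above ``threshold``.

    Sorted by descending score, ties broken lexicographically by node ID.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rows = [
        (node, p[i])
        for node, i in net.index.items()
        if node not in seeds.members and p[i] > threshold
    ]
    df = pd.DataFrame(rows, columns=["gene", "score"])
    df = df.sort_values(["score", "gene"], ascending=[False, True]).reset_index(drop=True)
    if df.empty:
        logger.info("no candidate exceeds threshold %g", threshold)
    return df


def permutation_fdr(
    net: Network,
    M: TransitionMatrix,
    seeds: GeneSet,
    candidates: pd.DataFrame,
    n_perm: int = 1000,
    cfg: RwrConfig | None = None,
    rng_seed: int = 0,
    seed_sets: Sequence[Sequence[str]] | None = None,
    exclude_seeds: bool = False,
) -> pd.DataFrame:
    """Empirical FDR of candidate scores against random seed sets.

    Draws ``n_perm`` seed sets of the mapped-seed size uniformly without
    replacement from all network nodes (by default including the true
    seeds; ``exclude_seeds`` removes them from the pool) and reruns the
    walk for each.  For candidate g, ``delta`` counts the permutations in
    which g's permuted score is strictly larger than its observed score
    and ``fdr = delta / n_perm``.  An explicit ``seed_sets`` sequence
    (e.g. an exhaustive enumeration) overrides the random draw.
    """
    cfg = cfg or RwrConfig()
    if candidates.empty:
        raise ValueError("candidate list is empty")
    mapped = [g for g in sorted(seeds.members) if g in net.index]
    k = len(mapped)
    pool = net.nodes
    if exclude_seeds:
        pool = [n for n in pool if n not in seeds.members]
    if k > len(pool):
        raise ValueError(f"seed-set size {k} exceeds sampling pool {len(pool)}")

    if seed_sets is None:
        rng = np.random.default_rng(rng_seed)
        pool_arr = np.array(pool)
        seed_sets = [rng.choice(pool_arr, size=k, replace=False) for _ in range(n_perm)]
    else:
        seed_sets = [list(s) for s in seed_sets]
    n_perm = len(seed_sets)

    n = net.n_nodes
    P0 = np.zeros((n, n_perm))
    for j, s in enumerate(seed_sets):
        idx = [net.index[g] for g in s]
        P0[idx, j] = 1.0 / len(idx)
    scores = _run_rwr_batch(M, P0, cfg)

    cand_idx = np.array([net.index[g] for g in candidates["gene"]])
    observed = candidates["score"].to_numpy()
    delta = (scores[cand_idx, :] > observed[:, None]).sum(axis=1)
    out = pd.DataFrame(
        {
            "gene": candidates["gene"].to_numpy(),
            "observed_score": observed,
            "delta": delta.astype(int),
            "fdr": delta / n_perm,
        }
    )
    return out


def exhaustive_seed_sets(net: Network, k: int) -> list[tuple[str, ...]]:
    """All C(n, k) seed sets over the network nodes (tiny graphs only)."""
    n_sets = math.comb(net.n_nodes, k)
    if n_sets > 200_000:
        raise ValueError(f"{n_sets} seed sets is too many to enumerate")
    return list(combinations(net.nodes, k))


def assemble_catalog(
    validated: GeneSet,
    fdr: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    idmap: IdMap | None = None,
) -> pd.DataFrame:
    """Merge validated seeds with candidates passing ``fdr < cutoff``.

    Candidate node IDs are translated to symbols through ``idmap`` when
    given (unmapped IDs are dropped with a log entry); any symbol already
    validated keeps its ``validated`` origin.  Returns a DataFrame with
    columns ``symbol`` and ``origin``.
    """
    if not 0.0 < fdr_cutoff <= 1.0:
        raise ValueError("fdr_cutoff must be in (0, 1]")
    passing = fdr.loc[fdr["fdr"] < fdr_cutoff, "gene"]
    predicted: set[str] = set()
    unmapped: list[str] = []
    for gene in passing:
        if idmap is not None:
            if gene in idmap:
                predicted.add(idmap.symbol(gene))
            else:
                unmapped.append(gene)
        else:
            predicted.add(gene)
    if unmapped:
        logger.warning("%d predicted accessions had no symbol and were dropped",
                       len(unmapped))
    predicted -= validated.members
    rows = [(s, "validated") for s in sorted(validated.members)]
    rows += [(s, "predicted") for s in sorted(predicted)]
    catalog = pd.DataFrame(rows, columns=["symbol", "origin"])
    logger.info("catalog: %d validated + %d predicted = %d genes",
                len(validated), len(predicted), len(catalog))
    return catalog
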