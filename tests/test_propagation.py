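"""Network build, restart walks, and the permutation FDR screen.

The independent oracles here are a dense linear solve of the stationary
equation and an exhaustive enumeration of all seed sets on a tiny graph.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from netprop import (
    GeneSet,
    RwrConfig,
    assemble_catalog,
    build_network,
    column_normalize,
    make_seed_vector,
    permutation_fdr,
    run_rwr,
    select_candidates,
    synth_network,
    SynthConfig,
)
from netprop.net_io import IdMap
from netprop.propagation import Network, exhaustive_seed_sets, rwr_closed_form
import scipy.sparse as sp


def edge_table(rows):
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])


def random_network(rng, n_nodes):
    """Erdos-Renyi style scored edge list over n_nodes, always connected enough."""
    rows = []
    nodes = [f"N{i:03d}" for i in range(n_nodes)]
    for i in range(1, n_nodes):  # spanning tree to avoid isolated nodes
        j = int(rng.integers(0, i))
        rows.append((nodes[i], nodes[j], 950))
    for _ in range(n_nodes):
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            rows.append((nodes[i], nodes[j], int(rng.integers(900, 1000))))
    return build_network(edge_table(rows), min_score=899)


class TestBuildNetwork:
    def test_strict_score_filter(self):
        net = build_network(
            edge_table([("A", "B", 900), ("B", "C", 899)]), min_score=899
        )
        assert net.nodes == ["A", "B"]
        assert net.n_edges == 1

    def test_all_above_threshold_retained(self):
        net = build_network(
            edge_table([("A", "B", 950), ("B", "C", 999), ("C", "D", 960)]),
            min_score=899,
        )
        assert net.n_edges == 3 and net.n_nodes == 4

    def test_no_surviving_edges_is_an_error(self):
        with pytest.raises(ValueError):
            build_network(edge_table([("A", "B", 500)]), min_score=899)

    def test_generator_bookkeeping(self, small_synth):
        _, edges, _, _ = small_synth
        k = int((edges["combined_score"] > 899).sum())
        net = build_network(edges, min_score=899)
        assert net.n_edges == k


class TestColumnNormalize:
    def test_path_graph_middle_column(self, path_graph_network):
        net, M = path_graph_network
        j = net.index["B"]
        col = M.matrix.toarray()[:, j]
        assert col[net.index["A"]] == pytest.approx(0.5)
        assert col[net.index["C"]] == pytest.approx(0.5)

    def test_star_center_column(self):
        net = build_network(
            edge_table([("HUB", "L1", 950), ("HUB", "L2", 950), ("HUB", "L3", 950)]),
            min_score=899,
        )
        M = column_normalize(net)
        col = M.matrix.toarray()[:, net.index["HUB"]]
        leaves = [net.index[x] for x in ("L1", "L2", "L3")]
        assert np.allclose(col[leaves], 1 / 3)

    def test_all_columns_stochastic_on_random_graph(self):
        rng = np.random.default_rng(11)
        net = random_network(rng, 60)
        M = column_normalize(net)
        sums = np.asarray(M.matrix.sum(axis=0)).ravel()
        assert np.allclose(sums[~M.zero_columns], 1.0, atol=1e-12)


class TestSeedVector:
    def test_uniform_over_mapped_seeds(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 80)
        seeds = GeneSet.from_iterable("s", net.nodes[:76])
        p0 = make_seed_vector(net, seeds)
        assert np.all(p0[[net.index[g] for g in seeds]] == pytest.approx(1 / 76))
        assert p0.sum() == pytest.approx(1.0)

    def test_single_seed_gets_unit_mass(self, path_graph_network):
        net, _ = path_graph_network
        p0 = make_seed_vector(net, GeneSet.from_iterable("s", ["A"]))
        assert p0[net.index["A"]] == 1.0

    def test_unmapped_seeds_logged_not_counted(self, path_graph_network, caplog):
        net, _ = path_graph_network
        with caplog.at_level("WARNING", logger="netprop.propagation"):
            p0 = make_seed_vector(
                net, GeneSet.from_iterable("s", ["A", "B", "X1", "X2"])
            )
        assert np.isclose(p0.sum(), 1.0)
        assert p0[net.index["A"]] == pytest.approx(0.5)
        assert "X1" in caplog.text and "X2" in caplog.text

    def test_no_mapped_seed_is_an_error(self, path_graph_network):
        net, _ = path_graph_network
        with pytest.raises(ValueError):
            make_seed_vector(net, GeneSet.from_iterable("s", ["NOPE"]))


class TestRunRwr:
    def test_dangling_seed_converges_to_alpha(self):
        # a node with no outgoing mass keeps only the restart term
        net = Network(nodes=["A"], adjacency=sp.csr_matrix((1, 1)))
        M = column_normalize(net)
        p = run_rwr(M, np.array([1.0]), RwrConfig(alpha=0.3))
        assert p[0] == pytest.approx(0.3, abs=1e-6)

    def test_restart_only_limit_returns_p0(self, path_graph_network):
        net, M = path_graph_network
        p0 = make_seed_vector(net, GeneSet.from_iterable("s", ["A"]))
        p = run_rwr(M, p0, RwrConfig(alpha=1.0))
        assert np.allclose(p, p0)

    def test_matches_direct_linear_solve(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            net = random_network(rng, int(rng.integers(20, 60)))
            M = column_normalize(net)
            seeds = GeneSet.from_iterable("s", list(net.nodes[:5]))
            p0 = make_seed_vector(net, seeds)
            p_iter = run_rwr(M, p0, RwrConfig(alpha=0.3, tol=1e-12))
            p_exact = rwr_closed_form(M, p0, alpha=0.3)
            assert np.max(np.abs(p_iter - p_exact)) < 1e-8

    def test_probability_mass_conserved(self):
        rng = np.random.default_rng(31)
        net = random_network(rng, 50)
        M = column_normalize(net)
        p0 = make_seed_vector(net, GeneSet.from_iterable("s", net.nodes[:7]))
        p = run_rwr(M, p0, RwrConfig())
        assert abs(p.sum() - 1.0) < 1e-10

    @pytest.mark.parametrize("graph_seed", [1, 2, 3])
    def test_seed_mass_monotone_in_restart_probability(self, graph_seed):
        rng = np.random.default_rng(graph_seed)
        net = random_network(rng, 40)
        M = column_normalize(net)
        seeds = GeneSet.from_iterable("s", net.nodes[:5])
        idx = [net.index[g] for g in seeds]
        p0 = make_seed_vector(net, seeds)
        masses = [
            run_rwr(M, p0, RwrConfig(alpha=a, tol=1e-10))[idx].sum()
            for a in (0.1, 0.3, 0.5, 0.9)
        ]
        assert np.all(np.diff(masses) >= -1e-12)


class TestSelectCandidates:
    def test_empty_when_all_below_threshold(self, path_graph_network):
        net, M = path_graph_network
        p = np.array([1e-6, 1e-6, 1e-6])
        out = select_candidates(p, net, GeneSet.from_iterable("s", ["A"]), 1e-4)
        assert out.empty

    def test_seed_nodes_excluded_regardless_of_score(self, path_graph_network):
        net, _ = path_graph_network
        p = np.array([0.9, 0.05, 0.05])
        out = select_candidates(p, net, GeneSet.from_iterable("s", ["A"]), 1e-4)
        assert "A" not in set(out["gene"])
        assert list(out["gene"]) == ["B", "C"]  # tie broken lexicographically

    def test_planted_module_ranks_above_background(self, small_synth, small_network):
        _, _, idmap, truth = small_synth
        net, M = small_network
        seed_acc = GeneSet.from_iterable(
            "s", (idmap.accession(g) for g in truth.seed_genes)
        )
        p = run_rwr(M, make_seed_vector(net, seed_acc))
        ranked = select_candidates(p, net, seed_acc, 1e-12)
        ranks = {g: r for r, g in enumerate(ranked["gene"])}
        module_acc = {
            idmap.accession(g)
            for g in truth.module_genes.members - truth.seed_genes.members
        } & set(net.nodes)
        other = set(ranks) - module_acc
        assert np.median([ranks[g] for g in module_acc]) < np.median(
            [ranks[g] for g in other]
        )


class TestPermutationFdr:
    def test_untouchable_candidate_has_zero_fdr(self, path_graph_network):
        net, M = path_graph_network
        seeds = GeneSet.from_iterable("s", ["A"])
        candidates = pd.DataFrame({"gene": ["B"], "score": [10.0]})  # unbeatable
        out = permutation_fdr(net, M, seeds, candidates, n_perm=50, rng_seed=1)
        assert out.loc[0, "fdr"] == 0.0

    def test_fdr_is_exceedance_fraction(self, small_synth, small_network):
        _, _, idmap, truth = small_synth
        net, M = small_network
        seed_acc = GeneSet.from_iterable(
            "s", (idmap.accession(g) for g in truth.seed_genes)
        )
        p = run_rwr(M, make_seed_vector(net, seed_acc))
        cand = select_candidates(p, net, seed_acc, 1e-4).head(20)
        out = permutation_fdr(net, M, seed_acc, cand, n_perm=100, rng_seed=9)
        assert np.all(out["fdr"] == out["delta"] / 100)
        assert out["fdr"].between(0, 1).all()
        # reproducibility under the same rng seed
        again = permutation_fdr(net, M, seed_acc, cand, n_perm=100, rng_seed=9)
        pd.testing.assert_frame_equal(out, again)

    def test_exhaustive_enumeration_matches_brute_force(self):
        # 8-node graph, all C(8,2)=28 seed sets; oracle recomputes every
        # walk by dense linear solve and counts exceedances independently
        rows = [
            ("A", "B", 950), ("B", "C", 950), ("C", "D", 950), ("D", "E", 950),
            ("E", "F", 950), ("F", "G", 950), ("G", "H", 950), ("H", "A", 950),
            ("A", "E", 950), ("B", "F", 950),
        ]
        net = build_network(edge_table(rows), min_score=899)
        M = column_normalize(net)
        seeds = GeneSet.from_iterable("s", ["A", "B"])
        p = run_rwr(M, make_seed_vector(net, seeds), RwrConfig(tol=1e-12))
        cand = select_candidates(p, net, seeds, 1e-6)
        sets = exhaustive_seed_sets(net, 2)
        assert len(sets) == 28
        out = permutation_fdr(
            net, M, seeds, cand, cfg=RwrConfig(tol=1e-12), seed_sets=sets
        )
        for _, row in out.iterrows():
            gi = net.index[row["gene"]]
            delta_oracle = 0
            for pair in combinations(net.nodes, 2):
                p0 = np.zeros(net.n_nodes)
                p0[[net.index[g] for g in pair]] = 0.5
                if rwr_closed_form(M, p0, alpha=0.3)[gi] > row["observed_score"]:
                    delta_oracle += 1
            assert row["delta"] == delta_oracle
            assert row["fdr"] == delta_oracle / 28


class TestAssembleCatalog:
    def _fdr(self, genes, fdrs):
        return pd.DataFrame(
            {"gene": genes, "observed_score": 0.1, "delta": 0, "fdr": fdrs}
        )

    def test_validated_takes_precedence(self):
        validated = GeneSet.from_iterable("v", ["A"])
        catalog = assemble_catalog(validated, self._fdr(["A", "B"], [0.0, 0.0]), 0.05)
        assert dict(zip(catalog["symbol"], catalog["origin"])) == {
            "A": "validated",
            "B": "predicted",
        }

    def test_no_passing_candidates_leaves_validated_only(self):
        validated = GeneSet.from_iterable("v", ["A", "B"])
        catalog = assemble_catalog(validated, self._fdr(["C"], [0.9]), 0.05)
        assert set(catalog["symbol"]) == {"A", "B"}
        assert (catalog["origin"] == "validated").all()

    def test_cutoff_is_strict(self):
        validated = GeneSet.from_iterable("v", ["A"])
        catalog = assemble_catalog(
            validated, self._fdr(["B", "C"], [0.05, 0.049]), 0.05
        )
        assert set(catalog.loc[catalog["origin"] == "predicted", "symbol"]) == {"C"}

    def test_idmap_translation(self):
        idmap = IdMap({"P1": "SYM1", "P2": "SYM2"})
        validated = GeneSet.from_iterable("v", ["SYM2"])
        catalog = assemble_catalog(
            validated, self._fdr(["P1", "P2"], [0.0, 0.0]), 0.05, idmap=idmap
        )
        assert dict(zip(catalog["symbol"], catalog["origin"])) == {
            "SYM1": "predicted",
            "SYM2": "validated",
        }
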