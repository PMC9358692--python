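"""Seeded generators for every input the pipeline consumes.

The generators emulate the shape of the real inputs — a scale-free PPI
network with STRING-style confidence scores, case/control log2
expression cohorts, and signature-based bulk mixtures — while planting a
known ground truth so every downstream stage can be checked against what
was actually put in:

* ``synth_network`` grows a preferential-attachment backbone and
  densifies a randomly chosen module; seed genes are drawn from the
  module, so propagation has a planted neighbourhood to recover.
* ``synth_expression`` plants differential expression on the module
  genes (and some off-module decoys) with cohort-concordant directions.
  One designated *informative pair* gets the largest effect in both
  training cohorts; every other module gene is strongly informative in
  only one of the two, so feature selection should recover exactly the
  pair.
* ``synth_mixtures`` builds a marker-block signature matrix and mixes it
  with Dirichlet-drawn fractions; the first cell type's fraction is also
  wired into the informative pair's expression so the correlation stage
  has a planted strong association.

Every generator is a pure function of :class:`SynthConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .net_io import EdgeTable, ExpressionStudy, GeneSet, IdMap, EDGE_COLUMNS

logger = logging.getLogger("netprop.synthetic_data")

__all__ = ["SynthConfig", "GroundTruth", "synth_network", "synth_expression",
           "synth_mixtures"]


def _symbol(i: int) -> str:
    return f"G{i:04d}"


def _accession(i: int) -> str:
    return f"PROT{i:04d}"


@dataclass
class SynthConfig:
    """All knobs of the synthetic study, with the default study design.

    The default cohort designs mirror a two-training- plus one-test-cohort
    blood study (39/24, 69/23 and 6/3 case/control samples); expression is
    log2-scale with per-gene baselines ~ N(8, 1) and sample noise
    ``noise_sd``; planted effects are ``de_effect`` log2 units (doubled
    for the informative pair).  The deconvolution reference has 22 cell
    types with 10 marker genes each.
    """

    rng_seed: int = 0
    # network; seed count stays ~1% of nodes, matching the regime where
    # a random permutation set rarely contains the candidate itself
    n_nodes: int = 1000
    attach_param: int = 3
    module_size: int = 40
    module_extra_edge_prob: float = 0.5
    n_seed_genes: int = 10
    decoy_edge_frac: float = 0.5
    # expression
    cohort_designs: tuple[tuple[str, int, int], ...] = (
        ("cohort_a", 39, 24),
        ("cohort_b", 69, 23),
        ("cohort_test", 6, 3),
    )
    de_effect: float = 1.0
    noise_sd: float = 0.5
    n_offmodule_de: int = 30
    informative_boost: float = 2.0
    nonpreferred_factor: float = 0.55
    # mixtures
    n_celltypes: int = 22
    n_signature_genes: int = 220
    n_mixture_samples: int = 40
    dirichlet_alpha: float = 1.0
    mixture_noise: float = 0.1

    def __post_init__(self) -> None:
        if self.module_size > self.n_nodes:
            raise ValueError("module_size must not exceed n_nodes")
        if self.n_seed_genes > self.module_size:
            raise ValueError("n_seed_genes must not exceed module_size")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_celltypes < 2:
            raise ValueError("need >= 2 cell types")
        if min(self.n_nodes, self.module_size, self.n_seed_genes,
               self.attach_param, self.n_signature_genes,
               self.n_mixture_samples) < 1:
            raise ValueError("all sizes must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: the module, seeds, DE genes, pair, and fractions."""

    module_genes: GeneSet
    seed_genes: GeneSet
    de_directions: dict[str, str] = field(default_factory=dict)
    informative_pair: tuple[str, str] | None = None
    preferred_cohort: dict[str, str] = field(default_factory=dict)
    true_fractions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.seed_genes.members <= self.module_genes.members:
            raise ValueError("seed genes must lie inside the module")
        if self.informative_pair is not None:
            pair = set(self.informative_pair)
            if self.de_directions and not pair <= set(self.de_directions):
                raise ValueError("informative pair must be planted DE genes")
            if not pair <= self.module_genes.members:
                raise ValueError("informative pair must lie inside the module")

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(self.de_directions)


def synth_network(cfg: SynthConfig) -> tuple[EdgeTable, IdMap, GroundTruth]:
    """Scale-free network with a densified planted module and decoy edges.

    True edges carry STRING-style scores in [900, 999]; decoy edges
    between non-adjacent pairs carry sub-threshold scores in [1, 899], so
    the score filter at 899 recovers exactly the true structure.
    """
    rng = np.random.default_rng([17, cfg.rng_seed])
    graph = nx.barabasi_albert_graph(
        cfg.n_nodes, cfg.attach_param, seed=int(rng.integers(2**31))
    )
    module_nodes = sorted(rng.choice(cfg.n_nodes, size=cfg.module_size, replace=False))
    for u, v in combinations(module_nodes, 2):
        if not graph.has_edge(u, v) and rng.random() < cfg.module_extra_edge_prob:
            graph.add_edge(u, v)

    true_edges = sorted((min(u, v), max(u, v)) for u, v in graph.edges())
    n_decoys = int(len(true_edges) * cfg.decoy_edge_frac)
    decoys: set[tuple[int, int]] = set()
    guard = 0
    while len(decoys) < n_decoys and guard < 50 * n_decoys:
        u, v = rng.integers(cfg.n_nodes, size=2)
        guard += 1
        if u == v:
            continue
        pair = (min(u, v), max(u, v))
        if graph.has_edge(*pair) or pair in decoys:
            continue
        decoys.add(pair)

    records = [
        (_accession(u), _accession(v), int(rng.integers(900, 1000)))
        for u, v in true_edges
    ] + [
        (_accession(u), _accession(v), int(rng.integers(1, 900)))
        for u, v in sorted(decoys)
    ]
    edges = pd.DataFrame(records, columns=EDGE_COLUMNS)
    edges = edges.sort_values(EDGE_COLUMNS[:2]).reset_index(drop=True)

    idmap = IdMap({_accession(i): _symbol(i) for i in range(cfg.n_nodes)})
    module_symbols = [_symbol(i) for i in module_nodes]
    seed_symbols = sorted(
        map(str, rng.choice(module_symbols, size=cfg.n_seed_genes, replace=False))
    )
    # the informative pair sits at the best-connected non-seed module
    # nodes: biomarkers are catalog members by construction, so the pair
    # must be reliably reachable by propagation from the seeds
    module_set = set(module_nodes)
    non_seed_nodes = [i for i in module_nodes if _symbol(i) not in seed_symbols]
    within_degree = {
        i: sum(1 for j in graph.neighbors(i) if j in module_set)
        for i in non_seed_nodes
    }
    central = sorted(non_seed_nodes,
                     key=lambda i: (-within_degree[i], i))[:2]
    pair = tuple(sorted(_symbol(i) for i in central)) if len(central) == 2 else None
    truth = GroundTruth(
        module_genes=GeneSet.from_iterable("planted_module", module_symbols),
        seed_genes=GeneSet.from_iterable("planted_seeds", seed_symbols),
        informative_pair=pair,
    )
    logger.info("synthetic network: %d nodes, %d true + %d decoy edges, "
                "module %d, seeds %d", cfg.n_nodes, len(true_edges), len(decoys),
                cfg.module_size, cfg.n_seed_genes)
    return edges, idmap, truth


def _plant_design(cfg: SynthConfig, truth: GroundTruth,
                  rng: np.random.Generator) -> GroundTruth:
    """Assign DE directions, the informative pair, and cohort preferences."""
    module = sorted(truth.module_genes.members)
    non_module = sorted(set(_symbol(i) for i in range(cfg.n_nodes))
                        - truth.module_genes.members)
    off_de = [str(g) for g in rng.choice(non_module,
                                         size=min(cfg.n_offmodule_de,
                                                  len(non_module)),
                                         replace=False)]
    de_genes = module + sorted(off_de)
    directions = {g: ("up" if rng.random() < 0.5 else "down") for g in de_genes}
    if truth.informative_pair is not None:
        pair = truth.informative_pair
    else:
        non_seed_module = sorted(truth.module_genes.members
                                 - truth.seed_genes.members)
        pool = non_seed_module if len(non_seed_module) >= 2 else module
        pair = tuple(sorted(map(str, rng.choice(pool, size=2, replace=False))))
    training = [c[0] for c in cfg.cohort_designs[:2]]
    preferred = {}
    for g in de_genes:
        if g in pair:
            continue
        preferred[g] = training[int(rng.random() < 0.5)] if len(training) == 2 \
            else training[0]
    return GroundTruth(
        module_genes=truth.module_genes,
        seed_genes=truth.seed_genes,
        de_directions=directions,
        informative_pair=pair,
        preferred_cohort=preferred,
        true_fractions=truth.true_fractions,
    )


def synth_expression(
    cfg: SynthConfig, truth: GroundTruth
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Log2-scale cohorts with planted, cohort-concordant effects.

    All module genes plus ``n_offmodule_de`` off-module decoys are
    differentially expressed in every cohort with a shared direction.
    The informative pair's shift is ``informative_boost * de_effect``
    everywhere; every other planted gene gets the full ``de_effect`` only
    in its preferred training cohort and ``nonpreferred_factor *
    de_effect`` in the other, which decorrelates the two cohorts'
    importance rankings below the pair.  Returns the cohorts and the
    ground truth completed with directions, pair, and preferences.
    """
    rng = np.random.default_rng([29, cfg.rng_seed])
    if not truth.de_directions:
        truth = _plant_design(cfg, truth, rng)
    genes = [_symbol(i) for i in range(cfg.n_nodes)]
    training = {c[0] for c in cfg.cohort_designs[:2]}
    studies = []
    for cohort_id, n_case, n_control in cfg.cohort_designs:
        n_samples = n_case + n_control
        baseline = rng.normal(8.0, 1.0, size=len(genes))
        values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd,
                                                size=(len(genes), n_samples))
        for gi, g in enumerate(genes):
            if g not in truth.de_directions:
                continue
            if truth.informative_pair and g in truth.informative_pair:
                effect = cfg.informative_boost * cfg.de_effect
            else:
                pref = truth.preferred_cohort.get(g)
                if cohort_id in training and pref is not None and pref != cohort_id:
                    effect = cfg.nonpreferred_factor * cfg.de_effect
                else:
                    effect = cfg.de_effect
            sign = 1.0 if truth.de_directions[g] == "up" else -1.0
            values[gi, :n_case] += sign * effect
        samples = [f"{cohort_id}_s{j:03d}" for j in range(n_samples)]
        labels = pd.Series(["case"] * n_case + ["control"] * n_control,
                           index=samples, name="label")
        matrix = pd.DataFrame(values, index=genes, columns=samples)
        studies.append(ExpressionStudy(cohort_id=cohort_id, matrix=matrix,
                                       labels=labels))
    return studies, truth


def synth_mixtures(
    cfg: SynthConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, ExpressionStudy, GroundTruth]:
    """Marker-block signature, Dirichlet mixtures, and known fractions.

    The signature has ``n_celltypes`` columns with disjoint high-value
    marker blocks on a low uniform background (linear scale).  Mixtures
    are signature x fractions plus Gaussian noise scaled to
    ``mixture_noise`` of the mean signal.  When a ground truth with an
    informative pair is supplied, the pair's expression is appended to
    the mixture matrix as an affine function of the first cell type's
    fraction, planting a strong positive correlation.
    """
    rng = np.random.default_rng([43, cfg.rng_seed])
    sig_genes = [f"MKR{i:04d}" for i in range(cfg.n_signature_genes)]
    cells = [f"celltype_{k:02d}" for k in range(cfg.n_celltypes)]
    sig = rng.uniform(0.5, 1.5, size=(cfg.n_signature_genes, cfg.n_celltypes))
    block = max(1, cfg.n_signature_genes // cfg.n_celltypes)
    for k in range(cfg.n_celltypes):
        rows = slice(k * block, min((k + 1) * block, cfg.n_signature_genes))
        sig[rows, k] += rng.uniform(8.0, 12.0, size=sig[rows, k].shape)
    signature = pd.DataFrame(sig, index=sig_genes, columns=cells)

    fractions = rng.dirichlet([cfg.dirichlet_alpha] * cfg.n_celltypes,
                              size=cfg.n_mixture_samples)
    clean = sig @ fractions.T
    noise_sd = cfg.mixture_noise * clean.mean()
    mixtures = clean + rng.normal(0.0, noise_sd, size=clean.shape) \
        if noise_sd > 0 else clean.copy()
    samples = [f"mix_s{j:03d}" for j in range(cfg.n_mixture_samples)]
    matrix = pd.DataFrame(mixtures, index=sig_genes, columns=samples)

    frame = pd.DataFrame(fractions, index=samples, columns=cells)
    if truth is not None and truth.informative_pair is not None:
        # plant a strong association: pair expression tracks celltype_00
        f0 = fractions[:, 0]
        for j, g in enumerate(truth.informative_pair):
            jitter = rng.normal(0.0, 0.25 * (f0.std() or 1.0), size=len(f0))
            matrix.loc[g] = 5.0 + (4.0 if j == 0 else 2.0) * f0 + jitter
        out_truth = GroundTruth(
            module_genes=truth.module_genes, seed_genes=truth.seed_genes,
            de_directions=truth.de_directions,
            informative_pair=truth.informative_pair,
            preferred_cohort=truth.preferred_cohort, true_fractions=frame,
        )
    else:
        placeholder = GeneSet.from_iterable("none", ["_"])
        out_truth = GroundTruth(module_genes=placeholder, seed_genes=placeholder,
                                true_fractions=frame)
    n_half = cfg.n_mixture_samples // 2
    labels = pd.Series(["case"] * n_half
                       + ["control"] * (cfg.n_mixture_samples - n_half),
                       index=samples, name="label")
    study = ExpressionStudy(cohort_id="mixtures", matrix=matrix, labels=labels)
    return signature, study, out_truth
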