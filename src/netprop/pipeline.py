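"""End-to-end orchestration from a single YAML config.

Stage order: network construction -> random walk with restart ->
permutation FDR -> catalog -> per-cohort quantile normalisation and
differential expression -> concordant panel -> random-forest selection
-> neural-network classification with train/transfer ROC -> signature
deconvolution -> biomarker/fraction correlations.  Inputs come either
from files (``inputs`` block) or from the seeded synthetic generators
(``synthetic`` block).  Every stage's counts land in a machine-readable
:class:`RunReport`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import classify as cls
from . import deconvolve as dec
from . import diffexpr as dx
from . import net_io
from . import propagation as prop
from . import select_features as sel
from . import synthetic_data as synth
from .net_io import GeneSet

logger = logging.getLogger("netprop.pipeline")

__all__ = ["RunReport", "run_pipeline", "default_config"]

_KNOWN_BLOCKS = {
    "synthetic", "inputs", "network", "rwr", "permutation", "diffexpr",
    "select", "classify", "deconvolve",
}


def default_config() -> dict[str, Any]:
    """The pipeline defaults: every threshold at its canonical value."""
    return {
        "synthetic": {"rng_seed": 0},
        "network": {"min_score": 899},
        "rwr": {"alpha": 0.3, "tol": 1e-6, "max_iter": 1000,
                "candidate_threshold": 1e-4},
        "permutation": {"n_perm": 1000, "fdr_cutoff": 0.05, "rng_seed": 0},
        "diffexpr": {"adj_p_cutoff": 0.05, "fc_cutoff": 1.2},
        "select": {"tree_grid": [100, 250, 500],
                   "fraction": 0.25, "rng_seed": 0},
        "classify": {"hidden": 5, "rng_seed": 0},
        "deconvolve": {"nus": [0.25, 0.5, 0.75], "n_perm": 1000,
                       "p_cutoff": 0.05, "rng_seed": 0},
    }


@dataclass
class RunReport:
    """Per-stage counts and headline results of one pipeline run."""

    config: dict[str, Any]
    n_nodes: int = 0
    n_edges: int = 0
    n_seeds_mapped: int = 0
    n_candidates: int = 0
    n_predicted: int = 0
    catalog_size: int = 0
    n_degs: dict[str, int] = field(default_factory=dict)
    panel_size: int = 0
    n_trees: dict[str, int] = field(default_factory=dict)
    retained_per_cohort: dict[str, list[str]] = field(default_factory=dict)
    key_features: list[str] = field(default_factory=list)
    train_auc: dict[str, float] = field(default_factory=dict)
    transfer_auc: float | None = None
    transfer_model_cohort: str | None = None
    n_mixture_samples: int = 0
    n_samples_retained: int = 0
    top_correlation: dict[str, Any] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _load_config(config: str | Path | dict[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    unknown = set(config) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    if ("synthetic" in config) == ("inputs" in config):
        raise ValueError("config needs exactly one of 'synthetic' or 'inputs'")
    merged = default_config()
    merged.pop("synthetic")
    for block, values in config.items():
        if block in merged and isinstance(values, dict):
            merged[block] = {**merged[block], **values}
        else:
            merged[block] = values
    return merged


def _load_inputs(cfg: dict[str, Any]):
    if "synthetic" in cfg:
        scfg = synth.SynthConfig(**cfg["synthetic"])
        edges, idmap, truth = synth.synth_network(scfg)
        studies, truth = synth.synth_expression(scfg, truth)
        signature, mixture, truth = synth.synth_mixtures(scfg, truth)
        return edges, idmap, truth.seed_genes, studies, signature, mixture, truth
    paths = cfg["inputs"]
    edges = net_io.read_ppi_links(paths["links"])
    idmap = net_io.read_protein_info(paths["info"])
    seeds = net_io.read_gene_list(paths["seeds"], name="seeds")
    studies = [
        net_io.read_expression_table(c["expr"], c["labels"], c["cohort_id"])
        for c in paths["cohorts"]
    ]
    signature = pd.read_csv(paths["signature"], sep="\t", index_col=0)
    mixture = net_io.read_expression_table(
        paths["mixture"]["expr"], paths["mixture"]["labels"], "mixtures"
    )
    return edges, idmap, seeds, studies, signature, mixture, None


def run_pipeline(
    config: str | Path | dict[str, Any], out_dir: str | Path | None = None
) -> RunReport:
    """Execute every stage in order and return the run report.

    A stage failure propagates with the stage name attached.  When
    ``out_dir`` is given, per-stage TSVs and ``report.json`` are written
    there.
    """
    cfg = _load_config(config)
    report = RunReport(config=cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    t0 = time.perf_counter()
    try:
        edges, idmap, seeds, studies, signature, mixture, truth = _load_inputs(cfg)
        report.stage_seconds[stage] = time.perf_counter() - t0

        stage = "network"
        t0 = time.perf_counter()
        net = prop.build_network(edges, min_score=cfg["network"]["min_score"])
        M = prop.column_normalize(net)
        report.n_nodes, report.n_edges = net.n_nodes, net.n_edges
        report.stage_seconds[stage] = time.perf_counter() - t0

        stage = "propagation"
        t0 = time.perf_counter()
        rwr_cfg = prop.RwrConfig(
            alpha=cfg["rwr"]["alpha"], tol=cfg["rwr"]["tol"],
            max_iter=cfg["rwr"]["max_iter"],
            candidate_threshold=cfg["rwr"]["candidate_threshold"],
        )
        seed_accessions = GeneSet.from_iterable(
            "seed_accessions",
            (idmap.accession(s) for s in seeds if s in idmap.symbol_to_accession),
        )
        p0 = prop.make_seed_vector(net, seed_accessions)
        report.n_seeds_mapped = int((p0 > 0).sum())
        p = prop.run_rwr(M, p0, rwr_cfg)
        candidates = prop.select_candidates(
            p, net, seed_accessions, rwr_cfg.candidate_threshold
        )
        report.n_candidates = len(candidates)
        report.stage_seconds[stage] = time.perf_counter() - t0

        stage = "permutation_fdr"
        t0 = time.perf_counter()
        fdr = prop.permutation_fdr(
            net, M, seed_accessions, candidates,
            n_perm=cfg["permutation"]["n_perm"], cfg=rwr_cfg,
            rng_seed=cfg["permutation"]["rng_seed"],
        )
        catalog = prop.assemble_catalog(
            seeds, fdr, fdr_cutoff=cfg["permutation"]["fdr_cutoff"], idmap=idmap
        )
        report.n_predicted = int((catalog["origin"] == "predicted").sum())
        report.catalog_size = len(catalog)
        report.stage_seconds[stage] = time.perf_counter() - t0

        stage = "diffexpr"
        t0 = time.perf_counter()
        normed = [dx.quantile_normalize(s) for s in studies]
        deg_tables = {
            s.cohort_id: dx.differential_expression(
                s, adj_p_cutoff=cfg["diffexpr"]["adj_p_cutoff"],
                fc_cutoff=cfg["diffexpr"]["fc_cutoff"],
            )
            for s in normed
        }
        report.n_degs = {c: int(t["is_deg"].sum()) for c, t in deg_tables.items()}
        train_a, train_b = normed[0], normed[1]
        panel = dx.derive_biomarker_panel(
            deg_tables[train_a.cohort_id], deg_tables[train_b.cohort_id], catalog
        )
        report.panel_size = len(panel)
        report.stage_seconds[stage] = time.perf_counter() - t0

        stage = "select_features"
        t0 = time.perf_counter()
        retained: dict[str, GeneSet] = {}
        for study in (train_a, train_b):
            n_trees = sel.tune_tree_count(
                study, panel, grid=list(cfg["select"]["tree_grid"]),
                rng_seed=cfg["select"]["rng_seed"],
            )
            report.n_trees[study.cohort_id] = n_trees
            imp = sel.rank_rf_importance(study, panel, n_trees=n_trees,
                                         rng_seed=cfg["select"]["rng_seed"])
            kept = sel.retain_top_fraction(imp, fraction=cfg["select"]["fraction"])
            retained[study.cohort_id] = kept
            report.retained_per_cohort[study.cohort_id] = sorted(kept.members)
        key = sel.intersect_key_features(retained[train_a.cohort_id],
                                         retained[train_b.cohort_id])
        report.key_features = sorted(key.members)
        report.stage_seconds[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        key_panel = panel[panel["symbol"].isin(key.members)].reset_index(drop=True)
        models, rocs = {}, {}
        if not key_panel.empty:
            for study in (train_a, train_b):
                bin_m = cls.binarize_by_median(study, key_panel)
                model = cls.fit_nn_classifier(
                    bin_m, study.labels, hidden=cfg["classify"]["hidden"],
                    rng_seed=cfg["classify"]["rng_seed"],
                )
                roc = cls.evaluate_roc(model, bin_m, study.labels)
                models[study.cohort_id], rocs[study.cohort_id] = model, roc
                report.train_auc[study.cohort_id] = roc.auc
            best_cohort = max(rocs, key=lambda c: rocs[c].auc)
            report.transfer_model_cohort = best_cohort
            if len(normed) > 2:
                test_study = normed[2]
                bin_test = cls.binarize_by_median(test_study, key_panel)
                roc_test = cls.evaluate_roc(models[best_cohort], bin_test,
                                            test_study.labels)
                report.transfer_auc = roc_test.auc
        else:
            logger.warning("key-feature set empty; classification skipped")
        report.stage_seconds[stage] = time.perf_counter() - t0

        stage = "deconvolve"
        t0 = time.perf_counter()
        fractions = dec.deconvolve_mixture(
            mixture, signature, nus=tuple(cfg["deconvolve"]["nus"]),
            n_perm=cfg["deconvolve"]["n_perm"],
            rng_seed=cfg["deconvolve"]["rng_seed"],
        )
        report.n_mixture_samples = len(fractions)
        kept_fractions = dec.filter_significant_samples(
            fractions, p_cutoff=cfg["deconvolve"]["p_cutoff"]
        )
        report.n_samples_retained = len(kept_fractions)
        report.stage_seconds[stage] = time.perf_counter() - t0

        stage = "correlate"
        t0 = time.perf_counter()
        corr_table = None
        biomarkers = [g for g in report.key_features
                      if g in mixture.matrix.index]
        if biomarkers and len(kept_fractions) >= 3:
            expr = mixture.matrix.loc[biomarkers, kept_fractions.index].T
            cell_cols = list(signature.columns)
            corr_table = dec.correlate_features(
                expr, kept_fractions[cell_cols], method="spearman"
            )
            best = corr_table.loc[corr_table["coefficient"].abs().idxmax()]
            report.top_correlation = {
                "feature_a": best["feature_a"], "feature_b": best["feature_b"],
                "coefficient": float(best["coefficient"]), "band": best["band"],
            }
        report.stage_seconds[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # containment chain: seeds within catalog, panel within catalog, key
    # within panel -- violated only by an implementation defect
    catalog_symbols = set(catalog["symbol"])
    assert set(seeds.members) <= catalog_symbols
    assert set(panel["symbol"]) <= catalog_symbols
    assert set(report.key_features) <= set(panel["symbol"])

    if out is not None:
        pd.DataFrame({"node": net.nodes, "score": p}).to_csv(
            out / "scores.tsv", sep="\t", index=False)
        fdr.to_csv(out / "fdr.tsv", sep="\t", index=False)
        catalog.to_csv(out / "catalog.tsv", sep="\t", index=False)
        for cohort_id, table in deg_tables.items():
            table.to_csv(out / f"deg_{cohort_id}.tsv", sep="\t")
        panel.to_csv(out / "panel.tsv", sep="\t", index=False)
        fractions.to_csv(out / "fractions.tsv", sep="\t")
        if corr_table is not None:
            corr_table.to_csv(out / "correlations.tsv", sep="\t", index=False)
        report.to_json(out / "report.json")
    return report
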