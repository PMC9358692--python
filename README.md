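# netprop

Seed-gene network propagation and immune-biomarker discovery for
case/control blood transcriptomes, with a self-contained synthetic
benchmark carrying planted ground truth.

## The problem

Ischemic-stroke immunology (and disease genomics generally) often starts
from a short list of literature-validated disease genes and asks two
questions: *which other genes in the interactome belong to the same
disease process*, and *which of those genes separate patients from
controls well enough to serve as biomarkers?* `netprop` implements the
full chain that answers both:

1. **Network propagation.** A high-confidence protein–protein
   interaction network `G` is built from STRING-style links by keeping
   pairs with combined score > 899. A random walk with restart is run
   from the validated seed genes:

       P(t+1) = (1 − α) · M · P(t) + α · P(0)

   with `M` the column-normalised adjacency of `G`, restart probability
   α = 0.3, uniform restart vector `P(0)` over the seeds (1/k each), and
   convergence when ‖P(t+1) − P(t)‖₁ < 10⁻⁶. Non-seed genes scoring
   above 10⁻⁴ become candidates.
2. **Permutation FDR.** Random seed sets of the same size are propagated
   (1,000 by default); a candidate's FDR is the fraction of random sets
   that score it strictly higher than the real seeds did, `FDR(g) =
   δ / n_perm`. Candidates with FDR < 0.05 join the validated seeds in
   the **gene catalog**.
3. **Differential expression.** Each cohort is quantile-normalised and
   tested gene-wise (Welch t, Benjamini–Hochberg); a gene is a DEG at
   adjusted p < 0.05 and fold change ≥ 1.2. The **biomarker panel** is
   the direction-concordant intersection of two cohorts' DEGs with the
   catalog.
4. **Feature selection.** Panel genes are ranked per cohort by random
   forest mean-decrease-Gini importance; the top 25 % (ceiling) of each
   cohort are intersected into the **key biomarkers**.
5. **Classification.** Key-biomarker expression is binarized against
   each cohort's own medians (≥ median → 1 for up-regulated markers,
   reversed for down-regulated), fed to a one-hidden-layer network of 5
   logistic units, and evaluated by ROC AUC with a DeLong 95 % CI —
   including train-on-one-cohort / test-on-another transfer.
6. **Deconvolution.** Bulk samples are decomposed over a 22-cell-type
   signature by linear-kernel ν-SVR (ν ∈ {0.25, 0.5, 0.75}, lowest-RMSE
   fit wins), coefficients clipped at zero and renormalised so fractions
   sum to one, with permutation p-values per sample; estimated fractions
   are then correlated (Spearman) with biomarker expression, banded as
   |r| > 0.70 strong, 0.50–0.70 moderate, 0.30–0.50 weak-moderate,
   < 0.30 weak.

Every input the chain consumes — STRING-dialect links/info files, seed
lists, expression cohorts, signature matrices — can be generated
synthetically with planted truth (`netprop.synthetic_data`), so the
whole workflow is testable offline.

## Worked example

```python
from netprop import run_pipeline

report = run_pipeline({
    "synthetic":   {"rng_seed": 1},
    "permutation": {"n_perm": 200, "rng_seed": 1},
    "deconvolve":  {"n_perm": 20, "rng_seed": 1},
}, out_dir="run1")
print(report.catalog_size, report.panel_size, report.key_features)
print(report.transfer_auc, report.top_correlation)
```

prints

```
51 36 ['G0272', 'G0871']
1.0 {'feature_a': 'G0272', 'feature_b': 'celltype_00',
     'coefficient': 0.9717..., 'band': 'strong'}
```

Reading: from a 1,000-node synthetic interactome with a planted 40-gene
module and 10 seeds, propagation plus the permutation screen built a
51-gene catalog; 36 catalog genes were concordant DEGs in both training
cohorts; random-forest selection narrowed those to exactly the planted
informative pair, G0272 and G0871; the 5-unit logistic network trained
on one cohort classified the held-out 6-case/3-control cohort with AUC
1.0; and the first key biomarker's expression tracked the planted
cell-type fraction with a strong Spearman correlation (0.97). Per-stage tables (`scores.tsv`,
`fdr.tsv`, `catalog.tsv`, `deg_*.tsv`, `panel.tsv`, `fractions.tsv`,
`correlations.tsv`) and `report.json` land in `run1/`.

The same stages are scriptable from the shell:

```bash
netprop synth --out inputs/
netprop run-rwr --links inputs/links.txt.gz --info inputs/info.txt \
    --seeds inputs/seeds.txt --n-perm 1000 --rng-seed 1 --out rwr/
netprop diffexpr --expr inputs/expr_cohort_a.tsv \
    --labels inputs/labels_cohort_a.tsv --out deg_a.tsv
```

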