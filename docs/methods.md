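# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations behind `netprop`. Nothing here reports a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Propagation model

The walker state is a probability vector over network nodes updated as
`P(t+1) = (1 − α) M P(t) + α P(0)`. `M` is the column-normalised
adjacency, `M[i, j] = A[i, j] / deg(j)`, applied directly so the
operator is column-stochastic: when the network has no isolated nodes,
total probability mass is conserved at every step (asserted to 1e-10 in
the property suite). Some presentations write the update with a
transposed row-normalised matrix; for a symmetric adjacency the two
notations describe the same operator, and we standardise on the
column-stochastic form because mass conservation is what makes the
stationary vector interpretable as a distribution.

Parameters and defaults:

* `alpha = 0.3` — restart probability; larger values keep mass closer
  to the seeds (the summed seed-node score is non-decreasing in α,
  property-tested).
* `tol = 1e-6` on the L1 norm of successive differences. The norm in
  the stopping rule is underspecified in much of the propagation
  literature; L1 is the convention of the restart-walk papers this
  workflow follows and is configurable.
* `max_iter = 1000` — a guard, not a tuning knob; non-convergence is
  flagged and logged, never silently fatal.
* `candidate_threshold = 1e-4` — strict inequality, matching the strict
  readings used throughout (score > 899, permuted > observed,
  fdr < 0.05).

Isolated nodes produce zero columns in `M`; they are flagged and their
mass decays to `α P(0)` (the dangling-node closed form, unit-tested).
The iterative solution is checked against the dense closed form
`P* = α (I − (1 − α) M)⁻¹ P(0)` to 1e-8 in the max norm on random
graphs of up to 100 nodes.

## Permutation FDR

Random seed sets of the mapped-seed size are drawn uniformly without
replacement from all network nodes — including the true seeds, since
excluding them is an undocumented variant (available behind
`exclude_seeds=True`). Degree-matched sampling is deliberately not the
default. For candidate g, `delta` counts permutations whose score for g
strictly exceeds the observed score; `fdr = delta / n_perm`. The
implementation propagates all permutation restart vectors as one matrix
iteration, which makes an exhaustive enumeration of every C(n, k) seed
set on small graphs cheap; exact agreement with an independent
brute-force enumeration (dense solve per seed set) is part of the
acceptance suite.

A scaling property worth knowing: a random seed set that happens to
contain candidate g itself always scores g above its observed value, so
self-seeding alone contributes ≈ k/n to every candidate's FDR. At the
workflow's native scale (76 seeds in a ~19k-node interactome) this is
0.4 % and negligible, but a desk-scale benchmark must preserve the
regime: the synthetic default is 10 seeds in 1,000 nodes (1 %), not a
proportionally seeded small graph where self-seeding would consume the
whole 5 % FDR budget.

## Differential expression

Case-minus-control log2 fold change, two-sided Welch t-test per gene,
Benjamini–Hochberg across all genes; DEG iff adjusted p < 0.05 and
|log2FC| ≥ log2(1.2). The fold-change rule is interpreted on the log2
scale (the data are log2 intensities); an empirical-Bayes moderated
test is a possible refinement but the plain Welch test keeps the stage
dependency-free and its planted-truth operating characteristics
(sensitivity ≈ 0.9 at effect 1.0, σ 0.5, n 39/24; null false-positive
fraction ≤ 2× nominal) are verified directly. Genes with zero variance
in both groups get p = 1 and are logged. Quantile normalisation maps
every sample onto the mean-of-sorted-columns reference; ties receive
the mean of their tied ranks' reference values (via average ranks and
linear interpolation).

## Feature selection

Random forests (scikit-learn, `max_features='sqrt'`, unlimited depth —
the classic randomForest defaults) rank panel genes by mean decrease in
Gini impurity. The retained set is the `ceil(0.25 · n)` most important
genes, boundary ties broken lexicographically; with a 36-gene panel
that is 9 genes per cohort. Tree-count tuning minimises out-of-bag
error with ties going to the smaller count. The default tuning grid is
{100, 250, 500}: on strongly separable data OOB error plateaus
immediately, so a grid reaching down to a handful of trees lets the
tie-break select forests whose importance estimates are far too noisy
to rank features — the quantity this stage exists to estimate. Users
who want a wide exhaustive search can pass any grid.

## Classification

Expression of each key biomarker is binarized against the median of
*that* cohort's samples — up-regulated markers score 1 at or above the
median, down-regulated markers at or below — and a test cohort is
always binarized with its own medians before a transferred model scores
it. The classifier is a single hidden layer of 5 logistic units with a
logistic output (scikit-learn `MLPClassifier`, L-BFGS, iteration cap
2000, seeded); its output probability serves as the multifactor ROC
score, which is equivalent to a weighted combination of the binarized
markers through the trained weights. AUC is the tie-corrected
Mann–Whitney statistic computed from placement values; the 95 % CI is
DeLong's normal-theory interval on the placement-value variance,
clipped to [0, 1]. Degenerate all-equal scores report AUC 0.5 with a
collapsed CI and a warning. A flexible network overfits noise, so null
behaviour (AUC ≈ 0.5) is asserted on an independent null draw rather
than on training data.

## Deconvolution

Per sample: restrict to genes shared with the signature, z-score the
sample and each signature column, fit linear-kernel ν-SVR at
ν ∈ {0.25, 0.5, 0.75}, keep the lowest-RMSE fit, clip negative
coefficients, renormalise to fractions summing to one (non-negativity
and the unit sum are invariants asserted on every emitted sample).
Mixture values are treated as linear-scale, the standard convention for
signature-based deconvolution; a log2 input can be anti-logged with the
CLI flag. Per-sample significance uses a permutation null shared across
samples: gene-shuffled samples are pushed through the identical fitting
path and a sample's p-value is the fraction of null reconstruction
correlations at or above its own. Building one null of `n_perm` draws
(rather than `n_perm` per sample) keeps cost linear while testing the
same statistic. Quantile normalisation is never applied to the
deconvolution input.

Correlation bands follow the conventional magnitude scale (> 0.70
strong, 0.50–0.70 moderate, 0.30–0.50 weak-moderate, < 0.30 weak);
boundary values fall into the stronger band.

## Enrichment

Generic over-representation: hypergeometric upper tail for each
user-supplied term against a user-supplied (or annotation-derived)
universe, BH-adjusted across terms, selection reported at raw p < 0.05
with the adjusted value alongside. No ontology structure is modelled.

## Synthetic study design

The generators are pure functions of `SynthConfig` and emulate the
shape, not the marginals, of the real inputs:

* **Network** — preferential-attachment backbone (1,000 nodes, 3 edges
  per arrival) with a 40-node module densified by adding each missing
  within-module edge with probability 0.5; true edges score 900–999,
  decoy non-edges score 1–899 so the >899 filter recovers exactly the
  true structure. Ten seeds are drawn from the module (the 1 % seed/node
  ratio discussed above). The planted *informative pair* sits at the two
  best-connected non-seed module nodes: biomarkers in this workflow are
  catalog members by construction, so the pair must be reliably
  reachable by propagation — planting it at the module periphery would
  turn the end-to-end benchmark into a lottery over topology rather
  than a test of the stages.
* **Expression** — three cohorts of 39/24, 69/23 and 6/3 case/control
  samples (two training, one held-out test), log2 scale, per-gene
  baselines ~ N(8, 1), sample noise σ = 0.5. All module genes plus 30
  off-module decoys are differentially expressed with directions shared
  across cohorts. The informative pair gets a 2.0 log2-unit shift in
  every cohort; every other planted gene gets the full 1.0 shift only
  in its randomly assigned preferred training cohort and 0.55 in the
  other. The graded, cohort-decorrelated effects keep recovery
  non-trivial: DEG sensitivity sits near 0.9 rather than 1.0, and the
  two cohorts' importance rankings agree only on the pair.
* **Mixtures** — a 220-gene × 22-cell-type signature with disjoint
  10-gene marker blocks on a low uniform background; mixtures are
  signature × Dirichlet(1) fractions plus Gaussian noise at a
  configurable fraction of the mean signal (default 10 %). When a
  ground truth with an informative pair is supplied, the pair's
  expression is appended as an affine function of the first cell type's
  fraction, planting a strong positive correlation for the final stage
  to find.

What passing on these data does **not** show: robustness to probe-level
artefacts, batch effects, heavy-tailed expression noise, correlated
gene-gene structure beyond the planted signal, realistic STRING score
distributions, or signature collinearity of the kind real leukocyte
references exhibit. The benchmark isolates the pipeline's logic and
statistics, not its behaviour on any specific public dataset, and the
published per-dataset numbers (DEG counts, cohort AUCs) are therefore
not reproduction targets here.

## Problem sizes used in the checks

The acceptance script and heavy tests run the permutation screen at
`n_perm = 200` (the FDR granularity of 1/200 comfortably resolves the
0.05 cutoff), five generator seeds for recovery rates, twenty for null
calibration, and 100 random graphs for the closed-form equivalence
check; the deconvolution recovery checks use 15-sample mixtures. These
sizes are the package's chosen benchmark design and are stated in each
check's output.

## Known limitations

* The moderated-t option for small cohorts is not implemented; the 6/3
  test cohort is used only for transfer evaluation, never for DEG
  calling in the default pipeline.
* The deconvolution permutation null is shared across samples; with
  very heterogeneous library sizes a per-sample null could differ.
* `IdMap` resolves a duplicated symbol to the lexicographically first
  accession, which is a convention, not biology.
* Gini importance is known to favour high-cardinality/continuous
  features and to split credit between correlated predictors; the
  pipeline inherits these properties deliberately, since they are part
  of the method being implemented.
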