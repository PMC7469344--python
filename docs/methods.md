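# Methods

This note documents the models, the numerical choices, and the synthetic
benchmark behind `lncboost`, and states what the shipped tests do and do not
demonstrate.

## Problem setting

Given `N_d` diseases, `N_l` lncRNAs and a binary association matrix
`LNCDIS` of experimentally supported links, the task is binary
classification of (disease, lncRNA) pairs. Known pairs are positives;
because true negatives are unobservable, an equal number of unlabeled
zero cells is sampled uniformly at random as presumed negatives (1:1
undersampling; no weighting or synthetic oversampling).

## Similarity layers

**Disease semantic similarity.** Each disease is mapped to one or more
dot-delimited hierarchy tree codes; its DAG is the union of the prefix
chains of all its codes, with the disease itself as the target leaf. Two
scores are computed:

* *Decay-based (DISSS1).* The target contributes 1; every ancestor
  contributes δ times the best contribution among its children inside the
  DAG, which equals `δ^h` for shortest hop distance `h`. We compute this by
  breadth-first search over reversed edges rather than by recursion, which
  is equivalent on DAGs and also terminates on degenerate hierarchies where
  one disease's code nests inside another's (folding the term graph into a
  cycle). δ defaults to 0.5, the conventional value.
* *Frequency-based (DISSS2).* Every term contributes its corpus information
  content `−log(n_term/N_d)` (natural log; base configurable), where
  `n_term` counts the disease DAGs containing the term and `N_d` is the
  corpus size. A term shared by all diseases therefore carries zero
  information. The sign convention is `negative_log` by default so that
  contributions are non-negative and the pairwise score lands in [0, 1]
  with a unit diagonal; the literal (negative) log form is retained as
  `disss2_sign='as_printed'` for auditability but cannot be normalized
  meaningfully. Whether the target term's own weight enters its total is
  configurable (`include_target_term`, default on).

Both pairwise scores are the shared-ancestor contribution mass divided by
the sum of the two per-disease totals. Diseases absent from the hierarchy
file get empty DAGs and all-zero rows (diagonal included), are reported,
and fall back to the interaction kernel at fusion time. Disease names are
matched to hierarchy records case-insensitively after whitespace
normalization.

**lncRNA functional similarity.** Best-match average of the semantic
similarities of the two lncRNAs' disease sets (each disease in one set is
matched to its most similar disease in the other; both directions averaged).
Disease sets are derived from the association matrix — in strict mode, the
training portion only (see below). lncRNAs with empty sets get zero rows.

**Gaussian interaction-profile kernels.** `exp(−μ‖u−v‖²)` over matrix rows
(diseases) or columns (lncRNAs). The bandwidth is `μ = μ′ / mean‖profile‖²`
with μ′ = 0.5; dividing by the mean squared norm makes the bandwidth
scale-free, which is what "bandwidth control" is for. The literal
multiplicative variant is retained as `bandwidth_rule='multiply_as_printed'`.
An all-zero matrix leaves the bandwidth undefined under the divide rule and
raises.

**Fusion.** `DISS(i,j)` is the average of the two semantic scores when both
diseases carry semantic information, else the kernel value; same for
`LNCS` on the lncRNA side. "Carries semantic information" is decided per
entity (non-empty DAG / non-empty disease set, detected by a positive
self-similarity), not per entry: a genuine semantic similarity of 0 between
two mapped diseases — disjoint ancestor sets — is informative and is kept.
The entrywise alternative (replace every zero with the kernel value,
`presence='entry'`) is retained; it systematically overwrites exact zeros
with mid-range kernel background and measurably blurs the class boundary
on the synthetic benchmark.

## Feature assembly

A pair (dᵢ, lⱼ) is encoded as the concatenation, in fixed order, of: the
disease-side similarity row (length `N_d`), the lncRNA-side similarity row
(length `N_l`), and — when the interaction layer is in the layout — the
interaction profile of dᵢ over lncRNAs and of lⱼ over diseases. When both
the semantic and kernel matrix of one side are selected, the fused matrix
is used; with a single one, that matrix directly. 15 named layouts cover
the full network (FHN, all five layers) plus four-, three- and two-layer
ablations (THN1–4, TriHN1–6, DHN1–4); the exact layer checklists of the
smaller networks are not standardized, so the
exact name→layer mapping here is a repository convention printed to the run
log (`feature_builder.LAYOUT_PRESETS`), and the ablation runner reports
results per layer set so comparisons do not depend on the naming.

`mask_target` zeroes the pair's own cell inside both interaction profiles,
so no feature row encodes its own label. It defaults on in strict mode and
off in paper-faithful mode.

## Autoencoder

Single hidden layer, sigmoid activations on both encoder and decoder,
per-element cross-entropy reconstruction loss (inputs min–max scaled to
[0, 1]; the scaler is fitted on training data only and stored with the
model). Optimization is plain mini-batch gradient descent: batch 128,
100 epochs, fixed step size 0.5, seeded uniform(−0.05, 0.05) weight
initialization. The latent width defaults to 128 (the layer width is not
dictated by the method; a sweep utility is trivial via `AeTrainConfig`);
it is clamped to the input dimension when a small layout yields fewer
features. The full-data loss is recorded once per epoch. Note that the
descent contract (final loss below initial) is only meaningful on
compressible inputs; on i.i.d. uniform noise the initial loss already sits
at the optimum ln 2.

## Gradient boosting

Binomial-deviance boosting of depth-3 regression trees: `F₀` is the
training log-odds; each round fits a least-squares tree to the residual
`y − p` and replaces each leaf value with the Newton step
`Σ residual / Σ p(1−p)` over the leaf; the update is damped by η = 0.1.
An exact global line-search step (one ρ per tree, found by bounded scalar
minimization of the log-loss) is available as `step_rule=
'global_line_search'` for fidelity experiments. No stochastic subsampling.
Default 1200 trees, seed 0. The CART tree fitting itself is delegated to
scikit-learn's `DecisionTreeRegressor` (deterministic under a fixed
`random_state`, which subsumes the split tie-break rule); the boosting
loop, the loss, the step rules and the staged loss trace are implemented
here, and the test suite checks agreement with scikit-learn's independent
`GradientBoostingClassifier` within 0.02 test AUC under matched
hyperparameters.

## Evaluation protocols

Confusion metrics (accuracy, sensitivity, specificity, precision, MCC, F1)
are computed at threshold 0.5 (configurable); degenerate margins yield 0
with a flag rather than an exception. AUC is the trapezoidal area of the
ROC curve, which equals the Mann–Whitney concordance probability with ties
counted ½ (verified against a brute-force oracle in tests). Hold-out is a
stratified 8:2 split; 10-fold CV uses stratified shuffled folds and reports
per-fold metrics plus their arithmetic means; leave-one-out CV pools the
`n` held-out scores into a single report (a single left-out sample has no
per-fold AUC). The repeated-F1 comparison runs `n_rep` (default 20)
hold-out repetitions with shared split seeds for both configurations and a
two-sample t-test; identical results are flagged and given p = 1.

**Leakage modes.** In `strict` mode every fold rebuilds the interaction
matrix from training-fold positives, recomputes the functional and kernel
similarities from it, refits the scaler/autoencoder/booster, and masks each
pair's own interaction cell. In `paper_faithful` mode all similarity
matrices are precomputed once from the full known matrix and masking is
off — the single-precomputation workflow common in this literature, which
leaks held-out links into features and inflates scores; outputs are always
labeled with the mode. Disease semantic similarity depends only on the
hierarchy, so it is computed once and cached in both modes.

**Candidate ranking (case-study protocol).** All links of the query
disease are removed from training positives; the model is retrained on the
remainder plus freshly sampled negatives (drawn outside the query row) and
scores every candidate pair, ties broken by lncRNA index. After removal the
query's disease-side interaction profile is identically zero — a feature
block that is out-of-distribution relative to training pairs and carries no
information — so the ranking model is trained on the lncRNA-side
interaction block only (logged). Recovery then rests on the semantic rows
and each candidate's links to diseases similar to the query, which is the
intended guilt-by-association signal.

## Synthetic benchmark

The generator encodes the core modeling assumption — lncRNAs associated
with the same or semantically close diseases share function — as a planted
co-cluster model. Diseases and lncRNAs are partitioned into `n_clusters`
contiguous blocks; each disease cluster occupies its own disjoint subtree
of a rooted hierarchy (branching 3, depth 4 by default), with members on
*consecutive* leaves so that they share low-level ancestors, as real
disease-category subtrees do — this is what makes the semantic layers
genuinely informative rather than decorative. Associations are Bernoulli:
probability `p_in = 0.5` inside a (disease-cluster, lncRNA-cluster) match,
`p_out = 0.01` elsewhere, with optional label-noise flips last. The default
study conditions are 60 diseases × 120 lncRNAs and 10 clusters (seed 7),
sized so a strict-mode 10-fold CV with the tree count scaled to 200 runs
in about a minute and a half on one CPU.

What the benchmark does *not* emulate: the heavy-tailed degree
distributions, multi-cluster disease membership, incomplete hierarchy
coverage and annotation biases of the curated databases. Passing the
planted-recovery tests demonstrates that the implementation extracts
exactly the structure the method is designed for; it does not certify
real-data performance, which in the literature is additionally inflated by
the single-precomputation (paper_faithful) workflow (compare the two modes to see the gap).
Note also that with `p_in = 0.5` within-cluster non-links are genuinely
ambiguous — sampled negatives inside a matching cluster are
indistinguishable from positives by construction — so even the Bayes
optimum on this benchmark is well below AUC 1 (≈ 0.93 for the default
conditions, estimated with the cluster oracle).

## Determinism and provenance

Every stochastic step (negative sampling, splits, weight initialization,
label permutation) takes an explicit seed; fixed seeds give bit-identical
models, and the full-pipeline runner writes a manifest with the resolved
configuration and a SHA-256 checksum per artifact, so re-running a manifest
reproduces all artifacts byte-for-byte. Matrices interchange as labeled TSV
at 12 significant digits; models serialize to JSON.

## Known limitations

* Negative sampling treats unlabeled pairs as negatives; some are
  undiscovered positives.
* LOOCV in strict mode retrains the entire stack per sample and is only
  practical at reduced sizes.
* The autoencoder is a fixed single-hidden-layer design (no denoising or
  sparsity); the latent width default is a pragmatic choice, not tuned per
  dataset.
* Real MeSH descriptor files are not parsed; only the flat
  `disease<TAB>tree-code` dialect is supported.
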