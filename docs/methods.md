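# Methods

## Problem and model

Given known drug–target interactions, protein sequences, and drug
substructure fingerprints, the package predicts whether an unobserved
(drug, protein) pair interacts. The working hypothesis is the usual one in
ligand-based screening: chemically similar drugs tend to share bioactivity,
and evolutionary profiles capture the binding-relevant signal in protein
sequences. Prediction is framed as balanced binary classification over a
fused feature space.

## Protein descriptor (PsePSSM)

A protein of length L is represented by its L×20 position-specific score
matrix (PSSM): log-odds scores of each residue position mutating into each
standard amino acid. Profiles come from PSI-BLAST ASCII output (defaults
e-value 0.001, 3 iterations, log-odds block); a deterministic BLOSUM62
fallback profile exists so the whole pipeline runs with no external binary.
The canonical column order is the one PSI-BLAST prints
(`ARNDCQEGHILKMFPSTWYV`); readers map any header order onto it.

Each row is z-scored across its 20 columns with the **population** (1/20)
variance; a constant row would divide by zero and maps to zeros instead,
which preserves dimensionality and is the natural "no information" encoding.
The descriptor is the concatenation of the 20 column means with, per lag
λ = 1…Λ, the 20 mean squared lag-differences (1/(L−λ)) Σ (e_ij − e_{i+λ,j})².
Consequences used as test invariants: the descriptor has exactly 20·(Λ+1)
entries, lag terms are non-negative, a constant profile maps to the zero
vector, and any uniform affine rescaling a·S+b of the raw scores leaves the
descriptor unchanged.

**Λ (lag_max)** defaults to 10 (220-dim descriptor) — a conventional PsePSSM
setting that stays well-defined for short proteins; proteins with L ≤ Λ are
rejected rather than padded because the lag-term denominator would not be
positive. The squared-difference form with the 1/(L−λ) normalization is
taken literally; some PsePSSM variants normalize differently.

## Drug descriptor

The 881-bit PubChem subgraph-key fingerprint, 0-based key order, consumed
as-is (no filtering or weighting). Two table dialects are parsed: a plain
881-character 0/1 string and the PubChem base64 encoding (4-byte big-endian
bit-length prefix, packed bits MSB-first). Computing keys from chemical
structures is out of scope.

## Pair dataset

Positives are the known network edges; negatives are drawn uniformly
without replacement from the unknown pair space, by default one negative
per positive (balanced — standard for this task, where true negatives are
unverifiable). Sampling is done once per dataset with a recorded seed.
Feature fusion is drug block first: [881 fingerprint bits | 20·(Λ+1)
PsePSSM values]; the order is arbitrary but fixed and recorded in the
dataset sidecar so exports are self-describing.

## Feature-weighted rotation forest

**χ² weighting.** Pearson independence statistic per feature over its
value × class contingency table. Continuous columns are first discretized
into equal-frequency quantile bins (default n_bins = 5; quantile bins are
robust to the heavy-tailed lag terms); columns with ≤ 2 distinct values
pass through untouched. Cells with zero expectation contribute nothing.
Features are ranked by descending weight and the top
ceil(chi2_keep · n) kept (ties to the lower index). **chi2_keep defaults to
1.0**: how many features the weighting stage should remove is not specified
by the method description, so removal is opt-in.

**Rotation ensemble.** Per tree: the retained features are randomly
partitioned into K subsets with sizes differing by at most 1; per subset a
PCA is fitted on a bootstrap sample of round(r·N) training rows (with
replacement); the K square loading blocks form a block-diagonal rotation
matrix R_i re-indexed to the original feature order; a CART tree (Gini,
grown to purity — the base learner is otherwise unspecified, and unpruned
trees are the rotation-forest default) is fitted on X·R_i. The method
description is ambiguous about whether r subsamples features or instances;
instance bootstrap (the original rotation-forest reading) is implemented,
because per-subset feature subsampling would break the square block
structure of R_i. PCA uses an eigendecomposition of the bootstrap
covariance rather than a truncated SVD so the loading block is a complete
orthonormal basis even for degenerate samples (zero-variance directions get
unit eigenvectors); hence R_iᵀR_i = I holds by construction and is asserted
to 1e-8 in the tests. Eigenvector signs are fixed (largest-magnitude entry
positive) for determinism.

**Prediction.** Confidence per class is the average over trees of the leaf
class frequencies on the rotated input; rows sum to 1. The predicted label
is the argmax, with an exact 0.5/0.5 tie resolved to class 0 (documented
deterministic policy). Defaults (K, r, L) = (16, 0.8, 21), the tuned
configuration.

**Seeding.** A single integer seed drives a NumPy `default_rng`; feature
partitions, bootstraps and tree random states all derive from it, so a fit
is bit-reproducible. Cross-validation derives per-fold model seeds as
`seed·1000 + fold`. Models serialize via joblib; a reloaded model returns
bit-identical confidences.

## Evaluation

Accuracy, sensitivity, precision and MCC from the confusion counts (class 1
positive); any metric with a zero denominator is reported as 0 so fold
aggregation stays total. ROC is a descending-threshold sweep with trapezoid
AUC, which equals the pair-ordering statistic with half-credit ties (tested
to 1e-12 against brute force). Cross-validation is stratified with seeded
shuffling — stratification guarantees both classes in every fold at
balanced sizes; summaries report mean ± **population** standard deviation,
formatted in percent to two decimals. Per-fold AUCs are averaged; fold ROC
curves are not interpolated into one curve. Grid search is exhaustive by
mean CV accuracy with first-in-grid tie-breaking; varying Λ re-featurizes
proteins, so Λ enters the grid through a caller-supplied mapping of lag to
dataset. Candidate ranking trains on all labeled pairs and scores the
unknown pair space, sorted by descending confidence with lexicographic
tie-break.

## Synthetic data generator

The generator emulates the three inputs with a known ground truth:

- **Profiles**: integer noise in [−4, 4] plus a conservation-scaled bonus
  (10 at conservation 1, default 0.8) on one designated residue per
  position — a favored-residue pattern crudely mimicking conserved columns.
- **Fingerprints**: 881 i.i.d. Bernoulli bits, default density 0.1
  (sparse, like real substructure keys).
- **Network**: feature columns are z-scored over the pair space, a sparse
  latent vector with `latent_dim` standard-normal coordinates scores each
  pair, scores are median-centered and scale-normalized, and labels are
  Bernoulli(sigmoid(signal_strength · score)). Median-centering pins the
  positive rate near one half (draws outside 10–60% are regenerated with
  the next seed, logged). The signal lives in the fused space so both
  modalities carry information; the score is standardized so
  signal_strength is interpretable in logit units.

Default study conditions: 40 drugs × 40 targets, latent_dim 20,
signal_strength 8, protein lengths 60–120, seed 7 — giving ≈1570 balanced
pairs × 1101 features. Under these conditions five-fold CV reaches mean
AUC ≥ 0.90 and accuracy ≥ 0.80, and collapses to AUC ≈ 0.5 on permuted
labels; this planted-signal recovery is the package's primary end-to-end
property.

**What passing shows and does not show.** The generator produces i.i.d.
bits and a clean low-rank logistic signal. Real DTI data have correlated
substructures, phylogenetic structure among proteins, hubness in the
interaction network, and unverifiable negatives. Recovery on the benchmark
demonstrates the pipeline is wired correctly and the classifier can find a
multivariate signal spanning both blocks at realistic dimensions — not that
it attains any particular accuracy on real interaction data.

## Problem sizes and numerical choices

The test suite uses scaled-down fixtures (tens of entities, L ≤ 21 trees)
everywhere except the primary recovery test, which runs the full 40×40
study once; the ensemble-stability check (fold-AUC variance at L = 21 ≤
L = 1, averaged over 10 seeds) runs on a 150×30 planted dataset.
Degenerate-row tolerance is 1e-12; rotation orthogonality is asserted at
1e-8; χ² and AUC oracle agreement at 1e-10 and 1e-12.

## Known limitations

- Binary classification only; no probability calibration.
- Negatives are assumed uniform over the unknown space; no
  similarity-aware or reliability-weighted negative selection.
- Non-standard residues (B, Z, X, U, `*`) are rejected rather than
  imputed, because the descriptor's semantics are undefined for them.
- The PSI-BLAST wrapper requires an externally formatted database and is
  optional; nothing in the package ships one.
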