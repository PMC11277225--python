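# Methods

This note records what each stage of the toolkit computes, the assumptions
behind it, the defaults that matter, and the choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Standardization

A raw SMILES is standardized by: parse → keep the largest fragment
containing at least one carbon (heavy-atom count, ties to input order) →
neutralize charged atoms where adding or removing protons suffices
(zwitterionic centres adjacent to an opposite charge, e.g. nitro groups,
are left intact) → RDKit canonical SMILES with implicit hydrogens.
Unparseable inputs and fragment sets with no organic fragment are returned
as `Rejection` values with reasons `parse_failure` /
`no_organic_fragment`; batch loaders count them instead of failing.
Standardization is idempotent on its own outputs (property-tested).
Hydrogens stay implicit in the canonical string; molecular graphs carry
per-atom H counts as features instead, which keeps graphs small and follows
the dominant convention.

Duplicate rows are resolved by canonical SMILES, first occurrence kept —
the natural choice when file order encodes provenance priority.

## Splits

Train/test/validation at 8:1:1 by default, stratified by label, seeded
(default 42). Allocation uses largest-remainder rounding per class,
coordinated against the global part sizes: naive per-class rounding can
leave a small part empty when class remainders tie (e.g. 5+5 records at
8:1:1), so per-class leftovers are assigned to the parts that still need
members, in order of per-class remainder. Each part's class proportion
matches the whole within one molecule per class.

## Descriptor filtering

Descriptors come from RDKit's full 2D descriptor list (~210 named values;
failures are imputed as 0 and logged so the matrix is always complete). The
two-stage screen first drops columns whose fraction of exact zeros is
strictly greater than 0.9, then drops columns whose Shannon entropy is
strictly below 2.5 bits. Both comparisons are strict, so boundary columns
survive. The filters are engine-agnostic: any externally computed
descriptor CSV passes through the same semantics.

Entropy uses 10 equal-width bins spanning the observed [min, max] (the
maximum falls in the last bin), H = −Σ pᵢ log₂ pᵢ over nonempty bins, and a
constant column is defined to have 0 bits. Ten bins is the smallest round
count for which a 2.5-bit threshold can discriminate (a threshold of
2.5 bits requires more than 2^2.5 ≈ 5.66 occupiable bins) while leaving
headroom to the log₂ 10 ≈ 3.32-bit ceiling. Equal-width binning over the
observed range makes the statistic invariant under affine rescaling of a
column, so it is indifferent to whether descriptors were normalized first.

## Chemical space and clustering

Fingerprints (Morgan radius 2, 2048 bits by default; MACCS 166 bits by
flag — RDKit emits 167 positions with bit 0 permanently unset, which is
dropped) are embedded two ways: PCA to two components (sign fixed so each
component's largest-magnitude loading is positive, making outputs
reproducible across linear-algebra backends) and exact-gradient t-SNE to
three dimensions at perplexity 30, PCA-initialized and seeded.
Exact-gradient t-SNE is quadratic in n but deterministic given a seed and
comfortably fast at toolkit scale (≤ a few thousand molecules); perplexity
is auto-lowered with a warning when n ≤ 3·perplexity.

Ward-linkage clustering runs on the 3D t-SNE coordinates and the dendrogram
is cut at k = 3 by default. Representative selection happens back in
fingerprint space: within each cluster, the member with the highest mean
Tanimoto similarity to its co-members, self-similarity excluded, ties to
the lowest index. Excluding self-similarity adds the same constant to every
candidate within a fixed cluster size, so the winner is unchanged either
way; exclusion simply keeps the reported mean interpretable. Singleton
clusters represent themselves with similarity 1.0. Tanimoto between two
all-zero fingerprints is defined as 1.0.

A caution on oracles: greedy Ward agglomeration does not globally minimize
the within-cluster variance objective for arbitrary point sets, so
exhaustive-enumeration checks are meaningful only on well-separated data
(the test suite uses two tight triads), where greedy and global optima
provably coincide.

## Classical baselines

The five families carry these grids: Bernoulli NB (fingerprints) α ∈ {0.01,
0.1, 1}, binarize ∈ {0, 0.5, 0.8} — for continuous descriptors the Gaussian
variant is used, since α/binarize are Bernoulli-specific; KNN k ∈ {3, 5, 7,
10, 15, 20} × metric ∈ {manhattan, euclidean, jaccard}; random forest
n_estimators ∈ {100, 200, 300} × criterion {gini, entropy} × max_depth {5,
10, 20, 30, ∞} × min_samples_leaf {1..10} × max_features {log2, sqrt, all};
RBF SVM γ ∈ {auto, 0.1, 0.2} × C ∈ {0.1, 1, 10, 100}; and a one-hidden-layer
(128 rectified units) network with early stopping as the neural baseline.
Every combination is fitted on the training part and the winner picked by
balanced accuracy on the validation part (robust to the 47/53 class
balance), ties to the first combination in enumeration order; the winner's
fit on the training part is used as-is, and the test part enters only at
final evaluation. A single validation split (not cross-validation) mirrors
the 8:1:1 design. On binary fingerprints the jaccard KNN metric equals
1 − Tanimoto, which the tests verify against the fingerprint module.

Zero-denominator metrics are reported as 0 with a flag rather than NaN, so
model summary tables never break. AUC is the rank (Mann–Whitney) statistic
with average-rank tie handling, computed from continuous scores
(probabilities where the model provides them, decision values otherwise);
thresholded metrics use 0.5 on probabilities.

## Hybrid model

Three encoders process complementary views of a molecule:

- **CNN** — token embedding (64) → three stacked same-padded 1D
  convolutions (kernels 3/5/7, 64 channels, ReLU), re-masked after every
  layer → masked global max-pool → linear to d₁ = 64.
- **Transformer** — embedding + sinusoidal positions → two blocks of
  4-head self-attention with residual connections and layer norm (padding
  excluded from attention keys) → masked mean-pool → linear to d₂ = 64.
- **GAT** — two multi-head graph-attention layers (4 heads, hidden 32,
  then 4×16) over dense-padded graphs with self-loops, LeakyReLU(0.2)
  attention logits, softmax over each atom's neighbourhood → masked mean
  pool → linear to d₃ = 64.

Tokenization is atom-aware (bracket atoms, Cl/Br, ring-closure digits and
`%nn` labels are single tokens; out-of-vocabulary tokens map to `<unk>`).
Graph nodes carry element one-hot (C/N/O/S/P/F/Cl/Br/I/other), degree
one-hot, formal charge, aromaticity and H-count one-hot (23 features);
edges are directed pairs, both directions per bond.

Masking is structural, not approximate: embeddings and convolution outputs
are zeroed at padded positions, pooling excludes them, attention assigns
−10⁹ logits to padded keys and non-edges. Consequently extending a
sequence's padding or permuting a graph's atoms leaves encoder outputs
bit-for-bit unchanged up to float association — both properties are tested
at 10⁻⁵.

Training is staged. Stage 1 gives each encoder a single-logit auxiliary
head and trains it with binary cross-entropy (Adam, 10⁻³, batch 64, up to
100 epochs, early stopping on validation loss with patience 10); the heads
are discarded afterwards. The loss is a toolkit choice — the architecture
description leaves the encoder training signal open, and a supervised
auxiliary objective is the simplest one that makes the extracted features
label-relevant. Stage 2 freezes the encoders, concatenates features in the
fixed order [CNN | Transformer | GAT], z-scores them on the training part,
and trains the VAE (encoder 192→128→(μ, log σ²), latent 32, decoder
mirrored) on reconstruction + KL. Stage 3 fits an XGBoost head (200 trees,
depth 4, learning rate 0.1, single-threaded histogram method) on the
latent means of the training molecules. Latent means, not samples, feed the
classifier, and inference always uses z = μ, so predictions are
deterministic; end-to-end determinism under a fixed seed is asserted by
the acceptance suite.

Stage-wise training (frozen-feature VAE) is the default rather than
end-to-end fine-tuning through the VAE: it is reproducible, cheap, and
matches the view of the VAE as a feature-fusion/denoising step; the
alternative reading (the VAE recalibrating encoder weights) is not
implemented as a default behavior.

**Reconstruction scaling.** The VAE loss uses squared error *summed over
feature dimensions* (averaged over the batch) plus the dimension-summed
KL. With the reconstruction *averaged* over the 192 fused dimensions
instead, the KL term carries roughly 192× more leverage and the posterior
collapses toward the prior, erasing exactly the class structure the latent
is supposed to preserve; sum-scaling is the canonical Gaussian
log-likelihood convention and keeps the two terms commensurate. kl_weight
stays 1.0.

The per-sample KL, −½ Σ(1 + log σ² − μ² − σ²), is non-negative with
equality only at μ = 0, log σ² = 0; log σ² is clipped to [−10, 10] for
numerical safety. All neural components run on a small reverse-mode
autodiff engine written on NumPy (tensor-level operations, topological
backward sweep), validated against central finite differences at 10⁻⁵ in
the test suite.

## Synthetic data

The generator emulates a curated binary reproductive-toxicity dataset at
desk scale: 300 molecules, 47% positives, 5% label noise as the default
benchmark conditions, split 8:1:1. Class-1 structures carry at least one
of three motifs — a nitroaromatic, a phenolic hydroxyl, or an aromatic
ortho-diester — echoing the three chemotype families (hydantoin-like,
phenolic, phthalate-ester) that cluster analysis of such data typically
surfaces; class-0 structures come from a motif-free pool (substituted
benzenes/cyclohexanes/pyridines, dialkyl amides, single esters and ethers)
and are audited against the motif SMARTS before acceptance. Substituents
are composed as alkyl × terminal-group products, giving a grammar of tens
of thousands of distinct valid structures, so a 300-molecule draw has
negligible train/test structural overlap (measured in the tests). Label
noise flips the structure↔label correspondence per molecule; at noise
→ 0.5 the motif-label mutual information vanishes and classifiers fall to
chance, which the negative-control check exploits (it uses noise 0.45,
since the spec of the generator requires noise < 0.5, and evaluates on the
pooled test+validation parts for a steadier estimate from 60 molecules).

What the fixture does *not* emulate: real structural diversity and
scaffold imbalance, activity cliffs, assay noise correlated with chemistry,
and dataset-size effects. Passing benchmarks on it demonstrates that the
pipeline recovers a recoverable substructural signal end to end — not that
it attains any particular accuracy on real toxicity data.

Descriptor-table generation realizes a requested zero-fraction exactly
(rounded to a count) and hits a target entropy within ±0.1 bits by binary
search over a point-mass/uniform mixture of bin occupations, followed by
greedy one-count exchanges; values are placed at bin centres with the top
bin kept occupied so the observed range reproduces the designed binning.
Infeasible pairs — e.g. zero-fraction 0.95 with 2 bits of entropy, whose
ceiling is ≈ 0.45 bits — raise with an explanation.

## Problem sizes and budgets

Default benchmark runs use n = 300 molecules with encoder training capped
at 30 epochs and VAE training at 60 (early stopping, patience 8), which
converges on the 240-molecule training part in roughly a minute of CPU
time; the determinism check uses n = 120 at 6/10 epochs since it compares
bytes, not accuracy. These sizes are the package's reference conditions
for a desk-scale, fully reproducible run; all of them are plain `SynthSpec`
/ `HybridConfig` parameters.

## Known limitations

- logS (ESOL-style estimate) and logD (logP with a crude ±log-unit
  correction for ionizable groups at pH 7.4) in the property profile are
  labeled approximate; they are descriptive radar-chart quantities and feed
  no model.
- The descriptor engine is RDKit's 2D set, not a reimplementation of any
  external descriptor program; only the filter semantics are contractual.
- Exact t-SNE and the pure-NumPy encoders are quadratic/loop-bound and not
  meant for datasets beyond a few thousand molecules.
- Ward on t-SNE coordinates inherits t-SNE's seed sensitivity; a flag
  allows Ward directly on fingerprint space for sensitivity analysis via
  `ward_cluster` on raw bit matrices.
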