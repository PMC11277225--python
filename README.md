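# reprotox

A toolkit for computational reproductive-toxicity screening of small
molecules. It is aimed at cheminformaticians and drug-safety researchers who
want an end-to-end, reproducible pipeline from raw SMILES tables to a trained
binary toxicity classifier, without web services or proprietary software.

The pipeline covers:

- **Standardization** — parse SMILES, keep the largest carbon-containing
  fragment (dropping salts, solvents and counterions), neutralize simple
  charges, canonicalize; failures are reported per row, never raised.
- **Featurization** — Morgan/ECFP fingerprints (radius 2, 2048 bits), MACCS
  keys (166 bits), and ~210 named 2D descriptors, screened by a two-stage
  filter: drop descriptors that are >90% exact zeros, then drop those whose
  Shannon entropy H = −Σ pᵢ log₂ pᵢ (10 equal-width bins) is below 2.5 bits.
- **Chemical space** — PCA to 2D, t-SNE (perplexity 30) to 3D, Ward-linkage
  clustering of the embedding, and a per-cluster representative molecule:
  the member maximizing mean Tanimoto similarity |A∩B|/|A∪B| to its
  co-members.
- **Classical baselines** — Naive Bayes, KNN, random forest, SVM and a
  feed-forward network over fingerprints or filtered descriptors, each
  grid-searched on a held-out validation part (selection by balanced
  accuracy; the test part is never touched during selection).
- **Hybrid deep model** — a SMILES CNN, a SMILES Transformer and a
  molecular-graph GAT are trained with supervised auxiliary heads, their
  features concatenated and compressed by a variational autoencoder
  (z = μ + σ·ε during training, z = μ at inference), and the latent means
  classified by gradient-boosted decision trees. The neural encoders run on
  a compact NumPy reverse-mode autodiff core bundled with the package
  (`reprotox.nn`), so no deep-learning framework is required.
- **Synthetic fixtures** — a fragment-grammar generator of valid, labeled
  molecules whose class signal is carried by three recognizable motifs
  (nitroaromatic, phenolic, phthalate-like ortho-diester), plus descriptor
  tables with controlled zero-fractions and entropies, so every stage can be
  exercised and audited offline.

Metrics follow the standard confusion-matrix suite: ACC, SE, SP, MCC, P,
F1, BA = (SE+SP)/2, and rank-based (Mann–Whitney) AUC with tie correction.

## Worked example

```python
import numpy as np
from reprotox import (SynthSpec, gen_toy_molecules, split_dataset,
                      fingerprint_matrix, split_indices, grid_search_fit,
                      evaluate_baseline, compute_descriptors,
                      zero_fraction_filter, entropy_filter)

records = gen_toy_molecules(SynthSpec(n=300, positive_fraction=0.47,
                                      label_noise=0.05, seed=42))
split = split_dataset(records, (0.8, 0.1, 0.1), seed=42)   # 240/30/30

X = fingerprint_matrix(records)            # 300 x 2048 Morgan bits
y = np.array([r.label for r in records])
idx = split_indices(records, split)
svm = grid_search_fit("svm", X, y, split, records=records, seed=42)
print(svm.chosen_params_)
print(evaluate_baseline(svm, X[idx["test"]], y[idx["test"]]).as_dict())

table = compute_descriptors(records)       # 300 x 210 named descriptors
stage1, rep1 = zero_fraction_filter(table)
stage2, rep2 = entropy_filter(stage1, prior=rep1)
print(table.shape[1], "->", len(rep2.kept))
```

prints

```
{'gamma': 'auto', 'C': 10.0}
{'ACC': 0.967, 'SE': 1.0, 'SP': 0.938, 'MCC': 0.935, 'P': 0.933,
 'F1': 0.966, 'BA': 0.969, 'AUC': 0.987}
210 -> 65
```

The SVM recovers the motif signal almost perfectly — held-out balanced
accuracy 0.969 with 5% label noise in play — and the two-stage screen keeps
65 of 210 descriptors (75 dropped as mostly-zero, 70 as low-entropy). The
hybrid pipeline is trained the same way:

```python
from reprotox import HybridConfig, train_hybrid

clf = train_hybrid(records, split, HybridConfig(encoder_epochs=30,
                                                vae_epochs=60, seed=42))
proba = clf.predict_proba([r.smiles for r in split.test])[:, 1]
```

A `reprotox` console script exposes the same stages
(`simulate`, `standardize`, `split`, `featurize`, `chemspace`,
`train-baseline`, `train-hybrid`, `predict`); see `reprotox --help`.

## Layout

```
src/reprotox/
  standardize.py   # MoleculeRecord, standardization, loading, splits
  featurize.py     # fingerprints, descriptors, entropy, filters, profile
  chemspace.py     # PCA / t-SNE, Ward clustering, representatives
  metrics.py       # confusion-matrix metrics, rank AUC
  baselines.py     # grid-searched classical models
  synthetic.py     # fragment-grammar molecules, controlled tables
  benchmark.py     # the reference synthetic benchmark conditions
  nn/              # autodiff core, layers, Adam
  hybrid/          # tokenizer, graphs, encoders, VAE, staged classifier
  cli.py           # click command-line interface
docs/methods.md    # model and design notes
```
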