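# causyn

Interpretable prediction of cancer drug-combination synergy from molecular
graphs, cell-line-specific protein-interaction networks and gene
expression.

Given a pair of drugs and a cell line, the model answers two questions:
*will the combination be synergistic* (a binary classification of the
synergy score's sign), and *through which genes* (a per-gene attribution
map). It is aimed at computational pharmacology groups who screen candidate
combinations in silico and need gene-level hypotheses they can push into
enrichment analysis or bench validation.

## Model

Each drug's SMILES string becomes a molecular graph encoded by a GCN
(`H⁽ˡ⁾ = relu(Â H⁽ˡ⁻¹⁾ W⁽ˡ⁾)`, `Â = D^{-1/2}(A+I)D^{-1/2}`) with global max
pooling; the pair embedding is the symmetric sum `D_ij = D_i + D_j`. Each
cell line gets a specific subnetwork of the global PPI graph — its target
proteins connected by a greedy shortest-path Steiner heuristic — whose
expression values are encoded by a second GCN. Cross-attention (queries and
values from the cell's genes, keys from the drug pair) fuses the two into a
drug-aware gene network `G′ = (Cre, Asp)`.

Two small MLPs then score every node and edge with complementary
causal/shortcut attention (`α_c + α_s = 1`), splitting `G′` by Hadamard
masking into a causal subgraph `G_c` (what actually drives synergy) and a
shortcut subgraph `G_s` (confounding signal). Training minimizes

```
L = L_causal + λ₁·L_bias + λ₂·L_interv
```

— cross-entropy on the causal prediction `Φ_c(D_ij ∥ h_Gc)`, a KL term
pushing shortcut predictions toward random labels, and a
backdoor-adjustment term that re-predicts each sample after swapping in
random shortcut representations from the batch. The causal node mask `M_x`
of a trained model is the attribution map: its top 25% per record are that
combination's *key genes*, and the top 20% of cumulative key-gene counts
per cell line are the line's *critical genes*.

The network runs on a small NumPy reverse-mode autodiff engine (float64;
gradients verified against finite differences), so the package has no
deep-learning framework dependency.

## Worked example

Generate a synthetic screen with a planted causal mechanism, fit the
classifier, and check both prediction and attribution:

```python
import numpy as np
from sklearn.metrics import roc_auc_score
from causyn import CausalSynergyClassifier, generate, SyntheticSpec
from causyn.interpret import attribution_rank_auc
from causyn.synthetic import oracle_bayes_auc

synth = generate(SyntheticSpec(seed=1))    # 60 genes, 8 cell lines, 500 records
bundle = synth.load()

recs = [r for r in bundle.records if r.label is not None]
X = np.array([(r.drug1, r.drug2, r.cell_line) for r in recs], dtype=object)
y = np.array([r.label for r in recs])

clf = CausalSynergyClassifier(bundle=bundle, epochs=100, patience=25,
                              n_interventions=2, random_state=0)
clf.fit(X[:450], y[:450])

proba = clf.predict_proba(X[450:])[:, 1]
print("held-out AUC:", round(roc_auc_score(y[450:], proba), 3))
print("bayes ceiling:", round(oracle_bayes_auc(synth), 3))
print("attribution rank-AUC:",
      round(attribution_rank_auc(clf.net_, clf.dataset_,
                                 set(synth.planted_genes)), 3))
```

```
held-out AUC: 0.87
bayes ceiling: 0.88
attribution rank-AUC: 0.814
```

The model separates synergistic from non-synergistic held-out records at
AUC 0.87, essentially at the bundle's generative noise ceiling of 0.88,
and ranking all network genes by their mean causal-mask value places the
six planted causal genes above the non-planted ones with rank-AUC 0.814.
Attribution from a single record's mask is noisier than this aggregate;
the reference experiment (`causyn.experiments.causal_recovery_experiment`)
additionally averages mask profiles over training restarts.

A command-line interface wraps the same library:

```bash
causyn simulate --seed 1 --out data/          # write the five input tables
causyn build-network --data data/ --out-dir nets/
causyn train --data data/ --seed 0
causyn coldstart --data data/ --mode cell --repeats 5
causyn interpret --data data/ --out-dir genes/
```

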