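# Methods

`causyn` predicts whether a pair of drugs acts synergistically on a cancer
cell line, and attributes each prediction to the genes that drive it. This
note records the model, its assumptions, the parameters that matter, what
the synthetic benchmark does and does not emulate, and the numerical and
design choices that were genuinely open.

## Inputs and preprocessing

Five plain-text tables define a dataset: drug → SMILES, a PPI edge list, a
cell-line → target-gene map, a genes × cell-lines expression matrix, and a
synergy table of (drug1, drug2, cell line, score) records. Scores > 0 are
labelled synergistic, < 0 non-synergistic; a score of exactly 0 has no
defined class and the record is excluded. Unordered duplicate pair
orientations are collapsed (the pair embedding is symmetric, so they carry
no extra information). Expression is z-scored, by default per gene across
cell lines (`standardize="per_gene"`), optionally per cell line across
genes; zero-variance slices map to 0.

## Cell-line-specific networks

Each cell line's target proteins seed a subnetwork of the global PPI graph.
Construction is a greedy Steiner-style heuristic on unit edge weights:
every seed starts as a fragment; the two fragments joined by the globally
shortest path are merged (introducing the path's intermediate nodes and
edges) until one fragment remains. Seeds unreachable from the main
component are dropped. Ties between equal-length candidate paths are broken
lexicographically on (sorted endpoint pair, node sequence), and all
traversals use sorted adjacency, so construction is fully deterministic.
The result keeps only path edges (a tree); the full induced subgraph is
available behind `induced_edges=True` for the raw-PPI ablation. On all
connected graphs with ≤ 7 nodes (exhaustively enumerated) the heuristic's
edge count lies between the exact Steiner optimum and the sum of pairwise
seed distances; exact Steiner solving at scale is a non-goal.

## Model

* **Drug encoder.** SMILES → heavy-atom molecular graph (RDKit); atom
  features are a 29-dimensional concatenation of one-hot element (16-slot
  vocabulary), one-hot degree 0–5, formal charge, aromaticity, and one-hot
  total-H count 0–4. A GCN stack `H^(l) = relu(Â H^(l-1) W^(l))` with
  `Â = D^{-1/2}(A+I)D^{-1/2}` followed by global max pooling gives a 1 × h
  drug vector; the pair embedding is the elementwise sum `D_ij = D_i +
  D_j`, so predictions are invariant to pair order. Both drugs share one
  encoder.
* **Cell encoder.** The specific network's expression vector (Gn × 1) goes
  through its own GCN stack over the normalized specific-topology
  adjacency, giving Ce′ (Gn × h).
* **Cross-attention fusion.** Q = Ce′W_Q, K = D_ij^T W_K, V = Ce′W_V;
  attention logits Q K^T/√b are softmax-normalized over the gene axis and
  rescaled by Gn so the mean gate is 1 (a Hadamard gate at softmax scale
  would shrink the fused features ~Gn-fold relative to the residual
  stream). A learned h → b projection reduces the gate to Gn × b, V′ =
  gate ⊙ V, and the residual concatenation Cre = [V′ ∥ Ce′] gives fused
  node features of width h + L·b for L cross-attention layers.
* **Causal decoupling.** A node MLP and an edge MLP score every node and
  unordered edge with a 2-way softmax, giving complementary causal/shortcut
  attention (α_c + α_s = 1, β_c + β_s = 1). The causal subgraph is the
  Hadamard-masked graph (features × α_c, edges × β_c), the shortcut
  subgraph its complement; each is summarized by a GCN + readout (mean by
  default). The propagation matrix of a masked subgraph gates the *fixed*
  normalized adjacency elementwise by the edge mask, leaving self-loops
  unmasked — mask gradients flow through the gate but not through degree
  renormalization.
* **Objective.** `L = L_causal + λ1·L_bias + λ2·L_interv`:
  cross-entropy of the causal prediction z_Gc = Φ_c(D_ij ∥ h_Gc);
  KL(y_rand ‖ z_Gs) pushing the shortcut head toward random one-hot targets
  (resampled every step, uniform class marginal); and the
  backdoor-adjustment surrogate, which re-predicts each sample after adding
  a randomly drawn shortcut representation from the batch (|T̂| draws,
  default 2 in the reference experiment) and demands the correct label.
  Defaults λ1 = λ2 = 0.5. The classifier heads are one-hidden-layer MLPs:
  the synergy label depends on the *product* of cell responsiveness and the
  drug-pair effect, which a linear readout cannot represent. The intervened
  prediction reuses Φ_c's parameters, making the intervention a consistency
  constraint rather than a new head. Probabilities are clamped at 1e-12
  before logs.

All tensors are float64 and gradients come from a small reverse-mode
autodiff engine written for this package; analytic gradients of the full
objective agree with central finite differences to 1e-3 relative error
(tested).

## Optimization

Adam (lr 1e-3, batch 64) with decoupled weight decay (1e-3 in the reference
experiment) in two phases:

1. **Trunk phase.** Encoders, attention and heads train with both mask MLPs
   held at their zero-initialized symmetric point (every score exactly
   0.5). Early stopping monitors a 3-epoch moving average of validation
   AUC after a 10-epoch burn-in (patience 25 of 100 epochs in the reference
   experiment) and restores the best state — on a ~50-record validation set
   raw per-epoch AUC spikes are common, and restoring to a spurious early
   peak discards most of the training.
2. **Mask phase.** The trunk is frozen and only the mask MLPs train for a
   fixed 30 epochs; the mask parameters are averaged over the last two
   thirds of the phase (stochastic weight averaging).

The two-phase schedule exists because mask attribution is a non-convex
byproduct of training: when masks and trunk train jointly, which side of
the causal/shortcut split captures the label signal is decided by the
random interplay of early updates, and runs can converge with inverted or
flat masks. Against a frozen trunk, the mask MLPs — which score nodes from
their features alone and therefore cannot memorize individual cell lines —
have a reproducible descent direction; weight averaging removes the
remaining epoch-to-epoch jitter.

Two regularizers matter for attribution. With few cell lines the trunk can
read cell identity from *any* gene's expression (a fingerprint code) and
memorize each line's responsiveness, which predicts perfectly in
distribution but attributes to arbitrary genes. Train-time node dropout
(p = 0.3: each gene's expression zeroed independently per batch, inverted
scaling) makes single-gene fingerprints unreliable while leaving
multi-gene signal readable, and weight decay disfavors the memorization
solution. Both improved test AUC as well as attribution in the reference
experiment.

The objective is non-convex and a minority of runs never leave the basin
in which predictions use drug features alone; such runs are recognizable
by a smoothed-validation optimum in the first few epochs. The reference
experiment re-initializes and retrains such runs (up to two retries), the
same convergence-failure policy as ``n_init`` in k-means or EM fitting.

## Evaluation

Splits are stratified 8:1:1 (random mode), five-times five-fold CV over the
train+validation pool with a fixed test set, or one of three cold-start
regimes: drug cold start (80% of drugs "known"; training restricted to
known-known pairs), drug-combination cold start (10% of unordered pairs
held out; any record mentioning either held-out drug leaves the training
set), and cell-line cold start (80/20 over cell lines). Leakage constraints
are asserted after every split. Metrics: AUC-ROC (rank statistic), AUC-PR
(step integration), F1 and accuracy at threshold 0.5. Grid search covers
lr ∈ {1e-2 … 1e-5} × batch ∈ {16 … 256} × cross-attention layers ∈ {1,2,3}
× pooling ∈ {max, mean} (120 cells), selecting by validation AUC with ties
to the lower learning rate, then the smaller batch.

## Interpretability

For a trained model, the causal node mask M_x of a record is the vector of
per-gene causal scores α_c in specific-network node order. Genes at or
above the 75th percentile of a record's mask are its key genes (all
boundary ties included, so at least 25% are selected); accumulating
key-gene membership over a cell line's synergistic records and taking the
top 20% of the count distribution (ties included, zero counts excluded)
gives the cell line's critical genes. Ranked count tables are exported as
two-column text for external enrichment services; no network calls are
made. Accumulation uses records labelled synergistic by default; a flag
restricts it to records also predicted synergistic.

## Synthetic benchmark

The generator emits all five inputs plus ground truth, with a planted
mechanism: a random connected PPI graph over N = 60 genes (average degree
≈ 4: a random spanning tree plus Bernoulli extras), k = 6 planted genes
included in every cell line's targets alongside 8 random extras, 8 cell
lines of which an exact count (round(0.75 × 8) = 6, drawn without
replacement) are responsive — planted expression shifted by w = 2.0; all
other expression standard normal — and 12 bundled small drug-like
molecules (six aromatic, six acyclic). The synergy score of
(d1, d2, c) is `w · mean(planted expression in c) · s(d1, d2) + ε` with
ε ~ N(0, 0.3²) and s a fixed symmetric descriptor (z-scored heavy-atom-
count sum plus an aromatic-ring term); the label is the score's sign, and
10% of scores have their sign flipped. 500 unique (pair, cell) records are
drawn; duplicates are impossible by construction. The Bayes ceiling — the
AUC of the true noiseless score against the noisy labels — is ~0.85–0.91
at these settings.

The responsive count is exact rather than Bernoulli-sampled: differential
response *is* the planted mechanism, and a stratified draw guarantees both
responsive and non-responsive cell lines in every bundle (an independent
0.75 coin per cell line would produce an all-responsive panel — in which
the planted genes are not causal for the labels and the recovery question
is ill-posed — about 10% of the time). Effect size, noise level and
descriptor are documented above so the ceiling is computable in closed
form from a bundle.

The benchmark's expression pipeline standardizes per cell line, not per
gene. The planted mechanism is a between-cell-line shift, and per-gene
z-scoring forces every gene's marginal distribution to mean 0/sd 1 — a
Monte-Carlo likelihood-ratio bound shows a single forward pass (which sees
one cell line) would then retain almost no per-node trace of planted-ness
(optimal value-based discrimination ≈ 0.54 AUC), making node-level
attribution impossible for any model. Within-cell-line scaling preserves
exactly the gene ranking the attribution experiment is designed to
recover. Real panels with many cell lines should keep the per-gene default.

What the generator does not emulate: realistic synergy-score marginals
(Loewe/Bliss), transcriptome covariance structure, dose dependence, or
identifier nomenclature issues. Passing the recovery experiment shows the
pipeline can learn and attribute a planted multiplicative
drug-by-expression mechanism at desk scale; it does not certify
performance on real screens.

## Reference experiment

`causyn.experiments.causal_recovery_experiment` trains the classifier on
three bundles (seeds s, s+1, s+2), three restarts each, and reports mean
test metrics, the Bayes ceiling, and the attribution rank-AUC — planted vs
non-planted genes ranked by each gene's mean causal-mask value over
synergistic records, with restart mask profiles averaged before ranking
(flat failed runs contribute little variance, so the consistent signal
dominates). The ablation variant freezes masks at the causal extreme with
zero disentanglement weights, reducing the model to a plain GCN +
cross-attention classifier whose flat mask carries no attribution signal
(rank-AUC 0.5). Problem sizes (60 genes, 8 cell lines, 500 records, 100 +
30 epochs, three restarts) were chosen so the whole experiment runs in
minutes on one CPU.

## Known limitations

* Attribution quality is a training byproduct, not an optimized objective;
  individual runs vary, which is why the reference experiment averages
  restarts and seeds.
* With few cell lines, genes whose expression is spuriously correlated
  with responsiveness across the panel are legitimate alternative
  explanations; no in-distribution method can fully separate them from the
  planted set.
* The shortcut head can satisfy its random-target loss regardless of the
  masks, so the bias term contributes little disentanglement pressure in
  practice; the intervention term and the two-phase schedule do that work.
* The Steiner heuristic is exact only on small graphs; on large PPI
  networks it is an approximation with the stated bounds unverified beyond
  8 nodes.
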