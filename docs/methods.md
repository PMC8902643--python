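# Methods

## Problem setting

Experimentally confirmed circRNA–disease associations are scarce (on the
order of hundreds of pairs over hundreds of circRNAs), while abundant
association data exists for related entity types: circRNA–miRNA,
disease–gene, disease–miRNA, disease–lncRNA and disease–drug. The package
predicts unobserved circRNA–disease links by (1) compressing each entity's
heterogeneous association profile into a fixed-length embedding and
(2) classifying (circRNA, disease) embedding pairs.

All association inputs are two-column edge lists. Names are normalized by
trimming, case-folding and collapsing internal whitespace runs; no
cross-database alias resolution is attempted (that is data curation, not
method). Each entity class gets a fused binary adjacency matrix: circRNA
rows over a disease block plus a miRNA block; disease rows over gene, miRNA,
lncRNA and drug blocks. Entry (i, j) = 1 iff the pair was observed. Column
blocks are concatenated in declared configuration order and offsets are
stored with the matrix, so embeddings are reproducible; all-zero columns are
pruned by default (they contribute no reconstruction gradient), with a flag
to retain them. When no disease-side relation table is available at all, the
disease adjacency falls back to the transposed circRNA–disease table so
diseases still have a profile.

## Entity relation network (embedding stage)

Entity i's embedding v_i is row i of a trainable projection matrix W_emb
(the one-hot × matrix product is implemented as a row lookup). A two-layer
head reconstructs the entity's association profile:

    P_i = σ( σ( relu(v_i) · W1 ) · W2 ),

where σ is the logistic function. The double-logistic head (an inner
logistic before the second linear map) is unconventional but implemented
exactly as specified; it bounds the hidden activations in (0, 1). No bias
terms by default (`use_bias` enables them). The loss is the squared
reconstruction error; the optimizer minimizes the mean per matrix entry (so
the learning rate is independent of matrix size) while `ern_loss` reports
the plain sum. Training is deliberately unregularized and run toward
overfitting: a near-exact reconstruction forces entities with similar
profiles to behave similarly downstream, and on any small binary matrix the
trained head thresholded at 0.5 reproduces the matrix exactly.

Defaults: embedding_dim 128, hidden_dim 256, Adam at 1e-3, full-batch,
2000 epochs, early stop when the per-entry MSE falls below 1e-4. Weights are
initialized from a symmetric uniform distribution scaled by 1/sqrt(fan-in)
(the embedding matrix scales with the embedding width instead, since rows
are looked up rather than summed over), seeded; training is bit-for-bit
reproducible given (seed, config, input).

### Out-of-vocabulary embedding (general embedder)

A separate feedforward map F_m (one rectifier hidden layer of `hidden_dim`
units, linear output, biases) is fitted to the pairs (profile row,
trained embedding row), approximating the inverse of the reconstruction
head. Any entity — in vocabulary or not — can then be embedded from a
binary profile alone. The fit target is a mean squared error of 1e-5
(or 2000 epochs, Adam at 10× the embedding learning rate). The tight
target matters: at 1e-3 the mean error permits single-coordinate errors
near 0.09, which would break the contract that refitted embeddings match
trained embeddings to within 0.05 per coordinate; at 1e-5 the observed
maximum error is ~0.01 across seeds, at negligible cost.

## Pseudo-siamese classifier

Disease and circRNA embeddings come from different semantic spaces, so the
two branches share an architecture but no weights:

    u = E_d(v_disease),  v = E_c(v_circ),
    P = σ( head([u; v; u − v; u ⊙ v]) ).

Each extractor is one rectifier hidden layer (64 units) into a 64-dim linear
feature; the head is one rectifier hidden layer (64 units) into a single
logistic unit. The difference and element-wise product blocks let the head
read local agreement between branches directly. Training is binary
cross-entropy with Adam (1e-3), mini-batches of 64, up to 200 epochs.

Two measures guard against label-noise memorization, which matters because
the negatives are *presumed* (sampled unobserved pairs) and, on synthetic
data, a known fraction of labels contradicts the latent structure:

- a stratified 10% validation split with early stopping (patience 20,
  best-validation weights restored). On noisy data the held-out
  cross-entropy turns upward long before the epoch budget; training to
  completion demonstrably erodes held-out ranking quality.
- `cross_validate` trains 5 independently initialized classifiers per fold
  and averages their probabilities. Embedding training dominates runtime,
  so the ensemble is nearly free and damps initialization variance.

If the pair set is too small for a stratified split, early stopping is
silently disabled and training runs the full budget.

## Evaluation protocol

Positives are the observed circRNA–disease pairs; an equal number of
negatives is drawn uniformly, without replacement, from the complement of
the circRNA × disease grid, once, before folding (a per-fold resampling
variant is available by passing a custom pair set). Stratified k-fold
(default k = 5) cross-validation reports accuracy, sensitivity, precision,
F1 (= 2TP / (2TP + FP + FN)) and AUC per fold, and mean ± sample (n−1)
standard deviation across folds. A probability equal to the class threshold
(default 0.5) is called positive; degenerate denominators (e.g. precision
with TP + FP = 0) yield a flagged NaN sentinel that summaries exclude
rather than a silent zero.

AUC is computed as the midrank statistic (probability that a random
positive outscores a random negative, ties counted one half) — exact and
tie-safe — and separately as the trapezoidal area under the ROC curve; the
two agree and both are exposed.

**Leakage guard.** The circRNA adjacency fuses the circRNA–disease links
themselves, so embeddings trained on the full adjacency would see held-out
test labels. By default, each fold's held-out positive links are masked out
of the adjacency before embedding training for that fold. Disabling the
guard (`--paper-mode`) reproduces the naive protocol and inflates scores.
Note the guard induces a train/test asymmetry of its own (training
positives keep their link in the profile, held-out positives do not),
which is one reason the classifier's early stopping is important.

**Candidate ranking.** For one disease, all circRNAs are sorted by
descending predicted probability with lexicographic tie-break on the name;
recall@t is the fraction of the disease's known positives scoring strictly
above t (NaN when no known positives are supplied). Out-of-vocabulary
diseases are embedded from a supplied profile via the general embedder.

## Synthetic benchmark

The generator plants a K-group latent structure: every entity of every type
gets a group label; each candidate pair in each of the six relations is
linked independently with probability p_in (same group) or p_out
(otherwise). Group labels are assigned by shuffling a balanced label vector
(each group receives ⌊n/K⌋ or ⌈n/K⌉ members) so no group is empty and the
deterministic p_in=1/p_out=0 fixture always contains duplicate-profile
entities. All six relations share p_in/p_out — the simplest structure under
which multi-source fusion is informative.

Default benchmark condition: 40 circRNAs × 20 diseases, auxiliary
vocabularies of 60 miRNAs, 60 genes, 30 lncRNAs, 30 drugs, K = 4,
p_in = 0.9, p_out = 0.05. These sizes keep a full fivefold run around half
a minute on one core while leaving ~400 labeled pairs, enough for stable
fold metrics.

What the planted model does and does not emulate: it produces the
"entities sharing latent groups share association profiles" signal the
embedding stage assumes, with controllable noise, but real association data
is scale-free and degree-heterogeneous, negatives are not verified
non-associations, and database name inconsistencies are absent. Passing the
recovery tests therefore demonstrates that the pipeline extracts planted
multi-source structure — not that real-data headline numbers are
reproduced.

An information ceiling is built into the condition: given the latent
groups, edges are independent, so no predictor can beat scoring by group
membership. At the defaults ~14% of positives are cross-group (p_out) edges
and ~3% of sampled negatives are same-group non-edges, capping AUC around
0.91–0.95 depending on the draw; measured mean held-out AUC across seeds is
≈ 0.88–0.96, i.e. close to the ceiling. With p_in = p_out = 0.26 (the
density-matched null) there is nothing to recover and AUC sits at chance.

## Numerical and degenerate-input choices

- All randomness flows through seeded NumPy generators; derived seeds are
  simple offsets of the user seed. Two runs with identical configs and
  seeds produce byte-identical metric CSVs.
- Duplicate pairs in a prediction batch are scored once and share
  bitwise-identical probabilities (batched BLAS can otherwise differ in the
  last ulp by row position).
- Non-finite training losses abort with a divergence error rather than
  propagating NaNs.
- An all-zero association profile embeds to a finite vector (the general
  embedder's bias path).
- Pairs referencing entities outside the row vocabulary are dropped with a
  logged count when building adjacencies (the sources cover different
  entity sets); unknown entities in a scoring request raise.

## Known limitations

- The real six-database corpus is out of scope: no native dump parsers, no
  alias/ontology name unification. Published headline metrics on that
  corpus are therefore not reproduced here.
- The double-logistic head saturates slowly under MSE; exact-overfit
  behaviour is only asserted for small matrices (≤ ~32×32).
- Negative sampling treats all unobserved pairs as exchangeable; no
  hard-negative or degree-matched sampling.
- The classifier ensemble and early stopping reduce, but cannot remove, the
  variance induced by the leakage guard's train/test asymmetry on small
  benchmarks.
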