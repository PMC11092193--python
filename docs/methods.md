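# Methods

## Problem and model

Given a set of `n` proteins with amino-acid sequences and a partially
observed protein–protein interaction (PPI) network, the package predicts
whether a candidate pair of proteins interacts. The method builds a single
*initial information matrix* that fuses two views of the proteins, learns a
low-dimensional embedding of each protein from it, and classifies candidate
pairs from the concatenated embeddings.

**Network view.** The interaction profile of protein `i` is row `A(i)` of the
binary adjacency matrix. The Gaussian interaction-profile (GIP) kernel

    S_network(i, j) = exp(-gamma_r * ||A(i) - A(j)||^2)

with bandwidth `gamma_r = n / sum_i ||A(i)||^2` (the reciprocal of the mean
squared profile norm; for a binary adjacency this is `n / (2|E|)`) turns
shared interaction partners into similarity. For binary rows the squared
Euclidean distance equals the Hamming distance between profiles, which the
tests exploit. The bandwidth is undefined on an edgeless graph, so all-zero
adjacencies are rejected upstream.

**Sequence view.** The Levenshtein distance `LD(s, t)` — the minimum number
of single-residue insertions, deletions and substitutions converting one
sequence into the other — is converted to a similarity. The conversion is a
genuine design choice; the default

    S_seq(i, j) = 1 - LD(s_i, s_j) / max(|s_i|, |s_j|)

maps to `[0, 1]` with unit diagonal, matching the range of the GIP kernel so
that the two views fuse on a common scale. Two alternatives are available
(`sum`: divide by `|s|+|t|`; `exp`: `exp(-LD)`). Ambiguity codes B/J/O/U/X/Z
are accepted and treated as ordinary distinct symbols — the edit distance
operates on raw strings and no alphabet rule is imposed. The distance itself
is computed by `edlib` (global Needleman–Wunsch alignment in distance mode);
the test suite checks it against an exhaustive recursive oracle.

**Fusion.** `M = alpha * S_network + (1 - alpha) * S_seq`, elementwise, with
`alpha` in `[0, 1]`. `alpha = 0` keeps only sequence information,
`alpha = 1` only network information. The endpoints are returned as exact
copies of the source matrices so the single-source pipelines are reproduced
bitwise. The default sweep grid is `{0, 0.125, ..., 1}` (nine values);
selection maximises mean cross-validated accuracy with ties broken toward
the smaller `alpha`.

Similarity matrices are computed on the full network, including pairs later
held out as cross-validation test examples — this matches the protocol the
method was described with, but it does leak test edges into the features. A
leakage-controlled mode (`mask_test_edges`) recomputes `S_network` per fold
with the test fold's positive edges removed and retrains the autoencoder per
fold; it is off by default for fidelity, and its reports are the ones to
trust when estimating generalisation to unseen interactions.

## Stacked-autoencoder embedding

Each protein's raw feature vector is its row of `M` (dimension `n`). A
stacked autoencoder with encoder widths `[n, 1024, 512, 128]` and an untied
mirrored decoder is trained end-to-end to minimise the mean squared
reconstruction error `F = (1/N) sum_i ||x_i - g(f(x_i))||^2`. Defaults:
logistic-sigmoid activations on every layer (the inputs live in `[0, 1]`),
Adam with learning rate 0.001, minibatches of 32, at most 100 epochs, early
stopping with patience 30 monitoring a held-out 10 % row split, best-epoch
parameters restored. The decoder is discarded after training; the
128-dimensional bottleneck output is the node embedding.

Design notes:

* *End-to-end vs greedy.* The stack is trained as one network under a single
  loss with one optimiser and epoch budget; classic greedy layer-wise
  stacking is available via `greedy=True` for comparison.
* *Width capping.* The default hidden widths presume `n > 1024`. For smaller
  inputs each width is capped at its predecessor (e.g. `n = 300` resolves to
  `[300, 300, 300, 128]`) so the autoencoder never widens — a widening
  autoencoder trivially memorises.
* *Activation.* A `relu` mode (ReLU hidden layers, linear bottleneck and
  reconstruction) is available; sigmoid is the default. With sigmoid units
  the trained codes tend to saturate toward near-binary values, so distinct
  fusion weights can map to identical downstream predictions — visible in
  the flat accuracy profile across much of the alpha grid on synthetic data.
* *Scaling.* Fused rows are used as-is (already in `[0, 1]`); a min–max
  option exists. Training uses float32 arithmetic; runs are bitwise
  reproducible per seed within an environment.

## Classification and evaluation

A pair `(a, b)` (stored canonically as `min_index, max_index`) is
represented by the concatenation `[f(x_a), f(x_b)]` (width 256 by default).
Classifiers: RBF-kernel SVM (default, `C = 1`, `gamma = 'scale'` — the
automatic `1/(d * var)` rule), XGBoost, random forest and Gaussian naive
Bayes with library defaults and fixed seeds. Evaluation is stratified 5-fold
cross-validation; per fold the suite reports accuracy, precision,
sensitivity, F1, the Matthews correlation coefficient and AUC. ROC scores
use the SVM's signed decision value rather than calibrated probabilities —
monotone in any calibrated probability, hence AUC-identical and cheaper.
Ratios with zero denominators are reported as 0 with a warning flag so
aggregate means stay defined. The SAE is trained once on all rows and the
embedding reused across folds (the unsupervised phase never sees labels);
per-fold retraining is available behind a flag.

## Synthetic data generator

The generator emulates an attributed PPI network in which network structure
and sequence divergence are two noisy views of one latent community
membership — the regime where fusing the views should beat either alone:

* communities assigned round-robin; edges drawn independently with
  probability `p_in` within and `p_out` between communities (planted
  partition);
* one uniform-random ancestor sequence per community; each protein's
  sequence is its ancestor with iid substitutions at rate `mu` (drawn
  uniformly from the 19 non-identical residues) and a Poisson number of
  single-residue indels;
* positives are exactly the sampled edges; negatives are uniform non-edges
  at a configurable ratio (localisation-informed negative selection is out
  of scope).

Default preset: 300 proteins, 6 communities, `p_in = 0.25`, `p_out = 0.02`,
120-residue ancestors, `mu = 0.15`, one expected indel, balanced negatives —
about 2 600 edges and 5 200 labelled pairs, sized so the full nine-point
alpha sweep runs in minutes on one CPU.

What the generator does **not** emulate: scale-free degree distributions,
domain-level sequence structure, composition bias, and
localisation-informed negatives. Passing tests therefore demonstrate the
pipeline's internal correctness and the fusion effect in a controlled
regime, not performance on curated interactome data.

## Numerical choices and limitations

* Similarity matrices are validated to be symmetric within 1e-12 with unit
  diagonal and entries in `[0, 1]`; kernels are symmetrised explicitly
  against floating-point drift.
* Identical adjacency rows legitimately give network similarity 1 for
  distinct proteins; no de-duplication is performed.
* Tie-break in the alpha sweep: smaller alpha wins at equal mean accuracy.
* Degenerate inputs rejected with named errors: edgeless networks, empty
  sequences, all-negative pair sets, negative sampling beyond the available
  non-edges.
* On small synthetic instances the GIP kernel has low contrast (profiles are
  sparse and bandwidths small), so the network-only endpoint can
  underperform the sequence-only endpoint — the fusion claim is about the
  interior matching or beating both endpoints, not about which endpoint is
  stronger.
* The package does not parse curated interactome databases and does not
  perform redundancy filtering of sequences; identifier mapping between
  sequence and interaction sources is the user's responsibility.
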