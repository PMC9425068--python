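# Methods

## Model

`gcnlmf` scores genes for association with a single disease from two
inputs: a gene–gene interaction network and a small labeled gene set
(known positives plus sampled negatives). The model has two stages.

**Feature propagation.** The adjacency A (symmetric, non-negative weights,
zero diagonal) is given self-loops, Ā = A + I, and symmetrically
degree-normalized, Â = D^(−1/2) Ā D^(−1/2) with D = diag(row sums of Ā).
Â is symmetric with spectral radius at most 1, so repeated application
smooths node features without blow-up. Features pass through layers
H^(i+1) = σ(Â H^(i) W^(i)). The W^(i) are *not trained*: no supervised
objective exists at this stage, so each W^(i) is a fixed orthonormal
projection drawn from a seeded generator, and the encoder is deterministic
neighborhood aggregation. Default input features are one-hot node
indicators (F⁰ = N), so after two layers a gene's embedding summarizes its
two-hop weighted neighborhood, randomly projected to 64 and then 32
dimensions (ReLU between layers, identity on the output layer).

**Logistic matrix factorization.** Gene i's association probability is
p_i = σ(x_u·y_i + β_u + β_i) with disease factors x_u ∈ R^f, gene factors
y_i (rows of Y), and free biases. Observed associations r_i ∈ {0, 1} enter
a confidence-weighted Bernoulli likelihood; the penalized log-posterior is

    Σ_i [ w_i z_i − (1 + w_i) log(1 + e^{z_i}) ]
        − (λ/2)‖x_u‖² − (λ/2) Σ_i ‖y_i‖²,      z_i = x_u·y_i + β_u + β_i,

with w_i = a·r_i by default (`weighting="linear"`); the alternative
logarithmic confidence mapping w_i = a·log(1 + r_i/ε) is available as
`weighting="log"` and is the only place the scale ε enters. Gaussian
priors on the factors give the L2 terms; biases are unregularized. Note a
consequence of the weighted likelihood: a lone positive's optimum
probability is a/(1+a), not 1, so a controls how hard positives are pushed.

**Fusion.** Y is initialized from the column-standardized embeddings
(`y_init="gcn"`). Only genes in the training mask contribute to the
posterior, its gradients, and the Y-penalty; unlabeled genes' rows stay
frozen at their embeddings. A held-out gene is therefore scored by the
trained disease vector against its network embedding — this frozen-row
pathway is what generalizes label information over the topology.
`y_init="random"` replaces the embeddings with seeded noise and reproduces
plain logistic MF as an ablation.

**Optimization.** The posterior is maximized by alternating gradient
ascent: one AdaGrad step on the disease side (x_u, β_u) with the gene side
fixed, then one on the gene side (masked rows of Y, β). Per-coordinate
AdaGrad scaling (floor 1e-8) makes a single learning rate (0.05) workable
across parameter blocks. The posterior is recorded every pass; a
non-finite value aborts with the iteration named. The default 3000 passes
is chosen where the posterior trace flattens (gain below ~0.3 per 100
passes on few-hundred-gene problems); there is no early stopping because
no validation signal exists inside a fold.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `gcn_layer_dims` | (64, 32) | hidden and output widths of the two propagation layers; two layers is the standard depth for neighborhood aggregation |
| `gcn_activation` | relu | hidden nonlinearity; output layer is linear |
| `gcn_weight_seed` | 17 | seed of the orthonormal projection draw |
| `n_factors` (f) | 32 | latent dimension; must not exceed the embedding width |
| `a` | 2.0 | positive-confidence weight; lone-positive optimum p = a/(1+a) |
| `epsilon` | 1.0 | confidence scale, consulted only under `weighting="log"` |
| `lam` (λ) | 0.5 | L2 penalty on x_u and trained Y rows (dimensionless) |
| `iterations` | 3000 | alternating passes; see convergence note above |
| `learning_rate` | 0.05 | AdaGrad base step |
| `init_seed` | 0 | seed for x_u noise (scale 1e-3) and random Y init |

Evaluation defaults: 200 sampled negatives, stratified 10-fold CV, ROC AUC
in Mann–Whitney midrank form, AUPR as step-wise average precision with
ties broken against the positive class (pessimistic: tied negatives rank
ahead of tied positives, so ties never flatter the ranking). Fold summary
uses the population standard deviation of the 10 fold values.

## Synthetic benchmark

The generator plants a single dense module in a sparse background (a
two-parameter planted partition): `module_size` genes pairwise connected
with probability p_in, all other pairs with p_out, unweighted edges. The
reference scenario is 500 genes, a 40-gene module, p_in = 0.30 vs
p_out = 0.02, 40 labeled positives (echoing a ~41-gene curated disease
set) and 200 sampled negatives. Expected degrees are ≈ 20.9 inside the
module vs ≈ 10.0 outside, i.e. a strong but not trivial topological
signal. The no-signal control sets p_in = p_out, where cross-validated
AUC must sit near 0.5.

What this does and does not show: the benchmark exercises exactly the
signal the method consumes — elevated within-module connectivity — under a
homogeneous degree distribution. Real interaction networks are scale-free,
have study-bias-driven degree inflation of well-known disease genes,
confidence-weighted edges, and positives that are not a single coherent
module. Passing the planted benchmark demonstrates the pipeline recovers a
clean topological module; it does not certify performance on any specific
curated network, which depends on resource version and coverage.

## Numerical and design choices

- **Normalization exponent.** The degree normalization is the symmetric
  D^(−1/2) Ā D^(−1/2) of the standard graph-convolution construction,
  keeping Â symmetric and its spectrum in [−1, 1].
- **Stable probabilities.** Sigmoids are computed in branch-stable form
  and clipped to the open interval (tiny, 1 − ulp), so saturated scores
  remain valid probabilities; log-likelihoods use `logaddexp`.
- **Edge-list semantics.** Duplicate edges keep the maximum weight
  (idempotent under re-export), self-edges in input files are dropped
  (self-loops enter only through Ā = A + I), and weighted degrees are used
  as given. Gene identity is the upper-cased symbol; no ID mapping.
- **Determinism.** All randomness flows through seeded generators; ranked
  output breaks probability ties lexicographically by symbol; the CLI
  derives per-stage seeds from one run seed by hashing, and writes floats
  with shortest-round-trip repr so reruns are byte-identical.
- **Isolated labeled genes** are appended as degree-0 nodes by default
  (they still receive a self-loop, so they are scorable, just uninformed);
  a strict `error` policy is available.
- **Label noise rounding.** The simulated mislabeled-positive count is
  floor(label_noise × n_positives), making small-sample tests exact.
- **Two-stage fitting.** Propagation and factorization are fit in
  sequence, coupled only through initialization. This is the minimal
  coupling consistent with both components; no end-to-end objective is
  invented for the untrained encoder.

## Known limitations

- **Single-disease bias memorization.** With one disease, every gene has
  at most one observation, so the free per-gene biases β_i can fit the
  training labels almost entirely on their own (|β_i| of order 1 against
  factor terms of order 10^-2 at convergence). Held-out ranking therefore
  rides on a comparatively small factor-alignment signal.
- **Run-to-run variance.** Because the encoder is a random projection and
  the generalizing signal is small, cross-validated mean AUC on the
  reference scenario varies by roughly ±0.1 across projection draws
  (equivalently, across input gene orderings, which re-mix the projection).
  The pinned benchmark configuration is reported reproducibly; treat any
  single draw's AUC with that spread in mind, and average over encoder
  seeds when comparing variants.
- **Dense algebra.** The adjacency is dense in memory (O(N²)); networks of
  a few thousand genes are comfortable, proteome-scale networks are not
  the target.
- **Masked-gene freezing** means training never refines unlabeled genes'
  factors; that is intentional (it is the generalization pathway) but it
  makes predictions for unlabeled genes entirely dependent on embedding
  quality.
- The multi-disease case is structurally supported (the updates keep both
  sides) but untested beyond the degenerate 1×N observation vector.
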