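# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not establish.

## Problem setting

Given a binary drug–target interaction matrix and a collection of auxiliary
relations — drug–disease, drug–side-effect and target–disease bipartite
networks, chemical and sequence similarity matrices, binary interaction
networks, and an optional per-drug text-embedding matrix — predict held-out
interactions. Prediction is transductive node classification on a
drug–target-pair (DTP) graph: all candidate pairs (positives plus sampled
negatives) are nodes of one graph; held-out pairs keep their features and
edges but their labels never enter the loss.

## Pipeline stages

### One-mode projection and thresholding

A bipartite incidence matrix *M* is projected as *S = M Mᵀ*, whose entry
*(u, v)* counts the partners shared by entities *u* and *v* (the diagonal
carries degrees). *S* is binarized at a threshold *k_sim*, by default the
0.9 quantile of its off-diagonal values; the comparison is inclusive
(*≥ k_sim* keeps the edge). The diagonal is zeroed at this stage and a
self-loop is re-added exactly once inside the encoder's normalization, so
entities are never double self-weighted. Weighted similarity matrices skip
the projection and are thresholded the same way, each source with its own
threshold. A differentiable threshold variant (hard forward, sigmoid
surrogate gradient with temperature τ) exists for contexts where a
threshold should receive gradients; the per-source similarity thresholds
use the deterministic quantile because nothing upstream of them is trained.

### Source encoders

Each thresholded graph is encoded by one symmetric-normalized graph
convolution. The baseline operator is
*Z = σ( D^(−1/2)(A+I)D^(−1/2) · E · W )*; the trained pipeline uses its
lazy (teleport-style) form

  Z = (1−w)·E·W + w·Â·E·W,  Â = D^(−1/2)(A+I)D^(−1/2),

with *w = 0.25* and linear σ by default (ReLU available). Setting *w = 1*
recovers the plain convolution. The lazy form exists because one full
normalized convolution replaces each entity's embedding almost entirely by
a neighborhood average (the self-weight is ≈ 1/degree); interaction
prediction needs individual-level precision, and a dominant self-term
preserves it while still injecting neighborhood evidence.

The initial embedding table *E* (one per entity class, shared across that
class's sources) is a **fixed structural feature matrix**: the top-*d*
spectral factors *Q_d Λ_d^(1/2)* of the class's designated similarity
network (chemical similarity for drugs, sequence similarity for targets),
so *E Eᵀ* approximates that similarity. A seeded Gaussian table is the
fallback when no such network exists, and `train_embeddings=True` makes *E*
trainable. Fixed tables are the default because free per-entity embeddings
optimized jointly with the classifier memorize the training pairs (training
AUROC near 1) while destroying the geometry that generalizes to held-out
pairs; the spectral table pins the geometry and leaves adaptation to the
(much smaller) per-source maps.

The per-source maps *W* start at identity and the text map starts at the
least-squares projection of the text matrix onto *E*, so at initialization
every source presents its structural embedding unchanged and coherently
oriented; training only has to reweight and refine. Gaussian-initialized
maps start each source as an independent random rotation, and averaging
incoherently rotated sources in the fusion stage measurably degrades the
fused representation.

### Graph-generated fusion

Per entity, the *p* source embeddings *z ∈ R^(p×d)* give *Q = z zᵀ*; the
generated source graph is *G = [Q ≥ k]* with self-loops forced on (every
source must have a nonempty neighborhood) and *k* a learnable scalar per
entity class, initialized at the median off-diagonal value of *Q* so the
starting graph is never degenerate. The gate is hard in the forward pass
with a straight-through sigmoid gradient (temperature τ = 1). A single
shared attention head (LeakyReLU slope 0.2, attention vectors initialized
small) produces α over the generated edges, sources aggregate as
*h_s = Σ_j α_sj (W z_j)*, and the entity embedding is the unweighted mean
over the *p* rows of *h*. Pooling over the source axis is one of two
readings of the aggregation; the other (pooling over generated-graph
columns) is numerically identical after the symmetric construction used
here.

### Pair graph

Pair features are the end-to-end concatenation *[H_D(d) ‖ H_T(t)]*. Two
pair nodes are adjacent iff they share the drug or the target — the only
topological commonality two pairs possess; an alternative feature-based
construction (inner-product threshold at a quantile, default 0.9) is kept
as an ablation. Negative pairs are sampled uniformly without replacement
from the zero cells at an integer ratio (1:1 default; 1:2, 1:3 supported)
and participate in adjacency construction exactly like positives, so graph
structure never leaks labels. The adjacency has zero diagonal; self-loops
are added inside the encoder.

### Pair encoder and objective

The encoder is two graph-attention layers (64 hidden, 64 out, one head,
ELU between) over the sparse edge list with self-loops. Two deliberate
departures from the textbook layer:

* **Residual skips.** Each layer adds a learned linear skip *H W_skip* to
  the attention aggregate. Softmax attention spreads a node's own features
  over its neighbors, and for pair classification the node's own features
  carry the decisive (multiplicative) signal; without the skip the encoder
  cannot even match a plain multilayer perceptron on clean features.
* **Attention-coefficient dropout** (rate 0.6) during training, applied
  after normalization, never to features. The neighborhood of a pair node
  is a near-unique fingerprint, and undropped attention lets the network
  memorize training labels through it; dropping coefficients suppresses
  that path while the (deterministic) skip path learns the transferable
  signal. Feature dropout is deliberately not used: the interaction signal
  lives in products of coordinates from the two halves of the pair feature,
  and zeroing coordinates destroys it.

Each epoch, two views are drawn: every undirected pair-graph edge is
removed independently with probability ρ and every feature dimension
(column) is zeroed with probability ρ (ρ = 0.3 default; ρ = 0 reproduces
the input exactly). Both views and the original graph are encoded by the
same parameters. The contrastive term uses per-dimension population
standard deviations *s* and column encodings centered and L2-normalized
with an ε-floor (ε = 1e−12; a constant column normalizes to ≈ 0 without
error):

  L_CL = −α Σᵢ X̃₁ᵢ·X̃₂ᵢ + β Σᵢ ( (s₁ᵢ−λ)² + (s₂ᵢ−λ)² )

with α = β = λ = 1. Classification is logistic on the original-graph
encoding; cross-entropy is summed (mean reduction available) with
probabilities clamped to [ε, 1−ε] under a warning. The joint objective is
L = L_CE + L_CL, optimized by Adam (lr 1e−3, 300 epochs, full batch;
optional cosine decay and trailing-window prediction averaging are off by
default). Three variants share one code path: `full` steps on L;
`no_causal` computes and logs L_CL but steps on L_CE; `supervised` builds
no views. Parameter initialization, augmentation, and dropout draw from
three independent seeded streams, so `full` with α = β = 0 and ρ = 0 is
bit-identical to `supervised` — the zero-coefficient contrastive branch
contributes exact-zero gradients.

The constrained view of the objective (match view means subject to a fixed
per-dimension spread) is implemented only through this relaxed penalty; no
projection step exists. No explicit causal/non-causal node partition is
ever computed — the invariance pressure of L_CL is the operational content.
An optional selector for "stable" nodes ranks nodes by the Euclidean
distance between their two view encodings; the change metric is an
interpretation, labeled as such in its docstring.

## Automatic differentiation

No GPU tensor framework is used. `dtifuse.autodiff` is a reverse-mode
engine over numpy arrays with exactly the operations the model needs —
dense and sparse-constant matmul, a differentiable weighted sparse matmul
for attention aggregation, batched matmul for the per-entity fusion,
elementwise arithmetic with broadcasting, reductions, activations, and the
straight-through gate. Finite-difference agreement at 1e−5 (1e−4 for the
composed contrastive loss) is part of the test suite. Attention softmax
uses per-destination max subtraction; normalization quality is monitored
every forward pass (worst row-sum deviation is reported per run).

## Synthetic benchmark

All entity classes draw i.i.d. standard Gaussian latent factors (U, V, C,
E; dimension 8 by default). Interactions are Bernoulli in
σ(a·U_iV_j + b) with a = 1 and b calibrated by bisection to the requested
density (0.08 over 60×80 by default). Auxiliary bipartite networks are the
top-density quantile of the corresponding factor products; similarity
networks are U Uᵀ (V Vᵀ) plus symmetrized Gaussian noise (sd 0.1), clipped
at zero to satisfy nonnegativity; binary interaction networks threshold
the noiseless product at the density quantile; the text stand-in is
U + noise (sd 0.1). The latent inner product scores held-out pairs as an
oracle ceiling, and the train-positive degree product is the popularity
floor; at the default configuration the acceptance script computes a
pipeline mean test AUROC between those two references.

What the generator does **not** emulate: chemical fingerprints or sequence
semantics (only their network-shaped interface), hub-dominated degree
distributions, block/community structure, measurement sparsity patterns, or
biased (non-uniform) negative labels. Passing tests therefore demonstrate
that the pipeline recovers planted low-rank interaction structure from
redundant noisy views at desk scale — not performance on any real
repository, where label noise, covariate shift, and non-factor structure
dominate.

## Splits and metrics

Random splits permute pairs into 0.8/0.1/0.1 train/validation/test. Cold
splits hold out whole drugs (or targets): shuffled entities are assigned to
test, then validation, until each fraction's pair budget is met, so
held-out entities provably never occur in a training pair. AUROC is
rank-based (ties half-weighted), AUPR is average precision, accuracy uses a
0.5 threshold; all three are computed by scikit-learn behind the package's
metric functions, with a brute-force pairwise oracle cross-checking AUROC
in the tests. Validation-based early stopping is available but off by
default; determinism is preferred.

## Numerical and degenerate-input choices

* Thresholding is inclusive everywhere (≥ keeps the edge).
* Isolated nodes are handled by the self-loop added during normalization;
  no degree is ever zero.
* An empty augmented graph (ρ = 1) is legal: encoding falls back to
  self-loops only.
* Feature-based pair adjacency symmetrizes after quantile comparison to
  guard against ties.
* Divergence (non-finite joint loss) aborts training with the epoch and
  both loss terms in the message.
* All randomness flows from explicit integer seeds through named
  `SeedSequence` streams; repeated runs are bit-identical on one machine.

## Known limitations

* The upstream encoders adapt through small per-source maps; with
  `train_embeddings=True` the embedding tables can be trained end-to-end,
  but at small sample sizes this trades planted-structure recovery for
  label memorization.
* The feature-based pair-adjacency ablation fixes its structure from the
  initial features rather than rebuilding it as features evolve.
* Multi-head attention is supported in the pair encoder (averaged heads)
  but the differentiable fusion stage is single-head.
* The pair graph is dense in memory (N² adjacency); at the intended desk
  scale (N ≲ a few thousand pairs) this is comfortable, but much larger
  corpora would need a sparse pair-graph build.
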