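# dtifuse

Drug–target interaction (DTI) prediction from heterogeneous biological
networks, for computational drug-discovery researchers who want a tested,
desk-scale implementation of pair-graph classification with multi-source
fusion and invariance-regularized contrastive training.

## The method

Identifying which drugs bind which protein targets is a bottleneck of drug
repurposing. Beyond the known interaction matrix itself, public resources
describe drugs and targets through many auxiliary relations — drug–disease
and drug–side-effect associations, chemical-structure similarity, protein
sequence similarity, target–disease links, and free-text drug descriptions.
`dtifuse` fuses these sources and casts interaction prediction as node
classification on a graph of candidate drug–target pairs:

1. **Source encoding.** Each bipartite network *M* is projected onto one
   entity class by the shared-neighbor product *S = M Mᵀ*, thresholded into
   a binary same-class graph (edge iff *S(u,v) ≥ k_sim*), and encoded by a
   symmetric-normalized graph convolution
   *Z = σ( D^(-1/2)(A+I)D^(-1/2) · E · W )* into one embedding per entity.
   Weighted similarity networks are thresholded directly; a precomputed
   per-drug text-embedding matrix enters through a linear map.
2. **Graph-generated fusion.** For each entity, its *p* source embeddings
   *z ∈ R^(p×d)* define a source–source product *Q = z zᵀ*; thresholding
   *Q* at a learnable *k* (straight-through relaxation) generates a small
   graph over the information sources, a shared graph-attention layer with
   coefficients *α_ij = softmax_i( LeakyReLU( a[Wz_i ‖ Wz_j] ) )* mixes the
   sources along its edges, and mean pooling yields the fused embedding
   *H_D ∈ R^(n×d')*, *H_T ∈ R^(m×d')*.
3. **Drug–target-pair (DTP) graph.** Every known interaction plus sampled
   non-interactions becomes a node with feature *[H_D(d) ‖ H_T(t)]*; two
   pair nodes are adjacent when they share the drug or the target.
4. **Invariance-regularized training.** Each epoch draws two stochastic
   views of the pair graph (random edge removal and feature-dimension
   masking at rate ρ), encodes both and the original graph with one shared
   two-layer graph-attention encoder, and minimizes

   L = L_CE + L_CL,  with
   L_CL = −α Σᵢ X̃₁ᵢ·X̃₂ᵢ + β Σᵢ ( ‖s₁ᵢ−λ‖² + ‖s₂ᵢ−λ‖² ),

   where X̃ are column-normalized view encodings and sᵢ the per-dimension
   standard deviations. The alignment term keeps representation directions
   stable under perturbation — suppressing perturbation-sensitive,
   non-causal signal — while the spread term holds each dimension's
   variance near the target λ; L_CE is the (summed) cross-entropy of a
   logistic classifier on the unaugmented encoding.

Training is implemented on a compact in-package reverse-mode autodiff
engine over numpy/scipy, with gradient correctness guarded by
finite-difference tests.

A synthetic benchmark generator plants shared Gaussian latent factors
beneath all networks — interactions are Bernoulli in the latent inner
product, with density calibrated by bisection — so every stage is testable
offline, with the latent inner product as an oracle ceiling and a
degree-product popularity baseline as the floor.

## Worked example

```python
from dtifuse.experiment import ExperimentConfig, run_experiment

out = run_experiment(ExperimentConfig(seed=1))
r = out["report"]
print(f"auroc={r.auroc:.4f} aupr={r.aupr:.4f} acc={r.acc:.4f}")
print(f"degree baseline={out['degree_baseline_auroc']:.4f} "
      f"oracle={out['oracle_auroc']:.4f}")
```

prints

```
auroc=0.8509 aupr=0.8110 acc=0.8182
degree baseline=0.6054 oracle=0.9343
```

This generates the default synthetic benchmark (60 drugs × 80 targets,
latent dimension 8, interaction density 0.08), builds a 770-node pair graph
(1:1 negative sampling), trains for 300 epochs, and evaluates on the 10 %
held-out pairs. The model's AUROC of 0.85 sits where it should: well above
the structure-free degree-product baseline (0.61) and below the planted
latent oracle (0.93), i.e. the pipeline recovers most — not all — of the
planted interaction signal.

The same pipeline is scriptable from the shell:

```bash
dtifuse generate --seed 3 --out data/          # write the file layout
dtifuse train --config cfg.yaml --seed 3 --out run/
dtifuse ablate --config cfg.yaml --seed 3 --variant no_causal --out run_nc/
dtifuse coldstart --config cfg.yaml --seed 3 --mode cold_drug --out run_cold/
```

Each run writes `metrics.json`, a per-epoch `history.tsv` (L_CE, L_CL,
validation AUROC), a parameter checkpoint, and the pair graph as node/edge
tables.

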