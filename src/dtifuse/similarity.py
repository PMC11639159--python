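"""One-mode projection, thresholding, and per-source graph-conv encoding.

Each auxiliary bipartite network (e.g. drug-disease) is projected onto its
row class by the shared-neighbor product S = M M^T, thresholded into a
binary same-class adjacency, and encoded by a single symmetric-normalized
graph convolution into one d-dimensional embedding per entity.  Weighted
similarity networks (chemical, sequence) skip the projection and are
thresholded directly.  The per-drug text-embedding matrix, when present,
enters as its own source through a seeded linear map to dimension d.

The threshold k_sim is realized either as a fixed value, as a quantile of
the off-diagonal similarity values (default 0.9), or - in contexts where
gradients flow - as a straight-through relaxed gate
(:func:`dtifuse.autodiff.straight_through_ge`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    BinaryAdjacency,
    BipartiteNetwork,
    ConfigurationError,
    HeteroDataset,
    MultiSourceTensor,
    SimilarityNetwork,
    ValidationError,
)

_ACTIVATIONS = {
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
    "tanh": np.tanh,
}


@dataclass
class SourceEncoderParams:
    """Parameters of one source encoder: initial embeddings, linear map, threshold."""

    E: np.ndarray
    W: np.ndarray
    activation: str = "relu"
    k_sim: float = 0.0

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=np.float64)
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.E.ndim != 2 or self.W.ndim != 2 or self.W.shape[0] != self.E.shape[1]:
            raise ValidationError("E (n x d) and W (d x d') shapes are inconsistent")
        if not (np.isfinite(self.E).all() and np.isfinite(self.W).all()):
            raise ValidationError("encoder parameters contain non-finite entries")
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")


def project_homology(B: BipartiteNetwork) -> SimilarityNetwork:
    """One-mode projection S = M M^T counting shared column neighbors.

    S[u, v] is the number of column entities linked to both row u and row v;
    the diagonal carries row degrees.
    """
    M = B.M.astype(np.int64)
    S = M @ M.T
    return SimilarityNetwork(B.row_index, S.astype(np.float64))


def binarize(S: SimilarityNetwork, k_sim: float) -> BinaryAdjacency:
    """Threshold a similarity network: edge iff similarity >= k_sim.

    The diagonal (self-similarity, i.e. degree) is zeroed; self-loops are
    re-added once inside the encoder's normalization so entities are never
    double self-weighted.
    """
    A = (S.S >= k_sim).astype(np.int8)
    np.fill_diagonal(A, 0)
    return BinaryAdjacency(S.index, A, float(k_sim))


def quantile_threshold(S: SimilarityNetwork, q: float = 0.9) -> float:
    """k_sim as the q-quantile of off-diagonal similarity values."""
    n = S.S.shape[0]
    off = S.S[~np.eye(n, dtype=bool)]
    if off.size == 0:
        return 0.0
    return float(np.quantile(off, q))


def spectral_embedding(S: np.ndarray, d: int) -> np.ndarray:
    """Top-d spectral factors of a symmetric similarity matrix.

    Columns are eigenvectors scaled by sqrt of the (clipped-nonnegative)
    eigenvalues, so X X^T approximates S; zero-padded if rank < d.  Used as
    fixed structure-derived initial entity embeddings.
    """
    Sym = (np.asarray(S, dtype=np.float64) + np.asarray(S).T) / 2.0
    w, Q = np.linalg.eigh(Sym)
    idx = np.argsort(w)[::-1][:d]
    w = np.clip(w[idx], 0.0, None)
    X = Q[:, idx] * np.sqrt(w)[None, :]
    if X.shape[1] < d:
        X = np.pad(X, ((0, 0), (0, d - X.shape[1])))
    return X


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^(-1/2) (A + I) D^(-1/2)."""
    A_hat = np.asarray(A, dtype=np.float64) + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)  # self-loop guarantees d >= 1
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


def encode_source(A: BinaryAdjacency, params: SourceEncoderParams) -> np.ndarray:
    """One symmetric-normalized graph convolution:
    Z = act( D^(-1/2)(A+I)D^(-1/2) . E . W ).
    """
    n = A.index.size
    if params.E.shape[0] != n:
        raise ValidationError(
            f"E has {params.E.shape[0]} rows, adjacency has {n} nodes"
        )
    act = _ACTIVATIONS[params.activation]
    Z = act(normalized_adjacency(A.A) @ params.E @ params.W)
    if not np.isfinite(Z).all():
        raise ValidationError("encoded source contains non-finite entries")
    return Z


@dataclass
class SourceSpec:
    """One configured information source.

    kind:
      * ``bipartite``  - project M M^T then threshold and encode
      * ``similarity`` - threshold the given similarity matrix and encode
      * ``text``       - linear map of the dataset's text-embedding matrix
    ``k_sim_quantile`` selects the threshold as a quantile of off-diagonal
    similarities unless an explicit ``k_sim`` is given.
    """

    name: str
    kind: str
    network: str | None = None
    k_sim: float | None = None
    k_sim_quantile: float = 0.9

    def __post_init__(self):
        if self.kind not in ("bipartite", "similarity", "text"):
            raise ConfigurationError(f"unknown source kind {self.kind!r}")
        if self.kind != "text" and self.network is None:
            raise ConfigurationError(f"source {self.name!r} needs a network name")


@dataclass
class MultiSourceConfig:
    """Per-class source inventory plus shared encoding hyperparameters.

    ``neighbor_weight`` is the lazy-propagation coefficient of the
    differentiable source encoders: z = (1-w) E W + w (A_hat E W).  At 1.0
    this is exactly the plain normalized graph convolution; the smaller
    default keeps each entity's own embedding dominant so that individual
    latent structure survives the neighborhood smoothing.

    ``structure_network`` entries name the similarity network whose spectral
    factors initialize each class's entity-embedding table.
    """

    drug_sources: list[SourceSpec]
    target_sources: list[SourceSpec]
    d: int = 8
    activation: str = "identity"
    neighbor_weight: float = 0.25
    drug_structure_network: str = "drug_chemical_sim"
    target_structure_network: str = "target_seq_sim"
    seed: int = 0


def _source_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-source stream, independent of source ordering."""
    h = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, h]))


def _shared_initial_embedding(seed: int, tag: str, n: int, d: int) -> np.ndarray:
    rng = _source_rng(seed, f"E:{tag}")
    return rng.normal(0.0, 1.0 / np.sqrt(d), size=(n, d))


def resolve_source(dataset: HeteroDataset, spec: SourceSpec) -> tuple[str, np.ndarray]:
    """Resolve one source spec into its constant structure.

    Returns ``("text", matrix)`` for the text source, otherwise
    ``("graph", A_hat)`` where A_hat is the symmetric-normalized adjacency
    (self-loops included) of the thresholded similarity graph.
    """
    if spec.kind == "text":
        if dataset.text_embeddings is None:
            raise ConfigurationError(
                f"source {spec.name!r} requires text embeddings, dataset has none"
            )
        return "text", dataset.text_embeddings

    if spec.network not in dataset.networks:
        raise ConfigurationError(
            f"source {spec.name!r} references network {spec.network!r} "
            f"absent from the dataset"
        )
    net = dataset.networks[spec.network]
    if spec.kind == "bipartite":
        if not isinstance(net, BipartiteNetwork):
            raise ConfigurationError(f"network {spec.network!r} is not bipartite")
        S = project_homology(net)
    else:
        if not isinstance(net, SimilarityNetwork):
            raise ConfigurationError(f"network {spec.network!r} is not a similarity network")
        S = net
    k = spec.k_sim if spec.k_sim is not None else quantile_threshold(S, spec.k_sim_quantile)
    return "graph", normalized_adjacency(binarize(S, k).A)


def _encode_one(dataset: HeteroDataset, spec: SourceSpec, E: np.ndarray,
                d: int, activation: str, seed: int) -> np.ndarray:
    kind, struct = resolve_source(dataset, spec)
    if kind == "text":
        rng = _source_rng(seed, f"W:{spec.name}")
        d_text = struct.shape[1]
        W_text = rng.normal(0.0, 1.0 / np.sqrt(d_text), size=(d_text, d))
        return struct @ W_text
    rng = np.random.default_rng(_source_rng(seed, f"W:{spec.name}").integers(2**31))
    W = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, d))
    act = _ACTIVATIONS[activation]
    Z = act(struct @ E @ W)
    if not np.isfinite(Z).all():
        raise ValidationError("encoded source contains non-finite entries")
    return Z


def build_multisource(dataset: HeteroDataset, config: MultiSourceConfig
                      ) -> tuple[MultiSourceTensor, MultiSourceTensor]:
    """Stack one embedding per configured source into (entities, sources, d).

    The initial embedding E is shared per entity class across its sources
    (one lookup table per class); each source has its own linear map W and
    threshold, all drawn from seeded per-source streams so that excluding
    one source never perturbs the others.
    """
    d = config.d
    E_drug = _shared_initial_embedding(config.seed, "drug", dataset.n_drugs, d)
    E_target = _shared_initial_embedding(config.seed, "target", dataset.n_targets, d)

    def stack(specs: list[SourceSpec], E: np.ndarray, index) -> MultiSourceTensor:
        if not specs:
            raise ConfigurationError("at least one source per entity class is required")
        slices = [
            _encode_one(dataset, s, E, d, config.activation, config.seed) for s in specs
        ]
        Z = np.stack(slices, axis=1)
        return MultiSourceTensor(index, tuple(s.name for s in specs), Z)

    return (
        stack(config.drug_sources, E_drug, dataset.drugs),
        stack(config.target_sources, E_target, dataset.targets),
    )


def default_source_config(dataset: HeteroDataset, d: int = 8, seed: int = 0,
                          include_text: bool = True) -> MultiSourceConfig:
    """Source inventory mirroring the standard heterogeneous DTI setup:
    drug-disease, drug-side-effect, drug interaction, chemical similarity
    (+ text) for drugs; target-disease, target interaction, sequence
    similarity for targets.  Sources whose networks the dataset lacks are
    skipped silently only if optional (text); named networks must exist.
    """
    drug_sources = [
        SourceSpec("drug_disease", "bipartite", "drug_disease"),
        SourceSpec("drug_side_effect", "bipartite", "drug_side_effect"),
        SourceSpec("drug_interaction", "similarity", "drug_interaction"),
        SourceSpec("drug_chemical", "similarity", "drug_chemical_sim"),
    ]
    if include_text and dataset.text_embeddings is not None:
        drug_sources.append(SourceSpec("text", "text"))
    target_sources = [
        SourceSpec("target_disease", "bipartite", "target_disease"),
        SourceSpec("target_interaction", "similarity", "target_interaction"),
        SourceSpec("target_sequence", "similarity", "target_seq_sim"),
    ]
    return MultiSourceConfig(drug_sources, target_sources, d=d, seed=seed)
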