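"""Per-entity source-graph generation and attention-based fusion.

For each entity, its p source embeddings z in R^(p x d) define a
source-source product Q = z z^T; thresholding Q at k yields a small
generated graph over the information sources.  A graph-attention layer with
a shared parameter set then mixes the sources along the generated edges,
and mean pooling over the p source rows gives the entity's fused embedding.
One parameter set is shared by all drugs and a second by all targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ConfigurationError, MultiSourceTensor, ValidationError


@dataclass
class GeneratedSourceGraph:
    """Generated graph over one entity's information sources."""

    entity_id: str
    Q: np.ndarray
    G: np.ndarray
    k: float

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=np.float64)
        self.G = np.asarray(self.G)
        if not np.allclose(self.Q, self.Q.T):
            raise ValidationError("source product Q must be symmetric")
        if not np.isin(self.G, (0, 1)).all() or not np.array_equal(self.G, self.G.T):
            raise ValidationError("generated graph must be binary and symmetric")


@dataclass
class AttentionParams:
    """Shared graph-attention parameters: W (d x d'), a (2d') per head."""

    W: np.ndarray
    a: np.ndarray
    negative_slope: float = 0.2
    heads: int = 1

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.heads < 1:
            raise ValidationError("heads must be >= 1")
        # Per-head parameters are stacked along a leading axis when heads > 1.
        if self.heads == 1 and self.W.ndim == 2:
            self.W = self.W[None]
            self.a = self.a[None]
        if self.W.ndim != 3 or self.W.shape[0] != self.heads:
            raise ValidationError("W must have shape (heads, d, d')")
        if self.a.shape != (self.heads, 2 * self.W.shape[2]):
            raise ValidationError("a must have shape (heads, 2d')")
        if not (np.isfinite(self.W).all() and np.isfinite(self.a).all()):
            raise ValidationError("attention parameters contain non-finite entries")

    @property
    def d_out(self) -> int:
        return self.W.shape[2]

    @classmethod
    def init(cls, d: int, d_out: int, rng: np.random.Generator,
             negative_slope: float = 0.2, heads: int = 1) -> "AttentionParams":
        W = rng.normal(0.0, 1.0 / np.sqrt(d), size=(heads, d, d_out))
        a = rng.normal(0.0, 1.0 / np.sqrt(2 * d_out), size=(heads, 2 * d_out))
        return cls(W, a, negative_slope, heads)


def source_product(z_i: np.ndarray) -> np.ndarray:
    """Q = z z^T over one entity's source embeddings; Q[u,u] = ||z_u||^2."""
    z_i = np.asarray(z_i, dtype=np.float64)
    if not np.isfinite(z_i).all():
        raise ValidationError("source embeddings contain non-finite entries")
    return z_i @ z_i.T


def generate_graph(Q: np.ndarray, k: float, entity_id: str = "",
                   mode: str = "hard", tau: float = 1.0,
                   self_loops: bool = True) -> GeneratedSourceGraph:
    """Threshold Q at k: edge iff Q[u,v] >= k (inclusive).

    ``relaxed`` mode emits the same hard graph in the forward pass; its
    gradient surrogate sigmoid((Q-k)/tau) lives in
    :func:`dtifuse.autodiff.straight_through_ge` for training contexts.
    Self-loops are forced on so every source has a nonempty neighborhood.
    """
    if mode not in ("hard", "relaxed"):
        raise ConfigurationError(f"unknown threshold mode {mode!r}")
    if mode == "relaxed" and tau <= 0:
        raise ConfigurationError("tau must be positive in relaxed mode")
    Q = np.asarray(Q, dtype=np.float64)
    G = (Q >= k).astype(np.int8)
    if self_loops:
        np.fill_diagonal(G, 1)
    return GeneratedSourceGraph(entity_id, Q, G, float(k))


def attention_coefficients(G: np.ndarray, z: np.ndarray,
                           params: AttentionParams) -> np.ndarray:
    """Masked softmax attention over the generated graph's edges.

    Returns alpha of shape (heads, p, p) squeezed to (p, p) for one head;
    alpha[i, j] = 0 wherever G[i, j] = 0, and each row sums to 1 over the
    permitted neighbors (self-loops included).
    """
    G = np.asarray(G)
    z = np.asarray(z, dtype=np.float64)
    p = z.shape[0]
    if G.shape != (p, p):
        raise ValidationError(f"graph shape {G.shape} != ({p}, {p})")
    d_out = params.d_out
    Wz = np.einsum("hde,pd->hpe", params.W, z)  # (heads, p, d')
    e_src = np.einsum("hpe,he->hp", Wz, params.a[:, :d_out])
    e_dst = np.einsum("hpe,he->hp", Wz, params.a[:, d_out:])
    e = e_src[:, :, None] + e_dst[:, None, :]
    e = np.where(e > 0, e, params.negative_slope * e)
    mask = G.astype(bool)[None]
    e = np.where(mask, e, -np.inf)
    e = e - e.max(axis=2, keepdims=True)
    ex = np.where(mask, np.exp(e), 0.0)
    alpha = ex / ex.sum(axis=2, keepdims=True)
    return alpha[0] if params.heads == 1 else alpha


def fuse_entity(g: GeneratedSourceGraph, z_i: np.ndarray,
                params: AttentionParams) -> np.ndarray:
    """h_i[s] = sum_j alpha[s, j] (W z_j); heads are averaged."""
    alpha = attention_coefficients(g.G, z_i, params)
    Wz = np.einsum("hde,pd->hpe", params.W, np.asarray(z_i, dtype=np.float64))
    if params.heads == 1:
        return alpha @ Wz[0]
    h = np.einsum("hpq,hqe->hpe", alpha, Wz)
    return h.mean(axis=0)


def mean_pool(h: np.ndarray) -> np.ndarray:
    """Unweighted mean over the source axis."""
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValidationError("expected a (p, d') matrix with p >= 1")
    return h.mean(axis=0)


@dataclass
class FusedEmbeddings:
    H_D: np.ndarray
    H_T: np.ndarray

    def __post_init__(self):
        self.H_D = np.asarray(self.H_D, dtype=np.float64)
        self.H_T = np.asarray(self.H_T, dtype=np.float64)
        if not (np.isfinite(self.H_D).all() and np.isfinite(self.H_T).all()):
            raise ValidationError("fused embeddings contain non-finite entries")


@dataclass
class FusionConfig:
    d_out: int = 8
    heads: int = 1
    k_mode: str = "median"  # median | fixed | quantile
    k_value: float = 0.0
    k_quantile: float = 0.5
    tau: float = 1.0
    negative_slope: float = 0.2
    seed: int = 0


def _resolve_k(Q_all: np.ndarray, cfg: FusionConfig) -> float:
    """Shared threshold k over all entities' off-diagonal Q values.

    ``median`` (default) mirrors initializing a learnable k at the median of
    off-diagonal products, which guarantees a non-degenerate starting graph.
    """
    if cfg.k_mode == "fixed":
        return cfg.k_value
    p = Q_all.shape[1]
    off = Q_all[:, ~np.eye(p, dtype=bool)].ravel()
    if off.size == 0:
        return -np.inf
    if cfg.k_mode == "median":
        return float(np.median(off))
    if cfg.k_mode == "quantile":
        return float(np.quantile(off, cfg.k_quantile))
    raise ConfigurationError(f"unknown k mode {cfg.k_mode!r}")


def _fuse_class(Z: MultiSourceTensor, params: AttentionParams,
                cfg: FusionConfig) -> tuple[np.ndarray, list[GeneratedSourceGraph]]:
    n, p, _ = Z.Z.shape
    Q_all = np.einsum("npd,nqd->npq", Z.Z, Z.Z)
    k = _resolve_k(Q_all, cfg)
    graphs = []
    H = np.empty((n, params.d_out))
    for i in range(n):
        g = generate_graph(Q_all[i], k, entity_id=Z.index.ids[i], tau=cfg.tau)
        h = fuse_entity(g, Z.Z[i], params)
        H[i] = mean_pool(h)
        graphs.append(g)
    return H, graphs


def fuse_all(ZD: MultiSourceTensor, ZT: MultiSourceTensor, cfg: FusionConfig,
             return_graphs: bool = False):
    """source_product -> generate_graph -> attention fusion -> mean pooling,
    per entity; one parameter set shared across drugs, a second across
    targets."""
    d = ZD.Z.shape[2]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x66757365]))
    params_d = AttentionParams.init(d, cfg.d_out, rng, cfg.negative_slope, cfg.heads)
    params_t = AttentionParams.init(ZT.Z.shape[2], cfg.d_out, rng,
                                    cfg.negative_slope, cfg.heads)
    H_D, graphs_d = _fuse_class(ZD, params_d, cfg)
    H_T, graphs_t = _fuse_class(ZT, params_t, cfg)
    fused = FusedEmbeddings(H_D, H_T)
    if return_graphs:
        return fused, graphs_d, graphs_t
    return fused


def export_generated_graphs(graphs: list[GeneratedSourceGraph],
                            source_names: tuple[str, ...], path) -> None:
    """Per-entity source-graph edge list with Q weights, for inspection."""
    with open(path, "w") as fh:
        fh.write("entity\tsource_u\tsource_v\tQ\tedge\n")
        for g in graphs:
            p = g.Q.shape[0]
            for u in range(p):
                for v in range(u, p):
                    fh.write(
                        f"{g.entity_id}\t{source_names[u]}\t{source_names[v]}"
                        f"\t{g.Q[u, v]:.6g}\t{int(g.G[u, v])}\n"
                    )
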