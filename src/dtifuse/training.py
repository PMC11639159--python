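"""Invariance-regularized contrastive training on the drug-target-pair graph.

Each epoch draws two stochastic views of the pair graph (independent edge
removal and feature-dimension masking at rate rho), encodes both views and
the original graph with one shared two-layer graph-attention encoder, and
steps a joint objective

    L = L_CE + L_CL,
    L_CL = -alpha * sum_i  X~1_i . X~2_i
           + beta * sum_i (||s1_i - lambda||^2 + ||s2_i - lambda||^2),

where X~ are the column-normalized view encodings and s_i the per-dimension
(population) standard deviations before normalization.  The alignment term
pulls the two views' per-dimension directions together; the spread term
keeps each dimension's standard deviation near the target lambda, so signal
that survives random perturbation (the invariant, "causal" part) dominates
the learned representation.  Classification cross-entropy is computed on
the original, unaugmented graph encoding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .data_model import ValidationError
from .dtp import DTPGraph
from .metrics import auroc


class TrainingDivergedError(RuntimeError):
    """The joint loss became non-finite."""


# ---------------------------------------------------------------------------
# Augmentation


@dataclass
class AugmentedView:
    """A perturbed copy of the pair graph: edge subset + masked feature dims."""

    A_aug: np.ndarray
    H_aug: np.ndarray
    edge_mask: np.ndarray  # retained-edge indicator over the upper-tri edge list
    feat_mask: np.ndarray  # retained-dimension indicator
    rho: float

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("perturbation rate rho must lie in [0, 1]")


def augment(A: np.ndarray, H: np.ndarray, rho: float,
            rng: np.random.Generator) -> AugmentedView:
    """Independently remove each undirected edge and zero each feature
    dimension (column) with probability rho."""
    if not 0.0 <= rho <= 1.0:
        raise ValidationError("perturbation rate rho must lie in [0, 1]")
    iu, ju = np.nonzero(np.triu(A, 1))
    keep_edges = rng.random(iu.size) >= rho
    A_aug = np.zeros_like(np.asarray(A))
    A_aug[iu[keep_edges], ju[keep_edges]] = 1
    A_aug = A_aug + A_aug.T
    keep_dims = rng.random(H.shape[1]) >= rho
    H_aug = np.asarray(H, dtype=np.float64) * keep_dims[None, :]
    return AugmentedView(A_aug, H_aug, keep_edges, keep_dims, float(rho))


def augment_graph(graph: DTPGraph, rho: float, seed: int) -> AugmentedView:
    return augment(graph.A, graph.H, rho, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Graph-attention encoder (sparse edge representation)


@dataclass
class EdgeStructure:
    """COO edges including self-loops plus the dst-incidence matrix S (N x E)."""

    src: np.ndarray
    dst: np.ndarray
    S_dst: sp.csr_matrix
    n_nodes: int


def edge_structure(A: np.ndarray) -> EdgeStructure:
    n = A.shape[0]
    r, c = np.nonzero(A)
    src = np.concatenate([r, np.arange(n)])
    dst = np.concatenate([c, np.arange(n)])
    e = src.size
    S = sp.csr_matrix((np.ones(e), (dst, np.arange(e))), shape=(n, e))
    return EdgeStructure(src, dst, S, n)


class GATLayer:
    """One graph-attention layer; multi-head outputs are averaged.

    A learned linear residual (W_skip) is added to the attention aggregate:
    neighborhood attention spreads a node's own features over its (possibly
    many) neighbors, and for pair classification the node's own features
    carry the decisive signal, so each layer keeps an explicit skip path.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 heads: int = 1, negative_slope: float = 0.2,
                 residual: bool = True):
        self.heads = heads
        self.negative_slope = negative_slope
        self.W = [ad.parameter((d_in, d_out), rng) for _ in range(heads)]
        self.a_src = [ad.parameter((d_out, 1), rng) for _ in range(heads)]
        self.a_dst = [ad.parameter((d_out, 1), rng) for _ in range(heads)]
        self.W_skip = ad.parameter((d_in, d_out), rng) if residual else None
        self.last_row_dev = 0.0  # max |row-sum(alpha) - 1| of the last forward

    @property
    def params(self) -> list[Tensor]:
        skip = [self.W_skip] if self.W_skip is not None else []
        return self.W + self.a_src + self.a_dst + skip

    def __call__(self, struct: EdgeStructure, H: Tensor,
                 drop_rng: np.random.Generator | None = None,
                 p_drop: float = 0.0) -> Tensor:
        outs = []
        devs = []
        for h in range(self.heads):
            HW = H @ self.W[h]
            # per-edge attention logits from per-node score halves (E x 1)
            s_src = HW @ self.a_src[h]
            s_dst = HW @ self.a_dst[h]
            e = ad.leaky_relu(
                ad.take_rows(s_src, struct.src) + ad.take_rows(s_dst, struct.dst),
                self.negative_slope,
            )
            # numerically stable segment softmax over incoming edges per node
            mx = np.full(struct.n_nodes, -np.inf)
            np.maximum.at(mx, struct.dst, e.data[:, 0])
            ex = ad.exp(e - mx[struct.dst, None])
            denom = ad.spmm(struct.S_dst, ex)
            alpha = ex * ad.take_rows(denom, struct.dst) ** -1.0
            row_sums = struct.S_dst @ alpha.data
            devs.append(float(np.abs(row_sums - 1.0).max()))
            if drop_rng is not None and p_drop > 0.0:
                keep = (drop_rng.random(alpha.shape) >= p_drop) / (1.0 - p_drop)
                alpha = alpha * keep  # attention dropout, after normalization
            outs.append(ad.weighted_spmm(alpha, struct.src, struct.dst,
                                         struct.n_nodes, HW))
        self.last_row_dev = max(devs)
        out = outs[0]
        for o in outs[1:]:
            out = out + o
        if self.heads > 1:
            out = out * (1.0 / self.heads)
        if self.W_skip is not None:
            out = out + H @ self.W_skip
        return out


class DTPAttentionEncoder:
    """Two stacked graph-attention layers with ELU in between; one shared
    parameter set encodes both augmented views and the original graph."""

    def __init__(self, d_in: int, hidden: int, d_out: int,
                 rng: np.random.Generator, heads: int = 1,
                 negative_slope: float = 0.2):
        self.layers = [
            GATLayer(d_in, hidden, rng, heads, negative_slope),
            GATLayer(hidden, d_out, rng, heads, negative_slope),
        ]
        self.attention_row_dev = 0.0  # worst deviation seen over all forwards

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]

    def __call__(self, struct: EdgeStructure, H: Tensor,
                 drop_rng: np.random.Generator | None = None,
                 p_drop: float = 0.0) -> Tensor:
        x = ad.elu(self.layers[0](struct, H, drop_rng, p_drop))
        x = self.layers[1](struct, x, drop_rng, p_drop)
        self.attention_row_dev = max(
            self.attention_row_dev, *(l.last_row_dev for l in self.layers)
        )
        return x


def encode_view(A: np.ndarray, H, encoder: DTPAttentionEncoder,
                drop_rng: np.random.Generator | None = None,
                p_drop: float = 0.0) -> Tensor:
    """Encode one (adjacency, features) view with the shared encoder."""
    return encoder(edge_structure(A), ad.tensor(H), drop_rng, p_drop)


# ---------------------------------------------------------------------------
# End-to-end differentiable pipeline upstream of the pair encoder


def fuse_batch(Z: Tensor, W_att: Tensor, a_src: Tensor, a_dst: Tensor,
               k: Tensor, tau: float, negative_slope: float
               ) -> tuple[Tensor, float]:
    """Differentiable per-entity source-graph generation + attention fusion.

    Z is (entities, p, d).  Q = z z^T is gated at the learnable threshold k
    through a straight-through relaxation, self-loops forced on, and a
    shared single-head attention mixes the transformed sources along the
    generated edges; mean pooling over the p source rows gives one
    embedding per entity.  Returns (H, max attention row-sum deviation).
    """
    p = Z.shape[1]
    eye = np.eye(p)
    Q = ad.bmm(Z, ad.swapaxes(Z, 1, 2))
    G = ad.straight_through_ge(Q, k, tau)
    G = G * (1.0 - eye) + eye  # self-loops forced on
    Wz = ad.bmm(Z, W_att)
    s1 = ad.bmm(Wz, a_src)
    s2 = ad.bmm(Wz, a_dst)
    e = ad.leaky_relu(s1 + ad.swapaxes(s2, 1, 2), negative_slope)
    c = e.data.max(axis=2, keepdims=True)
    ex = ad.exp(e - c) * G
    alpha = ex * ex.sum(axis=2, keepdims=True) ** -1.0
    dev = float(np.abs(alpha.data.sum(axis=2) - 1.0).max())
    h = ad.bmm(alpha, Wz)
    return h.mean(axis=1), dev


class MultiSourcePairModel:
    """Differentiable upstream pipeline: per-source graph convolutions over
    fixed thresholded similarity graphs, learnable-threshold source-graph
    fusion, and pair-feature concatenation.

    The graph structures (thresholded source adjacencies, the text matrix,
    the pair index lists) and the entity-embedding tables E are constants;
    E defaults to the spectral factors of each class's structure similarity
    network (chemical for drugs, sequence for targets), falling back to a
    seeded Gaussian table when that network is absent.  The per-source
    linear maps start at identity and the fusion map at a (padded) identity
    with small attention vectors, so every source initially presents its
    structural embedding unchanged and training only has to reweight and
    refine.  The per-source maps, fusion attention, fusion thresholds, and
    everything downstream train jointly.
    """

    def __init__(self, dataset, ms_cfg, fusion_cfg, nodes, seed: int,
                 embedding_init: str = "spectral",
                 train_embeddings: bool = False):
        from .similarity import resolve_source, spectral_embedding

        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D6F6465]))
        d = ms_cfg.d
        self.tau = fusion_cfg.tau
        self.negative_slope = fusion_cfg.negative_slope
        self.d_fused = fusion_cfg.d_out
        self.neighbor_weight = ms_cfg.neighbor_weight
        self.activation = ms_cfg.activation
        if self.activation not in ("identity", "relu"):
            raise ValidationError(
                f"model activation must be identity or relu, got {self.activation!r}"
            )
        self.fusion_row_dev = 0.0

        def embedding_table(n: int, structure_name: str) -> Tensor:
            net = dataset.networks.get(structure_name)
            if embedding_init == "spectral" and net is not None:
                E = Tensor(spectral_embedding(net.S, d),
                           requires_grad=train_embeddings)
            else:
                E = ad.parameter((n, d), rng, scale=1.0 / np.sqrt(d))
                E.requires_grad = train_embeddings
            return E

        def build_class(specs, n, structure_name):
            E = embedding_table(n, structure_name)
            sources = []
            for s in specs:
                kind, struct = resolve_source(dataset, s)
                if kind == "text":
                    # least-squares alignment of the text matrix onto the
                    # embedding table, so the text source starts coherent
                    # with the structural sources instead of randomly rotated
                    W0, *_ = np.linalg.lstsq(struct, E.data, rcond=None)
                    W = Tensor(W0, requires_grad=True)
                else:
                    W = Tensor(np.eye(d), requires_grad=True)
                sources.append((kind, struct, W))
            W_att = Tensor(np.eye(d, fusion_cfg.d_out), requires_grad=True)
            a_src = ad.parameter((fusion_cfg.d_out, 1), rng,
                                 scale=0.1 / np.sqrt(fusion_cfg.d_out))
            a_dst = ad.parameter((fusion_cfg.d_out, 1), rng,
                                 scale=0.1 / np.sqrt(fusion_cfg.d_out))
            k = Tensor(np.zeros((1, 1)), requires_grad=True)
            return {"E": E, "sources": sources, "W_att": W_att,
                    "a_src": a_src, "a_dst": a_dst, "k": k}

        self.drug = build_class(ms_cfg.drug_sources, dataset.n_drugs,
                                ms_cfg.drug_structure_network)
        self.target = build_class(ms_cfg.target_sources, dataset.n_targets,
                                  ms_cfg.target_structure_network)
        self.d_idx = np.array([nd.drug_idx for nd in nodes])
        self.t_idx = np.array([nd.target_idx for nd in nodes])
        # initialize each threshold at the median off-diagonal source product
        for side in (self.drug, self.target):
            Z = self._encode_sources(side)
            Q = np.matmul(Z.data, Z.data.swapaxes(1, 2))
            p = Q.shape[1]
            off = Q[:, ~np.eye(p, dtype=bool)]
            side["k"].data[:] = np.median(off) if off.size else 0.0

    @property
    def params(self) -> list[Tensor]:
        out = []
        for side in (self.drug, self.target):
            if side["E"].requires_grad:
                out.append(side["E"])
            out.extend(W for _, _, W in side["sources"])
            out.extend([side["W_att"], side["a_src"], side["a_dst"], side["k"]])
        return out

    def _encode_sources(self, side) -> Tensor:
        E = side["E"]
        w = self.neighbor_weight
        slices = []
        for kind, struct, W in side["sources"]:
            if kind == "text":
                z = Tensor(struct) @ W
            else:
                EW = E @ W
                z = EW * (1.0 - w) + (Tensor(struct) @ EW) * w
                if self.activation == "relu":
                    z = ad.relu(z)
            n, d = z.shape
            slices.append(z.reshape(n, 1, d))
        return ad.concat(slices, axis=1)

    def _fuse_class(self, side) -> Tensor:
        Z = self._encode_sources(side)
        H, dev = fuse_batch(Z, side["W_att"], side["a_src"], side["a_dst"],
                            side["k"], self.tau, self.negative_slope)
        self.fusion_row_dev = max(self.fusion_row_dev, dev)
        return H

    def entity_embeddings(self) -> tuple[Tensor, Tensor]:
        return self._fuse_class(self.drug), self._fuse_class(self.target)

    def pair_features(self) -> Tensor:
        """Row i = [H_D[drug_i] || H_T[target_i]], shape (N, 2 d_fused)."""
        H_D, H_T = self.entity_embeddings()
        return ad.concat(
            [ad.take_rows(H_D, self.d_idx), ad.take_rows(H_T, self.t_idx)], axis=1
        )


# ---------------------------------------------------------------------------
# Losses


@dataclass
class CausalLossParams:
    alpha: float = 1.0
    beta: float = 1.0
    lam: float = 1.0
    eps: float = 1e-12

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be nonnegative")
        if self.lam <= 0 or self.eps <= 0:
            raise ValidationError("lambda and eps must be positive")


@dataclass
class LossReport:
    L_CE: float
    L_CL: float
    L: float
    alignment: float = float("nan")
    std_penalty: float = float("nan")


def normalize_dims(X: Tensor, eps: float = 1e-12) -> tuple[Tensor, Tensor]:
    """Column-wise: population std s_i, then center and L2-normalize so each
    column has unit norm (up to the eps floor for constant columns)."""
    X = ad.tensor(X)
    if X.shape[0] < 2:
        raise ValidationError("normalize_dims needs at least two rows")
    mu = X.mean(axis=0, keepdims=True)
    c = X - mu
    s = (c ** 2.0).mean(axis=0) ** 0.5
    norm = (c ** 2.0).sum(axis=0) ** 0.5 + eps
    return c * norm ** -1.0, s


def causal_loss(X1: Tensor, X2: Tensor,
                params: CausalLossParams) -> tuple[Tensor, dict]:
    """L_CL = -alpha sum_i X~1_i . X~2_i + beta sum_i (s1_i-lambda)^2+(s2_i-lambda)^2."""
    X1, X2 = ad.tensor(X1), ad.tensor(X2)
    if X1.shape != X2.shape:
        raise ValidationError(f"view shapes differ: {X1.shape} vs {X2.shape}")
    Xt1, s1 = normalize_dims(X1, params.eps)
    Xt2, s2 = normalize_dims(X2, params.eps)
    align = (Xt1 * Xt2).sum()
    pen = ((s1 - params.lam) ** 2.0).sum() + ((s2 - params.lam) ** 2.0).sum()
    loss = (-params.alpha) * align + params.beta * pen
    return loss, {"alignment": align.item(), "std_penalty": pen.item()}


def classify(X: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map + logistic squashing: pi(x) = sigma(x.w + b), in (0, 1)."""
    return ad.sigmoid(X @ w + b)


def bce_loss(pi: Tensor, y: np.ndarray, reduction: str = "sum",
             eps: float = 1e-12) -> Tensor:
    """Summed (or mean) binary cross-entropy; probabilities outside (0,1)
    are clamped to [eps, 1-eps] with a warning."""
    pi = ad.tensor(pi)
    y = np.asarray(y, dtype=np.float64).reshape(pi.shape)
    if ((pi.data <= eps) | (pi.data >= 1 - eps)).any():
        warnings.warn("probabilities clamped to the open unit interval", RuntimeWarning)
    p = ad.clip(pi, eps, 1.0 - eps)
    ll = Tensor(y) * ad.log(p) + Tensor(1.0 - y) * ad.log(1.0 - p)
    total = -ll.sum()
    if reduction == "mean":
        return total * (1.0 / y.size)
    if reduction != "sum":
        raise ValidationError(f"unknown reduction {reduction!r}")
    return total


# ---------------------------------------------------------------------------
# Training loop


@dataclass
class TrainConfig:
    alpha: float = 1.0
    beta: float = 1.0
    lam: float = 1.0
    rho: float = 0.3
    d_out: int = 64
    hidden: int = 64
    heads: int = 1
    negative_slope: float = 0.2
    lr: float = 1e-3
    lr_schedule: str = "constant"  # constant | cosine
    weight_decay: float = 0.0
    dropout: float = 0.6
    epochs: int = 300
    score_window: int = 1  # average predicted probabilities over the last k epochs
    reduction: str = "sum"
    standardize: bool = True
    eps: float = 1e-12


@dataclass
class TrainResult:
    scores: np.ndarray                 # final pi on the original graph, length N
    history: pd.DataFrame              # epoch, L_CE, L_CL, L, val_auroc
    encoder: DTPAttentionEncoder
    classifier: tuple[Tensor, Tensor]
    config: TrainConfig
    seed: int
    variant: str
    max_attention_row_dev: float
    feature_scale: tuple[np.ndarray, np.ndarray] | None

    def predict(self, A: np.ndarray, H: np.ndarray) -> np.ndarray:
        """Score arbitrary pair graphs with the trained parameters."""
        if self.feature_scale is not None:
            mu, sd = self.feature_scale
            H = (np.asarray(H, dtype=np.float64) - mu) / sd
        X = encode_view(A, H, self.encoder)
        w, b = self.classifier
        return classify(X, w, b).data[:, 0]


def _standardize(H: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = H.mean(axis=0)
    sd = H.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (H - mu) / sd, mu, sd


def train(graph: DTPGraph, train_idx: np.ndarray, config: TrainConfig,
          seed: int, val_idx: np.ndarray | None = None,
          variant: str = "full",
          model: MultiSourcePairModel | None = None) -> TrainResult:
    """Joint optimization of the contrastive and classification objectives.

    variants:
      * ``full``       - step on L = L_CE + L_CL (two fresh views per epoch)
      * ``no_causal``  - L_CL computed and logged but excluded from the step
      * ``supervised`` - plain supervised pair classification; no views built

    When ``model`` is given, the upstream source encoders and fusion stage
    train jointly with the pair encoder (pair features are recomputed each
    epoch); otherwise the graph's stored features are used as fixed inputs.

    Parameter initialization and augmentation draw from independent seeded
    streams, so a supervised run and a full run share identical initial
    parameters under the same seed.
    """
    if variant not in ("full", "no_causal", "supervised"):
        raise ValidationError(f"unknown training variant {variant!r}")
    train_idx = np.asarray(train_idx, dtype=np.int64)
    y = graph.labels.astype(np.float64)

    # independent streams: parameter init, view augmentation, dropout.
    # a supervised run never touches the augmentation stream, so it shares
    # initial parameters and dropout draws with a full run of the same seed.
    init_ss, aug_ss, drop_ss = np.random.SeedSequence(seed).spawn(3)
    init_rng = np.random.default_rng(init_ss)
    aug_rng = np.random.default_rng(aug_ss)
    drop_rng = np.random.default_rng(drop_ss)

    scale = None
    if model is None:
        if config.standardize:
            H0, mu, sd = _standardize(graph.H)
            scale = (mu, sd)
        else:
            H0 = np.asarray(graph.H, dtype=np.float64)
        d_in = H0.shape[1]
    else:
        d_in = 2 * model.d_fused

    encoder = DTPAttentionEncoder(d_in, config.hidden, config.d_out,
                                  init_rng, config.heads, config.negative_slope)
    w = ad.parameter((config.d_out, 1), init_rng)
    b = Tensor(np.zeros(1), requires_grad=True)
    params = encoder.params + [w, b] + (model.params if model is not None else [])
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    loss_params = CausalLossParams(config.alpha, config.beta, config.lam, config.eps)
    struct0 = edge_structure(graph.A)
    y_train = y[train_idx]

    def pair_features() -> Tensor:
        return Tensor(H0) if model is None else model.pair_features()

    rows = []
    window = max(1, min(config.score_window, config.epochs))
    score_acc = np.zeros(graph.n_nodes)
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
        opt.zero_grad()
        H = pair_features()
        L_CL = None
        breakdown = {"alignment": float("nan"), "std_penalty": float("nan")}
        if variant != "supervised":
            v1 = augment(graph.A, H.data, config.rho, aug_rng)
            v2 = augment(graph.A, H.data, config.rho, aug_rng)
            X1 = encode_view(v1.A_aug, H * v1.feat_mask[None, :], encoder,
                             aug_rng, config.dropout)
            X2 = encode_view(v2.A_aug, H * v2.feat_mask[None, :], encoder,
                             aug_rng, config.dropout)
            L_CL, breakdown = causal_loss(X1, X2, loss_params)

        X = encoder(struct0, H, drop_rng, config.dropout)
        pi = classify(X, w, b)
        L_CE = bce_loss(ad.take_rows(pi, train_idx), y_train, config.reduction)
        L = L_CE + L_CL if variant == "full" else L_CE

        if not np.isfinite(L.data):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}: "
                f"L_CE={L_CE.item()!r}, L_CL={None if L_CL is None else L_CL.item()!r}"
            )
        L.backward()
        opt.step()

        scores = pi.data[:, 0]  # scores of the pre-step forward this epoch
        if epoch >= config.epochs - window:
            score_acc += scores
        val_auc = float("nan")
        if val_idx is not None and len(val_idx) and len(np.unique(y[val_idx])) == 2:
            val_auc = auroc(scores[val_idx], y[val_idx])
        rows.append({
            "epoch": epoch,
            "L_CE": L_CE.item(),
            "L_CL": float("nan") if L_CL is None else L_CL.item(),
            "L": L.item(),
            "alignment": breakdown["alignment"],
            "std_penalty": breakdown["std_penalty"],
            "val_auroc": val_auc,
        })

    if window > 1:
        # averaged predictions over the trailing window smooth out step noise
        scores = score_acc / window
    else:
        # final forward with the post-update parameters
        scores = classify(encoder(struct0, pair_features()), w, b).data[:, 0]

    return TrainResult(
        scores=scores,
        history=pd.DataFrame(rows),
        encoder=encoder,
        classifier=(w, b),
        config=config,
        seed=seed,
        variant=variant,
        max_attention_row_dev=max(
            encoder.attention_row_dev,
            model.fusion_row_dev if model is not None else 0.0,
        ),
        feature_scale=scale,
    )


def select_stable_nodes(X1: np.ndarray, X2: np.ndarray,
                        fraction: float) -> np.ndarray:
    """Indices of the nodes least changed between two view encodings.

    The change metric is the Euclidean distance between a node's two view
    embeddings; this is one concrete reading of "nodes with minor changes"
    and is provided as an optional training-set selector.
    """
    d = np.linalg.norm(np.asarray(X1) - np.asarray(X2), axis=1)
    k = max(1, int(round(fraction * d.size)))
    return np.argsort(d, kind="stable")[:k]


def save_checkpoint(result: TrainResult, path) -> None:
    """Parameters + config + seed, as a compressed npz beside a JSON sidecar."""
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in
              enumerate(result.encoder.params + list(result.classifier))}
    np.savez_compressed(path, **arrays)
    meta = {"config": asdict(result.config), "seed": result.seed,
            "variant": result.variant}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint_into(result: TrainResult, path) -> None:
    data = np.load(Path(path).with_suffix(".npz"))
    params = result.encoder.params + list(result.classifier)
    for i, p in enumerate(params):
        p.data = data[f"p{i}"]
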