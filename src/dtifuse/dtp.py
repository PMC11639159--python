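"""Drug-target-pair (DTP) graph construction.

Interaction prediction is cast as node classification: each candidate
(drug, target) pair is a node whose feature vector is the concatenation of
the fused drug and target embeddings, and two pair nodes are adjacent when
they share the drug or the target (default topology mode), or when their
pair-feature inner product exceeds a quantile threshold (feature mode,
used by the ablation).  Negative pairs are sampled uniformly from the
non-interacting cells at a configurable ratio and participate in adjacency
construction identically to positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import BipartiteNetwork, ConfigurationError, ValidationError


class SamplingError(ValueError):
    """Requested more negative pairs than non-interacting cells exist."""


@dataclass(frozen=True)
class DTPNode:
    drug_idx: int
    target_idx: int
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValidationError("pair label must be 0 or 1")


@dataclass
class DTPGraph:
    """The pair network: nodes, concatenated features, pair-pair adjacency."""

    nodes: list[DTPNode]
    H: np.ndarray
    A: np.ndarray
    mode: str

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        self.A = np.asarray(self.A)
        n = len(self.nodes)
        if self.H.shape[0] != n or self.A.shape != (n, n):
            raise ValidationError("feature/adjacency shapes do not match node count")
        if not np.array_equal(self.A, self.A.T) or np.diagonal(self.A).any():
            raise ValidationError("pair adjacency must be symmetric with zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> np.ndarray:
        return np.array([nd.label for nd in self.nodes], dtype=np.int64)

    @property
    def drug_indices(self) -> np.ndarray:
        return np.array([nd.drug_idx for nd in self.nodes], dtype=np.int64)

    @property
    def target_indices(self) -> np.ndarray:
        return np.array([nd.target_idx for nd in self.nodes], dtype=np.int64)


def sample_pairs(dti: BipartiteNetwork, neg_ratio: int, seed: int) -> list[DTPNode]:
    """All interacting cells as positives plus ``neg_ratio`` times as many
    negatives drawn uniformly without replacement from the zero cells."""
    if neg_ratio < 1 or int(neg_ratio) != neg_ratio:
        raise ConfigurationError("neg_ratio must be a positive integer")
    M = dti.M
    pos_r, pos_c = np.nonzero(M)
    n_pos = pos_r.size
    n_neg = int(neg_ratio) * n_pos
    zero_flat = np.flatnonzero(M == 0)
    if n_neg > zero_flat.size:
        raise SamplingError(
            f"requested {n_neg} negatives but only {zero_flat.size} zero cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zero_flat, size=n_neg, replace=False)
    neg_r, neg_c = np.unravel_index(chosen, M.shape)
    nodes = [DTPNode(int(r), int(c), 1) for r, c in zip(pos_r, pos_c)]
    nodes += [DTPNode(int(r), int(c), 0) for r, c in zip(neg_r, neg_c)]
    return nodes


def pair_features(H_D: np.ndarray, H_T: np.ndarray,
                  nodes: list[DTPNode]) -> np.ndarray:
    """Row i = [H_D[drug_i] || H_T[target_i]] (end-to-end concatenation)."""
    H_D = np.asarray(H_D, dtype=np.float64)
    H_T = np.asarray(H_T, dtype=np.float64)
    if H_D.ndim != 2 or H_T.ndim != 2 or H_D.shape[1] == 0 or H_T.shape[1] == 0:
        raise ValidationError("embeddings must be 2-D with positive width")
    d_idx = np.array([nd.drug_idx for nd in nodes])
    t_idx = np.array([nd.target_idx for nd in nodes])
    if len(nodes) and (d_idx.max() >= H_D.shape[0] or t_idx.max() >= H_T.shape[0]):
        raise IndexError("pair references an entity row outside the embedding matrix")
    return np.hstack([H_D[d_idx], H_T[t_idx]])


def build_adjacency(nodes: list[DTPNode], mode: str = "shared_entity",
                    H: np.ndarray | None = None, q: float = 0.9) -> np.ndarray:
    """Pair-pair adjacency.

    ``shared_entity``: A[i, j] = 1 iff pairs i and j share the drug or the
    target (i != j) - the only topological commonality two pairs possess.
    ``feature_based``: A[i, j] = 1 iff the inner product of pair-feature
    rows i, j reaches the q-quantile of all off-diagonal inner products.
    """
    n = len(nodes)
    if mode == "shared_entity":
        d = np.array([nd.drug_idx for nd in nodes])
        t = np.array([nd.target_idx for nd in nodes])
        A = ((d[:, None] == d[None, :]) | (t[:, None] == t[None, :])).astype(np.int8)
    elif mode == "feature_based":
        if H is None:
            raise ConfigurationError("feature_based adjacency requires pair features H")
        P = np.asarray(H, dtype=np.float64) @ np.asarray(H, dtype=np.float64).T
        off = P[~np.eye(n, dtype=bool)]
        thr = np.quantile(off, q) if off.size else np.inf
        A = (P >= thr).astype(np.int8)
        A = np.maximum(A, A.T)  # guard against quantile ties breaking symmetry
    else:
        raise ConfigurationError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(A, 0)
    return A


def build_dtp_graph(dti: BipartiteNetwork, H_D: np.ndarray, H_T: np.ndarray,
                    neg_ratio: int = 1, seed: int = 0,
                    mode: str = "shared_entity", q: float = 0.9) -> DTPGraph:
    nodes = sample_pairs(dti, neg_ratio, seed)
    H = pair_features(H_D, H_T, nodes)
    A = build_adjacency(nodes, mode, H=H, q=q)
    return DTPGraph(nodes, H, A, mode)


def export_dtp_graph(graph: DTPGraph, dti: BipartiteNetwork, out_dir) -> None:
    """Node table (drug id, target id, label) + edge list, both TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "drug": [dti.row_index.ids[nd.drug_idx] for nd in graph.nodes],
        "target": [dti.col_index.ids[nd.target_idx] for nd in graph.nodes],
        "label": [nd.label for nd in graph.nodes],
    }).to_csv(out / "dtp_nodes.tsv", sep="\t", index=False)
    rows, cols = np.nonzero(np.triu(graph.A, 1))
    pd.DataFrame({"i": rows, "j": cols}).to_csv(
        out / "dtp_edges.tsv", sep="\t", index=False
    )
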