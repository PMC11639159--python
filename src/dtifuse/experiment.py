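"""Dataset splits (random / cold-start), baselines, and experiment orchestration.

``run_experiment`` wires the whole pipeline together: generate or load a
heterogeneous dataset, encode each information source, fuse per entity,
build the drug-target-pair graph, train transductively (labels of held-out
pairs are never seen; their nodes stay in the graph), and report AUROC /
AUPR / ACC on the held-out pairs, alongside the degree-product baseline
and - on synthetic data - the planted-latent oracle ceiling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import (
    BipartiteNetwork,
    ConfigurationError,
    EntityIndex,
    HeteroDataset,
    SimilarityNetwork,
    load_edge_list,
    load_matrix,
)
from .dtp import (
    DTPGraph,
    DTPNode,
    build_adjacency,
    build_dtp_graph,
    export_dtp_graph,
    sample_pairs,
)
from .fusion import FusionConfig
from .metrics import auroc, evaluate_scores
from .similarity import default_source_config
from .synthetic import SyntheticConfig, generate, oracle_scores
from .training import MultiSourcePairModel, TrainConfig, save_checkpoint, train


class SplitError(ValueError):
    """Requested split is infeasible."""


@dataclass
class SplitSpec:
    mode: str = "random"  # random | cold_drug | cold_target
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    neg_ratio: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("random", "cold_drug", "cold_target"):
            raise SplitError(f"unknown split mode {self.mode!r}")
        self.fractions = tuple(float(f) for f in self.fractions)
        if len(self.fractions) != 3 or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise SplitError("train/val/test fractions must sum to 1")
        if min(self.fractions) < 0 or self.fractions[0] <= 0:
            raise SplitError("fractions must be nonnegative with a nonempty train part")


def make_split(nodes: list[DTPNode], spec: SplitSpec
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split pair nodes into train/val/test index arrays.

    ``random`` splits pairs directly.  The cold modes hold out whole
    entities: every pair of a held-out drug (resp. target) lands in test
    (resp. val), so held-out entities never appear in any training pair.
    """
    n = len(nodes)
    rng = np.random.default_rng(spec.seed)
    f_train, f_val, f_test = spec.fractions
    if spec.mode == "random":
        perm = rng.permutation(n)
        n_train = int(round(f_train * n))
        n_val = int(round(f_val * n))
        train = perm[:n_train]
        val = perm[n_train:n_train + n_val]
        test = perm[n_train + n_val:]
    else:
        key = (np.array([nd.drug_idx for nd in nodes])
               if spec.mode == "cold_drug"
               else np.array([nd.target_idx for nd in nodes]))
        entities = rng.permutation(np.unique(key))
        counts = {e: int((key == e).sum()) for e in entities}
        test_set: set = set()
        val_set: set = set()
        i, acc = 0, 0
        while i < len(entities) and acc < f_test * n:
            test_set.add(entities[i])
            acc += counts[entities[i]]
            i += 1
        acc = 0
        while i < len(entities) and acc < f_val * n:
            val_set.add(entities[i])
            acc += counts[entities[i]]
            i += 1
        if i >= len(entities):
            raise SplitError("not enough entities to fill the held-out fractions")
        mask_test = np.isin(key, list(test_set))
        mask_val = np.isin(key, list(val_set))
        test = np.flatnonzero(mask_test)
        val = np.flatnonzero(mask_val)
        train = np.flatnonzero(~(mask_test | mask_val))
        if train.size == 0 or test.size == 0:
            raise SplitError("cold split left train or test empty")
    return np.sort(train), np.sort(val), np.sort(test)


def degree_product_baseline(nodes: list[DTPNode], train_idx: np.ndarray,
                            eval_idx: np.ndarray) -> np.ndarray:
    """Score eval pairs by (train-positive degree of drug) x (of target).

    A structure-free popularity baseline: it sees only how often each entity
    interacts in the training positives, not which partners.
    """
    d = np.array([nd.drug_idx for nd in nodes])
    t = np.array([nd.target_idx for nd in nodes])
    y = np.array([nd.label for nd in nodes])
    deg_d = np.zeros(d.max() + 1)
    deg_t = np.zeros(t.max() + 1)
    pos_train = train_idx[y[train_idx] == 1]
    np.add.at(deg_d, d[pos_train], 1)
    np.add.at(deg_t, t[pos_train], 1)
    return deg_d[d[eval_idx]] * deg_t[t[eval_idx]]


# ---------------------------------------------------------------------------
# Dataset directory layout (mirrors synthetic.write_dataset)

_BIPARTITE_LAYOUT = {
    "dti": ("drug", "target"),
    "drug_disease": ("drug", "disease"),
    "drug_side_effect": ("drug", "side_effect"),
    "target_disease": ("target", "disease"),
}
_SIMILARITY_LAYOUT = {
    "drug_chemical_sim": "drug",
    "target_seq_sim": "target",
    "drug_interaction": "drug",
    "target_interaction": "target",
}


def load_dataset(directory) -> HeteroDataset:
    """Load the standard id-list / edge-list / matrix layout."""
    d = Path(directory)
    indices = {
        "drug": EntityIndex.from_file("drug", d / "drugs.txt"),
        "target": EntityIndex.from_file("target", d / "targets.txt"),
        "disease": EntityIndex.from_file("disease", d / "diseases.txt"),
        "side_effect": EntityIndex.from_file("side_effect", d / "side_effects.txt"),
    }
    networks = {}
    for name, (rc, cc) in _BIPARTITE_LAYOUT.items():
        path = d / f"{name}.tsv"
        if name != "dti" and not path.exists():
            continue
        networks[name] = load_edge_list(path, indices[rc], indices[cc])
    for name, cls in _SIMILARITY_LAYOUT.items():
        path = d / f"{name}.mat.tsv"
        if path.exists():
            networks[name] = SimilarityNetwork(indices[cls], load_matrix(path, indices[cls]))
    dti = networks.pop("dti")
    text_path = d / "text_embeddings.mat.tsv"
    text = load_matrix(text_path) if text_path.exists() else None
    return HeteroDataset(
        drugs=indices["drug"], targets=indices["target"],
        diseases=indices["disease"], side_effects=indices["side_effect"],
        networks=networks, dti=dti, text_embeddings=text,
    )


# ---------------------------------------------------------------------------
# Orchestration

ABLATIONS = ("none", "no_text", "no_causal", "feature_graph")


@dataclass
class ExperimentConfig:
    seed: int = 7
    synthetic: SyntheticConfig | None = None
    dataset_dir: str | None = None
    encoder_d: int = 8
    fusion: FusionConfig = None
    neg_ratio: int = 1
    dtp_mode: str = "shared_entity"
    dtp_quantile: float = 0.9
    split: SplitSpec = None
    train: TrainConfig = None
    ablation: str = "none"

    def __post_init__(self):
        if self.synthetic is None and self.dataset_dir is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if self.fusion is None:
            self.fusion = FusionConfig(seed=self.seed)
        if self.split is None:
            self.split = SplitSpec(seed=self.seed)
        if self.train is None:
            self.train = TrainConfig()
        if self.ablation not in ABLATIONS and not self.ablation.startswith("drop_source:"):
            raise ConfigurationError(f"unknown ablation {self.ablation!r}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "ExperimentConfig":
        cfg = dict(cfg)
        seed = cfg.pop("seed", 7)
        kwargs = {"seed": seed}
        if "synthetic" in cfg:
            kwargs["synthetic"] = SyntheticConfig(**{"seed": seed, **cfg.pop("synthetic")})
        if "dataset_dir" in cfg:
            kwargs["dataset_dir"] = cfg.pop("dataset_dir")
        if "fusion" in cfg:
            kwargs["fusion"] = FusionConfig(**{"seed": seed, **cfg.pop("fusion")})
        if "split" in cfg:
            kwargs["split"] = SplitSpec(**{"seed": seed, **cfg.pop("split")})
        if "train" in cfg:
            kwargs["train"] = TrainConfig(**cfg.pop("train"))
        for key in ("encoder_d", "neg_ratio", "dtp_mode", "dtp_quantile", "ablation"):
            if key in cfg:
                kwargs[key] = cfg.pop(key)
        if cfg:
            raise ConfigurationError(f"unknown config keys: {sorted(cfg)}")
        return cls(**kwargs)


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """End-to-end run; returns a dict with the metric report and extras."""
    stage = "dataset"
    try:
        if config.dataset_dir is not None:
            dataset, latents = load_dataset(config.dataset_dir), None
        else:
            dataset, latents = generate(config.synthetic)

        stage = "source encoding"
        ms_cfg = default_source_config(
            dataset, d=config.encoder_d, seed=config.seed,
            include_text=config.ablation != "no_text",
        )
        if config.ablation.startswith("drop_source:"):
            name = config.ablation.split(":", 1)[1]
            ms_cfg.drug_sources = [s for s in ms_cfg.drug_sources if s.name != name]
            ms_cfg.target_sources = [s for s in ms_cfg.target_sources if s.name != name]

        stage = "pair graph"
        nodes = sample_pairs(dataset.dti, config.neg_ratio, config.seed)
        model = MultiSourcePairModel(dataset, ms_cfg, config.fusion, nodes,
                                     config.seed)
        H0 = model.pair_features().data  # initial features; structure source
        dtp_mode = ("feature_based" if config.ablation == "feature_graph"
                    else config.dtp_mode)
        A = build_adjacency(nodes, dtp_mode, H=H0, q=config.dtp_quantile)
        graph = DTPGraph(nodes, H0, A, dtp_mode)

        stage = "split"
        train_idx, val_idx, test_idx = make_split(graph.nodes, config.split)

        stage = "training"
        variant = "no_causal" if config.ablation == "no_causal" else "full"
        result = train(graph, train_idx, config.train, config.seed,
                       val_idx=val_idx, variant=variant, model=model)

        stage = "evaluation"
        y = graph.labels
        report = evaluate_scores(result.scores[test_idx], y[test_idx])
        out = {
            "report": report,
            "history": result.history,
            "train_result": result,
            "model": model,
            "graph": graph,
            "splits": (train_idx, val_idx, test_idx),
            "dataset": dataset,
        }
        baseline = degree_product_baseline(graph.nodes, train_idx, test_idx)
        out["degree_baseline_auroc"] = auroc(baseline, y[test_idx])
        if latents is not None:
            oracle = oracle_scores(latents, graph.drug_indices[test_idx],
                                   graph.target_indices[test_idx])
            out["oracle_auroc"] = auroc(oracle, y[test_idx])
            out["latents"] = latents
    except Exception as err:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {err}") from err

    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        result.history.to_csv(out_path / "history.tsv", sep="\t", index=False)
        metrics = {
            **report.as_dict(),
            "degree_baseline_auroc": out.get("degree_baseline_auroc"),
            "oracle_auroc": out.get("oracle_auroc"),
            "max_attention_row_dev": result.max_attention_row_dev,
            "ablation": config.ablation,
            "seed": config.seed,
        }
        (out_path / "metrics.json").write_text(json.dumps(metrics, indent=2))
        save_checkpoint(result, out_path / "checkpoint.npz")
        export_dtp_graph(graph, dataset.dti, out_path)
    return out
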