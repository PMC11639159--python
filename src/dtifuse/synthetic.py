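"""Synthetic heterogeneous drug/target benchmark with planted latent structure.

Every entity class gets i.i.d. Gaussian latent factors (U drugs, V targets,
C diseases, E side effects).  Interactions follow the factor geometry:

* DTI cell (i, j) ~ Bernoulli( sigmoid( a * U_i . V_j + b ) ), with the
  offset b calibrated by bisection so the expected density matches the
  request;
* auxiliary bipartite networks (drug-disease, drug-side-effect,
  target-disease) are the top-density quantile of the corresponding factor
  inner products;
* homogeneous similarity networks are U U^T (resp. V V^T) plus symmetric
  Gaussian noise, clipped at zero to satisfy nonnegativity; the
  "interaction" variants are binarized at the density quantile;
* the text-embedding stand-in is U plus Gaussian noise of sd text_noise_sd.

Because all networks and the text matrix are driven by the same latent
factors that generate the interactions, multi-source fusion has a planted
signal to recover, and the latent inner product U_i . V_j serves as the
oracle score that upper-bounds any learned model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import (
    BipartiteNetwork,
    ConfigurationError,
    EntityIndex,
    HeteroDataset,
    SimilarityNetwork,
    save_edge_list,
    save_matrix,
)


@dataclass
class SyntheticConfig:
    n_drugs: int = 60
    n_targets: int = 80
    n_diseases: int = 40
    n_side_effects: int = 50
    latent_dim: int = 8
    dti_density: float = 0.08
    aux_density: float = 0.10
    sim_density: float = 0.15
    interaction_scale: float = 1.0
    noise_sd: float = 0.1
    text_noise_sd: float = 0.1
    seed: int = 7

    def __post_init__(self):
        for name in ("n_drugs", "n_targets", "n_diseases", "n_side_effects"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2")
        if self.latent_dim < 1:
            raise ConfigurationError("latent_dim must be >= 1")
        for name in ("dti_density", "aux_density", "sim_density"):
            r = getattr(self, name)
            if not 0.0 < r < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1)")


@dataclass
class Latents:
    U: np.ndarray
    V: np.ndarray
    C: np.ndarray
    E: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_offset(logits: np.ndarray, density: float,
                      lo: float = -30.0, hi: float = 30.0,
                      iters: int = 80) -> float:
    """Bisection on b so mean(sigmoid(logits + b)) == density."""
    f_lo = _sigmoid(logits + lo).mean() - density
    f_hi = _sigmoid(logits + hi).mean() - density
    if f_lo > 0 or f_hi < 0:
        raise ConfigurationError(
            f"requested density {density} unreachable within calibration bounds"
        )
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if _sigmoid(logits + mid).mean() - density > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _threshold_bipartite(scores: np.ndarray, density: float) -> np.ndarray:
    thr = np.quantile(scores, 1.0 - density)
    return (scores >= thr).astype(np.int8)


def _noisy_similarity(F: np.ndarray, noise_sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    S = F @ F.T
    noise = rng.normal(0.0, noise_sd, size=S.shape)
    S = S + (noise + noise.T) / 2.0
    S = (S + S.T) / 2.0
    return np.clip(S, 0.0, None)


def _binary_similarity(F: np.ndarray, density: float) -> np.ndarray:
    S = F @ F.T
    n = S.shape[0]
    off = S[~np.eye(n, dtype=bool)]
    thr = np.quantile(off, 1.0 - density)
    A = (S >= thr).astype(np.float64)
    np.fill_diagonal(A, 0.0)
    return np.maximum(A, A.T)


def _ids(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i:04d}" for i in range(n))


def generate(config: SyntheticConfig) -> tuple[HeteroDataset, Latents]:
    """Draw one dataset; fully deterministic under config.seed."""
    rng = np.random.default_rng(config.seed)
    k = config.latent_dim
    U = rng.normal(size=(config.n_drugs, k))
    V = rng.normal(size=(config.n_targets, k))
    C = rng.normal(size=(config.n_diseases, k))
    E = rng.normal(size=(config.n_side_effects, k))

    drugs = EntityIndex("drug", _ids("D", config.n_drugs))
    targets = EntityIndex("target", _ids("T", config.n_targets))
    diseases = EntityIndex("disease", _ids("Di", config.n_diseases))
    side_effects = EntityIndex("side_effect", _ids("Se", config.n_side_effects))

    logits = config.interaction_scale * (U @ V.T)
    b = _calibrate_offset(logits, config.dti_density)
    p = _sigmoid(logits + b)
    M_dti = (rng.random(p.shape) < p).astype(np.int8)

    networks = {
        "drug_disease": BipartiteNetwork(
            drugs, diseases, _threshold_bipartite(U @ C.T, config.aux_density)),
        "drug_side_effect": BipartiteNetwork(
            drugs, side_effects, _threshold_bipartite(U @ E.T, config.aux_density)),
        "target_disease": BipartiteNetwork(
            targets, diseases, _threshold_bipartite(V @ C.T, config.aux_density)),
        "drug_chemical_sim": SimilarityNetwork(
            drugs, _noisy_similarity(U, config.noise_sd, rng)),
        "target_seq_sim": SimilarityNetwork(
            targets, _noisy_similarity(V, config.noise_sd, rng)),
        "drug_interaction": SimilarityNetwork(
            drugs, _binary_similarity(U, config.sim_density)),
        "target_interaction": SimilarityNetwork(
            targets, _binary_similarity(V, config.sim_density)),
    }
    text = U + rng.normal(0.0, 1.0, size=U.shape) * config.text_noise_sd

    dataset = HeteroDataset(
        drugs=drugs, targets=targets, diseases=diseases, side_effects=side_effects,
        networks=networks,
        dti=BipartiteNetwork(drugs, targets, M_dti),
        text_embeddings=text,
    )
    return dataset, Latents(U, V, C, E)


def oracle_scores(latents: Latents, drug_idx: np.ndarray,
                  target_idx: np.ndarray) -> np.ndarray:
    """score(i, j) = U_i . V_j - the planted-signal ceiling reference."""
    return np.einsum(
        "ik,ik->i", latents.U[np.asarray(drug_idx)], latents.V[np.asarray(target_idx)]
    )


def write_dataset(dataset: HeteroDataset, latents: Latents | None, out_dir) -> None:
    """Write the standard edge-list/matrix/id-list layout data_model reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.drugs.to_file(out / "drugs.txt")
    dataset.targets.to_file(out / "targets.txt")
    dataset.diseases.to_file(out / "diseases.txt")
    dataset.side_effects.to_file(out / "side_effects.txt")
    save_edge_list(dataset.dti, out / "dti.tsv")
    for name, net in dataset.networks.items():
        if isinstance(net, BipartiteNetwork):
            save_edge_list(net, out / f"{name}.tsv")
        else:
            save_matrix(net.S, out / f"{name}.mat.tsv")
    if dataset.text_embeddings is not None:
        save_matrix(dataset.text_embeddings, out / "text_embeddings.mat.tsv")
    if latents is not None:
        for tag, F in (("U", latents.U), ("V", latents.V),
                       ("C", latents.C), ("E", latents.E)):
            save_matrix(F, out / f"latent_{tag}.mat.tsv")
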