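"""Domain types and plain-text I/O for heterogeneous drug/target network data.

The method operates purely on networks and embedding matrices: bipartite
interaction networks (drug-disease, drug-side-effect, target-disease, and
the ground-truth drug-target network), homogeneous similarity networks
(chemical, sequence, interaction), and an optional per-drug text-embedding
matrix.  Entity order always comes from an explicit per-class id list, never
from edge files, so indexing is reproducible.

Edge lists are two-column (plus optional weight) TSV/CSV files; matrices are
whitespace-delimited text written at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class IndexAlignmentError(KeyError):
    """An identifier does not belong to the entity index it was used with."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""


class ConfigurationError(ValueError):
    """A configuration references something the dataset does not provide."""


ENTITY_CLASSES = ("drug", "target", "disease", "side_effect")


@dataclass(frozen=True)
class EntityIndex:
    """An ordered, immutable mapping from string ids to positions."""

    entity_class: str
    ids: tuple[str, ...]
    _pos: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.entity_class not in ENTITY_CLASSES:
            raise ValidationError(
                f"unknown entity class {self.entity_class!r}; expected one of {ENTITY_CLASSES}"
            )
        object.__setattr__(self, "ids", tuple(self.ids))
        pos = {e: i for i, e in enumerate(self.ids)}
        if len(pos) != len(self.ids):
            raise ValidationError(f"duplicate ids in {self.entity_class} index")
        object.__setattr__(self, "_pos", pos)

    @property
    def size(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, entity_id: str) -> int:
        try:
            return self._pos[entity_id]
        except KeyError:
            raise IndexAlignmentError(
                f"id {entity_id!r} not in the {self.entity_class} index"
            ) from None

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._pos

    @classmethod
    def from_file(cls, entity_class: str, path) -> "EntityIndex":
        ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(entity_class, tuple(ids))

    def to_file(self, path) -> None:
        Path(path).write_text("\n".join(self.ids) + "\n")


def _check_binary(M: np.ndarray, what: str) -> None:
    if not np.isin(M, (0, 1)).all():
        raise ValidationError(f"{what} must be binary (0/1)")


@dataclass
class BipartiteNetwork:
    """A binary incidence matrix between two entity classes."""

    row_index: EntityIndex
    col_index: EntityIndex
    M: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M)
        if self.M.shape != (self.row_index.size, self.col_index.size):
            raise ValidationError(
                f"matrix shape {self.M.shape} does not match indices "
                f"({self.row_index.size}, {self.col_index.size})"
            )
        _check_binary(self.M, "bipartite incidence matrix")


@dataclass
class SimilarityNetwork:
    """A symmetric nonnegative similarity matrix over one entity class."""

    index: EntityIndex
    S: np.ndarray

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=np.float64)
        n = self.index.size
        if self.S.shape != (n, n):
            raise ValidationError(f"similarity matrix shape {self.S.shape} != ({n}, {n})")
        if not np.array_equal(self.S, self.S.T):
            raise ValidationError("similarity matrix must be symmetric")
        if (self.S < 0).any():
            raise ValidationError("similarity matrix must be nonnegative")


@dataclass
class BinaryAdjacency:
    """A thresholded similarity network: binary, symmetric."""

    index: EntityIndex
    A: np.ndarray
    threshold_used: float

    def __post_init__(self):
        self.A = np.asarray(self.A)
        n = self.index.size
        if self.A.shape != (n, n):
            raise ValidationError(f"adjacency shape {self.A.shape} != ({n}, {n})")
        _check_binary(self.A, "binary adjacency")
        if not np.array_equal(self.A, self.A.T):
            raise ValidationError("binary adjacency must be symmetric")


@dataclass
class HeteroDataset:
    """All entity indices and named networks of one heterogeneous dataset.

    ``networks`` maps names (e.g. ``"drug_disease"``) to BipartiteNetwork or
    SimilarityNetwork objects whose indices must be the dataset's own.
    ``text_embeddings``, when present, has one row per drug.
    """

    drugs: EntityIndex
    targets: EntityIndex
    diseases: EntityIndex
    side_effects: EntityIndex
    networks: dict
    dti: BipartiteNetwork
    text_embeddings: np.ndarray | None = None

    def __post_init__(self):
        known = {
            id(self.drugs), id(self.targets), id(self.diseases), id(self.side_effects)
        }
        known_ids = {
            "drug": self.drugs, "target": self.targets,
            "disease": self.diseases, "side_effect": self.side_effects,
        }

        def check_index(ix: EntityIndex, where: str):
            if id(ix) in known:
                return
            ref = known_ids[ix.entity_class]
            if ix.ids != ref.ids:
                raise ValidationError(
                    f"network {where!r} uses a {ix.entity_class} index that is not "
                    "the dataset's own"
                )

        for name, net in self.networks.items():
            if isinstance(net, BipartiteNetwork):
                check_index(net.row_index, name)
                check_index(net.col_index, name)
            elif isinstance(net, SimilarityNetwork):
                check_index(net.index, name)
            else:
                raise ValidationError(f"network {name!r} has unsupported type {type(net)}")
        check_index(self.dti.row_index, "dti")
        check_index(self.dti.col_index, "dti")
        if self.dti.row_index.entity_class != "drug" or self.dti.col_index.entity_class != "target":
            raise ValidationError("dti must be a drug x target network")
        if self.text_embeddings is not None:
            self.text_embeddings = np.asarray(self.text_embeddings, dtype=np.float64)
            if self.text_embeddings.shape[0] != self.drugs.size:
                raise ValidationError(
                    f"text_embeddings has {self.text_embeddings.shape[0]} rows, "
                    f"expected {self.drugs.size} (one per drug)"
                )

    @property
    def n_drugs(self) -> int:
        return self.drugs.size

    @property
    def n_targets(self) -> int:
        return self.targets.size


@dataclass
class MultiSourceTensor:
    """Per-entity stack of per-source embeddings: (entities, sources, d)."""

    index: EntityIndex
    source_names: tuple[str, ...]
    Z: np.ndarray

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=np.float64)
        self.source_names = tuple(self.source_names)
        if self.Z.ndim != 3:
            raise ValidationError("multi-source tensor must be 3-dimensional")
        if self.Z.shape[0] != self.index.size:
            raise ValidationError("first extent must equal the entity count")
        if self.Z.shape[1] != len(self.source_names):
            raise ValidationError(
                f"{len(self.source_names)} source names but tensor has "
                f"{self.Z.shape[1]} source slices"
            )
        if not np.isfinite(self.Z).all():
            raise ValidationError("multi-source tensor contains non-finite entries")

    @property
    def n_sources(self) -> int:
        return len(self.source_names)

    def without(self, name: str) -> "MultiSourceTensor":
        """Drop one named source (ablation switch)."""
        if name not in self.source_names:
            raise ConfigurationError(f"source {name!r} not present: {self.source_names}")
        keep = [i for i, s in enumerate(self.source_names) if s != name]
        return MultiSourceTensor(
            self.index, tuple(self.source_names[i] for i in keep), self.Z[:, keep, :]
        )


# ---------------------------------------------------------------------------
# I/O


def load_edge_list(path, row_index: EntityIndex, col_index: EntityIndex) -> BipartiteNetwork:
    """Read a two-column (optionally weighted) edge list into a binary network.

    Delimiter (tab or comma) is auto-detected.  A first line whose first two
    fields are both absent from their indices is treated as a header.
    Repeated pairs binarize to a single 1; unknown ids raise
    IndexAlignmentError naming the id and line.
    """
    text = Path(path).read_text()
    M = np.zeros((row_index.size, col_index.size), dtype=np.int8)
    lines = [ln for ln in text.splitlines()]
    start = 0
    parsed: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        delim = "\t" if "\t" in line else ","
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected at least two fields")
        parsed.append((lineno, fields[0], fields[1]))
    if parsed:
        first = parsed[0]
        if first[1] not in row_index and first[2] not in col_index and start == 0:
            parsed = parsed[1:]  # header row
    for lineno, r, c in parsed:
        if r not in row_index:
            raise IndexAlignmentError(
                f"{path}: line {lineno}: unknown {row_index.entity_class} id {r!r}"
            )
        if c not in col_index:
            raise IndexAlignmentError(
                f"{path}: line {lineno}: unknown {col_index.entity_class} id {c!r}"
            )
        M[row_index.position(r), col_index.position(c)] = 1
    return BipartiteNetwork(row_index, col_index, M)


def save_edge_list(net: BipartiteNetwork, path, delimiter: str = "\t") -> None:
    rows, cols = np.nonzero(net.M)
    with open(path, "w") as fh:
        for r, c in zip(rows, cols):
            fh.write(f"{net.row_index.ids[r]}{delimiter}{net.col_index.ids[c]}\n")


def save_matrix(matrix: np.ndarray, path) -> None:
    """Write a dense matrix as delimited text at full round-trip precision."""
    np.savetxt(path, np.asarray(matrix), fmt="%.17g", delimiter="\t")


def load_matrix(path, index: EntityIndex | None = None,
                expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    M = np.loadtxt(path, delimiter="\t", ndmin=2)
    if index is not None:
        expected_shape = (index.size, index.size)
    if expected_shape is not None and M.shape != tuple(expected_shape):
        raise ValidationError(
            f"{path}: matrix shape {M.shape} does not match expected {expected_shape}"
        )
    return M


def load_similarity(path, index: EntityIndex) -> SimilarityNetwork:
    return SimilarityNetwork(index, load_matrix(path, index))
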