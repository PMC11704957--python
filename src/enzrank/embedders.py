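"""Sequence embedders: pluggable per-residue representations, mean pooling,
and cross-validated layer selection.

A protein language model exposes one representation matrix (length x dim) per
transformer block ("layer"); a fixed-size sequence vector is obtained by
averaging the residue rows of one chosen layer. Any backend implementing the
:class:`Embedder` protocol can be used; the package ships a deterministic
:class:`SurrogateEmbedder` whose representations encode local sequence
content (residue + neighbors + physicochemistry) so that the full workflow is
testable without model downloads. A pretrained-model adapter only needs to
implement the same three-method contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .seqio import FitnessDataset, SequenceRecord, VALID_RESIDUES

__all__ = [
    "EmbedderSpec",
    "ResidueMatrix",
    "EmbeddingMatrix",
    "Embedder",
    "SurrogateEmbedder",
    "surrogate_residues",
    "pool_mean",
    "embed_dataset",
    "select_best_layer",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"  # X encodes as all-zero one-hot
_AA_INDEX = {a: i for i, a in enumerate(_AA)}

# Per-residue physicochemical scalars, roughly unit-scaled:
# Kyte-Doolittle hydrophobicity /4.5, side-chain volume /100 A^3,
# formal charge at pH 7, polarity flag, aromaticity flag.
_PHYSCHEM = {
    "A": (0.40, 0.89, 0.0, 0.0, 0.0),
    "C": (0.56, 1.09, 0.0, 0.0, 0.0),
    "D": (-0.78, 1.11, -1.0, 1.0, 0.0),
    "E": (-0.78, 1.38, -1.0, 1.0, 0.0),
    "F": (0.62, 1.90, 0.0, 0.0, 1.0),
    "G": (-0.09, 0.60, 0.0, 0.0, 0.0),
    "H": (-0.71, 1.53, 0.1, 1.0, 1.0),
    "I": (1.00, 1.67, 0.0, 0.0, 0.0),
    "K": (-0.87, 1.69, 1.0, 1.0, 0.0),
    "L": (0.84, 1.67, 0.0, 0.0, 0.0),
    "M": (0.42, 1.63, 0.0, 0.0, 0.0),
    "N": (-0.78, 1.14, 0.0, 1.0, 0.0),
    "P": (-0.36, 1.13, 0.0, 0.0, 0.0),
    "Q": (-0.78, 1.44, 0.0, 1.0, 0.0),
    "R": (-1.00, 1.74, 1.0, 1.0, 0.0),
    "S": (-0.18, 0.89, 0.0, 1.0, 0.0),
    "T": (-0.16, 1.16, 0.0, 1.0, 0.0),
    "V": (0.93, 1.40, 0.0, 0.0, 0.0),
    "W": (-0.20, 2.28, 0.0, 0.0, 1.0),
    "Y": (-0.29, 1.93, 0.0, 1.0, 1.0),
    "X": (0.0, 1.4, 0.0, 0.0, 0.0),
}

_N_FEATURES = 3 * 20 + 5  # one-hot of (prev, self, next) + physchem of self


@dataclass(frozen=True)
class EmbedderSpec:
    """Static description of an embedding backend."""

    name: str
    n_layers: int
    dim: int
    deterministic: bool

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.dim < 1:
            raise ValueError("n_layers and dim must be >= 1")


@dataclass
class ResidueMatrix:
    """Per-residue representations of one sequence at one layer.

    Rows correspond to residue positions only; special begin/end tokens of a
    transformer backend are excluded before construction.
    """

    sequence_id: str
    layer: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("residue matrix must be 2-D with >= 1 row")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"non-finite entries for {self.sequence_id!r}")


@dataclass
class EmbeddingMatrix:
    """n x dim matrix of pooled sequence vectors, row-aligned to ``ids``."""

    ids: list[str]
    layer: int
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.ids):
            raise ValueError("row count must match number of ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in embedding matrix")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite embedding entries")

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def rows_for(self, ids: Sequence[str]) -> np.ndarray:
        index = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"no embedding for ids {missing[:5]}")
        return self.X[[index[i] for i in ids]]


@runtime_checkable
class Embedder(Protocol):
    """Backend contract: a spec plus per-sequence residue representations."""

    @property
    def spec(self) -> EmbedderSpec: ...

    def residues(self, record: SequenceRecord, layer: int) -> ResidueMatrix: ...


def pool_mean(residues: ResidueMatrix) -> np.ndarray:
    """Mean-pool a residue matrix into one vector (column means)."""
    if residues.matrix.shape[0] < 1:
        raise ValueError("cannot pool an empty residue matrix")
    return residues.matrix.mean(axis=0)


def _content_seed(seed: int, layer: int, sequence: str) -> list[int]:
    digest = hashlib.sha1(sequence.encode()).digest()
    return [seed, layer, int.from_bytes(digest[:4], "big")]


def _residue_features(sequence: str) -> np.ndarray:
    L = len(sequence)
    feats = np.zeros((L, _N_FEATURES))
    for i, aa in enumerate(sequence):
        if aa not in _PHYSCHEM:
            raise ValueError(f"invalid residue {aa!r} at position {i + 1}")
        prev_aa = sequence[i - 1] if i > 0 else None
        next_aa = sequence[i + 1] if i < L - 1 else None
        if prev_aa is not None and prev_aa in _AA_INDEX:
            feats[i, _AA_INDEX[prev_aa]] = 1.0
        if aa in _AA_INDEX:
            feats[i, 20 + _AA_INDEX[aa]] = 1.0
        if next_aa is not None and next_aa in _AA_INDEX:
            feats[i, 40 + _AA_INDEX[next_aa]] = 1.0
        feats[i, 60:65] = _PHYSCHEM[aa]
    return feats


def _projection(layer: int, dim: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Sparse signed-coordinate projection, fixed per (layer, dim, seed).

    Each of the 65 local features lands on one output coordinate with a
    random sign; distinct coordinates whenever dim allows, so the projection
    is injective on feature space and pooled vectors stay axis-aligned.
    """
    rng = np.random.default_rng([seed, layer, dim])
    coords = rng.choice(dim, size=_N_FEATURES, replace=dim < _N_FEATURES)
    signs = rng.choice([-1.0, 1.0], size=_N_FEATURES)
    return coords, signs


# Standardized Kyte-Doolittle hydrophobicity: the residue code written into
# the context-addressed channel (zero mean, unit variance over the 20 AAs).
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}
_kd_values = np.array([_KD[a] for a in _AA])
HYDROPHOBICITY_Z = {
    a: float((_KD[a] - _kd_values.mean()) / _kd_values.std()) for a in _AA
}
HYDROPHOBICITY_Z["X"] = 0.0

# Relative channel scales: the context-addressed (locus) channel must
# dominate the composition channel for pooled vectors to stay locus-resolved.
_CONTEXT_AMPLITUDE = 4.0
_MARGINAL_SCALE = 0.25


def _context_coord(prev: str, nxt: str, layer: int, dim: int, seed: int) -> int:
    digest = hashlib.blake2b(
        f"{seed}|{layer}|{prev}_{nxt}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % dim


def surrogate_residues(
    sequence: str, layer: int, dim: int = 128, seed: int = 0
) -> ResidueMatrix:
    """Deterministic per-residue representation standing in for a pLLM block.

    Row ``i`` depends only on the residues at positions ``i-1, i, i+1``,
    through two channels:

    * the one-hot encodings of the residue and of each neighbor plus five
      physicochemical scalars, placed on seeded random signed coordinates;
    * a context-addressed channel: the standardized hydrophobicity of the
      central residue, amplified and written at a coordinate hashed from the
      neighbor pair. Because neighbor pairs are near-unique along a random
      reference, this channel survives mean pooling as locus-resolved
      information — a purely linear projection of per-position features
      would collapse to amino-acid composition under the pooling average.

    Layer 0 additionally carries unit Gaussian noise (seeded by the sequence
    content, not its id), so higher layers are strictly more informative by
    construction.
    """
    if dim < 8:
        raise ValueError("surrogate dim must be >= 8")
    if layer < 0:
        raise ValueError("layer must be >= 0")
    sequence = sequence.upper()
    feats = _residue_features(sequence)
    coords, signs = _projection(layer, dim, seed)
    matrix = np.zeros((len(sequence), dim))
    np.add.at(matrix, (slice(None), coords), feats * signs * _MARGINAL_SCALE)
    for i, aa in enumerate(sequence):
        prev = sequence[i - 1] if i > 0 else "^"
        nxt = sequence[i + 1] if i < len(sequence) - 1 else "$"
        c = _context_coord(prev, nxt, layer, dim, seed)
        matrix[i, c] += _CONTEXT_AMPLITUDE * HYDROPHOBICITY_Z[aa]
    if layer == 0:
        noise_rng = np.random.default_rng(_content_seed(seed, layer, sequence))
        matrix = matrix + noise_rng.standard_normal(matrix.shape)
    return ResidueMatrix(sequence_id="", layer=layer, matrix=matrix)


class SurrogateEmbedder:
    """Deterministic local-context embedder used for testing and simulation.

    Defaults: 3 addressable layers (layer 0 = signal + unit noise, layers
    1..2 = clean signal under independent projections), 128 dimensions.
    """

    def __init__(self, dim: int = 128, n_layers: int = 3, seed: int = 0) -> None:
        self._spec = EmbedderSpec(
            name="surrogate", n_layers=n_layers, dim=dim, deterministic=True
        )
        self.seed = seed

    @property
    def spec(self) -> EmbedderSpec:
        return self._spec

    def residues(self, record: SequenceRecord, layer: int) -> ResidueMatrix:
        if not 0 <= layer < self._spec.n_layers:
            raise ValueError(
                f"layer {layer} out of range [0, {self._spec.n_layers})"
            )
        rm = surrogate_residues(record.sequence, layer, self._spec.dim, self.seed)
        rm.sequence_id = record.id
        return rm


def embed_dataset(
    records: Sequence[SequenceRecord], embedder: Embedder, layer: int
) -> EmbeddingMatrix:
    """Mean-pool every record at one layer into an :class:`EmbeddingMatrix`.

    Row ``i`` depends only on ``records[i]``; deterministic backends give
    bit-identical output across calls.
    """
    spec = embedder.spec
    if not 0 <= layer < spec.n_layers:
        raise ValueError(f"layer {layer} out of range [0, {spec.n_layers})")
    rows = []
    for rec in records:
        try:
            rows.append(pool_mean(embedder.residues(rec, layer)))
        except Exception as exc:  # noqa: BLE001 - re-raise with the id
            raise RuntimeError(f"embedding failed for {rec.id!r}: {exc}") from exc
    X = np.vstack(rows) if rows else np.empty((0, spec.dim))
    return EmbeddingMatrix(ids=[r.id for r in records], layer=layer, X=X)


def _id_folds(ids: Sequence[str], folds: int, seed: int) -> tuple[list[str], list[list[str]]]:
    # Fold membership keyed by id (sorted then seeded shuffle) so dataset
    # order does not change the partition; the shuffled order also fixes the
    # row order used for training, keeping the whole selection order-free.
    ordered = sorted(ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ordered)
    return ordered, [list(part) for part in np.array_split(ordered, folds)]


def select_best_layer(
    dataset: FitnessDataset,
    embedder: Embedder,
    regressor_spec,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, list[float]]:
    """Pick the most predictive transformer block by k-fold cross-validation.

    For every layer, the dataset is embedded, a regressor is tuned and fit on
    each training fold (grid search as in :func:`enzrank.regression.
    grid_search_train`) and scored by Spearman rho on the held-out fold; the
    layer with the highest mean out-of-fold rho wins, ties going to the
    lowest layer index. Returns ``(best_layer, per_layer_scores)``.
    """
    from . import regression  # late import: regression is embedder-agnostic

    n = len(dataset)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"dataset of size {n} cannot be split into {folds} folds")
    ordered_ids, fold_ids = _id_folds(dataset.ids, folds, seed)
    if min(len(f) for f in fold_ids) < 2:
        raise ValueError("every fold needs >= 2 samples for Spearman scoring")
    y_by_id = dict(zip(dataset.ids, dataset.transformed_values()))
    scores: list[float] = []
    for layer in range(embedder.spec.n_layers):
        emb = embed_dataset(dataset.records, embedder, layer)
        fold_rhos = []
        for test_ids in fold_ids:
            test_set = set(test_ids)
            train_ids = [i for i in ordered_ids if i not in test_set]
            model = regression.grid_search_train(
                emb.rows_for(train_ids),
                np.array([y_by_id[i] for i in train_ids]),
                regressor_spec,
                train_ids=train_ids,
                layer=layer,
            )
            preds = regression.predict(model, emb.rows_for(test_ids))
            fold_rhos.append(
                regression.spearman_rho(
                    preds, [y_by_id[i] for i in test_ids]
                )
            )
        scores.append(float(np.mean(fold_rhos)))
    best_layer = int(np.argmax(scores))  # argmax takes the lowest index on ties
    return best_layer, scores
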