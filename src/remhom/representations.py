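"""Protein representations: per-residue matrices, pooled vectors, stores.

A model assigns each domain of length ``l`` a per-residue embedding matrix
``s`` of shape ``l x D``; the protein-level vector ``p`` is the mean over the
residue axis.  Similarity between proteins is the cosine of their pooled
vectors.  Stores are keyed containers (HDF5 or NPZ) holding one dataset per
domain id plus ``model_name`` / ``layout`` / ``dim`` metadata, with
``layout`` in ``{"pooled", "per_residue"}``.  The store contract requires
exporters to strip any special-token rows: pooling runs over exactly the
``l`` residue rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np

from .errors import (
    DegenerateRepresentationError,
    DimensionMismatchError,
    SchemaError,
)

_NPZ_META_KEY = "__remhom_meta__"
LAYOUTS = ("pooled", "per_residue")


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-residue embedding matrix ``s`` of shape ``l x D`` for one domain."""

    domain_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise SchemaError(
                f"domain {self.domain_id!r}: embedding matrix must be 2-D with "
                f"positive shape, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise SchemaError(f"domain {self.domain_id!r}: non-finite embedding entries")
        object.__setattr__(self, "values", values)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Representation:
    """Pooled protein-level vector ``p`` for one domain."""

    domain_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        vector = np.asarray(self.vector, dtype=float)
        if vector.ndim != 1 or vector.size < 1:
            raise SchemaError(
                f"domain {self.domain_id!r}: representation must be a 1-D vector"
            )
        if not np.all(np.isfinite(vector)):
            raise SchemaError(f"domain {self.domain_id!r}: non-finite vector entries")
        object.__setattr__(self, "vector", vector)

    @property
    def dim(self) -> int:
        return self.vector.size


class RepresentationStore:
    """A named set of pooled vectors with one common dimension."""

    def __init__(self, model_name: str, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise SchemaError(f"store {model_name!r}: no vectors")
        self.model_name = model_name
        self._vectors: dict[str, np.ndarray] = {}
        dims: dict[int, list[str]] = {}
        for domain_id, vec in vectors.items():
            rep = vec if isinstance(vec, Representation) else Representation(domain_id, vec)
            self._vectors[domain_id] = rep.vector
            dims.setdefault(rep.dim, []).append(domain_id)
        if len(dims) > 1:
            raise DimensionMismatchError(
                f"store {model_name!r}: mixed vector dimensions "
                + "; ".join(f"D={d}: {ids[:5]}" for d, ids in sorted(dims.items()))
            )
        self.dim = next(iter(dims))

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, domain_id: str) -> bool:
        return domain_id in self._vectors

    def __getitem__(self, domain_id: str) -> np.ndarray:
        return self._vectors[domain_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._vectors)

    def matrix(self, ids) -> np.ndarray:
        """Stack the vectors for ``ids`` (row order follows ``ids``)."""
        return np.stack([self._vectors[i] for i in ids])

    def items(self):
        return self._vectors.items()


def pool_mean(matrix: EmbeddingMatrix) -> Representation:
    """Mean-pool a per-residue matrix over the sequence length.

    ``p_j = (1/l) * sum_k s[k, j]``, accumulated in double precision.
    """
    vector = np.mean(np.asarray(matrix.values, dtype=np.float64), axis=0)
    return Representation(matrix.domain_id, vector)


def cosine_similarity(u, v) -> float:
    """Cosine similarity ``u.v / (|u||v|)`` between two pooled vectors.

    Symmetric and invariant to positive rescaling.  Zero-norm vectors are
    rejected: they indicate corrupt input and silently scoring them zero
    would bias the rankings.
    """
    u = u.vector if isinstance(u, Representation) else np.asarray(u, dtype=float)
    v = v.vector if isinstance(v, Representation) else np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionMismatchError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateRepresentationError("zero-norm representation in cosine similarity")
    return float(np.dot(u, v) / (nu * nv))


def save_representation_store(store: RepresentationStore, path) -> None:
    """Write a pooled store to ``.h5``/``.hdf5`` or ``.npz``."""
    _save(path, store.model_name, "pooled", store.dim, dict(store.items()))


def save_embedding_matrices(
    matrices: Mapping[str, EmbeddingMatrix], model_name: str, path
) -> None:
    """Write a per-residue store (one ``l x D`` dataset per domain id)."""
    if not matrices:
        raise SchemaError("no matrices to save")
    dims = {m.dim for m in matrices.values()}
    if len(dims) > 1:
        raise DimensionMismatchError(f"mixed matrix dimensions {sorted(dims)}")
    _save(path, model_name, "per_residue", dims.pop(),
          {k: m.values for k, m in matrices.items()})


def _save(path, model_name: str, layout: str, dim: int, arrays: dict) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as handle:
            handle.attrs["model_name"] = model_name
            handle.attrs["layout"] = layout
            handle.attrs["dim"] = dim
            for key, values in arrays.items():
                handle.create_dataset(key, data=np.asarray(values, dtype=np.float64))
    elif path.suffix == ".npz":
        meta = json.dumps({"model_name": model_name, "layout": layout, "dim": dim})
        np.savez(path, **{_NPZ_META_KEY: np.array(meta)}, **arrays)
    else:
        raise SchemaError(f"unsupported store suffix {path.suffix!r} (use .h5/.hdf5/.npz)")


def _load_arrays(path) -> tuple[dict, dict[str, np.ndarray]]:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as handle:
            meta = {k: handle.attrs[k] for k in ("model_name", "layout", "dim")
                    if k in handle.attrs}
            arrays = {key: np.asarray(handle[key]) for key in handle.keys()}
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as handle:
            if _NPZ_META_KEY not in handle:
                raise SchemaError(f"{path}: missing store metadata")
            meta = json.loads(str(handle[_NPZ_META_KEY]))
            arrays = {k: handle[k] for k in handle.files if k != _NPZ_META_KEY}
    else:
        raise SchemaError(f"unsupported store suffix {path.suffix!r} (use .h5/.hdf5/.npz)")
    if "layout" not in meta:
        raise SchemaError(f"{path}: store metadata lacks 'layout'")
    if meta["layout"] not in LAYOUTS:
        raise SchemaError(f"{path}: unknown layout {meta['layout']!r}")
    return meta, arrays


def load_embedding_matrices(path) -> tuple[str, dict[str, EmbeddingMatrix]]:
    """Load a per-residue store as raw matrices."""
    meta, arrays = _load_arrays(path)
    if meta["layout"] != "per_residue":
        raise SchemaError(f"{path}: layout is {meta['layout']!r}, not per_residue")
    name = str(meta.get("model_name", "unknown"))
    return name, {k: EmbeddingMatrix(k, v) for k, v in arrays.items()}


def load_representation_store(path, pool_if_needed: bool = True) -> RepresentationStore:
    """Load a store; mean-pool per-residue matrices when ``pool_if_needed``."""
    meta, arrays = _load_arrays(path)
    name = str(meta.get("model_name", "unknown"))
    if meta["layout"] == "per_residue":
        if not pool_if_needed:
            raise SchemaError(
                f"{path}: per-residue store; pass pool_if_needed=True or use "
                "load_embedding_matrices"
            )
        vectors = {k: pool_mean(EmbeddingMatrix(k, v)).vector for k, v in arrays.items()}
    else:
        bad = [k for k, v in arrays.items() if np.asarray(v).ndim != 1]
        if bad:
            raise SchemaError(f"{path}: pooled store holds non-vector datasets {bad[:5]}")
        vectors = arrays
    return RepresentationStore(name, vectors)
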