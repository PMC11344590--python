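"""Synthetic SCOP-like hierarchies, sequences and embeddings.

The generator builds a balanced Class -> Fold -> Superfamily -> Family ->
domain hierarchy and draws embeddings from an additive hierarchical Gaussian
model: each fold, superfamily and family owns an independent standard-normal
centroid in R^D, and a domain's pooled vector is

    p = w_fold * c_fold + w_sf * c_superfamily + w_family * c_family + eps,

with per-domain noise ``eps ~ N(0, noise_sd^2 I)``.  Tuning the weights
against the noise controls how strongly cosine proximity encodes each level
of the hierarchy, which is exactly the assumption a retrieval benchmark over
embeddings probes.  A uniform-random baseline (vectors of i.i.d. U[0,1)
entries, length 150 by default) provides the null model.

Sequences are, by default, uncorrelated with the hierarchy — the embeddings,
not the sequences, carry the signal.  Setting
``family_sequence_similarity > 0`` instead mutates a per-family template so
that within-family sequence identity is controllable (used to exercise the
toy identity filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .representations import EmbeddingMatrix, RepresentationStore
from .scop import ClassificationPath, DomainDatabase, DomainRecord

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_CLASS_LETTERS = "abcdefg"


@dataclass(frozen=True)
class HierarchySpec:
    """Shape of a balanced synthetic hierarchy; total domains is the product."""

    n_folds: int
    superfamilies_per_fold: int
    families_per_superfamily: int
    domains_per_family: int
    seed: int = 0
    min_length: int = 50
    max_length: int = 200
    family_sequence_similarity: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_folds", "superfamilies_per_fold",
                     "families_per_superfamily", "domains_per_family"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 1 <= self.min_length <= self.max_length:
            raise ParameterError("require 1 <= min_length <= max_length")
        if not 0.0 <= self.family_sequence_similarity <= 1.0:
            raise ParameterError("family_sequence_similarity must be in [0, 1]")

    @property
    def n_domains(self) -> int:
        return (self.n_folds * self.superfamilies_per_fold
                * self.families_per_superfamily * self.domains_per_family)


@dataclass(frozen=True)
class SignalSpec:
    """Embedding dimension, per-level signal weights and noise level."""

    dim: int
    fold_weight: float = 0.0
    superfamily_weight: float = 0.0
    family_weight: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ParameterError("dim must be >= 2")
        weights = (self.fold_weight, self.superfamily_weight,
                   self.family_weight, self.noise_sd)
        if any(w < 0 for w in weights):
            raise ParameterError("weights and noise_sd must be non-negative")
        if all(w == 0 for w in weights):
            raise ParameterError("at least one weight or noise_sd must be positive")


def generate_hierarchy(spec: HierarchySpec) -> DomainDatabase:
    """Generate a balanced synthetic domain database.

    Fold ``j`` (0-based) is filed under class letter ``"abcdefg"[j % 7]`` with
    a globally unique fold number, so sccs paths enumerate the hierarchy
    systematically (``a.1.1.1``, ``a.1.1.2``, ..., ``b.2.1.1``, ...).  Domain
    ids are sequential (``syn00000``, ``syn00001``, ...).  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[DomainRecord] = []
    counter = 0
    for j in range(spec.n_folds):
        class_id = _CLASS_LETTERS[j % len(_CLASS_LETTERS)]
        fold_id = f"{class_id}.{j + 1}"
        for s in range(1, spec.superfamilies_per_fold + 1):
            sf_id = f"{fold_id}.{s}"
            for f in range(1, spec.families_per_superfamily + 1):
                family_id = f"{sf_id}.{f}"
                template = None
                if spec.family_sequence_similarity > 0.0:
                    length = int(rng.integers(spec.min_length, spec.max_length + 1))
                    template = rng.choice(_AMINO_ACIDS, size=length)
                path = ClassificationPath(class_id, fold_id, sf_id, family_id)
                for _ in range(spec.domains_per_family):
                    records.append(
                        DomainRecord(
                            domain_id=f"syn{counter:05d}",
                            classification=path,
                            sequence=_draw_sequence(rng, spec, template),
                            description=f"synthetic domain in family {family_id}",
                        )
                    )
                    counter += 1
    return DomainDatabase(tuple(records))


def _draw_sequence(rng, spec: HierarchySpec, template) -> str:
    if template is None:
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        return "".join(rng.choice(_AMINO_ACIDS, size=length))
    mutate = rng.random(template.size) >= spec.family_sequence_similarity
    seq = template.copy()
    seq[mutate] = rng.choice(_AMINO_ACIDS, size=int(mutate.sum()))
    return "".join(seq)


def _centroids(db: DomainDatabase, signal: SignalSpec, rng) -> dict[str, np.ndarray]:
    """Draw one centroid per fold, superfamily and family, in sorted order.

    Centroids for every level are drawn before any per-domain noise and in a
    fixed (sorted) order, so two SignalSpecs differing only in their weights
    share centroids and noise for the same seed.
    """
    folds = sorted({r.classification.fold_id for r in db})
    sfs = sorted({r.classification.superfamily_id for r in db})
    families = sorted({r.classification.family_id for r in db})
    centroids = {}
    for key in folds + sfs + families:
        centroids[key] = rng.standard_normal(signal.dim)
    return centroids


def generate_embeddings(db: DomainDatabase, signal: SignalSpec) -> RepresentationStore:
    """Draw pooled per-domain vectors from the additive centroid model."""
    rng = np.random.default_rng(signal.seed)
    centroids = _centroids(db, signal, rng)
    vectors = {}
    for rec in db:
        cls = rec.classification
        noise = rng.standard_normal(signal.dim) * signal.noise_sd
        vectors[rec.domain_id] = (
            signal.fold_weight * centroids[cls.fold_id]
            + signal.superfamily_weight * centroids[cls.superfamily_id]
            + signal.family_weight * centroids[cls.family_id]
            + noise
        )
    return RepresentationStore("synthetic-signal", vectors)


def generate_per_residue_embeddings(
    db: DomainDatabase, signal: SignalSpec, residue_noise_sd: float = 0.0
) -> dict[str, EmbeddingMatrix]:
    """Per-residue matrices whose mean pooling recovers the pooled vectors.

    Each domain's ``l x D`` matrix is its pooled-target vector broadcast over
    the ``l`` residues of its sequence plus independent per-residue noise, so
    the pooled estimate converges to the target at rate ``1/sqrt(l)``.
    """
    if residue_noise_sd < 0:
        raise ParameterError("residue_noise_sd must be non-negative")
    pooled = generate_embeddings(db, signal)
    rng = np.random.default_rng([signal.seed, 104729])
    matrices = {}
    for rec in db:
        length = len(rec.sequence)
        target = pooled[rec.domain_id]
        noise = rng.standard_normal((length, signal.dim)) * residue_noise_sd
        matrices[rec.domain_id] = EmbeddingMatrix(rec.domain_id, target[None, :] + noise)
    return matrices


def generate_random_representations(
    ids, length: int = 150, seed: int = 0
) -> RepresentationStore:
    """Uniform-random baseline: one i.i.d. U[0,1) vector per domain id.

    Length 150 matches the standard random-baseline construction for
    zero-shot retrieval; any fixed bounded support is equivalent under
    rank-based metrics.
    """
    ids = list(ids)
    if not ids:
        raise ParameterError("ids must be non-empty")
    if length < 2:
        raise ParameterError("length must be >= 2")
    rng = np.random.default_rng(seed)
    values = rng.random((len(ids), length))
    return RepresentationStore("random", {i: values[k] for k, i in enumerate(ids)})
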