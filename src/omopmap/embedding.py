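"""Text embeddings behind a provider contract, plus a precomputed concept index.

The original concept-mapping workflow relies on an external large-language-model
embedding service.  That service is neither deterministic across time nor
usable offline, so the package defines a narrow provider contract
(:class:`EmbeddingProvider`) and ships a fully deterministic reference
implementation, :class:`HashedNgramEmbedder`: normalized text is padded with
boundary markers, decomposed into character 3-grams, each 3-gram is hashed with
a seeded keyed hash to a coordinate bucket and a sign, contributions are
accumulated and the vector L2-normalized.  Hashed character n-grams are the
classic fastText/Vowpal-Wabbit trick: identical strings map to identical unit
vectors, near-identical strings to nearby ones, and everything is reproducible
from (dimension, seed) alone.

An :class:`EmbeddingIndex` precomputes one vector per concept name so that a
query embeds once and is scored against the whole vocabulary with a single
matrix product.  Indexes persist to disk with a self-describing header;
loading refuses an index whose provider configuration differs from the
session's, which prevents silently comparing vectors from different providers.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, runtime_checkable

import numpy as np

from omopmap.errors import ContractError, InputError
from omopmap.matcher import NORMALIZATION_SPEC, normalize_term
from omopmap.vocabulary import ConceptCollection


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Anything that turns text into a fixed-length unit-norm vector."""

    provider_id: str
    dimension: int

    def embed(self, text: str) -> np.ndarray: ...

    def config_header(self) -> dict: ...


class HashedNgramEmbedder:
    """Deterministic seeded character-3-gram hashing embedder.

    Parameters
    ----------
    dimension
        Length of the output vectors (default 512).
    seed
        Seed mixed into the keyed hash; identical (dimension, seed, text)
        always yields a bit-identical vector (default 42).

    Empty or whitespace-only text embeds to the zero vector (with a warning);
    all other text embeds to an exactly unit-norm vector.
    """

    PROVIDER_ID = "hashed-ngram-v1"
    NGRAM = 3
    BOUNDARY = "\x01"

    def __init__(self, dimension: int = 512, seed: int = 42):
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        self.provider_id = self.PROVIDER_ID
        self.dimension = dimension
        self.seed = seed
        self._key = str(seed).encode("utf-8")
        self._gram_cache: dict[str, tuple[int, float]] = {}

    def _hash_gram(self, gram: str) -> tuple[int, float]:
        cached = self._gram_cache.get(gram)
        if cached is None:
            digest = hashlib.blake2b(gram.encode("utf-8"), key=self._key, digest_size=8).digest()
            value = int.from_bytes(digest, "big")
            bucket = (value >> 1) % self.dimension
            sign = 1.0 if value & 1 else -1.0
            cached = (bucket, sign)
            self._gram_cache[gram] = cached
        return cached

    def embed(self, text: str) -> np.ndarray:
        normalized = normalize_term(text)
        vec = np.zeros(self.dimension, dtype=np.float64)
        if not normalized:
            warnings.warn("embedding empty text: returning the zero vector", stacklevel=2)
            return vec
        padded = self.BOUNDARY + normalized + self.BOUNDARY
        for i in range(len(padded) - self.NGRAM + 1):
            bucket, sign = self._hash_gram(padded[i : i + self.NGRAM])
            vec[bucket] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec

    def config_header(self) -> dict:
        return {
            "provider_id": self.provider_id,
            "dimension": self.dimension,
            "seed": self.seed,
            "normalization_spec": NORMALIZATION_SPEC,
        }


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two embedding vectors, in [-1, 1].

    Vectors from providers honoring the unit-norm contract make this the plain
    inner product; non-unit input is normalized defensively.  If either vector
    is zero the similarity is defined as 0.0 with a warning.  Mismatched
    dimensions are a caller error.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ContractError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("cosine similarity with a zero vector is defined as 0.0", stacklevel=2)
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


@dataclass
class EmbeddingIndex:
    """Precomputed embeddings over a concept collection.

    ``matrix`` holds one unit-norm row per concept, aligned with
    ``concept_ids``.  ``failures`` lists concept_ids the provider could not
    embed (e.g. names that normalize to the empty string); those rows are
    zero vectors and never outrank a real candidate.
    """

    provider_id: str
    dimension: int
    seed: int
    normalization_spec: str
    concept_ids: np.ndarray  # shape (n,), int64
    matrix: np.ndarray  # shape (n, dimension), float64
    failures: list[int] = field(default_factory=list)
    provider: Optional[EmbeddingProvider] = None

    def __len__(self) -> int:
        return len(self.concept_ids)

    def vector_for(self, concept_id: int) -> np.ndarray:
        pos = np.flatnonzero(self.concept_ids == concept_id)
        if pos.size == 0:
            raise KeyError(f"concept_id {concept_id} not in index")
        return self.matrix[pos[0]]

    def similarities(self, query_vector: np.ndarray) -> np.ndarray:
        """Cosine similarity of one query vector against every indexed concept."""
        q = np.asarray(query_vector, dtype=np.float64)
        if q.shape != (self.dimension,):
            raise ContractError(f"query dimension {q.shape} != index dimension {self.dimension}")
        return self.matrix @ q

    def header(self) -> dict:
        return {
            "provider_id": self.provider_id,
            "dimension": self.dimension,
            "seed": self.seed,
            "normalization_spec": self.normalization_spec,
        }

    def save(self, path: str | Path) -> None:
        """Persist as a single .npz with an embedded JSON header."""
        np.savez(
            Path(path),
            header=np.array(json.dumps(self.header())),
            concept_ids=self.concept_ids,
            matrix=self.matrix,
            failures=np.array(self.failures, dtype=np.int64),
        )


def build_index(collection: ConceptCollection, provider: EmbeddingProvider) -> EmbeddingIndex:
    """Embed the normalized name of every concept in the collection.

    A provider failure on an individual term is recorded in ``failures`` (the
    concept keeps a zero row) and the index is still returned.
    """
    if len(collection) == 0:
        raise ContractError("cannot build an index over an empty collection")
    ids = np.array([c.concept_id for c in collection], dtype=np.int64)
    matrix = np.zeros((len(ids), provider.dimension), dtype=np.float64)
    failures: list[int] = []
    for row, concept in enumerate(collection):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vec = provider.embed(concept.concept_name)
            if not np.any(vec):
                raise ValueError("zero vector")
            matrix[row] = vec
        except Exception:
            failures.append(int(ids[row]))
    header = provider.config_header()
    return EmbeddingIndex(
        provider_id=header["provider_id"],
        dimension=header["dimension"],
        seed=header.get("seed", 0),
        normalization_spec=header.get("normalization_spec", NORMALIZATION_SPEC),
        concept_ids=ids,
        matrix=matrix,
        failures=failures,
        provider=provider,
    )


def load_index(path: str | Path, provider: Optional[EmbeddingProvider] = None) -> EmbeddingIndex:
    """Reload a persisted index, verifying its header against the session provider.

    If ``provider`` is omitted and the header names the reference provider,
    the provider is reconstructed from the header so queries can be embedded.
    A header mismatch (different provider_id, dimension, or seed) is refused.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"index file not found: {path}")
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        concept_ids = data["concept_ids"]
        matrix = data["matrix"]
        failures = [int(x) for x in data["failures"]]

    if provider is None:
        if header["provider_id"] != HashedNgramEmbedder.PROVIDER_ID:
            raise ContractError(
                f"index built with provider {header['provider_id']!r}; "
                "pass the matching provider to load_index"
            )
        provider = HashedNgramEmbedder(dimension=header["dimension"], seed=header["seed"])
    else:
        session = provider.config_header()
        for key in ("provider_id", "dimension", "seed"):
            if key in session and session.get(key) != header.get(key):
                raise ContractError(
                    f"index header {key}={header.get(key)!r} does not match "
                    f"session provider {key}={session.get(key)!r}; refusing to query"
                )

    return EmbeddingIndex(
        provider_id=header["provider_id"],
        dimension=header["dimension"],
        seed=header["seed"],
        normalization_spec=header["normalization_spec"],
        concept_ids=concept_ids,
        matrix=matrix,
        failures=failures,
        provider=provider,
    )
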