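"""Term-level embedding backends and an exhaustive cosine-similarity index.

Ontology terms are embedded one string at a time: each concept contributes a
family of vectors, one for its primary label and one per synonym, every vector
carrying a ``(text, url)`` payload so retrieval hits remain traceable to their
concept.  Retrieval is an exact top-k scan under cosine similarity — at
desk scale (tens of thousands of terms) approximate-nearest-neighbour
structures buy nothing, so none are used.

Two backends are provided.  :class:`HashedNgramEmbedder` is a fully offline,
deterministic embedder (hashed character n-gram frequencies, L2-normalized)
used by all tests and fixtures.  :class:`RemoteEmbeddingBackend` adapts an
OpenAI-style embeddings endpoint (ada-002 vectors, d=1536) behind the same
contract; it needs network credentials and is never exercised by the test
suite.
"""

from __future__ import annotations

import hashlib
import json
import os
import urllib.request
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ontology import OntologyConcept

__all__ = [
    "EmbeddingBackend",
    "HashedNgramEmbedder",
    "RemoteEmbeddingBackend",
    "TermVector",
    "VectorIndex",
    "RetrievalHit",
    "cosine",
    "build_index",
    "search_topk",
]


class EmbeddingBackend(ABC):
    """Contract: map a non-empty text string to a real vector of fixed length.

    Within one backend instance the same input text must always yield the
    identical vector.
    """

    name: str
    dimension: int

    @abstractmethod
    def embed(self, text: str) -> np.ndarray:
        """Embed one string; raises ValueError on empty/blank input."""


class HashedNgramEmbedder(EmbeddingBackend):
    """Deterministic offline embedder: hashed character n-gram frequencies.

    Lowercased text is padded and decomposed into character n-grams; each
    n-gram is hashed with a keyed BLAKE2 digest (so vectors are bit-identical
    across processes and runs, independent of PYTHONHASHSEED) into one of
    ``dimension`` buckets with a ±1 sign, and the bucket-count vector is
    L2-normalized.  Strings sharing word stems or differing by word order
    land near each other under cosine, which is all the pipeline needs.
    """

    def __init__(self, dimension: int = 512, n: int = 3, seed: int = 0):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.name = f"hashed-ngram-{n}g-d{dimension}"
        self.dimension = dimension
        self.n = n
        self.seed = seed
        self._key = str(seed).encode()

    def _bucket(self, gram: str) -> tuple[int, float]:
        h = hashlib.blake2b(gram.encode("utf-8"), key=self._key, digest_size=8).digest()
        val = int.from_bytes(h, "big")
        sign = 1.0 if val & 1 else -1.0
        return (val >> 1) % self.dimension, sign

    def embed(self, text: str) -> np.ndarray:
        if text is None or not text.strip():
            raise ValueError("cannot embed an empty or blank string")
        s = " ".join(text.lower().split())
        padded = f"\x02{s}\x03"
        v = np.zeros(self.dimension, dtype=np.float64)
        grams = [padded[i : i + self.n] for i in range(max(1, len(padded) - self.n + 1))]
        # unigram words as well, so word swaps stay close
        grams.extend(s.split())
        for g in grams:
            idx, sign = self._bucket(g)
            v[idx] += sign
        norm = np.linalg.norm(v)
        if norm == 0.0:  # pragma: no cover - needs pathological hash collisions
            v[0] = 1.0
            norm = 1.0
        return v / norm


class RemoteEmbeddingBackend(EmbeddingBackend):
    """Adapter for an OpenAI-style ``/embeddings`` endpoint (e.g. ada-002).

    Credentials come from the environment (``ONTOMAP_EMBED_API_KEY``).  This
    adapter fulfils the same contract as the offline embedder; it is the
    integration point for production runs and is not used in tests.
    """

    def __init__(
        self,
        endpoint: str = "https://api.openai.com/v1/embeddings",
        model: str = "text-embedding-ada-002",
        dimension: int = 1536,
        api_key_env: str = "ONTOMAP_EMBED_API_KEY",
        timeout: float = 30.0,
        max_retries: int = 2,
    ):
        self.name = f"remote:{model}"
        self.dimension = dimension
        self.endpoint = endpoint
        self.model = model
        self.api_key_env = api_key_env
        self.timeout = timeout
        self.max_retries = max_retries

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - network
        if text is None or not text.strip():
            raise ValueError("cannot embed an empty or blank string")
        key = os.environ.get(self.api_key_env)
        if not key:
            raise RuntimeError(f"set {self.api_key_env} to use the remote embedding backend")
        body = json.dumps({"model": self.model, "input": text}).encode()
        last_err: Exception | None = None
        for _ in range(self.max_retries + 1):
            req = urllib.request.Request(
                self.endpoint,
                data=body,
                headers={"Content-Type": "application/json", "Authorization": f"Bearer {key}"},
            )
            try:
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    payload = json.loads(resp.read())
                vec = np.asarray(payload["data"][0]["embedding"], dtype=np.float64)
                if vec.shape != (self.dimension,):
                    raise RuntimeError(
                        f"backend returned dimension {vec.shape}, expected {self.dimension}"
                    )
                return vec
            except Exception as err:  # noqa: BLE001 - retried then re-raised
                last_err = err
        raise RuntimeError(f"embedding failed for text {text!r}: {last_err}")


@dataclass(frozen=True)
class TermVector:
    """One embedded label/synonym with its (text, url) payload."""

    vector: np.ndarray
    payload_text: str
    payload_url: str


@dataclass(frozen=True)
class RetrievalHit:
    term: TermVector
    score: float
    rank: int


class VectorIndex:
    """In-process exhaustive cosine index over term vectors.

    Stores one row per term with a ``(text, url)`` payload and, as side
    metadata, each concept's primary label (so retrieval results can present
    the concept label even when a synonym matched).
    """

    def __init__(self, dimension: int):
        self.dimension = dimension
        self._vectors: list[np.ndarray] = []
        self.payloads: list[tuple[str, str]] = []
        self.labels: dict[str, str] = {}
        self._matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.payloads)

    def add(self, term: TermVector) -> None:
        if term.vector.shape != (self.dimension,):
            raise ValueError(
                f"vector of dimension {term.vector.shape} in index of dimension {self.dimension}"
            )
        if not term.payload_text:
            raise ValueError("payload_text must be non-empty")
        self._vectors.append(np.asarray(term.vector, dtype=np.float64))
        self.payloads.append((term.payload_text, term.payload_url))
        self._matrix = None

    @property
    def entries(self) -> list[TermVector]:
        return [
            TermVector(vector=v, payload_text=t, payload_url=u)
            for v, (t, u) in zip(self._vectors, self.payloads)
        ]

    def _unit_matrix(self) -> np.ndarray:
        if self._matrix is None:
            m = np.vstack(self._vectors) if self._vectors else np.empty((0, self.dimension))
            norms = np.linalg.norm(m, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError("index contains a zero-norm vector")
            self._matrix = m / norms
        return self._matrix

    # --- serialization: JSON lines, one entry per line -------------------

    def save(self, path: str | Path) -> None:
        """Write the index as JSONL: a header line, then one entry per line."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(json.dumps({"dimension": self.dimension, "labels": self.labels}) + "\n")
            for vec, (text, url) in zip(self._vectors, self.payloads):
                fh.write(
                    json.dumps({"vector": vec.tolist(), "payload": {"text": text, "url": url}})
                    + "\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "VectorIndex":
        path = Path(path)
        with path.open() as fh:
            header = json.loads(fh.readline())
            index = cls(dimension=int(header["dimension"]))
            index.labels = dict(header.get("labels", {}))
            for line in fh:
                rec = json.loads(line)
                index.add(
                    TermVector(
                        vector=np.asarray(rec["vector"], dtype=np.float64),
                        payload_text=rec["payload"]["text"],
                        payload_url=rec["payload"]["url"],
                    )
                )
        return index


def cosine(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine similarity u·v / (||u|| ||v||); raises on zero-norm input."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))


def build_index(
    concepts: Iterable[OntologyConcept], backend: EmbeddingBackend
) -> VectorIndex:
    """Embed every primary label and every synonym of every concept.

    Each concept yields a family of vectors — one per term — all sharing the
    concept identifier in their payload, so the index size equals
    Σ(1 + |synonyms|) over concepts.
    """
    index = VectorIndex(dimension=backend.dimension)
    n = 0
    for concept in concepts:
        n += 1
        index.labels[concept.concept_id] = concept.label
        for term in concept.terms:
            try:
                vec = backend.embed(term)
            except ValueError:
                raise
            except Exception as err:
                raise RuntimeError(f"embedding failed for term {term!r}: {err}") from err
            index.add(TermVector(vector=vec, payload_text=term, payload_url=concept.concept_id))
    if n == 0:
        raise ValueError("no concepts to index")
    return index


def search_topk(index: VectorIndex, query: Sequence[float], k: int) -> list[RetrievalHit]:
    """Exact top-k retrieval by cosine similarity.

    Returns ``min(k, len(index))`` hits sorted by non-increasing score; equal
    scores are ordered by ``(payload_url, payload_text)`` lexicographically so
    runs are reproducible.  Scores are quantized to 12 decimals before ranking
    (and reported as such): BLAS may evaluate identical rows through different
    SIMD code paths, so without quantization duplicate vectors can differ in
    the last ulp and dodge the deterministic tie-break.  An empty index yields
    an empty result.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(index) == 0:
        return []
    q = np.asarray(query, dtype=np.float64)
    if q.shape != (index.dimension,):
        raise ValueError(f"query dimension {q.shape} does not match index dimension {index.dimension}")
    qnorm = np.linalg.norm(q)
    if qnorm == 0.0:
        raise ValueError("query vector has zero norm")
    scores = np.round(index._unit_matrix() @ (q / qnorm), 12)
    order = sorted(
        range(len(index)),
        key=lambda i: (-scores[i], index.payloads[i][1], index.payloads[i][0]),
    )
    hits = []
    entries = index.entries
    for rank, i in enumerate(order[: min(k, len(index))], start=1):
        hits.append(RetrievalHit(term=entries[i], score=float(scores[i]), rank=rank))
    return hits
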