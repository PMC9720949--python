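"""Pluggable fixed-length sequence-embedding providers.

Four protein-language-model descriptor families are declared with their
published dimensionalities (UniRep 1900, TAPE 768, ESM-1b/ESM-1v 1280);
their pretrained weights are optional external adapters registered at run
time.  A deterministic ``mock`` provider (a pure hash-seeded function of
the sequence) is always available and stands in for tests and offline runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import FeatureError, ProviderUnavailable
from .seqfeat import FeatureVector

UNIREP_BASE_DIM = 1900

_KNOWN_POOLING = ("mean-hidden", "unirep-concat")


@dataclass(frozen=True)
class EmbeddingSpec:
    """Provider name, output dimensionality, and pooling rule."""

    name: str
    dim: int
    pooling: str = "mean-hidden"

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        if self.pooling not in _KNOWN_POOLING:
            raise ValueError(f"unknown pooling {self.pooling!r}")


def spec_for(name: str, mock_dim: int = 8, unirep_parts: int = 1) -> EmbeddingSpec:
    """Canonical spec per provider.  ``unirep_parts`` encodes the UniRep
    concatenation rule (1 = averaged hidden states only, 3 = average +
    final hidden + final cell)."""
    if name == "unirep":
        return EmbeddingSpec("unirep", UNIREP_BASE_DIM * unirep_parts, "unirep-concat")
    if name == "tape":
        return EmbeddingSpec("tape", 768)
    if name in ("esm1b", "esm1v"):
        return EmbeddingSpec(name, 1280)
    if name == "mock":
        return EmbeddingSpec("mock", mock_dim)
    raise ValueError(f"unknown provider {name!r}")


# adapter registry: name -> callable(seq, spec) -> vector
_ADAPTERS: dict[str, Callable[[str, EmbeddingSpec], np.ndarray]] = {}


def register_adapter(
    name: str, fn: Callable[[str, EmbeddingSpec], np.ndarray]
) -> None:
    _ADAPTERS[name] = fn


def _mock_embed(seq: str, spec: EmbeddingSpec) -> np.ndarray:
    digest = hashlib.sha256(
        f"{spec.name}:{spec.dim}:{seq}".encode()
    ).digest()
    seed = int.from_bytes(digest[:4], "big")
    rng = np.random.default_rng(seed)
    return rng.standard_normal(spec.dim)


def embed(seq: str, spec: EmbeddingSpec) -> np.ndarray:
    """Fixed-length embedding of one sequence; deterministic per (seq, spec)."""
    if spec.name == "mock":
        vec = _mock_embed(seq, spec)
    elif spec.name in _ADAPTERS:
        vec = np.asarray(_ADAPTERS[spec.name](seq, spec), dtype=float)
    else:
        raise ProviderUnavailable(
            f"no adapter registered for provider {spec.name!r}"
        )
    if vec.shape != (spec.dim,):
        raise FeatureError(
            f"provider {spec.name!r} returned shape {vec.shape}, "
            f"expected ({spec.dim},)"
        )
    return vec


def concat_features(f46: FeatureVector, emb: np.ndarray, provider: str) -> FeatureVector:
    """Append a namespaced embedding block after the biochemical block."""
    emb = np.asarray(emb, dtype=float)
    if emb.ndim != 1:
        raise FeatureError("embedding must be a 1-D vector")
    if emb.size == 0:
        return f46
    emb_names = [f"emb_{provider}_{i}" for i in range(emb.size)]
    clash = set(emb_names) & set(f46.names)
    if clash:
        raise FeatureError(f"feature name collision: {sorted(clash)[:3]}")
    provenance = dict(f46.provenance)
    provenance.update({n: "embedding" for n in emb_names})
    return FeatureVector(
        names=list(f46.names) + emb_names,
        values=np.concatenate([f46.values, emb]),
        provenance=provenance,
        complete=f46.complete,
    )


def embedding_table(
    ids: list[str], seqs: list[str], spec: EmbeddingSpec
) -> pd.DataFrame:
    """Embed many sequences into a cacheable id-indexed table."""
    rows = np.stack([embed(s, spec) for s in seqs])
    cols = [f"emb_{spec.name}_{i}" for i in range(spec.dim)]
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=cols)
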