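"""Compound and confounder condition embeddings.

The compound embedder is a deterministic hashed character n-gram encoder
over SMILES strings: structurally similar compounds (shared substructure
tokens) receive similar vectors, and any string — including compounds never
seen during training — is embeddable. This preserves the conditioning
contract a pretrained molecular language model provides, without external
weights.

Confounder embeddings map categorical ids (source, plate-level batch, well
position, field of view) through fixed per-table vectors; their
concatenation with the compound vector forms the context the generator is
conditioned on. MoA/target labels and hidden phenotypes are absent from
this context by construction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .scm import ConfounderAssignment
from .utils import as_rng


def _ngram_index(ngram: str, dim: int) -> tuple[int, float]:
    """Stable hash of an n-gram to (bucket, sign); independent of PYTHONHASHSEED."""
    h = hashlib.blake2b(ngram.encode(), digest_size=8).digest()
    value = int.from_bytes(h, "little")
    return value % dim, 1.0 if (value >> 63) & 1 else -1.0


def embed_compound(smiles: str, dim: int = 64) -> np.ndarray:
    """L2-normalized hashed character n-gram (n in {2, 3}) count embedding."""
    if not isinstance(smiles, str) or len(smiles) == 0:
        raise ValueError("smiles must be a non-empty string")
    vec = np.zeros(dim)
    for n in (2, 3):
        if len(smiles) < n:
            # pad so very short strings still produce a defined vector
            grams = [smiles.ljust(n, "_")]
        else:
            grams = [smiles[i : i + n] for i in range(len(smiles) - n + 1)]
        for g in grams:
            idx, sign = _ngram_index(g, dim)
            vec[idx] += sign
    norm = np.linalg.norm(vec)
    if norm == 0:  # all counts cancelled; fall back to a deterministic unit vector
        idx, _ = _ngram_index(smiles, dim)
        vec[idx] = 1.0
        norm = 1.0
    return vec / norm


@dataclass
class EmbeddingTables:
    """Fixed per-category embedding tables keyed by string id.

    Vocabularies are frozen at construction (training time); looking up an
    id outside a vocabulary raises — generation for unseen confounder
    levels is refused rather than silently remapped.
    """

    source: dict[str, np.ndarray]
    batch: dict[str, np.ndarray]
    well: dict[str, np.ndarray]
    fov: dict[str, np.ndarray]

    @classmethod
    def build(
        cls,
        sources: list[str],
        batches: list[str],
        wells: list[str],
        fovs: list[str],
        dims: tuple[int, int, int, int] = (4, 8, 4, 2),
        seed: int | np.random.Generator = 0,
    ) -> "EmbeddingTables":
        rng = as_rng(seed)

        def table(ids, dim):
            return {
                i: rng.standard_normal(dim) / np.sqrt(dim) for i in sorted(set(ids))
            }

        return cls(
            source=table(sources, dims[0]),
            batch=table(batches, dims[1]),
            well=table(wells, dims[2]),
            fov=table(fovs, dims[3]),
        )

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return tuple(
            next(iter(t.values())).size for t in (self.source, self.batch, self.well, self.fov)
        )

    def vocabularies(self) -> dict[str, list[str]]:
        return {
            "source": sorted(self.source),
            "batch": sorted(self.batch),
            "well": sorted(self.well),
            "fov": sorted(self.fov),
        }


@dataclass
class ConditionEmbedding:
    """The five condition vectors and their concatenation (the cross-model context)."""

    compound_vec: np.ndarray
    source_vec: np.ndarray
    batch_vec: np.ndarray
    well_vec: np.ndarray
    fov_vec: np.ndarray

    @property
    def context(self) -> np.ndarray:
        return np.concatenate(
            [self.compound_vec, self.source_vec, self.batch_vec, self.well_vec, self.fov_vec]
        )


def embed_confounders(
    assignment: ConfounderAssignment,
    tables: EmbeddingTables,
    compound_vec: np.ndarray | None = None,
) -> ConditionEmbedding:
    """Look up the condition vectors for one confounder assignment.

    The batch table is sized at plate granularity (each plate is its own
    batch for conditioning purposes), so ``assignment.plate_id`` keys the
    batch table.
    """

    def lookup(table, key, name):
        try:
            return table[key]
        except KeyError:
            raise KeyError(f"unknown {name} id {key!r}; not in embedding vocabulary")

    return ConditionEmbedding(
        compound_vec=np.zeros(0) if compound_vec is None else np.asarray(compound_vec, float),
        source_vec=lookup(tables.source, assignment.source_id, "source"),
        batch_vec=lookup(tables.batch, assignment.plate_id, "batch"),
        well_vec=lookup(tables.well, assignment.well_name, "well"),
        fov_vec=lookup(tables.fov, str(assignment.fov_index), "fov"),
    )
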