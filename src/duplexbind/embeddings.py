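"""Fixed-dimension structure embeddings for ligands and proteins.

The binding scorer consumes 300-d ligand vectors and 100-d protein vectors
through a provider contract: any object with ``side``, ``dimension`` and a
deterministic ``embed(structure) -> vector``.  Externally pre-trained
embedding tables (word2vec-style models trained on large chemical/protein
corpora) plug in via :class:`TableEmbedding`; the default providers are
self-contained hashed n-gram embeddings: token counts (character 2-4-grams
of a SMILES string; overlapping amino-acid trigrams of a sequence) hashed
into a fixed number of buckets and L2-normalised.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HashedLigandEmbedding",
    "HashedProteinEmbedding",
    "TableEmbedding",
    "read_embedding_table",
    "AMINO_ACIDS",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
# ambiguous/rare residue codes collapse to a single wildcard token
_WILDCARDS = set("XUBZ")


def _bucket(token: str, dimension: int, hash_seed: int) -> int:
    digest = hashlib.blake2b(
        token.encode("utf-8"), digest_size=8, salt=hash_seed.to_bytes(8, "little")
    ).digest()
    return int.from_bytes(digest, "little") % dimension


class HashedLigandEmbedding:
    """Character n-gram (n=2..4) hashing embedding for SMILES strings."""

    side = "ligand"

    def __init__(self, dimension: int = 300, hash_seed: int = 17):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        self.hash_seed = hash_seed

    def embed(self, smiles: str) -> np.ndarray:
        if not smiles:
            raise ValueError("empty ligand structure string")
        vec = np.zeros(self.dimension)
        for n in (2, 3, 4):
            for i in range(max(len(smiles) - n + 1, 0)):
                vec[_bucket(smiles[i : i + n], self.dimension, self.hash_seed)] += 1.0
        if not vec.any():  # strings shorter than the smallest n-gram
            vec[_bucket(smiles, self.dimension, self.hash_seed)] += 1.0
        return vec / np.linalg.norm(vec)


class HashedProteinEmbedding:
    """Overlapping amino-acid trigram hashing embedding.

    Exposes the count pipeline (``trigrams``/``trigram_counts``/
    ``embed_from_counts``) so single-trigram perturbations can be applied to
    the counts before re-embedding.
    """

    side = "protein"

    def __init__(self, dimension: int = 100, hash_seed: int = 23):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        self.hash_seed = hash_seed

    def _canonical(self, sequence: str) -> str:
        seq = sequence.upper()
        out = []
        for ch in seq:
            if ch in AMINO_ACIDS:
                out.append(ch)
            elif ch in _WILDCARDS:
                out.append("X")
            else:
                raise ValueError(f"illegal amino-acid character {ch!r}")
        if len(out) < 3:
            raise ValueError("sequence must contain at least 3 residues")
        return "".join(out)

    def trigrams(self, sequence: str) -> list[str]:
        """Stride-1 trigram token at each start position (length n-2)."""
        seq = self._canonical(sequence)
        return [seq[i : i + 3] for i in range(len(seq) - 2)]

    def trigram_counts(self, sequence: str) -> Counter:
        return Counter(self.trigrams(sequence))

    def embed_from_counts(self, counts: Mapping[str, float]) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for token, c in counts.items():
            if c:
                vec[_bucket(token, self.dimension, self.hash_seed)] += float(c)
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def embed(self, sequence: str) -> np.ndarray:
        return self.embed_from_counts(self.trigram_counts(sequence))


class TableEmbedding:
    """Embedding lookup for externally computed vectors (id -> vector).

    Unknown identifiers map to the table's mean vector (a reserved slot)
    rather than failing.
    """

    def __init__(self, table: Mapping[str, np.ndarray], side: str):
        if not table:
            raise ValueError("empty embedding table")
        self.side = side
        self._table = {k: np.asarray(v, dtype=float) for k, v in table.items()}
        dims = {v.size for v in self._table.values()}
        if len(dims) != 1:
            raise ValueError("inconsistent embedding dimensions in table")
        self.dimension = dims.pop()
        self._unknown = np.mean(list(self._table.values()), axis=0)

    def embed(self, identifier: str) -> np.ndarray:
        return self._table.get(identifier, self._unknown)


def read_embedding_table(path, side: str) -> TableEmbedding:
    """Read a TSV of id \\t v1 .. vd into a TableEmbedding."""
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return TableEmbedding({str(k): row.to_numpy() for k, row in df.iterrows()}, side)
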