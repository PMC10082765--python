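"""Signed (duplex) bipartite annotation networks.

A duplex network holds protein-ligand annotations in two layers: a positive
layer of binding annotations and a negative layer of non-binding annotations.
The joint state of a pair across both layers is a *multilink*: (1,0) binding,
(0,1) non-binding, (0,0) unannotated.  The state (1,1) is forbidden because a
pair cannot simultaneously bind and not bind.

Ligands are keyed by opaque strings (typically InChIKeys) and proteins by
sequence accessions or FASTA header tokens; the model never interprets keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DuplexNetwork",
    "DegreeRecord",
    "DegreeStats",
    "ForbiddenMultilinkError",
    "ZeroTotalDegreeError",
    "degree_ratio",
    "multidegrees",
    "fit_power_law_exponent",
    "read_duplex_tsv",
    "write_duplex_tsv",
]

Edge = tuple[str, str]


class ForbiddenMultilinkError(ValueError):
    """A pair carries both a positive and a negative annotation."""


class ZeroTotalDegreeError(ValueError):
    """Degree ratio requested for a node without any annotation."""


@dataclass(frozen=True)
class DuplexNetwork:
    """Bipartite duplex network of signed protein-ligand annotations.

    Parameters
    ----------
    ligand_ids, protein_ids
        Ordered, unique node identifiers for each side.
    positive_edges, negative_edges
        Disjoint sets of (ligand_id, protein_id) pairs; every endpoint must
        be registered on the correct side.
    """

    ligand_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    positive_edges: frozenset[Edge]
    negative_edges: frozenset[Edge]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand_ids", tuple(self.ligand_ids))
        object.__setattr__(self, "protein_ids", tuple(self.protein_ids))
        object.__setattr__(self, "positive_edges", frozenset(self.positive_edges))
        object.__setattr__(self, "negative_edges", frozenset(self.negative_edges))
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise ValueError("duplicate ligand identifiers")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein identifiers")
        overlap = self.positive_edges & self.negative_edges
        if overlap:
            raise ForbiddenMultilinkError(
                f"pairs annotated both positive and negative: {sorted(overlap)[:5]}"
            )
        lig, prot = set(self.ligand_ids), set(self.protein_ids)
        for (l, p) in self.positive_edges | self.negative_edges:
            if l not in lig:
                raise ValueError(f"edge endpoint {l!r} is not a registered ligand")
            if p not in prot:
                raise ValueError(f"edge endpoint {p!r} is not a registered protein")

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        positive_edges: Iterable[Edge],
        negative_edges: Iterable[Edge],
        ligand_ids: Sequence[str] | None = None,
        protein_ids: Sequence[str] | None = None,
    ) -> "DuplexNetwork":
        """Build a network, inferring node sets from edges when not given."""
        pos = frozenset((str(l), str(p)) for l, p in positive_edges)
        neg = frozenset((str(l), str(p)) for l, p in negative_edges)
        if ligand_ids is None:
            ligand_ids = sorted({l for l, _ in pos} | {l for l, _ in neg})
        if protein_ids is None:
            protein_ids = sorted({p for _, p in pos} | {p for _, p in neg})
        return cls(tuple(ligand_ids), tuple(protein_ids), pos, neg)

    # -- basic counts ---------------------------------------------------

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_positive(self) -> int:
        """Number of positive annotations (L^+)."""
        return len(self.positive_edges)

    @property
    def n_negative(self) -> int:
        """Number of negative annotations (L^-)."""
        return len(self.negative_edges)

    def ligand_index(self) -> dict[str, int]:
        return {l: i for i, l in enumerate(self.ligand_ids)}

    def protein_index(self) -> dict[str, int]:
        return {p: j for j, p in enumerate(self.protein_ids)}

    def multidegree_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-node multidegrees as arrays (k_pos, k_neg, t_pos, t_neg).

        k_* are indexed by ligand order, t_* by protein order.
        """
        li, pi = self.ligand_index(), self.protein_index()
        k_pos = np.zeros(self.n_ligands, dtype=np.int64)
        k_neg = np.zeros(self.n_ligands, dtype=np.int64)
        t_pos = np.zeros(self.n_proteins, dtype=np.int64)
        t_neg = np.zeros(self.n_proteins, dtype=np.int64)
        for l, p in self.positive_edges:
            k_pos[li[l]] += 1
            t_pos[pi[p]] += 1
        for l, p in self.negative_edges:
            k_neg[li[l]] += 1
            t_neg[pi[p]] += 1
        return k_pos, k_neg, t_pos, t_neg

    def positive_only(self) -> "DuplexNetwork":
        """The network restricted to its binding (positive) layer."""
        return DuplexNetwork(self.ligand_ids, self.protein_ids, self.positive_edges, frozenset())


@dataclass(frozen=True)
class DegreeRecord:
    """Multidegree of one node: counts of positive and negative annotations."""

    node_id: str
    side: str  # "ligand" or "protein"
    k_pos: int
    k_neg: int

    @property
    def k_total(self) -> int:
        return self.k_pos + self.k_neg

    @property
    def rho(self) -> float:
        """Degree ratio k+/(k+ + k-); raises for isolated nodes."""
        return degree_ratio(self.k_pos, self.k_neg)


@dataclass(frozen=True)
class DegreeStats:
    """Power-law tail fit of a degree sequence (diagnostic, not inferential)."""

    gamma: float
    k_min: int
    n_tail: int


def degree_ratio(k_pos: int, k_neg: int) -> float:
    """Fraction of a node's annotations that are positive.

    The degree ratio rho = k+/(k+ + k-) quantifies annotation imbalance: values
    near 1 (0) mean a node is seen almost only binding (non-binding), which is
    the signal topology-driven models exploit as a shortcut.
    """
    if k_pos < 0 or k_neg < 0:
        raise ValueError("degrees must be non-negative")
    total = k_pos + k_neg
    if total == 0:
        raise ZeroTotalDegreeError("degree ratio undefined for an isolated node")
    return k_pos / total


def multidegrees(net: DuplexNetwork) -> list[DegreeRecord]:
    """One DegreeRecord per node (ligands first, then proteins)."""
    k_pos, k_neg, t_pos, t_neg = net.multidegree_arrays()
    out = [
        DegreeRecord(l, "ligand", int(k_pos[i]), int(k_neg[i]))
        for i, l in enumerate(net.ligand_ids)
    ]
    out += [
        DegreeRecord(p, "protein", int(t_pos[j]), int(t_neg[j]))
        for j, p in enumerate(net.protein_ids)
    ]
    return out


def fit_power_law_exponent(
    degrees: Sequence[int], k_min: int = 1
) -> DegreeStats:
    """Continuous-approximation (Hill) MLE of a power-law degree exponent.

    gamma = 1 + n / sum(ln(k / (k_min - 1/2))) over observations k >= k_min.
    The half-shift is the standard continuity correction for integer degrees.
    """
    if k_min < 1:
        raise ValueError("k_min must be a positive integer")
    tail = np.asarray([k for k in degrees if k >= k_min], dtype=float)
    if tail.size < 10:
        raise ValueError(f"need at least 10 observations >= k_min, got {tail.size}")
    if np.unique(tail).size < 2:
        raise ValueError("all tail degrees identical; exponent undefined")
    gamma = 1.0 + tail.size / float(np.sum(np.log(tail / (k_min - 0.5))))
    return DegreeStats(gamma=gamma, k_min=k_min, n_tail=int(tail.size))


# -- edge-list I/O ------------------------------------------------------

_COLUMNS = ["ligand_id", "protein_id", "label"]


def read_duplex_tsv(path) -> DuplexNetwork:
    """Read a signed edge list (ligand_id, protein_id, label in {1,0})."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    pos: set[Edge] = set()
    neg: set[Edge] = set()
    for row_pos, (_, row) in enumerate(df.iterrows(), start=2):  # line 1 is header
        lig, prot, label = row["ligand_id"], row["protein_id"], row["label"]
        if not lig or not prot or label not in {"0", "1"}:
            raise ValueError(f"{path}: malformed row at line {row_pos}")
        edge = (lig, prot)
        if label == "1":
            if edge in neg:
                raise ForbiddenMultilinkError(
                    f"{path}: line {row_pos}: pair {edge} has conflicting labels"
                )
            pos.add(edge)
        else:
            if edge in pos:
                raise ForbiddenMultilinkError(
                    f"{path}: line {row_pos}: pair {edge} has conflicting labels"
                )
            neg.add(edge)
    return DuplexNetwork.from_edges(pos, neg)


def write_duplex_tsv(net: DuplexNetwork, path) -> None:
    rows = [(l, p, 1) for l, p in sorted(net.positive_edges)]
    rows += [(l, p, 0) for l, p in sorted(net.negative_edges)]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
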