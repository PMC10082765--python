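"""From raw kinetic records to signed annotations and network-derived negatives.

Raw measurements (Ki, Kd, IC50, EC50 in nM) are thresholded into binding
(<= 1e3 nM) and absolute non-binding (>= 1e6 nM) annotations, after removing
assays run outside 20-45 C.  Unannotated pairs that are far apart on the
positive-only bipartite graph are then declared negatives: exactly 7 hops for
training, finite >= 11 hops for evaluation — distances at which the expected
kinetic constant sits above the non-binding threshold.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import DuplexNetwork

__all__ = [
    "CONSTANT_TYPES",
    "InteractionRecord",
    "LabeledPair",
    "filter_temperature",
    "label_from_kinetics",
    "merge_curated_positives",
    "shortest_path_distances",
    "sample_network_negatives",
    "build_eval_negatives",
    "enforce_both_annotations",
    "class_balance_report",
    "read_records_tsv",
    "write_labeled_pairs_tsv",
    "read_labeled_pairs_tsv",
]

CONSTANT_TYPES = frozenset({"Ki", "Kd", "IC50", "EC50"})


@dataclass(frozen=True)
class InteractionRecord:
    """One kinetic measurement of a protein-ligand pair (value in nM)."""

    ligand_id: str
    protein_id: str
    constant_type: str
    value_nM: float
    temperature_C: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.constant_type not in CONSTANT_TYPES:
            raise ValueError(f"unknown kinetic constant type {self.constant_type!r}")
        if not (self.value_nM > 0):
            raise ValueError("kinetic values must be positive (nM)")


@dataclass(frozen=True)
class LabeledPair:
    """A binary-labelled pair with provenance.

    ``distance`` records the shortest-path hop count at sampling time and is
    present exactly for network-derived pairs (always an odd integer, since
    ligand-protein distances on a bipartite graph are odd).
    """

    ligand_id: str
    protein_id: str
    label: str  # "positive" | "negative"
    provenance: str = "experimental"  # experimental | curated_positive | network_derived
    distance: int | None = None

    def __post_init__(self) -> None:
        if self.label not in {"positive", "negative"}:
            raise ValueError(f"bad label {self.label!r}")
        if self.provenance == "network_derived" and self.distance is None:
            raise ValueError("network-derived pairs must carry a distance")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.ligand_id, self.protein_id)


def filter_temperature(
    records: Iterable[InteractionRecord],
    low: float = 20.0,
    high: float = 45.0,
    keep_missing: bool = True,
) -> list[InteractionRecord]:
    """Drop measurements taken outside [low, high] C (ambiguous assay conditions)."""
    out = []
    for r in records:
        if r.temperature_C is None:
            if keep_missing:
                out.append(r)
        elif low <= r.temperature_C <= high:
            out.append(r)
    return out


def label_from_kinetics(
    records: Iterable[InteractionRecord],
    pos_max_nM: float = 1e3,
    neg_min_nM: float = 1e6,
) -> tuple[list[LabeledPair], list[tuple[tuple[str, str], str]]]:
    """Threshold kinetic measurements into signed annotations.

    Measurements are aggregated by median within each constant type per pair.
    A pair is positive if any aggregated value <= pos_max_nM and none
    >= neg_min_nM; negative if any >= neg_min_nM and none <= pos_max_nM.
    Pairs with conflicting or only intermediate evidence are dropped, with the
    reason returned alongside.
    """
    if not pos_max_nM < neg_min_nM:
        raise ValueError("pos_max_nM must be below neg_min_nM")
    by_pair_type: dict[tuple[str, str], dict[str, list[float]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for r in records:
        by_pair_type[(r.ligand_id, r.protein_id)][r.constant_type].append(r.value_nM)

    labeled: list[LabeledPair] = []
    dropped: list[tuple[tuple[str, str], str]] = []
    for pair in sorted(by_pair_type):
        agg = [median(vals) for vals in by_pair_type[pair].values()]
        has_pos = any(v <= pos_max_nM for v in agg)
        has_neg = any(v >= neg_min_nM for v in agg)
        if has_pos and not has_neg:
            labeled.append(LabeledPair(*pair, label="positive"))
        elif has_neg and not has_pos:
            labeled.append(LabeledPair(*pair, label="negative"))
        elif has_pos and has_neg:
            dropped.append((pair, "conflicting evidence across thresholds"))
        else:
            dropped.append((pair, "only intermediate kinetic values"))
    return labeled, dropped


def merge_curated_positives(
    curated: Iterable[tuple[str, str]],
    experimental: Sequence[LabeledPair],
) -> list[LabeledPair]:
    """Merge curated binding annotations with thresholded experimental ones.

    A curated pair contradicted by an experimental negative is excluded
    entirely; a curated pair also experimentally positive is kept once (with
    its experimental provenance).
    """
    exp_neg = {p.pair for p in experimental if p.label == "negative"}
    exp_pos = {p.pair for p in experimental if p.label == "positive"}
    out = list(experimental)
    seen = exp_neg | exp_pos
    for pair in curated:
        pair = (str(pair[0]), str(pair[1]))
        if pair in seen:
            continue
        seen.add(pair)
        out.append(LabeledPair(*pair, label="positive", provenance="curated_positive"))
    return out


# -- shortest-path machinery on the positive-only graph -----------------

_LPREF, _PPREF = "L::", "P::"


def _positive_graph(net: DuplexNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(_LPREF + l for l in net.ligand_ids)
    g.add_nodes_from(_PPREF + p for p in net.protein_ids)
    g.add_edges_from((_LPREF + l, _PPREF + p) for l, p in net.positive_edges)
    return g


def shortest_path_distances(
    positive_net: DuplexNetwork,
    sources: Iterable[str] | None = None,
) -> dict[tuple[str, str], int]:
    """BFS hop counts from each source ligand to every reachable protein.

    Only the positive (binding) layer is used; ligand-protein distances on the
    bipartite graph are odd.  Unreachable pairs are omitted (infinite).
    """
    g = _positive_graph(positive_net.positive_only())
    if sources is None:
        sources = positive_net.ligand_ids
    dist: dict[tuple[str, str], int] = {}
    for lig in sources:
        lengths = nx.single_source_shortest_path_length(g, _LPREF + lig)
        for node, d in lengths.items():
            if node.startswith(_PPREF):
                dist[(lig, node[len(_PPREF):])] = d
    return dist


def sample_network_negatives(
    positive_net: DuplexNetwork,
    distance: int = 7,
    n_samples: int = 1,
    seed: int = 0,
    min_only: bool = False,
) -> list[LabeledPair]:
    """Sample unannotated pairs at a target hop distance as training negatives.

    Pairs exactly ``distance`` hops apart on the positive-only graph (or at
    least that far when ``min_only``) are sampled uniformly without
    replacement.  If the eligible pool is smaller than ``n_samples`` the whole
    pool is returned with a warning.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if distance % 2 == 0:
        raise ValueError("ligand-protein distances are odd")
    dist = shortest_path_distances(positive_net)
    if min_only:
        pool = sorted(p for p, d in dist.items() if d >= distance)
    else:
        pool = sorted(p for p, d in dist.items() if d == distance)
    rng = np.random.default_rng(seed)
    if len(pool) < n_samples:
        warnings.warn(
            f"only {len(pool)} pairs at distance "
            f"{'>=' if min_only else '=='} {distance}; returning all",
            stacklevel=2,
        )
        chosen = pool
    else:
        idx = rng.choice(len(pool), size=n_samples, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
    return [
        LabeledPair(l, p, label="negative", provenance="network_derived",
                    distance=dist[(l, p)])
        for l, p in chosen
    ]


def build_eval_negatives(
    positive_net: DuplexNetwork,
    min_distance: int = 11,
    absolute_negatives: Sequence[LabeledPair] = (),
    train_pairs: Iterable[tuple[str, str]] = (),
) -> list[LabeledPair]:
    """Negatives for testing/validation: finite >= min_distance hops, plus
    experimentally absolute negatives; never overlapping the training pairs."""
    if min_distance % 2 == 0:
        raise ValueError("min_distance must be odd")
    train = set(train_pairs)
    dist = shortest_path_distances(positive_net)
    out = [
        LabeledPair(l, p, label="negative", provenance="network_derived", distance=d)
        for (l, p), d in sorted(dist.items())
        if d >= min_distance and (l, p) not in train
    ]
    seen = {p.pair for p in out}
    for p in absolute_negatives:
        if p.label != "negative":
            raise ValueError("absolute_negatives must be negative pairs")
        if p.pair not in train and p.pair not in seen:
            out.append(p)
            seen.add(p.pair)
    return out


def enforce_both_annotations(pairs: Sequence[LabeledPair]) -> list[LabeledPair]:
    """Keep only pairs whose every endpoint retains both annotation signs.

    Nodes with single-signed annotations are removed together with their
    pairs; removal can leave neighbours single-signed, so the pass iterates
    to a fixed point.
    """
    current = list(pairs)
    while True:
        pos_nodes: set[tuple[str, str]] = set()
        neg_nodes: set[tuple[str, str]] = set()
        for p in current:
            nodes = (("ligand", p.ligand_id), ("protein", p.protein_id))
            (pos_nodes if p.label == "positive" else neg_nodes).update(nodes)
        bad = (pos_nodes - neg_nodes) | (neg_nodes - pos_nodes)
        if not bad:
            return current
        current = [
            p
            for p in current
            if ("ligand", p.ligand_id) not in bad and ("protein", p.protein_id) not in bad
        ]


def class_balance_report(pairs: Iterable[LabeledPair]) -> tuple[int, int, float]:
    """(n_pos, n_neg, n_pos/n_neg); the ratio is inf when there are no negatives."""
    n_pos = n_neg = 0
    for p in pairs:
        if p.label == "positive":
            n_pos += 1
        else:
            n_neg += 1
    ratio = math.inf if n_neg == 0 else n_pos / n_neg
    return n_pos, n_neg, ratio


# -- TSV I/O ------------------------------------------------------------

def read_records_tsv(path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["ligand_id", "protein_id", "constant_type", "value_nM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in df.iterrows():
        temp = row.get("temperature_C", "")
        out.append(
            InteractionRecord(
                ligand_id=row["ligand_id"],
                protein_id=row["protein_id"],
                constant_type=row["constant_type"],
                value_nM=float(row["value_nM"]),
                temperature_C=float(temp) if temp not in ("", "NA") else None,
                source=row.get("source", ""),
            )
        )
    return out


def write_labeled_pairs_tsv(pairs: Sequence[LabeledPair], path) -> None:
    pd.DataFrame(
        [
            (p.ligand_id, p.protein_id, p.label, p.provenance,
             "" if p.distance is None else p.distance)
            for p in pairs
        ],
        columns=["ligand_id", "protein_id", "label", "provenance", "distance"],
    ).to_csv(path, sep="\t", index=False)


def read_labeled_pairs_tsv(path) -> list[LabeledPair]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        LabeledPair(
            row["ligand_id"], row["protein_id"], row["label"], row["provenance"],
            int(row["distance"]) if row["distance"] else None,
        )
        for _, row in df.iterrows()
    ]
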