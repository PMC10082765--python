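import numpy as np
import pytest

from duplexbind import DuplexNetwork


def random_duplex(
    n_ligands: int,
    n_proteins: int,
    n_edges: int,
    seed: int,
    pos_fraction: float = 0.6,
) -> DuplexNetwork:
    """Random sparse duplex network used across the suite (never saturated
    for the sizes the tests request)."""
    rng = np.random.default_rng(seed)
    lig = [f"l{i}" for i in range(n_ligands)]
    prot = [f"p{j}" for j in range(n_proteins)]
    pairs = set()
    while len(pairs) < n_edges:
        pairs.add((lig[rng.integers(n_ligands)], prot[rng.integers(n_proteins)]))
    pairs = sorted(pairs)
    n_pos = int(round(pos_fraction * len(pairs)))
    order = rng.permutation(len(pairs))
    pos = [pairs[i] for i in sorted(order[:n_pos])]
    neg = [pairs[i] for i in sorted(order[n_pos:])]
    return DuplexNetwork.from_edges(pos, neg, lig, prot)


@pytest.fixture
def symmetric_3x3() -> DuplexNetwork:
    """Disjoint perfect matchings: each node one positive and one negative."""
    pos = [("l0", "p0"), ("l1", "p1"), ("l2", "p2")]
    neg = [("l0", "p1"), ("l1", "p2"), ("l2", "p0")]
    return DuplexNetwork.from_edges(pos, neg)
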