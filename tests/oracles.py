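"""Independent oracle implementations used by the test suite.

These deliberately avoid the code paths they check: brute-force enumeration,
generic convex optimisation, and dense all-pairs shortest paths.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import floyd_warshall

from duplexbind import DuplexNetwork


def auroc_pairwise(labels, scores) -> float:
    """O(n^2) definition: P(random positive outranks random negative), ties 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (pos.size * neg.size)


def average_precision_sweep(labels, scores) -> float:
    """Exhaustive threshold sweep over distinct scores (descending)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    thresholds = sorted(set(scores.tolist()), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def best_f1_sweep(labels, scores) -> tuple[float, float]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    best = (None, -1.0)
    for t in sorted(set(scores.tolist())):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        if f1 > best[1]:
            best = (t, f1)
    return best


def all_pairs_distances(net: DuplexNetwork) -> dict[tuple[str, str], float]:
    """Ligand-protein hop distances on the positive layer via Floyd-Warshall."""
    n_l, n_t = net.n_ligands, net.n_proteins
    n = n_l + n_t
    adj = lil_matrix((n, n))
    li, pi = net.ligand_index(), net.protein_index()
    for l, p in net.positive_edges:
        a, b = li[l], n_l + pi[p]
        adj[a, b] = 1
        adj[b, a] = 1
    dist = floyd_warshall(adj.tocsr(), unweighted=True, directed=False)
    out = {}
    for l in net.ligand_ids:
        for p in net.protein_ids:
            out[(l, p)] = float(dist[li[l], n_l + pi[p]])
    return out


def duplex_dual_minimization(net: DuplexNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Solve the max-ent dual by generic convex minimisation (L-BFGS-B).

    Optimises the negated-exponential multipliers in log space for node-layers
    with non-zero multidegree; returns dense (p_pos, p_neg) matrices.
    """
    k_pos, k_neg, t_pos, t_neg = net.multidegree_arrays()
    n_l, n_t = net.n_ligands, net.n_proteins
    masks = [k_pos > 0, k_neg > 0, t_pos > 0, t_neg > 0]
    sizes = [int(m.sum()) for m in masks]
    targets = [k_pos, k_neg, t_pos, t_neg]

    def unpack(theta):
        vals = []
        off = 0
        for m, size, full in zip(masks, sizes, (k_pos, k_neg, t_pos, t_neg)):
            v = np.zeros(full.size)
            v[m] = np.exp(theta[off : off + size])
            vals.append(v)
            off += size
        return vals  # xp, xn, yp, yn

    def objective(theta):
        xp, xn, yp, yn = unpack(theta)
        A = np.outer(xp, yp)
        B = np.outer(xn, yn)
        D = 1.0 + A + B
        # free energy: sum log D + sum lambda*k  (lambda = -log x)
        f = np.log(D).sum()
        off = 0
        for m, size, target, v in zip(masks, sizes, targets, (xp, xn, yp, yn)):
            f -= np.sum(np.log(v[m]) * target[m])
            off += size
        # gradient wrt theta (= log x): x dF/dx
        P = A / D
        Q = B / D
        grads = [
            (P.sum(axis=1) - k_pos)[masks[0]],
            (Q.sum(axis=1) - k_neg)[masks[1]],
            (P.sum(axis=0) - t_pos)[masks[2]],
            (Q.sum(axis=0) - t_neg)[masks[3]],
        ]
        return f, np.concatenate(grads)

    theta0 = np.zeros(sum(sizes))
    res = optimize.minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
    )
    xp, xn, yp, yn = unpack(res.x)
    A = np.outer(xp, yp)
    B = np.outer(xn, yn)
    D = 1.0 + A + B
    return A / D, B / D
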