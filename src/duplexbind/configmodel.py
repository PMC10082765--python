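"""Maximum-entropy duplex configuration model for signed bipartite networks.

The model is the canonical (max-ent) ensemble of duplex bipartite networks
that preserves, on average, every node's positive and negative multidegree.
Entropy maximisation with those constraints yields pairwise multilink
probabilities

    p_ij^+ = x_i^+ y_j^+ / D_ij,   p_ij^- = x_i^- y_j^- / D_ij,
    D_ij   = 1 + x_i^+ y_j^+ + x_i^- y_j^-,

where x_i^m = exp(-lambda_i^m) and y_j^m = exp(-mu_j^m) are the exponentiated
(negated) Lagrange multipliers of ligand i and protein j in layer m, and
p^+ + p^- + p^0 = 1 for every pair.  Because the dual problem is convex, the
solution is unique and independent of initialisation.

Binding prediction is conditional on observing *some* annotation:

* transductive (both nodes fitted): p^+ / (p^+ + p^-)
* semi-inductive (one node unseen): the known node's degree ratio rho
* inductive (both unseen): the global positive fraction L^+/(L^+ + L^-)

The latter two follow analytically from the constraints, which makes the
configuration model a features-blind baseline: it cannot rank unseen-by-unseen
pairs at all (constant score), exposing topological shortcut learning in
models that only appear to use molecular features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import DegreeRecord, DuplexNetwork, ZeroTotalDegreeError, degree_ratio

__all__ = [
    "DuplexConfigModel",
    "DuplexConfigResults",
    "ConvergenceError",
    "UndefinedConditionalError",
    "fit_configuration_model",
]

# multipliers are capped at exp(+-_CAP_EXP) to avoid silent divergence when a
# constraint saturates (a node annotated to every partner)
_CAP_EXP = 30.0


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class UndefinedConditionalError(ZeroDivisionError):
    """Conditional binding probability is 0/0 for the requested pair."""


def detect_saturated_nodes(net: DuplexNetwork) -> list[str]:
    """Nodes whose multidegree constraints admit no finite multipliers.

    Two boundary patterns are detected: (a) a node whose layer degree can only
    be met by probability-one links to every active partner in that layer, and
    (b) a node whose total degree equals the number of partners it can be
    annotated with at all (its reachable p00 entries are forced to zero).
    Fits involving such nodes cap the multipliers and warn instead of
    converging.
    """
    k_pos, k_neg, t_pos, t_neg = net.multidegree_arrays()
    sat_lig = np.zeros(net.n_ligands, dtype=bool)
    sat_prot = np.zeros(net.n_proteins, dtype=bool)
    for k_side, t_side in ((k_pos, t_pos), (k_neg, t_neg)):
        active_l = int((k_side > 0).sum())
        active_t = int((t_side > 0).sum())
        sat_lig |= (k_side > 0) & (k_side >= active_t)
        sat_prot |= (t_side > 0) & (t_side >= active_l)
    reach_l = (
        (k_pos > 0) * int((t_pos > 0).sum()) + (k_neg > 0) * int((t_neg > 0).sum())
        - (k_pos > 0) * (k_neg > 0) * int(((t_pos > 0) & (t_neg > 0)).sum())
    )
    reach_t = (
        (t_pos > 0) * int((k_pos > 0).sum()) + (t_neg > 0) * int((k_neg > 0).sum())
        - (t_pos > 0) * (t_neg > 0) * int(((k_pos > 0) & (k_neg > 0)).sum())
    )
    total_l = k_pos + k_neg
    total_t = t_pos + t_neg
    sat_lig |= (total_l > 0) & (total_l >= reach_l)
    sat_prot |= (total_t > 0) & (total_t >= reach_t)
    return [net.ligand_ids[i] for i in np.nonzero(sat_lig)[0]] + [
        net.protein_ids[j] for j in np.nonzero(sat_prot)[0]
    ]


class DuplexConfigModel:
    """Entropy-maximisation model of a duplex network's multidegree sequence.

    Parameters
    ----------
    net : DuplexNetwork
        The signed annotation network whose multidegrees are the constraints.
    """

    def __init__(self, net: DuplexNetwork):
        if net.n_ligands < 1 or net.n_proteins < 1:
            raise ValueError("network must have at least one node on each side")
        self.net = net
        self.k_pos, self.k_neg, self.t_pos, self.t_neg = net.multidegree_arrays()

    def fit(
        self,
        tol: float = 1e-10,
        max_iter: int = 5000,
        damping: float = 0.5,
    ) -> "DuplexConfigResults":
        """Solve the dual fixed point and return fitted results.

        Alternating fixed-point iteration on x^m <- k^m / sum_j(y^m / D) with
        geometric damping ``x <- x_old^(1-damping) * x_prop^damping``.
        """
        if not (0.0 < damping <= 1.0):
            raise ValueError("damping must lie in (0, 1]")
        kp = self.k_pos.astype(float)
        kn = self.k_neg.astype(float)
        tp = self.t_pos.astype(float)
        tn = self.t_neg.astype(float)

        cap = float(np.exp(_CAP_EXP))
        saturated = detect_saturated_nodes(self.net)

        # scale-correct warm start; the convex dual makes the end point unique
        xp = kp / np.sqrt(kp.sum() + 1.0)
        xn = kn / np.sqrt(kn.sum() + 1.0)
        yp = tp / np.sqrt(tp.sum() + 1.0)
        yn = tn / np.sqrt(tn.sum() + 1.0)

        def _update(k_layer, x_old, y_layer, D):
            # sum over partners of y^m / D; zero-degree nodes stay at x = 0
            denom = (y_layer[None, :] / D).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                prop = np.where(denom > 0, k_layer / np.where(denom > 0, denom, 1.0), 0.0)
            out = np.where(
                (x_old > 0) & (prop > 0),
                x_old ** (1.0 - damping) * prop**damping,
                prop,
            )
            return np.minimum(out, cap)

        residual = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            D = 1.0 + np.outer(xp, yp) + np.outer(xn, yn)
            xp = _update(kp, xp, yp, D)
            xn = _update(kn, xn, yn, D)
            D = 1.0 + np.outer(xp, yp) + np.outer(xn, yn)
            yp = _update(tp, yp, xp, D.T)
            yn = _update(tn, yn, xn, D.T)

            D = 1.0 + np.outer(xp, yp) + np.outer(xn, yn)
            p10 = np.outer(xp, yp) / D
            p01 = np.outer(xn, yn) / D
            residual = max(
                np.abs(p10.sum(axis=1) - kp).max(initial=0.0),
                np.abs(p01.sum(axis=1) - kn).max(initial=0.0),
                np.abs(p10.sum(axis=0) - tp).max(initial=0.0),
                np.abs(p01.sum(axis=0) - tn).max(initial=0.0),
            )
            if residual <= tol:
                break

        if saturated and residual > tol:
            warnings.warn(
                f"saturated constraints for nodes {saturated}; multipliers capped "
                f"and residual {residual:.3e} left above tol",
                RuntimeWarning,
                stacklevel=2,
            )
        elif residual > tol:
            raise ConvergenceError(
                f"fixed point not converged after {max_iter} iterations "
                f"(residual {residual:.3e} > tol {tol:.1e})",
                residual=float(residual),
            )

        D = 1.0 + np.outer(xp, yp) + np.outer(xn, yn)
        return DuplexConfigResults(
            model=self,
            x_pos=xp,
            x_neg=xn,
            y_pos=yp,
            y_neg=yn,
            iterations=it,
            max_residual=float(residual),
            log_partition=float(np.log(D).sum()),
            saturated_nodes=saturated,
        )


@dataclass
class DuplexConfigResults:
    """Fitted multipliers of the duplex configuration model.

    ``x_pos[i] = exp(-lambda_i^+)`` etc.; a value is exactly zero iff the
    corresponding multidegree is zero.
    """

    model: DuplexConfigModel
    x_pos: np.ndarray
    x_neg: np.ndarray
    y_pos: np.ndarray
    y_neg: np.ndarray
    iterations: int
    max_residual: float
    log_partition: float
    saturated_nodes: list[str] = field(default_factory=list)

    @property
    def net(self) -> DuplexNetwork:
        return self.model.net

    # -- pairwise probabilities -----------------------------------------

    def multilink_probabilities(self, i: int, j: int) -> tuple[float, float, float]:
        """(p^+, p^-, p^0) for ligand index i and protein index j."""
        if not (0 <= i < self.net.n_ligands and 0 <= j < self.net.n_proteins):
            raise IndexError("pair index out of range")
        a = self.x_pos[i] * self.y_pos[j]
        b = self.x_neg[i] * self.y_neg[j]
        D = 1.0 + a + b
        return a / D, b / D, 1.0 / D

    def probability_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (p^+, p^-) matrices over all ligand x protein pairs."""
        a = np.outer(self.x_pos, self.y_pos)
        b = np.outer(self.x_neg, self.y_neg)
        D = 1.0 + a + b
        return a / D, b / D

    # -- conditional binding predictors ---------------------------------

    def predict_transductive(self, i: int, j: int) -> float:
        """Conditional binding probability p^+/(p^+ + p^-) for fitted nodes."""
        p10, p01, _ = self.multilink_probabilities(i, j)
        if p10 + p01 == 0.0:
            raise UndefinedConditionalError(
                "pair has zero probability of any annotation (0/0 conditional)"
            )
        return p10 / (p10 + p01)

    def predict_semi_inductive(self, known_node: DegreeRecord) -> float:
        """Binding probability when one endpoint is unseen: the known node's rho.

        At the fitted solution the average of p^+ over the unseen side equals
        k^+/N, so the conditional reduces exactly to the degree ratio.  The
        unseen-ligand case (known protein) is the symmetric extrapolation.
        """
        return degree_ratio(known_node.k_pos, known_node.k_neg)

    def predict_inductive(self) -> float:
        """Binding probability for unseen-by-unseen pairs: L^+/(L^+ + L^-)."""
        total = self.net.n_positive + self.net.n_negative
        if total == 0:
            raise ZeroTotalDegreeError("network carries no annotations")
        return self.net.n_positive / total

    def predict_pair(
        self,
        pair: tuple[str, str],
        train_ligands: set[str],
        train_proteins: set[str],
    ) -> tuple[float, str]:
        """Route a pair to the predictor matching its scenario.

        Returns (probability, scenario) with scenario in
        {"transductive", "semi_inductive", "inductive"}.
        """
        lig, prot = pair
        lig_known = lig in train_ligands
        prot_known = prot in train_proteins
        if lig_known and prot_known:
            li, pi = self.net.ligand_index(), self.net.protein_index()
            return self.predict_transductive(li[lig], pi[prot]), "transductive"
        if lig_known:
            i = self.net.ligand_index()[lig]
            rec = DegreeRecord(lig, "ligand", int(self.model.k_pos[i]), int(self.model.k_neg[i]))
            return self.predict_semi_inductive(rec), "semi_inductive"
        if prot_known:
            j = self.net.protein_index()[prot]
            rec = DegreeRecord(prot, "protein", int(self.model.t_pos[j]), int(self.model.t_neg[j]))
            return self.predict_semi_inductive(rec), "semi_inductive"
        return self.predict_inductive(), "inductive"

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        net = self.net
        lines = [
            "Duplex configuration model (maximum entropy)",
            "=" * 44,
            f"ligands: {net.n_ligands}   proteins: {net.n_proteins}",
            f"positive annotations L+: {net.n_positive}   negative L-: {net.n_negative}",
            f"iterations: {self.iterations}   max residual: {self.max_residual:.3e}",
            f"log partition function: {self.log_partition:.6g}",
            f"saturated nodes: {len(self.saturated_nodes)}",
            f"inductive conditional L+/(L+ + L-): "
            f"{self.net.n_positive / max(self.net.n_positive + self.net.n_negative, 1):.4f}",
        ]
        return "\n".join(lines)


def fit_configuration_model(
    net: DuplexNetwork,
    tol: float = 1e-10,
    max_iter: int = 5000,
    damping: float = 0.5,
) -> DuplexConfigResults:
    """Convenience wrapper: ``DuplexConfigModel(net).fit(...)``."""
    return DuplexConfigModel(net).fit(tol=tol, max_iter=max_iter, damping=damping)
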