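"""Scenario splits, tie-aware metrics, and shortcut diagnostics.

Three evaluation scenarios probe what a binding model actually learned:

* transductive — test pairs whose ligand and protein both appear in training
  (only the edge is new);
* semi-inductive — the test protein is unseen, the ligand is known;
* inductive — both endpoints are unseen.

Topology-driven predictors ace the first two and collapse to a constant on
the third, so tie handling in the metrics matters: AUROC uses the
Mann-Whitney midrank formulation (ties count 1/2), AUPRC is uninterpolated
average precision with tied scores grouped per threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .dataprep import LabeledPair
from .network import DuplexNetwork, multidegrees

__all__ = [
    "ScenarioSplit",
    "MetricsReport",
    "ShortcutDiagnostics",
    "make_scenario_splits",
    "auroc",
    "auprc",
    "optimal_f1_threshold",
    "confusion_at_threshold",
    "evaluate_predictions",
    "spearman",
    "shortcut_diagnostics",
    "feature_shuffle_control",
    "binarize_affinities",
]

SCENARIOS = ("transductive", "semi_inductive", "inductive")


@dataclass
class ScenarioSplit:
    scenario: str
    fold: int
    train_pairs: list[LabeledPair]
    test_pairs: list[LabeledPair]
    train_ligands: set[str]
    train_proteins: set[str]
    seed: int

    def validate(self) -> None:
        train_set = {p.pair for p in self.train_pairs}
        for p in self.test_pairs:
            if p.pair in train_set:
                raise ValueError("train/test pair overlap")
            lig_in = p.ligand_id in self.train_ligands
            prot_in = p.protein_id in self.train_proteins
            if self.scenario == "transductive" and not (lig_in and prot_in):
                raise ValueError("transductive test pair with unseen node")
            if self.scenario == "semi_inductive" and not (lig_in and not prot_in):
                raise ValueError("semi-inductive test pair must have unseen protein only")
            if self.scenario == "inductive" and (lig_in or prot_in):
                raise ValueError("inductive test pair with seen node")


def _fold_slices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def make_scenario_splits(
    pairs: Sequence[LabeledPair],
    scenario: str,
    n_folds: int = 5,
    seed: int = 0,
) -> list[ScenarioSplit]:
    """Cross-validation folds for one of the three evaluation scenarios.

    Transductive folds partition the pairs; test pairs touching a node absent
    from the fold's training pairs are discarded.  Semi-inductive folds
    partition the proteins.  Inductive folds partition both node sets jointly:
    only held-out-by-held-out pairs are tested and cross pairs are discarded
    from that fold.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    pairs = list(pairs)
    ligands = sorted({p.ligand_id for p in pairs})
    proteins = sorted({p.protein_id for p in pairs})

    splits: list[ScenarioSplit] = []
    if scenario == "transductive":
        for f, test_idx in enumerate(_fold_slices(len(pairs), n_folds, rng)):
            test_mask = np.zeros(len(pairs), dtype=bool)
            test_mask[test_idx] = True
            train = [p for i, p in enumerate(pairs) if not test_mask[i]]
            tl = {p.ligand_id for p in train}
            tp = {p.protein_id for p in train}
            test = [
                p for i, p in enumerate(pairs)
                if test_mask[i] and p.ligand_id in tl and p.protein_id in tp
            ]
            splits.append(ScenarioSplit(scenario, f, train, test, tl, tp, seed))
    elif scenario == "semi_inductive":
        for f, held in enumerate(_fold_slices(len(proteins), n_folds, rng)):
            held_prots = {proteins[i] for i in held}
            train = [p for p in pairs if p.protein_id not in held_prots]
            tl = {p.ligand_id for p in train}
            tp = {p.protein_id for p in train}
            test = [
                p for p in pairs
                if p.protein_id in held_prots and p.ligand_id in tl
            ]
            splits.append(ScenarioSplit(scenario, f, train, test, tl, tp, seed))
    else:  # inductive: hold out disjoint node subsets on both sides
        lig_folds = _fold_slices(len(ligands), n_folds, rng)
        prot_folds = _fold_slices(len(proteins), n_folds, rng)
        for f in range(n_folds):
            held_l = {ligands[i] for i in lig_folds[f]}
            held_p = {proteins[i] for i in prot_folds[f]}
            train = [
                p for p in pairs
                if p.ligand_id not in held_l and p.protein_id not in held_p
            ]
            test = [
                p for p in pairs
                if p.ligand_id in held_l and p.protein_id in held_p
            ]
            tl = {p.ligand_id for p in train}
            tp = {p.protein_id for p in train}
            test = [p for p in test if p.ligand_id not in tl and p.protein_id not in tp]
            splits.append(ScenarioSplit(scenario, f, train, test, tl, tp, seed))

    for s in splits:
        if not s.train_pairs or not s.test_pairs:
            raise ValueError(
                f"infeasible {scenario} fold {s.fold}: "
                f"{len(s.train_pairs)} train / {len(s.test_pairs)} test pairs"
            )
        s.validate()
    return splits


# -- tie-aware metrics --------------------------------------------------

def _check_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-d and equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    return y, s


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Tie-aware AUROC via the Mann-Whitney midrank statistic.

    Equals the probability that a random positive outranks a random negative,
    with tied scores counted 1/2 — so a constant predictor scores exactly 0.5.
    """
    y, s = _check_scores(labels, scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Uninterpolated average precision with tied scores grouped.

    Thresholds sweep the distinct scores in descending order; each group of
    tied scores enters at once, so constant scores give exactly the test-set
    prevalence.
    """
    y, s = _check_scores(labels, scores)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    # last index of each tied block = a valid operating point
    block_end = np.nonzero(np.diff(s_sorted, append=np.nan) != 0)[0]
    tp_b = tp[block_end]
    fp_b = fp[block_end]
    prec = tp_b / (tp_b + fp_b)
    dtp = np.diff(tp_b, prepend=0.0)
    return float(np.sum(dtp * prec) / n_pos)


def optimal_f1_threshold(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[float, float]:
    """Score threshold (from the observed scores) maximising F1.

    Prediction rule is score >= threshold; F1 ties break toward the lowest
    threshold.
    """
    y, s = _check_scores(labels, scores)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("threshold search needs both classes present")
    best_t, best_f1 = None, -1.0
    for t in np.unique(s):  # ascending; strict > below keeps the lowest tie
        pred = s >= t
        tp = float(np.sum(pred & (y == 1)))
        fp = float(np.sum(pred & (y == 0)))
        fn = float(np.sum(~pred & (y == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


@dataclass
class MetricsReport:
    """Tie-aware metric bundle at a fixed decision threshold.

    ``sensitivity`` is tp/(tp+fn); ``precision`` (tp/(tp+fp)) is also carried
    so both readings of a "fraction of predicted binders that bind" are
    available unambiguously.
    """

    auroc: float
    auprc: float
    f1: float
    sensitivity: float
    precision: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def summary(self) -> str:
        return (
            f"AUROC {self.auroc:.4f}  AUPRC {self.auprc:.4f}  F1 {self.f1:.4f}\n"
            f"threshold {self.threshold:.4f}  sensitivity(tp/(tp+fn)) "
            f"{self.sensitivity:.4f}  precision(tp/(tp+fp)) {self.precision:.4f}\n"
            f"tp {self.tp}  fp {self.fp}  tn {self.tn}  fn {self.fn}"
        )


def confusion_at_threshold(
    labels: Sequence[int], scores: Sequence[float], threshold: float
) -> MetricsReport:
    """Confusion counts and derived metrics with rule score >= threshold."""
    y, s = _check_scores(labels, scores)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    prec = tp / (tp + fp) if tp + fp > 0 else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    both = 0 < y.sum() < y.size
    return MetricsReport(
        auroc=auroc(y, s) if both else float("nan"),
        auprc=auprc(y, s) if y.sum() > 0 else float("nan"),
        f1=f1,
        sensitivity=sens,
        precision=prec,
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def evaluate_predictions(
    labels: Sequence[int], scores: Sequence[float]
) -> MetricsReport:
    """Full metric bundle at the F1-optimal threshold."""
    t, _ = optimal_f1_threshold(labels, scores)
    return confusion_at_threshold(labels, scores, t)


def binarize_affinities(
    affinities_kcal_mol: Sequence[float], threshold: float = -1.75
) -> np.ndarray:
    """Binding labels from docking-style free energies: binder iff dG <= threshold."""
    return (np.asarray(affinities_kcal_mol, dtype=float) <= threshold).astype(int)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


# -- shortcut diagnostics ----------------------------------------------

@dataclass
class ShortcutDiagnostics:
    """Correlations exposing topology-driven ("shortcut") prediction.

    High Spearman between per-node mean predictions and degree ratios means
    the model scores nodes by their annotation imbalance; negative Spearman
    between degree and mean kinetic value is the planted/observed driver of
    that imbalance.
    """

    spearman_rho_ligand: float | None
    spearman_rho_protein: float | None
    spearman_degree_kinetic_ligand: float | None = None
    spearman_degree_kinetic_protein: float | None = None


def _per_node_mean(
    predictions: Mapping[tuple[str, str], float], index: int
) -> dict[str, float]:
    sums: dict[str, list[float]] = {}
    for pair, score in predictions.items():
        sums.setdefault(pair[index], []).append(score)
    return {k: float(np.mean(v)) for k, v in sums.items()}


def shortcut_diagnostics(
    net_train: DuplexNetwork,
    predictions: Mapping[tuple[str, str], float],
    kinetic_values: Mapping[tuple[str, str], float] | None = None,
) -> ShortcutDiagnostics:
    """Correlate per-node mean predictions with training degree ratios.

    When raw kinetic values are supplied, also correlates node degree with
    the node's mean kinetic value (both sides).
    """
    recs = {(r.side, r.node_id): r for r in multidegrees(net_train)}

    def _rho_corr(side: str, index: int) -> float | None:
        means = _per_node_mean(predictions, index)
        xs, ys = [], []
        for node, m in means.items():
            r = recs.get((side, node))
            if r is not None and r.k_total > 0:
                xs.append(r.rho)
                ys.append(m)
        try:
            return spearman(xs, ys)
        except ValueError:
            return None

    def _kin_corr(side: str, index: int) -> float | None:
        if kinetic_values is None:
            return None
        means = _per_node_mean(kinetic_values, index)
        xs, ys = [], []
        for node, m in means.items():
            r = recs.get((side, node))
            if r is not None and r.k_total > 0:
                xs.append(r.k_total)
                ys.append(m)
        try:
            return spearman(xs, ys)
        except ValueError:
            return None

    return ShortcutDiagnostics(
        spearman_rho_ligand=_rho_corr("ligand", 0),
        spearman_rho_protein=_rho_corr("protein", 1),
        spearman_degree_kinetic_ligand=_kin_corr("ligand", 0),
        spearman_degree_kinetic_protein=_kin_corr("protein", 1),
    )


# -- shuffle control ----------------------------------------------------

Trainer = Callable[
    [Sequence[LabeledPair], Mapping[str, str], Mapping[str, str], int],
    Callable[[Sequence[LabeledPair]], np.ndarray],
]


def feature_shuffle_control(
    train_pairs: Sequence[LabeledPair],
    test_pairs: Sequence[LabeledPair],
    ligand_structures: Mapping[str, str],
    protein_structures: Mapping[str, str],
    trainer: Trainer,
    seed: int = 0,
) -> tuple[MetricsReport, MetricsReport]:
    """Retrain with structures permuted across node ids (annotations fixed).

    ``trainer(train_pairs, ligand_structures, protein_structures, seed)`` must
    return a scoring function over pairs.  A model that truly reads molecular
    features collapses to chance under the shuffle; a topology-only model is
    unaffected.  Returns (metrics_original, metrics_shuffled) on test_pairs.
    """
    rng = np.random.default_rng(seed)

    def _run(lig_map, prot_map) -> MetricsReport:
        score_fn = trainer(train_pairs, lig_map, prot_map, seed)
        scores = np.asarray(score_fn(test_pairs), dtype=float)
        labels = [1 if p.label == "positive" else 0 for p in test_pairs]
        return evaluate_predictions(labels, scores)

    original = _run(dict(ligand_structures), dict(protein_structures))

    lig_keys = sorted(ligand_structures)
    prot_keys = sorted(protein_structures)
    lig_vals = [ligand_structures[k] for k in lig_keys]
    prot_vals = [protein_structures[k] for k in prot_keys]
    shuffled_lig = dict(zip(lig_keys, [lig_vals[i] for i in rng.permutation(len(lig_vals))]))
    shuffled_prot = dict(zip(prot_keys, [prot_vals[i] for i in rng.permutation(len(prot_vals))]))
    shuffled = _run(shuffled_lig, shuffled_prot)
    return original, shuffled
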