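"""Feed-forward binding scorer over pluggable embeddings, with 5-fold ensembling.

The scorer maps a (ligand embedding, protein embedding) pair to a binding
probability through a small two-branch network: each branch linearly projects
its embedding to a shared hidden width; the branch outputs, their
concatenation and their elementwise product (which lets the head express
ligand-protein interactions that pure concatenation cannot) feed two hidden
layers into a logistic output.  Training minimises binary cross-entropy with
Adam and stops early when the validation ranking stalls.  An ensemble trains
one member per cross-validation fold and averages the member probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataprep import LabeledPair
from .embeddings import HashedLigandEmbedding, HashedProteinEmbedding

__all__ = [
    "ScorerParams",
    "BindingScorerModel",
    "BindingScorerResults",
    "BindingEnsemble",
    "EnsembleResults",
]


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class ScorerParams:
    """Weights of the two-branch feed-forward head plus its training record."""

    weights: dict[str, np.ndarray]
    seed: int
    loss_trace: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "loss_trace": self.loss_trace,
                "weights": {k: v.tolist() for k, v in self.weights.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScorerParams":
        obj = json.loads(text)
        return cls(
            weights={k: np.asarray(v, dtype=float) for k, v in obj["weights"].items()},
            seed=obj["seed"],
            loss_trace=list(obj["loss_trace"]),
        )


def _init_params(lig_dim: int, prot_dim: int, hidden: int, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    h2 = max(hidden // 2, 1)

    def glorot(n_in, n_out):
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, size=(n_in, n_out))

    return {
        "Wl": glorot(lig_dim, hidden), "bl": np.zeros(hidden),
        "Wp": glorot(prot_dim, hidden), "bp": np.zeros(hidden),
        "W1": glorot(3 * hidden, hidden), "b1": np.zeros(hidden),
        "W2": glorot(hidden, h2), "b2": np.zeros(h2),
        "w3": glorot(h2, 1), "b3": np.zeros(1),
    }


def _scale(X: np.ndarray) -> np.ndarray:
    # embeddings are unit-L2; rescale by sqrt(dim) so per-unit pre-activations
    # start at O(1) under Glorot init
    return X * np.sqrt(X.shape[1])


def _forward_scaled(w: Mapping[str, np.ndarray], Xl: np.ndarray, Xp: np.ndarray):
    hl = Xl @ w["Wl"] + w["bl"]
    hp = Xp @ w["Wp"] + w["bp"]
    # concatenation alone cannot express ligand-protein interactions, so the
    # branch outputs also enter through their elementwise product
    h = np.concatenate([hl, hp, hl * hp], axis=1)
    h1 = _relu(h @ w["W1"] + w["b1"])
    h2 = _relu(h1 @ w["W2"] + w["b2"])
    z = (h2 @ w["w3"] + w["b3"]).ravel()
    return _sigmoid(z), (hl, hp, h, h1, h2)


def _forward(w: Mapping[str, np.ndarray], Xl: np.ndarray, Xp: np.ndarray):
    return _forward_scaled(w, _scale(Xl), _scale(Xp))


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def _gradients(w, Xl, Xp, y):
    Xl, Xp = _scale(Xl), _scale(Xp)
    p, (hl, hp, h, h1, h2) = _forward_scaled(w, Xl, Xp)
    n = y.size
    dz = (p - y)[:, None] / n  # d BCE / d logit
    g = {}
    g["w3"] = h2.T @ dz
    g["b3"] = dz.sum(axis=0)
    dh2 = (dz @ w["w3"].T) * (h2 > 0)
    g["W2"] = h1.T @ dh2
    g["b2"] = dh2.sum(axis=0)
    dh1 = (dh2 @ w["W2"].T) * (h1 > 0)
    g["W1"] = h.T @ dh1
    g["b1"] = dh1.sum(axis=0)
    dh = dh1 @ w["W1"].T
    hidden = hl.shape[1]
    dprod = dh[:, 2 * hidden :]
    dhl = dh[:, :hidden] + dprod * hp
    dhp = dh[:, hidden : 2 * hidden] + dprod * hl
    g["Wl"] = Xl.T @ dhl
    g["bl"] = dhl.sum(axis=0)
    g["Wp"] = Xp.T @ dhp
    g["bp"] = dhp.sum(axis=0)
    return g, _bce(p, y)


class BindingScorerModel:
    """Trainable binding scorer built from labelled pairs and providers.

    Parameters
    ----------
    train_pairs : sequence of LabeledPair
    ligand_structures, protein_structures : mapping id -> structure string
    lig_provider, prot_provider : embedding providers (hashed fallbacks by
        default, 300-d ligand / 100-d protein)
    hidden : shared branch width of the feed-forward head
    """

    def __init__(
        self,
        train_pairs: Sequence[LabeledPair],
        ligand_structures: Mapping[str, str],
        protein_structures: Mapping[str, str],
        lig_provider=None,
        prot_provider=None,
        hidden: int = 64,
    ):
        labels = {p.label for p in train_pairs}
        if labels != {"positive", "negative"}:
            raise ValueError("training pairs must contain both labels")
        self.train_pairs = list(train_pairs)
        self.ligand_structures = dict(ligand_structures)
        self.protein_structures = dict(protein_structures)
        self.lig_provider = lig_provider or HashedLigandEmbedding()
        self.prot_provider = prot_provider or HashedProteinEmbedding()
        self.hidden = hidden
        for p in self.train_pairs:
            if p.ligand_id not in self.ligand_structures:
                raise KeyError(f"no structure for ligand {p.ligand_id!r}")
            if p.protein_id not in self.protein_structures:
                raise KeyError(f"no structure for protein {p.protein_id!r}")

    # embeddings are deterministic, so cache per structure id
    def _embed_pairs(self, pairs: Sequence[LabeledPair]):
        lig_cache: dict[str, np.ndarray] = {}
        prot_cache: dict[str, np.ndarray] = {}
        Xl = np.empty((len(pairs), self.lig_provider.dimension))
        Xp = np.empty((len(pairs), self.prot_provider.dimension))
        for r, p in enumerate(pairs):
            if p.ligand_id not in lig_cache:
                lig_cache[p.ligand_id] = self.lig_provider.embed(
                    self.ligand_structures[p.ligand_id]
                )
            if p.protein_id not in prot_cache:
                prot_cache[p.protein_id] = self.prot_provider.embed(
                    self.protein_structures[p.protein_id]
                )
            Xl[r] = lig_cache[p.ligand_id]
            Xp[r] = prot_cache[p.protein_id]
        y = np.array([1.0 if p.label == "positive" else 0.0 for p in pairs])
        return Xl, Xp, y

    def fit(
        self,
        seed: int = 0,
        max_epochs: int = 200,
        patience: int = 15,
        learning_rate: float = 3e-3,
        batch_size: int = 64,
        val_fraction: float = 0.15,
        val_pairs: Sequence[LabeledPair] | None = None,
    ) -> "BindingScorerResults":
        """Adam on binary cross-entropy with early stopping on validation loss.

        The validation loss is the ranking loss 1 - AUROC (binary
        cross-entropy when the validation split is single-class): trained
        scorers grow overconfident long before their ranking degrades, so a
        probability loss would stop far too early.
        """
        rng = np.random.default_rng(seed)
        if val_pairs is None:
            idx = rng.permutation(len(self.train_pairs))
            n_val = max(int(round(val_fraction * len(idx))), 1)
            val = [self.train_pairs[i] for i in idx[:n_val]]
            train = [self.train_pairs[i] for i in idx[n_val:]]
        else:
            train, val = self.train_pairs, list(val_pairs)
        Xl, Xp, y = self._embed_pairs(train)
        Xlv, Xpv, yv = self._embed_pairs(val)

        w = _init_params(
            self.lig_provider.dimension, self.prot_provider.dimension, self.hidden, seed
        )
        m = {k: np.zeros_like(v) for k, v in w.items()}
        v2 = {k: np.zeros_like(v) for k, v in w.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_loss, best_w, stale = np.inf, {k: a.copy() for k, a in w.items()}, 0
        trace: list[float] = []
        val_both_classes = 0 < yv.sum() < yv.size

        def _val_loss() -> float:
            p = _forward(w, Xlv, Xpv)[0]
            if val_both_classes:
                from .evaluation import auroc

                return 1.0 - auroc(yv, p)
            return _bce(p, yv)

        for _epoch in range(max_epochs):
            order = rng.permutation(y.size)
            for start in range(0, y.size, batch_size):
                sl = order[start : start + batch_size]
                g, _ = _gradients(w, Xl[sl], Xp[sl], y[sl])
                t += 1
                for k in w:
                    m[k] = b1 * m[k] + (1 - b1) * g[k]
                    v2[k] = b2 * v2[k] + (1 - b2) * g[k] ** 2
                    mhat = m[k] / (1 - b1**t)
                    vhat = v2[k] / (1 - b2**t)
                    w[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_loss = _val_loss()
            trace.append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss, stale = val_loss, 0
                best_w = {k: a.copy() for k, a in w.items()}
            else:
                stale += 1
                if stale >= patience:
                    break

        params = ScorerParams(weights=best_w, seed=seed, loss_trace=trace)
        return BindingScorerResults(model=self, params=params, val_loss=best_loss)


@dataclass
class BindingScorerResults:
    """A trained scorer: frozen weights plus prediction methods."""

    model: BindingScorerModel
    params: ScorerParams
    val_loss: float

    def predict_vectors(self, lig_vec: np.ndarray, prot_vec: np.ndarray) -> float:
        p, _ = _forward(
            self.params.weights,
            np.atleast_2d(lig_vec),
            np.atleast_2d(prot_vec),
        )
        return float(np.clip(p[0], 1e-12, 1 - 1e-12))

    def predict(self, ligand_structure: str, protein_structure: str) -> float:
        return self.predict_vectors(
            self.model.lig_provider.embed(ligand_structure),
            self.model.prot_provider.embed(protein_structure),
        )

    def predict_pairs(
        self,
        pairs: Sequence[LabeledPair],
        ligand_structures: Mapping[str, str] | None = None,
        protein_structures: Mapping[str, str] | None = None,
    ) -> np.ndarray:
        lig = ligand_structures or self.model.ligand_structures
        prot = protein_structures or self.model.protein_structures
        return np.array(
            [self.predict(lig[p.ligand_id], prot[p.protein_id]) for p in pairs]
        )

    def summary(self) -> str:
        return (
            f"Binding scorer (two-branch MLP, hidden={self.model.hidden})\n"
            f"train pairs: {len(self.model.train_pairs)}  seed: {self.params.seed}\n"
            f"epochs run: {len(self.params.loss_trace)}  "
            f"best validation loss (1 - AUROC): {self.val_loss:.4f}"
        )


class BindingEnsemble:
    """Cross-validated ensemble of binding scorers (arithmetic-mean output).

    One member is trained per fold, validated on that fold's held-out pairs;
    the ensemble prediction is the mean of the member probabilities.
    """

    def __init__(
        self,
        train_pairs: Sequence[LabeledPair],
        ligand_structures: Mapping[str, str],
        protein_structures: Mapping[str, str],
        n_folds: int = 5,
        lig_provider=None,
        prot_provider=None,
        hidden: int = 64,
    ):
        if n_folds < 2:
            raise ValueError("need at least 2 folds")
        self.train_pairs = list(train_pairs)
        self.ligand_structures = dict(ligand_structures)
        self.protein_structures = dict(protein_structures)
        self.n_folds = n_folds
        self.lig_provider = lig_provider or HashedLigandEmbedding()
        self.prot_provider = prot_provider or HashedProteinEmbedding()
        self.hidden = hidden

    def fit(self, seed: int = 0, **fit_kwargs) -> "EnsembleResults":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(self.train_pairs))
        folds = np.array_split(perm, self.n_folds)
        members = []
        for f, hold in enumerate(folds):
            hold_set = set(hold.tolist())
            tr = [self.train_pairs[i] for i in perm if i not in hold_set]
            va = [self.train_pairs[i] for i in hold]
            model = BindingScorerModel(
                tr,
                self.ligand_structures,
                self.protein_structures,
                lig_provider=self.lig_provider,
                prot_provider=self.prot_provider,
                hidden=self.hidden,
            )
            members.append(model.fit(seed=seed + 1 + f, val_pairs=va, **fit_kwargs))
        return EnsembleResults(ensemble=self, members=members)


@dataclass
class EnsembleResults:
    ensemble: BindingEnsemble
    members: list[BindingScorerResults]

    def member_scores(self, ligand_structure: str, protein_structure: str) -> np.ndarray:
        return np.array(
            [m.predict(ligand_structure, protein_structure) for m in self.members]
        )

    def predict(self, ligand_structure: str, protein_structure: str) -> float:
        return float(self.member_scores(ligand_structure, protein_structure).mean())

    def predict_with_variance(
        self, ligand_structure: str, protein_structure: str
    ) -> tuple[float, float]:
        s = self.member_scores(ligand_structure, protein_structure)
        return float(s.mean()), float(s.var())

    def predict_vectors(self, lig_vec: np.ndarray, prot_vec: np.ndarray) -> float:
        return float(
            np.mean([m.predict_vectors(lig_vec, prot_vec) for m in self.members])
        )

    def predict_pairs(
        self,
        pairs: Sequence[LabeledPair],
        ligand_structures: Mapping[str, str] | None = None,
        protein_structures: Mapping[str, str] | None = None,
    ) -> np.ndarray:
        lig = ligand_structures or self.ensemble.ligand_structures
        prot = protein_structures or self.ensemble.protein_structures
        return np.array(
            [self.predict(lig[p.ligand_id], prot[p.protein_id]) for p in pairs]
        )

    def summary(self) -> str:
        losses = ", ".join(f"{m.val_loss:.4f}" for m in self.members)
        return (
            f"Binding ensemble: {len(self.members)} members "
            f"(hidden={self.ensemble.hidden})\n"
            f"member validation loss (1 - AUROC): {losses}"
        )
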