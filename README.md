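# duplexbind

Topology-aware baselines and honest evaluation for protein–ligand binding
prediction.

Curated binding databases are *signed bipartite networks*: ligands and protein
targets connected by positive (binding, e.g. K_d ≤ 10³ nM) and negative
(non-binding, K_d ≥ 10⁶ nM) annotations. Annotation counts are fat-tailed and
anti-correlated with affinity, so most nodes carry almost only one sign of
annotation. A machine-learning model can then score pairs from node degrees
alone — a *topological shortcut* — and still look excellent under standard
cross-validation, while learning nothing about chemistry. `duplexbind` gives
you the tools to detect, quantify and defeat this failure mode:

- **A features-blind null model.** The maximum-entropy (canonical)
  configuration model of the duplex network preserves every node's expected
  positive and negative multidegree. With multilink states m ∈ {(1,0), (0,1),
  (0,0)} (binding / non-binding / unannotated; (1,1) is forbidden), entropy
  maximisation gives pairwise probabilities

  p⁺ᵢⱼ = xᵢ⁺yⱼ⁺/Dᵢⱼ, p⁻ᵢⱼ = xᵢ⁻yⱼ⁻/Dᵢⱼ, Dᵢⱼ = 1 + xᵢ⁺yⱼ⁺ + xᵢ⁻yⱼ⁻,

  where x = e^(−λ), y = e^(−μ) are exponentiated Lagrange multipliers.
  Conditional binding predictions follow analytically: p⁺/(p⁺+p⁻) for seen
  nodes (transductive), the degree ratio ρᵢ = kᵢ⁺/(kᵢ⁺+kᵢ⁻) when one node is
  unseen (semi-inductive), and the global positive fraction L⁺/(L⁺+L⁻) when
  both are unseen (inductive) — a constant, so its inductive AUROC is exactly
  0.5. Any model that does not beat this null on unseen nodes has learned
  topology, not molecules.
- **Network-derived negatives.** Unannotated pairs exactly 7 hops apart on the
  positive-only graph become training negatives (expected affinity at that
  distance is beyond the non-binding threshold); finite ≥ 11-hop pairs and
  experimental absolute negatives are reserved for evaluation; nodes without
  both annotation signs are filtered to a fixed point.
- **Three-scenario evaluation.** Transductive / semi-inductive / inductive
  splits, tie-aware AUROC (Mann–Whitney midranks) and AUPRC (uninterpolated
  average precision), F1-optimal thresholds, Spearman shortcut diagnostics,
  and the structure-shuffle control (permute SMILES/sequences across node ids,
  retrain, compare).
- **A binding scorer that can generalise.** A small feed-forward head over
  pluggable fixed-dimension embeddings (300-d ligand, 100-d protein; hashed
  n-gram fallbacks included, pre-trained tables pluggable via TSV), trained in
  a 5-fold ensemble whose prediction is the member mean.
- **Binding-site profiles.** Perturb every amino-acid trigram of a sequence,
  re-score, and read candidate binding sites off the valleys of the resulting
  binding-probability profile, optionally prioritised away from α-helices.
- **Synthetic worlds.** Seeded generators for (a) degree/affinity-imbalanced
  networks reproducing the shortcut pathology and (b) a latent-feature world
  where inductive generalisation is achievable by construction.

## Worked example

```python
import duplexbind as db

net = db.fixture_ripk1_toy()          # a ligand with 1 positive, 2 negatives
res = db.DuplexConfigModel(net).fit() # max-ent fit of the duplex network
print(res.summary())

rec = {r.node_id: r for r in db.multidegrees(net)}["ripk1_in_7"]
print("degree ratio        ", round(rec.rho, 4))
print("semi-inductive score", round(res.predict_semi_inductive(rec), 4))
print("inductive score     ", res.predict_inductive())
```

prints

```
Duplex configuration model (maximum entropy)
============================================
ligands: 3   proteins: 4
positive annotations L+: 4   negative L-: 4
iterations: 114   max residual: 8.679e-11
log partition function: 13.8629
saturated nodes: 0
inductive conditional L+/(L+ + L-): 0.5000
degree ratio         0.3333
semi-inductive score 0.3333
inductive score      0.5
```

The fitted expected multidegrees match the observed ones to 10⁻¹⁰; the
semi-inductive prediction for the worked-example ligand equals its degree
ratio 1/3 exactly (the analytic identity, not a coincidence); and every
unseen-by-unseen pair would receive the constant 0.5, which is why the null
cannot rank novel molecules.

For the full contrast on a synthetic latent-feature world — configuration
model at AUROC 0.5 versus the embedding ensemble at ≥ 0.7 on unseen nodes,
collapsing back to 0.5 under the structure shuffle — see
`tests/test_acceptance.py::test_inductive_generalisation_recovery_and_shuffle_collapse`.

A command-line interface mirrors the library: `duplexbind simulate`,
`prepare`, `sample-negatives`, `fit-null`, `train`, `predict`, `evaluate`,
`diagnose`, `profile-sites` (see `duplexbind --help`).

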