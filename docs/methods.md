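# Methods

## The duplex configuration model

Protein–ligand annotations form a bipartite *duplex* network: N_L ligands and
N_T proteins interacting in a positive (binding) and a negative (non-binding)
layer. The joint state of a pair is a multilink m ∈ {(1,0), (0,1), (0,0)};
(1,1) is forbidden because binding and non-binding cannot coexist. Per-node
multidegrees k_i^m (ligands) and t_j^m (proteins) count each link type.

The null model is the canonical maximum-entropy ensemble constrained to
reproduce all four multidegree families in expectation. With Lagrange
multipliers λ_i^m, μ_j^m and x = e^(−λ), y = e^(−μ), the ensemble factorises
over pairs with

    p_ij^(1,0) = x_i⁺ y_j⁺ / D_ij,  p_ij^(0,1) = x_i⁻ y_j⁻ / D_ij,
    D_ij = 1 + x_i⁺ y_j⁺ + x_i⁻ y_j⁻,

and p⁺ + p⁻ + p⁰ = 1 per pair. Binding prediction is conditional on a pair
being annotated at all: p⁺/(p⁺+p⁻) for fitted pairs. Averaging over an unseen
side, the constraints collapse this to the known node's degree ratio
ρ = k⁺/(k⁺+k⁻); averaging over both sides gives L⁺/(L⁺+L⁻). These identities
are asserted in the tests to 1e−8 and make the model a features-blind
baseline: on fully inductive test sets its score is constant, hence tie-aware
AUROC is exactly 0.5 and AUPRC equals test prevalence.

### Solver

The convex dual is solved by damped alternating fixed-point iteration,

    x_i^m ← k_i^m / Σ_j (y_j^m / D_ij),

with geometric damping x ← x_old^(1−γ) · x_prop^γ (γ = 0.5 by default),
side-alternating sweeps, warm start x^m = k^m/√(L^m+1). Convergence is
declared when the largest absolute gap between expected and observed
multidegrees falls below `tol` (default 1e−10 absolute; desk-scale networks
take 50–150 iterations). Zero-degree node-layers keep x = 0 exactly. The dual
is strictly convex in the pairwise products x_i y_j, so all convergent runs
agree in probabilities; the multipliers themselves carry a per-layer scale
gauge (x·c, y/c) and are not individually identified — comparisons are always
made in probability space. A generic L-BFGS minimisation of the dual free
energy is kept in the test suite as an independent oracle.

### Saturated (boundary) ensembles

Some degree sequences admit no finite multipliers: a node whose layer degree
equals the number of active partners in that layer (its links are forced to
probability one), or whose total degree equals the number of partners it can
be annotated with at all (its p⁰ entries are forced to zero). These are
detected upfront (`detect_saturated_nodes`); fits involving them cap
multipliers at e^30, warn, and report the nodes and the residual attained
rather than failing silently. Rare subset-level boundary cases that escape
detection surface as an explicit non-convergence error carrying the residual.
Conditionals of the form 0/0 (both layers structurally absent for a pair)
raise instead of defaulting to 0.5, so callers must decide.

## Data preparation

Kinetic measurements (Ki, Kd, IC50, EC50, in nM) are labelled by fixed
thresholds: ≤ 10³ nM positive, ≥ 10⁶ nM negative, boundaries inclusive.
Records outside 20–45 °C are discarded; records without a stated temperature
are kept by default because curated interaction lists carry none. Multiple
measurements of a pair are aggregated by median within each constant type;
pairs with evidence on both sides of the thresholds, or only between them,
are dropped with a stated reason. Aggregation by median is a deterministic,
outlier-robust choice. Curated binding annotations merge in as positives
unless the same pair carries an experimental negative, in which case the pair
is excluded entirely.

Network-derived negatives use hop distances on the positive-only bipartite
graph (ligand–protein distances are odd): training negatives are sampled
uniformly without replacement at distance exactly 7 (a `min_only` switch
relaxes this to ≥ 7), evaluation negatives are all finite pairs at ≥ 11 hops
plus experimental absolute negatives, never overlapping training pairs.
Unreachable (infinite-distance) pairs are excluded from both pools: a hop
count presupposes a path. Every sampled pair is re-verifiable against an
independent all-pairs shortest-path oracle in the tests. The both-signs
filter removes pairs incident to nodes whose remaining annotations are
single-signed and iterates to a fixed point, because one removal can leave a
neighbour single-signed; a single pass does not guarantee the stated
post-condition.

## Splits and metrics

Transductive folds partition pairs; test pairs touching a node absent from
the fold's training pairs are discarded. Semi-inductive folds partition
proteins; test pairs must have a seen ligand. Inductive folds partition both
node sets jointly; only held-out-by-held-out pairs are tested and cross pairs
are dropped from that fold. All invariants are validated on construction.

AUROC uses the Mann–Whitney midrank formulation (ties count 1/2). AUPRC is
uninterpolated average precision with tied scores entering as one threshold
block, so constant scores give exactly the prevalence. The F1-optimal
threshold is searched over observed scores with ties broken toward the lowest
threshold. Confusion reports carry both tp/(tp+fn) (labelled sensitivity) and
tp/(tp+fp) (labelled precision) to keep the two readings of "fraction of
predicted binders that bind" unambiguous. Docking-style affinities binarise
at −1.75 kcal/mol (binder iff ΔG at or below threshold). Shortcut diagnostics
are Spearman correlations (Pearson on midranks) between per-node mean
predictions and training degree ratios, and between node degree and mean
kinetic value.

## Embeddings and the binding scorer

The scorer consumes fixed-dimension vectors through a provider contract
(`side`, `dimension`, deterministic `embed`). Default providers are
self-contained hashed n-gram embeddings: character 2–4-grams of a SMILES
string into 300 buckets; overlapping amino-acid trigrams (wildcards X/U/B/Z
collapsed) into 100 buckets; both L2-normalised, hashing via salted blake2b
so vectors are stable across processes. Pre-trained embedding tables
(word2vec-style models trained on large corpora) plug in through
`TableEmbedding`/`read_embedding_table`; unknown ids map to the table mean
rather than failing.

The head is deliberately small: linear branch projections 300→64 and 100→64,
then the concatenation of the two branch outputs *and their elementwise
product* feeds 192→64→32→1 with ReLU and a logistic output. The product term
is essential: pure concatenation cannot represent ligand–protein interaction
terms, and binding is an interaction — in the latent-feature test world the
label has zero marginal signal in either molecule alone. Inputs are rescaled
by √dim so unit-L2 embeddings give O(1) pre-activations under Glorot
initialisation.

Training is mini-batch Adam (learning rate 3e−3, batch 64) on binary
cross-entropy, at most 200 epochs. Early stopping monitors the *ranking* of a
validation split (loss 1 − AUROC, patience 15): trained scorers become
overconfident — validation cross-entropy diverges — long before their ranking
degrades, so a probability-based stop would halt near initialisation. When
the validation split is single-class the monitor falls back to
cross-entropy. Given a seed, the loss trace and predictions are bit-for-bit
reproducible. The ensemble trains one member per cross-validation fold
(default 5), each validated on its held-out fold, and predicts the arithmetic
mean of member probabilities (member variance available alongside).

## Binding-site profiles

For a trained scorer and a protein of length n, the profile has n−2 entries:
at each trigram start position the occurrence count of that trigram is
decremented, the protein is re-embedded from the modified counts, and the
pair re-scored. This is the smallest perturbation consistent with removing
one trigram occurrence; both raw perturbed scores and baseline-minus-score
deltas are emitted. Valley calling smooths with a moving average (window 5),
flags positions below mean − 0.5·std of the smoothed profile, merges runs
separated by gaps ≤ 2, and assigns each valley the depth baseline − raw
minimum; all three knobs are exposed. Valley calling is invariant under
adding a constant to the profile. Secondary structure, when supplied as a
per-residue H/E/C string, fills each valley's helix fraction over its covered
residues (trigram window start..end+2); valleys more than half helix are
dropped and survivors are ranked by depth, reflecting that α-helices favour
buried, weakly interacting environments while β-sheets and coils are the
preferred binding environments.

## Synthetic worlds

`gen_imbalanced_duplex` emulates the statistical pathology of curated binding
data. Degrees are drawn from discrete power laws (target exponents 2.94 for
ligands, 2.84 for proteins) via inverse-CDF sampling with the half-integer
continuity shift, and wired by bipartite stub matching; stub totals are
equalised by duplicating stubs on the deficient side (size-biased, preserving
the degree-sequence shape) and multi-edges collapse. Each wired pair receives
log10 Kd = a − b·log10(k_i·t_j) + ε with defaults a = 5.0, b = 2.5,
ε ~ N(0, 1.5²), chosen so that, at the default 2000×1000 size, (i) both label
classes appear at all scales used in the tests, (ii) the planted degree–Kd
anti-correlation is clearly diagnosable (Spearman below −0.2 on both sides on
log-affinities), and (iii) annotations are strongly imbalanced (most degree
ratios at the extremes), the regime in which topological shortcuts thrive.
Pairs between the thresholds yield records but no annotation, as in real
pipelines. Affinity aggregation in the diagnostics uses log10 values: the
planted law is log-linear and linear-scale means are dominated by single
heavy-tail draws.

`gen_feature_world` builds the complementary world where features, not
topology, decide binding: each node carries a latent standard-Gaussian vector
(dimension 8), a pair binds iff the logistic of the latent dot product
exceeds 1/2 (labels flipped with probability 0.05), and a seeded fraction of
pairs is observed as annotations. Structures are synthetic strings: each
latent coordinate is quantised into 8 equiprobable levels and a fixed random
token per (dimension, level) is emitted (4-character SMILES-alphabet tokens
×2 for ligands, amino-acid trigrams ×3 for proteins), so hashed n-gram
embeddings are noisy linear images of the latents (first canonical
correlation with the latents exceeds 0.5). What this world does *not*
emulate: real chemistry, realistic degree structure, or any relationship
between string syntax and physics — passing on it shows a model can exploit
structure-borne information when it exists, not that it understands
molecules.

## Problem sizes and estimator settings used in the checks

The end-to-end inductive-recovery check uses 500 ligands × 400 proteins with
5% of pairs observed (~10 000 annotations): enough *node diversity* for an
embedding model to learn a transferable structure→latent map — with few
hundred nodes the scorer can only memorise node identities and inductive
AUROC stays near chance even though the information is present (a ridge
oracle reading the latents off the embeddings reaches AUROC ≈ 0.86 at this
size, bounding what the head could achieve). Constraint-recovery and
normalisation checks run on networks up to ~70×70; solver-vs-oracle
equivalence on 50 random duplexes up to 6×6.

The Hill estimator γ̂ = 1 + n/Σ ln(k/(k_min − ½)) is a continuous
approximation: on integer degrees it is biased low for k_min in the
distribution head (≈ −0.6 at k_min = 1), shrinking to < 0.02 by k_min ≈ 6.
Recovery tests therefore fit the tail (k_min = 6 on raw samples, k_min = 3 on
realized network degrees) and the estimator is documented as a diagnostic,
not an inferential tool.

## Known limitations

- The configuration model is analytic-only: no Monte-Carlo sampling of
  ensemble realisations.
- Semi-inductive prediction for an unseen *ligand* (known protein) is the
  symmetric extrapolation of the unseen-target formula and is tagged as such
  in routed output.
- Hashed fallback embeddings collide by construction; they are stand-ins for
  pre-trained embeddings in tests and demos, not chemically meaningful
  representations.
- The valley-calling thresholds are heuristics with exposed knobs, not
  calibrated detectors; profiles inherit any bias of the underlying scorer.
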