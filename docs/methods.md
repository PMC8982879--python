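# Methods

This note documents the model, its parameters, the synthetic data the
package is validated on, and the design decisions taken where the design
was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model

### Structure graphs and invariant features

A single chain is reduced to its ordered C-alpha trace. The graph is
complete: every residue pair is connected with weight
`A_ij = omega / max(D_ij, eps)` (`omega = 4`, `eps = 2`), which bounds
all entries to (0, 2], gives a self-loop of exactly 2, and caps the
weight of sterically impossible short distances. The adjacency is used
as is — the epsilon floor and the bounded range already play the role
normalisation would.

Node features must be invariant to rigid motion so that the descriptor
is a function of conformation only:

* **Reference-point distances.** The chain is split into a dyadic
  hierarchy of contiguous fragments: level m (m = 0..M−1) has 2^m
  fragments, fragment g spanning residues
  `[floor((g−1) N_r / 2^m), ceil(g N_r / 2^m))`. Each fragment
  contributes its centroid; every residue's feature vector holds its
  distances to all 2^M − 1 centroids, emitted in (level, fragment)
  order. At the default M = 5 that is 31 reference points. The
  hierarchy encodes where a residue sits relative to the global fold at
  five spatial scales. Chains must have at least 2^(M−1) = 16 residues
  so every finest-level fragment is non-empty; that is the package's
  only length filter.
* **Bend-angle cosine.** For interior residues,
  `cos theta_i = (v_i − v_{i−1})·(v_{i+1} − v_i) / (|v_i − v_{i−1}||v_{i+1} − v_i|)`;
  terminal residues (and residues flanking a zero-length segment) get 0.
  This is the local-geometry complement to the global distance features.

Both feature families are functions of inter-point distances and angles
only, hence exactly SE(3)-invariant; they are also achiral, so
mirror-image folds receive identical descriptors — a known limitation.

### Encoder

`raw features (N_r × 32)` → MLP → BiLSTM → residual GC blocks → max pool:

1. an MLP lifts the 32 raw features (distance columns pre-scaled by 0.1
   so all inputs are O(1) without batch statistics);
2. a bidirectional LSTM concatenates forward/backward hidden states per
   residue — graph convolution aggregates neighborhoods permutation-
   invariantly and cannot see chain order, so sequential context must be
   injected before it;
3. residual graph-convolution blocks
   `X'' = leaky_relu(A · relu(A X W1) · W2 + X W_s)`, ReLU and dropout
   after the first convolution of each block, `W_s` the identity
   whenever dimensions already match;
4. a global max pool over residues, then L2 normalisation, yields the
   descriptor; the final node matrix (rows L2-normalised on output) is
   the residue-level embedding used for alignment.

The descriptor length L is an architecture constant independent of
chain length.

### Contrastive training

Momentum contrast with two same-architecture encoders: the query encoder
(trained by SGD with momentum) and a key encoder updated only by
`theta_k ← m·theta_k + (1−m)·theta_q`. Keys encoded each iteration are
pushed into a FIFO queue (initialised with random unit vectors) whose
entries are the InfoNCE negatives; when full, the earliest entries
dequeue.

The dynamic training-data partition supplies positives and the negative
rule: per query, database structures are ranked by ground-truth
similarity (ties broken by ascending id); the positive is sampled
uniformly from the top-K% subset; a structure is a valid negative only
if strictly less similar to the query than the sampled positive. Queue
entries violating that predicate are masked out of the loss denominator;
entries without a similarity record (the random initial vectors) always
count as negatives. The InfoNCE denominator includes the positive term,
so the loss is non-negative and equals ln(n+1) when all n negatives tie
the positive. The alternative "static" partition (positives = the
0.9 × max structural-neighbor set, negatives = the rest) is provided for
the ablation comparison.

Validation (mean per-query AUPRC of plain-cosine ranking under the
0.9 × max neighbor rule) runs at a fixed cadence and drives a
divide-by-10 plateau schedule (patience 5 evaluations, relative
improvement threshold 1e-3, at most 3 decays); the parameters with the
best validation AUPRC are restored at the end of training. Gradients
are globally norm-clipped (default 5.0); a non-finite loss aborts with a
diagnostic. One master seed feeds separate derived streams for
parameter initialisation, queue initialisation, sampling and dropout, so
single-threaded runs are bit-reproducible.

## Parameters

| parameter | default | desk-scale (`*.small()`) | meaning |
|---|---|---|---|
| omega, eps | 4, 2 | same | adjacency normalisation (A in (0,2], diag 2) |
| M | 5 | same | 2^M−1 = 31 reference points, d = 32 features |
| L (descriptor_dim) | 512 | 64 | descriptor / residue-embedding width |
| mlp_dims | (64, 128) | (32,) | MLP widths before the BiLSTM |
| lstm_hidden | 64 | 16 | per-direction LSTM width |
| n_res_blocks / gc_dim | 3 / 256 | 1 / 64 | residual GC stack |
| dropout | 0.1 | 0.0 | after the first GC layer of each block |
| tau | 0.07 | same | InfoNCE temperature |
| queue n | 1024 | 128 | negative-queue capacity |
| m (EMA) | 0.999 | 0.99 | key-encoder momentum |
| K% | 30 | same | dynamic-partition subset size |
| batch / lr / SGD momentum | 64 / 0.1 / 0.9 | 8 / 0.02 / 0.9 | optimiser |
| iterations | 2.4e5 (full scale); 20 × dataset if unset | 400–800 typical | training length |
| gap open / extend | 0 / 0.1 | same | residue-alignment gap model |
| rho | 0.9 | same | structural-neighbor threshold |

Full-scale defaults follow the published training recipe; the
desk-scale column is this package's reduced configuration for CPU-sized
experiments. Two desk-scale values need justification: the EMA momentum
is lowered to 0.99 because at 0.999 the key encoder would still sit
halfway between its initial and current parameters after ~700
iterations, filling the queue with stale keys (at 2.4e5 iterations this
effect vanishes, hence the full-scale 0.999); the learning rate 0.02 was
chosen once for stability of the small no-BatchNorm network. L = 512 as
the full-scale descriptor width is this package's choice — the
descriptor length is an architecture constant the original recipe does
not state.

## Design decisions

* **Bend-angle formula.** The angle feature is implemented as the cosine
  of the bend angle between consecutive chain segments. A literal
  transcription of the printed formula would be a ratio of segment
  lengths (its numerator is a segment's squared norm), contradicting the
  stated meaning "angles formed by three consecutive C-alpha atoms"; the
  geometric reading is adopted.
* **InfoNCE denominator.** The printed loss sums the denominator over
  negatives only; the standard form (positive included) is implemented,
  guaranteeing a non-negative loss with an exact ln(n+1) uniform case.
* **Length-scaling asymmetry direction.** The formula makes a longer key
  *shrink* the distance: d(a,b) ≤ d(b,a) when l_a < l_b. (Prose
  descriptions sometimes state the opposite inequality; the formula and
  its worked value 0.4 are taken as authoritative, and this is the
  direction TM-score's query-length normalisation induces.)
* **Top-K hit ratio is not monotone in K.** With the min(K, N_nbr)
  denominator, Ratio_K can drop as K grows while K < N_nbr (one neighbor
  at rank 1 of five gives Ratio_1 = 1, Ratio_2 = 1/2); monotonicity
  holds once K ≥ N_nbr. Tests assert only what holds.
* **No padded batching / no batch normalisation.** Mini-batches are
  processed structure by structure with gradient accumulation — on one
  CPU with numpy, padding buys nothing and the mask machinery falls
  away. Without cross-sample batch statistics, (shuffled) batch
  normalisation is moot and omitted; input pre-scaling plus gradient
  clipping fill its stabilising role at this scale.
* **Training uses plain cosine; length scaling is test-time only.**
* **Gap model.** "Open 0, extend 0.1" is implemented as affine with the
  extension charged on every gap column including the first (a gap of g
  columns costs 0.1·g at the default open of 0). Gap-to-gap transitions
  between the two gap states are allowed: with negative similarities it
  can be optimal to leave a residue of each structure unmatched.
* **Residue-level embeddings** are the final GC-block node matrix,
  L2-normalised per row only where consumed as residue descriptors.
* **Ranking determinism.** Distance ties break by ascending structure
  id; the query is excluded from its own ranking by id equality.
* **Neighbor rule.** TM_max excludes the self pair (otherwise self
  TM = 1 would trivialise the threshold); the arg-max structure is
  always a neighbor. Queries with zero neighbors are excluded from
  ranking metrics with a warning.
* **Significance gate.** Normality of the 10 paired half-sample means is
  checked with Shapiro-Wilk at alpha = 0.05 → paired t-test if normal,
  Wilcoxon signed-rank otherwise; all-zero differences report
  "identical", p = 1.
* **Model selection.** Training returns the best-validation-AUPRC
  parameters rather than the last iterate; at desk scale the contrastive
  objective can drift past its best retrieval operating point.

## Synthetic data: what it emulates and what it does not

`make_benchmark` emulates a miniature fold database: each archetype is an
idealised C-alpha trace (helix bundle wound around an up/down guide
curve; near-extended strand meanders; a mixed helix+hairpin; smooth
random coils) built by walking a parametric curve at 3.8 Å steps
(consecutive C-alpha distances within [3.7, 3.9] Å). Families are made
by Gaussian coordinate noise at graded scales (defaults 0.25–2 Å), a
SHAKE-like relaxation restoring spacing to 3.8 ± 0.15 Å, and a random
rigid motion so every consumer exercises invariance.

Ground truth is a same-length TM-score: with the identity residue
correspondence, a Kabsch fit is refined by 5 iteratively reweighted
rounds (weights `1/(1+(d/d0)^2)^2`, keeping the best TM-sum), with
`d0 = max(1.24 (L−15)^(1/3) − 1.8, 0.5)` — the floor because the
cube-root form goes negative below L = 22. Archetypes get distinct
lengths, so the oracle's equal-length restriction never binds within a
family; cross-family pairs receive a configurable floor of 0.17, the
literature's random-pair expectation. This avoids implementing a full
alignment-searching TM computation, which is out of scope.

A green test on this data establishes that the pipeline — featurization,
contrastive optimisation, retrieval, evaluation, alignment — recovers a
known similarity structure well above chance. It does not establish
performance on real fold databases: real domains have side chains,
irregular loop geometry, domain insertions, and cross-length homology
that the floor-score convention flattens; absolute metric values here do
not transfer.

## Numerical choices

* Descriptors are L2-normalised with a 1e-12 epsilon; `info_nce` and the
  queue reject vectors whose norm deviates from 1 by more than 1e-4.
* The InfoNCE softmax is computed through a max-shifted log-sum-exp.
* Kabsch uses SVD with the determinant correction (reflections are never
  returned); degenerate tie directions fall to numpy's SVD conventions.
* NW traceback ties break diagonal > up > left at a 1e-9 score
  tolerance.
* Autodiff is float64 throughout; gradients are checked against central
  finite differences in the test suite.
* `tm_oracle` keeps the maximum TM over reweighting rounds, making the
  result symmetric in its arguments to ≤ 1e-9 for equal lengths.

## Known limitations

* No chirality term: mirror folds are indistinguishable by construction.
* The TM oracle requires equal lengths; cross-length supervision is the
  constant floor, so the model sees no graded cross-length signal.
* Desk-scale training budgets (hundreds of iterations, 60 structures)
  are orders of magnitude below the published regime; conclusions about
  the *relative* benefit of training components at this scale are noisy,
  which is why the partition ablation is asserted as a majority vote
  over seeds, direction only.
* The residue aligner is deliberately simple (no end-gap variants, no
  iterative refinement) — it demonstrates that embeddings carry
  correspondence information, not alignment-tool quality.
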