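# Methods

## The model

`biographfusion` answers knowledge-graph queries of the form
*(head entity, relation, ?)* over multi-relational biomedical graphs
(disease–gene, protein–chemical, ontology links, ...).  Its score for a
candidate tail couples two branches that are trained jointly:

**Global semantic branch (CP).**  The graph's binary adjacency tensor is
modelled in factorized canonical-polyadic form by three matrices — head
embeddings `E_h (|V| x D)`, relation embeddings `E_r (|R| x D)` and tail
embeddings `E_t (|V| x D)`.  A triple's semantic compatibility is the
trilinear product `phi(h, r, t) = sum_d e_h(d) e_r(d) e_t(d)`.

**Query-guided structural branch (GSP).**  Starting from the query entity
(whose initial representation is its CP row), each of `L` layers

1. expands the frontier along every outgoing augmented edge (the graph
   carries one inverse edge per fact and an identity self-loop per entity);
2. refines relation embeddings with a single-step LSTM cell whose input is
   the relation embedding and whose hidden state is the head-entity
   embedding (contextual relation refinement, CRR); the query relation is
   refined the same way against the query entity;
3. aggregates per-edge messages
   `h_t = tanh(W sum alpha (h_head + e_rel))`, where the gate
   `alpha = sigmoid(w_a' ReLU(W_a (h_head + e_rel + e_qrel)))` is a
   per-edge sigmoid conditioned on the refined query relation;
4. scores every candidate with a linear relevance readout
   `s_t = W_samp h_t` and keeps the top `K`.  At inference this is exact
   top-K (ties by ascending entity index); during training it is `K`
   Gumbel-perturbed hard argmax picks without replacement whose backward
   pass uses the softmax relaxation's gradient (straight-through).  The
   query node is always retained.

The final score is the fusion `lambda * f + (1 - lambda) * phi`, with
`f = w' h_qa` the readout of the answer's final representation (0 if the
candidate never entered the subgraph) and `phi` computed with the
LSTM-refined query relation, so the refinement influences both branches.

**Loss.**  Multi-class log-loss over *all* entities (other true answers
included; filtering is evaluation-only) plus `gamma` times the N3 penalty
`|e_qe|_3^3 + |e_qr^L|_3^3 + |e_qa|_3^3` (L1 / squared-L2 selectable).
Evaluation reports filtered MRR / Hit@1 / Hit@10 with pessimistic tie
handling (the answer loses ties).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `embedding_dim` (D) | 32 | CP rank / representation width |
| `n_layers` (L) | 6 | propagation steps; bounds path length |
| `top_k` (K) | 100 | frontier size kept per layer |
| `fusion_weight` (lambda) | 0.7 | structural-vs-semantic mix |
| `gamma` | 1e-3 | embedding-penalty strength (dimensionless) |
| `temperature` | 1.0 | Gumbel noise scale during training selection |
| `batch_size` | 16 | queries per gradient step |
| `lr` | 1e-3 | Adam step size |

Every training fact also contributes its inverse query
(`train_inverse`).  Early stopping monitors validation MRR (patience 10
epochs) and the best-validation snapshot is restored.

## Training-time answer masking

For each training query the fact `(qe, qr, qa)` *and its inverse* are
hidden from that query's frontier expansion.  Without this, the structural
branch simply learns to copy the direct edge — which is absent for
held-out queries — and validation performance collapses to chance while
the training loss falls.  This is the standard protocol in query-guided
subgraph reasoning.  We also evaluated force-retaining the answer in the
training-time selection; it guarantees a learning signal but creates
exposure bias (selection never learns to keep the answer on its own
merits) and measurably hurts held-out ranking, so it is not used.

## Numerical choices

* **Degree-aware message initialization.**  Node updates *sum* over all
  incoming edges; with mean degree `d` the tanh pre-activations grow like
  `sqrt(d)`–`d` and the network is born saturated (we measured mean
  |pre-activation| ~ 12 at layer 3 under generic initialization, i.e. a
  dead gradient).  Each layer's `W` is therefore initialized with scale
  `1 / (sqrt(D) (1 + d))` where `d` is the graph's mean outgoing degree.
* **Near-pass-through refiner initialization.**  A generically
  initialized LSTM cell (gates near 0.5, random candidate weights) maps
  every relation embedding to a small, nearly relation-independent vector
  — the attention then cannot tell relations apart and path-following
  never starts.  The refiner starts with input/output gate biases at +1
  and the candidate weight at the identity plus noise, so refinement is
  approximately relation-preserving at initialization and context
  sensitivity is learned on top.
* **Coupled selection/readout initialization.**  The relevance row
  `W_samp` starts as a copy of the readout `w` (they remain independent
  parameters).  Selection then keeps exactly the candidates the readout
  ranks high from the first epoch, so the two learned components cannot
  fail independently: a run where the readout never differentiates would
  otherwise also leave the selection arbitrary, and the answer would be
  absent from the inference-time subgraph for most queries.
* **Shared vs separate refiners.**  By default one cell refines both edge
  relations and the query relation.  Empirically the two roles conflict
  when parameters are shared (the edge-refinement gradients degrade the
  stability of the query-relation code that the attention conditions on);
  `separate_query_refiner=True` gives each role its own parameters and is
  used in the benchmark configurations below.
* **Optimizer.**  Adam (Adagrad selectable) with optional decoupled
  weight decay, global-norm gradient clipping, and halving of the step
  size when validation MRR stalls.
* **Selection details.**  The straight-through backward pass applies the
  exact Jacobian of the summed per-pick masked softmaxes (computed in a
  single vectorized pass via within-segment suffix sums).  Because the
  Gumbel perturbation is fixed within a selection round, the iterative
  argmax picks equal the top-K of the perturbed scores; ties break by
  ascending entity index so runs are reproducible.  Scores of candidates
  filtered at ranking time are set to -inf; all-equal scores rank the
  answer last (pessimistic).
* **Degenerate inputs.**  An empty candidate set stops propagation with a
  warning and the last non-empty frontier is kept; `K >=` candidate count
  keeps everything; a zero-scale initialization is valid (all-zero
  factors).

## Synthetic data: what it emulates, what it does not

Real benchmark graphs (disease–gene, protein–chemical, ontology) are
external downloads; the package ships two generators that reproduce the
*statistical structure the two branches assume*, so every claim the test
suite makes is about mechanism, not biology:

* `generate_cp_kg` plants rank-`r` factors and emits the top-scoring
  cells as facts — a graph whose truth *is* a low-rank tensor.  A purely
  semantic model should recover held-out links.
* `generate_rule_kg` samples random body-relation facts and materializes
  every rule-head triple implied by composing them (e.g.
  `disease_chemical(a, c) <= disease_gene(a, b) and gene_chemical(b, c)`),
  holds out a fraction of the rule heads as valid/test queries (their
  edges removed), and injects spurious random facts.  Recovering the
  held-out heads requires multi-hop structural reasoning; the retained
  rule heads are training queries and the body facts are background
  structure.

Neither generator emulates the degree heterogeneity, typed-entity
structure, or annotation noise of real biomedical databases; passing the
recovery tests shows the two branches work as designed, not that the
model reaches any particular accuracy on DisGeNET-scale data.

Default conditions for the rule benchmark: 50 entities, 3 base relations,
one body-length-2 rule, 8 sampled facts per entity, 5 % spurious facts,
split 70/10/20 — roughly 450 training and 130 held-out test rule heads.
The CP benchmark uses 40 entities, planted rank 4, 8 facts per entity.

## Benchmark configurations and problem sizes

Chosen by validation MRR on the synthetic graphs, sized so the full suite
runs comfortably on one CPU:

* **Rule recovery (full model):** D=16, L=3, K=20, lambda=0.7, Adam
  lr 1e-2, batch 64, gamma=0.3 (N3), weight decay 1e-3, separate query
  refiner, forward-direction training queries only, up to 150 epochs
  with early stopping; the semantic-only comparison uses the identical
  configuration with the ablation flag flipped.
* **CP recovery (semantic-only):** D=32, Adam lr 0.1, squared-L2
  gamma=0.03, batch 16, up to 300 epochs.

The strong `gamma` in the hybrid configuration is load-bearing: with a
weak penalty the semantic branch's scores outgrow the bounded structural
readout, dominate the shared softmax, and the structural branch stops
learning.

Two exploratory training schedules are exposed but off by default:
scheduled answer guidance (force-retain the answer during selection with
a probability annealing to zero) and K continuation (train-time top-K
annealing from full coverage down to the configured K).  Neither
improved held-out ranking in our experiments; they are kept as
configuration options for study.

## Known limitations

* Training of the structural branch is bimodal: runs either organize
  into a path-following solution or settle into a flat one where every
  reached entity scores near zero, and which basin a run finds is
  sensitive to the random initialization and data order.  The strong
  embedding penalty, the coupled selection/readout initialization and
  separate refiners raise the success rate substantially (roughly three
  in four seeds on the rule benchmark), but individual seeds can still
  land in the flat basin; medians over seeds are the meaningful summary.
* The per-edge sigmoid attention (the printed formula) performs no
  normalization over edges; very high-degree nodes therefore rely on the
  degree-aware initialization and the learned gates to keep message
  magnitudes bounded.
* The straight-through estimator is biased by construction; the
  finite-difference gradient validation is run with deterministic
  selection and `K >= |V|`, the only regime where analytic and numeric
  gradients are mathematically comparable.
* Checkpoints store arrays with a JSON metadata header (npz container);
  they are version-tagged but not guaranteed stable across package
  versions.
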