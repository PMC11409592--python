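# Methods

## Model

A document of T tokens is represented as a graph with one node per token
*position* (not per unique word type); embeddings are shared by word type, so
a word appearing k times contributes k nodes and hence k terms to the
sum-pooling readout. This reconciles the word-node picture of graph-of-words
representations with positional neighborhoods: the neighbors of a node are
the positions within token distance d in the text, and the neighborhood size
is not configured separately from d — both are one windowing concept.

Messages are neighbor embeddings scaled by trainable edge weights shared
globally by *ordered* word pair. Three aggregation rules are implemented:

- `max` — dimension-wise maximum over incoming weighted messages, followed by
  the retention update r ← (1−η)·M + η·r with per-node trainable η squashed
  into (0,1) by a sigmoid. This is the reference text-level GCN behavior,
  kept for comparison; it requires per-node bookkeeping and does not batch
  well.
- `dense_sum` — M = A·H with A the full (T×T) weighted adjacency matrix.
  Quadratic in T; retained as the transparent oracle the sparse path is
  tested against.
- `sparse_sum` (default) — the same weighted sum computed by gathering
  edge-indexed rows and scatter-summing by target node; in batched training
  this is one sparse matrix product over the whole batch graph.

With the sum rules the registered self edge (w, w) carries the information
the retention coefficient carries under the max rule, so η defaults off; it
remains available (`use_eta=True`) in every mode for reference fidelity.

Word pairs never registered during training resolve to a single *public*
trainable weight (identifier 0). Together with the UNK token this makes
inference closed over arbitrary new documents: deployment to a registry whose
data never entered training requires shipping only the parameter tables.

The readout sums final node states over real (non-PAD) nodes and applies one
linear head + softmax per task: y_t = softmax(σ(V_t·pooled + b_t)). σ is the
rectifier by default (identity and tanh are available); the nonlinearity
sits between the head and the softmax, so the trunk is linear and the model
is close in spirit to a learned, structure-weighted bag of embeddings — which
is also why it trains quickly and stably.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `window` (d) | 10 | max token distance defining co-occurrence; 10 was the best-performing distance with dropout in the benchmark grid (2/5/10) |
| `embedding_dim` (w) | 300 | node-embedding length; at 202,373 word types this gives the 60,711,900-entry embedding block that dominates (~90%) the parameter count |
| `edge_min_count` | 1 | corpus-count threshold for registering a word pair; rarer pairs use the public weight |
| `self_loops` | on | registers (w, w) pairs for every non-PAD word; required by `max` mode, plays η's role in sum modes |
| `aggregation` | `sparse_sum` | see above |
| `n_layers` | 1 | aggregation+update rounds; the lineage this model belongs to uses a single pass |
| `dropout` | 0.25 | applied to the pooled document vector at training time (benchmark grid: 0.0/0.25) |
| `batch_size` | 256 | benchmark grid: 64/256/512/10240 |
| `learning_rate` | 1e-3 | Adam; standard for sparse-gradient embedding models |
| `min_count` | 1 | keep every word type, mirroring full-vocabulary training at corpus scale |
| `max_len` | 1500 | head truncation (earliest tokens kept) — diagnosis fields typically lead a report; tail truncation available |

Initialization: embedding rows ~ N(0, 1/w) with the PAD row frozen at zero
and excluded from pooling; edge weights 1 + N(0, 0.01²) so the initial
aggregation is close to an unweighted neighborhood sum; heads have small
random V and zero bias; η starts at 0.5. Missing labels are masked out of the
loss (registry data is routinely partial), with equal weights across tasks.
Early stopping monitors the validation aggregate (mean of 2×n_tasks F1
scores) with patience 5 by default and returns the best-validation
parameters. Training is single-worker and fully seeded; identical seeds give
bit-identical loss trajectories and logs.

## Gradients and numerics

All arithmetic is float64. The backward pass is written by hand: the model is
a chain of embedding lookup, sparse linear aggregation, (optional) convex
retention update, masked sum-pooling, dropout, a linear head, one elementwise
nonlinearity and softmax cross-entropy, each with a closed-form adjoint. The
suite checks the implementation against central finite differences (1e-4
relative tolerance) for embedding, edge-weight and head entries. Under the
max rule the gradient is routed to the argmax edge per (node, dimension),
split equally on exact ties. Cross-entropy is computed from pre-softmax
activations via log-sum-exp. Sparse and dense sum paths agree to summation
-order rounding (observed ≤ ~1e-14 on random graphs; the contract asserts
1e-5). A non-finite training loss aborts with a diagnostic rather than
continuing.

Micro/macro F1 are delegated to scikit-learn. Macro averaging runs over the
classes observed in truth ∪ predictions by default: tasks with hundreds of
registered classes never realize all of them in a finite test set, and this
keeps a score of 1.0 meaning "every realized class perfectly predicted".
Registry-universe averaging (all registered classes, absent ones scoring 0)
is available via `class_universe="registry"`. Zero-denominator per-class F1
is defined as 0.

## Synthetic corpus

The generator emulates the structure of registry pathology reports without
any real text: per document, one templated field phrase per non-omitted task
(field omission rate 0.08 exercises the loss mask), with word inversion
(p=0.3), parenthetical insertion (p=0.3) and synonym substitution (p=0.5)
applied independently, interleaved with 1–3 filler sentences. Class counts
are reduced (site 6, subsite 12 nested two-per-site, laterality 4, histology
10, behavior 3, grade 5) to keep desk-scale runtime while preserving the
few-class vs many-class contrast; class priors follow a power law with
exponent 1.5 over class rank, giving rarest-class frequencies near 1.5% —
severe but learnable imbalance at a few thousand documents. Optional noise
tokens (off by default) can be injected between words.

With noise off, labels are deterministic functions of the text: the template
families of different classes within a task never share a complete token
set, so a rule-based matcher (`rule_based_labels`) recovers every non-omitted
label exactly. This guarantees the classification problem is solvable and
makes near-perfect F1 the correct training target — a converged model that
scores materially below 1.0 indicates a defect, not noise.

What passing on this corpus does **not** show: real reports have much larger
vocabularies (~200k types vs a few hundred), longer and less structured
prose, hundreds of classes per task with genuinely ambiguous boundary cases,
and labels that are not functions of any single phrase. Synthetic results
validate the machinery (representation, training, deployment fallbacks,
evaluation), not clinical task performance; the published per-task benchmark
scores bundled in `gowmpn.benchmarks` exist so the 12-score aggregate
statistic can be exercised, and are not recomputable without restricted data.

## Problem sizes in the test and acceptance runs

The learning-behavior check trains on 5,000 generated documents (validation
fraction 0.15) with w=48, d=3, dropout 0.25, batch 256, Adam at 5e-3 for up
to 60 epochs with patience 10 — a configuration chosen once as a desk-scale
training protocol; it converges to validation micro-F1 1.0 on all six tasks
in ~30 epochs. The single-task comparison run uses the same corpus, split and
evaluation protocol on the grade task. Sparse/dense equivalence is measured
over 100 random graphs of up to 50 nodes and w ≤ 16.

## Known limitations

- No distributed or GPU execution; this is a CPU reference implementation
  whose contribution is correctness and auditability, not wall-clock scale.
- `dense_sum` materializes a (T×T) matrix per document and `max` materializes
  per-edge contribution matrices; both are for small-to-medium documents.
- The edge registry stores ordered pairs in a Python dict; at 200k-word
  vocabularies with large d its memory footprint grows with the realized
  pair count, and `edge_min_count` pruning becomes advisable.
- Checkpoints embed vocabulary and registry verbatim and are versioned; no
  cross-version migration is attempted.
- The aggregate of 12 F1 scores is a comparison statistic only and carries no
  clinical meaning.
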