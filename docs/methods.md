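# Methods

## Protocol

One server coordinates `K` clients over `T` communication rounds.
Client `k` holds `n_k` labeled images (`n = Σ n_k`). The model `u` is a
small CNN whose parameter arrays are tagged *shallow* (all convolution
stages) or *deep* (all fully connected stages); the tags partition the
arrays, and `split`/`merge` of the two groups is an exact identity.

Per round `t = 1 … T`:

1. **Flag schedule.** `flag = 1` iff `t mod ES == 0` (rounds numbered
   from 1). `ES = 1` degenerates to synchronous full exchange.
2. **Selection.** `m = max(⌊C·K⌋, 1)` clients drawn uniformly without
   replacement.
3. **Broadcast.** Selected clients receive the full global model
   (flag = 1) or only its shallow group (flag = 0), which they overlay
   onto the deep arrays they retained from earlier rounds.
4. **Local training.** `E` epochs of mini-batch gradient steps (batch
   `B`, rate `η`, per-epoch reshuffle, short final batch kept). All
   layers are trained regardless of the flag; the flag restricts only
   what is *returned* (full model vs shallow group).
5. **Cache refresh.** A full return sets both the cached full model and
   its shallow projection and both timestamps to `t`; a shallow return
   refreshes only the shallow cache and `timestamp_s`. Hence
   `timestamp_g ≤ timestamp_s` always.
6. **Aggregation** over all `K` caches with raw weights
   `w_k = (n_k/n)·α^−(t − timestamp_k)`, normalized to sum to 1. On
   flag = 1 rounds the whole global model is replaced; on flag = 0
   rounds only its shallow group is, the deep group carrying forward
   from the last full exchange.
7. **Evaluation** of the global model on a held-out set; scalar traffic
   logged (uplink = downlink = responders × group size).

Normalizing by the weight sum is a deliberate choice: the raw weights
are sub-unit, so an unnormalized sum would shrink every parameter
toward zero each round. The normalized rule is a convex combination
(every aggregated scalar lies within the clients' range) and reduces
exactly to the `n_k`-weighted FedAvg mean when all caches are fresh —
the test suite checks trajectory equality with the synchronous FedAvg
implementation at `ES = 1, C = 1` to `1e-10` per scalar per round.

Stateless clients that are never selected still participate in the
aggregate through their cached initialization at timestamp 0; their
influence decays geometrically in `α`. Increasing one client's
staleness strictly decreases its normalized weight (tested property).

## Baselines

*FedAvg*: full-model exchange every round, `n_k`-weighted mean over the
responders only. *FedSGD*: each selected client computes one exact
full-batch gradient at the current global model; the server applies a
single step with the `n_k`-weighted mean gradient. FedSGD is
algebraically identical to FedAvg when each client takes exactly one
full-batch step (`E = 1, B = n_k`), checked numerically.

## Model

Input `(H, W, C)` images in `[0, 1]`. Per convolution stage: valid
convolution (configurable kernel/stride) → ReLU → 2×2 pooling, stride
2, average by default (max available by config), skipped when a spatial
dimension is below 2 and cropped on odd sizes. Then fully connected
stages with ReLU between them, inverted dropout (default rate 0.2)
after the first hidden FC stage during training only, a final linear
stage to `L` logits, and softmax cross-entropy via a log-sum-exp
stable formulation. Everything is float64.

Initialization: He-style scaled uniform, `W ~ U(±√(6/fan_in))`, biases
zero, seeded. Default architecture: two 3×3 stages of 8 and 16 filters
on 16×16×1 input, one hidden FC of width 32 — 3,460 parameters, of
which 1,248 are shallow.

Gradients are exact analytic backpropagation; the suite verifies them
against central finite differences (`ε = 1e-6`, relative error
`< 1e-5`) on ≤ 500-parameter networks over 20 seeds, for both pooling
kinds.

Dropout placement and rate, and the plain-SGD default optimizer
(Adam available per config, with moment state re-initialized each
round), are package choices where the protocol definition is silent.

## Synthetic data

Each class is a deterministic template — a filled disk of radius
fraction `r` with a sinusoidal ring texture of frequency `f` and
interior intensity `μ` on a 0.35 background — plus i.i.d. Gaussian
pixel noise (default sd 0.1), clipped to `[0, 1]`. With noise sd 0
every image of a class is identical. The default palette staggers
`μ`, `r`, `f` so neighbouring classes differ in at least two
parameters; the desk default task is 4 classes × 200 training and 50
evaluation images at 16×16×1.

What the generator emulates: class-conditional appearance with
controllable within-class variability and the published class-imbalance
bookkeeping (the eight-class totals and their five-client split are
carried as arithmetic fixtures and reproduced by the balanced
partitioner for every ±1-balanced published row). What it does *not*
emulate: dermoscopy realism (hair, color constancy, intra-class shape
variation), label noise, or client-specific acquisition shift. A green
learning test therefore establishes that the protocol's optimization
and aggregation machinery works, not that any accuracy level transfers
to real lesion images — the published GPU-scale benchmark numbers are
explicitly out of this package's scope.

Partitions: *balanced* (per class, seeded shuffle, remainder to
lowest-indexed clients; any two clients differ by ≤ 1 per class) and
*Dirichlet* (per-class client shares from a symmetric Dirichlet with
largest-remainder rounding, for non-IID stress tests; concentration
→ ∞ recovers the balanced split).

## Parameters that matter

| parameter | default | units / range | note |
| --- | --- | --- | --- |
| `K` (clients) | 5 | — | published client count |
| `C` (fraction) | 1.0 | (0, 1] | `m = max(⌊C·K⌋, 1)` selected |
| `T` (rounds) | 50 desk / 1000 paper | rounds | |
| `ES` (exchange period) | 2 | rounds | 1 ⇒ synchronous full exchange |
| `α` (staleness base) | e/2 ≈ 1.359 | > 1 | no published value; e/2 gives a gentle decay (weight ≈ 0.74 per round of staleness) |
| `E` (local epochs) | 3 desk / 60 paper | epochs | |
| `B` (batch size) | 32 desk / 128 paper | samples | |
| `η` (learning rate) | 0.001 | — | published setting; the desk learning-sanity world uses 0.01 |
| dropout rate | 0.2 | [0, 1) | after first hidden FC stage |

## Numerical and degenerate-case choices

- Zero-denominator metrics (e.g. precision of a never-predicted class)
  report 0 with a per-class `undefined` flag; macro averages are
  unweighted means including such zeros.
- Recall and sensitivity are the same quantity (`TP/(TP+FN)`) and are
  reported once.
- Argmax prediction ties break toward the lowest class index.
- `E = 0` returns the incoming parameters unchanged; `T = 0` yields an
  empty history and the initial model.
- A client with no data (or a failing client) is skipped with a logged
  warning; the round proceeds with the responders.
- Communication is counted in parameter scalars, converted to bytes at
  4 bytes/scalar (float32 on the wire); over `T` rounds the uplink is
  `m·(⌊T/ES⌋·|full| + (T−⌊T/ES⌋)·|shallow|)`.
- Seeds: one master seed per run; selection, per-(round, client)
  training, dropout, and data generation streams are derived through
  `numpy.random.SeedSequence` spawn keys, so runs are bit-reproducible
  and the asynchronous and baseline loops see identical client
  randomness for the same master seed.

## Known limitations

- "Asynchronous" means the layer-wise staggered exchange of the
  protocol, not wall-clock asynchrony: there is no network transport,
  straggler, or dropout-of-device simulation.
- The suitability-based client selection mentioned alongside the
  protocol has no published formula; selection is uniform random.
- The numpy CNN is desk-scale: single CPU, float64, no batch-norm or
  augmentation. The `paper` profile (1000 rounds, 60 epochs, batch 128)
  is provided but sized for real compute budgets.
- Published benchmark-table accuracies stem from GPU training on the
  real eight-class dermoscopy dataset and are not reproduced here.
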