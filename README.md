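# fedlesion

A desk-scale simulator for **asynchronous, layer-partitioned federated
learning** on multiclass skin-lesion image classification.

## The problem

Hospitals hold dermoscopy images they cannot pool centrally for privacy
reasons. Federated learning (FL) trains a shared classifier by
exchanging model parameters instead of images, but synchronous FL sends
the *whole* model every communication round, which is expensive. This
package simulates a protocol that cuts that cost two ways:

1. **Layer-partitioned exchange.** The CNN's parameters are split into a
   *shallow* group (convolutional stages, which learn generic image
   features) and a *deep* group (fully connected stages). The shallow
   group travels every round; the full model travels only every `ES`
   rounds (the *exchange period*). Round `t` is a full-exchange round
   (flag = 1) when `t mod ES == 0`.
2. **Temporally weighted aggregation.** The server caches the last
   parameters received from every client `k` with a timestamp, and
   aggregates over *all* `K` caches — not just the round's responders —
   weighting client `k` by

       w_k ∝ (n_k / n) · α^−(t − timestamp_k),    α > 1,

   i.e. data share times a staleness decay, normalized to sum to 1.
   With every cache fresh this reduces *exactly* to federated averaging
   (FedAvg), which is one of the package's tested invariants.

Synchronous **FedAvg** and **FedSGD** baselines, multiclass diagnostic
metrics (per-class and macro accuracy / precision / recall / specificity
/ F1 via one-vs-rest reduction of the confusion matrix), and a
per-round **communication ledger** (transmitted parameter scalars and
bytes) are included. Everything runs on synthetic lesion-like images
(class-specific disk/ring templates plus Gaussian pixel noise), so no
dataset download is needed; the published eight-class ISIC-2019
bookkeeping tables ship as arithmetic fixtures for partition accounting.

The CNN (convolution → ReLU → 2×2 average pooling, fully connected
stages, dropout, softmax cross-entropy) is implemented directly in
numpy with exact hand-derived gradients, verified against central
finite differences at `rtol < 1e-5`.

## Worked example

```python
from fedlesion.experiment import ExperimentConfig, compare_algorithms

cfg = ExperimentConfig(rounds=20, lr=0.01, seed=1)   # 4 classes x 200 images,
                                                     # K=5 clients, ES=2, alpha=e/2
print(compare_algorithms(cfg, seeds=[1], algorithms=["fedavg", "async"], target=0.9))
```

prints

```
           final_accuracy_mean  final_accuracy_sd  rounds_to_target_mean  seeds_reaching_target  total_uplink_scalars
algorithm
fedavg                   1.000                0.0                   13.0                      1                346000
async                    0.995                0.0                   18.0                      1                235400
```

Both algorithms solve the synthetic 4-class task within 20 rounds, but
the asynchronous protocol uploads 235,400 parameter scalars against
FedAvg's 346,000 — the saving comes from the 10 shallow-only rounds,
which move 1,248 of the model's 3,460 scalars per client instead of all
of them.

The same experiment is available from the shell:

```bash
fedlesion run --algorithm async --rounds 20 --lr 0.01 --seed 1 --out runs/demo
fedlesion report runs/demo
```

which writes `history.csv`, `manifest.json`, a model checkpoint, and
per-class metric tables under `runs/demo/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch: it rebuilds the
five-client balanced partition of the published class totals and prints
the client-wise distribution table, then runs the seeded
async-vs-FedAvg comparison above and writes the result file.

## Layout

| module | contents |
| --- | --- |
| `fedlesion.data` | synthetic image generator, balanced/Dirichlet client partitions, distribution tables, PNG/NPZ interchange |
| `fedlesion.model` | CNN with shallow/deep tagging, exact gradients, split/merge, checkpoints |
| `fedlesion.client` | local mini-batch training, flag-dependent returns, evaluation |
| `fedlesion.server` | round loop, client selection, flag schedule, temporal weighting |
| `fedlesion.baselines` | FedAvg and FedSGD references |
| `fedlesion.metrics` | confusion matrix, one-vs-rest metrics, communication ledger |
| `fedlesion.experiment` | config profiles, run driver, manifests, algorithm comparison |
| `fedlesion.cli` | `fedlesion generate-data / run / report` |

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.
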