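# rhetsec

Sentence-level classification of medical abstracts into rhetorical
sections — **objective, methods, results, conclusion** — with two
complementary methods over sentence embeddings, plus a fully seeded
synthetic data stack so everything runs offline on one CPU.

Who it is for: researchers working on rhetorical/sequential sentence
classification of scientific abstracts (e.g. for literature-search
filtering or structured-abstract reconstruction), particularly in
settings where labelled corpora are scarce and training data must be
synthesised.

## What is inside

**Unsupervised route.** Embeddings are clustered with a
neighbor-consistency objective: a softmax head `f(·)` is trained so a
point and its k mined nearest neighbors `N_x` get the same cluster,
with an entropy regulariser over the mean cluster usage `p`:

```
L = -(1/|D|) Σ_x Σ_{k∈N_x} log( f(x)·f(k) )  +  λ Σ_i p_i log p_i
```

Without the λ-term, everything collapses into one cluster; with it,
usage stays near uniform. Cluster ids are scored against labels by the
optimal Hungarian cluster→class matching. A k-means baseline is
included.

**Supervised route (multi-encoder cascade, MEC).** Three augmented
views of each embedding V — a constant-shift perturbation `V + n`, an
autoencoder `AE(V)` pretrained on duplicate-sentence pairs, and a
denoising autoencoder `DA(V + ε)`, `ε ~ N(0, σ²I)` — cross-supervise
each other through dynamic-convolution layers (input-gated mixtures of
K candidate kernel banks), and their outputs are concatenated with V
for a softmax classifier.

**Synthetic data.** A template-bank corpus generator (Chinese and
English) with class-typical discourse cues and per-abstract shared
topics, and a unit-sphere mixture simulator with a single
class-separation knob. Both are exact, seeded, and tested.

All trainable pieces are small numpy models with hand-derived,
finite-difference-verified gradients — no deep-learning framework
required.

## Worked example

```python
import numpy as np
from rhetsec import (ConfusionMatrix, metrics, RunConfig, run_pipeline)

# score a published-style clustering confusion matrix
m = ConfusionMatrix(np.array([
    [20250, 1247,   24,  530],
    [  705, 20496,  397,  345],
    [  210,   626, 18005, 2990],
    [  102,   141, 1585, 19876],
]))
rep = metrics(m, decimals=4)
print(rep.accuracy, rep.precision[0], rep.recall[2])
```

prints

```
0.8983 0.9522 0.8247
```

— overall accuracy 0.8983 (89.83% of the 87,529 test sentences on the
matrix diagonal), precision 0.9522 for the *objective* column, recall
0.8247 for the *results* row.

Running the whole pipeline on a 2,000-sentence synthetic Chinese corpus
(generate → encode → fine-tune → cluster + MEC → evaluate):

```python
summary = run_pipeline(RunConfig(counts_per_class=(500,)*4, dim=128, seed=11),
                       "out/run")
print(summary)
```

prints

```
{'probe_accuracy': 1.0, 'clustering_accuracy': 0.98,
 'clustering_macro_f1': 0.9800698311275309, 'kmeans_accuracy': 0.99,
 'mec_accuracy': 0.985, 'mec_macro_f1': 0.9850476332424176}
```

— the fine-tuning probe fits the training labels perfectly, the
SCAN-style head reaches 0.98 Hungarian-matched accuracy on the held-out
abstracts (k-means 0.99 on the same fine-tuned embeddings), and the
supervised MEC classifier reaches 0.985. The output directory contains
the corpus, embedding stores, checkpoints, per-stage reports, and a
manifest with content hashes; rerunning with the same config reproduces
every artifact byte-for-byte.

The same stages are available as a CLI:

```bash
rhetsec generate --counts 3750,3750,3750,3750 --language zh --seed 7 --out corpus.jsonl
rhetsec encode --in corpus.jsonl --dim 768 --seed 7 --out emb.bin
rhetsec cluster --emb emb.bin --k 5 --clusters 4 --epochs 30 --seed 7 --out assign.tsv
rhetsec evaluate --truth corpus.jsonl --pred assign.tsv --mode clustering --out report/
rhetsec run --seed 11 --out out/run        # full pipeline
rhetsec ablate --seed 11 --out out/ablate  # fine-tune × dynamic-conv grid
```

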