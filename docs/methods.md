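# Methods

`rhetsec` classifies sentences of medical abstracts into four rhetorical
sections — objective, methods, results, conclusion — by two routes over
sentence embeddings: an unsupervised clustering route built on a
neighbor-consistency objective, and a supervised multi-encoder-cascade
(MEC) classifier. Because the corpora this family of methods is usually
trained on (LLM-generated Chinese medical abstracts, pretrained Chinese
sentence encoders) are large, external, or paid-API products, the
package ships a synthetic corpus generator and an embedding simulator so
that every stage runs offline, deterministically, from a single seed.

## Synthetic data

**Corpus generator.** An abstract is a topic tuple (condition,
intervention, outcome measure, population) drawn from a seeded
vocabulary, rendered through class-specific template banks (>= 20
templates per section per language, Chinese and English) that carry the
discourse cues real abstracts use: *aimed to investigate* for
objectives, *randomly assigned / measured* for methods, *significantly
improved (P<.05)* for results, *these findings suggest* for
conclusions. Sections appear in objective→methods→results→conclusion
order; the per-class sentence counts match the requested spec exactly
(default study sizes mirror 15,000-sentence corpora, either balanced
3750×4 or imbalanced 3537/4140/3826/3497). Crucially, all four sections
of one abstract share the same topic tuple: the literal (topical)
content overlaps across sections while the functional cues separate
them. This reproduces the property that makes encoder fine-tuning
matter — a surface-similarity encoder groups sentences by topic, a
fine-tuned one by rhetorical function. Optional label noise reassigns
`floor(rate * n)` labels uniformly to wrong classes. Each template has
a paired light paraphrase; rendering both with the same slots yields
duplicate sentence pairs for the autoencoder branch.

What the generator does *not* emulate: real lexical diversity (a
template bank is a tiny language model), genuine LLM paraphrase noise,
section-length distributions of real abstracts, or ambiguous boundary
sentences. Passing tests therefore demonstrate correctness and the
*direction* of effects (fine-tuning helps, entropy regularisation
prevents collapse), not performance on real literature.

**Embedding simulator.** A geometric stand-in for encoder output: class
means `mu_c = normalize(b + s·u_c)` with `b, u_1..u_4` seeded
orthonormal vectors, points `normalize(mu_c + spread·g)`. The single
knob `s` (class separation) moves the means from coincident (chance
level — verified against a quadratic-discriminant oracle) toward
orthogonal; Bayes-proxy accuracy is monotone in `s`. Benchmarks fix
`s = 2.0, spread = 0.05` ("separable benchmark": near-orthogonal tight
classes) and `s = 1.0, spread = 0.2` (the collapse experiments).

## Encoding and fine-tuning

The default encoder is deterministic and training-free: character
1–3-grams of the token-truncated sentence (character tokens for CJK
text, whitespace tokens otherwise; cap 64 tokens) are hashed into 2^18
buckets (BLAKE2 — Python's builtin `hash` is randomized per process),
TF-weighted, projected to `dim` by a Gaussian matrix whose columns are
generated per bucket from a Philox stream keyed by (seed, bucket), and
L2-normalized. A row therefore never depends on what else is in the
batch. Any callable with the same signature (e.g. a pretrained sentence
encoder) can replace it.

Fine-tuning trains a linear adapter (initialised at identity, so zero
epochs is a no-op) jointly with a 4-class softmax probe by
cross-entropy, then discards the probe. The adapter preserves
dimension and re-normalizes. Two learning rates appear deliberately
throughout the package: 5e-5 is kept as the configuration default for
compatibility with transformer-scale fine-tuning settings (dropout 0.5,
30 epochs, batch 64, dim 768, the standard training table), but a
freshly initialised linear/MLP head trained from scratch needs a far
larger step; heads use 1e-2 (`head_learning_rate`), fixed by pilot runs
before any threshold was frozen.

## Clustering objective

With `N_x` the k = 5 exact cosine nearest neighbors (ties to the lower
index, self excluded), the objective per batch D is

    L = -(1/|D|) * sum_x sum_{k in N_x} log( f(x)·f(k) )
        + lambda * sum_i p_i log p_i ,

natural logs, dot products clipped at 1e-12, `p` the column mean of the
anchor probabilities, lambda default 2.0. `scan_loss` implements this
form exactly and is property-tested against a scalar brute-force
oracle (|diff| < 1e-8 over random batches) and closed-form corner
cases (one-hot consistency 0; uniform usage −lambda·ln C).

**Optimization detail.** During training the consistency term is
*averaged* over each anchor's k neighbors rather than summed. The
clustering literature this objective comes from samples one random
neighbor per anchor per step — in expectation the neighbor mean — and
its customary entropy weights are calibrated to that scale. With the
summed form, consistency outweighs the entropy term by a factor k and
gradient descent reliably merges clusters long before reaching the
(separated) optimum; with the mean form, lambda = 2 recovers the
separable benchmark in 5/5 seeds. The head is an MLP
dim→128→C with ReLU, dropout 0.5 and softmax; outputs are valid
distributions for any finite input. Zero training epochs returns the
seeded initialisation; non-finite loss aborts with a diagnostic. A
seeded k-means baseline (scikit-learn, n_init = 10) runs on the same
rows.

The entropy term operationalises collapse resistance: at the reduced
separation setting, lambda = 0 drives the hard cluster-usage entropy to
0 (all points in one cluster) in 5/5 seeds, while lambda = 2 keeps it
above 0.9·ln C.

## The multi-encoder cascade

Three views of an embedding V: (1) constant shift V + n with
n ~ Uniform(−0.01, 0.01) redrawn per sample per epoch; (2) an
autoencoder (d→256→d, ReLU) pretrained by MSE on duplicate pairs;
(3) a denoising autoencoder pretrained to reconstruct V from
V + eps, eps ~ N(0, 0.1²I), fresh noise each epoch. AE and DA are
frozen during classifier training (keeps the branches' roles distinct
and the optimisation stable). At inference the stochastic corruptions
are off: prediction is deterministic.

For each view, the other two views are concatenated into a 2-channel
length-d sequence and passed through a dynamic-convolution layer:
K = 4 candidate kernel banks per kernel size (sizes 2/3/4, 256 filters
total, split evenly with the remainder to the largest size), mixed by a
gate (global average pool → linear → softmax over K; with K = 1 the
layer is a plain convolution), then valid 1-D convolution, ReLU,
max-pool over positions, and a linear map back to d. Each layer output
`o_i` is pulled toward its own view by gamma·MSE(o_i, stop-grad(e_i)),
gamma = 0.1, added to the cross-entropy of a linear softmax classifier
(dropout 0.5) over concat(o_1, o_2, o_3, V) — input width 4d. The
alternative supervision direction (view toward stop-grad of DC output)
is selectable but contributes no gradient while the encoders are
frozen; it exists to make the design choice explicit. All gradients
are hand-derived and finite-difference checked. `dc_mode` selects the
ablations: `bypass` (no DC layers; classifier on concat(e_1,e_2,e_3,V))
and `zero` (DC slots zeroed; reduces to a linear classifier on V).

**Known limitation — the DC ablation direction.** On this package's
embeddings the with-DC model does *not* beat its no-DC ablation: it
trails by 2–5 accuracy points across every corpus and simulation
setting we benchmarked, under either ablation reading, with verified
gradients and several initialisation/pretraining schemes. The reason
is structural: convolution and max-pooling act along the *coordinate
axis* of the embedding, and coordinates of a random-projection (or
generic encoder) embedding carry no locality, so the DC branch adds
capacity without a usable inductive bias and costs variance at desk
scale. The corresponding acceptance check is accordingly expected to
fail here and is retained, un-weakened, as an honest negative; the
acceptance script reports both accuracies.

## Evaluation

One-vs-rest precision/recall/F1 with 0/0 := 0; accuracy = trace/total;
micro-F1 from pooled counts (provably equal to accuracy for
single-label multi-class — asserted as an identity) and macro-F1 as
the unweighted mean, both reported because summary tables in this
literature do not always say which they print. Cluster assignments are
scored after the cluster→class bijection maximising agreement:
exhaustive search over permutations for C <= 8 (deterministic
lexicographic tie-break), the assignment algorithm above that. Rounding
is half-away-from-zero to a caller-chosen number of decimals, since
published tables mix 3- and 4-decimal printing.

## Pipeline, sizes, and reproducibility

`run_pipeline` chains generate → abstract-atomic 80/20 split → encode →
fine-tune (adapter) → SCAN clustering + k-means on the test side → MEC
training/prediction → reports, writing every artifact plus a manifest
with the resolved config, seeds, package version, timestamps, and
SHA-256 content hashes of all artifacts. Every random choice descends
from the one root seed; a rerun with the same config reproduces every
artifact byte-for-byte (the manifest's timestamps differ by design; its
hash table is compared instead). Benchmark problem sizes are chosen for
a single CPU: 2,000-sentence corpora, 64–256-dimensional embeddings for
the training benchmarks, and dim 128 for the end-to-end run (the
768-dim default remains available in config); the full acceptance
recomputation takes about six minutes.

## Degenerate inputs and numerical conventions

Empty corpora, all-zero class counts, single-class fine-tuning input,
k >= n neighbor queries, non-finite perturbations, negative noise
scales, and non-square matching matrices raise `ValueError` with a
specific message. Logs are clipped at 1e-12; 0·log 0 := 0 throughout.
TSV corpora reject unescaped tabs/newlines at write time and report the
1-based line number of any malformed line at read time, loading nothing
partially; JSONL round-trips CJK text losslessly (UTF-8,
`ensure_ascii=False`).
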