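"""End-to-end pipeline: generate -> encode -> fine-tune -> cluster / classify -> evaluate.

``RunConfig`` bundles every stage's settings (training defaults: dropout
0.5, 30 epochs, learning rate 5e-5, batch 64, max 64 tokens, dimension
768, convolution filter sizes (2,3,4) with 256 filters) plus seeds and
corpus parameters; it loads from strict YAML (unknown keys rejected)
and CLI flags override file values.  ``run_pipeline`` executes the
stages, writes every artifact plus a manifest recording the resolved
config, seeds, input/output content hashes, package version and
timestamps, and returns the collected metrics.  All randomness derives
from ``config.seed``; reruns with an identical config produce
byte-identical artifacts (the manifest's timestamps aside).

Two learning rates appear deliberately: ``learning_rate`` (5e-5) is the
transformer-scale default kept for configuration compatibility, while
``head_learning_rate`` (1e-2) is used for the freshly initialised
numpy heads this package actually trains — a from-scratch linear/MLP
head needs a far larger step size than fine-tuning a pretrained
network.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .corpus_synth import (CLASSES, CorpusSpec, SentenceRecord,
                           generate_abstract_corpus, generate_duplicate_pairs,
                           split_corpus)
from .docscan import ScanConfig, assign, kmeans_baseline, mine_neighbors, train_scan
from .encoding import EncoderConfig, encode, finetune_encoder
from .evaluation import confusion, evaluate_clustering, metrics
from .io import (save_adapter, save_cluster_head, save_embeddings,
                 save_mec_model, sha256_file, write_corpus)
from .mec import MecConfig, predict, train_autoencoder, train_mec

logger = logging.getLogger("rhetsec")

__all__ = ["RunConfig", "run_pipeline", "run_ablation",
           "run_pipeline_with_mec_mode", "configure_logging"]


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


class _Stage:
    """Context manager logging stage name, seed and elapsed time."""

    def __init__(self, name: str, seed: int):
        self.name, self.seed = name, seed

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage=%s seed=%d start", self.name, self.seed)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage=%s seed=%d done elapsed=%.2fs", self.name, self.seed, elapsed)
        else:
            logger.error("stage=%s seed=%d FAILED after %.2fs: %s",
                         self.name, self.seed, elapsed, exc)
        return False


@dataclass(frozen=True)
class RunConfig:
    # corpus
    counts_per_class: tuple[int, int, int, int] = (500, 500, 500, 500)
    language: str = "zh"
    label_noise_rate: float = 0.0
    train_fraction: float = 0.8
    # encoder
    dim: int = 768
    max_tokens: int = 64
    # shared training settings
    dropout: float = 0.5
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 5e-5
    head_learning_rate: float = 1e-2
    # clustering
    k: int = 5
    num_clusters: int = 4
    entropy_weight: float = 2.0
    hidden_width: int = 128
    # mec
    dc_kernel_sizes: tuple[int, ...] = (2, 3, 4)
    dc_total_filters: int = 256
    dc_candidate_kernels: int = 4
    supervision_weight: float = 0.1
    perturb_scale: float = 0.01
    dae_sigma: float = 0.1
    ae_hidden: int = 256
    # toggles
    finetune: bool = True
    run_clustering: bool = True
    run_mec: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("counts_per_class", "dc_kernel_sizes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["counts_per_class"] = list(d["counts_per_class"])
        d["dc_kernel_sizes"] = list(d["dc_kernel_sizes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")


def _write_assignment_tsv(path, ids, values) -> None:
    lines = ["id\tvalue"] + [f"{i}\t{v}" for i, v in zip(ids, values)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_report(out_dir: Path, name: str, cm, report) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / f"{name}_confusion.csv", cm.counts, fmt="%d", delimiter=",")
    (out_dir / f"{name}_metrics.json").write_text(
        json.dumps(report.as_dict(), sort_keys=True, indent=2), encoding="utf-8")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full pipeline into ``out_dir``; returns the metrics summary.

    Stages: corpus generation, abstract-atomic train/test split,
    encoding, optional label-supervised fine-tuning of the encoder
    (adapter), SCAN clustering of the test embeddings plus a k-means
    baseline, MEC supervised classification, and evaluation reports.
    One manifest with content hashes is written next to the artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    summary: dict = {}
    artifacts: list[Path] = []

    with _Stage("generate", config.seed):
        spec = CorpusSpec(counts_per_class=config.counts_per_class,
                          language=config.language,
                          label_noise_rate=config.label_noise_rate,
                          seed=config.seed)
        records = generate_abstract_corpus(spec)
        corpus_path = out / "corpus.jsonl"
        write_corpus(corpus_path, records)
        artifacts.append(corpus_path)
        train, test = split_corpus(records, config.train_fraction,
                                   1 - config.train_fraction, seed=config.seed + 1)

    with _Stage("encode", config.seed):
        enc_cfg = EncoderConfig(dim=config.dim, max_tokens=config.max_tokens,
                                seed=config.seed + 2)
        emb_train = encode(train, enc_cfg)
        emb_test = encode(test, enc_cfg)
        save_embeddings(out / "emb_train.bin", emb_train, enc_cfg.fingerprint())
        save_embeddings(out / "emb_test.bin", emb_test, enc_cfg.fingerprint())
        artifacts += [out / "emb_train.bin", Path(str(out / "emb_train.bin") + ".meta.json"),
                      out / "emb_test.bin", Path(str(out / "emb_test.bin") + ".meta.json")]

    if config.finetune:
        with _Stage("finetune", config.seed):
            adapter = finetune_encoder(train, emb_train, epochs=config.epochs,
                                       seed=config.seed + 3,
                                       learning_rate=config.head_learning_rate,
                                       batch_size=config.batch_size)
            emb_train = adapter.apply(emb_train)
            emb_test = adapter.apply(emb_test)
            save_adapter(out / "adapter.bin", adapter)
            artifacts.append(out / "adapter.bin")
            summary["probe_accuracy"] = adapter.probe_accuracy

    y_test = np.array([CLASSES.index(r.label) for r in test])
    y_train = np.array([CLASSES.index(r.label) for r in train])

    if config.run_clustering:
        with _Stage("cluster", config.seed):
            neighbors = mine_neighbors(emb_test, config.k)
            scan_cfg = ScanConfig(num_clusters=config.num_clusters,
                                  entropy_weight=config.entropy_weight,
                                  k=config.k, epochs=config.epochs,
                                  batch_size=config.batch_size,
                                  learning_rate=config.head_learning_rate,
                                  dropout=config.dropout,
                                  hidden_width=config.hidden_width,
                                  seed=config.seed + 4)
            head = train_scan(emb_test, neighbors, scan_cfg)
            clusters = assign(head, emb_test)
            save_cluster_head(out / "cluster_head.bin", head)
            _write_assignment_tsv(out / "assignments.tsv", emb_test.ids, clusters)
            np.savetxt(out / "scan_loss_trajectory.csv",
                       np.asarray(head.loss_trajectory), delimiter=",")
            artifacts += [out / "cluster_head.bin", out / "assignments.tsv",
                          out / "scan_loss_trajectory.csv"]
            cm, rep = evaluate_clustering(y_test, clusters)
            _write_report(out / "reports", "clustering", cm, rep)
            artifacts += [out / "reports" / "clustering_confusion.csv",
                          out / "reports" / "clustering_metrics.json"]
            summary["clustering_accuracy"] = rep.accuracy
            summary["clustering_macro_f1"] = rep.macro_f1

            km = kmeans_baseline(emb_test, config.num_clusters, seed=config.seed + 5)
            _, km_rep = evaluate_clustering(y_test, km)
            summary["kmeans_accuracy"] = km_rep.accuracy

    if config.run_mec:
        with _Stage("mec", config.seed):
            mec_cfg = MecConfig(dim=config.dim, perturb_scale=config.perturb_scale,
                                dae_sigma=config.dae_sigma, ae_hidden=config.ae_hidden,
                                dc_kernel_sizes=config.dc_kernel_sizes,
                                dc_total_filters=config.dc_total_filters,
                                dc_candidate_kernels=config.dc_candidate_kernels,
                                supervision_weight=config.supervision_weight,
                                dropout=config.dropout, epochs=config.epochs,
                                batch_size=config.batch_size,
                                learning_rate=config.learning_rate,
                                seed=config.seed + 6)
            pair_texts = generate_duplicate_pairs(
                max(64, len(train) // 4), language=config.language, seed=config.seed + 7)
            left = [SentenceRecord(text=a, abstract_id=f"p{i:05d}", sentence_index=0)
                    for i, (a, _) in enumerate(pair_texts)]
            right = [SentenceRecord(text=b, abstract_id=f"p{i:05d}", sentence_index=1)
                     for i, (_, b) in enumerate(pair_texts)]
            emb_left = encode(left, enc_cfg)
            emb_right = encode(right, enc_cfg)
            if config.finetune:
                emb_left = adapter.apply(emb_left)
                emb_right = adapter.apply(emb_right)
            pairs = list(zip(emb_left.values, emb_right.values))
            ae = train_autoencoder(pairs, mec_cfg, learning_rate=1e-3,
                                   seed=config.seed + 8)
            model = train_mec(emb_train, y_train, mec_cfg, ae=ae,
                              learning_rate=config.head_learning_rate)
            save_mec_model(out / "mec_model.bin", model)
            pred, _probs = predict(model, emb_test)
            _write_assignment_tsv(out / "predictions.tsv", emb_test.ids, pred)
            artifacts += [out / "mec_model.bin", out / "predictions.tsv"]
            cm = confusion(y_test, pred)
            rep = metrics(cm)
            _write_report(out / "reports", "supervised", cm, rep)
            artifacts += [out / "reports" / "supervised_confusion.csv",
                          out / "reports" / "supervised_metrics.json"]
            summary["mec_accuracy"] = rep.accuracy
            summary["mec_macro_f1"] = rep.macro_f1

    config.to_yaml(out / "config.yaml")
    artifacts.append(out / "config.yaml")
    manifest = {
        "command": "run",
        "config": json.loads(json.dumps(dataclasses.asdict(config))),
        "seeds": {"root": config.seed},
        "package_version": __version__,
        "started": t_start,
        "finished": time.time(),
        "artifact_hashes": {p.name if p.parent == out else f"reports/{p.name}":
                            sha256_file(p) for p in artifacts},
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2),
                                       encoding="utf-8")
    return summary


def run_ablation(config: RunConfig, out_dir, variants=("full", "no-finetune", "no-dc", "neither")) -> dict:
    """Run the ablation grid; one report directory per variant."""
    out = Path(out_dir)
    results = {}
    for variant in variants:
        v_cfg = dataclasses.replace(
            config,
            finetune=variant not in ("no-finetune", "neither"))
        v_out = out / variant
        if variant in ("no-dc", "neither"):
            summary = run_pipeline_with_mec_mode(v_cfg, v_out, "bypass")
        else:
            summary = run_pipeline(v_cfg, v_out)
        results[variant] = summary
    (out / "ablation_summary.json").write_text(
        json.dumps(results, sort_keys=True, indent=2), encoding="utf-8")
    return results


def run_pipeline_with_mec_mode(config: RunConfig, out_dir, dc_mode: str) -> dict:
    """Variant of ``run_pipeline`` whose MEC stage uses the given dc_mode."""
    # Reuse run_pipeline for all common stages by toggling run_mec off,
    # then run the MEC stage here with the requested mode.
    base = dataclasses.replace(config, run_mec=False)
    summary = run_pipeline(base, out_dir)
    if not config.run_mec:
        return summary
    out = Path(out_dir)
    spec = CorpusSpec(counts_per_class=config.counts_per_class,
                      language=config.language,
                      label_noise_rate=config.label_noise_rate, seed=config.seed)
    records = generate_abstract_corpus(spec)
    train, test = split_corpus(records, config.train_fraction,
                               1 - config.train_fraction, seed=config.seed + 1)
    enc_cfg = EncoderConfig(dim=config.dim, max_tokens=config.max_tokens,
                            seed=config.seed + 2)
    emb_train, emb_test = encode(train, enc_cfg), encode(test, enc_cfg)
    if config.finetune:
        adapter = finetune_encoder(train, emb_train, epochs=config.epochs,
                                   seed=config.seed + 3,
                                   learning_rate=config.head_learning_rate,
                                   batch_size=config.batch_size)
        emb_train, emb_test = adapter.apply(emb_train), adapter.apply(emb_test)
    y_train = np.array([CLASSES.index(r.label) for r in train])
    y_test = np.array([CLASSES.index(r.label) for r in test])
    mec_cfg = MecConfig(dim=config.dim, perturb_scale=config.perturb_scale,
                        dae_sigma=config.dae_sigma, ae_hidden=config.ae_hidden,
                        dc_kernel_sizes=config.dc_kernel_sizes,
                        dc_total_filters=config.dc_total_filters,
                        dc_candidate_kernels=config.dc_candidate_kernels,
                        supervision_weight=config.supervision_weight,
                        dropout=config.dropout, epochs=config.epochs,
                        batch_size=config.batch_size,
                        learning_rate=config.learning_rate,
                        seed=config.seed + 6, dc_mode=dc_mode)
    model = train_mec(emb_train, y_train, mec_cfg,
                      learning_rate=config.head_learning_rate)
    pred, _ = predict(model, emb_test)
    cm = confusion(y_test, pred)
    rep = metrics(cm)
    _write_report(out / "reports", "supervised", cm, rep)
    summary["mec_accuracy"] = rep.accuracy
    summary["mec_macro_f1"] = rep.macro_f1
    return summary
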