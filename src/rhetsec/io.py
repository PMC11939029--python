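"""File formats: corpora (JSONL/TSV), embedding stores, model checkpoints.

Corpus round-trips are lossless including CJK text.  Malformed input is
reported with its line number and nothing is loaded partially.  The
embedding store is a raw little-endian float32 matrix plus a JSON
sidecar carrying n, dim, row ids, the normalize flag and the encoder
fingerprint.  Checkpoints are a single binary file: an 8-byte length,
a JSON header (config, seed, loss trajectory, array manifest), then raw
float64 weight blocks in header order.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .corpus_synth import CLASSES, SentenceRecord
from .docscan import ClusterHead, ScanConfig
from .encoding import EmbeddingMatrix, EncoderAdapter
from .mec import DynamicConvLayer, EncoderParams, MecConfig, MecModel

__all__ = ["CorpusFormatError", "read_corpus", "write_corpus",
           "save_embeddings", "load_embeddings",
           "save_cluster_head", "load_cluster_head",
           "save_adapter", "load_adapter",
           "save_mec_model", "load_mec_model", "sha256_file"]

_CHECKPOINT_MAGIC = b"RSEC"
_TSV_COLUMNS = ("text", "label", "abstract_id", "sentence_index")


class CorpusFormatError(ValueError):
    """Malformed corpus input; carries the 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        super().__init__(f"{path}:{line_number}: {message}")
        self.line_number = line_number


# ---------------------------------------------------------------------------
# Corpora
# ---------------------------------------------------------------------------

def _record_to_dict(r: SentenceRecord) -> dict:
    return {"text": r.text, "label": r.label, "abstract_id": r.abstract_id,
            "sentence_index": r.sentence_index}


def write_corpus(path, records: list[SentenceRecord]) -> None:
    """Write JSONL (default) or TSV, chosen by file extension."""
    path = Path(path)
    if path.suffix == ".tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for i, r in enumerate(records):
            if "\t" in r.text or "\n" in r.text:
                raise ValueError(
                    f"record {i} contains a tab or newline; the TSV dialect "
                    "forbids unescaped tabs — use JSONL")
            lines.append(f"{r.text}\t{r.label or ''}\t{r.abstract_id}\t{r.sentence_index}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(_record_to_dict(r), ensure_ascii=False) + "\n")


def read_corpus(path) -> list[SentenceRecord]:
    """Read JSONL or TSV (by extension).  Any malformed line aborts the
    whole load with its line number."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    records: list[SentenceRecord] = []
    if path.suffix == ".tsv":
        lines = text.splitlines()
        if not lines or tuple(lines[0].split("\t")) != _TSV_COLUMNS:
            raise CorpusFormatError(path, 1, "missing or wrong TSV header")
        for ln, line in enumerate(lines[1:], start=2):
            fields = line.split("\t")
            if len(fields) != 4:
                raise CorpusFormatError(
                    path, ln, f"expected 4 tab-separated fields, got {len(fields)}")
            t, label, aid, sidx = fields
            try:
                records.append(SentenceRecord(text=t, label=label or None,
                                              abstract_id=aid, sentence_index=int(sidx)))
            except (ValueError, TypeError) as exc:
                raise CorpusFormatError(path, ln, str(exc)) from exc
    else:
        for ln, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(path, ln, f"invalid JSON: {exc.msg}") from exc
            try:
                records.append(SentenceRecord(
                    text=d["text"], label=d.get("label"),
                    abstract_id=d["abstract_id"], sentence_index=int(d["sentence_index"])))
            except KeyError as exc:
                raise CorpusFormatError(path, ln, f"missing key {exc}") from exc
            except (ValueError, TypeError) as exc:
                raise CorpusFormatError(path, ln, str(exc)) from exc
    return records


# ---------------------------------------------------------------------------
# Embedding store
# ---------------------------------------------------------------------------

def save_embeddings(path, emb: EmbeddingMatrix, fingerprint: str = "") -> None:
    path = Path(path)
    emb.values.astype("<f4").tofile(path)
    meta = {"n": emb.n, "dim": emb.dim, "ids": emb.ids,
            "normalize": emb.normalize, "encoder_fingerprint": fingerprint}
    Path(str(path) + ".meta.json").write_text(
        json.dumps(meta, ensure_ascii=False, sort_keys=True), encoding="utf-8")


def load_embeddings(path) -> tuple[EmbeddingMatrix, str]:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text(encoding="utf-8"))
    values = np.fromfile(path, dtype="<f4").astype(float).reshape(meta["n"], meta["dim"])
    return (EmbeddingMatrix(values=values, ids=list(meta["ids"]),
                            normalize=meta["normalize"]),
            meta.get("encoder_fingerprint", ""))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _save_checkpoint(path, header: dict, arrays: dict[str, np.ndarray]) -> None:
    header = dict(header)
    header["arrays"] = [{"name": k, "shape": list(v.shape)} for k, v in arrays.items()]
    header["format_version"] = 1
    blob = json.dumps(header, ensure_ascii=False, sort_keys=True).encode("utf-8")
    with Path(path).open("wb") as fh:
        fh.write(_CHECKPOINT_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        for v in arrays.values():
            fh.write(np.ascontiguousarray(v, dtype="<f8").tobytes())


def _load_checkpoint(path) -> tuple[dict, dict[str, np.ndarray]]:
    with Path(path).open("rb") as fh:
        if fh.read(4) != _CHECKPOINT_MAGIC:
            raise ValueError(f"{path} is not a rhetsec checkpoint")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen).decode("utf-8"))
        arrays = {}
        for spec in header["arrays"]:
            size = int(np.prod(spec["shape"])) if spec["shape"] else 1
            buf = fh.read(8 * size)
            arrays[spec["name"]] = np.frombuffer(buf, dtype="<f8").reshape(spec["shape"]).copy()
    return header, arrays


def save_cluster_head(path, head: ClusterHead) -> None:
    _save_checkpoint(path, {"kind": "cluster_head", "config": asdict(head.config),
                            "loss_trajectory": head.loss_trajectory},
                     {"W1": head.W1, "b1": head.b1, "W2": head.W2, "b2": head.b2})


def load_cluster_head(path) -> ClusterHead:
    header, arrays = _load_checkpoint(path)
    cfg = ScanConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                        for k, v in header["config"].items()})
    return ClusterHead(W1=arrays["W1"], b1=arrays["b1"], W2=arrays["W2"],
                       b2=arrays["b2"], config=cfg,
                       loss_trajectory=list(header["loss_trajectory"]))


def save_adapter(path, adapter: EncoderAdapter) -> None:
    _save_checkpoint(path, {"kind": "adapter", "epochs": adapter.epochs,
                            "seed": adapter.seed,
                            "initial_loss": adapter.initial_loss,
                            "final_loss": adapter.final_loss,
                            "probe_accuracy": adapter.probe_accuracy},
                     {"weight": adapter.weight, "bias": adapter.bias})


def load_adapter(path) -> EncoderAdapter:
    header, arrays = _load_checkpoint(path)
    return EncoderAdapter(weight=arrays["weight"], bias=arrays["bias"],
                          epochs=header["epochs"], seed=header["seed"],
                          initial_loss=header["initial_loss"],
                          final_loss=header["final_loss"],
                          probe_accuracy=header["probe_accuracy"])


def _encoder_arrays(prefix: str, enc: EncoderParams) -> dict[str, np.ndarray]:
    return {f"{prefix}/W1": enc.W1, f"{prefix}/b1": enc.b1,
            f"{prefix}/W2": enc.W2, f"{prefix}/b2": enc.b2}


def save_mec_model(path, model: MecModel) -> None:
    cfg = asdict(model.config)
    arrays = {"clf_W": model.clf_W, "clf_b": model.clf_b}
    arrays.update(_encoder_arrays("ae", model.ae))
    arrays.update(_encoder_arrays("da", model.da))
    if model.dc_layers is not None:
        for i, layer in enumerate(model.dc_layers):
            for k, v in layer.params.items():
                arrays[f"dc{i}/{k}"] = v
    _save_checkpoint(path, {"kind": "mec", "config": cfg,
                            "loss_trajectory": model.loss_trajectory,
                            "trained_dim": int(model.ae.W1.shape[1])}, arrays)


def load_mec_model(path) -> MecModel:
    header, arrays = _load_checkpoint(path)
    raw_cfg = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in header["config"].items()}
    cfg = MecConfig(**raw_cfg)
    dim = header["trained_dim"]

    def enc(prefix):
        return EncoderParams(W1=arrays[f"{prefix}/W1"], b1=arrays[f"{prefix}/b1"],
                             W2=arrays[f"{prefix}/W2"], b2=arrays[f"{prefix}/b2"])

    dc_layers = None
    if cfg.dc_mode == "dynamic":
        dc_layers = []
        for i in range(3):
            layer = DynamicConvLayer(dim, cfg, seed=0)
            for k in list(layer.params):
                layer.params[k] = arrays[f"dc{i}/{k}"]
            dc_layers.append(layer)
    return MecModel(config=cfg, ae=enc("ae"), da=enc("da"), dc_layers=dc_layers,
                    clf_W=arrays["clf_W"], clf_b=arrays["clf_b"],
                    loss_trajectory=list(header["loss_trajectory"]))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
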