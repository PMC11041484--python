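"""Readers, writers and the run configuration.

Formats
-------
- Corpora: JSONL (one object per line with keys ``text``, ``label`` and an
  optional ``id``) or CSV with header ``text,label`` — UTF-8 throughout.
- Embeddings: delimited text (label column first, then the vector), or a
  little-endian float64 binary matrix (``.f64`` — row-major, no header)
  with a JSON sidecar (``<file>.json``) holding ``shape``, ``labels``,
  ``ids`` and ``dtype``.
- Pairs: TSV ``i  j  same_class`` (see ``pairs.PairSet``).
- Metrics: TSV with columns
  ``method  backend  shots  iteration  precision  recall  fscore``
  where ``iteration`` is the 0-based index or ``mean``.
- Run configuration: YAML, lossless round-trip.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .embeddings import (
    EmbeddingSet,
    LabeledCorpus,
    embed_corpus,
    get_backend,
)
from .evaluation import MetricsRecord, evaluate_averaged
from .exceptions import ConfigurationError, DataError
from .pt_snn import PTSNNClassifier
from .soe_snn import EncoderConfig, SOESNNClassifier

logger = logging.getLogger("fewshot_snn")

__all__ = [
    "read_corpus",
    "write_corpus_jsonl",
    "read_embeddings_text",
    "write_embeddings_text",
    "read_embeddings_binary",
    "write_embeddings_binary",
    "metrics_frame",
    "write_metrics_tsv",
    "RunConfig",
    "make_classifier_factory",
    "run_experiment",
]

METRICS_COLUMNS = [
    "method", "backend", "shots", "iteration", "precision", "recall", "fscore",
]


# ---------------------------------------------------------------------------
# corpora


def read_corpus(path: str | Path) -> LabeledCorpus:
    """Read a labeled corpus; the suffix selects JSONL vs CSV."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"corpus file not found: {path}")
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        return _read_corpus_jsonl(path)
    if path.suffix.lower() == ".csv":
        return _read_corpus_csv(path)
    raise ConfigurationError(
        f"unsupported corpus format {path.suffix!r}; use .jsonl or .csv"
    )


def _read_corpus_jsonl(path: Path) -> LabeledCorpus:
    texts, labels, ids = [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DataError(f"{path}:{lineno + 1}: invalid JSON ({exc})") from None
            if "text" not in obj or "label" not in obj:
                raise DataError(f"{path}:{lineno + 1}: missing 'text' or 'label'")
            texts.append(str(obj["text"]))
            labels.append(str(obj["label"]))
            ids.append(str(obj.get("id", f"s{lineno:04d}")))
    if not texts:
        raise DataError(f"no records in {path}")
    return LabeledCorpus(tuple(texts), tuple(labels), tuple(ids))


def _read_corpus_csv(path: Path) -> LabeledCorpus:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"text", "label"} <= set(reader.fieldnames):
            raise DataError(f"{path}: CSV header must contain 'text' and 'label'")
        texts, labels, ids = [], [], []
        for i, row in enumerate(reader):
            texts.append(row["text"])
            labels.append(row["label"])
            ids.append(row.get("id") or f"s{i:04d}")
    if not texts:
        raise DataError(f"no records in {path}")
    return LabeledCorpus(tuple(texts), tuple(labels), tuple(ids))


def write_corpus_jsonl(corpus: LabeledCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, text, label in corpus:
            fh.write(json.dumps({"id": sid, "text": text, "label": label}) + "\n")


# ---------------------------------------------------------------------------
# embeddings


def write_embeddings_text(es: EmbeddingSet, path: str | Path) -> None:
    """Delimited text: ``id<TAB>label<TAB>v0<TAB>v1...`` one row per vector."""
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(es.n_samples):
            vec = "\t".join(repr(float(x)) for x in es.vectors[i])
            fh.write(f"{es.ids[i]}\t{es.labels[i]}\t{vec}\n")


def read_embeddings_text(path: str | Path) -> EmbeddingSet:
    ids, labels, rows = [], [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: malformed row {parts!r}")
            ids.append(parts[0])
            labels.append(parts[1])
            rows.append([float(x) for x in parts[2:]])
    if not rows:
        raise DataError(f"no rows in {path}")
    return EmbeddingSet(np.asarray(rows), labels, ids)


def write_embeddings_binary(es: EmbeddingSet, path: str | Path) -> None:
    """Row-major little-endian float64 matrix + JSON sidecar for metadata."""
    path = Path(path)
    es.vectors.astype("<f8").tofile(path)
    sidecar = {
        "dtype": "<f8",
        "shape": list(es.vectors.shape),
        "labels": es.labels.tolist(),
        "ids": list(es.ids),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh)


def read_embeddings_binary(path: str | Path) -> EmbeddingSet:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    vectors = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    return EmbeddingSet(vectors, meta["labels"], meta["ids"])


# ---------------------------------------------------------------------------
# metrics


def metrics_frame(
    record: MetricsRecord, method: str, backend: str, shots: int
) -> pd.DataFrame:
    rows = [
        {
            "method": method, "backend": backend, "shots": shots,
            "iteration": str(i),
            "precision": record.per_iteration[i, 0],
            "recall": record.per_iteration[i, 1],
            "fscore": record.per_iteration[i, 2],
        }
        for i in range(record.m_iterations)
    ]
    rows.append(
        {
            "method": method, "backend": backend, "shots": shots,
            "iteration": "mean",
            "precision": record.mean[0],
            "recall": record.mean[1],
            "fscore": record.mean[2],
        }
    )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """One reproducible experiment: method x backend x shot grid.

    Every source of randomness flows from the named seeds here; re-running
    the same config reproduces the metrics file exactly.
    """

    method: str = "pt-snn"
    backend: str = "hashed-ngram"
    backend_dimension: int = 256
    shots: tuple[int, ...] = (4, 8, 16)
    m_iterations: int = 3
    episode_mode: str = "complement"
    averaging: str = "macro"
    seed: int = 0
    encoder: dict | None = None
    data_path: str | None = None
    out_path: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("pt-snn", "soe-snn"):
            raise ConfigurationError(
                f"unknown method {self.method!r}; use 'pt-snn' or 'soe-snn'"
            )
        self.shots = tuple(int(s) for s in self.shots)
        if any(s < 1 for s in self.shots):
            raise ConfigurationError(f"shots must all be >= 1, got {self.shots}")
        if self.m_iterations < 1:
            raise ConfigurationError("m_iterations must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["shots"] = list(self.shots)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**payload)


def make_classifier_factory(config: RunConfig, input_dim: int):
    """Zero-argument classifier factory for the episodic evaluator."""
    if config.method == "pt-snn":
        return PTSNNClassifier
    enc_kwargs = dict(config.encoder or {})
    enc_kwargs.setdefault("input_dim", input_dim)
    enc_kwargs.setdefault("seed", config.seed)
    if "chunk_length" not in enc_kwargs:
        # largest divisor of d not exceeding the default sequence length
        enc_kwargs["chunk_length"] = next(
            c for c in range(16, 0, -1) if input_dim % c == 0
        )
    enc_cfg = EncoderConfig(**enc_kwargs)
    return lambda: SOESNNClassifier(enc_cfg)


def run_experiment(config: RunConfig, data: EmbeddingSet | None = None) -> pd.DataFrame:
    """Evaluate the configured method over the shot grid; return the metrics table.

    ``data`` may be passed directly; otherwise ``config.data_path`` is read
    (a corpus, embedded with the configured backend, or a saved embedding
    set by suffix).  Writes the TSV to ``config.out_path`` when set.
    """
    if data is None:
        if config.data_path is None:
            raise ConfigurationError("no data: set data_path or pass an EmbeddingSet")
        path = Path(config.data_path)
        if path.suffix.lower() in (".jsonl", ".ndjson", ".csv"):
            corpus = read_corpus(path)
            backend = get_backend(config.backend, dimension=config.backend_dimension)
            data = embed_corpus(corpus, backend)
        elif path.suffix.lower() in (".tsv", ".txt"):
            data = read_embeddings_text(path)
        else:
            data = read_embeddings_binary(path)

    factory = make_classifier_factory(config, data.dim)
    frames = []
    for k in config.shots:
        logger.info(
            "evaluating method=%s backend=%s k=%d m=%d seed=%d n=%d",
            config.method, config.backend, k, config.m_iterations,
            config.seed, data.n_samples,
        )
        record = evaluate_averaged(
            data,
            factory,
            k_shots=k,
            m_iterations=config.m_iterations,
            mode=config.episode_mode,
            averaging=config.averaging,
            base_seed=config.seed,
        )
        frames.append(metrics_frame(record, config.method, config.backend, k))
    result = pd.concat(frames, ignore_index=True)
    if config.out_path:
        write_metrics_tsv(result, config.out_path)
        logger.info("wrote metrics to %s", config.out_path)
    return result
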