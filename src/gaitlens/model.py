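"""Spatio-temporal temporal-attention graph convolutional network (ST-TAGCN)
for 7-frame gait-cycle graphs, with supervised training and latent-embedding
extraction.

Each of the (default three) stacked blocks applies

1. a spatial graph convolution over the skeleton adjacency (self-loops,
   symmetric degree normalization),
2. scaled dot-product temporal self-attention across the 7 frames,
   independently per joint (so temporal mixing never crosses joints —
   spatial context enters only through the graph convolution),
3. a residual connection and ReLU.

The classifier head projects the last block's channels down to
``embedding_channels`` (default 3) with a learned per-node 1x1 projection —
restoring the input graph's 18x7x3 shape — then flattens into a small fully
connected network producing class logits.  Because the projection is trained
jointly with the classifier, the 18x7x3 latent array extracted after
training is both class-discriminative and node-aligned with the input
skeleton.

Implementation note: the network runs on a small reverse-mode autodiff
engine built on NumPy (:mod:`gaitlens.nn.autograd`); at these sizes (18
nodes, 7 frames, tens of channels) CPU matmuls are more than fast enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

from .nn import Tensor, cross_entropy
from .schema import DEFAULT_SCHEMA, JointSchema
from .types import CYCLE_FRAMES, GaitCycleInstance


class StratificationError(ValueError):
    """A class is missing from one of the train/val/test splits."""


@dataclass(frozen=True)
class ModelConfig:
    n_blocks: int = 3
    channels_per_block: tuple[int, ...] = (64, 128, 256)
    embedding_channels: int = 3
    n_classes: int = 2
    attention_heads: int = 4
    dropout: float = 0.0
    hidden_units: int = 64

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if len(self.channels_per_block) != self.n_blocks:
            raise ValueError("channels_per_block length must equal n_blocks")
        if self.embedding_channels < 1:
            raise ValueError("embedding_channels must be >= 1")
        for c in self.channels_per_block:
            if c % self.attention_heads != 0:
                raise ValueError(
                    f"channel width {c} not divisible by "
                    f"{self.attention_heads} attention heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 120
    learning_rate: float = 0.001
    batch_size: int = 128
    split: tuple[float, float, float] = (0.70, 0.20, 0.10)
    folds: int = 5
    seed: int = 0
    momentum: float = 0.9
    clip_norm: float = 5.0  # global gradient-norm clip; 0 disables

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _glorot(rng: np.random.Generator, *shape) -> Tensor:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class STTAGCN:
    """The model object: parameters, forward pass, embedding extraction."""

    def __init__(self, config: ModelConfig, schema: JointSchema = DEFAULT_SCHEMA,
                 seed: int = 0):
        self.config = config
        self.schema = schema
        self.seed = seed
        self.adjacency = Tensor(schema.adjacency(self_loops=True, normalized=True))
        self.trained = False
        self.history: dict[str, list[float]] = {"loss": [], "train_accuracy": []}
        self.classes_: Optional[list[str]] = None
        self.input_mean = np.zeros(3)
        self.input_std = np.ones(3)
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        V, T = self.schema.n_joints, CYCLE_FRAMES
        p: dict[str, Tensor] = {}
        in_c = 3
        for b, out_c in enumerate(cfg.channels_per_block):
            p[f"b{b}.Wg"] = _glorot(rng, in_c, out_c)
            p[f"b{b}.bg"] = Tensor(np.zeros(out_c), requires_grad=True)
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"b{b}.{name}"] = _glorot(rng, out_c, out_c)
            if in_c != out_c:
                p[f"b{b}.Wres"] = _glorot(rng, in_c, out_c)
            in_c = out_c
        p["proj"] = _glorot(rng, V, in_c, cfg.embedding_channels)
        flat = V * T * cfg.embedding_channels
        p["W1"] = _glorot(rng, flat, cfg.hidden_units)
        p["b1"] = Tensor(np.zeros(cfg.hidden_units), requires_grad=True)
        p["W2"] = _glorot(rng, cfg.hidden_units, cfg.n_classes)
        p["b2"] = Tensor(np.zeros(cfg.n_classes), requires_grad=True)
        self.params = p

    # ---- forward ---------------------------------------------------------
    def _block(self, x: Tensor, b: int) -> Tensor:
        p = self.params
        h = (self.adjacency @ x) @ p[f"b{b}.Wg"] + p[f"b{b}.bg"]  # (N,T,V,C)
        n, t, v, c = h.shape
        heads = self.config.attention_heads
        dh = c // heads
        ht = h.transpose(0, 2, 1, 3)                              # (N,V,T,C)

        def split_heads(m: Tensor) -> Tensor:
            return m.reshape(n, v, t, heads, dh).transpose(0, 1, 3, 2, 4)

        q = split_heads(ht @ p[f"b{b}.Wq"])
        k = split_heads(ht @ p[f"b{b}.Wk"])
        val = split_heads(ht @ p[f"b{b}.Wv"])
        scores = (q @ k.transpose(0, 1, 2, 4, 3)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1) @ val                      # (N,V,h,T,dh)
        attn = attn.transpose(0, 1, 3, 2, 4).reshape(n, v, t, c)
        attn = (attn @ p[f"b{b}.Wo"]).transpose(0, 2, 1, 3)       # (N,T,V,C)

        res = x @ p[f"b{b}.Wres"] if f"b{b}.Wres" in p else x
        return (attn + res).relu()

    def _latent(self, x: Tensor) -> Tensor:
        """Blocks + per-node channel projection -> (N, T, V, embedding_channels)."""
        for b in range(self.config.n_blocks):
            x = self._block(x, b)
        n, t, v, c = x.shape
        e = x.transpose(2, 0, 1, 3).reshape(v, n * t, c) @ self.params["proj"]
        return e.reshape(v, n, t, self.config.embedding_channels).transpose(1, 2, 0, 3)

    def forward(self, velocities: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> tuple[Tensor, Tensor]:
        """Run the network on an (N, 7, 18, 3) velocity batch.

        Returns ``(logits, latent)`` where latent is (N, 7, 18, emb).
        """
        x = np.asarray(velocities, dtype=float)
        if x.ndim == 3:
            x = x[None]
        x = (x - self.input_mean) / self.input_std
        e = self._latent(Tensor(x))
        n = e.shape[0]
        h = (e.reshape(n, -1) @ self.params["W1"] + self.params["b1"]).relu()
        if training and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            mask = (rng or np.random.default_rng()).random(h.shape) < keep
            h = h * Tensor(mask / keep)
        logits = h @ self.params["W2"] + self.params["b2"]
        return logits, e

    def predict(self, velocities: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(velocities)
        return logits.data.argmax(axis=1)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.grad = None


def build_model(config: ModelConfig, schema: JointSchema = DEFAULT_SCHEMA,
                seed: int = 0) -> STTAGCN:
    """Construct an untrained ST-TAGCN for the given skeleton schema."""
    return STTAGCN(config, schema, seed=seed)


# ---- training ------------------------------------------------------------

def _encode_labels(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[l] for l in labels]), classes


def grouped_split(subjects: Sequence[str], labels: Sequence[str],
                  fractions: tuple[float, float, float], seed: int,
                  max_tries: int = 50) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subject-grouped train/val/test index split, stratification-checked.

    Whole subjects are assigned to one split each (no subject leakage); the
    assignment is re-drawn until every class appears in every non-empty
    split, failing with :class:`StratificationError` after ``max_tries``.
    """
    subjects = np.asarray(subjects)
    labels = np.asarray(labels)
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    classes = set(labels)
    for _ in range(max_tries):
        perm = rng.permutation(uniq)
        n_train = max(1, int(round(fractions[0] * len(uniq))))
        n_val = max(1, int(round(fractions[1] * len(uniq)))) if fractions[1] > 0 else 0
        # keep at least one subject for a requested test split
        while fractions[2] > 0 and n_train + n_val >= len(uniq):
            if n_val > 1:
                n_val -= 1
            elif n_train > 1:
                n_train -= 1
            else:
                break
        train_s = set(perm[:n_train])
        val_s = set(perm[n_train:n_train + n_val])
        test_s = set(perm[n_train + n_val:])
        idx = {
            "train": np.flatnonzero(np.isin(subjects, list(train_s))),
            "val": np.flatnonzero(np.isin(subjects, list(val_s))),
            "test": np.flatnonzero(np.isin(subjects, list(test_s))),
        }
        ok = all(set(labels[v]) == classes for v in idx.values() if len(v))
        if ok:
            return idx["train"], idx["val"], idx["test"]
    raise StratificationError(
        "could not build a subject-grouped split with every class in every "
        "split; need more subjects per class")


def fit(model: STTAGCN, velocities: np.ndarray, y: np.ndarray,
        config: TrainConfig) -> STTAGCN:
    """Mini-batch SGD (with momentum) on softmax cross-entropy, in place."""
    x = np.asarray(velocities, dtype=float)
    model.input_mean = x.mean(axis=(0, 1, 2))
    std = x.std(axis=(0, 1, 2))
    model.input_std = np.where(std > 1e-12, std, 1.0)
    rng = np.random.default_rng(config.seed)
    velocity_buf = {id(p): np.zeros_like(p.data) for p in model.parameters()}
    n = len(y)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            model.zero_grad()
            logits, _ = model.forward(x[batch], training=True, rng=rng)
            loss = cross_entropy(logits, y[batch])
            loss.backward()
            if config.clip_norm > 0:
                gnorm = np.sqrt(sum(float((p.grad ** 2).sum())
                                    for p in model.parameters()))
                if gnorm > config.clip_norm:
                    scale = config.clip_norm / gnorm
                    for p in model.parameters():
                        p.grad *= scale
            for p in model.parameters():
                buf = velocity_buf[id(p)]
                buf *= config.momentum
                buf -= config.learning_rate * p.grad
                p.data += buf
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[batch]).sum())
        model.history["loss"].append(float(np.mean(losses)))
        model.history["train_accuracy"].append(correct / n)
    model.trained = True
    return model


def train(model_config: ModelConfig, instances: list[GaitCycleInstance],
          labels: Sequence[str], config: TrainConfig,
          schema: JointSchema = DEFAULT_SCHEMA,
          ) -> tuple[STTAGCN, list[dict[str, float]]]:
    """Supervised training with subject-grouped stratified splits.

    Runs ``config.folds`` independent splits (re-seeded from ``config.seed``),
    reporting held-out test accuracy and macro-F1 per fold, and returns the
    model trained on the first fold's training split.
    """
    y, classes = _encode_labels(list(labels))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    x = np.stack([i.velocities for i in instances])
    subjects = [i.subject_id for i in instances]

    fold_metrics: list[dict[str, float]] = []
    first_model: Optional[STTAGCN] = None
    for fold in range(config.folds):
        tr, _va, te = grouped_split(subjects, list(labels), config.split,
                                    seed=config.seed + fold)
        m = build_model(model_config, schema, seed=config.seed + fold)
        m.classes_ = classes
        fit(m, x[tr], y[tr], config)
        pred = m.predict(x[te])
        fold_metrics.append({
            "fold": float(fold),
            "test_accuracy": float(accuracy_score(y[te], pred)),
            "test_macro_f1": float(f1_score(y[te], pred, average="macro",
                                            zero_division=0)),
        })
        if first_model is None:
            first_model = m
            first_model.split_indices_ = {"train": tr, "val": _va, "test": te}
    assert first_model is not None
    return first_model, fold_metrics


def save_model(model: STTAGCN, path) -> None:
    """Write a checkpoint: config snapshot, parameters, input statistics."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    arrays = {k.replace(".", "__"): t.data for k, t in model.params.items()}
    np.savez(path.with_suffix(".npz"), input_mean=model.input_mean,
             input_std=model.input_std, **arrays)
    meta = {"config": asdict(model.config), "seed": model.seed,
            "trained": model.trained, "classes": model.classes_,
            "history": model.history}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path, schema: JointSchema = DEFAULT_SCHEMA) -> STTAGCN:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = dict(meta["config"])
    cfg["channels_per_block"] = tuple(cfg["channels_per_block"])
    model = STTAGCN(ModelConfig(**cfg), schema, seed=meta["seed"])
    data = np.load(path.with_suffix(".npz"))
    for k in model.params:
        model.params[k].data = data[k.replace(".", "__")]
    model.input_mean = data["input_mean"]
    model.input_std = data["input_std"]
    model.trained = meta["trained"]
    model.classes_ = meta["classes"]
    model.history = meta["history"]
    return model


def extract_embeddings(model: STTAGCN,
                       instances: list[GaitCycleInstance]) -> np.ndarray:
    """Latent 18x7x3 arrays for each instance, from the trained model.

    The classifier head is bypassed; the last block's output passes through
    the learned per-node channel projection only.  Output shape is
    ``(n, 18, 7, embedding_channels)``.
    """
    if not model.trained:
        raise RuntimeError("model is untrained; call fit/train before "
                           "extracting embeddings")
    x = np.stack([i.velocities for i in instances])
    out = []
    for start in range(0, len(x), 256):
        _, e = model.forward(x[start:start + 256])
        out.append(e.data.transpose(0, 2, 1, 3))  # (N,T,V,C) -> (N,V,T,C)
    return np.concatenate(out)
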