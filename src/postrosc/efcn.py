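"""Embedded fully convolutional network (EFCN) pair for sequential
decision and outcome prediction, with embedding transfer between the tasks.

Each categorical feature owns a learned embedding table (level-count x dim).
A record's embeddings are concatenated, in schema feature order, into one
1-D sequence over which convolutional blocks (convolution -> batch
normalization -> rectifier) operate; global average pooling and a logistic
head produce the positive-class probability.  The implementation is plain
numpy with hand-written backpropagation and Adam — small enough networks and
vocabularies that a framework buys nothing, and full control over weight
layout is what makes bit-exact embedding transfer easy to assert.

Training protocol: binary cross-entropy, early stopping on validation AUROC
with a patience window, best-validation-epoch weights returned.  The
survival network is created from the trained decision network by copying
every shared feature's embedding table verbatim; only the coronary
angiography (CA) embedding — the one feature new to the survival task — and,
by default, the non-embedding layers are freshly initialized
(``transfer_all=True`` also copies the convolutional stack and head).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from postrosc.data_model import FeatureSchema, InputSet
from postrosc.encoding import IndexMatrix
from postrosc.metrics import auroc


def default_embedding_dim(level_count: int) -> int:
    """min(16, ceil((levels+1)/2)): small tables for small vocabularies."""
    return min(16, math.ceil((level_count + 1) / 2))


@dataclass(frozen=True)
class EFCNArchitecture:
    """Hyper-structure of an EFCN.

    ``conv_blocks`` is a list of (filters, kernel_width).  The default stack
    (128, 256, 128 filters with kernels 8, 5, 3) is the canonical
    fully-convolutional classifier this family derives from; ``compact()``
    is a 32-filter preset for small registries and fast experiments.
    """

    conv_blocks: tuple[tuple[int, int], ...] = ((128, 8), (256, 5), (128, 3))
    use_batch_norm: bool = True
    dropout_rate: float = 0.0
    embedding_dim_rule: Callable[[int], int] = default_embedding_dim

    def __post_init__(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("at least one conv block required")
        for filters, kw in self.conv_blocks:
            if filters < 1 or kw < 1:
                raise ValueError("conv filters and kernel widths must be >=1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @classmethod
    def compact(cls, **kwargs) -> "EFCNArchitecture":
        kwargs.setdefault("conv_blocks", ((32, 5), (32, 3)))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "conv_blocks": [list(b) for b in self.conv_blocks],
            "use_batch_norm": self.use_batch_norm,
            "dropout_rate": self.dropout_rate,
        }


@dataclass
class TrainConfig:
    """Optimization settings: Adam, early stopping on validation AUROC."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    monitor: str = "auroc"  # "auroc" for model selection, "loss" to favor
    # calibration (useful when probabilities are thresholded downstream)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class EFCN:
    """One trained (or trainable) embedded fully convolutional classifier."""

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(
        self,
        features: Sequence[str],
        level_counts: Sequence[int],
        arch: EFCNArchitecture,
        seed: int,
    ):
        if any(k < 2 for k in level_counts):
            raise ValueError("every feature needs >=2 levels to embed")
        self.features = tuple(features)
        self.level_counts = tuple(int(k) for k in level_counts)
        self.arch = arch
        self.seed = int(seed)
        self.embed_dims = tuple(
            arch.embedding_dim_rule(k) for k in self.level_counts
        )
        if any(d < 1 for d in self.embed_dims):
            raise ValueError("embedding dims must be >=1")
        self.seq_len = sum(self.embed_dims)
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self._init_weights(np.random.default_rng(seed))

    # -- construction -----------------------------------------------------

    def _init_weights(self, rng: np.random.Generator) -> None:
        p, b = self.params, self.buffers
        for name, k, d in zip(self.features, self.level_counts, self.embed_dims):
            p[f"emb_{name}"] = rng.normal(0.0, 0.2, size=(k, d))
        c_in = 1
        for i, (filters, kw) in enumerate(self.arch.conv_blocks):
            p[f"conv{i}_W"] = rng.normal(
                0.0, math.sqrt(2.0 / (c_in * kw)), size=(filters, c_in, kw)
            )
            p[f"conv{i}_b"] = np.zeros(filters)
            if self.arch.use_batch_norm:
                p[f"bn{i}_gamma"] = np.ones(filters)
                p[f"bn{i}_beta"] = np.zeros(filters)
                b[f"bn{i}_mean"] = np.zeros(filters)
                b[f"bn{i}_var"] = np.ones(filters)
            c_in = filters
        p["head_W"] = rng.normal(0.0, math.sqrt(2.0 / c_in), size=c_in)
        p["head_b"] = np.zeros(1)

    def parameter_count(self) -> int:
        return sum(v.size for v in self.params.values())

    def embedding_table(self, feature: str) -> np.ndarray:
        return self.params[f"emb_{feature}"]

    def clone(self) -> "EFCN":
        other = copy.copy(self)
        other.params = {k: v.copy() for k, v in self.params.items()}
        other.buffers = {k: v.copy() for k, v in self.buffers.items()}
        return other

    # -- forward / backward ----------------------------------------------

    def _embed(self, X: np.ndarray) -> np.ndarray:
        segments = [
            self.params[f"emb_{name}"][X[:, j]]
            for j, name in enumerate(self.features)
        ]
        return np.concatenate(segments, axis=1)  # (n, seq_len)

    @staticmethod
    def _conv_pad(kw: int) -> tuple[int, int]:
        return (kw - 1) // 2, kw // 2

    def _forward(self, X: np.ndarray, training: bool, rng=None):
        cache: dict = {"X": X}
        seq = self._embed(X)
        x = seq[:, None, :].astype(float)  # (n, 1, L)
        cache["seq_shape"] = seq.shape
        for i, (filters, kw) in enumerate(self.arch.conv_blocks):
            left, right = self._conv_pad(kw)
            xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
            win = np.lib.stride_tricks.sliding_window_view(xp, kw, axis=2)
            cols = win.transpose(0, 2, 1, 3).reshape(
                x.shape[0], x.shape[2], -1
            )  # (n, L, C_in*kw)
            W = self.params[f"conv{i}_W"].reshape(filters, -1)
            z = cols @ W.T + self.params[f"conv{i}_b"]  # (n, L, C_out)
            z = z.transpose(0, 2, 1)  # (n, C_out, L)
            cache[f"cols{i}"] = cols
            cache[f"x_in_shape{i}"] = x.shape
            if self.arch.use_batch_norm:
                if training:
                    mu = z.mean(axis=(0, 2))
                    var = z.var(axis=(0, 2))
                    m = self.BN_MOMENTUM
                    self.buffers[f"bn{i}_mean"] *= 1 - m
                    self.buffers[f"bn{i}_mean"] += m * mu
                    self.buffers[f"bn{i}_var"] *= 1 - m
                    self.buffers[f"bn{i}_var"] += m * var
                else:
                    mu = self.buffers[f"bn{i}_mean"]
                    var = self.buffers[f"bn{i}_var"]
                std = np.sqrt(var + self.BN_EPS)
                xhat = (z - mu[None, :, None]) / std[None, :, None]
                cache[f"xhat{i}"] = xhat
                cache[f"std{i}"] = std
                z = (
                    self.params[f"bn{i}_gamma"][None, :, None] * xhat
                    + self.params[f"bn{i}_beta"][None, :, None]
                )
            mask = z > 0
            cache[f"relu{i}"] = mask
            x = z * mask
        gap = x.mean(axis=2)  # (n, C_last)
        cache["gap_len"] = x.shape[2]
        if training and self.arch.dropout_rate > 0.0:
            keep = 1.0 - self.arch.dropout_rate
            drop = (rng.random(gap.shape) < keep) / keep
            gap = gap * drop
            cache["drop"] = drop
        cache["gap"] = gap
        logit = gap @ self.params["head_W"] + self.params["head_b"][0]
        return logit, cache

    def _backward(self, dlogit: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        gap = cache["gap"]
        grads["head_W"] = gap.T @ dlogit
        grads["head_b"] = np.array([dlogit.sum()])
        dgap = np.outer(dlogit, self.params["head_W"])
        if "drop" in cache:
            dgap = dgap * cache["drop"]
        L = cache["gap_len"]
        dx = np.repeat(dgap[:, :, None], L, axis=2) / L
        for i in reversed(range(len(self.arch.conv_blocks))):
            dz = dx * cache[f"relu{i}"]
            if self.arch.use_batch_norm:
                xhat = cache[f"xhat{i}"]
                std = cache[f"std{i}"]
                gamma = self.params[f"bn{i}_gamma"]
                grads[f"bn{i}_gamma"] = (dz * xhat).sum(axis=(0, 2))
                grads[f"bn{i}_beta"] = dz.sum(axis=(0, 2))
                m = dz.shape[0] * dz.shape[2]
                dmean = dz.mean(axis=(0, 2))
                dxhat_mean = (dz * xhat).mean(axis=(0, 2))
                dz = (
                    gamma[None, :, None]
                    / std[None, :, None]
                    * (dz - dmean[None, :, None] - xhat * dxhat_mean[None, :, None])
                )
            filters, kw = self.arch.conv_blocks[i]
            cols = cache[f"cols{i}"]
            n, _, Lc = cache[f"x_in_shape{i}"]
            dz_t = dz.transpose(0, 2, 1)  # (n, L, C_out)
            W = self.params[f"conv{i}_W"].reshape(filters, -1)
            grads[f"conv{i}_W"] = (
                dz_t.reshape(-1, filters).T @ cols.reshape(-1, cols.shape[2])
            ).reshape(self.params[f"conv{i}_W"].shape)
            grads[f"conv{i}_b"] = dz.sum(axis=(0, 2))
            dcols = dz_t @ W  # (n, L, C_in*kw)
            c_in = cols.shape[2] // kw
            dcols = dcols.reshape(n, Lc, c_in, kw).transpose(0, 2, 1, 3)
            left, right = self._conv_pad(kw)
            dxp = np.zeros((n, c_in, Lc + left + right))
            for k in range(kw):
                dxp[:, :, k : k + Lc] += dcols[:, :, :, k]
            dx = dxp[:, :, left : left + Lc]
        dseq = dx[:, 0, :]  # (n, seq_len)
        X = cache["X"]
        start = 0
        for j, name in enumerate(self.features):
            d = self.embed_dims[j]
            g = np.zeros_like(self.params[f"emb_{name}"])
            np.add.at(g, X[:, j], dseq[:, start : start + d])
            grads[f"emb_{name}"] = g
            start += d
        return grads

    # -- inference --------------------------------------------------------

    def predict(self, X: "IndexMatrix | np.ndarray", batch_size: int = 4096) -> np.ndarray:
        """Positive-class probabilities; eval mode, deterministic."""
        mat = X.matrix if isinstance(X, IndexMatrix) else np.asarray(X)
        if mat.ndim != 2 or mat.shape[1] != len(self.features):
            raise ValueError(
                f"input width {mat.shape} incompatible with "
                f"{len(self.features)}-feature network"
            )
        for j, k in enumerate(self.level_counts):
            if mat[:, j].max(initial=0) >= k or mat[:, j].min(initial=0) < 0:
                raise ValueError(f"level index out of range for {self.features[j]!r}")
        out = np.empty(len(mat))
        for s in range(0, len(mat), batch_size):
            logit, _ = self._forward(mat[s : s + batch_size], training=False)
            out[s : s + batch_size] = _sigmoid(logit)
        return out


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def build_efcn(
    schema: FeatureSchema,
    arch: EFCNArchitecture,
    input_set: InputSet,
    seed: int,
) -> EFCN:
    """Untrained network over the given input set, seeded initialization."""
    features = schema.inputs(input_set)
    level_counts = [len(schema.levels(name)) for name in features]
    return EFCN(features, level_counts, arch, seed)


def expected_parameter_count(
    schema: FeatureSchema, arch: EFCNArchitecture, input_set: InputSet
) -> int:
    """Closed-form parameter count for a built network."""
    features = schema.inputs(input_set)
    total = 0
    for name in features:
        k = len(schema.levels(name))
        total += k * arch.embedding_dim_rule(k)
    c_in = 1
    for filters, kw in arch.conv_blocks:
        total += filters * c_in * kw + filters
        if arch.use_batch_norm:
            total += 2 * filters
        c_in = filters
    total += c_in + 1  # logistic head
    return total


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def train_efcn(
    network: EFCN,
    train: tuple[IndexMatrix, Sequence[int]],
    validation: tuple[IndexMatrix, Sequence[int]],
    hyper: Optional[TrainConfig] = None,
) -> list[dict]:
    """Fit in place; returns per-epoch history.

    Early stopping on validation AUROC with the configured patience; the
    weights (and batch-norm statistics) from the best validation epoch are
    restored before returning.  Deterministic given the network seed and
    ``hyper.seed`` under single-threaded execution.
    """
    hyper = hyper or TrainConfig()
    if hyper.monitor not in ("auroc", "loss"):
        raise ValueError(f"unknown monitor {hyper.monitor!r}")
    Xtr = train[0].matrix if isinstance(train[0], IndexMatrix) else np.asarray(train[0])
    ytr = np.asarray(train[1], dtype=float)
    Xva = (
        validation[0].matrix
        if isinstance(validation[0], IndexMatrix)
        else np.asarray(validation[0])
    )
    yva = np.asarray(validation[1], dtype=int)
    if len(set(ytr.astype(int))) < 2:
        raise ValueError("training labels are single-class")
    if len(set(yva)) < 2:
        raise ValueError("validation labels are single-class")

    rng = np.random.default_rng(hyper.seed)
    opt = _Adam(network.params, hyper.learning_rate)
    history: list[dict] = []
    best_auc = -np.inf
    best_state: Optional[tuple[dict, dict]] = None
    stale = 0
    n = len(Xtr)
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, hyper.batch_size):
            idx = order[s : s + hyper.batch_size]
            logit, cache = network._forward(Xtr[idx], training=True, rng=rng)
            p = _sigmoid(logit)
            losses.append(_bce(p, ytr[idx]) * len(idx))
            dlogit = (p - ytr[idx]) / len(idx)
            grads = network._backward(dlogit, cache)
            opt.step(network.params, grads)
        val_pred = network.predict(Xva)
        val_auc = auroc(val_pred, yva)
        val_loss = _bce(val_pred, yva.astype(float))
        history.append(
            {
                "epoch": epoch,
                "train_loss": sum(losses) / n,
                "val_auroc": val_auc,
                "val_loss": val_loss,
            }
        )
        score = val_auc if hyper.monitor == "auroc" else -val_loss
        if score > best_auc + 1e-6:
            best_auc = score
            best_state = (
                {k: v.copy() for k, v in network.params.items()},
                {k: v.copy() for k, v in network.buffers.items()},
            )
            stale = 0
        else:
            stale += 1
            if stale >= hyper.patience:
                break
    if best_state is not None:
        network.params, network.buffers = best_state
    return history


def transfer_embeddings(
    decision_model: EFCN,
    schema: FeatureSchema,
    arch: EFCNArchitecture,
    seed: int,
    transfer_all: bool = False,
) -> tuple[EFCN, dict[str, str]]:
    """Survival network warm-started from the decision network's embeddings.

    Every feature shared with the decision task receives that table verbatim;
    the CA embedding is freshly initialized (it is the only new input).  By
    default conv/norm/head weights are also fresh; ``transfer_all=True``
    copies them too.  The decision model is never mutated.
    """
    if tuple(decision_model.features) != schema.decision_inputs:
        raise ValueError("decision model features do not match schema")
    survival = build_efcn(schema, arch, "survival", seed)
    manifest: dict[str, str] = {}
    for name in schema.decision_inputs:
        src = decision_model.params[f"emb_{name}"]
        if src.shape != survival.params[f"emb_{name}"].shape:
            raise ValueError(f"embedding shape mismatch for {name!r}")
        survival.params[f"emb_{name}"] = src.copy()
        manifest[name] = "transferred"
    manifest[schema.ca_feature] = "randomly_initialized"
    if transfer_all:
        for key, val in decision_model.params.items():
            if not key.startswith("emb_"):
                survival.params[key] = val.copy()
        for key, val in decision_model.buffers.items():
            survival.buffers[key] = val.copy()
    return survival, manifest


@dataclass
class EFCNBundle:
    """The trained decision/survival pair plus its transfer provenance."""

    decision_model: EFCN
    survival_model: EFCN
    transfer_manifest: dict[str, str]
    training_history: dict[str, list[dict]]
    seeds: dict[str, int]

    def clone(self) -> "EFCNBundle":
        return EFCNBundle(
            decision_model=self.decision_model.clone(),
            survival_model=self.survival_model.clone(),
            transfer_manifest=dict(self.transfer_manifest),
            training_history={k: list(v) for k, v in self.training_history.items()},
            seeds=dict(self.seeds),
        )


def train_efcn_pair(
    schema: FeatureSchema,
    arch: EFCNArchitecture,
    train_records,
    validation_records,
    hyper: Optional[TrainConfig] = None,
    seed: int = 0,
    transfer_all: bool = False,
) -> EFCNBundle:
    """The sequential protocol: decision model first, then the survival model
    warm-started from its embeddings; the stored decision model is immutable
    during survival training (deep-copy contract)."""
    from postrosc.data_model import labels
    from postrosc.encoding import index_encode

    hyper = hyper or TrainConfig()
    Xtr_d = index_encode(train_records, schema, "decision")
    Xva_d = index_encode(validation_records, schema, "decision")
    decision = build_efcn(schema, arch, "decision", seed)
    hist_d = train_efcn(
        decision,
        (Xtr_d, labels(train_records, "decision")),
        (Xva_d, labels(validation_records, "decision")),
        hyper,
    )
    frozen_decision = decision.clone()

    survival, manifest = transfer_embeddings(
        frozen_decision, schema, arch, seed=seed + 1, transfer_all=transfer_all
    )
    Xtr_s = index_encode(train_records, schema, "survival")
    Xva_s = index_encode(validation_records, schema, "survival")
    hist_s = train_efcn(
        survival,
        (Xtr_s, labels(train_records, "outcome")),
        (Xva_s, labels(validation_records, "outcome")),
        hyper,
    )
    return EFCNBundle(
        decision_model=frozen_decision,
        survival_model=survival,
        transfer_manifest=manifest,
        training_history={"decision": hist_d, "survival": hist_s},
        seeds={"decision": seed, "survival": seed + 1, "shuffle": hyper.seed},
    )


def save_checkpoint(network: EFCN, path: str) -> None:
    """Write weights (npz) plus a JSON sidecar describing the network."""
    arrays = {f"param::{k}": v for k, v in network.params.items()}
    arrays.update({f"buffer::{k}": v for k, v in network.buffers.items()})
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    meta = {
        "features": list(network.features),
        "level_counts": list(network.level_counts),
        "seed": network.seed,
        "arch": network.arch.to_dict(),
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def load_checkpoint(path: str) -> EFCN:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", encoding="utf-8") as fh:
        meta = json.load(fh)
    arch = EFCNArchitecture(
        conv_blocks=tuple(tuple(b) for b in meta["arch"]["conv_blocks"]),
        use_batch_norm=meta["arch"]["use_batch_norm"],
        dropout_rate=meta["arch"]["dropout_rate"],
    )
    net = EFCN(meta["features"], meta["level_counts"], arch, meta["seed"])
    with np.load(base + ".npz") as data:
        for key in data.files:
            kind, name = key.split("::", 1)
            target = net.params if kind == "param" else net.buffers
            target[name] = data[key]
    return net
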