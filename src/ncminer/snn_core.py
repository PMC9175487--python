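"""The Siamese similarity model: shared MLP head, cosine body, sigmoid score.

Both compounds of a pair pass through the *same* embedding MLP H (weight
sharing); the parameter-free body B is the cosine of the angle between the
two embeddings, and the model output is

    score(x1, x2) = sigmoid( cos( H(x1), H(x2) ) )

so every score lies strictly inside (sigmoid(-1), sigmoid(1)) ~ (0.269, 0.731)
and the conventional 0.5 decision threshold is exactly the sign of the
embedding cosine.  Training minimizes mean binary cross-entropy over labeled
pairs with the Adam optimizer; forward, backward and Adam are implemented
here directly on NumPy arrays, which keeps runs bit-reproducible from a
single seed (parameter init, dropout masks and batch shuffling all draw from
one Generator).

Architecture default is a three-layer head (input -> 2048 -> 2048 -> 2048)
with ReLU + dropout 0.5 after each hidden activation and a linear final
layer; depth and widths are configurable (``hidden_dims``), down to the
literal two-layer form Z = W2 f(W1 X + b1) + b2.
"""

from __future__ import annotations

import copy
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_io import FingerprintSpec
from .errors import (
    CheckpointError,
    ConfigurationError,
    DimensionError,
    NCMinerError,
    SpecMismatchError,
)

CHECKPOINT_VERSION = 1
BCE_EPS = 1e-7  # log clamp


# ---------------------------------------------------------------------------
# elementary pieces (kept standalone so oracles can probe them directly)
# ---------------------------------------------------------------------------

def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def cosine_distance(z1: np.ndarray, z2: np.ndarray):
    """Cosine of the angle between embeddings (the model's "body").

    Works on single vectors or (batch, dim) arrays.  An all-zero vector has
    no direction; its cosine is defined as 0 (warned, never NaN).
    """
    z1 = np.asarray(z1, dtype=np.float64)
    z2 = np.asarray(z2, dtype=np.float64)
    if z1.shape != z2.shape:
        raise DimensionError(f"embedding shapes differ: {z1.shape} vs {z2.shape}")
    single = z1.ndim == 1
    if single:
        z1, z2 = z1[None, :], z2[None, :]
    n1 = np.linalg.norm(z1, axis=1)
    n2 = np.linalg.norm(z2, axis=1)
    denom = n1 * n2
    zero = denom == 0.0
    if zero.any():
        warnings.warn("cosine of an all-zero embedding defined as 0.0")
    out = np.where(zero, 0.0, np.einsum("ij,ij->i", z1, z2) / np.where(zero, 1.0, denom))
    out = np.clip(out, -1.0, 1.0)  # guard against rounding past the bounds
    return float(out[0]) if single else out


def bce_loss(scores, labels, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy with log arguments clamped to [eps, 1-eps]."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if s.size == 0:
        raise ConfigurationError("bce_loss of an empty batch is undefined")
    if s.shape != y.shape:
        raise DimensionError("scores and labels differ in length")
    s = np.clip(s, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


# ---------------------------------------------------------------------------
# head parameters
# ---------------------------------------------------------------------------

@dataclass
class HeadParams:
    """Weights/biases of the shared embedding MLP plus its layout."""

    weights: list  # W_i with shape (fan_in, fan_out)
    biases: list
    input_dim: int
    hidden_dims: tuple
    dropout_rate: float = 0.5

    @classmethod
    def initialize(
        cls,
        input_dim: int,
        hidden_dims: tuple = (2048, 2048, 2048),
        dropout_rate: float = 0.5,
        rng: np.random.Generator | None = None,
    ) -> "HeadParams":
        """He-normal initialization (appropriate for the ReLU hidden layers)."""
        rng = rng or np.random.default_rng(0)
        dims = (input_dim, *hidden_dims)
        weights, biases = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            weights.append((rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32))
            biases.append(np.zeros(fan_out, dtype=np.float32))
        return cls(weights, biases, input_dim, tuple(hidden_dims), dropout_rate)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def embedding_dim(self) -> int:
        return self.hidden_dims[-1]

    def copy(self) -> "HeadParams":
        return HeadParams(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.input_dim,
            self.hidden_dims,
            self.dropout_rate,
        )


def _forward_head(
    head: HeadParams,
    X: np.ndarray,
    train_mode: bool,
    rng: np.random.Generator | None = None,
):
    """Forward pass; returns (Z, cache) where cache holds what backward needs.

    Hidden layers: linear -> ReLU -> inverted dropout (train mode only).
    Final layer is linear.  Dropout is not applied to the input.
    """
    A = np.asarray(X, dtype=np.float32)
    pre_acts, post_acts, masks = [], [A], []
    p = head.dropout_rate
    for i, (W, b) in enumerate(zip(head.weights, head.biases)):
        Z = A @ W + b
        pre_acts.append(Z)
        if i < head.n_layers - 1:
            A = np.maximum(Z, 0.0)
            if train_mode and p > 0.0:
                mask = (rng.random(A.shape) >= p).astype(np.float32) / np.float32(1.0 - p)
                A = A * mask
            else:
                mask = None
            masks.append(mask)
            post_acts.append(A)
        else:
            A = Z
    return A, (pre_acts, post_acts, masks)


def _backward_head(head: HeadParams, cache, dZ: np.ndarray):
    """Gradients of loss w.r.t. head weights/biases and input, given dL/dZ_out."""
    pre_acts, post_acts, masks = cache
    grads_W = [None] * head.n_layers
    grads_b = [None] * head.n_layers
    dA = dZ.astype(np.float32)
    for i in reversed(range(head.n_layers)):
        if i < head.n_layers - 1:
            if masks[i] is not None:
                dA = dA * masks[i]
            dA = dA * (pre_acts[i] > 0)
        grads_W[i] = post_acts[i].T @ dA
        grads_b[i] = dA.sum(axis=0)
        if i > 0:
            dA = dA @ head.weights[i].T
    return grads_W, grads_b


def embed(
    head: HeadParams,
    fp: np.ndarray,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Map fingerprint(s) through the head.  Eval mode is deterministic;
    train mode applies dropout (requires an rng)."""
    if mode not in ("train", "eval"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    fp = np.asarray(fp, dtype=np.float32)
    single = fp.ndim == 1
    X = fp[None, :] if single else fp
    if X.shape[1] != head.input_dim:
        raise SpecMismatchError(
            f"fingerprint length {X.shape[1]} != model input_dim {head.input_dim}"
        )
    if mode == "train" and rng is None:
        raise ConfigurationError("train-mode embedding needs an rng for dropout")
    Z, _ = _forward_head(head, X, train_mode=(mode == "train"), rng=rng)
    return Z[0] if single else Z


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    def validate(self):
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class SiameseModel:
    """Shared head + cosine body + sigmoid output, with provenance."""

    head: HeadParams
    fingerprint_spec: FingerprintSpec
    training_log: list = field(default_factory=list)

    @classmethod
    def create(
        cls,
        fingerprint_spec: FingerprintSpec,
        hidden_dims: tuple = (2048, 2048, 2048),
        dropout_rate: float = 0.5,
        seed: int = 0,
    ) -> "SiameseModel":
        rng = np.random.default_rng(seed)
        head = HeadParams.initialize(
            fingerprint_spec.n_bits, hidden_dims, dropout_rate, rng
        )
        return cls(head=head, fingerprint_spec=fingerprint_spec)

    def check_spec(self, spec: FingerprintSpec) -> None:
        if spec != self.fingerprint_spec:
            raise SpecMismatchError(
                f"data fingerprint spec {spec} != model spec {self.fingerprint_spec}"
            )

    def embed(self, fp, mode: str = "eval", rng=None) -> np.ndarray:
        return embed(self.head, fp, mode=mode, rng=rng)

    def similarity_score(self, fp_a, fp_b) -> float | np.ndarray:
        """sigmoid(cosine(H(a), H(b))) in eval mode; symmetric in its arguments."""
        z1 = self.embed(fp_a)
        z2 = self.embed(fp_b)
        return sigmoid(cosine_distance(z1, z2))


def similarity_score(model: SiameseModel, fp_a, fp_b):
    return model.similarity_score(fp_a, fp_b)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list, grads: list) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)


def _pairs_to_arrays(pairs):
    X1 = np.stack([p.fp_a for p in pairs]).astype(np.float32)
    X2 = np.stack([p.fp_b for p in pairs]).astype(np.float32)
    y = np.array([p.label for p in pairs], dtype=np.float64)
    return X1, X2, y


def _batch_scores(model: SiameseModel, X1, X2, batch=1024):
    out = np.empty(X1.shape[0])
    for i in range(0, X1.shape[0], batch):
        z1 = model.embed(X1[i : i + batch])
        z2 = model.embed(X2[i : i + batch])
        out[i : i + batch] = sigmoid(cosine_distance(z1, z2))
    return out


def evaluate_pairs_bce(model: SiameseModel, pairs) -> float:
    """Eval-mode mean BCE of a pair list (no dropout, no weight updates)."""
    X1, X2, y = _pairs_to_arrays(pairs)
    return bce_loss(_batch_scores(model, X1, X2), y)


def train(
    model: SiameseModel,
    train_pairs,
    val_pairs=None,
    cfg: TrainConfig | None = None,
    phase: str = "train",
) -> SiameseModel:
    """Minimize mean BCE over pairs with Adam; early stopping on validation BCE.

    Updates the model head in place and appends one entry per phase to
    ``model.training_log`` (per-epoch train/val losses, config, seed).  With a
    non-empty validation set, training stops after ``cfg.patience`` epochs
    without improvement and the best-validation weights are restored.
    Fully deterministic for a fixed seed (single-threaded BLAS assumed for
    bitwise reproducibility).
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    if not train_pairs:
        raise ConfigurationError("train() needs a nonempty training pair list")
    if train_pairs[0].fp_a.size != model.head.input_dim:
        raise SpecMismatchError(
            f"pair fingerprints ({train_pairs[0].fp_a.size} bits) do not match "
            f"model input_dim {model.head.input_dim}"
        )
    rng = np.random.default_rng(cfg.seed)
    X1, X2, y = _pairs_to_arrays(train_pairs)
    n = X1.shape[0]
    head = model.head
    params = head.weights + head.biases
    opt = _Adam(params, cfg.learning_rate)

    history = []
    best_val = np.inf
    best_params = None
    bad_epochs = 0
    use_val = bool(val_pairs)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            b1, b2, by = X1[idx], X2[idx], y[idx]
            Z1, cache1 = _forward_head(head, b1, train_mode=True, rng=rng)
            Z2, cache2 = _forward_head(head, b2, train_mode=True, rng=rng)
            Z1d = Z1.astype(np.float64)
            Z2d = Z2.astype(np.float64)
            n1 = np.linalg.norm(Z1d, axis=1)
            n2 = np.linalg.norm(Z2d, axis=1)
            safe = np.where((n1 == 0) | (n2 == 0), 1.0, n1 * n2)
            dot = np.einsum("ij,ij->i", Z1d, Z2d)
            c = np.where((n1 == 0) | (n2 == 0), 0.0, dot / safe)
            s = sigmoid(c)
            loss = bce_loss(s, by)
            if not np.isfinite(loss):
                raise NCMinerError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * idx.size
            # d BCE/d cosine for sigmoid+BCE collapses to (s - y)/B
            dc = (s - by) / idx.size
            with np.errstate(divide="ignore", invalid="ignore"):
                dZ1 = dc[:, None] * (Z2d / safe[:, None] - (c / np.maximum(n1, 1e-30) ** 2)[:, None] * Z1d)
                dZ2 = dc[:, None] * (Z1d / safe[:, None] - (c / np.maximum(n2, 1e-30) ** 2)[:, None] * Z2d)
            gW1, gb1 = _backward_head(head, cache1, dZ1)
            gW2, gb2 = _backward_head(head, cache2, dZ2)
            grads = [a + b for a, b in zip(gW1, gW2)] + [a + b for a, b in zip(gb1, gb2)]
            opt.step(params, grads)
        train_bce = epoch_loss / n
        val_bce = evaluate_pairs_bce(model, val_pairs) if use_val else None
        history.append({"epoch": epoch, "train_bce": train_bce, "val_bce": val_bce})
        if use_val:
            if val_bce < best_val - 1e-12:
                best_val = val_bce
                best_params = (head.copy(), opt.t)
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break

    if use_val and best_params is not None:
        restored = best_params[0]
        head.weights[:] = restored.weights
        head.biases[:] = restored.biases

    model.training_log.append(
        {
            "phase": phase,
            "config": copy.copy(cfg).__dict__,
            "epochs_run": len(history),
            "history": history,
            "best_val_bce": None if not use_val else (None if best_val == np.inf else best_val),
        }
    )
    return model


def fine_tune(
    model: SiameseModel,
    new_pairs,
    val_pairs=None,
    cfg: TrainConfig | None = None,
) -> SiameseModel:
    """Transfer-learning phase: continue optimization from the current
    weights on a new pair set (all layers trainable; nothing frozen)."""
    if new_pairs and new_pairs[0].fp_a.size != model.head.input_dim:
        raise SpecMismatchError(
            f"fine-tune pairs ({new_pairs[0].fp_a.size} bits) do not match "
            f"model input_dim {model.head.input_dim}"
        )
    cfg = cfg or TrainConfig()
    if cfg.max_epochs == 0:
        model.training_log.append(
            {"phase": "transfer", "config": copy.copy(cfg).__dict__,
             "epochs_run": 0, "history": [], "best_val_bce": None}
        )
        return model
    return train(model, new_pairs, val_pairs, cfg, phase="transfer")


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: SiameseModel, path: str | Path) -> None:
    """Single-archive checkpoint: weights + architecture + fingerprint spec +
    training log, with a version field so load never guesses shapes."""
    path = Path(path)
    meta = {
        "version": CHECKPOINT_VERSION,
        "architecture": {
            "input_dim": model.head.input_dim,
            "hidden_dims": list(model.head.hidden_dims),
            "dropout_rate": model.head.dropout_rate,
        },
        "fingerprint_spec": model.fingerprint_spec.to_dict(),
        "training_log": model.training_log,
    }
    arrays = {"meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, (W, b) in enumerate(zip(model.head.weights, model.head.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    path.write_bytes(buf.getvalue())


def load_model(path: str | Path) -> SiameseModel:
    path = Path(path)
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"unsupported checkpoint version {meta.get('version')!r}"
                )
            if "fingerprint_spec" not in meta or "architecture" not in meta:
                raise CheckpointError("checkpoint missing fingerprint spec or architecture")
            arch = meta["architecture"]
            n_layers = len(arch["hidden_dims"])
            weights = [data[f"W{i}"] for i in range(n_layers)]
            biases = [data[f"b{i}"] for i in range(n_layers)]
    except (KeyError, ValueError, OSError) as exc:
        raise CheckpointError(f"cannot load checkpoint {path}: {exc}") from exc
    head = HeadParams(
        weights, biases, arch["input_dim"], tuple(arch["hidden_dims"]), arch["dropout_rate"]
    )
    return SiameseModel(
        head=head,
        fingerprint_spec=FingerprintSpec.from_dict(meta["fingerprint_spec"]),
        training_log=meta["training_log"],
    )
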