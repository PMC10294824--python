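"""Modified VGG16 classifier for 128 x 128 heart-sound feature maps.

The network is a fixed census of seven 3x3 convolution layers, three 2x2 max
pooling layers (spatial trace 128 -> 64 -> 32 -> 16) and four fully-connected
layers ending in a 2-way softmax (normal vs abnormal).  Channel widths are
configurable; the census is not.

The implementation is a self-contained numpy CNN: same-padded convolution via
sliding windows and BLAS contractions, Kaiming-initialised weights, Adam on a
cross-entropy loss, with an explicit seed for every random choice so training
runs are bit-reproducible on a fixed machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import ABNORMAL, NORMAL

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "TrainResult",
    "VGGStyleCNN",
    "build_model",
    "oversample_balance",
    "stratified_record_split",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

CLASSES = (NORMAL, ABNORMAL)  # index 0 = normal, 1 = abnormal (positive)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer census of the modified VGG16: 7 convs in 3 pooled blocks, then
    4 fully-connected layers ending in 2 classes."""

    input_shape: tuple[int, int] = (128, 128)
    conv_blocks: tuple[tuple[int, ...], ...] = ((32, 32), (64, 64), (128, 128, 128))
    fc_sizes: tuple[int, ...] = (256, 128, 64, 2)

    def __post_init__(self) -> None:
        n_conv = sum(len(b) for b in self.conv_blocks)
        if n_conv != 7:
            raise ValueError(f"architecture requires exactly 7 conv layers, got {n_conv}")
        if len(self.conv_blocks) != 3:
            raise ValueError("architecture requires exactly 3 max-pool blocks")
        if len(self.fc_sizes) != 4:
            raise ValueError("architecture requires exactly 4 fully-connected layers")
        if self.fc_sizes[-1] != 2:
            raise ValueError("final layer width must be 2 (normal/abnormal)")
        h, w = self.input_shape
        if h % 8 or w % 8:
            raise ValueError("input sides must be divisible by 8 (three 2x2 pools)")

    @property
    def spatial_trace(self) -> tuple[tuple[int, int], ...]:
        h, w = self.input_shape
        trace = [(h, w)]
        for _ in self.conv_blocks:
            h, w = h // 2, w // 2
            trace.append((h, w))
        return tuple(trace)


def small_architecture() -> ArchitectureSpec:
    """Desk-scale widths (same census) for CPU training experiments."""
    return ArchitectureSpec(conv_blocks=((4, 4), (8, 8), (16, 16, 16)),
                            fc_sizes=(64, 32, 16, 2))


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.  Defaults follow the reference recipe
    (Adam, lr 1e-4, batch 160, cross-entropy, 20% validation, oversampling,
    Kaiming init); desk-scale experiments override lr/batch/epochs."""

    learning_rate: float = 1e-4
    batch_size: int = 160
    epochs: int = 30
    val_fraction: float = 0.20
    oversample: bool = True
    steps_per_epoch: int | None = None  # None = full pass over the data
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class TrainResult:
    train_acc: np.ndarray
    val_acc: np.ndarray
    train_loss: np.ndarray
    val_loss: np.ndarray
    best_epoch: int
    best_state: list[np.ndarray]

    @property
    def best_val_acc(self) -> float:
        return float(self.val_acc[self.best_epoch])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, self.train_acc.size + 1),
            "train_acc": self.train_acc, "val_acc": self.val_acc,
            "train_loss": self.train_loss, "val_loss": self.val_loss,
        })


# ---------------------------------------------------------------------------
# layers
#
# The 3x3 same-padded convolutions are the hot path of CPU training, so the
# inner loops are JIT-compiled with numba; everything else is plain numpy.

from numba import njit  # noqa: E402


@njit(cache=True, fastmath=True)
def _conv3x3_fwd(xp, w):  # xp (B,C,H+2,W+2), w (O,C,3,3) -> (B,O,H,W)
    b_n, c_n, hp, wp = xp.shape
    o_n = w.shape[0]
    h_n, w_n = hp - 2, wp - 2
    out = np.zeros((b_n, o_n, h_n, w_n), dtype=xp.dtype)
    for b in range(b_n):
        for o in range(o_n):
            for c in range(c_n):
                for u in range(3):
                    for v in range(3):
                        wgt = w[o, c, u, v]
                        for h in range(h_n):
                            for j in range(w_n):
                                out[b, o, h, j] += wgt * xp[b, c, h + u, j + v]
    return out


@njit(cache=True, fastmath=True)
def _conv3x3_dw(xp, dout):  # -> dW (O,C,3,3)
    b_n, c_n, hp, wp = xp.shape
    o_n = dout.shape[1]
    h_n, w_n = hp - 2, wp - 2
    dw = np.zeros((o_n, c_n, 3, 3), dtype=xp.dtype)
    for b in range(b_n):
        for o in range(o_n):
            for c in range(c_n):
                for u in range(3):
                    for v in range(3):
                        acc = np.float32(0.0)
                        for h in range(h_n):
                            for j in range(w_n):
                                acc += dout[b, o, h, j] * xp[b, c, h + u, j + v]
                        dw[o, c, u, v] += acc
    return dw


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.W = rng.standard_normal((c_out, c_in, 3, 3)).astype(np.float32) \
            * np.sqrt(2.0 / fan_in, dtype=np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        if train:
            self._xp = xp
        y = _conv3x3_fwd(xp, self.W)
        y += self.b[None, :, None, None]
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.ascontiguousarray(dout)
        self.dW = _conv3x3_dw(self._xp, dout)
        self.db = dout.sum(axis=(0, 2, 3))
        # gradient w.r.t. input = same-padded conv with the flipped,
        # in/out-transposed kernel
        dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
        w_t = np.ascontiguousarray(
            self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        return _conv3x3_fwd(dp, w_t)


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        xr = np.ascontiguousarray(
            x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        ).reshape(b, c, h // 2, w // 2, 4)
        if train:
            # first-occurrence argmax: deterministic tie-break
            self._idx = xr.argmax(axis=-1)
            self._shape = x.shape
            out = np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]
        else:
            out = xr.max(axis=-1)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        g = np.zeros((b, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(g, self._idx[..., None], dout[..., None], axis=-1)
        return np.ascontiguousarray(
            g.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        ).reshape(self._shape)


class _Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)).astype(np.float32) \
            * np.sqrt(2.0 / n_in, dtype=np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class VGGStyleCNN:
    """The 7-conv / 3-pool / 4-FC network, Kaiming-initialised per seed."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = 1
        for block in spec.conv_blocks:
            for c_out in block:
                layers.append(_Conv3x3(c_in, c_out, rng))
                layers.append(_ReLU())
                c_in = c_out
            layers.append(_MaxPool2())
        layers.append(_Flatten())
        h, w = spec.spatial_trace[-1]
        n_in = c_in * h * w
        for i, n_out in enumerate(spec.fc_sizes):
            layers.append(_Dense(n_in, n_out, rng))
            if i < len(spec.fc_sizes) - 1:
                layers.append(_ReLU())
            n_in = n_out
        self.layers = layers

    # -- introspection ------------------------------------------------------
    def conv_layers(self) -> list[_Conv3x3]:
        return [l for l in self.layers if isinstance(l, _Conv3x3)]

    def dense_layers(self) -> list[_Dense]:
        return [l for l in self.layers if isinstance(l, _Dense)]

    def parameters(self) -> list[tuple[object, str, np.ndarray]]:
        out = []
        for layer in self.layers:
            for name, p, _ in layer.params():
                out.append((layer, name, p))
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for _, _, p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (_, _, p), s in zip(self.parameters(), state, strict=True):
            p[...] = s

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Input (B, 128, 128) or (B, 1, 128, 128) -> logits (B, 2)."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        x = x.astype(np.float32, copy=False)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None, :, :]
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(_softmax(self.forward(x[i:i + batch_size])))
        return np.concatenate(out, axis=0)

    def activation_trace(self, x: np.ndarray) -> list[tuple[int, ...]]:
        """Shapes after each layer for a single input (structure check)."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        x = x.astype(np.float32)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, False)
            shapes.append(x.shape)
        return shapes


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> VGGStyleCNN:
    return VGGStyleCNN(spec or ArchitectureSpec(), seed=seed)


# ---------------------------------------------------------------------------
# data handling

def oversample_balance(manifest: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Duplicate minority-class rows (sampling with replacement) until the
    two classes are equally frequent.  Majority rows are untouched."""
    counts = manifest["label"].value_counts()
    for cls in CLASSES:
        if counts.get(cls, 0) == 0:
            raise ValueError(f"class {cls!r} absent; cannot oversample")
    if counts[NORMAL] == counts[ABNORMAL]:
        return manifest.copy()
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    rng = np.random.default_rng(seed)
    pool = manifest[manifest["label"] == minority]
    extra = pool.iloc[rng.integers(0, len(pool), size=deficit)]
    return pd.concat([manifest, extra], ignore_index=True)


def stratified_record_split(record_ids: np.ndarray, labels: np.ndarray,
                            val_fraction: float, seed: int,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Split *records* (not segments) into train/validation, stratified by
    label, so no record's segments straddle the split.  Returns boolean
    masks over the input arrays."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"record_id": record_ids, "label": labels})
    rec = df.drop_duplicates("record_id")
    val_records: set[str] = set()
    for cls in rec["label"].unique():
        ids = rec.loc[rec["label"] == cls, "record_id"].to_numpy()
        ids = ids[rng.permutation(ids.size)]
        n_val = max(1, int(round(val_fraction * ids.size))) if ids.size > 1 else 0
        val_records.update(ids[:n_val])
    val_mask = df["record_id"].isin(val_records).to_numpy()
    return ~val_mask, val_mask


# ---------------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for _, _, p in params]
        self.v = [np.zeros_like(p) for _, _, p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for i, (layer, name, p) in enumerate(self.params):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _xent_loss_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = _softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def train(model: VGGStyleCNN, X: np.ndarray, y: np.ndarray,
          record_ids: np.ndarray | None = None,
          cfg: TrainConfig | None = None) -> TrainResult:
    """Train with Adam + cross-entropy.

    The stratified validation split is made at the *record* level before any
    oversampling; oversampling (if enabled) is applied to the training
    portion only.  ``y`` holds class indices (0 normal, 1 abnormal) or label
    strings.  Per-epoch train/validation accuracy and loss are recorded; the
    parameters of the best-validation epoch are kept.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray([CLASSES.index(v) if isinstance(v, str) else int(v) for v in y])
    X = np.asarray(X, dtype=np.float32)
    if record_ids is None:
        record_ids = np.array([f"r{i}" for i in range(len(y))])
    record_ids = np.asarray(record_ids, dtype=object)

    train_mask, val_mask = stratified_record_split(
        record_ids, y, cfg.val_fraction, cfg.seed)
    if not val_mask.any():  # tiny datasets: fall back to a per-segment split
        idx = np.random.default_rng(cfg.seed).permutation(len(y))
        n_val = max(1, int(round(cfg.val_fraction * len(y))))
        val_mask = np.zeros(len(y), bool)
        val_mask[idx[:n_val]] = True
        train_mask = ~val_mask

    tr_idx = np.flatnonzero(train_mask)
    if cfg.oversample:
        df = pd.DataFrame({"idx": tr_idx,
                           "label": [CLASSES[c] for c in y[tr_idx]]})
        df = oversample_balance(df, seed=cfg.seed + 1)
        tr_idx = df["idx"].to_numpy()
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_mask], y[val_mask]

    optim = _Adam(model.parameters(), cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 2)
    n = len(ytr)
    bs = min(cfg.batch_size, n)

    hist = {k: [] for k in ("train_acc", "val_acc", "train_loss", "val_loss")}
    best_epoch, best_val, best_state = 0, -np.inf, model.get_state()
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct, seen = [], 0, 0
        steps = range(0, n, bs)
        if cfg.steps_per_epoch is not None:
            steps = list(steps)[: cfg.steps_per_epoch]
        for start in steps:
            sel = order[start:start + bs]
            logits = model.forward(Xtr[sel], train=True)
            loss, dlogits = _xent_loss_grad(logits, ytr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch + 1}")
            if cfg.learning_rate > 0:
                model.backward(dlogits)
                optim.step()
            losses.append(loss * sel.size)
            correct += int((logits.argmax(axis=1) == ytr[sel]).sum())
            seen += sel.size
        hist["train_loss"].append(sum(losses) / seen)
        hist["train_acc"].append(correct / seen)
        vlogits = model.forward(Xval)
        vloss, _ = _xent_loss_grad(vlogits, yval)
        vacc = float((vlogits.argmax(axis=1) == yval).mean())
        hist["val_loss"].append(vloss)
        hist["val_acc"].append(vacc)
        if vacc > best_val:
            best_val, best_epoch, best_state = vacc, _epoch, model.get_state()

    return TrainResult(
        train_acc=np.array(hist["train_acc"]),
        val_acc=np.array(hist["val_acc"]),
        train_loss=np.array(hist["train_loss"]),
        val_loss=np.array(hist["val_loss"]),
        best_epoch=best_epoch, best_state=best_state)


def predict(model: VGGStyleCNN, X: np.ndarray,
            batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Labels (string) and class probabilities for a batch of feature maps."""
    proba = model.predict_proba(np.asarray(X, dtype=np.float32), batch_size)
    labels = np.array([CLASSES[i] for i in proba.argmax(axis=1)])
    return labels, proba


# ---------------------------------------------------------------------------
# persistence

def save_checkpoint(model: VGGStyleCNN, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{i:03d}": p for i, (_, _, p) in enumerate(model.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"conv_blocks": [list(b) for b in model.spec.conv_blocks],
            "fc_sizes": list(model.spec.fc_sizes),
            "input_shape": list(model.spec.input_shape)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> VGGStyleCNN:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = ArchitectureSpec(
        input_shape=tuple(meta["input_shape"]),
        conv_blocks=tuple(tuple(b) for b in meta["conv_blocks"]),
        fc_sizes=tuple(meta["fc_sizes"]))
    model = VGGStyleCNN(spec, seed=0)
    data = np.load(path.with_suffix(".npz"))
    model.set_state([data[f"p{i:03d}"] for i in range(len(data.files))])
    return model
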