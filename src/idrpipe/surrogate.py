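"""Sequence-to-scalar recurrent regression.

A bidirectional gated recurrent (GRU) regressor trained with an L1
objective on (sequence, scalar) pairs — the fast estimator that replaces
explicit simulation once trained on simulator output. One-hot encoding
over the fixed alphabet ACDEFGHIKLMNPQRSTVWY, final-state pooling of both
directions into a linear scalar head, Adam optimization, and epoch
selection by the lowest validation loss. The train/validation/test split
defaults to 64:16:20 with five-fold cross-validation available over the
train+validation pool.

The network is implemented directly in numpy (forward and
backpropagation-through-time), so training is deterministic for a given
seed on one platform. Labels are standardized internally before the L1
objective and un-standardized at prediction time. Variable-length batches
are padded and masked; masking freezes the recurrent state past each
sequence's true length, so padded-batch predictions equal single-sequence
predictions exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqfeatures import CANONICAL_AA

__all__ = [
    "TrainingConfig", "RegressionModel", "one_hot_encode", "one_hot_decode",
    "split_and_fold", "train_regressor", "cross_validate", "predict_batch",
    "evaluate",
]

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
N_AA = len(CANONICAL_AA)


def one_hot_encode(seq: str) -> np.ndarray:
    """L x 20 one-hot matrix over the fixed canonical alphabet order."""
    seq = str(getattr(seq, "seq", seq)).upper()
    out = np.zeros((len(seq), N_AA))
    for i, ch in enumerate(seq):
        j = _AA_INDEX.get(ch)
        if j is None:
            raise ValueError(f"non-canonical residue {ch!r} at position {i + 1}")
        out[i, j] = 1.0
    return out


def one_hot_decode(mat: np.ndarray) -> str:
    return "".join(CANONICAL_AA[j] for j in np.argmax(mat, axis=1))


# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    cv_folds: int = 5
    cv_epochs: int = 500
    final_epochs: int = 750
    split: tuple[int, int, int] = (64, 16, 20)
    hidden_layers: int = 2
    hidden_dim: int = 32
    batch_size: int = 16
    loss: str = "l1"
    seed: int = 0

    def __post_init__(self):
        if sum(self.split) != 100:
            raise ValueError("split percentages must sum to 100")
        if self.loss != "l1":
            raise ValueError("only the L1 objective is supported")
        if not (1 <= self.hidden_layers <= 2):
            warnings.warn(f"hidden_layers {self.hidden_layers} outside the standard 1-2 range")
        if not (10 <= self.hidden_dim <= 55):
            warnings.warn(f"hidden_dim {self.hidden_dim} outside the standard 10-55 range")
        if not (4 <= self.batch_size <= 32):
            warnings.warn(f"batch_size {self.batch_size} outside the standard 4-32 range")


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    raw = [w * total for w in weights]
    base = [math.floor(r) for r in raw]
    for i in sorted(range(len(raw)), key=lambda i: -(raw[i] - base[i]))[: total - sum(base)]:
        base[i] += 1
    return base


def split_and_fold(records: Sequence, split=(64, 16, 20), k: int = 5, seed: int = 0):
    """Seeded disjoint train/val/test split plus k folds over train+val.

    Returns a dict of index arrays: train, val, test, folds (list of k
    arrays partitioning train+val). Proportions use largest-remainder
    rounding so counts are exact (1,000 records at 64:16:20 -> 640 train).
    """
    n = len(records)
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} records for {k}-fold CV; have {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train, n_val, n_test = _largest_remainder(n, [s / 100 for s in split])
    train = order[:n_train]
    val = order[n_train:n_train + n_val]
    test = order[n_train + n_val:]
    pool = np.concatenate([train, val])
    fold_sizes = _largest_remainder(len(pool), [1 / k] * k)
    folds, at = [], 0
    for fs in fold_sizes:
        folds.append(pool[at:at + fs])
        at += fs
    return {"train": train, "val": val, "test": test, "folds": folds}


# ---------------------------------------------------------------------------
# GRU machinery

def _init_gru_params(rng, input_dim: int, hidden: int) -> dict[str, np.ndarray]:
    def glorot(shape):
        lim = math.sqrt(6.0 / sum(shape))
        return rng.uniform(-lim, lim, size=shape)

    p = {}
    for gate in "zrn":
        p[f"W{gate}"] = glorot((input_dim, hidden))
        p[f"U{gate}"] = glorot((hidden, hidden))
        p[f"b{gate}"] = np.zeros(hidden)
    return p


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gru_forward(p, X, mask, reverse: bool):
    """Run one GRU direction over a padded batch.

    X: (B, L, I); mask: (B, L) with 1 on valid steps. Returns per-step
    hidden states H (B, L, Hd), the final state, and the cache for BPTT.
    The state is frozen on masked steps, so padding never affects it.
    """
    B, L, _ = X.shape
    H = p["Wz"].shape[1]
    h = np.zeros((B, H))
    steps = range(L - 1, -1, -1) if reverse else range(L)
    out = np.zeros((B, L, H))
    cache = []
    for t in steps:
        x = X[:, t, :]
        m = mask[:, t][:, None]
        z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
        r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
        rh = r * h
        n = np.tanh(x @ p["Wn"] + rh @ p["Un"] + p["bn"])
        h_cand = (1.0 - z) * n + z * h
        h_new = m * h_cand + (1.0 - m) * h
        cache.append((t, x, h.copy(), z, r, n, rh, m))
        h = h_new
        out[:, t, :] = h
    return out, h, cache


def _gru_backward(p, cache, dH, dh_final):
    """BPTT for one direction. dH: (B, L, Hd) gradient on per-step outputs;
    dh_final: gradient on the final state. Returns (grads, dX)."""
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    B, L, _ = dH.shape
    dX = np.zeros((B, L, p["Wz"].shape[0]))
    dh = dh_final.copy()
    for (t, x, h_prev, z, r, n, rh, m) in reversed(cache):
        dh = dh + dH[:, t, :]
        dcand = dh * m
        dh_prev = dh * (1.0 - m)
        dz = dcand * (h_prev - n)
        dn = dcand * (1.0 - z)
        dh_prev += dcand * z
        da_n = dn * (1.0 - n * n)
        grads["Wn"] += x.T @ da_n
        grads["Un"] += rh.T @ da_n
        grads["bn"] += da_n.sum(axis=0)
        drh = da_n @ p["Un"].T
        dX[:, t, :] += da_n @ p["Wn"].T
        dr = drh * h_prev
        dh_prev += drh * r
        da_r = dr * r * (1.0 - r)
        grads["Wr"] += x.T @ da_r
        grads["Ur"] += h_prev.T @ da_r
        grads["br"] += da_r.sum(axis=0)
        dX[:, t, :] += da_r @ p["Wr"].T
        dh_prev += da_r @ p["Ur"].T
        da_z = dz * z * (1.0 - z)
        grads["Wz"] += x.T @ da_z
        grads["Uz"] += h_prev.T @ da_z
        grads["bz"] += da_z.sum(axis=0)
        dX[:, t, :] += da_z @ p["Wz"].T
        dh_prev += da_z @ p["Uz"].T
        dh = dh_prev
    return grads, dX


class _BiGRUNet:
    """Stacked bidirectional GRU with final-state pooling and a linear head."""

    def __init__(self, hidden_layers: int, hidden_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden_layers = hidden_layers
        self.hidden_dim = hidden_dim
        self.layers = []
        in_dim = N_AA
        for _ in range(hidden_layers):
            self.layers.append({
                "fwd": _init_gru_params(rng, in_dim, hidden_dim),
                "bwd": _init_gru_params(rng, in_dim, hidden_dim),
            })
            in_dim = 2 * hidden_dim
        lim = math.sqrt(6.0 / (2 * hidden_dim + 1))
        self.W_head = rng.uniform(-lim, lim, size=(2 * hidden_dim, 1))
        self.b_head = np.zeros(1)

    # -- parameter flattening -------------------------------------------
    def named_params(self):
        for li, layer in enumerate(self.layers):
            for d in ("fwd", "bwd"):
                for k, v in layer[d].items():
                    yield f"layer{li}.{d}.{k}", v
        yield "W_head", self.W_head
        yield "b_head", self.b_head

    def set_param(self, name, value):
        if name == "W_head":
            self.W_head = value
        elif name == "b_head":
            self.b_head = value
        else:
            li, d, k = name.split(".")
            self.layers[int(li[5:])][d][k] = value

    def state_dict(self):
        return {k: v.copy() for k, v in self.named_params()}

    def load_state_dict(self, sd):
        for k, v in sd.items():
            self.set_param(k, v.copy())

    # -- forward / backward ---------------------------------------------
    def forward(self, X, mask, want_cache: bool = False):
        B, L, _ = X.shape
        inp = X
        caches = []
        for layer in self.layers:
            Hf, hf, cf = _gru_forward(layer["fwd"], inp, mask, reverse=False)
            Hb, hb, cb = _gru_forward(layer["bwd"], inp, mask, reverse=True)
            caches.append((cf, cb, inp))
            inp = np.concatenate([Hf, Hb], axis=2)
        pooled = np.concatenate([hf, hb], axis=1)    # final-state pooling
        preds = (pooled @ self.W_head + self.b_head).ravel()
        if want_cache:
            return preds, (caches, pooled, mask)
        return preds

    def backward(self, dpreds, cache):
        caches, pooled, mask = cache
        B = pooled.shape[0]
        grads = {}
        dpooled = dpreds[:, None] @ self.W_head.T           # (B, 2H)
        grads["W_head"] = pooled.T @ dpreds[:, None]
        grads["b_head"] = np.array([dpreds.sum()])
        H = self.hidden_dim
        dhf, dhb = dpooled[:, :H], dpooled[:, H:]
        dH_next = None      # gradient wrt this layer's per-step output
        for li in range(len(self.layers) - 1, -1, -1):
            cf, cb, inp = caches[li]
            L = inp.shape[1]
            if dH_next is None:
                dHf = np.zeros((B, L, H))
                dHb = np.zeros((B, L, H))
            else:
                dHf, dHb = dH_next[:, :, :H], dH_next[:, :, H:]
            gf, dXf = _gru_backward(self.layers[li]["fwd"], cf, dHf,
                                    dhf if li == len(self.layers) - 1 else np.zeros((B, H)))
            gb, dXb = _gru_backward(self.layers[li]["bwd"], cb, dHb,
                                    dhb if li == len(self.layers) - 1 else np.zeros((B, H)))
            for k, v in gf.items():
                grads[f"layer{li}.fwd.{k}"] = v
            for k, v in gb.items():
                grads[f"layer{li}.bwd.{k}"] = v
            dH_next = dXf + dXb
        return grads


def _pad_batch(encoded: Sequence[np.ndarray]):
    B = len(encoded)
    L = max(e.shape[0] for e in encoded)
    X = np.zeros((B, L, N_AA))
    mask = np.zeros((B, L))
    for i, e in enumerate(encoded):
        X[i, : e.shape[0]] = e
        mask[i, : e.shape[0]] = 1.0
    return X, mask


# ---------------------------------------------------------------------------

@dataclass
class RegressionModel:
    net: _BiGRUNet
    target: str
    config: TrainingConfig
    label_mean: float
    label_scale: float
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    data_hash: str = ""
    train_length_range: tuple[int, int] = (0, 0)

    def predict(self, seq: str) -> float:
        X, mask = _pad_batch([one_hot_encode(seq)])
        return float(self.net.forward(X, mask)[0] * self.label_scale + self.label_mean)


def _adam_step(params, grads, m, v, t, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    for k in params:
        g = grads[k]
        m[k] = beta1 * m[k] + (1 - beta1) * g
        v[k] = beta2 * v[k] + (1 - beta2) * g * g
        mh = m[k] / (1 - beta1 ** t)
        vh = v[k] / (1 - beta2 ** t)
        params[k][...] = params[k] - lr * mh / (np.sqrt(vh) + eps)


def _l1_loss_and_grad(preds, labels):
    resid = preds - labels
    return float(np.mean(np.abs(resid))), np.sign(resid) / len(resid)


def _epoch_loss(net, encoded, labels, batch_size):
    total, n = 0.0, 0
    for lo in range(0, len(encoded), batch_size):
        X, mask = _pad_batch(encoded[lo:lo + batch_size])
        preds = net.forward(X, mask)
        total += np.abs(preds - labels[lo:lo + batch_size]).sum()
        n += len(preds)
    return total / n


def train_regressor(dataset: Sequence[tuple[str, float]], config: TrainingConfig,
                    target: str = "property", epochs: int | None = None,
                    val_fraction: float = 0.2, val_indices=None):
    """Train the bidirectional recurrent regressor with the L1 objective.

    ``dataset`` is (sequence, label) pairs; at least 50 examples. The
    train/validation partition is seeded; per-epoch train and validation
    losses are recorded and the returned model carries the weights from
    the epoch with the lowest validation loss.
    """
    data = [(str(getattr(s, "seq", s)), float(y)) for s, y in dataset]
    if len(data) < 50:
        raise ValueError(f"need at least 50 labeled examples; have {len(data)}")
    labels_all = np.array([y for _, y in data])
    if not np.all(np.isfinite(labels_all)):
        raise ValueError("labels must be finite")
    epochs = epochs if epochs is not None else config.final_epochs

    rng = np.random.default_rng(config.seed)
    if val_indices is not None:
        val_idx = np.asarray(val_indices, dtype=int)
        train_idx = np.array([i for i in range(len(data)) if i not in set(val_idx.tolist())])
    else:
        order = rng.permutation(len(data))
        n_val = max(1, int(round(val_fraction * len(data))))
        val_idx, train_idx = order[:n_val], order[n_val:]

    mean = float(labels_all[train_idx].mean())
    scale = float(labels_all[train_idx].std()) or 1.0
    encoded = [one_hot_encode(s) for s, _ in data]
    z = (labels_all - mean) / scale

    net = _BiGRUNet(config.hidden_layers, config.hidden_dim, seed=config.seed)
    params = dict(net.named_params())
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}

    tr_enc = [encoded[i] for i in train_idx]
    tr_lab = z[train_idx]
    va_enc = [encoded[i] for i in val_idx]
    va_lab = z[val_idx]
    lengths = [e.shape[0] for e in encoded]

    train_losses, val_losses = [], []
    best_val, best_state, best_epoch = np.inf, None, -1
    step = 0
    for epoch in range(epochs):
        perm = rng.permutation(len(tr_enc))
        ep_loss, n_batches = 0.0, 0
        for lo in range(0, len(perm), config.batch_size):
            sel = perm[lo:lo + config.batch_size]
            X, mask = _pad_batch([tr_enc[i] for i in sel])
            preds, cache = net.forward(X, mask, want_cache=True)
            loss, dpreds = _l1_loss_and_grad(preds, tr_lab[sel])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"NaN/Inf loss at epoch {epoch}, batch {n_batches}: diverged "
                    f"(lr={config.learning_rate}, hidden={config.hidden_dim})")
            grads = net.backward(dpreds, cache)
            step += 1
            _adam_step(params, grads, m, v, step, config.learning_rate)
            ep_loss += loss
            n_batches += 1
        train_losses.append(ep_loss / max(n_batches, 1))
        vl = _epoch_loss(net, va_enc, va_lab, config.batch_size)
        val_losses.append(vl)
        if vl < best_val:
            best_val, best_state, best_epoch = vl, net.state_dict(), epoch
    net.load_state_dict(best_state)

    digest = hashlib.sha256(json.dumps([[s, y] for s, y in data]).encode()).hexdigest()[:16]
    return RegressionModel(net=net, target=target, config=config,
                           label_mean=mean, label_scale=scale,
                           train_losses=train_losses, val_losses=val_losses,
                           best_epoch=best_epoch, data_hash=digest,
                           train_length_range=(min(lengths), max(lengths)))


def cross_validate(dataset, config: TrainingConfig, target: str = "property"):
    """K-fold cross-validation over the train+validation pool of the
    64:16:20 split: each fold serves once as the validation set. Returns
    per-fold best validation losses."""
    data = [(str(getattr(s, "seq", s)), float(y)) for s, y in dataset]
    parts = split_and_fold(data, split=config.split, k=config.cv_folds, seed=config.seed)
    results = []
    for fi, fold in enumerate(parts["folds"]):
        fold_set = set(fold.tolist())
        pool = np.concatenate([parts["train"], parts["val"]])
        train_idx = [i for i in pool if i not in fold_set]
        sub = [data[i] for i in train_idx] + [data[i] for i in fold]
        cfg = TrainingConfig(**{**asdict(config), "seed": config.seed + fi})
        model = train_regressor(sub, cfg, target=target, epochs=config.cv_epochs,
                                val_indices=range(len(train_idx), len(sub)))
        results.append({"fold": fi, "best_val_loss": min(model.val_losses),
                        "best_epoch": model.best_epoch})
    return results


def predict_batch(model: RegressionModel, seqs: Sequence[str],
                  batch_size: int = 32) -> np.ndarray:
    """Batched prediction, order preserved. Non-canonical sequences get
    NaN with a warning and the batch continues; lengths outside the
    training range trigger an extrapolation warning."""
    seqs = [str(getattr(s, "seq", s)) for s in seqs]
    out = np.full(len(seqs), np.nan)
    enc, keep = [], []
    lo_len, hi_len = model.train_length_range
    for i, s in enumerate(seqs):
        try:
            e = one_hot_encode(s)
        except ValueError as exc:
            warnings.warn(f"sequence {i}: {exc}; returning NaN")
            continue
        if hi_len and not (lo_len <= e.shape[0] <= hi_len):
            warnings.warn(f"sequence {i} length {e.shape[0]} outside training range "
                          f"[{lo_len}, {hi_len}]: extrapolating")
        enc.append(e)
        keep.append(i)
    for lo in range(0, len(enc), batch_size):
        X, mask = _pad_batch(enc[lo:lo + batch_size])
        preds = model.net.forward(X, mask)
        for j, p in enumerate(preds):
            out[keep[lo + j]] = p * model.label_scale + model.label_mean
    return out


def evaluate(model: RegressionModel, test_set: Sequence[tuple[str, float]]):
    """(R^2, RMSE, residuals) on a labeled test set; R^2 is NaN for a
    single-point test set."""
    if not len(test_set):
        raise ValueError("empty test set")
    seqs = [s for s, _ in test_set]
    labels = np.array([y for _, y in test_set], dtype=float)
    preds = predict_batch(model, seqs)
    resid = preds - labels
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    if len(labels) < 2 or np.allclose(labels, labels[0]):
        return float("nan"), rmse, resid
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((labels - labels.mean()) ** 2))
    return 1.0 - ss_res / ss_tot, rmse, resid
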