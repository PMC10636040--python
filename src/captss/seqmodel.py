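"""Convolutional network over the 200 bp around a cluster summit.

Architecture: conv(4ch -> 128 filters, width 8) + ReLU, conv(128 -> 64,
width 4) + ReLU, batch norm, max pool (kernel 2, stride 2, no padding),
dropout(0.4), flatten, dense(32) + ReLU, dense(2) + sigmoid. Trained with
plain SGD (momentum) on a per-output binary cross-entropy against one-hot
targets, on a 6:2:2 train/test/validation split; the checkpoint with the
lowest validation loss is kept. The 32-unit dense activations serve as the
sequence embedding for the combined classifier; the jointly trained variant
instead concatenates the four cluster features to those 32 units before the
final dense layer.

Implemented directly on NumPy (float32, im2col convolutions, manual
backprop). The max-pool geometry and the placement of the single batch-norm
(after the second convolution) are recorded in saved checkpoints so that
model files are self-describing.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

log = logging.getLogger(__name__)

BASE_CHANNELS = "ATCG"  # one-hot channel order: A, T, C, G


def one_hot_encode(seq: str, length: int = 200) -> np.ndarray:
    """Encode a DNA sequence as a (4, length) matrix, channels (A, T, C, G);
    N (or any other symbol) gives an all-zero column."""
    if len(seq) != length:
        raise ValueError(f"expected a {length} nt sequence, got {len(seq)} nt")
    out = np.zeros((4, length), dtype=np.float32)
    for i, base in enumerate(seq.upper()):
        ch = BASE_CHANNELS.find(base)
        if ch >= 0:
            out[ch, i] = 1.0
    return out


@dataclass
class SequenceModelConfig:
    seq_len: int = 200
    conv1_filters: int = 128
    conv1_width: int = 8
    conv2_filters: int = 64
    conv2_width: int = 4
    pool_kernel: int = 2
    pool_stride: int = 2
    dropout_p: float = 0.4
    fc1_units: int = 32
    fc2_units: int = 2
    batch_size: int = 256
    epochs: int = 500
    lr: float = 0.003
    momentum: float = 0.8
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)  # train/test/validation
    n_extra_features: int = 0  # >0 selects the jointly trained variant
    seed: int = 0


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    # x (N, C, L), W (F, C, K) -> (N, F, L-K+1)
    K = W.shape[2]
    cols = sliding_window_view(x, K, axis=2)            # (N, C, Lout, K)
    N, C, Lout, _ = cols.shape
    flat = cols.transpose(0, 2, 1, 3).reshape(N * Lout, C * K)
    out = flat @ W.reshape(W.shape[0], C * K).T + b
    return out.reshape(N, Lout, -1).transpose(0, 2, 1), flat


def _conv_backward(dout: np.ndarray, flat_cols: np.ndarray, x_shape, W: np.ndarray):
    # dout (N, F, Lout)
    N, C, L = x_shape
    F, _, K = W.shape
    Lout = dout.shape[2]
    dflat = dout.transpose(0, 2, 1).reshape(N * Lout, F)
    dW = (dflat.T @ flat_cols).reshape(F, C, K)
    db = dflat.sum(axis=0)
    # dx via full correlation with the flipped kernel
    pad = np.zeros((N, F, Lout + 2 * (K - 1)), dtype=dout.dtype)
    pad[:, :, K - 1:K - 1 + Lout] = dout
    cols = sliding_window_view(pad, K, axis=2)           # (N, F, L, K)
    Wf = W[:, :, ::-1]
    dx = np.einsum("nflk,fck->ncl", cols, Wf, optimize=True)
    return dW, db, dx.astype(dout.dtype)


class SeqCNN:
    """The network, its SGD training loop and the embedding extractor."""

    def __init__(self, cfg: SequenceModelConfig | None = None):
        self.cfg = cfg or SequenceModelConfig()
        c = self.cfg
        rng = np.random.default_rng(c.seed)
        self._rng = rng
        l1 = c.seq_len - c.conv1_width + 1
        l2 = l1 - c.conv2_width + 1
        self._lpool = (l2 - c.pool_kernel) // c.pool_stride + 1
        self._flat = c.conv2_filters * self._lpool
        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.params = {
            "W1": he((c.conv1_filters, 4, c.conv1_width), 4 * c.conv1_width),
            "b1": np.zeros(c.conv1_filters, np.float32),
            "W2": he((c.conv2_filters, c.conv1_filters, c.conv2_width),
                     c.conv1_filters * c.conv2_width),
            "b2": np.zeros(c.conv2_filters, np.float32),
            "gamma": np.ones(c.conv2_filters, np.float32),
            "beta": np.zeros(c.conv2_filters, np.float32),
            "W3": he((self._flat, c.fc1_units), self._flat),
            "b3": np.zeros(c.fc1_units, np.float32),
            "W4": he((c.fc1_units + c.n_extra_features, c.fc2_units),
                     c.fc1_units + c.n_extra_features),
            "b4": np.zeros(c.fc2_units, np.float32),
        }
        self.running_mean = np.zeros(c.conv2_filters, np.float32)
        self.running_var = np.ones(c.conv2_filters, np.float32)
        self._vel = {k: np.zeros_like(v) for k, v in self.params.items()}

    # ----- forward -----
    def _forward(self, X: np.ndarray, extra: np.ndarray | None, train: bool):
        c, p = self.cfg, self.params
        cache: dict = {"X": X}
        z1, cols1 = _conv_forward(X, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0)
        z2, cols2 = _conv_forward(a1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0)
        if train:
            mu = a2.mean(axis=(0, 2))
            var = a2.var(axis=(0, 2))
            self.running_mean = 0.9 * self.running_mean + 0.1 * mu
            self.running_var = 0.9 * self.running_var + 0.1 * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + 1e-5)
        xhat = (a2 - mu[None, :, None]) * inv[None, :, None]
        bn = p["gamma"][None, :, None] * xhat + p["beta"][None, :, None]
        # max pool
        N, F, L2 = bn.shape
        lp = self._lpool
        windows = bn[:, :, :lp * c.pool_stride].reshape(N, F, lp, c.pool_kernel)
        arg = windows.argmax(axis=3)
        pooled = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]
        if train and c.dropout_p > 0:
            mask = (self._rng.random(pooled.shape) >= c.dropout_p).astype(np.float32)
            dropped = pooled * mask / (1.0 - c.dropout_p)
        else:
            mask = None
            dropped = pooled
        flat = dropped.reshape(N, -1)
        h_pre = flat @ p["W3"] + p["b3"]
        h = np.maximum(h_pre, 0)
        h_in = h if extra is None else np.concatenate([h, extra.astype(np.float32)], axis=1)
        logits = h_in @ p["W4"] + p["b4"]
        out = 1.0 / (1.0 + np.exp(-logits))
        cache.update(z1=z1, a1=a1, cols1=cols1, z2=z2, a2=a2, cols2=cols2,
                     xhat=xhat, inv=inv, arg=arg, mask=mask, pooled_shape=pooled.shape,
                     flat=flat, h_pre=h_pre, h=h, h_in=h_in, out=out, mu=mu)
        return out, cache

    # ----- backward -----
    def _backward(self, cache: dict, y: np.ndarray):
        c, p = self.cfg, self.params
        out = cache["out"]
        N = out.shape[0]
        target = np.zeros_like(out)
        target[np.arange(N), y] = 1.0
        grads: dict[str, np.ndarray] = {}
        dlogits = (out - target) / (N * out.shape[1])  # BCE + sigmoid
        grads["W4"] = cache["h_in"].T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dh_in = dlogits @ p["W4"].T
        dh = dh_in[:, :c.fc1_units]
        dh_pre = dh * (cache["h_pre"] > 0)
        grads["W3"] = cache["flat"].T @ dh_pre
        grads["b3"] = dh_pre.sum(axis=0)
        dflat = dh_pre @ p["W3"].T
        ddrop = dflat.reshape(cache["pooled_shape"])
        if cache["mask"] is not None:
            ddrop = ddrop * cache["mask"] / (1.0 - c.dropout_p)
        # un-pool
        Nb, F, lp = cache["pooled_shape"]
        dwin = np.zeros((Nb, F, lp, c.pool_kernel), dtype=np.float32)
        np.put_along_axis(dwin, cache["arg"][..., None], ddrop[..., None], axis=3)
        dbn = np.zeros_like(cache["a2"])
        dbn[:, :, :lp * c.pool_stride] = dwin.reshape(Nb, F, lp * c.pool_kernel)
        # batch norm backward (per channel over N and L)
        xhat, inv = cache["xhat"], cache["inv"]
        grads["gamma"] = (dbn * xhat).sum(axis=(0, 2))
        grads["beta"] = dbn.sum(axis=(0, 2))
        m = dbn.shape[0] * dbn.shape[2]
        dxhat = dbn * p["gamma"][None, :, None]
        da2 = (inv[None, :, None] / m) * (
            m * dxhat - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True))
        dz2 = (da2 * (cache["z2"] > 0)).astype(np.float32)
        grads["W2"], grads["b2"], da1 = _conv_backward(
            dz2, cache["cols2"], cache["a1"].shape, p["W2"])
        dz1 = (da1 * (cache["z1"] > 0)).astype(np.float32)
        grads["W1"], grads["b1"], _ = _conv_backward(
            dz1, cache["cols1"], cache["X"].shape, p["W1"])
        return grads

    def _loss(self, out: np.ndarray, y: np.ndarray) -> float:
        target = np.zeros_like(out)
        target[np.arange(len(y)), y] = 1.0
        eps = 1e-7
        return float(-(target * np.log(out + eps)
                       + (1 - target) * np.log(1 - out + eps)).mean())

    # ----- public API -----
    def fit(self, X: np.ndarray, y: np.ndarray,
            extra: np.ndarray | None = None, verbose: bool = False):
        """Train on a 6:2:2 split of (X, y); keeps the parameters of the
        epoch with the lowest validation loss. Returns per-epoch history."""
        c = self.cfg
        if extra is None and c.n_extra_features:
            raise ValueError("config expects extra features")
        n = len(X)
        ratio = np.bincount(y)
        if ratio.size == 2 and ratio.max() > 10 * max(ratio.min(), 1):
            log.warning("class imbalance beyond 10:1 (%s)", ratio.tolist())
        rng = np.random.default_rng(c.seed)
        order = rng.permutation(n)
        n_train = int(round(c.split[0] * n))
        n_test = int(round(c.split[1] * n))
        idx_train = order[:n_train]
        idx_test = order[n_train:n_train + n_test]
        idx_val = order[n_train + n_test:]
        X = np.asarray(X, np.float32)
        ex = None if extra is None else np.asarray(extra, np.float32)
        best_val, best_params, best_stats = np.inf, None, None
        history = []
        for epoch in range(c.epochs):
            perm = rng.permutation(len(idx_train))
            for start in range(0, len(perm), c.batch_size):
                bi = idx_train[perm[start:start + c.batch_size]]
                out, cache = self._forward(X[bi], None if ex is None else ex[bi], True)
                grads = self._backward(cache, y[bi])
                for k, g in grads.items():
                    self._vel[k] = c.momentum * self._vel[k] - c.lr * g.astype(np.float32)
                    self.params[k] += self._vel[k]
            val_out, _ = self._forward(X[idx_val], None if ex is None else ex[idx_val], False)
            val_loss = self._loss(val_out, y[idx_val])
            history.append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                best_stats = (self.running_mean.copy(), self.running_var.copy())
            if verbose and epoch % 10 == 0:
                log.info("epoch %d val loss %.4f", epoch, val_loss)
        if best_params is not None:
            self.params = best_params
            self.running_mean, self.running_var = best_stats
        self._split = {"train": idx_train, "test": idx_test, "val": idx_val}
        return np.array(history)

    def predict_proba(self, X: np.ndarray, extra: np.ndarray | None = None,
                      batch: int = 512) -> np.ndarray:
        """Per-class sigmoid outputs, shape (n, 2); column 1 is the genuine
        TSS probability."""
        X = np.asarray(X, np.float32)
        outs = []
        for s in range(0, len(X), batch):
            e = None if extra is None else np.asarray(extra[s:s + batch], np.float32)
            out, _ = self._forward(X[s:s + batch], e, False)
            outs.append(out)
        return np.concatenate(outs) if outs else np.empty((0, 2))

    def embed(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        """Activations of the 32-unit dense layer (the sequence embedding)."""
        X = np.asarray(X, np.float32)
        outs = []
        for s in range(0, len(X), batch):
            _, cache = self._forward(X[s:s + batch], None
                                     if not self.cfg.n_extra_features
                                     else np.zeros((min(batch, len(X) - s),
                                                    self.cfg.n_extra_features),
                                                   np.float32), False)
            outs.append(cache["h"])
        return np.concatenate(outs) if outs else np.empty((0, self.cfg.fc1_units))

    def save(self, path: str | os.PathLike) -> None:
        meta = {"format": "captss-seqcnn", "config": vars(self.cfg) | {
            "split": list(self.cfg.split)}, "pool": {"kernel": self.cfg.pool_kernel,
            "stride": self.cfg.pool_stride, "padding": 0},
            "batchnorm_placement": "after conv2"}
        np.savez(str(path), meta=json.dumps(meta),
                 running_mean=self.running_mean, running_var=self.running_var,
                 **self.params)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SeqCNN":
        data = np.load(str(path), allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfgd = meta["config"]
        cfgd["split"] = tuple(cfgd["split"])
        model = cls(SequenceModelConfig(**cfgd))
        for k in model.params:
            model.params[k] = data[k]
        model.running_mean = data["running_mean"]
        model.running_var = data["running_var"]
        return model


def train_sequence_model(sequences: list[str], labels: np.ndarray,
                         cfg: SequenceModelConfig | None = None,
                         extra: np.ndarray | None = None):
    """Encode, train, and return (model, held-out-test AUROC)."""
    from sklearn.metrics import roc_auc_score

    cfg = cfg or SequenceModelConfig()
    X = np.stack([one_hot_encode(s, cfg.seq_len) for s in sequences])
    y = np.asarray(labels, int)
    model = SeqCNN(cfg)
    model.fit(X, y, extra=extra)
    idx = model._split["test"]
    prob = model.predict_proba(X[idx], None if extra is None else extra[idx])[:, 1]
    auroc = roc_auc_score(y[idx], prob) if len(np.unique(y[idx])) == 2 else float("nan")
    return model, float(auroc)
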