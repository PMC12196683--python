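"""The hybrid 1D CNN-LSTM gesture classifier, implemented in NumPy.

Default topology (``paper_literal``)::

    input (750 x 4)
      -> causal conv1d(24 filters, kernel 6) -> ReLU -> layer norm
      -> causal conv1d(48 filters, kernel 6) -> ReLU -> layer norm
      -> global average pooling over time          (collapses time to 1)
      -> LSTM(64) -> dropout 0.3
      -> LSTM(32) -> dropout 0.2
      -> dense(n_classes) -> softmax

Note the pooling stage sits *before* the recurrent stack, which collapses
the time axis to a single step and reduces the LSTMs to gated dense
layers; this layer order is kept deliberately as the reference topology.
Two ablation variants are provided: ``lstm_last`` (no pooling; the last
LSTM output feeds the classifier) and ``gap_after_lstm`` (pooling applied
to the LSTM output sequence instead).

Training follows a fixed recipe: Adam, initial learning rate 0.002 decayed
by 10x every 100 epochs, global-norm gradient clipping at 1, mini-batches
of 32, shuffling every epoch, up to 300 epochs with monitoring-only
validation checks every 150 optimizer iterations on a 10% class-stratified
held-out fraction. Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_VARIANTS = ("paper_literal", "lstm_last", "gap_after_lstm")


@dataclass(frozen=True)
class ArchitectureConfig:
    input_channels: int = 4
    conv_filters: tuple[int, int] = (24, 48)
    kernel_size: int = 6
    lstm_units: tuple[int, int] = (64, 32)
    dropout_rates: tuple[float, float] = (0.3, 0.2)
    n_classes: int = 7
    topology_variant: str = "paper_literal"

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if any(not 0 <= d < 1 for d in self.dropout_rates):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.topology_variant not in _VARIANTS:
            raise ValueError(f"unknown topology_variant {self.topology_variant!r}; "
                             f"expected one of {_VARIANTS}")


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.002
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 100          # epochs
    gradient_clip_threshold: float = 1.0
    batch_size: int = 32
    max_epochs: int = 300
    validation_period: int = 150       # optimizer iterations between val checks
    validation_fraction: float = 0.1   # class-stratified, monitoring only
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("initial_lr", "lr_drop_period", "gradient_clip_threshold",
                     "batch_size", "max_epochs", "validation_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5]")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Piecewise-constant schedule: drop by ``lr_drop_factor`` every period.

    ``epoch`` is 1-based; epochs 1..100 use the initial rate, 101..200 one
    factor down, and so on.
    """
    if not 1 <= epoch <= config.max_epochs:
        raise ValueError(f"epoch must be in [1, {config.max_epochs}], got {epoch}")
    return config.initial_lr * config.lr_drop_factor ** ((epoch - 1) // config.lr_drop_period)


@dataclass
class TrainingLog:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_lr: list[float] = field(default_factory=list)
    val_checks: list[dict] = field(default_factory=list)   # iteration/epoch/loss/acc

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"epoch": np.arange(1, len(self.epoch_loss) + 1),
                             "loss": self.epoch_loss, "lr": self.epoch_lr})


# ---------------------------------------------------------------- layer math

def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _orthogonal(rng, n):
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(np.float32)


def _causal_conv_forward(x, W, b, K):
    """x (B,T,Cin) -> y (B,T,F); causal left padding of K-1 zeros."""
    B, T, Cin = x.shape
    xp = np.pad(x, ((0, 0), (K - 1, 0), (0, 0)))
    win = sliding_window_view(xp, K, axis=1)           # (B,T,Cin,K)
    col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * T, K * Cin)
    y = col @ W + b
    return y.reshape(B, T, -1), col


def _causal_conv_backward(dy, col, W, K, Cin):
    B, T, F = dy.shape
    dyf = dy.reshape(B * T, F)
    dW = col.T @ dyf
    db = dyf.sum(axis=0)
    # dx: correlate dy (right-padded) with the kernel flipped in time
    Wback = np.ascontiguousarray(
        W.reshape(K, Cin, F)[::-1].transpose(0, 2, 1)).reshape(K * F, Cin)
    dyp = np.pad(dy, ((0, 0), (0, K - 1), (0, 0)))
    win = sliding_window_view(dyp, K, axis=1)          # (B,T,F,K)
    col2 = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * T, K * F)
    dx = (col2 @ Wback).reshape(B, T, Cin)
    return dx, dW, db


_LN_EPS = 1e-5


def _layernorm_forward(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * gamma + beta, (xhat, inv)


def _layernorm_backward(dy, cache, gamma):
    xhat, inv = cache
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gamma
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dgamma, dbeta


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_forward(x, W, R, b, U):
    """x (B,T,in) -> h sequence (B,T,U). Gate order: input, forget, cell, output."""
    B, T, _ = x.shape
    h = np.zeros((B, U), dtype=x.dtype)
    c = np.zeros((B, U), dtype=x.dtype)
    hs = np.empty((B, T, U), dtype=x.dtype)
    cache = []
    for t in range(T):
        z = x[:, t] @ W + h @ R + b
        i = _sigmoid(z[:, :U])
        f = _sigmoid(z[:, U:2 * U])
        g = np.tanh(z[:, 2 * U:3 * U])
        o = _sigmoid(z[:, 3 * U:])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        hs[:, t] = h
        cache.append((i, f, g, o, c_prev, tc, h_prev))
    return hs, cache


def _lstm_backward(dh_seq, x, hs, cache, W, R, U):
    """dh_seq (B,T,U) gradients w.r.t. every hidden output."""
    B, T, _ = x.shape
    dW = np.zeros_like(W)
    dR = np.zeros_like(R)
    db = np.zeros(4 * U, dtype=x.dtype)
    dx = np.empty_like(x)
    dh_next = np.zeros((B, U), dtype=x.dtype)
    dc_next = np.zeros((B, U), dtype=x.dtype)
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = cache[t]
        dh = dh_seq[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1 - tc ** 2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                             dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
        dW += x[:, t].T @ dz
        dR += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ W.T
        dh_next = dz @ R.T
    return dx, dW, dR, db


# ------------------------------------------------------------------- model

class CNNLSTM:
    """The 1D CNN-LSTM classifier with explicit forward/backward passes.

    Parameters are float32 NumPy arrays; initialization, epoch shuffling,
    dropout masks and the validation split all draw from a single generator
    seeded by ``TrainConfig.seed``, so training is bit-reproducible.
    """

    def __init__(self, arch: ArchitectureConfig, rng: np.random.Generator | None = None):
        self.arch = arch
        self.train_config: TrainConfig | None = None
        rng = rng or np.random.default_rng(0)
        K = arch.kernel_size
        Cin = arch.input_channels
        F1, F2 = arch.conv_filters
        U1, U2 = arch.lstm_units
        p = {}
        p["conv1_W"] = _glorot(rng, (K * Cin, F1)); p["conv1_b"] = np.zeros(F1, np.float32)
        p["ln1_g"] = np.ones(F1, np.float32); p["ln1_b"] = np.zeros(F1, np.float32)
        p["conv2_W"] = _glorot(rng, (K * F1, F2)); p["conv2_b"] = np.zeros(F2, np.float32)
        p["ln2_g"] = np.ones(F2, np.float32); p["ln2_b"] = np.zeros(F2, np.float32)
        for name, nin, units in (("lstm1", F2, U1), ("lstm2", U1, U2)):
            p[f"{name}_W"] = _glorot(rng, (nin, 4 * units))
            p[f"{name}_R"] = np.concatenate(
                [_orthogonal(rng, units) for _ in range(4)], axis=1)
            b = np.zeros(4 * units, np.float32)
            b[units:2 * units] = 1.0        # forget-gate bias
            p[f"{name}_b"] = b
        p["fc_W"] = _glorot(rng, (U2, arch.n_classes))
        p["fc_b"] = np.zeros(arch.n_classes, np.float32)
        self.params = p

    # -- forward / backward ------------------------------------------------

    def _forward(self, X, train=False, rng=None):
        """Return (logits, cache). X is (B, T, input_channels) float32."""
        a = self.arch
        p = self.params
        K = a.kernel_size
        c1, col1 = _causal_conv_forward(X, p["conv1_W"], p["conv1_b"], K)
        r1 = np.maximum(c1, 0)
        n1, ln1c = _layernorm_forward(r1, p["ln1_g"], p["ln1_b"])
        c2, col2 = _causal_conv_forward(n1, p["conv2_W"], p["conv2_b"], K)
        r2 = np.maximum(c2, 0)
        n2, ln2c = _layernorm_forward(r2, p["ln2_g"], p["ln2_b"])

        if a.topology_variant == "paper_literal":
            seq = n2.mean(axis=1, keepdims=True)        # (B, 1, F2)
        else:
            seq = n2
        U1, U2 = a.lstm_units
        h1, l1c = _lstm_forward(seq, p["lstm1_W"], p["lstm1_R"], p["lstm1_b"], U1)
        h1d, m1 = self._dropout(h1, a.dropout_rates[0], train, rng)
        h2, l2c = _lstm_forward(h1d, p["lstm2_W"], p["lstm2_R"], p["lstm2_b"], U2)
        if a.topology_variant == "gap_after_lstm":
            feat = h2.mean(axis=1)
        else:                                           # paper_literal / lstm_last
            feat = h2[:, -1]
        featd, m2 = self._dropout(feat, a.dropout_rates[1], train, rng)
        logits = featd @ p["fc_W"] + p["fc_b"]
        cache = (X, c1, r1, ln1c, n1, col1, c2, col2, r2, ln2c, n2, seq,
                 h1, l1c, h1d, m1, h2, l2c, feat, featd, m2)
        return logits, cache

    @staticmethod
    def _dropout(x, rate, train, rng):
        if not train or rate == 0:
            return x, None
        mask = (rng.random(x.shape) >= rate).astype(np.float32) / (1 - rate)
        return x * mask, mask

    def _backward(self, dlogits, cache):
        a = self.arch
        p = self.params
        K = a.kernel_size
        (X, c1, r1, ln1c, n1, col1, c2, col2, r2, ln2c, n2, seq,
         h1, l1c, h1d, m1, h2, l2c, feat, featd, m2) = cache
        g = {}
        g["fc_W"] = featd.T @ dlogits
        g["fc_b"] = dlogits.sum(axis=0)
        dfeat = dlogits @ p["fc_W"].T
        if m2 is not None:
            dfeat = dfeat * m2
        B, T, _ = seq.shape
        dh2 = np.zeros_like(h2)
        if a.topology_variant == "gap_after_lstm":
            dh2 += dfeat[:, None, :] / T
        else:
            dh2[:, -1] = dfeat
        dh1d, g["lstm2_W"], g["lstm2_R"], g["lstm2_b"] = _lstm_backward(
            dh2, h1d, h2, l2c, p["lstm2_W"], p["lstm2_R"], a.lstm_units[1])
        if m1 is not None:
            dh1d = dh1d * m1
        dseq, g["lstm1_W"], g["lstm1_R"], g["lstm1_b"] = _lstm_backward(
            dh1d, seq, h1, l1c, p["lstm1_W"], p["lstm1_R"], a.lstm_units[0])
        if a.topology_variant == "paper_literal":
            dn2 = np.broadcast_to(dseq[:, 0:1, :] / n2.shape[1], n2.shape).astype(dseq.dtype)
        else:
            dn2 = dseq
        dr2, g["ln2_g"], g["ln2_b"] = _layernorm_backward(dn2, ln2c, p["ln2_g"])
        dc2 = dr2 * (c2 > 0)
        dn1, g["conv2_W"], g["conv2_b"] = _causal_conv_backward(
            dc2, col2, p["conv2_W"], K, a.conv_filters[0])
        dr1, g["ln1_g"], g["ln1_b"] = _layernorm_backward(dn1, ln1c, p["ln1_g"])
        dc1 = dr1 * (c1 > 0)
        _, g["conv1_W"], g["conv1_b"] = _causal_conv_backward(
            dc1, col1, p["conv1_W"], K, a.input_channels)
        return g

    # -- public API --------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        """Class probabilities, one row per segment; rows sum to 1."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[2] != self.arch.input_channels:
            raise ValueError(f"expected (n, samples, {self.arch.input_channels}) input, "
                             f"got {X.shape}")
        out = []
        for i in range(0, X.shape[0], batch_size):
            logits, _ = self._forward(X[i:i + batch_size], train=False)
            out.append(_softmax(logits))
        return np.concatenate(out, axis=0) if out else np.empty((0, self.arch.n_classes))

    def fit(self, X, y, config: TrainConfig) -> TrainingLog:
        """Train in place; returns the TrainingLog."""
        _, log = train(self, X, y, config)
        return log

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {"arch": asdict(self.arch)}
        if self.train_config is not None:
            meta["train"] = asdict(self.train_config)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CNNLSTM":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arch_d = meta["arch"]
        for key in ("conv_filters", "lstm_units", "dropout_rates"):
            arch_d[key] = tuple(arch_d[key])
        model = cls(ArchitectureConfig(**arch_d))
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        if "train" in meta:
            model.train_config = TrainConfig(**meta["train"])
        return model


def build_model(arch: ArchitectureConfig, seed: int = 0) -> CNNLSTM:
    """Construct an untrained network with seeded initialization."""
    return CNNLSTM(arch, np.random.default_rng(seed))


def parameter_count(arch: ArchitectureConfig) -> int:
    """Trainable parameter count implied by the architecture config."""
    return build_model(arch).n_parameters()


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_label(scores: np.ndarray) -> np.ndarray:
    """Argmax per row; ties resolve to the lowest class index."""
    scores = np.asarray(scores)
    if scores.ndim != 2 or scores.shape[0] == 0:
        raise ValueError("scores must be a non-empty 2-D matrix")
    return np.argmax(scores, axis=1)


def _stratified_split(y, fraction, rng):
    """Indices (train, val); ``fraction`` of each class goes to val."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = int(round(fraction * len(idx)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx).astype(np.int64), np.sort(val_idx).astype(np.int64)


def train(model: CNNLSTM, X, y, config: TrainConfig):
    """Gradient-clipped Adam training for the full epoch budget.

    No early stopping: validation checks every ``validation_period``
    iterations are monitoring only. Returns ``(model, TrainingLog)``.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if y.max(initial=0) >= model.arch.n_classes or y.min(initial=0) < 0:
        raise ValueError(f"labels must be in [0, {model.arch.n_classes}); "
                         f"found range [{y.min()}, {y.max()}]")
    rng = np.random.default_rng(config.seed)
    # re-initialize weights from the training seed for full reproducibility
    model.params = CNNLSTM(model.arch, rng).params
    model.train_config = config

    if config.validation_fraction > 0 and len(X) >= 2 * len(np.unique(y)):
        tr_idx, val_idx = _stratified_split(y, config.validation_fraction, rng)
    else:
        tr_idx, val_idx = np.arange(len(X)), np.empty(0, dtype=np.int64)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    log = TrainingLog()
    step = 0
    n = len(Xtr)
    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits, cache = model._forward(xb, train=True, rng=rng)
            probs = _softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            losses.append(float(loss))
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = model._backward(dlogits.astype(np.float32), cache)
            # global-norm gradient clipping
            gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
            if gnorm > config.gradient_clip_threshold:
                scale = config.gradient_clip_threshold / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            step += 1
            bc1 = 1 - beta1 ** step
            bc2 = 1 - beta2 ** step
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                model.params[k] -= (lr * (m[k] / bc1)
                                    / (np.sqrt(v[k] / bc2) + eps)).astype(np.float32)
            if len(Xval) and step % config.validation_period == 0:
                vprobs = model.predict_proba(Xval)
                vloss = -np.mean(np.log(vprobs[np.arange(len(yval)), yval] + 1e-12))
                vacc = float(np.mean(predict_label(vprobs) == yval))
                log.val_checks.append({"iteration": step, "epoch": epoch,
                                       "val_loss": float(vloss), "val_acc": vacc})
        log.epoch_loss.append(float(np.mean(losses)))
        log.epoch_lr.append(lr)
    return model, log
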