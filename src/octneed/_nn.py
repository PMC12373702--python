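"""Minimal deterministic 3-D convolutional network in numpy.

A small twin-encoder network for pairs of volumetric OCT inputs: a
shared 3-D convolutional encoder is applied to the Week-8 and Week-16
volumes, the two embeddings are concatenated and passed through a small
dense head producing one logit.  Forward and backward passes are plain
numpy (im2col matmuls), optimized with Adam, trained with weighted
binary cross-entropy and early stopping on validation loss.  Everything
is seeded and single-threaded-reproducible: identical inputs, config
and seed give bit-identical weights.

Shapes are kept deliberately small (inputs are average-pooled at the
stem) so that training runs in seconds on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = ["NetConfig", "init_weights", "forward_logits", "train", "predict_proba", "weights_hash"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimization settings of the volumetric network."""

    input_shape: Tuple[int, int, int] = (28, 52, 72)
    stem_pool: Tuple[int, int, int] = (2, 4, 4)
    channels: Tuple[int, int] = (8, 16)
    kernel: int = 3
    pool: Tuple[int, int, int] = (2, 2, 2)
    head_width: int = 16
    learning_rate: float = 3e-3
    finetune_lr_scale: float = 0.3
    head_warmup_epochs: int = 12
    epochs: int = 60
    batch_size: int = 32
    patience: int = 10
    weight_decay: float = 1e-4
    class_weighted: bool = True
    seed: int = 0

    @property
    def encoder_keys(self):
        return ("conv1_w", "conv1_b", "conv2_w", "conv2_b")

    @property
    def head_keys(self):
        return ("fc1_w", "fc1_b", "fc2_w", "fc2_b")


def _stem_shape(cfg: NetConfig):
    return tuple(s // p for s, p in zip(cfg.input_shape, cfg.stem_pool))


def _pooled_shape(cfg: NetConfig):
    return tuple(s // p for s, p in zip(_stem_shape(cfg), cfg.pool))


def init_weights(cfg: NetConfig, rng: np.random.Generator,
                 encoder: Optional[Dict[str, np.ndarray]] = None) -> Dict[str, np.ndarray]:
    """He-style initialization; optionally reuse a pretrained encoder."""
    c1, c2 = cfg.channels
    k3 = cfg.kernel ** 3
    w = {}
    if encoder is not None:
        for key in cfg.encoder_keys:
            w[key] = encoder[key].astype(np.float32).copy()
    else:
        w["conv1_w"] = (rng.standard_normal((k3 * 1, c1)) * np.sqrt(2.0 / k3)).astype(np.float32)
        w["conv1_b"] = np.zeros(c1, dtype=np.float32)
        w["conv2_w"] = (rng.standard_normal((k3 * c1, c2)) * np.sqrt(2.0 / (k3 * c1))).astype(np.float32)
        w["conv2_b"] = np.zeros(c2, dtype=np.float32)
    d_in = 2 * c2
    w["fc1_w"] = (rng.standard_normal((d_in, cfg.head_width)) * np.sqrt(2.0 / d_in)).astype(np.float32)
    w["fc1_b"] = np.zeros(cfg.head_width, dtype=np.float32)
    w["fc2_w"] = (rng.standard_normal((cfg.head_width, 1)) * np.sqrt(1.0 / cfg.head_width)).astype(np.float32)
    w["fc2_b"] = np.zeros(1, dtype=np.float32)
    return w


def _avg_pool(x: np.ndarray, factors) -> np.ndarray:
    n, c = x.shape[:2]
    d, h, wd = (s // f for s, f in zip(x.shape[2:], factors))
    fd, fh, fw = factors
    x = x[:, :, :d * fd, :h * fh, :wd * fw]
    return x.reshape(n, c, d, fd, h, fh, wd, fw).mean(axis=(3, 5, 7))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) -> (N, D*H*W, C*k^3) patch matrix, 'same' padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # win: (N, C, D, H, W, k, k, k) -> (N, D, H, W, C, k, k, k)
    win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    n, d, h, wd = win.shape[:4]
    return np.ascontiguousarray(win).reshape(n, d * h * wd, -1)


def _col2im(dp: np.ndarray, shape, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch grads back to the input grid."""
    n, c, d, h, wd = shape
    p = k // 2
    dp = dp.reshape(n, d, h, wd, c, k, k, k)
    dx = np.zeros((n, c, d + 2 * p, h + 2 * p, wd + 2 * p), dtype=dp.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                dx[:, :, i:i + d, j:j + h, l:l + wd] += dp[:, :, :, :, :, i, j, l].transpose(0, 4, 1, 2, 3)
    return dx[:, :, p:p + d, p:p + h, p:p + wd]


def _max_pool(x: np.ndarray, factors):
    n, c = x.shape[:2]
    d, h, wd = (s // f for s, f in zip(x.shape[2:], factors))
    fd, fh, fw = factors
    xc = x[:, :, :d * fd, :h * fh, :wd * fw]
    r = xc.reshape(n, c, d, fd, h, fh, wd, fw).transpose(0, 1, 2, 4, 6, 3, 5, 7)
    r = np.ascontiguousarray(r).reshape(n, c, d, h, wd, fd * fh * fw)
    idx = np.argmax(r, axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, (idx, xc.shape, factors)


def _max_unpool(dout: np.ndarray, cache, full_shape):
    idx, xc_shape, factors = cache
    n, c, dcrop, hcrop, wcrop = xc_shape
    fd, fh, fw = factors
    d, h, wd = dout.shape[2:]
    dr = np.zeros((n, c, d, h, wd, fd * fh * fw), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(n, c, d, h, wd, fd, fh, fw).transpose(0, 1, 2, 5, 3, 6, 4, 7)
    dxc = dr.reshape(n, c, d * fd, h * fh, wd * fw)
    dx = np.zeros((n, c) + tuple(full_shape), dtype=dout.dtype)
    dx[:, :, :d * fd, :h * fh, :wd * fw] = dxc
    return dx


def _encoder_forward(x: np.ndarray, w: Dict[str, np.ndarray], cfg: NetConfig, cache: Optional[dict]):
    """Shared encoder: stem avg-pool, conv-relu, max-pool, conv-relu, GAP."""
    s = _avg_pool(x[:, None], cfg.stem_pool)                    # (n, 1, d, h, w)
    p1 = _im2col(s, cfg.kernel)
    z1 = p1 @ w["conv1_w"] + w["conv1_b"]
    a1 = np.maximum(z1, 0.0)
    c1 = cfg.channels[0]
    d, h, wd = s.shape[2:]
    a1v = a1.reshape(s.shape[0], d, h, wd, c1).transpose(0, 4, 1, 2, 3)
    m1, mp_cache = _max_pool(a1v, cfg.pool)
    p2 = _im2col(m1, cfg.kernel)
    z2 = p2 @ w["conv2_w"] + w["conv2_b"]
    a2 = np.maximum(z2, 0.0)
    c2 = cfg.channels[1]
    emb = a2.mean(axis=1)                                       # GAP -> (n, c2)
    if cache is not None:
        cache.update(dict(s_shape=s.shape, p1=p1, z1=z1, mp_cache=mp_cache,
                          m1_shape=m1.shape, p2=p2, z2=z2, n_vox2=a2.shape[1]))
    return emb


def _encoder_backward(demb: np.ndarray, w, cfg: NetConfig, cache) -> Dict[str, np.ndarray]:
    grads = {}
    n = demb.shape[0]
    da2 = np.repeat(demb[:, None, :], cache["n_vox2"], axis=1) / cache["n_vox2"]
    dz2 = da2 * (cache["z2"] > 0)
    grads["conv2_w"] = np.tensordot(cache["p2"], dz2, axes=([0, 1], [0, 1]))
    grads["conv2_b"] = dz2.sum(axis=(0, 1))
    dp2 = dz2 @ w["conv2_w"].T
    dm1 = _col2im(dp2, cache["m1_shape"], cfg.kernel)
    stem = cache["s_shape"]
    da1v = _max_unpool(dm1, cache["mp_cache"], stem[2:])
    da1 = da1v.transpose(0, 2, 3, 4, 1).reshape(n, -1, cfg.channels[0])
    dz1 = da1 * (cache["z1"] > 0)
    grads["conv1_w"] = np.tensordot(cache["p1"], dz1, axes=([0, 1], [0, 1]))
    grads["conv1_b"] = dz1.sum(axis=(0, 1))
    return grads


def forward_logits(x: np.ndarray, w: Dict[str, np.ndarray], cfg: NetConfig,
                   cache: Optional[dict] = None) -> np.ndarray:
    """Logits for a batch of (n, 2, D, H, W) volume pairs."""
    n = x.shape[0]
    flat = x.reshape((n * 2,) + x.shape[2:]).astype(np.float32)
    enc_cache = {} if cache is not None else None
    emb = _encoder_forward(flat, w, cfg, enc_cache)
    feats = emb.reshape(n, -1)
    z1 = feats @ w["fc1_w"] + w["fc1_b"]
    a1 = np.maximum(z1, 0.0)
    logits = (a1 @ w["fc2_w"] + w["fc2_b"])[:, 0]
    if cache is not None:
        cache.update(dict(enc=enc_cache, feats=feats, hz1=z1, ha1=a1))
    return logits


def _backward(dlogits: np.ndarray, w, cfg: NetConfig, cache) -> Dict[str, np.ndarray]:
    n = dlogits.shape[0]
    grads = {}
    grads["fc2_w"] = cache["ha1"].T @ dlogits[:, None]
    grads["fc2_b"] = dlogits.sum(keepdims=True)
    da1 = dlogits[:, None] @ w["fc2_w"].T
    dz1 = da1 * (cache["hz1"] > 0)
    grads["fc1_w"] = cache["feats"].T @ dz1
    grads["fc1_b"] = dz1.sum(axis=0)
    dfeats = dz1 @ w["fc1_w"].T
    demb = dfeats.reshape(n * 2, -1)
    grads.update(_encoder_backward(demb, w, cfg, cache["enc"]))
    return grads


def _bce_with_logits(logits, y, sample_weight):
    z = logits.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    wsum = sample_weight.sum()
    dlogits = sample_weight * (1.0 / (1.0 + np.exp(-z)) - y) / wsum
    return float((sample_weight * loss).sum() / wsum), dlogits.astype(np.float32)


def _sample_weights(y: np.ndarray, class_weighted: bool) -> np.ndarray:
    if not class_weighted:
        return np.ones_like(y, dtype=np.float64)
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((1 - y).sum()), 1)
    w = np.where(y > 0.5, len(y) / (2.0 * n_pos), len(y) / (2.0 * n_neg))
    return w.astype(np.float64)


def predict_proba(x: np.ndarray, w: Dict[str, np.ndarray], cfg: NetConfig,
                  batch_size: int = 64) -> np.ndarray:
    out = []
    for i in range(0, x.shape[0], batch_size):
        logits = forward_logits(x[i:i + batch_size], w, cfg)
        out.append(1.0 / (1.0 + np.exp(-logits)))
    return np.concatenate(out) if out else np.zeros(0)


def train(
    x: np.ndarray,
    y: np.ndarray,
    cfg: NetConfig,
    x_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    init: Optional[Dict[str, np.ndarray]] = None,
    lr: Optional[float] = None,
    epochs: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    trainable: Optional[Tuple[str, ...]] = None,
    early_stop: bool = True,
):
    """Adam training with early stopping on (weighted) validation loss.

    Returns ``(best_weights, history)`` where history holds per-epoch
    train/validation losses.  With ``epochs=0`` the initial weights are
    returned untouched (useful for probing a pretrained encoder with a
    fresh head); ``trainable`` restricts updates to a subset of weights
    (frozen-encoder head warm-up).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    w = init if init is not None else init_weights(cfg, rng)
    w = {k: v.copy() for k, v in w.items()}
    n_epochs = cfg.epochs if epochs is None else epochs
    history = {"train_loss": [], "val_loss": []}
    if n_epochs == 0:
        return w, history

    lr = cfg.learning_rate if lr is None else lr
    y = np.asarray(y, dtype=np.float64)
    sw = _sample_weights(y, cfg.class_weighted)
    sw_val = None
    if x_val is not None and len(x_val):
        y_val = np.asarray(y_val, dtype=np.float64)
        sw_val = _sample_weights(y_val, cfg.class_weighted)

    m = {k: np.zeros_like(v, dtype=np.float64) for k, v in w.items()}
    v2 = {k: np.zeros_like(v, dtype=np.float64) for k, v in w.items()}
    t = 0
    best = {k: vv.copy() for k, vv in w.items()}
    best_loss, since_best = np.inf, 0
    n = x.shape[0]
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        ep_loss, ep_n = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            cache = {}
            logits = forward_logits(x[idx], w, cfg, cache)
            loss, dlogits = _bce_with_logits(logits, y[idx], sw[idx])
            grads = _backward(dlogits, w, cfg, cache)
            t += 1
            for k in w:
                if trainable is not None and k not in trainable:
                    continue
                g = grads[k].reshape(w[k].shape).astype(np.float64)
                if cfg.weight_decay and k.endswith("_w"):
                    g = g + cfg.weight_decay * w[k]
                m[k] = 0.9 * m[k] + 0.1 * g
                v2[k] = 0.999 * v2[k] + 0.001 * g * g
                mhat = m[k] / (1 - 0.9**t)
                vhat = v2[k] / (1 - 0.999**t)
                w[k] = (w[k] - lr * mhat / (np.sqrt(vhat) + 1e-8)).astype(np.float32)
            ep_loss += loss * len(idx)
            ep_n += len(idx)
        history["train_loss"].append(ep_loss / ep_n)
        if sw_val is not None:
            logits_v = forward_logits(x_val, w, cfg)
            vloss, _ = _bce_with_logits(logits_v, y_val, sw_val)
        else:
            vloss = history["train_loss"][-1]
        history["val_loss"].append(vloss)
        if vloss < best_loss - 1e-6:
            best_loss = vloss
            best = {k: vv.copy() for k, vv in w.items()}
            since_best = 0
        else:
            since_best += 1
            if early_stop and since_best >= cfg.patience:
                break
    if not early_stop:
        best = w
    return best, history


def weights_hash(w: Dict[str, np.ndarray]) -> str:
    import hashlib

    h = hashlib.sha256()
    for k in sorted(w):
        h.update(k.encode())
        h.update(np.ascontiguousarray(w[k]).tobytes())
    return h.hexdigest()
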