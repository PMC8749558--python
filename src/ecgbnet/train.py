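"""Straight-through-estimator training of the binarized beat classifier.

A small, self-contained numpy trainer that produces deploy-ready folded
parameters for the inference engines.  Latent real-valued weights are
binarized with ``sign`` in the forward pass; the gradient passes straight
through wherever the latent weight lies in [-1, 1] and is clipped outside
(the standard straight-through estimator).  Hidden activations are likewise
``sign`` of the batch-normalized accumulator, with the straight-through
window taken on the normalized value.  The last unit's batch-norm affine
feeds a softmax cross-entropy loss during training; at deployment the
softmax is dropped (arg-max only) and every hidden batch-norm is folded
into an integer threshold.

Training exists to demonstrate end-to-end identification on synthetic
subjects; it is not a replica of any published training recipe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .model_spec import NetworkSpec
from .reference_engine import Beat, FoldedUnitParams, fold_bn, reference_forward

__all__ = ["train_ste", "evaluate", "TrainResult"]

_EPS = 1e-5


@dataclass
class TrainResult:
    params: List[FoldedUnitParams]
    loss_history: List[float]
    train_accuracy: float


class _Adam:
    def __init__(self, shape, lr):
        self.lr = lr
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, w, grad):
        self.t += 1
        self.m = 0.9 * self.m + 0.1 * grad
        self.v = 0.999 * self.v + 0.001 * grad * grad
        mh = self.m / (1 - 0.9 ** self.t)
        vh = self.v / (1 - 0.999 ** self.t)
        return w - self.lr * mh / (np.sqrt(vh) + 1e-8)


class _UnitState:
    """Latent weights + batch-norm state for one unit."""

    def __init__(self, unit, rng, lr):
        self.unit = unit
        if unit.kind == "conv":
            shape = (unit.n_filters, unit.in_channels, unit.kernel_size)
        else:
            shape = (unit.n_filters, unit.in_channels)
        self.w = rng.uniform(-1, 1, size=shape)
        n = unit.n_filters
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.opt_w = _Adam(shape, lr)
        self.opt_g = _Adam(n, lr)
        self.opt_b = _Adam(n, lr)


def _sign(x):
    return np.where(x >= 0, 1.0, -1.0)


def _conv_fwd(x, wb):
    win = np.lib.stride_tricks.sliding_window_view(x, wb.shape[2], axis=2)
    return np.einsum("nclk,fck->nfl", win, wb), win


def _conv_bwd(dacc, win, wb, x_shape):
    dw = np.einsum("nfl,nclk->fck", dacc, win)
    dx = np.zeros(x_shape)
    lout = dacc.shape[2]
    for k in range(wb.shape[2]):
        dx[:, :, k:k + lout] += np.einsum("nfl,fc->ncl", dacc, wb[:, :, k])
    return dw, dx


def _bn_fwd(acc, st, axes):
    mean = acc.mean(axis=axes)
    var = acc.var(axis=axes)
    st.run_mean = 0.9 * st.run_mean + 0.1 * mean
    st.run_var = 0.9 * st.run_var + 0.1 * var
    bshape = [1, -1] + [1] * (acc.ndim - 2)
    xhat = (acc - mean.reshape(bshape)) / np.sqrt(var.reshape(bshape) + _EPS)
    y = st.gamma.reshape(bshape) * xhat + st.beta.reshape(bshape)
    return y, (xhat, var, bshape)


def _bn_bwd(dy, cache, st, axes):
    xhat, var, bshape = cache
    m = dy.size // dy.shape[1]
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    dxhat = dy * st.gamma.reshape(bshape)
    inv = 1.0 / np.sqrt(var.reshape(bshape) + _EPS)
    dacc = inv / m * (m * dxhat - dxhat.sum(axis=axes).reshape(bshape)
                      - xhat * (dxhat * xhat).sum(axis=axes).reshape(bshape))
    return dacc, dgamma, dbeta


def train_ste(spec: NetworkSpec, beats: Sequence[Beat], epochs: int = 40,
              seed: int = 0, lr: float = 0.01,
              batch_size: int = 32) -> TrainResult:
    """Train the binarized network on labelled beats; returns folded params.

    Beats must carry ``subject_id`` labels covering at least two classes in
    ``[0, n_classes)``.  The returned parameters are fully folded (integer
    thresholds from the running batch-norm statistics) and are consumable
    by both inference engines and the parameter file.
    """
    labels = np.array([b.subject_id for b in beats])
    if any(l is None for l in labels):
        raise ValueError("all beats must be labelled")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training needs at least two distinct subjects")
    if labels.min() < 0 or labels.max() >= spec.n_classes:
        raise ValueError(f"labels must lie in [0, {spec.n_classes})")
    x_all = np.stack([b.samples.astype(np.float64) for b in beats])[:, None, :]
    n = len(beats)
    rng = np.random.default_rng(seed)
    states = [_UnitState(u, rng, lr) for u in spec.units]
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x, y_true = x_all[idx], labels[idx]
            caches = []
            h = x
            for st in states:
                u = st.unit
                wb = _sign(st.w)
                if u.kind == "conv":
                    acc, win = _conv_fwd(h, wb)
                    flat_in = None
                else:
                    flat_in = h.transpose(0, 2, 1).reshape(len(idx), -1)
                    acc = (flat_in @ wb.T)[:, :, None]
                    win = None
                pool_idx = None
                if u.has_pool:
                    p = u.pool_size
                    shaped = acc.reshape(acc.shape[0], acc.shape[1], -1, p)
                    pool_idx = shaped.argmax(axis=3)
                    acc = shaped.max(axis=3)
                axes = (0, 2) if acc.ndim == 3 else (0,)
                ybn, bn_cache = _bn_fwd(acc, st, axes)
                if u.is_last:
                    out = ybn[:, :, 0]
                else:
                    out = _sign(ybn)
                caches.append((h, wb, win, flat_in, pool_idx, ybn, bn_cache, axes))
                h = out
            # softmax cross-entropy
            logits = h - h.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            epoch_loss += -np.log(p[np.arange(len(idx)), y_true] + 1e-12).sum()
            dlogits = p.copy()
            dlogits[np.arange(len(idx)), y_true] -= 1.0
            dlogits /= len(idx)
            dh = dlogits
            for st, cache in zip(reversed(states), reversed(caches)):
                u = st.unit
                h_in, wb, win, flat_in, pool_idx, ybn, bn_cache, axes = cache
                if u.is_last:
                    dy = dh[:, :, None]
                else:
                    dy = dh * (np.abs(ybn) <= 1.0)  # STE through sign
                dacc, dgamma, dbeta = _bn_bwd(dy, bn_cache, st, axes)
                if pool_idx is not None:
                    p_sz = u.pool_size
                    up = np.zeros(dacc.shape[:2] + (dacc.shape[2] * p_sz,))
                    n0, n1, n2 = pool_idx.shape
                    i0, i1, i2 = np.ogrid[:n0, :n1, :n2]
                    up[i0, i1, i2 * p_sz + pool_idx] = dacc
                    dacc = up
                if u.kind == "conv":
                    dwb, dh = _conv_bwd(dacc, win, wb, h_in.shape)
                else:
                    dacc2 = dacc[:, :, 0]
                    dwb = dacc2.T @ flat_in
                    dflat = dacc2 @ wb
                    dh = dflat.reshape(h_in.shape[0], h_in.shape[2],
                                       h_in.shape[1]).transpose(0, 2, 1)
                dw = dwb * (np.abs(st.w) <= 1.0)  # STE through weight sign
                st.w = np.clip(st.opt_w.step(st.w, dw), -1, 1)
                st.gamma = st.opt_g.step(st.gamma, dgamma)
                st.beta = st.opt_b.step(st.beta, dbeta)
        losses.append(epoch_loss / n)
    params = _fold_states(states)
    acc = evaluate(spec, params, beats)
    return TrainResult(params=params, loss_history=losses, train_accuracy=acc)


def _fold_states(states) -> List[FoldedUnitParams]:
    params = []
    for st in states:
        w = _sign(st.w).astype(np.int8)
        sigma = np.sqrt(st.run_var + _EPS)
        if st.unit.is_last:
            params.append(FoldedUnitParams(
                w, gamma=st.gamma.copy(), beta=st.beta.copy(),
                mu=st.run_mean.copy(), sigma=sigma))
        else:
            taus, dirs = zip(*(
                fold_bn(g, b, m, s)
                for g, b, m, s in zip(st.gamma, st.beta, st.run_mean, sigma)))
            params.append(FoldedUnitParams(
                w, thresholds=np.array(taus, dtype=np.int64),
                directions=np.array([int(d) for d in dirs], dtype=np.uint8)))
    return params


def evaluate(spec: NetworkSpec, params, beats: Sequence[Beat],
             forward=reference_forward) -> float:
    """Per-beat classification accuracy on labelled beats."""
    hits = sum(forward(spec, params, b)[0] == b.subject_id for b in beats)
    return hits / len(beats)
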