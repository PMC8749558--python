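"""Plain-integer reference forward pass — the oracle the packed engine must match.

All hidden-unit arithmetic is exact integer arithmetic: a valid (no padding,
stride 1) 1-D convolution of an integer feature map with ±1 weights, an
optional non-overlapping max-pool applied to the raw accumulators, and a
binarization implemented as an integer threshold comparison obtained by
folding the batch-norm parameters.  Only the last unit produces real-valued
scores, through the per-class batch-norm affine
``gamma * (a - mu) / sigma + beta``; classification takes the arg-max of
those scores directly (a "pseudo-softmax": softmax is monotone, so the
probability transform is skipped).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model_spec import NetworkSpec

__all__ = [
    "Direction",
    "FoldedUnitParams",
    "Beat",
    "conv1d_valid",
    "maxpool",
    "fold_bn",
    "binarize_thresholded",
    "pseudo_softmax_argmax",
    "reference_forward",
]

BEAT_LEN = 180


class Direction(enum.IntEnum):
    """Comparator paired with a folded threshold tau.

    GE: +1 iff a >= tau (positive batch-norm gain);
    LE: +1 iff a <= tau (negative gain);
    CONST_POS / CONST_NEG: gain is zero, the channel is constant.
    """

    GE = 0
    LE = 1
    CONST_POS = 2
    CONST_NEG = 3


@dataclass
class FoldedUnitParams:
    """Deploy-time parameters of one unit.

    ``weights`` is a ±1 int8 tensor, shape (n_filters, in_channels, K) for
    conv units or (n_neurons, in_dim) for the fc unit.  Hidden units carry
    per-filter integer ``thresholds`` with ``directions``; the last unit
    instead carries the per-class batch-norm affine (gamma, beta, mu, sigma).
    """

    weights: np.ndarray
    thresholds: Optional[np.ndarray] = None
    directions: Optional[np.ndarray] = None
    gamma: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None
    mu: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.int8)
        if not np.isin(self.weights, (-1, 1)).all():
            raise ValueError("weights must take values in {-1, +1} only")
        if self.thresholds is not None:
            self.thresholds = np.asarray(self.thresholds, dtype=np.int64)
            self.directions = np.asarray(self.directions, dtype=np.uint8)
        if self.sigma is not None:
            self.gamma = np.asarray(self.gamma, dtype=np.float64)
            self.beta = np.asarray(self.beta, dtype=np.float64)
            self.mu = np.asarray(self.mu, dtype=np.float64)
            self.sigma = np.asarray(self.sigma, dtype=np.float64)
            if not (self.sigma > 0).all():
                raise ValueError("sigma must be > 0")

    @property
    def is_last(self) -> bool:
        return self.sigma is not None


@dataclass
class Beat:
    """A 180-sample, signed 8-bit ECG beat window."""

    samples: np.ndarray
    subject_id: Optional[int] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if s.shape != (BEAT_LEN,):
            raise ValueError(f"beat must have exactly {BEAT_LEN} samples, got {s.shape}")
        if s.min() < -128 or s.max() > 127:
            raise ValueError("beat samples must fit signed 8-bit range")
        self.samples = s.astype(np.int8)


def conv1d_valid(inp: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Exact-integer valid 1-D cross-correlation.

    ``acc[f, x] = sum_c sum_k inp[c, x+k] * w[f, c, k]`` for an integer map
    of shape (Cin, Lin) and ±1 weights of shape (Cout, Cin, K); returns the
    int64 accumulator map of shape (Cout, Lin - K + 1).
    """
    inp = np.asarray(inp, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.int64)
    if inp.ndim != 2 or weights.ndim != 3 or weights.shape[1] != inp.shape[0]:
        raise ValueError(
            f"shape mismatch: input {inp.shape} vs weights {weights.shape}"
        )
    cin, lin = inp.shape
    k = weights.shape[2]
    if k > lin:
        raise ValueError(f"kernel {k} longer than input {lin}")
    win = np.lib.stride_tricks.sliding_window_view(inp, k, axis=1)  # (Cin, Lout, K)
    return np.einsum("clk,fck->fl", win, weights)


def maxpool(acc: np.ndarray, pool: int) -> np.ndarray:
    """Non-overlapping max over ``pool``-wide windows along the last axis.

    Applied to the raw integer accumulators, before binarization.
    """
    acc = np.asarray(acc)
    length = acc.shape[-1]
    if length % pool != 0:
        raise ValueError(f"length {length} not divisible by pool window {pool}")
    shaped = acc.reshape(acc.shape[:-1] + (length // pool, pool))
    return shaped.max(axis=-1)


def fold_bn(gamma: float, beta: float, mu: float, sigma: float):
    """Fold batch-norm-then-sign into an integer threshold comparison.

    The binarized output is +1 iff ``gamma*(a - mu)/sigma + beta >= 0``.
    For gamma > 0 this is ``a >= mu - beta*sigma/gamma``; an integer ``a``
    satisfies it iff ``a >= ceil(...)``, so tau = ceil with direction GE.
    For gamma < 0 the inequality flips: tau = floor with direction LE.
    gamma = 0 gives a constant channel: sign(beta), with sign(0) = +1
    (the usual BNN convention).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if gamma > 0:
        return int(math.ceil(mu - beta * sigma / gamma)), Direction.GE
    if gamma < 0:
        return int(math.floor(mu - beta * sigma / gamma)), Direction.LE
    return 0, (Direction.CONST_NEG if beta < 0 else Direction.CONST_POS)


def binarize_thresholded(acc: np.ndarray, thresholds: np.ndarray,
                         directions: np.ndarray) -> np.ndarray:
    """Apply per-filter threshold comparisons to an accumulator map.

    Returns a ±1 int8 map of the same shape; thresholds/directions broadcast
    over the filter (first) axis.
    """
    acc = np.asarray(acc)
    tau = np.asarray(thresholds).reshape((-1,) + (1,) * (acc.ndim - 1))
    dirs = np.asarray(directions).reshape(tau.shape)
    out = np.where(dirs == Direction.GE, acc >= tau, acc <= tau)
    out = np.where(dirs == Direction.CONST_POS, True, out)
    out = np.where(dirs == Direction.CONST_NEG, False, out)
    return np.where(out, 1, -1).astype(np.int8)


def pseudo_softmax_argmax(scores: Sequence[float]) -> int:
    """Predicted class = arg-max of the batch-normalized output scores.

    Softmax is strictly monotone, so its arg-max is the arg-max of the raw
    scores; the probability transform is skipped.  Ties go to the lowest
    index.
    """
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("need at least one class score")
    return int(np.argmax(scores))


def reference_forward(spec: NetworkSpec, params: Sequence[FoldedUnitParams],
                      beat: Beat, return_trace: bool = False):
    """Run the full network on one beat; returns (class index, scores).

    The first unit consumes the signed 8-bit samples directly (signed
    add/subtract accumulation against ±1 weights); hidden units consume ±1
    maps.  With ``return_trace=True`` additionally returns the list of
    post-pool integer accumulator maps of every unit, which the packed
    engine must reproduce bit for bit.
    """
    if len(params) != len(spec.units):
        raise ValueError(f"expected {len(spec.units)} unit params, got {len(params)}")
    first = spec.units[0]
    expected = first.in_length if first.kind == "conv" else first.in_channels
    if len(beat.samples) != expected:
        raise ValueError(
            f"network expects {expected} input samples, beat has {len(beat.samples)}"
        )
    fmap = beat.samples[np.newaxis, :].astype(np.int64)
    traces = []
    for unit, p in zip(spec.units, params):
        if unit.kind == "conv":
            if p.weights.shape != (unit.n_filters, unit.in_channels, unit.kernel_size):
                raise ValueError(
                    f"conv weights {p.weights.shape} do not match unit "
                    f"({unit.n_filters},{unit.in_channels},{unit.kernel_size})"
                )
            acc = conv1d_valid(fmap, p.weights)
            if unit.has_pool:
                acc = maxpool(acc, unit.pool_size)
        else:
            flat = fmap.T.reshape(-1)  # channel-major within each position
            if p.weights.shape != (unit.n_filters, unit.in_channels):
                raise ValueError(
                    f"fc weights {p.weights.shape} do not match unit "
                    f"({unit.n_filters},{unit.in_channels})"
                )
            acc = (p.weights.astype(np.int64) @ flat)[:, np.newaxis]
        traces.append(acc)
        if unit.is_last:
            if not p.is_last:
                raise ValueError("last unit params must carry the per-class affine")
            scores = p.gamma * (acc[:, 0] - p.mu) / p.sigma + p.beta
        else:
            if p.thresholds is None:
                raise ValueError("hidden unit params must carry thresholds")
            fmap = binarize_thresholded(acc, p.thresholds, p.directions).astype(np.int64)
    cls = pseudo_softmax_argmax(scores)
    if return_trace:
        return cls, scores, traces
    return cls, scores
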