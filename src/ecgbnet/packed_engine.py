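"""Bit-packed inference datapath and the binary parameter file.

This module re-implements, bit for bit, the accelerated datapath: weights
and hidden feature maps are held as 64-bit words in channel-major ``(c, x)``
order, hidden-unit dot products are XNOR-popcount operations over those
words, and the two feature-map buffers alternate in ping-pong fashion from
unit to unit.  The contract with :mod:`ecgbnet.reference_engine` is exact
equivalence: identical integer accumulators in every unit and therefore an
identical predicted class, for every input.

Packing layout
--------------
A filter's ±1 weights are flattened channel-fastest (flat index
``x * Cin + c``) and packed 64 per word: bit ``b`` of word ``j`` holds flat
index ``64*j + b``, with bit 0 the lowest channel and weight +1 encoded as
bit value 1.  A ±1 feature map of shape (C, L) packs to an (L, C/64) word
array, channel-major within each position — so a conv filter's word
sequence lines up exactly with the word sequence of its input window, and
the fc unit's word sequence lines up with the flattened packed map.

The parameter file ("EIBN v1", little-endian) serializes the architecture
header, per-unit records and per-filter payloads; ``read_params_file`` is
the exact inverse of ``write_params_file``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model_spec import (
    PACK_LANES,
    NetworkSpec,
    UnitSpec,
    infer_shapes,
)
from .reference_engine import (
    Beat,
    FoldedUnitParams,
    binarize_thresholded,
    conv1d_valid,
    maxpool,
    pseudo_softmax_argmax,
)

__all__ = [
    "PackedUnitParams",
    "PackedFeatureMap",
    "ParamsFormatError",
    "pack_weights",
    "unpack_weights",
    "pack_feature_map",
    "unpack_feature_map",
    "xnor_dot",
    "packed_forward",
    "write_params_file",
    "read_params_file",
    "accounted_payload_bytes",
]

MAGIC = b"EIBN"
VERSION = 1
_POW2 = (np.uint64(1) << np.arange(PACK_LANES, dtype=np.uint64))


class ParamsFormatError(ValueError):
    """Malformed parameter file; carries the byte offset of the defect."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


def _pack_bit_rows(bits: np.ndarray) -> np.ndarray:
    """Pack a (..., nbits) 0/1 array into (..., ceil(nbits/64)) uint64 words."""
    nbits = bits.shape[-1]
    nwords = -(-nbits // PACK_LANES)
    padded = np.zeros(bits.shape[:-1] + (nwords * PACK_LANES,), dtype=np.uint64)
    padded[..., :nbits] = bits
    lanes = padded.reshape(bits.shape[:-1] + (nwords, PACK_LANES))
    return (lanes * _POW2).sum(axis=-1, dtype=np.uint64)


def _unpack_bit_rows(words: np.ndarray, nbits: int) -> np.ndarray:
    """Inverse of :func:`_pack_bit_rows`: (..., nwords) words -> (..., nbits) bits."""
    shifts = np.arange(PACK_LANES, dtype=np.uint64)
    lanes = (words[..., np.newaxis] >> shifts) & np.uint64(1)
    flat = lanes.reshape(words.shape[:-1] + (-1,))
    return flat[..., :nbits].astype(np.uint8)


@dataclass
class PackedUnitParams:
    """One unit's parameters in packed, serializable form.

    ``weight_words`` has shape (n_filters, words_per_filter); padded tail
    bits are zero and ``valid_lanes`` records the number of meaningful bits
    of each word (64 except possibly the last).  Hidden units carry a signed
    64-bit ``threshold`` plus a direction tag per filter; the last unit
    carries the per-class affine, stored as 32-bit reals in the file.
    """

    weight_words: np.ndarray
    valid_lanes: np.ndarray
    thresholds: Optional[np.ndarray] = None
    directions: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = None  # (n_classes, 4): gamma, beta, mu, sigma

    def __post_init__(self) -> None:
        self.weight_words = np.asarray(self.weight_words, dtype=np.uint64)
        self.valid_lanes = np.asarray(self.valid_lanes, dtype=np.int64)

    @property
    def words_per_filter(self) -> int:
        return self.weight_words.shape[1]

    @property
    def byte_size(self) -> int:
        """Accounted bytes per filter: weight words plus one threshold word."""
        return 8 * self.words_per_filter + 8

    @property
    def is_last(self) -> bool:
        return self.affine is not None


@dataclass
class PackedFeatureMap:
    """A ±1 feature map packed channel-major: (length, channels/64) words."""

    words: np.ndarray
    channels: int
    length: int

    @property
    def byte_size(self) -> int:
        return self.channels * self.length // 8


def pack_weights(folded: FoldedUnitParams, unit: UnitSpec) -> PackedUnitParams:
    """Reorder a unit's ±1 weights from (x, c) to (c, x) and bit-pack them."""
    w = folded.weights
    if unit.kind == "conv":
        flat = np.transpose(w, (0, 2, 1)).reshape(w.shape[0], -1)  # channel fastest
    else:
        flat = w
    bits = (flat > 0).astype(np.uint64)
    words = _pack_bit_rows(bits)
    nbits = flat.shape[1]
    nwords = words.shape[1]
    valid = np.full(nwords, PACK_LANES, dtype=np.int64)
    tail = nbits - PACK_LANES * (nwords - 1)
    valid[-1] = tail
    if folded.is_last:
        affine = np.stack(
            [folded.gamma, folded.beta, folded.mu, folded.sigma], axis=1
        ).astype(np.float32)
        return PackedUnitParams(words, valid, affine=affine)
    return PackedUnitParams(
        words, valid,
        thresholds=np.asarray(folded.thresholds, dtype=np.int64),
        directions=np.asarray(folded.directions, dtype=np.uint8),
    )


def unpack_weights(packed: PackedUnitParams, unit: UnitSpec) -> FoldedUnitParams:
    """Exact inverse of :func:`pack_weights`."""
    nbits = unit.weight_bits
    bits = _unpack_bit_rows(packed.weight_words, nbits)
    pm = np.where(bits == 1, 1, -1).astype(np.int8)
    if unit.kind == "conv":
        w = pm.reshape(unit.n_filters, unit.kernel_size, unit.in_channels)
        w = np.transpose(w, (0, 2, 1))
    else:
        w = pm
    if packed.is_last:
        g, b, m, s = (packed.affine[:, i].astype(np.float64) for i in range(4))
        return FoldedUnitParams(w, gamma=g, beta=b, mu=m, sigma=s)
    return FoldedUnitParams(w, thresholds=packed.thresholds.copy(),
                            directions=packed.directions.copy())


def pack_feature_map(fmap: np.ndarray) -> PackedFeatureMap:
    """Pack a ±1 map of shape (C, L), C a multiple of 64, channel-major."""
    c, length = fmap.shape
    if c % PACK_LANES != 0:
        raise ValueError(f"channels {c} not a multiple of {PACK_LANES}")
    bits = (fmap.T > 0).astype(np.uint64)  # (L, C), channel fastest
    return PackedFeatureMap(_pack_bit_rows(bits), channels=c, length=length)


def unpack_feature_map(packed: PackedFeatureMap) -> np.ndarray:
    bits = _unpack_bit_rows(packed.words, packed.channels)
    return np.where(bits == 1, 1, -1).astype(np.int8).T


def xnor_dot(x_word: int, w_word: int, n_valid: int = PACK_LANES) -> int:
    """±1 dot product of two bit-encoded vectors in one word.

    Computes ``2 * popcount(XNOR(x, w) & mask(n_valid)) - n_valid``, which
    equals the sum over the valid lanes of the ±1 products.  Lanes above
    ``n_valid`` must be zero in both operands.
    """
    if not 1 <= n_valid <= PACK_LANES:
        raise ValueError(f"n_valid must be in [1, {PACK_LANES}], got {n_valid}")
    mask = (1 << n_valid) - 1
    x, w = int(x_word), int(w_word)
    return 2 * ((~(x ^ w)) & mask).bit_count() - n_valid


def _xnor_accumulate(windows: np.ndarray, weight_words: np.ndarray) -> np.ndarray:
    """Vectorized all-lanes-valid XNOR dot over word sequences.

    ``windows``: (n_positions, n_words) uint64; ``weight_words``:
    (n_filters, n_words) uint64.  Returns int64 accumulators of shape
    (n_filters, n_positions).
    """
    xnor = ~(windows[np.newaxis, :, :] ^ weight_words[:, np.newaxis, :])
    pop = np.bitwise_count(xnor).astype(np.int64).sum(axis=2)
    n_bits = PACK_LANES * windows.shape[1]
    return 2 * pop - n_bits


class _PingPong:
    """Two feature-map buffers whose producer/consumer roles swap each unit."""

    def __init__(self) -> None:
        self._bufs: list = [None, None]
        self._read = 0

    def read(self):
        return self._bufs[self._read]

    def write(self, fmap) -> None:
        dst = 1 - self._read
        assert fmap is not self._bufs[self._read], \
            "a unit must not write the buffer it is reading"
        self._bufs[dst] = fmap
        self._read = dst


def packed_forward(spec: NetworkSpec, packed: Sequence[PackedUnitParams],
                   beat: Beat, return_trace: bool = False):
    """Forward pass on packed parameters; bit-exact vs the reference engine.

    The first unit runs the signed 8-bit path (plain add/subtract against
    the unpacked ±1 weights — no XNOR, since the input is multi-bit); every
    hidden unit runs 64-lane XNOR-popcount accumulation over packed words.
    Returns (class index, per-class scores), plus the per-unit post-pool
    accumulator traces when ``return_trace`` is set.
    """
    if len(packed) != len(spec.units):
        raise ValueError(f"expected {len(spec.units)} packed units, got {len(packed)}")
    buffers = _PingPong()
    traces = []
    scores = None
    for i, (unit, p) in enumerate(zip(spec.units, packed)):
        if unit.is_first:
            folded = unpack_weights(p, unit)
            inp = beat.samples[np.newaxis, :].astype(np.int64)
            if unit.kind == "conv":
                acc = conv1d_valid(inp, folded.weights)
            else:
                acc = (folded.weights.astype(np.int64) @ inp.reshape(-1))[:, np.newaxis]
        else:
            if unit.in_channels % PACK_LANES != 0:
                raise ValueError(
                    f"unit {i}: in_channels {unit.in_channels} not packable"
                )
            fmap_in: PackedFeatureMap = buffers.read()
            if unit.kind == "conv":
                # windows of K consecutive positions share the filter's word order
                win = np.lib.stride_tricks.sliding_window_view(
                    fmap_in.words, unit.kernel_size, axis=0
                )  # (Lout, C/64, K)
                win = np.transpose(win, (0, 2, 1)).reshape(win.shape[0], -1)
                acc = _xnor_accumulate(np.ascontiguousarray(win), p.weight_words)
            else:
                flat_words = fmap_in.words.reshape(1, -1)
                acc = _xnor_accumulate(flat_words, p.weight_words)
        if unit.has_pool:
            acc = maxpool(acc, unit.pool_size)
        traces.append(acc)
        if unit.is_last:
            if not p.is_last:
                raise ValueError("last unit must carry the per-class affine")
            g, b, m, s = (p.affine[:, j].astype(np.float64) for j in range(4))
            scores = g * (acc[:, 0] - m) / s + b
        else:
            if p.thresholds is None:
                raise ValueError("hidden unit must carry thresholds")
            binary = binarize_thresholded(acc, p.thresholds, p.directions)
            buffers.write(pack_feature_map(binary))
    cls = pseudo_softmax_argmax(scores)
    if return_trace:
        return cls, scores, traces
    return cls, scores


def accounted_payload_bytes(spec: NetworkSpec) -> int:
    """Weight-plus-threshold payload of the whole network, in bytes.

    Per filter: 8 bytes per packed weight word plus one 64-bit threshold
    block.  This is the hardware accounting convention — direction tags and
    file headers are format metadata and are not counted.
    """
    return sum(u.n_filters * (8 * u.words_per_filter + 8) for u in spec.units)


# -- EIBN v1 binary parameter file ------------------------------------------

_HEADER = struct.Struct("<4sHHHH")
_UNIT = struct.Struct("<BBHIII")
_POOL_SIZE = 2  # fixed in format v1; the only pool window of this family


def write_params_file(spec: NetworkSpec, packed: Sequence[PackedUnitParams],
                      path) -> int:
    """Serialize (spec, packed) to an EIBN v1 file; returns bytes written."""
    if len(packed) != len(spec.units):
        raise ValueError("one PackedUnitParams per unit required")
    chunks = [_HEADER.pack(MAGIC, VERSION, len(spec.units), spec.kernel_size,
                           spec.n_classes)]
    for pos, (unit, p) in enumerate(zip(spec.units, packed)):
        chunks.append(_UNIT.pack(
            0 if unit.kind == "conv" else 1,
            1 if unit.has_pool else 0,
            pos, unit.in_channels, unit.out_channels, unit.out_length,
        ))
        words_le = p.weight_words.astype("<u8")
        if p.is_last:
            for f in range(unit.n_filters):
                chunks.append(words_le[f].tobytes())
                chunks.append(p.affine[f].astype("<f4").tobytes())
        else:
            for f in range(unit.n_filters):
                chunks.append(words_le[f].tobytes())
                chunks.append(struct.pack("<qB", int(p.thresholds[f]),
                                          int(p.directions[f])))
    blob = b"".join(chunks)
    with open(path, "wb") as fh:
        fh.write(blob)
    return len(blob)


def _take(buf: bytes, offset: int, n: int) -> bytes:
    if offset + n > len(buf):
        raise ParamsFormatError(
            f"truncated file: wanted {n} bytes, {len(buf) - offset} left", offset
        )
    return buf[offset:offset + n]


def read_params_file(path):
    """Parse an EIBN v1 file back into (NetworkSpec, [PackedUnitParams])."""
    with open(path, "rb") as fh:
        buf = fh.read()
    off = 0
    raw = _take(buf, off, _HEADER.size)
    magic, version, n_units, kernel_size, n_classes = _HEADER.unpack(raw)
    if magic != MAGIC:
        raise ParamsFormatError(f"bad magic {magic!r}", 0)
    if version != VERSION:
        raise ParamsFormatError(f"unsupported version {version}", 4)
    off += _HEADER.size
    units, packed = [], []
    for i in range(n_units):
        kind_b, has_pool, pos, in_c, out_c, out_len = _UNIT.unpack(
            _take(buf, off, _UNIT.size))
        if pos != i:
            raise ParamsFormatError(f"unit position {pos} out of order", off)
        off += _UNIT.size
        kind = "conv" if kind_b == 0 else "fc"
        is_last = i == n_units - 1
        if kind == "conv":
            in_len = out_len * (_POOL_SIZE if has_pool else 1) + kernel_size - 1
            nbits = in_c * kernel_size
        else:
            in_len = 1
            nbits = in_c
        unit = UnitSpec(
            kind=kind, n_filters=out_c, in_channels=in_c, in_length=in_len,
            kernel_size=kernel_size if kind == "conv" else None,
            has_pool=bool(has_pool), pool_size=_POOL_SIZE,
            out_channels=out_c, out_length=out_len,
            is_first=i == 0, is_last=is_last,
        )
        nwords = -(-nbits // PACK_LANES)
        words = np.empty((out_c, nwords), dtype=np.uint64)
        if is_last:
            affine = np.empty((out_c, 4), dtype=np.float32)
            for f in range(out_c):
                words[f] = np.frombuffer(_take(buf, off, 8 * nwords), dtype="<u8")
                off += 8 * nwords
                affine[f] = np.frombuffer(_take(buf, off, 16), dtype="<f4")
                off += 16
            thresholds = directions = None
        else:
            affine = None
            thresholds = np.empty(out_c, dtype=np.int64)
            directions = np.empty(out_c, dtype=np.uint8)
            for f in range(out_c):
                words[f] = np.frombuffer(_take(buf, off, 8 * nwords), dtype="<u8")
                off += 8 * nwords
                thresholds[f], directions[f] = struct.unpack(
                    "<qB", _take(buf, off, 9))
                off += 9
        valid = np.full(nwords, PACK_LANES, dtype=np.int64)
        if nwords:
            valid[-1] = nbits - PACK_LANES * (nwords - 1)
        units.append(unit)
        packed.append(PackedUnitParams(words, valid, thresholds=thresholds,
                                       directions=directions, affine=affine))
    if off != len(buf):
        raise ParamsFormatError(f"{len(buf) - off} trailing bytes", off)
    spec = NetworkSpec(units=units, kernel_size=kernel_size, n_classes=n_classes)
    if units:
        spec = infer_shapes(spec)
    return spec, packed
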