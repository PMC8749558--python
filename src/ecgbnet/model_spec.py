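"""Network architecture description and shape arithmetic.

A binarized 1-D CNN for beat-level ECG identification is described as an
ordered list of *units*: each unit is a convolutional (or fully connected)
layer with ±1 weights, an optional non-overlapping max-pool, and a
batch-normalization stage that is folded into an integer threshold at
deployment time.  Every other module (the reference and packed inference
engines, the memory/schedule model, the parameter file) derives its shapes
from the :class:`NetworkSpec` built here.

Feature maps are described in ``(c, x)`` = (channels, width) terms,
channel-major: within each width position the channel values are contiguous.
Hidden units must have channel counts that are multiples of 64 so that
feature maps and weights pack into 64-bit words.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Optional

__all__ = [
    "UnitSpec",
    "NetworkSpec",
    "InvalidArchitectureError",
    "PackingConstraintError",
    "default_ecg_id_bnet",
    "infer_shapes",
    "PACK_LANES",
]

#: Width of the packed weight/activation words, in bits.  Fixed: the packed
#: datapath processes 64 channel lanes per word.
PACK_LANES = 64


class InvalidArchitectureError(ValueError):
    """Shape arithmetic produced a non-positive or non-integral size."""


class PackingConstraintError(ValueError):
    """A hidden unit's channel count is not a multiple of 64."""


@dataclass
class UnitSpec:
    """One conv/fc unit: layer + optional max-pool + batch-norm stage.

    For ``kind == "fc"`` the unit consumes the flattened feature map:
    ``in_channels`` is the flattened input dimension and ``in_length``/
    ``out_length`` are 1.
    """

    kind: str  # "conv" | "fc"
    n_filters: int
    in_channels: Optional[int] = None
    in_length: Optional[int] = None
    kernel_size: Optional[int] = None  # conv only
    has_pool: bool = False
    pool_size: int = 2
    out_channels: Optional[int] = None
    out_length: Optional[int] = None
    is_first: bool = False
    is_last: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "fc"):
            raise InvalidArchitectureError(f"unknown unit kind {self.kind!r}")
        if self.n_filters < 1:
            raise InvalidArchitectureError("n_filters must be >= 1")

    @property
    def in_shape(self) -> tuple:
        return (self.in_channels, self.in_length)

    @property
    def out_shape(self) -> tuple:
        return (self.out_channels, self.out_length)

    @property
    def weight_bits(self) -> int:
        """Number of ±1 weights in one filter/neuron."""
        if self.kind == "conv":
            return self.in_channels * self.kernel_size
        return self.in_channels

    @property
    def words_per_filter(self) -> int:
        """64-bit words needed to pack one filter/neuron."""
        return -(-self.weight_bits // PACK_LANES)


@dataclass
class NetworkSpec:
    """An ordered stack of units plus the global hyper-parameters."""

    units: list = field(default_factory=list)
    kernel_size: int = 7
    n_classes: int = 0

    def __iter__(self) -> Iterable[UnitSpec]:
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kernel_size": self.kernel_size,
            "n_classes": self.n_classes,
            "units": [asdict(u) for u in self.units],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        units = [UnitSpec(**u) for u in d["units"]]
        return cls(units=units, kernel_size=d["kernel_size"], n_classes=d["n_classes"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _infer_unit(unit: UnitSpec, kernel_size: int, allow_unpacked: bool) -> UnitSpec:
    u = replace(unit)
    if u.kind == "conv":
        if u.kernel_size is None:
            u.kernel_size = kernel_size
        conv_len = u.in_length - u.kernel_size + 1
        if conv_len <= 0:
            raise InvalidArchitectureError(
                f"valid convolution of length {u.in_length} with kernel "
                f"{u.kernel_size} yields non-positive length {conv_len}"
            )
        if u.has_pool:
            if conv_len % u.pool_size != 0:
                raise InvalidArchitectureError(
                    f"conv output length {conv_len} not divisible by pool "
                    f"window {u.pool_size}; refusing to truncate"
                )
            conv_len //= u.pool_size
        u.out_length = conv_len
        u.out_channels = u.n_filters
    else:  # fc
        u.out_length = 1
        u.out_channels = u.n_filters
        if u.has_pool:
            raise InvalidArchitectureError("fc units cannot pool")
    if not u.is_first and u.in_channels % PACK_LANES != 0 and not allow_unpacked:
        raise PackingConstraintError(
            f"hidden unit in_channels={u.in_channels} is not a multiple of "
            f"{PACK_LANES}; required for 64-bit packing "
            "(pass allow_unpacked=True for the reference engine only)"
        )
    if not u.is_last and u.out_channels % PACK_LANES != 0 and not allow_unpacked:
        raise PackingConstraintError(
            f"hidden unit out_channels={u.out_channels} is not a multiple of "
            f"{PACK_LANES}; required for 64-bit packing"
        )
    return u


def infer_shapes(spec: NetworkSpec, allow_unpacked: bool = False) -> NetworkSpec:
    """Propagate shapes through the unit chain; idempotent.

    Fills every ``out_channels``/``out_length`` from the unit settings and
    checks the chaining invariant: each unit's input shape equals the
    previous unit's output shape (flattened, for the fc unit).  Raises
    :class:`InvalidArchitectureError` rather than silently truncating when a
    pooled length does not divide evenly, and
    :class:`PackingConstraintError` when a hidden unit's channel count
    cannot pack into 64-bit words (``allow_unpacked`` downgrades the latter
    for reference-engine-only experiments).
    """
    if not spec.units:
        return NetworkSpec(units=[], kernel_size=spec.kernel_size, n_classes=spec.n_classes)
    out_units = []
    prev = None
    for i, unit in enumerate(spec.units):
        u = replace(unit)
        u.is_first = i == 0
        u.is_last = i == len(spec.units) - 1
        if prev is not None:
            if u.kind == "fc" and prev.kind == "conv":
                expect = prev.out_channels * prev.out_length
            else:
                expect = prev.out_channels
            if u.in_channels is None:
                u.in_channels = expect
            elif u.in_channels != expect:
                raise InvalidArchitectureError(
                    f"unit {i}: in_channels={u.in_channels} does not chain "
                    f"from previous output ({expect})"
                )
            if u.kind == "fc":
                u.in_length = 1
            elif u.in_length is None:
                u.in_length = prev.out_length
            elif u.in_length != prev.out_length:
                raise InvalidArchitectureError(
                    f"unit {i}: in_length={u.in_length} does not chain from "
                    f"previous output length ({prev.out_length})"
                )
        else:
            if u.in_channels is None or (u.kind == "conv" and u.in_length is None):
                raise InvalidArchitectureError("first unit must state its input shape")
            if u.kind == "fc":
                u.in_length = 1
        u = _infer_unit(u, spec.kernel_size, allow_unpacked)
        out_units.append(u)
        prev = u
    n_classes = out_units[-1].n_filters
    return NetworkSpec(units=out_units, kernel_size=spec.kernel_size, n_classes=n_classes)


def default_ecg_id_bnet() -> NetworkSpec:
    """The default 5-unit beat-identification architecture.

    Four convolutional units and one fully connected unit over a 180-sample,
    8-bit beat window, with feature maps
    (1,180) → (128,174) → (64,168) → (128,162) → (64,78) → 50 class scores.
    The kernel size (7) and pool window (2) are forced by the shape chain:
    180−174 = 6 ⇒ K = 7 under valid convolution, and (162−6)/78 = 2 for the
    single non-overlapping max-pool.
    """
    spec = NetworkSpec(
        units=[
            UnitSpec(kind="conv", n_filters=128, in_channels=1, in_length=180),
            UnitSpec(kind="conv", n_filters=64),
            UnitSpec(kind="conv", n_filters=128),
            UnitSpec(kind="conv", n_filters=64, has_pool=True, pool_size=2),
            UnitSpec(kind="fc", n_filters=50),
        ],
        kernel_size=7,
        n_classes=50,
    )
    spec = infer_shapes(spec)
    # The derived constants are pinned to the published shape chain.
    expect = [(1, 180, 128, 174), (128, 174, 64, 168), (64, 168, 128, 162),
              (128, 162, 64, 78), (4992, 1, 50, 1)]
    got = [(u.in_channels, u.in_length, u.out_channels, u.out_length) for u in spec.units]
    assert got == expect, f"default architecture drifted: {got}"
    return spec
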