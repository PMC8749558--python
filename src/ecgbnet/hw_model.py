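"""Analytical model of the accelerator's memory, BRAM and schedule budget.

The accelerator holds everything on-chip: a parameters RAM with the whole
packed network, one input and one output feature-map RAM used in ping-pong
fashion, and one weights RAM per processing element (PE).  Each PE computes
one output feature map (one filter) per *session*; a layer with F filters
needs ceil(F / N_PEs) sessions, and parameter downloads for the next
session overlap execution of the current one (even/odd ping-pong), so each
PE's weight buffer must hold two filters.

Block RAMs are the 36 kb (36,864-bit) FPGA primitives; the parameters RAM
cascades them, the feature-map and weight RAMs use one each in the 512x72
configuration with 64 of the 72 bits carrying data.  The byte-addressable
SRAM of the host SoC uses the 4k x 9 configuration, one byte per word.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Tuple

from .model_spec import NetworkSpec, UnitSpec

__all__ = [
    "MemoryReport",
    "ScheduleReport",
    "BramPlan",
    "CapacityError",
    "BRAM_BITS",
    "memory_report",
    "schedule",
    "bram_plan",
    "sram_brams",
    "latency_budget",
    "meets_latency",
]

#: One FPGA block RAM, in bits ("36 kb" in the 1 kb = 1024 bit convention).
BRAM_BITS = 36 * 1024
#: Fixed BRAM overhead beside the PE weight RAMs: input + output fmap RAMs.
_FMAP_BRAMS = 2
#: Bytes per class score at the network output (32-bit values).
SCORE_BYTES = 4


class CapacityError(ValueError):
    """The plan does not fit in the available block RAMs."""


def _fmap_bytes(unit: UnitSpec, side: str) -> int:
    if side == "in":
        if unit.is_first:
            return unit.in_length  # 8-bit samples, one byte each
        if unit.kind == "fc":
            return unit.in_channels // 8
        return unit.in_channels * unit.in_length // 8
    if unit.is_last:
        return SCORE_BYTES * unit.n_filters
    return unit.out_channels * unit.out_length // 8


def filter_bytes(unit: UnitSpec) -> int:
    """Serialized size of one filter/neuron: packed words + threshold word."""
    return 8 * unit.words_per_filter + 8


@dataclass
class MemoryReport:
    """Per-unit and total byte accounting of feature maps and parameters."""

    unit_names: list
    input_fmap_bytes: list
    output_fmap_bytes: list
    param_bytes: list
    filter_bytes: list
    param_total_bytes: int
    max_fmap_bytes: int
    max_filter_bytes: int

    def to_dict(self) -> dict:
        return {
            "units": [
                {
                    "name": n,
                    "input_fmap_bytes": i,
                    "output_fmap_bytes": o,
                    "param_bytes": p,
                    "filter_bytes": f,
                }
                for n, i, o, p, f in zip(
                    self.unit_names, self.input_fmap_bytes,
                    self.output_fmap_bytes, self.param_bytes, self.filter_bytes)
            ],
            "param_total_bytes": self.param_total_bytes,
            "max_fmap_bytes": self.max_fmap_bytes,
            "max_filter_bytes": self.max_filter_bytes,
        }

    def render(self) -> str:
        head = f"{'Unit':<22}{'In fmap (B)':>12}{'Out fmap (B)':>13}" \
               f"{'Params (B)':>12}{'Filter (B)':>12}"
        lines = [head, "-" * len(head)]
        for n, i, o, p, f in zip(self.unit_names, self.input_fmap_bytes,
                                 self.output_fmap_bytes, self.param_bytes,
                                 self.filter_bytes):
            lines.append(f"{n:<22}{i:>12,}{o:>13,}{p:>12,}{f:>12,}")
        lines.append("-" * len(head))
        lines.append(f"{'Total params':<22}{'':>12}{'':>13}"
                     f"{self.param_total_bytes:>12,}{self.max_filter_bytes:>12,}")
        lines.append(f"Max fmap: {self.max_fmap_bytes:,} B  "
                     f"(two ping-pong buffers of at least this size)")
        return "\n".join(lines)


def memory_report(spec: NetworkSpec) -> MemoryReport:
    """Byte accounting of the packed network and its feature maps."""
    names, ins, outs, params, filts = [], [], [], [], []
    for i, u in enumerate(spec.units):
        kindname = "Conv" if u.kind == "conv" else "FC"
        names.append(f"{kindname} unit {i + 1}")
        ins.append(_fmap_bytes(u, "in"))
        outs.append(_fmap_bytes(u, "out"))
        fb = filter_bytes(u)
        filts.append(fb)
        params.append(u.n_filters * fb)
    return MemoryReport(
        unit_names=names,
        input_fmap_bytes=ins,
        output_fmap_bytes=outs,
        param_bytes=params,
        filter_bytes=filts,
        param_total_bytes=sum(params),
        max_fmap_bytes=max(ins + outs, default=0),
        max_filter_bytes=max(filts, default=0),
    )


@dataclass
class ScheduleReport:
    """Session counts for a given PE count, plus the PE weight-buffer bound."""

    n_pes: int
    unit_sessions: list
    total_sessions: int
    pe_weight_buffer_min_bytes: int

    def to_dict(self) -> dict:
        return {
            "n_pes": self.n_pes,
            "unit_sessions": list(self.unit_sessions),
            "total_sessions": self.total_sessions,
            "pe_weight_buffer_min_bytes": self.pe_weight_buffer_min_bytes,
        }

    def render(self) -> str:
        lines = [f"N_PEs = {self.n_pes}"]
        for i, s in enumerate(self.unit_sessions):
            lines.append(f"  unit {i + 1}: {s} session(s)")
        lines.append(f"  total: {self.total_sessions} sessions")
        lines.append(f"  PE weight buffer >= {self.pe_weight_buffer_min_bytes:,} B "
                     f"(two filters, ping-pong download)")
        return "\n".join(lines)

    def sessions(self) -> Iterator[Tuple[int, int, str]]:
        """Yield (unit index, session index, 'even'|'odd') in execution order.

        The parity drives the ping-pong parameter download: while the PEs
        execute an even session, the odd session's filters are downloaded,
        and vice versa.
        """
        for u, n in enumerate(self.unit_sessions):
            for s in range(n):
                yield u, s, ("even" if s % 2 == 0 else "odd")


def schedule(spec: NetworkSpec, n_pes: int) -> ScheduleReport:
    """Sessions per unit with ``n_pes`` PEs: ceil(n_filters / n_pes) each."""
    if n_pes < 1:
        raise ValueError("n_pes must be >= 1")
    per_unit = [math.ceil(u.n_filters / n_pes) for u in spec.units]
    rep = memory_report(spec)
    return ScheduleReport(
        n_pes=n_pes,
        unit_sessions=per_unit,
        total_sessions=sum(per_unit),
        pe_weight_buffer_min_bytes=2 * rep.max_filter_bytes,
    )


@dataclass
class BramPlan:
    """Block-RAM allocation: parameters, fmap buffers, one weights RAM per PE."""

    bram_bits: int
    params_brams: int
    input_brams: int
    output_brams: int
    weights_brams_per_pe: int
    max_pes: int
    available_brams: int

    def total_brams(self, n_pes: int) -> int:
        return (self.params_brams + self.input_brams + self.output_brams
                + self.weights_brams_per_pe * n_pes)

    def to_dict(self) -> dict:
        return {
            "bram_bits": self.bram_bits,
            "params_brams": self.params_brams,
            "input_brams": self.input_brams,
            "output_brams": self.output_brams,
            "weights_brams_per_pe": self.weights_brams_per_pe,
            "max_pes": self.max_pes,
            "available_brams": self.available_brams,
        }

    def render(self) -> str:
        fixed = self.params_brams + self.input_brams + self.output_brams
        return "\n".join([
            f"Parameters RAM : {self.params_brams} BRAM(s)",
            f"Input fmap RAM : {self.input_brams} BRAM (512x72, 64 bits used)",
            f"Output fmap RAM: {self.output_brams} BRAM (512x72, 64 bits used)",
            f"Weights RAM    : {self.weights_brams_per_pe} BRAM per PE",
            f"Total          : {fixed} + N_PEs BRAMs "
            f"(of {self.available_brams} available)",
            f"Max PEs        : {self.max_pes}",
        ])


def bram_plan(report: MemoryReport, available_brams: int = 50) -> BramPlan:
    """Allocate BRAMs for a memory report and derive the PE ceiling.

    The feature-map and per-PE weight RAMs each fit one 512x72 BRAM (the
    widest single-BRAM configuration; 64 of 72 bits used), so the PE count
    is capped at ``available - (params_brams + 2)``.
    """
    params_brams = math.ceil(report.param_total_bytes * 8 / BRAM_BITS)
    fixed = params_brams + _FMAP_BRAMS
    if fixed + 1 > available_brams:
        raise CapacityError(
            f"{fixed} fixed BRAMs + >=1 PE exceed the {available_brams} available"
        )
    if report.max_fmap_bytes * 8 > BRAM_BITS:
        raise CapacityError(
            f"feature map of {report.max_fmap_bytes} B exceeds one BRAM"
        )
    if 2 * report.max_filter_bytes * 8 > BRAM_BITS:
        raise CapacityError(
            f"double filter buffer of {2 * report.max_filter_bytes} B "
            f"exceeds one BRAM"
        )
    return BramPlan(
        bram_bits=BRAM_BITS,
        params_brams=params_brams,
        input_brams=1,
        output_brams=1,
        weights_brams_per_pe=1,
        max_pes=available_brams - fixed,
        available_brams=available_brams,
    )


def sram_brams(sram_bytes: int = 128 * 1024) -> int:
    """BRAMs needed for a byte-addressable SRAM in the 4k x 9 configuration.

    Each BRAM supplies 4096 one-byte words (the ninth bit is ignored), so a
    128 kB SRAM needs 128k / 4k = 32 BRAMs.
    """
    if sram_bytes <= 0:
        raise ValueError("sram_bytes must be > 0")
    return math.ceil(sram_bytes / 4096)


def latency_budget(beats: int = 3, bpm: float = 150.0) -> float:
    """Real-time identification budget in seconds: ``beats * 60 / bpm``.

    Identification needs a fixed number of consecutive beats; at the highest
    supported heart rate those arrive in this many seconds, so the whole
    pipeline must finish within it (default: 3 beats at 150 bpm = 1.2 s).
    """
    if bpm <= 0:
        raise ValueError("bpm must be > 0")
    return beats * 60.0 / bpm


def meets_latency(inference_seconds: float, beats: int = 3,
                  bpm: float = 150.0) -> bool:
    return inference_seconds <= latency_budget(beats, bpm)
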