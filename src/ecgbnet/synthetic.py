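"""Synthetic multi-subject ECG, beat segmentation and random network params.

Everything downstream — both inference engines, the parameter file, the
trainer — is exercised on data generated here, so no recordings need to be
downloaded.  A subject is a PQRST morphology template: five Gaussian bumps
(P, Q, R, S, T) with per-subject amplitudes, centers and widths drawn from
documented uniform ranges.  A recording repeats the template at jittered RR
intervals and adds white noise plus slow baseline wander.  Beats are cut as
180-sample windows with the R peak at sample 60, max-abs normalized and
quantized to signed 8-bit — the network's input format.

This generator makes no physiological-realism claims: it produces stable,
subject-distinctive morphologies suitable for testing an identification
pipeline, not clinical waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .model_spec import NetworkSpec
from .reference_engine import (
    BEAT_LEN,
    Beat,
    Direction,
    FoldedUnitParams,
    binarize_thresholded,
    conv1d_valid,
    maxpool,
    reference_forward,
)

__all__ = [
    "WAVE_NAMES",
    "SubjectTemplate",
    "ECGRecord",
    "generate_subject",
    "generate_recording",
    "detect_rpeaks",
    "segment_beats",
    "quantize_window",
    "random_params",
    "identify",
    "write_beats_csv",
    "read_beats_csv",
    "write_record_csv",
    "read_record_csv",
]

WAVE_NAMES = ("P", "Q", "R", "S", "T")
#: Window placement: the R peak sits at this sample of the 180-sample beat.
R_OFFSET = 60
DEFAULT_FS = 200.0

# Per-wave sampling ranges: (amplitude lo, hi), (center lo, hi) as a fraction
# of the RR interval relative to R, (width lo, hi) as a fraction of RR.
_WAVE_RANGES = {
    "P": ((0.08, 0.22), (-0.32, -0.22), (0.020, 0.035)),
    "Q": ((-0.20, -0.05), (-0.060, -0.035), (0.008, 0.014)),
    "R": ((0.90, 1.40), (-0.004, 0.004), (0.012, 0.022)),
    "S": ((-0.35, -0.10), (0.035, 0.060), (0.008, 0.014)),
    "T": ((0.15, 0.45), (0.22, 0.34), (0.035, 0.060)),
}


@dataclass
class SubjectTemplate:
    """One subject's beat morphology: five Gaussian waves plus a base rate."""

    amplitudes: dict
    centers: dict  # fraction of the RR interval, relative to the R peak
    widths: dict  # fraction of the RR interval
    heart_rate_bpm: float
    seed: int

    def __post_init__(self) -> None:
        if any(self.widths[w] <= 0 for w in WAVE_NAMES):
            raise ValueError("wave widths must be positive")
        r = abs(self.amplitudes["R"])
        if any(abs(self.amplitudes[w]) >= r for w in WAVE_NAMES if w != "R"):
            raise ValueError("R must be the largest wave")

    def wave_sum(self, t_frac: np.ndarray) -> np.ndarray:
        """Morphology at phases ``t_frac`` (fraction of RR, 0 = R peak)."""
        out = np.zeros_like(t_frac, dtype=np.float64)
        for w in WAVE_NAMES:
            a, c, s = self.amplitudes[w], self.centers[w], self.widths[w]
            out += a * np.exp(-0.5 * ((t_frac - c) / s) ** 2)
        return out


@dataclass
class ECGRecord:
    """A single-lead recording with ground-truth R-peak positions."""

    samples: np.ndarray
    sampling_rate: float
    subject_id: Optional[int]
    rpeak_positions: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.rpeak_positions = np.asarray(self.rpeak_positions, dtype=np.int64)
        if len(self.rpeak_positions) > 1 and not (np.diff(self.rpeak_positions) > 0).all():
            raise ValueError("rpeak positions must be strictly increasing")


def generate_subject(seed: int) -> SubjectTemplate:
    """Draw a deterministic subject template from the documented ranges."""
    rng = np.random.default_rng(seed)
    amps, centers, widths = {}, {}, {}
    for w in WAVE_NAMES:
        (alo, ahi), (clo, chi), (slo, shi) = _WAVE_RANGES[w]
        amps[w] = float(rng.uniform(alo, ahi))
        centers[w] = float(rng.uniform(clo, chi))
        widths[w] = float(rng.uniform(slo, shi))
    hr = float(rng.uniform(55.0, 90.0))
    return SubjectTemplate(amps, centers, widths, hr, seed)


def generate_recording(template: SubjectTemplate, duration_s: float = 30.0,
                       noise_sd: float = 0.02, hr_jitter: float = 0.04,
                       seed: int = 0, fs: float = DEFAULT_FS,
                       baseline_wander: float = 0.05) -> ECGRecord:
    """Repeat the template at jittered RR intervals; add noise and wander.

    ``hr_jitter`` is the relative s.d. of each RR interval; ``noise_sd`` the
    s.d. of the additive white noise in template amplitude units.  Baseline
    wander is a slow sinusoid (0.25 Hz, amplitude ``baseline_wander``) whose
    phase is drawn per recording.  Ground-truth R positions are recorded.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rr_mean = 60.0 / template.heart_rate_bpm
    rpeaks_t, t_r = [], rr_mean  # first R one mean interval in
    while t_r < duration_s - 0.2 * rr_mean:
        rpeaks_t.append(t_r)
        jitter = 1.0 + hr_jitter * rng.standard_normal() if hr_jitter > 0 else 1.0
        t_r += rr_mean * max(0.5, jitter)
    samples = np.zeros(n)
    for t_r in rpeaks_t:
        frac = (t - t_r) / rr_mean
        near = np.abs(frac) < 0.55  # one beat of support around each R
        samples[near] += template.wave_sum(frac[near])
    if noise_sd > 0:
        samples += noise_sd * rng.standard_normal(n)
    if baseline_wander > 0:
        phase = rng.uniform(0, 2 * np.pi)
        samples += baseline_wander * np.sin(2 * np.pi * 0.25 * t + phase)
    rpeaks = np.round(np.asarray(rpeaks_t) * fs).astype(np.int64)
    return ECGRecord(samples, fs, template.seed, rpeaks)


def detect_rpeaks(samples: np.ndarray, fs: float = DEFAULT_FS) -> np.ndarray:
    """Simple threshold-over-moving-average R detector for clean signals.

    Marks local maxima that exceed the moving average (0.75 s window) by
    half the global peak-to-average excursion, with a 0.3 s refractory
    period.  A stand-in for a real QRS detector; ground-truth positions are
    preferred when available.
    """
    x = np.asarray(samples, dtype=np.float64)
    win = max(3, int(0.75 * fs)) | 1
    kernel = np.ones(win) / win
    baseline = np.convolve(x, kernel, mode="same")
    excess = x - baseline
    thresh = 0.5 * excess.max()
    refractory = int(0.3 * fs)
    peaks, last = [], -refractory
    for i in range(1, len(x) - 1):
        if excess[i] >= thresh and excess[i] >= excess[i - 1] and excess[i] > excess[i + 1]:
            if i - last >= refractory:
                peaks.append(i)
                last = i
    return np.asarray(peaks, dtype=np.int64)


def quantize_window(window: np.ndarray) -> np.ndarray:
    """Max-abs normalize a real window and quantize to signed 8-bit.

    The largest absolute sample maps to 127; an all-zero window maps to
    zeros.  Round-half-to-even on the scaled values, so dequantization error
    is at most half a quantization step per sample.
    """
    window = np.asarray(window, dtype=np.float64)
    peak = np.abs(window).max()
    if peak == 0:
        return np.zeros(len(window), dtype=np.int8)
    return np.clip(np.rint(window / peak * 127), -128, 127).astype(np.int8)


def segment_beats(record: ECGRecord, use_detector: bool = False) -> List[Beat]:
    """Cut one 180-sample quantized beat window per R peak.

    The R peak lands at sample 60 of each window; windows that would run
    past either record edge are dropped.
    """
    if use_detector or len(record.rpeak_positions) == 0:
        rpeaks = detect_rpeaks(record.samples, record.sampling_rate)
    else:
        rpeaks = record.rpeak_positions
    beats = []
    n = len(record.samples)
    for r in rpeaks:
        lo = int(r) - R_OFFSET
        hi = lo + BEAT_LEN
        if lo < 0 or hi > n:
            continue
        beats.append(Beat(quantize_window(record.samples[lo:hi]),
                          subject_id=record.subject_id))
    return beats


def random_params(spec: NetworkSpec, seed: int = 0,
                  n_probe: int = 16) -> List[FoldedUnitParams]:
    """Random ±1 weights with activation-balancing thresholds.

    Weights are fair coin flips.  Thresholds are set unit by unit at the
    per-filter median accumulator observed on ``n_probe`` random 8-bit probe
    inputs propagated through the already-parameterized prefix, which keeps
    the +1 frequency of every hidden channel near one half instead of
    saturating.  The last unit gets the identity affine per class.
    """
    rng = np.random.default_rng(seed)
    first = spec.units[0]
    if first.kind == "conv":
        probe_shape = (n_probe, first.in_channels, first.in_length)
    else:
        probe_shape = (n_probe, 1, first.in_channels)
    probes = rng.integers(-128, 128, size=probe_shape).astype(np.int64)
    params: List[FoldedUnitParams] = []
    fmaps = probes
    for unit in spec.units:
        if unit.kind == "conv":
            shape = (unit.n_filters, unit.in_channels, unit.kernel_size)
        else:
            shape = (unit.n_filters, unit.in_channels)
        w = np.where(rng.random(shape) < 0.5, -1, 1).astype(np.int8)
        if unit.kind == "conv":
            accs = np.stack([conv1d_valid(f, w) for f in fmaps])
            if unit.has_pool:
                accs = np.stack([maxpool(a, unit.pool_size) for a in accs])
        else:
            flat = np.stack([f.T.reshape(-1) for f in fmaps])
            accs = (flat @ w.T.astype(np.int64))[:, :, np.newaxis]
        if unit.is_last:
            n = unit.n_filters
            p = FoldedUnitParams(w, gamma=np.ones(n), beta=np.zeros(n),
                                 mu=np.zeros(n), sigma=np.ones(n))
        else:
            tau = np.median(accs, axis=(0, 2)).astype(np.int64)
            dirs = np.full(unit.n_filters, Direction.GE, dtype=np.uint8)
            p = FoldedUnitParams(w, thresholds=tau, directions=dirs)
            fmaps = np.stack([
                binarize_thresholded(a, tau, dirs).astype(np.int64) for a in accs
            ])
        params.append(p)
    return params


def identify(spec: NetworkSpec, params: Sequence[FoldedUnitParams],
             beats: Sequence[Beat], n_beats: int = 3,
             forward=reference_forward) -> int:
    """Majority vote over the first ``n_beats`` beat-level predictions.

    Ties are broken toward the class with the highest mean score over the
    voted beats.  When every beat agrees this reduces to the per-beat
    arg-max.
    """
    if len(beats) < n_beats:
        raise ValueError(f"need at least {n_beats} beats, got {len(beats)}")
    votes, all_scores = [], []
    for beat in beats[:n_beats]:
        cls, scores = forward(spec, params, beat)
        votes.append(cls)
        all_scores.append(scores)
    counts = np.bincount(votes, minlength=spec.n_classes)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        return int(tied[0])
    mean_scores = np.mean(all_scores, axis=0)
    return int(tied[np.argmax(mean_scores[tied])])


# -- plain-text I/O ----------------------------------------------------------

def write_beats_csv(beats: Sequence[Beat], path) -> None:
    """One beat per row: label then 180 sample values (label -1 if unknown)."""
    with open(path, "w") as fh:
        for b in beats:
            label = -1 if b.subject_id is None else int(b.subject_id)
            fh.write(",".join([str(label)] + [str(int(s)) for s in b.samples]))
            fh.write("\n")


def read_beats_csv(path) -> List[Beat]:
    beats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            vals = [int(v) for v in line.split(",")]
            label = None if vals[0] < 0 else vals[0]
            beats.append(Beat(np.array(vals[1:], dtype=np.int8), subject_id=label))
    return beats


def write_record_csv(record: ECGRecord, path) -> None:
    """Header line with metadata, then one sample per line."""
    with open(path, "w") as fh:
        sid = -1 if record.subject_id is None else int(record.subject_id)
        rp = ";".join(str(int(r)) for r in record.rpeak_positions)
        fh.write(f"# fs={record.sampling_rate} subject={sid} rpeaks={rp}\n")
        for s in record.samples:
            fh.write(f"{s:.6f}\n")


def read_record_csv(path) -> ECGRecord:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("record CSV must start with a metadata header line")
        meta = dict(kv.split("=", 1) for kv in header[1:].split())
        samples = [float(line) for line in fh if line.strip()]
    sid = int(meta["subject"])
    rpeaks = [int(r) for r in meta["rpeaks"].split(";")] if meta["rpeaks"] else []
    return ECGRecord(np.array(samples), float(meta["fs"]),
                     None if sid < 0 else sid, np.array(rpeaks, dtype=np.int64))
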