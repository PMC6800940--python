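"""Heartbeat segmentation and QRS onset/offset localization.

A beat is the inclusive window [R-100, R+150] around a detected R peak
(251 samples at 360 Hz): local index 0 is taken as the start of the P wave,
100 is the R sample and 250 the end of the T wave.

QRS boundaries are found with a sliding window of m = 10 samples split into
two 5-sample halves.  Scanning right from shortly after the window start, an
index X_i is the QRS onset when the trailing half [X_i-4, X_i] is a
stationary baseline (its population variance S1 is below a flatness tolerance
and below the variance S2 of the leading half [X_i+1, X_i+5]) and the five
samples after X_i move strictly monotonically into the complex.  The offset
search runs from R toward the T wave with the mirrored predicate: five
strictly monotone samples leaving the complex followed by a stationary
baseline window.

The flatness tolerance is scale-free by default: a small fraction of the
largest 5-sample window variance seen anywhere in the beat, with an absolute
floor so an exactly flat beat is still judged flat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PRE_SAMPLES", "POST_SAMPLES", "BEAT_LENGTH", "R_LOCAL",
    "Heartbeat", "BoundarySearchConfig",
    "segment_beats", "variance", "find_qrs_start", "find_qrs_end",
    "localize_qrs",
]

PRE_SAMPLES = 100
POST_SAMPLES = 150
BEAT_LENGTH = PRE_SAMPLES + POST_SAMPLES + 1   # inclusive window => 251
R_LOCAL = PRE_SAMPLES


@dataclass
class Heartbeat:
    """One segmented beat with its fiducial points (local 0-based indices)."""

    samples: np.ndarray
    r_global: int
    r_local: int = R_LOCAL
    p_start: int = 0
    t_end: int = BEAT_LENGTH - 1
    qrs_start: int | None = None
    qrs_end: int | None = None
    qrs_fallback: bool = False
    label: bool | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size != BEAT_LENGTH:
            raise ValueError(f"a heartbeat holds {BEAT_LENGTH} samples, got {self.samples.size}")


@dataclass
class BoundarySearchConfig:
    m: int = 10                  # sliding-window size; halves of m // 2
    tau: float | None = None     # flatness tolerance in mV^2; None => scale-free
    rel_tau: float = 0.02        # fraction of the max half-window variance
    tau_floor: float = 1e-6      # absolute floor, mV^2
    monotone_run: int = 5        # strictly monotone samples entering/leaving the QRS
    start_offset: int = 4        # first scanned index after the window start
    fallback_halfwidth: int = 40  # ~111 ms at 360 Hz, used when the scan fails

    def __post_init__(self) -> None:
        if self.m % 2:
            raise ValueError("window size m must be even")
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be nonnegative")

    @property
    def half(self) -> int:
        return self.m // 2


def segment_beats(samples: np.ndarray, r_peaks: Sequence[int],
                  labels: Sequence[bool] | None = None) -> list[Heartbeat]:
    """Cut one beat per R peak whose full window lies inside the record.

    Peaks too close to either end are dropped (and logged); ``labels``, when
    given, must align with ``r_peaks``.
    """
    x = np.asarray(samples, dtype=np.float64)
    peaks = np.asarray(r_peaks, dtype=np.int64)
    if peaks.size > 1 and np.any(np.diff(peaks) <= 0):
        raise ValueError("r_peaks must be strictly increasing")
    out: list[Heartbeat] = []
    for k, r in enumerate(peaks):
        lo, hi = r - PRE_SAMPLES, r + POST_SAMPLES + 1
        if lo < 0 or hi > x.size:
            logger.info("dropping beat at sample %d: window [%d, %d) outside record", r, lo, hi)
            continue
        out.append(Heartbeat(samples=x[lo:hi].copy(), r_global=int(r),
                             label=None if labels is None else bool(labels[k])))
    return out


def variance(values: np.ndarray) -> float:
    """Population variance: mean squared deviation from the mean (divide by n)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("variance of an empty sequence is undefined")
    return float(np.mean((v - v.mean()) ** 2))


def _resolve_tau(beat: Heartbeat, config: BoundarySearchConfig) -> float:
    if config.tau is not None:
        return config.tau
    h = config.half
    x = beat.samples
    win = np.lib.stride_tricks.sliding_window_view(x, h)
    max_var = float(np.max(np.var(win, axis=1)))
    return max(config.rel_tau * max_var, config.tau_floor)


def _strictly_monotone(seg: np.ndarray) -> bool:
    d = np.diff(seg)
    return bool(np.all(d > 0) or np.all(d < 0))


def find_qrs_start(beat: Heartbeat, config: BoundarySearchConfig | None = None) -> int | None:
    """Scan [P_start, R] for the QRS onset; None when no index qualifies."""
    config = config or BoundarySearchConfig()
    x = beat.samples
    h = config.half
    tau = _resolve_tau(beat, config)
    lo = beat.p_start + config.start_offset
    hi = beat.r_local - (config.m - 2)          # i <= R - 8 for m = 10
    for i in range(lo, hi + 1):
        s1 = variance(x[i - h + 1: i + 1])      # [X_i-4, X_i]
        s2 = variance(x[i + 1: i + h + 1])      # [X_i+1, X_i+5]
        if s1 < s2 and s1 <= tau and _strictly_monotone(x[i: i + config.monotone_run + 1]):
            return i
    return None


def find_qrs_end(beat: Heartbeat, config: BoundarySearchConfig | None = None) -> int | None:
    """Scan [R, T_end] for the QRS offset; None when no index qualifies."""
    config = config or BoundarySearchConfig()
    x = beat.samples
    h = config.half
    tau = _resolve_tau(beat, config)
    lo = beat.r_local + h
    hi = beat.t_end - (h - 1)
    for j in range(lo, hi + 1):
        s1 = variance(x[j: j + h])              # [X_j, X_j+4]
        s2 = variance(x[j - h: j])              # [X_j-5, X_j-1]
        if s1 < s2 and s1 <= tau and _strictly_monotone(x[j - config.monotone_run: j + 1]):
            return j
    return None


def localize_qrs(beat: Heartbeat, config: BoundarySearchConfig | None = None) -> Heartbeat:
    """Set qrs_start/qrs_end on the beat, falling back to R -/+ 40 samples.

    The fallback (~111 ms half-width at 360 Hz) keeps every beat usable for
    feature extraction; it is flagged via ``qrs_fallback`` and logged.
    """
    config = config or BoundarySearchConfig()
    start = find_qrs_start(beat, config)
    end = find_qrs_end(beat, config)
    fallback = start is None or end is None
    if start is None:
        start = beat.r_local - config.fallback_halfwidth
    if end is None:
        end = beat.r_local + config.fallback_halfwidth
    if fallback:
        logger.info("QRS boundary fallback for beat at sample %d", beat.r_global)
    beat.qrs_start = int(start)
    beat.qrs_end = int(end)
    beat.qrs_fallback = fallback
    return beat
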