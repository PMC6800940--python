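"""Pan-Tompkins R-peak detection and detection scoring.

The classic stages — band-pass filter, derivative, squaring, moving-window
integration — feed an adaptive dual-threshold peak picker with running
signal/noise peak estimates (SPKI/NPKI), an 8-beat RR average with
search-back at half threshold when a beat is overdue, a 200 ms refractory
period, and optional T-wave rejection by slope comparison for candidates
arriving within 360 ms of the previous beat.

The original filters were derived for 200 Hz; here the band-pass is a 5-15 Hz
Butterworth designed at run time for the actual sampling rate, applied with
zero phase so every stage stays aligned with the input and detections can be
refined to the local extremum of the band-passed signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "DetectionScore",
    "pan_tompkins_stages",
    "detect_r_peaks",
    "score_detections",
    "match_beats",
]


@dataclass
class DetectionScore:
    """Beat-detection scoring against a reference annotation set."""

    all: int        # reference beats
    correct: int    # matched detections (true positives)
    wrong: int      # unmatched detections (false positives)
    missed: int     # unmatched references (false negatives)

    @property
    def se(self) -> float:
        return self.correct / self.all if self.all else float("nan")

    @property
    def ppv(self) -> float:
        det = self.correct + self.wrong
        return self.correct / det if det else float("nan")


def pan_tompkins_stages(signal: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    """Compute the four filter stages; all outputs are input-aligned.

    Returns a dict with keys ``bandpassed``, ``derivative``, ``squared`` and
    ``integrated``.  The integration window is round(0.150 * fs) samples.
    """
    x = np.asarray(signal, dtype=np.float64)
    if fs <= 0:
        raise ValueError("fs must be positive")
    win = max(int(round(0.150 * fs)), 1)
    if x.size < win:
        raise ValueError("signal shorter than the integration window")
    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    padlen = min(3 * 12, x.size - 1)
    bp = sps.sosfiltfilt(sos, x, padlen=padlen)
    # five-point derivative kernel, centered so stages remain aligned
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel, mode="same")
    squared = deriv * deriv
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")
    return {"bandpassed": bp, "derivative": deriv, "squared": squared,
            "integrated": integrated}


def _refine_peak(bp: np.ndarray, idx: int, half: int) -> int:
    lo, hi = max(idx - half, 0), min(idx + half + 1, bp.size)
    return lo + int(np.argmax(np.abs(bp[lo:hi])))


def detect_r_peaks(signal: np.ndarray, fs: float, *,
                   refractory_ms: float = 200.0,
                   reject_t_waves: bool = True) -> np.ndarray:
    """Detect R peaks; returns strictly increasing sample indices.

    Each accepted integrated-signal peak is refined to the largest-magnitude
    band-passed sample within +/-75 ms; two final detections are never closer
    than the refractory period.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("signal must be nonempty and finite")
    win = max(int(round(0.150 * fs)), 1)
    if x.size < max(win, 16):
        return np.array([], dtype=np.int64)
    stages = pan_tompkins_stages(x, fs)
    bp, deriv, mwi = stages["bandpassed"], stages["derivative"], stages["integrated"]

    refractory = int(round(refractory_ms / 1000.0 * fs))
    cands, _ = sps.find_peaks(mwi, distance=max(refractory, 1))
    if cands.size == 0:
        return np.array([], dtype=np.int64)

    # learning phase: initial estimates from the first two seconds
    head = mwi[: max(int(2 * fs), win)]
    spki = float(head.max())
    npki = float(head.mean()) * 0.5
    thr1 = npki + 0.25 * (spki - npki)

    slope_half = int(round(0.075 * fs))
    t_window = int(round(0.360 * fs))

    accepted: list[int] = []          # candidate indices of accepted beats
    rr_buf: list[float] = []

    def local_slope(i: int) -> float:
        lo, hi = max(i - slope_half, 0), min(i + slope_half + 1, deriv.size)
        return float(np.max(np.abs(deriv[lo:hi])))

    def accept(i: int, from_searchback: bool) -> None:
        nonlocal spki, npki, thr1
        peak = float(mwi[i])
        if from_searchback:
            spki = 0.25 * peak + 0.75 * spki
        else:
            spki = 0.125 * peak + 0.875 * spki
        if accepted:
            rr_buf.append(float(i - accepted[-1]))
            del rr_buf[:-8]
        accepted.append(i)
        thr1 = npki + 0.25 * (spki - npki)

    def mark_noise(i: int) -> None:
        nonlocal npki, thr1
        npki = 0.125 * float(mwi[i]) + 0.875 * npki
        thr1 = npki + 0.25 * (spki - npki)

    for pos, i in enumerate(cands):
        if mwi[i] > thr1:
            is_t_wave = False
            if reject_t_waves and accepted and (i - accepted[-1]) < t_window:
                # a T wave has a markedly gentler maximal slope than the QRS
                is_t_wave = local_slope(i) < 0.5 * local_slope(accepted[-1])
            if is_t_wave:
                mark_noise(i)
            else:
                accept(i, from_searchback=False)
        else:
            mark_noise(i)
            # search-back: if the expected beat is overdue, re-examine the
            # skipped candidates against half the threshold
            if rr_buf and accepted:
                rr_avg = float(np.mean(rr_buf))
                if (i - accepted[-1]) > 1.66 * rr_avg:
                    gap = [j for j in cands[:pos + 1]
                           if accepted[-1] + refractory < j <= i and mwi[j] > 0.5 * thr1]
                    if gap:
                        accept(max(gap, key=lambda j: mwi[j]), from_searchback=True)

    refined = sorted({_refine_peak(bp, i, slope_half) for i in accepted})
    # enforce the refractory period on the refined locations
    final: list[int] = []
    for r in refined:
        if final and r - final[-1] < refractory:
            if np.abs(bp[r]) > np.abs(bp[final[-1]]):
                final[-1] = r
        else:
            final.append(r)
    return np.asarray(final, dtype=np.int64)


def match_beats(detected: np.ndarray, reference: np.ndarray, fs: float,
                tolerance_ms: float = 150.0) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of sorted detections to sorted references.

    Walks both sequences left to right, pairing a detection with a reference
    whenever they fall within the tolerance; each side is used at most once.
    Returns (reference_position, detected_position) pairs.
    """
    det = np.asarray(detected, dtype=np.int64)
    ref = np.asarray(reference, dtype=np.int64)
    for arr, name in ((det, "detected"), (ref, "reference")):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} sequence is not sorted")
    tol = tolerance_ms / 1000.0 * fs
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < ref.size and j < det.size:
        d = det[j] - ref[i]
        if abs(d) <= tol:
            # prefer a closer later detection only if it cannot serve the
            # next reference better; plain pairing keeps the matching maximal
            pairs.append((i, j))
            i += 1
            j += 1
        elif d < 0:
            j += 1
        else:
            i += 1
    return pairs


def score_detections(detected: np.ndarray, reference: np.ndarray, fs: float,
                     tolerance_ms: float = 150.0) -> DetectionScore:
    """Score detections against references with the 150 ms matching rule."""
    det = np.asarray(detected, dtype=np.int64)
    ref = np.asarray(reference, dtype=np.int64)
    pairs = match_beats(det, ref, fs, tolerance_ms)
    correct = len(pairs)
    return DetectionScore(all=int(ref.size), correct=correct,
                          wrong=int(det.size) - correct,
                          missed=int(ref.size) - correct)
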