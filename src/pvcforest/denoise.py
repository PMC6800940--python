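"""Wavelet-domain ECG denoising.

The default pipeline decomposes the signal with the 8th-order Daubechies
wavelet (``db8``) to 5 levels, soft-thresholds the detail coefficients with
the universal threshold sigma*sqrt(2 ln n) (sigma estimated from the finest
detail level as median|d1|/0.6745), and reconstructs.  The periodization
boundary mode keeps the transform orthogonal, so coefficient energy equals
sample energy and soft thresholding can only shrink signal energy.

A small wavelet-selection helper ranks candidate bases by the peak absolute
normalized cross-correlation between the signal and each candidate's scaling
(low-pass decomposition) filter; the best-matching basis is the one whose
filter shape the signal locally resembles most.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

__all__ = ["DenoiseConfig", "denoise", "select_wavelet", "scaling_filter_correlation"]


@dataclass
class DenoiseConfig:
    wavelet: str = "db8"
    levels: int = 5
    threshold_rule: str = "universal"   # or "fixed"
    threshold_mode: str = "soft"        # or "hard"
    fixed_threshold: float = 0.0        # used when threshold_rule == "fixed"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_rule not in {"universal", "fixed"}:
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_mode not in {"soft", "hard"}:
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")


def denoise(signal: np.ndarray, config: DenoiseConfig | None = None) -> np.ndarray:
    """Denoise a 1-D signal by detail-coefficient thresholding.

    Output has the same length as the input.  The signal must be finite and
    at least ``2**levels`` samples long.
    """
    config = config or DenoiseConfig()
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if x.size < 2 ** config.levels:
        raise ValueError(
            f"signal of length {x.size} too short for {config.levels} decomposition levels"
        )
    coeffs = pywt.wavedec(x, config.wavelet, level=config.levels, mode="periodization")
    details = coeffs[1:]
    if config.threshold_rule == "universal":
        # noise scale from the finest detail level; robust to the QRS spikes
        sigma = np.median(np.abs(details[-1])) / 0.6745 if details[-1].size else 0.0
        thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
    else:
        thr = config.fixed_threshold
    if thr > 0:
        new_details = [pywt.threshold(d, thr, mode=config.threshold_mode) for d in details]
    else:
        new_details = list(details)   # nothing to shrink
    out = pywt.waverec([coeffs[0]] + new_details, config.wavelet, mode="periodization")
    return out[: x.size]


def scaling_filter_correlation(signal: np.ndarray, wavelet: str) -> np.ndarray:
    """Normalized cross-correlation of the signal with a wavelet's scaling filter.

    Returns one value per full-overlap lag: the dot product of the filter with
    the signal window, divided by the product of their Euclidean norms (0 for
    windows of negligible energy).  Values lie in [-1, 1].
    """
    x = np.asarray(signal, dtype=np.float64)
    h = np.asarray(pywt.Wavelet(wavelet).dec_lo, dtype=np.float64)
    m = h.size
    if x.size < m:
        raise ValueError(f"signal shorter than the {wavelet} scaling filter ({m} taps)")
    windows = np.lib.stride_tricks.sliding_window_view(x, m)
    dots = windows @ h
    norms = np.linalg.norm(windows, axis=1) * np.linalg.norm(h)
    out = np.zeros_like(dots)
    ok = norms > 1e-12
    out[ok] = dots[ok] / norms[ok]
    return out


def select_wavelet(signal: np.ndarray, candidates: Sequence[str]) -> str:
    """Pick the candidate wavelet whose scaling filter best matches the signal.

    The score of a candidate is the maximum absolute normalized
    cross-correlation over all lags; ties break toward the earlier candidate.
    """
    if not candidates:
        raise ValueError("candidate wavelet list is empty")
    best_name, best_score = None, -np.inf
    for name in candidates:
        score = float(np.max(np.abs(scaling_filter_correlation(signal, name))))
        if score > best_score:
            best_name, best_score = name, score
    assert best_name is not None
    return best_name
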