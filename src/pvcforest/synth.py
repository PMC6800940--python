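"""Synthetic two-class ECG generation with ground truth.

Three generators, all driven by one seeded RNG so output is bit-identical
across runs:

``generate_record``
    A 360 Hz single-lead stream of beats, each a sum of Gaussian bumps
    (P, Q, R, S, T).  PVC beats follow the textbook phenomenology: the P wave
    is suppressed, the QRS bumps are widened and taller (optionally
    sign-flipped), the preceding RR interval is shortened by a factor (default
    0.7) and the following compensatory pause preserves the 2*RR sum.  White
    noise, sinusoidal baseline wander and powerline interference are added
    after beat synthesis.  Ground-truth R locations and labels come back as
    beat annotations.

``generate_feature_table``
    Draws directly in the 4-D classifier feature space
    (pre_RR, post_RR, QRS_area, R_amp) from class-conditional Gaussians whose
    mean shifts encode the same phenomenology, with a controllable
    majority:minority ratio (13:1, 8:1, 4:1, 1:1 ...) and a global
    ``separation`` scale (0 = identical classes).

``generate_fiducial_beats``
    Piecewise-linear beats with exactly known QRS onset/offset (flat
    baseline, strictly linear flanks into and out of the R peak, smooth
    T bump), for auditing the boundary localizer against ground truth.

``write_wfdb`` emits a generated record as .hea / format-212 .dat / binary
and text annotations, consumable by :mod:`pvcforest.wfdb_io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import wfdb_io
from .beats import BEAT_LENGTH, R_LOCAL, Heartbeat
from .features import DEFAULT_SUBSET, LABEL_COLUMN
from .wfdb_io import BeatAnnotation, ECGRecord, RecordHeader, SignalSpec

__all__ = [
    "SynthConfig", "FeatureTableConfig",
    "generate_record", "generate_feature_table", "generate_fiducial_beats",
    "write_wfdb",
]

# Gaussian bump template for a normal beat: (amplitude mV, center s rel. R, width s)
_BEAT_TEMPLATE = {
    "P": (0.12, -0.18, 0.022),
    "Q": (-0.12, -0.030, 0.008),
    "R": (1.20, 0.0, 0.012),
    "S": (-0.18, 0.030, 0.008),
    "T": (0.30, 0.28, 0.045),
}


@dataclass
class SynthConfig:
    fs: float = 360.0
    n_beats: int = 300
    duration: float | None = None      # seconds; overrides n_beats when set
    mean_rr: float = 0.8               # 75 bpm
    rr_jitter: float = 0.04            # s, sd of the normal RR
    pvc_fraction: float = 0.1
    # PVC morphology knobs
    pvc_suppress_p: bool = True
    pvc_qrs_width: float = 2.5         # QRS bump width multiplier
    pvc_r_amp: float = 1.4             # QRS bump amplitude multiplier
    pvc_flip_r: bool = False           # negative-going PVC complexes
    pvc_pre_rr: float = 0.7            # preceding-RR shortening factor
    amp_jitter: float = 0.05           # per-beat multiplicative amplitude sd
    # additive noise
    white_sd: float = 0.01             # mV
    baseline_amp: float = 0.05         # mV
    baseline_freq: float = 0.33        # Hz (respiratory wander)
    powerline_amp: float = 0.01        # mV
    powerline_freq: float = 50.0       # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvc_fraction <= 1.0:
            raise ValueError("pvc_fraction must be in [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if min(self.pvc_qrs_width, self.pvc_r_amp, self.pvc_pre_rr) <= 0:
            raise ValueError("PVC morphology multipliers must be positive")


def _gauss(t: np.ndarray, amp: float, mu: float, sd: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)


def generate_record(config: SynthConfig | None = None,
                    ) -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Synthesize one labeled record; returns the record and ground truth."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    fs = config.fs

    n_beats = config.n_beats
    if config.duration is not None:
        # upper bound on beats that fit; surplus beats are trimmed below
        n_beats = int(np.ceil(config.duration / max(config.mean_rr * config.pvc_pre_rr, 0.2))) + 2

    # premature beats: Bernoulli marks, cleared at the edges and after another PVC
    is_pvc = rng.random(n_beats) < config.pvc_fraction
    if n_beats:
        is_pvc[0] = is_pvc[-1] = False
    for i in range(1, n_beats):
        if is_pvc[i] and is_pvc[i - 1]:
            is_pvc[i] = False

    # RR gaps; a PVC shortens its incoming gap and lengthens the outgoing one
    # so that the pair preserves 2 * nominal RR (compensatory pause)
    nominal = rng.normal(config.mean_rr, config.rr_jitter, size=max(n_beats - 1, 0))
    nominal = np.clip(nominal, 0.4 * config.mean_rr, 1.6 * config.mean_rr)
    gaps = nominal.copy()
    for i in range(1, n_beats):
        if is_pvc[i]:
            gaps[i - 1] = config.pvc_pre_rr * nominal[i - 1]
            if i < n_beats - 1:
                gaps[i] = (2.0 - config.pvc_pre_rr) * nominal[i - 1]
    r_times = 0.5 + np.concatenate([[0.0], np.cumsum(gaps)])

    if config.duration is not None:
        keep = r_times <= config.duration - 0.5
        r_times, is_pvc = r_times[keep], is_pvc[keep]
        n_samples = int(round(config.duration * fs))
    else:
        n_samples = int(np.ceil((r_times[-1] + 0.6) * fs)) if n_beats else int(fs)

    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)
    for rt, pvc in zip(r_times, is_pvc):
        scale = 1.0 + rng.normal(0.0, config.amp_jitter)
        for wave, (amp, mu, sd) in _BEAT_TEMPLATE.items():
            if pvc:
                if wave == "P" and config.pvc_suppress_p:
                    continue
                if wave in ("Q", "R", "S"):
                    amp = amp * config.pvc_r_amp * (-1.0 if config.pvc_flip_r else 1.0)
                    sd = sd * config.pvc_qrs_width
            lo = max(int((rt + mu - 6 * sd) * fs), 0)
            hi = min(int((rt + mu + 6 * sd) * fs) + 1, n_samples)
            if lo < hi:
                x[lo:hi] += _gauss(t[lo:hi], amp * scale, rt + mu, sd)

    if config.white_sd > 0:
        x += rng.normal(0.0, config.white_sd, size=n_samples)
    if config.baseline_amp > 0:
        x += config.baseline_amp * np.sin(
            2 * np.pi * config.baseline_freq * t + rng.uniform(0, 2 * np.pi))
    if config.powerline_amp > 0:
        x += config.powerline_amp * np.sin(
            2 * np.pi * config.powerline_freq * t + rng.uniform(0, 2 * np.pi))

    header = RecordHeader(
        record_name="synth", n_signals=1, fs=fs, n_samples=n_samples,
        signals=[SignalSpec(file_name="synth.dat", fmt=212, gain=200.0,
                            baseline=0, description="MLII")],
    )
    record = ECGRecord(header=header, lead="MLII", samples=x)
    anns = [wfdb_io.annotation_from_symbol(int(round(rt * fs)), "V" if pvc else "N")
            for rt, pvc in zip(r_times, is_pvc)]
    return record, anns


# ---------------------------------------------------------------------------
# Direct feature-space generator
# ---------------------------------------------------------------------------

# class-conditional Gaussians over (pre_RR, post_RR, QRS_area, R_amp);
# the PVC shifts mirror the morphology knobs: shortened pre_RR (x0.7),
# compensatory post_RR, wider+taller complex => larger area and amplitude.
_NORMAL_MEANS = np.array([0.80, 0.80, 0.10, 1.20])
_NORMAL_SDS = np.array([0.08, 0.08, 0.05, 0.30])
_PVC_MEANS = np.array([0.56, 1.00, 0.22, 1.65])
_PVC_SDS = np.array([0.08, 0.10, 0.09, 0.42])


@dataclass
class FeatureTableConfig:
    n: int = 7000
    ratio: float = 13.0        # majority:minority (non-PVC : PVC)
    separation: float = 1.0    # scales the PVC mean shift; 0 => null model
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.ratio <= 0:
            raise ValueError("need n >= 2 and a positive class ratio")


def generate_feature_table(config: FeatureTableConfig | None = None) -> pd.DataFrame:
    """Labeled 4-feature table from the class-conditional Gaussian model.

    Counts are exact: n_minority = round(n / (ratio + 1)).  Rows are shuffled;
    the label column is 1 for PVC.
    """
    config = config or FeatureTableConfig()
    rng = np.random.default_rng(config.seed)
    n_min = int(round(config.n / (config.ratio + 1.0)))
    n_maj = config.n - n_min
    pvc_means = _NORMAL_MEANS + config.separation * (_PVC_MEANS - _NORMAL_MEANS)
    X_maj = rng.normal(_NORMAL_MEANS, _NORMAL_SDS, size=(n_maj, 4))
    X_min = rng.normal(pvc_means, _PVC_SDS, size=(n_min, 4))
    X = np.vstack([X_maj, X_min])
    y = np.concatenate([np.zeros(n_maj, dtype=np.int64), np.ones(n_min, dtype=np.int64)])
    order = rng.permutation(config.n)
    df = pd.DataFrame(X[order], columns=list(DEFAULT_SUBSET))
    df[LABEL_COLUMN] = y[order]
    return df


def bayes_accuracy(config: FeatureTableConfig, n_mc: int = 200_000) -> float:
    """Monte-Carlo accuracy of the exact Gaussian likelihood-ratio classifier.

    An upper benchmark for any classifier trained on tables from
    :func:`generate_feature_table` (same priors and class-conditionals).
    """
    rng = np.random.default_rng(config.seed + 1)
    p_min = 1.0 / (config.ratio + 1.0)
    pvc_means = _NORMAL_MEANS + config.separation * (_PVC_MEANS - _NORMAL_MEANS)
    y = rng.random(n_mc) < p_min
    X = np.where(y[:, None],
                 rng.normal(pvc_means, _PVC_SDS, size=(n_mc, 4)),
                 rng.normal(_NORMAL_MEANS, _NORMAL_SDS, size=(n_mc, 4)))

    def loglik(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
        return np.sum(-0.5 * ((X - mu) / sd) ** 2 - np.log(sd), axis=1)

    post = (loglik(X, pvc_means, _PVC_SDS) + np.log(p_min)
            - loglik(X, _NORMAL_MEANS, _NORMAL_SDS) - np.log(1 - p_min))
    return float(np.mean((post > 0) == y))


# ---------------------------------------------------------------------------
# Boundary-localizer ground truth
# ---------------------------------------------------------------------------

def generate_fiducial_beats(n: int = 100, seed: int = 0,
                            ) -> list[tuple[Heartbeat, int, int]]:
    """Beats with exactly known QRS onset/offset.

    Each beat is flat baseline, a strictly linear rise from the onset to the
    R peak at local index 100, a strictly linear fall to the offset, flat
    again, then a smooth raised-cosine T bump.  Returns
    (beat, true_onset, true_offset) triples.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        onset = int(rng.integers(60, 91))
        offset = int(rng.integers(112, 146))
        amp = float(rng.uniform(0.8, 1.6))
        x = np.zeros(BEAT_LENGTH)
        x[onset:R_LOCAL + 1] = np.linspace(0.0, amp, R_LOCAL - onset + 1)
        x[R_LOCAL:offset + 1] = np.linspace(amp, 0.0, offset - R_LOCAL + 1)
        t_start = offset + int(rng.integers(10, 26))
        t_len = 60
        k = np.arange(t_len)
        x[t_start:t_start + t_len] += (0.25 * amp) * 0.5 * (1 - np.cos(2 * np.pi * k / t_len))
        out.append((Heartbeat(samples=x, r_global=R_LOCAL), onset, offset))
    return out


# ---------------------------------------------------------------------------
# WFDB output
# ---------------------------------------------------------------------------

def write_wfdb(record: ECGRecord, annotations: list[BeatAnnotation],
               directory: str | Path) -> dict[str, Path]:
    """Write a record as .hea + 212 .dat + binary .atr + text .txt annotations."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.header.record_name
    spec = record.header.signals[record.header.lead_index(record.lead)]
    raw = np.clip(np.round(record.samples * spec.gain + spec.baseline),
                  -2048, 2047).astype(np.int64)
    paths = {
        "hea": directory / f"{name}.hea",
        "dat": directory / f"{name}.dat",
        "atr": directory / f"{name}.atr",
        "txt": directory / f"{name}.txt",
    }
    wfdb_io.write_header(record.header, paths["hea"])
    wfdb_io.write_signal_212(paths["dat"], raw)
    wfdb_io.write_annotations(paths["atr"], annotations, dialect="mit_binary")
    wfdb_io.write_annotations(paths["txt"], annotations, dialect="text")
    return paths
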