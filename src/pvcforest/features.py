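"""Per-beat feature extraction.

Seven features per beat, none of them normalized (the downstream random
forest does not require standardized inputs):

=========  =======  ====================================================
name       units    definition
=========  =======  ====================================================
R_amp      mV       denoised amplitude at the R sample (sign preserved)
PR         s        (QRS_start - P_start) / fs
QRS        s        (QRS_end - QRS_start) / fs
QT         s        (T_end - QRS_start) / fs
QRS_area   mV.s     QRS * R_amp
pre_RR     s        (R_j - R_{j-1}) / fs
post_RR    s        (R_{j+1} - R_j) / fs
=========  =======  ====================================================

The first beat of a record has no preceding RR interval and the last has no
following one, so both are excluded from the feature table.  The default
classification subset is (pre_RR, post_RR, QRS_area, R_amp) — the four
features that individually discriminate PVC beats best.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .beats import Heartbeat

__all__ = [
    "FEATURE_NAMES", "DEFAULT_SUBSET",
    "beat_features", "rr_features", "feature_table", "select_subset",
]

FEATURE_NAMES: tuple[str, ...] = ("R_amp", "PR", "QRS", "QT", "QRS_area", "pre_RR", "post_RR")
DEFAULT_SUBSET: tuple[str, ...] = ("pre_RR", "post_RR", "QRS_area", "R_amp")
LABEL_COLUMN = "label"


def beat_features(beat: Heartbeat, fs: float = 360.0) -> dict[str, float]:
    """Morphological features of one beat (everything except the RR pair)."""
    if beat.qrs_start is None or beat.qrs_end is None:
        raise ValueError("beat fiducials are unset; run localize_qrs first")
    r_amp = float(beat.samples[beat.r_local])
    pr = (beat.qrs_start - beat.p_start) / fs
    qrs = (beat.qrs_end - beat.qrs_start) / fs
    qt = (beat.t_end - beat.qrs_start) / fs
    return {"R_amp": r_amp, "PR": pr, "QRS": qrs, "QT": qt, "QRS_area": qrs * r_amp}


def rr_features(r_peaks: Sequence[int], fs: float = 360.0) -> dict[int, tuple[float, float]]:
    """(pre_RR, post_RR) in seconds for every beat with both neighbours.

    Keyed by position in ``r_peaks``; positions 0 and n-1 are excluded.  Fewer
    than three peaks yields an empty result.
    """
    peaks = np.asarray(r_peaks, dtype=np.int64)
    if peaks.size > 1 and np.any(np.diff(peaks) <= 0):
        raise ValueError("r_peaks must be strictly increasing")
    if peaks.size < 3:
        import warnings
        warnings.warn("need at least 3 beats for RR features; returning none", stacklevel=2)
        return {}
    diffs = np.diff(peaks) / fs
    return {j: (float(diffs[j - 1]), float(diffs[j])) for j in range(1, peaks.size - 1)}


def feature_table(beats: Sequence[Heartbeat], r_peaks: Sequence[int],
                  fs: float = 360.0) -> pd.DataFrame:
    """Assemble the per-beat feature table (seven features + label).

    ``beats`` are matched to ``r_peaks`` by their global R sample; beats
    without both RR neighbours are dropped per the first/last exclusion rule.
    Labels may be None (unlabeled streams), emitted as a nullable column.
    """
    peaks = np.asarray(r_peaks, dtype=np.int64)
    rr = rr_features(peaks, fs)
    pos_of = {int(p): j for j, p in enumerate(peaks)}
    rows = []
    for b in beats:
        j = pos_of.get(b.r_global)
        if j is None or j not in rr:
            continue
        row = beat_features(b, fs)
        row["pre_RR"], row["post_RR"] = rr[j]
        row[LABEL_COLUMN] = b.label
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES) + [LABEL_COLUMN])
    return df


def select_subset(table: pd.DataFrame, names: Sequence[str] = DEFAULT_SUBSET) -> pd.DataFrame:
    """Project the feature table onto the named features (keeping the label)."""
    if len(names) == 0:
        raise ValueError("feature subset must be nonempty")
    unknown = [n for n in names if n not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature name(s) {unknown}; valid: {FEATURE_NAMES}")
    cols = list(names)
    if LABEL_COLUMN in table.columns:
        cols = cols + [LABEL_COLUMN]
    return table[cols].copy()
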