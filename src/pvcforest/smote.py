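"""Synthetic Minority Oversampling (SMOTE) for imbalanced beat tables.

New minority samples are interpolated between a minority point x and one of
its k nearest minority neighbours x': x_new = x + r * (x' - x) with
r ~ Uniform(0, 1), so every synthetic point lies componentwise between its
two parents.  Balancing to a target majority:minority ratio proceeds in two
stages: an integer magnification N (N synthetic points per minority sample)
covers the bulk, then residual points generated from randomly chosen minority
samples hit the target count exactly.  The majority class is never touched.

Randomness comes from one seeded generator; per synthetic sample the draw
order is (neighbour choice, interpolation coefficient r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SmoteConfig", "euclidean", "k_nearest", "synthesize", "balance", "parse_ratio"]


@dataclass
class SmoteConfig:
    k: int = 5                  # neighbours per minority sample
    target_ratio: float = 1.0   # desired majority:minority ratio (1.0 => 1:1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def parse_ratio(text: str) -> float:
    """Parse a 'maj:min' ratio string such as '4:1' into a float (4.0)."""
    parts = text.split(":")
    if len(parts) == 2:
        num, den = float(parts[0]), float(parts[1])
        if den <= 0:
            raise ValueError(f"invalid ratio {text!r}")
        return num / den
    return float(text)


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-dimension feature vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def k_nearest(x_index: int, S: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest members of S to S[x_index], excluding itself.

    Distance ties break by original index order (stable sort).
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} minority samples, have {n}")
    d = np.sqrt(np.sum((S - S[x_index]) ** 2, axis=1))
    d[x_index] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:k]


def synthesize(x: np.ndarray, x_prime: np.ndarray, r: float) -> np.ndarray:
    """Interpolated sample x + r * (x' - x); componentwise between parents."""
    x = np.asarray(x, dtype=np.float64)
    return x + r * (np.asarray(x_prime, dtype=np.float64) - x)


def balance(X: np.ndarray, y: np.ndarray,
            config: SmoteConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class of (X, y) to the configured ratio.

    Returns (X_aug, y_aug): the originals in input order followed by the
    synthetic minority samples.  Input that already meets the target is
    returned unchanged (as copies); single-class input is an error.
    """
    config = config or SmoteConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"balance requires exactly two classes, got {classes.size}")
    min_label = classes[np.argmin(counts)]
    n_min, n_maj = int(counts.min()), int(counts.max())
    target = int(round(n_maj / config.target_ratio))
    if n_min >= target:
        return X.copy(), y.copy()
    if n_min <= config.k:
        raise ValueError(f"minority class has {n_min} samples; k={config.k} requires more")

    S = X[y == min_label]
    rng = np.random.default_rng(config.seed)
    neighbours = np.stack([k_nearest(i, S, config.k) for i in range(n_min)])

    N = max(n_maj // (n_min * config.target_ratio) - 1, 0)
    N = int(N)
    synth: list[np.ndarray] = []

    def one_sample(i: int) -> np.ndarray:
        nb = neighbours[i][rng.integers(config.k)]
        r = rng.uniform(0.0, 1.0)
        return synthesize(S[i], S[nb], r)

    for _ in range(N):                      # N full passes over the minority set
        for i in range(n_min):
            synth.append(one_sample(i))
    residual = target - n_min * (N + 1)
    if residual > 0:
        picks = (rng.choice(n_min, size=residual, replace=False) if residual <= n_min
                 else rng.integers(0, n_min, size=residual))
        for i in picks:
            synth.append(one_sample(int(i)))

    X_aug = np.vstack([X] + [np.asarray(synth)]) if synth else X.copy()
    y_aug = np.concatenate([y, np.full(len(synth), min_label, dtype=y.dtype)])
    return X_aug, y_aug
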