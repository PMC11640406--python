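"""Transition-table feature extraction.

The transformed signal is a sequence over the alphabet 1..12; its first-order
transition counts form a 12×12 matrix (total count 12·L − 1 per beat).  Rows
are normalized to empirical transition probabilities with an additive epsilon
in the denominator (all-zero rows stay zero), and the matrix is flattened
row-major into a 144-dimensional feature vector: feature u (1-based) holds
cell (ceil(u/12), ((u−1) mod 12) + 1), i.e. from-lead = row, to-lead = column.

Within an aligned 12-block a value never repeats, so diagonal cells can only
be populated by transitions across sample boundaries.
"""

from __future__ import annotations

import numpy as np

from .synthetic import N_LEADS, BeatSet
from .transform import transform_beat

#: Default denominator guard for row normalization; invisible at beat-length
#: counts but keeps all-zero rows at zero.
DEFAULT_EPSILON = 1e-10

N_FEATURES = N_LEADS * N_LEADS


def count_transitions(tr: np.ndarray) -> np.ndarray:
    """12×12 integer matrix of consecutive-pair counts in a transformed signal.

    ``mat[a-1, b-1]`` counts positions j with tr[j] = a followed by tr[j+1] = b,
    including pairs that straddle aligned 12-block boundaries.
    """
    tr = np.asarray(tr)
    if tr.ndim != 1 or tr.size < 2:
        raise ValueError("transformed signal must be 1-D with at least 2 entries")
    if tr.min() < 1 or tr.max() > N_LEADS:
        raise ValueError(f"transformed signal values must lie in 1..{N_LEADS}")
    mat = np.zeros((N_LEADS, N_LEADS), dtype=np.int64)
    np.add.at(mat, (tr[:-1] - 1, tr[1:] - 1), 1)
    return mat


def normalize_rows(mat: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Row-wise normalization mat[k,:] / (sum(mat[k,:]) + epsilon)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mat = np.asarray(mat, dtype=float)
    row_sums = mat.sum(axis=1, keepdims=True)
    return mat / (row_sums + epsilon)


def flatten(matn: np.ndarray) -> np.ndarray:
    """Row-major flatten of the 12×12 matrix to the 144-feature vector."""
    matn = np.asarray(matn)
    if matn.shape != (N_LEADS, N_LEADS):
        raise ValueError(f"expected a {N_LEADS}x{N_LEADS} matrix, got {matn.shape}")
    return matn.ravel().copy()


def unflatten(fv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten`."""
    fv = np.asarray(fv)
    if fv.shape != (N_FEATURES,):
        raise ValueError(f"expected {N_FEATURES} features, got {fv.shape}")
    return fv.reshape(N_LEADS, N_LEADS).copy()


def beat_features(beat: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Full per-beat feature path: transform, count, normalize, flatten."""
    return flatten(normalize_rows(count_transitions(transform_beat(beat)), epsilon))


def extract_features(
    beats: BeatSet, epsilon: float = DEFAULT_EPSILON
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix X (n_beats × 144) and aligned labels y for a beat set."""
    X = np.empty((beats.n_beats, N_FEATURES), dtype=float)
    for n in range(beats.n_beats):
        X[n] = beat_features(beats.signals[n], epsilon)
    return X, beats.labels.copy()
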