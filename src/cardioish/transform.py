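"""Lead-rank transform: amplitudes -> descending-amplitude lead-index sequence.

At each of the L samples the 12 lead amplitudes are replaced by the
permutation of lead indexes (1..12) sorted by strictly descending amplitude,
and the L permutations are concatenated into one integer sequence of length
12·L.  The encoding is rank-only: invariant to positive rescaling of the
whole beat and to any per-sample constant added to all leads.

Ties are broken by the lower lead index (stable sort on the negated
amplitudes), which makes the transform deterministic on degenerate input
such as an all-zero sample.
"""

from __future__ import annotations

import numpy as np

from .synthetic import N_LEADS


def rank_block(block: np.ndarray) -> np.ndarray:
    """Rank one 12-value lead block: 1-based lead indexes by descending amplitude."""
    block = np.asarray(block, dtype=float)
    if block.shape != (N_LEADS,):
        raise ValueError(f"a lead block holds exactly {N_LEADS} values, got {block.shape}")
    if not np.all(np.isfinite(block)):
        raise ValueError("non-finite amplitude in lead block")
    return np.argsort(-block, kind="stable") + 1


def transform_beat(beat: np.ndarray) -> np.ndarray:
    """Transform a 12×L beat into its length-12L lead-index sequence.

    Positions 12m..12m+11 (0-based) hold the descending-amplitude ranking of
    sample m, so every aligned 12-block is a permutation of 1..12.
    """
    beat = np.asarray(beat, dtype=float)
    if beat.ndim != 2 or beat.shape[0] != N_LEADS:
        raise ValueError(f"beat must be ({N_LEADS}, L), got {beat.shape}")
    if beat.shape[1] < 1:
        raise ValueError("beat must have at least one sample")
    if not np.all(np.isfinite(beat)):
        raise ValueError("non-finite amplitude in beat")
    # argsort each column of -beat; stable so equal amplitudes keep lead order
    order = np.argsort(-beat, axis=0, kind="stable")  # (12, L), 0-based lead ids
    return (order.T + 1).ravel()
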