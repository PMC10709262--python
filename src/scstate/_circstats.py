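"""Small circular-statistics helpers."""

from __future__ import annotations

import numpy as np


def circular_mean(angles: np.ndarray) -> float:
    a = np.asarray(angles, dtype=float)
    return float(np.arctan2(np.sin(a).mean(), np.cos(a).mean()) % (2.0 * np.pi))


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular correlation coefficient.

    r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j)
        / sqrt(sum sin^2(a_i - a_j) * sum sin^2(b_i - b_j))

    Lies in [-1, 1]; invariant under rotation of either variable, sign flips
    under reflection.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    da = np.sin(a[:, None] - a[None, :])
    db = np.sin(b[:, None] - b[None, :])
    num = np.sum(np.triu(da * db, 1))
    den = np.sqrt(np.sum(np.triu(da**2, 1)) * np.sum(np.triu(db**2, 1)))
    if den == 0.0:
        return 0.0
    return float(num / den)


__all__ = ["circular_mean", "circular_correlation"]
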