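"""Entropy, information gain, and gain-ratio threshold search.

Shared by the cohort screening step (entropy-gain ranking of features) and
the tree builder (gain-ratio cut-offs for continuous features).  All
entropies are in bits (base 2).
"""

from __future__ import annotations

import numpy as np

__all__ = ["entropy_bits", "information_gain_discrete", "gain_ratio_threshold"]


def entropy_bits(labels: np.ndarray) -> float:
    """Shannon entropy H(y) in bits of a label array."""
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain_discrete(values: np.ndarray, labels: np.ndarray) -> float:
    """H(y) - sum_v p(v) H(y | value = v) for a discrete feature column."""
    if len(values) != len(labels):
        raise ValueError(
            f"length mismatch: {len(values)} values vs {len(labels)} labels"
        )
    total = len(labels)
    h = entropy_bits(labels)
    cond = 0.0
    for v in np.unique(values):
        mask = values == v
        cond += mask.sum() / total * entropy_bits(labels[mask])
    # clip tiny negative round-off
    return max(0.0, h - cond)


def gain_ratio_threshold(
    values: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Best threshold t (and its gain ratio) for the binary split value < t.

    Candidates are midpoints between consecutive sorted distinct values.  The
    gain ratio is information gain divided by the split entropy; ties are
    broken toward the smallest threshold.

    Raises ``ValueError`` when all values are equal (no split exists) or when
    no candidate has positive split information.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError(
            f"length mismatch: {len(values)} values vs {len(labels)} labels"
        )
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("cannot split a constant column")
    total = len(labels)
    h = entropy_bits(labels)
    best_t, best_ratio = None, -np.inf
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        t = (lo + hi) / 2.0
        mask = values < t
        n_lo = int(mask.sum())
        p_lo = n_lo / total
        p_hi = 1.0 - p_lo
        split_info = -(p_lo * np.log2(p_lo) + p_hi * np.log2(p_hi))
        gain = h - (p_lo * entropy_bits(labels[mask]) + p_hi * entropy_bits(labels[~mask]))
        ratio = gain / split_info
        if ratio > best_ratio + 1e-12:  # strict improvement; ties keep smallest t
            best_ratio, best_t = ratio, t
    return float(best_t), float(best_ratio)
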