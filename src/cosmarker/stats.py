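"""Core test statistics for marker-gene detection.

An ideal marker gene (MG) of subtype ``k`` is expressed only in subtype
``k`` and (near) zero everywhere else, so its cross-subtype mean-expression
pattern ``s = (s_1, ..., s_K)`` is proportional to the Cartesian unit vector
``e_k``.  The one-sample test statistic used throughout this package is the
cosine similarity between ``s`` and its best-matching unit vector,

    t = max_k cos(s, e_k) = max_k s_k / ||s||_2,

which equals 1 exactly for an ideal MG and is bounded below by 1/sqrt(K)
(attained by the constant pattern) on the non-negative orthant.

Also provided:

* a per-subtype variant ``cos(s, e_k) = s_k / ||s||_2`` used for
  subtype-specific nulls and subtype-signature scoring,
* a complementary statistic for subtype-downregulated genes (silent in one
  subtype, expressed in all others),
* the P1 marker-quality index (0 for an ideal MG set, 1 for maximally
  non-specific rows).

All argmax ties break toward the lowest subtype index so results are
deterministic.  Scores are invariant to positive rescaling of ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MgQuality",
    "cot_score",
    "cot_score_for_subtype",
    "cot_scores",
    "p1_index",
    "relative_reduction",
    "sdg_score",
    "sdg_scores",
    "subtype_scores",
]


@dataclass(frozen=True)
class MgQuality:
    """P1 marker-quality summary for a set of M candidate MG rows."""

    p1: float
    m: int
    k: int


def _validate_pattern(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("pattern must be a 1-D vector with K >= 2 entries")
    if np.any(s < 0):
        raise ValueError("pattern has negative entries; expression must be non-negative")
    if not np.any(s > 0):
        raise ValueError("zero pattern: cosine score is undefined")
    if not np.all(np.isfinite(s)):
        raise ValueError("pattern has non-finite entries")
    # scale by the max so norms neither overflow nor underflow; the cosine
    # is scale-invariant so this changes nothing mathematically
    return s / s.max()


def cot_score(s) -> tuple[int, float]:
    """Cosine score of one cross-subtype pattern.

    Returns ``(k_hat, t)`` where ``t = max_k s_k / ||s||_2`` and ``k_hat``
    is the 0-based index attaining the maximum (lowest index on ties).
    """
    s = _validate_pattern(s)
    cosines = s / np.linalg.norm(s)
    k_hat = int(np.argmax(cosines))
    return k_hat, float(cosines[k_hat])


def cot_score_for_subtype(s, k: int) -> float:
    """Cosine of a pattern against the unit vector of one given subtype.

    This is the subtype-specific statistic ``s_k / ||s||_2`` (no argmax),
    used for subtype-signature scoring and per-subtype null distributions.
    """
    s = _validate_pattern(s)
    if not 0 <= k < s.size:
        raise ValueError(f"subtype index {k} out of range for K={s.size}")
    return float(s[k] / np.linalg.norm(s))


def sdg_score(s) -> tuple[int, float]:
    """Score of a pattern against the ideal subtype-downregulated gene.

    An ideal SDG of subtype ``k`` is silent in ``k`` and uniformly expressed
    elsewhere, i.e. proportional to the complement-of-``k`` indicator.  The
    statistic is the cosine against that reference,

        t = max_k sum_{j != k} s_j / (sqrt(K-1) * ||s||_2),

    equal to 1 iff ``s`` is constant off ``k`` and zero at ``k``.
    """
    s = _validate_pattern(s)
    norm = np.linalg.norm(s)
    scores = (s.sum() - s) / (np.sqrt(s.size - 1) * norm)
    k_hat = int(np.argmax(scores))
    return k_hat, float(scores[k_hat])


def cot_scores(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`cot_score` over the rows of a features x K matrix."""
    patterns = _validate_matrix(patterns)
    norms = np.linalg.norm(patterns, axis=1)
    cosines = patterns / norms[:, None]
    k_hat = np.argmax(cosines, axis=1)
    return k_hat, cosines[np.arange(len(patterns)), k_hat]


def subtype_scores(patterns: np.ndarray, k: int) -> np.ndarray:
    """Vectorized :func:`cot_score_for_subtype` over rows."""
    patterns = _validate_matrix(patterns)
    if not 0 <= k < patterns.shape[1]:
        raise ValueError(f"subtype index {k} out of range for K={patterns.shape[1]}")
    return patterns[:, k] / np.linalg.norm(patterns, axis=1)


def sdg_scores(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`sdg_score` over rows."""
    patterns = _validate_matrix(patterns)
    norms = np.linalg.norm(patterns, axis=1)
    k = patterns.shape[1]
    scores = (patterns.sum(axis=1)[:, None] - patterns) / (np.sqrt(k - 1) * norms[:, None])
    k_hat = np.argmax(scores, axis=1)
    return k_hat, scores[np.arange(len(patterns)), k_hat]


def _validate_matrix(patterns: np.ndarray) -> np.ndarray:
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise ValueError("expected a 2-D matrix with K >= 2 columns")
    if np.any(patterns < 0):
        raise ValueError("negative entries; expression must be non-negative")
    if np.any(~np.any(patterns > 0, axis=1)):
        bad = np.flatnonzero(~np.any(patterns > 0, axis=1))
        raise ValueError(f"all-zero rows at positions {bad[:10].tolist()}")
    return patterns / patterns.max(axis=1, keepdims=True)


def p1_index(mg_profiles: np.ndarray) -> MgQuality:
    """Marker-quality index of an M x K matrix of candidate MG patterns.

        P1 = 1/(M(K-1)) * sum_i [ sum_j s_j(i) / max_k s_k(i) - 1 ]

    P1 = 0 iff every row is a scaled unit vector (the ideal MG set) and
    P1 = 1 iff every row is constant (no subtype specificity at all).
    """
    mg = _validate_matrix(mg_profiles)
    m, k = mg.shape
    contributions = mg.sum(axis=1) / mg.max(axis=1) - 1.0
    return MgQuality(p1=float(contributions.sum() / (m * (k - 1))), m=m, k=k)


def relative_reduction(p1_ref: float, p1_new: float) -> float:
    """Percent reduction of a quality index relative to a reference value."""
    if p1_ref <= 0:
        raise ValueError("reference index must be positive")
    return 100.0 * (p1_ref - p1_new) / p1_ref
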