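"""Shared numeric helpers: rank arithmetic, tie counting, RNG plumbing.

The ``>`` / ``=`` / ``>=`` comparisons used by every test and p-value
formula are centralized in :func:`tail_counts` so the conventions cannot
drift between modules.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["as_rng", "rank_threshold", "tail_counts", "order_statistic"]


def as_rng(seed_or_rng: "int | np.random.Generator | None") -> np.random.Generator:
    """Return a ``numpy.random.Generator``, building one from a seed if needed."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _floor_exact(x: float) -> int:
    # floor that is immune to cases like 0.05 * 720 == 36.000000000000007
    r = round(x)
    if abs(x - r) <= 1e-9 * max(1.0, abs(x)):
        return int(r)
    return math.floor(x)


def rank_threshold(alpha: float, n: int) -> int:
    """Rank ``k = ceil((1 - alpha) * n)`` for ``alpha in [0, 1)``.

    Computed as ``n - floor(alpha * n)`` (an exact identity) to avoid
    floating-point ceil artifacts.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha!r}")
    if n < 1:
        raise ValueError(f"need at least one statistic, got n={n}")
    return n - _floor_exact(alpha * n)


def order_statistic(stats: np.ndarray, k: int) -> float:
    """The k-th smallest value (1-based) of ``stats``."""
    stats = np.asarray(stats)
    if not 1 <= k <= stats.size:
        raise ValueError(f"rank {k} out of range for {stats.size} statistics")
    return float(np.partition(stats, k - 1)[k - 1])


def tail_counts(stats: np.ndarray, ref: float, tol: float = 0.0) -> "tuple[int, int]":
    """Counts ``(#{s > ref}, #{s == ref})`` with optional absolute tolerance.

    ``tol=0`` means bit-exact comparison, appropriate for permutation and
    sign-flip actions where tied statistics are exactly equal. A positive
    ``tol`` is for rotation designs where recomposition introduces rounding.
    """
    stats = np.asarray(stats)
    if tol == 0.0:
        greater = int(np.count_nonzero(stats > ref))
        equal = int(np.count_nonzero(stats == ref))
    else:
        greater = int(np.count_nonzero(stats > ref + tol))
        equal = int(np.count_nonzero(np.abs(stats - ref) <= tol))
    return greater, equal
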