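"""P-value constructions for full-group and random-transformation tests.

Comparison conventions, exactly as the formulas are stated: the counts ``D``
and ``B`` use ``>=``; the rejection rules use strict ``>``; the randomized
p-value splits into a strict part and a ``u``-weighted tie part. All counts
go through :func:`permtest._util.tail_counts`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from ._util import as_rng, tail_counts
from .transform_groups import DrawnVector, TransformationSet
from .perm_tests import _require_group, _set_observed, _set_statistics

__all__ = [
    "PValueReport",
    "full_group_pvalue",
    "count_B",
    "pvalue_plus_one",
    "pvalue_naive",
    "randomized_pvalue",
    "pvalue_upper",
    "report_from_draws",
]

logger = logging.getLogger("permtest")


@dataclass
class PValueReport:
    """All p-value representations computed from one set of draws.

    ``B`` counts ``>=``-exceedances over the *random* draws only
    (``identity_included=False``); the identity's guaranteed exceedance is
    what the ``+1`` corrections add back.
    """

    w: int
    D: "int | None" = None
    B: "int | None" = None
    p_full: "float | None" = None
    p_naive: "float | None" = None
    naive_flag: str = "not_valid_alone"
    p_plus_one: "float | None" = None
    p_randomized: "float | None" = None
    p_upper: "float | None" = None
    u: "float | None" = None
    identity_included: "bool | None" = None
    seed_record: "dict | None" = None

    def __post_init__(self) -> None:
        for name in ("p_full", "p_naive", "p_plus_one", "p_randomized", "p_upper"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} is outside [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


def full_group_pvalue(
    x: np.ndarray,
    G: TransformationSet,
    T,
    *,
    allow_nongroup: bool = False,
    tol: float = 0.0,
) -> PValueReport:
    """The classical permutation p-value ``D / #G`` over a certified group,
    with ``D = #{g in G: T(gX) >= T(X)}`` (a weak p-value always; a strict
    one under the equal-class condition)."""
    _require_group(G, allow_nongroup)
    x = np.asarray(x)
    stats = _set_statistics(x, G, T)
    observed = _set_observed(stats, x, G, T)
    greater, equal = tail_counts(stats, observed, tol)
    D = greater + equal
    n = len(G)
    return PValueReport(
        w=n, D=D, p_full=D / n, p_upper=D / n, identity_included=True
    )


def _stats_of(x: np.ndarray, draws, T) -> np.ndarray:
    if isinstance(draws, (DrawnVector, TransformationSet)):
        transformed = draws.apply_all(np.asarray(x))
        return np.asarray(T(transformed), dtype=float)
    stats = [float(T(g.apply(np.asarray(x)))) for g in draws]
    return np.asarray(stats, dtype=float)


def count_B(x: np.ndarray, draws, T, *, tol: float = 0.0) -> int:
    """``B = #{1 <= j <= w: T(g_j X) >= T(X)}`` over the provided draws.

    Whether the identity is among the draws is the caller's choice; the
    report-building helpers record it.
    """
    stats = _stats_of(x, draws, T)
    if stats.size == 0:
        raise ValueError("draws must be nonempty")
    greater, equal = tail_counts(stats, float(T(np.asarray(x))), tol)
    return greater + equal


def pvalue_plus_one(b: int, w: int) -> float:
    """``(b + 1) / (w + 1)``: a valid (weak) p-value whenever the ``w`` draws
    are uniform on the group (with replacement) or on distinct non-identity
    classes (without replacement), the identity being the ``+1``."""
    if not 0 <= b <= w:
        raise ValueError(f"need 0 <= b <= w, got b={b}, w={w}")
    return (b + 1) / (w + 1)


def pvalue_naive(b: int, w: int) -> float:
    """``b / w``: an unbiased estimate of the full-group p-value that is NOT
    itself a valid p-value (it has positive mass at 0). A structured warning
    is emitted on every call."""
    if w < 1:
        raise ValueError("w must be at least 1")
    if not 0 <= b <= w:
        raise ValueError(f"need 0 <= b <= w, got b={b}, w={w}")
    logger.warning(
        "the naive estimate B/w is not a valid p-value on its own "
        "(positive mass at 0); prefer (B+1)/(w+1)",
        extra={"code": "NAIVE_P"},
    )
    return b / w


def randomized_pvalue(x: np.ndarray, Gdrawn: DrawnVector, T, u: float, *, tol: float = 0.0) -> float:
    """The randomized p-value
    ``p' = #{T(g_j X) > T(X)}/w + u * #{T(g_j X) = T(X)}/w``
    over an identity-first transformation vector. Exactly uniform on [0, 1]
    under the invariance null; ``p' <= alpha`` iff the boundary-randomized
    test with the same ``u`` rejects."""
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must be in [0, 1], got {u}")
    Gdrawn.assert_identity_first()
    stats = _stats_of(x, Gdrawn, T)
    observed = float(stats[0])
    greater, equal = tail_counts(stats, observed, tol)
    return greater / Gdrawn.w + u * equal / Gdrawn.w


def pvalue_upper(x: np.ndarray, Gdrawn: DrawnVector, T, *, tol: float = 0.0) -> float:
    """Upper bound for the randomized p-value: ``#{T(g_j X) >= T(X)} / w``
    over the whole vector ``g_1..g_w`` (identity included).

    When the vector is the identity adjoined to ``w - 1`` random draws this
    equals ``(B + 1) / ((w - 1) + 1)``, i.e. the ``+1`` correction.
    """
    Gdrawn.assert_identity_first()
    stats = _stats_of(x, Gdrawn, T)
    observed = float(stats[0])
    greater, equal = tail_counts(stats, observed, tol)
    return (greater + equal) / Gdrawn.w


def report_from_draws(
    x: np.ndarray,
    Gdrawn: DrawnVector,
    T,
    *,
    u: "float | None" = None,
    rng: "np.random.Generator | int | None" = None,
    include_naive: bool = False,
    tol: float = 0.0,
) -> PValueReport:
    """Assemble every p-value representation from one identity-first vector.

    ``B`` is counted over the ``w - 1`` random draws; ``p_plus_one`` adjoins
    the identity as the ``+1`` (and therefore coincides with ``p_upper``).
    ``p_randomized`` is computed when ``u`` is given or an ``rng`` is
    provided to draw it.
    """
    Gdrawn.assert_identity_first()
    stats = _stats_of(x, Gdrawn, T)
    observed = float(stats[0])
    w = Gdrawn.w
    greater, equal = tail_counts(stats, observed, tol)
    geq_all = greater + equal
    b_random = geq_all - 1  # remove the identity's own >= count
    p_upper = geq_all / w
    p_plus = pvalue_plus_one(b_random, w - 1) if w > 1 else 1.0
    p_naive = None
    if include_naive:
        p_naive = pvalue_naive(b_random, w - 1) if w > 1 else None
    p_rand = None
    if u is None and rng is not None:
        u = float(as_rng(rng).random())
    if u is not None:
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"u must be in [0, 1], got {u}")
        p_rand = greater / w + u * equal / w
    return PValueReport(
        w=w,
        B=b_random,
        p_naive=p_naive,
        p_plus_one=p_plus,
        p_randomized=p_rand,
        p_upper=p_upper,
        u=u,
        identity_included=False,
        seed_record=Gdrawn.seed_record,
    )
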