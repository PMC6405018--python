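"""Test procedures based on groups of transformations.

All tests share the same order-statistic rejection rule: with statistics
``T^{(1)} <= ... <= T^{(N)}`` over a set or vector of transformations and
``k = ceil((1 - alpha) * N)``, reject when the observed statistic strictly
exceeds ``T^{(k)}``. The randomized variants additionally reject with
probability ``a = (alpha * N - M+) / M0`` at the boundary ``T(X) = T^{(k)}``,
which makes the rejection probability exactly ``alpha`` under the invariance
null.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import designs
from ._util import as_rng, order_statistic, rank_threshold, tail_counts
from .transform_groups import (
    Certificate,
    DrawnVector,
    Kind,
    Scheme,
    TransformationSet,
    apply_payloads,
    compose_payloads_right,
    inverse,
)

__all__ = [
    "TestResult",
    "full_group_test",
    "hoeffding_randomized_test",
    "random_perm_test",
    "representative_random_test",
    "randomized_random_perm_test",
    "subset_shift_test",
    "monte_carlo_test",
]

logger = logging.getLogger("permtest")


@dataclass
class TestResult:
    """Outcome of one test run, with enough provenance to replay it."""

    reject: bool
    alpha: float
    k: int
    threshold_value: float
    observed: float
    m_plus: int
    m_zero: int
    w: int
    a: "float | None" = None
    u: "float | None" = None
    pvalue: "float | None" = None
    b_geq: "int | None" = None  # #{j: T(g_j X) >= T(X)} over the statistics used
    seed_record: "dict | None" = None
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.m_zero < 1:
            raise ValueError("the threshold value must be attained (M0 >= 1)")
        if self.a is not None and not 0.0 <= self.a <= 1.0:
            raise ValueError("randomization probability a must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


#: Minimum set size at which the contrast-matrix evaluation pays off.
_CONTRAST_FAST_PATH_MIN = 512


def _set_statistics(x: np.ndarray, G: TransformationSet, T) -> np.ndarray:
    """Statistics ``T(g x)`` over every element of a set.

    For large permutation sets with a ``+/-1``-contrast statistic (the
    two-sample difference of sums) this evaluates ``S @ x`` with a cached
    signed indicator matrix instead of gathering and sorting each permuted
    copy: same values, bit-exact ties within statistic classes, and an order
    of magnitude faster for sets like the full symmetric group.
    """
    if (
        G.kind is Kind.INDEX_PERMUTATION
        and getattr(T, "case_control_contrast", False)
        and len(G) >= _CONTRAST_FAST_PATH_MIN
    ):
        S = getattr(G, "_contrast_cache", None)
        if S is None:
            S = designs.signed_contrast_matrix(G.payloads)
            G._contrast_cache = S
        return S @ np.asarray(x, dtype=float)
    return np.asarray(T(G.apply_all(x)), dtype=float)


def _set_observed(stats: np.ndarray, x: np.ndarray, G: TransformationSet, T) -> float:
    # the identity's own statistic, taken from the evaluated stack so the
    # observed value is bit-consistent with the tie counting
    if G.identity_index is not None:
        return float(stats[G.identity_index])
    return float(T(x))


def _decision_core(stats: np.ndarray, observed: float, alpha: float, tol: float):
    n = int(stats.shape[0])
    k = rank_threshold(alpha, n)
    threshold = order_statistic(stats, k)
    m_plus, m_zero = tail_counts(stats, threshold, tol)
    g_obs, e_obs = tail_counts(stats, observed, tol)
    reject = observed > threshold + tol
    return n, k, threshold, m_plus, m_zero, g_obs + e_obs, reject


def _require_group(G: TransformationSet, allow_nongroup: bool) -> None:
    if G.group_certificate is Certificate.VERIFIED_GROUP:
        return
    if allow_nongroup:
        if not getattr(G, "_nongroup_warned", False):  # once per set, not per call
            logger.warning(
                "running a permutation test over a transformation set that is NOT "
                "a verified group (certificate=%s); the level guarantee does not apply",
                G.group_certificate.value,
                extra={"code": "NONGROUP_OVERRIDE"},
            )
            G._nongroup_warned = True
        return
    raise ValueError(
        "transformation set is not certified as a group "
        f"(certificate={G.group_certificate.value}); run verify_group first or "
        "pass allow_nongroup=True to override (negative-control use only)"
    )


def full_group_test(
    x: np.ndarray,
    G: TransformationSet,
    T,
    alpha: float,
    *,
    allow_nongroup: bool = False,
    tol: float = 0.0,
) -> TestResult:
    """Deterministic test over every element of a certified group.

    Rejects when ``T(x)`` strictly exceeds ``T^{(k)}``, ``k = ceil((1-alpha)#G)``.
    Level at most ``alpha``; under an equal-class partition of the statistic
    it is exact precisely when ``alpha`` is a multiple of ``1/m``.
    """
    _require_group(G, allow_nongroup)
    x = np.asarray(x)
    stats = _set_statistics(x, G, T)
    observed = _set_observed(stats, x, G, T)
    n, k, thr, m_plus, m_zero, b_geq, reject = _decision_core(stats, observed, alpha, tol)
    return TestResult(
        reject=reject, alpha=alpha, k=k, threshold_value=thr, observed=observed,
        m_plus=m_plus, m_zero=m_zero, w=n, b_geq=b_geq, method="full_group",
    )


def hoeffding_randomized_test(
    x: np.ndarray,
    G: TransformationSet,
    T,
    alpha: float,
    rng: "np.random.Generator | int | None" = None,
    *,
    allow_nongroup: bool = False,
    tol: float = 0.0,
    u: "float | None" = None,
) -> TestResult:
    """Full-group test with boundary randomization; always exact.

    At the boundary ``T(x) == T^{(k)}`` rejects with probability
    ``a = (alpha * #G - M+) / M0`` (reject iff ``a > u`` for an independent
    uniform ``u``).
    """
    _require_group(G, allow_nongroup)
    x = np.asarray(x)
    stats = _set_statistics(x, G, T)
    observed = _set_observed(stats, x, G, T)
    n, k, thr, m_plus, m_zero, b_geq, reject = _decision_core(stats, observed, alpha, tol)
    a = (alpha * n - m_plus) / m_zero
    a = min(1.0, max(0.0, a))  # float guard only; mathematically a is in [0, 1]
    at_boundary = (abs(observed - thr) <= tol) if tol else (observed == thr)
    if not reject and at_boundary:
        if u is None:
            u = float(as_rng(rng).random())
        reject = a > u
    return TestResult(
        reject=reject, alpha=alpha, k=k, threshold_value=thr, observed=observed,
        m_plus=m_plus, m_zero=m_zero, w=n, a=a, u=u, b_geq=b_geq,
        method="hoeffding_randomized",
    )


def random_perm_test(
    x: np.ndarray,
    Gdrawn: DrawnVector,
    T,
    alpha: float,
    *,
    tol: float = 0.0,
) -> TestResult:
    """Level-``alpha`` test based on random transformations with the identity
    adjoined as ``g_1``.

    Sorts the ``w`` statistics ``T(g_j x)``; rejects when ``T(x)`` strictly
    exceeds ``T^{(k')}``, ``k' = ceil((1-alpha) w)``. The identity in position
    1 is the correctness-critical contract and is re-checked here.
    """
    Gdrawn.assert_identity_first()
    x = np.asarray(x)
    stats = np.asarray(T(Gdrawn.apply_all(x)), dtype=float)
    observed = float(stats[0])  # g_1 = id, so this is T(x) bit-exactly
    n, k, thr, m_plus, m_zero, b_geq, reject = _decision_core(stats, observed, alpha, tol)
    return TestResult(
        reject=reject, alpha=alpha, k=k, threshold_value=thr, observed=observed,
        m_plus=m_plus, m_zero=m_zero, w=n, b_geq=b_geq,
        seed_record=Gdrawn.seed_record, method="random_perm",
    )


def representative_random_test(
    x: np.ndarray,
    design: "designs.TwoSampleDesign",
    w: int,
    scheme: "Scheme | str",
    T,
    alpha: float,
    rng: "np.random.Generator | int | None" = None,
    *,
    tol: float = 0.0,
) -> TestResult:
    """Random test drawing class representatives of the two-sample design.

    Under without-replacement sampling of distinct non-identity classes the
    test is exact for all ``alpha`` in ``{0/w, 1/w, ..., (w-1)/w}`` when the
    statistic separates the classes (continuous data).
    """
    drawn = designs.representatives(design, as_rng(rng), w, scheme)
    result = random_perm_test(x, drawn, T, alpha, tol=tol)
    result.method = "representative_random"
    return result


def randomized_random_perm_test(
    x: np.ndarray,
    Gdrawn: DrawnVector,
    T,
    alpha: float,
    rng: "np.random.Generator | int | None" = None,
    *,
    tol: float = 0.0,
    u: "float | None" = None,
) -> TestResult:
    """Random-transformation test with boundary randomization; exactly level
    ``alpha`` under the invariance null, with no continuity assumption.

    At the boundary rejects iff ``a > u`` with
    ``a = (w * alpha - M+) / M0`` computed over the drawn statistics.
    """
    Gdrawn.assert_identity_first()
    x = np.asarray(x)
    stats = np.asarray(T(Gdrawn.apply_all(x)), dtype=float)
    observed = float(stats[0])
    n, k, thr, m_plus, m_zero, b_geq, reject = _decision_core(stats, observed, alpha, tol)
    a = (n * alpha - m_plus) / m_zero
    a = min(1.0, max(0.0, a))
    at_boundary = (abs(observed - thr) <= tol) if tol else (observed == thr)
    if not reject and at_boundary:
        if u is None:
            u = float(as_rng(rng).random())
        reject = a > u
    return TestResult(
        reject=reject, alpha=alpha, k=k, threshold_value=thr, observed=observed,
        m_plus=m_plus, m_zero=m_zero, w=n, a=a, u=u, b_geq=b_geq,
        seed_record=Gdrawn.seed_record, method="randomized_random_perm",
    )


def subset_shift_test(
    x: np.ndarray,
    G_star: TransformationSet,
    T,
    alpha: float,
    rng: "np.random.Generator | int | None" = None,
    *,
    h_index: "int | None" = None,
    tol: float = 0.0,
) -> TestResult:
    """Randomized test over a finite subset ``G*`` of a (possibly infinite) group.

    Draws ``h`` uniformly from ``G*`` and compares ``T(x)`` to the order
    statistics of ``T(g h^{-1} x)`` over ``g in G*``. Level at most ``alpha``;
    when ``G*`` is itself a group, ``G* h^{-1} = G*`` and the test coincides
    with the full-group test for every ``h``.
    """
    n_star = len(G_star)
    if n_star == 0:  # TransformationSet forbids this, but keep the contract explicit
        raise ValueError("G_star must be nonempty")
    if h_index is None:
        h_index = int(as_rng(rng).integers(n_star))
    elif not 0 <= h_index < n_star:
        raise ValueError(f"h_index {h_index} out of range for #G*={n_star}")
    h = G_star[h_index]
    shifted = compose_payloads_right(G_star.payloads, G_star.kind, inverse(h))
    x = np.asarray(x)
    stats = np.asarray(T(apply_payloads(x, G_star.kind, shifted)), dtype=float)
    observed = float(T(x))
    n, k, thr, m_plus, m_zero, b_geq, reject = _decision_core(stats, observed, alpha, tol)
    return TestResult(
        reject=reject, alpha=alpha, k=k, threshold_value=thr, observed=observed,
        m_plus=m_plus, m_zero=m_zero, w=n, b_geq=b_geq,
        seed_record={"h_index": h_index, "h": h.payload.tolist()},
        method="subset_shift",
    )


def monte_carlo_test(
    x: np.ndarray,
    null_sampler,
    T,
    w: int,
    alpha: float,
    rng: "np.random.Generator | int | None" = None,
) -> TestResult:
    """Plain Monte Carlo test: fresh datasets from a fully specified null.

    Draws ``X_2..X_w`` iid via ``null_sampler(rng)``, sets ``X_1 = x`` and
    applies the order-statistic rejection rule. Provided for the contrast
    with permutation tests, whose draws live on the orbit of ``x`` instead.
    Reports the Monte Carlo p-value ``B'/w``.
    """
    if w < 1:
        raise ValueError("w must be at least 1")
    rng = as_rng(rng)
    x = np.asarray(x, dtype=float)
    samples = np.empty((w, x.shape[0]), dtype=float)
    samples[0] = x
    for j in range(1, w):
        samples[j] = null_sampler(rng)
    stats = np.asarray(T(samples), dtype=float)
    observed = float(stats[0])
    n, k, thr, m_plus, m_zero, b_geq, reject = _decision_core(stats, observed, alpha, 0.0)
    return TestResult(
        reject=reject, alpha=alpha, k=k, threshold_value=thr, observed=observed,
        m_plus=m_plus, m_zero=m_zero, w=n, b_geq=b_geq, pvalue=b_geq / w,
        method="monte_carlo",
    )
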