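"""Synthetic data and the Monte Carlo harness for level/exactness claims.

Every test procedure has a named harness configuration here that estimates
its type-I error on fresh synthetic null data; random transformation vectors
are redrawn on every repetition, so the estimates target the unconditional
rejection probability. The anti-conservativeness demonstrations (naive
``B/w`` p-values; balanced permutations) live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import designs, perm_tests
from ._util import as_rng
from .transform_groups import (
    Certificate,
    Kind,
    Scheme,
    SignFlipGroup,
    SymmetricGroup,
    TransformationSet,
    draw_transformations,
    symmetric_group_set,
    sign_flip_group_set,
    verify_group,
)

__all__ = [
    "NullModel",
    "SimulationResult",
    "HarnessConfig",
    "generate_null",
    "generate_alternative",
    "estimate_type1",
    "phipson_naive_zero_oracle",
    "phipson_smyth_demo",
    "BalancedDemoResult",
    "balanced_demo",
    "LEVEL_CLAIMS",
    "LevelClaim",
]

_FAMILIES = ("gaussian", "exponential_centered", "bernoulli_signed", "integer_ties")


@dataclass(frozen=True)
class NullModel:
    """A synthetic null distribution satisfying the invariance its design needs.

    ``gaussian`` and ``bernoulli_signed`` are symmetric about zero (valid for
    sign-flip designs) and iid (valid for two-sample designs);
    ``exponential_centered`` is iid but asymmetric, so it is for two-sample
    designs only. ``integer_ties`` draws uniform integers from
    ``params['low']..params['high']`` (default 0..2); pass a symmetric support
    such as -1..1 when using it with sign flips.
    """

    family: str
    n: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        if self.n < 1:
            raise ValueError("n must be at least 1")


def generate_null(model: NullModel, rng: "np.random.Generator | int | None") -> np.ndarray:
    rng = as_rng(rng)
    if model.family == "gaussian":
        scale = model.params.get("scale", 1.0)
        return scale * rng.standard_normal(model.n)
    if model.family == "exponential_centered":
        rate = model.params.get("rate", 1.0)
        return rng.exponential(1.0 / rate, size=model.n) - 1.0 / rate
    if model.family == "bernoulli_signed":
        return (rng.integers(0, 2, size=model.n) * 2 - 1).astype(float)
    # integer_ties: small support forces tied statistics without degenerate orbits
    low = model.params.get("low", 0)
    high = model.params.get("high", 2)
    return rng.integers(low, high + 1, size=model.n).astype(float)


def generate_alternative(
    model: NullModel, shift: float, rng: "np.random.Generator | int | None"
) -> np.ndarray:
    """Location-shift alternative: for a two-sample layout (``params['design']
    == 'two_sample'``) the shift is added to the case half; otherwise to all
    entries (sign-flip layout)."""
    if shift < 0:
        raise ValueError("shift must be nonnegative")
    x = generate_null(model, rng)
    if model.params.get("design") == "two_sample":
        x = x.copy()
        x[: model.n // 2] += shift
    else:
        x = x + shift
    return x


@dataclass
class SimulationResult:
    reps: int
    rejections: int
    estimate: float
    se: float
    ci95: "tuple[float, float]"
    config_echo: dict
    seed: "int | None"

    def to_dict(self) -> dict:
        return asdict(self)


def _make_result(rejections: int, reps: int, config_echo: dict, seed) -> SimulationResult:
    estimate = rejections / reps
    se = math.sqrt(estimate * (1.0 - estimate) / reps)
    return SimulationResult(
        reps=reps,
        rejections=rejections,
        estimate=estimate,
        se=se,
        ci95=(estimate - 1.96 * se, estimate + 1.96 * se),
        config_echo=config_echo,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# harness configurations
# ---------------------------------------------------------------------------

_TESTS = (
    "full_group",
    "hoeffding",
    "random",
    "randomized_random",
    "representative",
    "subset_shift",
    "monte_carlo",
)
_DESIGNS = ("sign_flip", "two_sample", "rotation")


@dataclass(frozen=True)
class HarnessConfig:
    """Which test to run and on which design.

    ``n`` is the data vector length (for a two-sample design this is ``2n``
    in the per-arm notation). ``w`` is the transformation-vector length for
    the random variants. ``use_balanced_set`` swaps the full group for the
    non-group balanced set plus identity (negative control).
    """

    test: str
    design: str
    n: int
    w: "int | None" = None
    scheme: "Scheme | str" = Scheme.WITH_REPLACEMENT
    allow_nongroup: bool = False
    use_balanced_set: bool = False
    g_star_size: "int | None" = None
    tol: float = 0.0

    def __post_init__(self) -> None:
        if self.test not in _TESTS:
            raise ValueError(f"unknown test {self.test!r}; choose from {_TESTS}")
        if self.design not in _DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; choose from {_DESIGNS}")
        if self.test in ("random", "randomized_random", "representative", "monte_carlo"):
            if self.w is None or self.w < 1:
                raise ValueError(f"test {self.test!r} needs w >= 1")
        if self.design == "two_sample" and self.n % 2:
            raise ValueError("two-sample design needs an even data length")
        if self.test == "subset_shift" and self.design == "rotation":
            if not self.g_star_size:
                raise ValueError("rotation subset-shift needs g_star_size")


def _statistic_for(design: str):
    if design == "sign_flip":
        return designs.sum_statistic
    if design == "two_sample":
        return designs.two_sample_statistic
    return designs.first_coordinate


def _full_group_for(config: HarnessConfig) -> TransformationSet:
    if config.use_balanced_set:
        if config.design != "two_sample":
            raise ValueError("the balanced set is a two-sample construction")
        return _balanced_plus_identity(designs.TwoSampleDesign(config.n // 2))
    if config.design == "sign_flip":
        return sign_flip_group_set(config.n)
    if config.design == "two_sample":
        return symmetric_group_set(config.n)
    raise ValueError("full-group runs support sign_flip and two_sample designs")


def _balanced_plus_identity(design: "designs.TwoSampleDesign") -> TransformationSet:
    """The full balanced-permutation multiset with the identity adjoined.

    Certified ``verified_not_group`` when small enough to check exhaustively,
    else left unverified (it is never a group either way).
    """
    balanced = designs.balanced_permutation_multiset(design)
    with_id = TransformationSet(
        kind=Kind.INDEX_PERMUTATION,
        payloads=np.concatenate(
            [np.arange(design.total, dtype=np.intp)[None], balanced.payloads], axis=0
        ),
        identity_index=0,
    )
    if len(with_id) <= 2000:
        with_id = verify_group(with_id)
        assert with_id.group_certificate is Certificate.VERIFIED_NOT_GROUP
    return with_id


def _implicit_group_for(config: HarnessConfig):
    if config.design == "sign_flip":
        return SignFlipGroup(config.n)
    if config.design == "two_sample":
        return SymmetricGroup(config.n)
    raise ValueError("random draws support sign_flip and two_sample designs")


def _build_runner(config: HarnessConfig, model: NullModel, alpha: float, setup_rng):
    """Return ``runner(x, rng) -> bool`` executing the configured test once."""
    T = _statistic_for(config.design)
    tol = config.tol

    if config.test == "full_group":
        G = _full_group_for(config)
        allow = config.allow_nongroup or config.use_balanced_set
        return lambda x, rng: perm_tests.full_group_test(
            x, G, T, alpha, allow_nongroup=allow, tol=tol
        ).reject

    if config.test == "hoeffding":
        G = _full_group_for(config)
        allow = config.allow_nongroup or config.use_balanced_set
        return lambda x, rng: perm_tests.hoeffding_randomized_test(
            x, G, T, alpha, rng, allow_nongroup=allow, tol=tol
        ).reject

    if config.test in ("random", "randomized_random"):
        spec = _implicit_group_for(config)
        scheme = Scheme(config.scheme)
        w = config.w
        if config.test == "random":
            def runner(x, rng):
                drawn = draw_transformations(spec, w, scheme, rng)
                return perm_tests.random_perm_test(x, drawn, T, alpha, tol=tol).reject
        else:
            def runner(x, rng):
                drawn = draw_transformations(spec, w, scheme, rng)
                return perm_tests.randomized_random_perm_test(
                    x, drawn, T, alpha, rng, tol=tol
                ).reject
        return runner

    if config.test == "representative":
        design = designs.TwoSampleDesign(config.n // 2)
        scheme, w = config.scheme, config.w
        return lambda x, rng: perm_tests.representative_random_test(
            x, design, w, scheme, T, alpha, rng, tol=tol
        ).reject

    if config.test == "subset_shift":
        if config.design == "rotation":
            g_star = designs.rotation_subset(2, config.g_star_size, setup_rng).g_star
            shift_tol = tol if tol else 1e-9  # recomposed rotations round
        else:
            g_star = _full_group_for(config)
            shift_tol = tol
        return lambda x, rng: perm_tests.subset_shift_test(
            x, g_star, T, alpha, rng, tol=shift_tol
        ).reject

    # monte_carlo
    w = config.w
    sampler = lambda rng: generate_null(model, rng)
    return lambda x, rng: perm_tests.monte_carlo_test(x, sampler, T, w, alpha, rng).reject


def estimate_type1(
    test_config: HarnessConfig,
    model: NullModel,
    reps: int,
    alpha: float,
    seed: "int | None",
    *,
    min_reps: int = 1000,
) -> SimulationResult:
    """Empirical rejection rate of the configured test over ``reps`` fresh
    null datasets, with fresh transformation draws on every repetition."""
    if reps < min_reps:
        raise ValueError(f"reps={reps} below the minimum of {min_reps}")
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    if model.n != test_config.n and test_config.design != "rotation":
        raise ValueError(
            f"model length n={model.n} does not match config data length {test_config.n}"
        )
    rng = as_rng(seed)
    runner = _build_runner(test_config, model, alpha, rng)
    rejections = 0
    for _ in range(reps):
        x = generate_null(model, rng)
        if runner(x, rng):
            rejections += 1
    echo = {
        "config": asdict(test_config),
        "model": asdict(model),
        "alpha": alpha,
        "reps": reps,
    }
    echo["config"]["scheme"] = Scheme(test_config.scheme).value
    return _make_result(rejections, reps, echo, seed)


# ---------------------------------------------------------------------------
# Phipson-Smyth demonstration
# ---------------------------------------------------------------------------


def phipson_naive_zero_oracle(N: int, w: int) -> float:
    """Exact ``P(B = 0)`` for ``w`` with-replacement draws when the rank of
    the observed statistic is uniform on ``1..N``:
    ``N^{-(w+1)} * sum_{j=0}^{N-1} j^w``. Independent finite-sum oracle for
    the anti-conservativeness of the naive p-value."""
    total = sum(j**w for j in range(N))
    return float(Fraction(total, N ** (w + 1)))


def phipson_smyth_demo(
    w: int,
    c_grid,
    model: NullModel,
    reps: int,
    seed: "int | None",
) -> pd.DataFrame:
    """Empirical ``P(p_hat <= c)`` and ``P(p_tilde <= c)`` under a sign-flip
    null with ``w`` with-replacement draws (no identity among them).

    Returns one row per cutoff ``c`` with rates and binomial standard errors.
    The naive ``p_hat = B/w`` exceeds its nominal level for small ``c``;
    ``p_tilde = (B+1)/(w+1)`` stays valid.
    """
    if w < 2:
        raise ValueError("w must be at least 2")
    rng = as_rng(seed)
    n = model.n
    b_values = np.empty(reps, dtype=np.int64)
    for i in range(reps):
        x = generate_null(model, rng)
        signs = rng.integers(0, 2, size=(w, n)) * 2 - 1
        stats = (signs * x).sum(axis=1)
        b_values[i] = np.count_nonzero(stats >= x.sum())
    p_naive = b_values / w
    p_tilde = (b_values + 1) / (w + 1)
    rows = []
    for c in c_grid:
        rate_naive = float(np.mean(p_naive <= c))
        rate_tilde = float(np.mean(p_tilde <= c))
        rows.append(
            {
                "c": float(c),
                "p_naive_rate": rate_naive,
                "p_naive_se": math.sqrt(rate_naive * (1 - rate_naive) / reps),
                "p_plus_one_rate": rate_tilde,
                "p_plus_one_se": math.sqrt(rate_tilde * (1 - rate_tilde) / reps),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# balanced-permutation negative control
# ---------------------------------------------------------------------------


@dataclass
class BalancedDemoResult:
    """Paired comparison of the non-group balanced set against the honest group."""

    n: int
    alpha: float
    balanced: SimulationResult
    full_group: SimulationResult
    binom_pvalue: float  # one-sided, H0: balanced rate <= alpha

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "alpha": self.alpha,
            "balanced": self.balanced.to_dict(),
            "full_group": self.full_group.to_dict(),
            "binom_pvalue": self.binom_pvalue,
        }


def balanced_demo(
    n: int,
    alpha: float,
    reps: int,
    seed: "int | None",
    *,
    acknowledge_nongroup: bool = False,
    run_full_group: bool = True,
) -> BalancedDemoResult:
    """Type-I error of the full-group rejection rule run over the balanced
    set plus identity (NOT a group) on two-sample null data, paired with the
    honest full-group test on the same datasets.

    Refuses to run unless ``acknowledge_nongroup=True``: the balanced arm is
    anti-conservative by design and exists only as a negative control.
    """
    if n % 2 or n < 4:
        raise ValueError("n must be even and at least 4")
    if not acknowledge_nongroup:
        raise ValueError(
            "balanced_demo runs a deliberately invalid (non-group) test; "
            "pass acknowledge_nongroup=True to run it as a negative control"
        )
    total = 2 * n
    design = designs.TwoSampleDesign(n)
    balanced_plus_id = _balanced_plus_identity(design)
    honest = symmetric_group_set(total) if run_full_group else None
    model = NullModel("gaussian", total)
    T = designs.two_sample_statistic
    rng = as_rng(seed)
    rej_balanced = 0
    rej_honest = 0
    for _ in range(reps):
        x = generate_null(model, rng)
        if perm_tests.full_group_test(
            x, balanced_plus_id, T, alpha, allow_nongroup=True
        ).reject:
            rej_balanced += 1
        if honest is not None and perm_tests.full_group_test(x, honest, T, alpha).reject:
            rej_honest += 1
    echo = {"n": n, "alpha": alpha, "reps": reps, "set_size": len(balanced_plus_id)}
    balanced_result = _make_result(rej_balanced, reps, {**echo, "arm": "balanced"}, seed)
    honest_result = _make_result(rej_honest, reps, {**echo, "arm": "full_group"}, seed)
    binom_p = float(
        sps.binomtest(rej_balanced, reps, alpha, alternative="greater").pvalue
    )
    return BalancedDemoResult(
        n=n,
        alpha=alpha,
        balanced=balanced_result,
        full_group=honest_result,
        binom_pvalue=binom_p,
    )


# ---------------------------------------------------------------------------
# declarative registry of level/exactness claims
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LevelClaim:
    """One simulated level/exactness claim: a harness configuration, a null
    model, an alpha grid, and the acceptance band type.

    ``check`` is ``"exact"`` (rate within alpha +/- 3 SE), ``"upper"`` (rate
    at most alpha + 3 SE), or ``"grid_floor"`` (rate within
    ``floor(alpha*m)/m +/- 3 SE`` where ``m`` is the number of statistic
    classes).
    """

    claim_id: str
    config: HarnessConfig
    model: NullModel
    alphas: "tuple[float, ...]"
    reps: int
    check: str
    m_classes: "int | None" = None

    def expected_rate(self, alpha: float) -> "float | None":
        if self.check == "exact":
            return alpha
        if self.check == "grid_floor":
            return math.floor(alpha * self.m_classes + 1e-9) / self.m_classes
        return None  # upper bound only


LEVEL_CLAIMS: "tuple[LevelClaim, ...]" = (
    LevelClaim(
        "hoeffding_exact_continuous",
        HarnessConfig("hoeffding", "sign_flip", n=5),
        NullModel("gaussian", 5),
        (0.01, 0.05, 0.1),
        50_000,
        "exact",
    ),
    LevelClaim(
        "hoeffding_exact_ties",
        HarnessConfig("hoeffding", "sign_flip", n=5),
        NullModel("integer_ties", 5, {"low": -1, "high": 1}),
        (0.01, 0.05, 0.1),
        50_000,
        "exact",
    ),
    LevelClaim(
        "randomized_random_exact_continuous",
        HarnessConfig("randomized_random", "sign_flip", n=8, w=20),
        NullModel("gaussian", 8),
        (0.01, 0.05, 0.1),
        50_000,
        "exact",
    ),
    LevelClaim(
        "randomized_random_exact_ties",
        HarnessConfig("randomized_random", "sign_flip", n=8, w=20),
        NullModel("integer_ties", 8, {"low": -1, "high": 1}),
        (0.01, 0.05, 0.1),
        50_000,
        "exact",
    ),
    LevelClaim(
        "random_level_upper",
        HarnessConfig("random", "sign_flip", n=10, w=99),
        NullModel("gaussian", 10),
        (0.01, 0.05, 0.1),
        50_000,
        "upper",
    ),
    LevelClaim(
        "representative_without_replacement_exact",
        HarnessConfig(
            "representative",
            "two_sample",
            n=6,
            w=10,
            scheme=Scheme.REPRESENTATIVES_WITHOUT_REPLACEMENT,
        ),
        NullModel("gaussian", 6),
        (0.1,),
        50_000,
        "exact",
    ),
    LevelClaim(
        "full_group_grid_floor",
        HarnessConfig("full_group", "two_sample", n=6),
        NullModel("gaussian", 6),
        (0.03, 0.05, 0.08),
        20_000,
        "grid_floor",
        m_classes=20,
    ),
    LevelClaim(
        "rotation_subset_shift_upper",
        HarnessConfig("subset_shift", "rotation", n=2, g_star_size=12),
        NullModel("gaussian", 2),
        (0.05, 0.1),
        50_000,
        "upper",
    ),
    LevelClaim(
        "monte_carlo_exact",
        HarnessConfig("monte_carlo", "sign_flip", n=5, w=100),
        NullModel("gaussian", 5),
        (0.05,),
        50_000,
        "exact",
    ),
)
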