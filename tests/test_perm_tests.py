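import logging

import numpy as np
import pytest
from scipy import stats as sps

from permtest import (
    Kind,
    Scheme,
    SignFlipGroup,
    TransformationSet,
    TwoSampleDesign,
    draw_transformations,
    full_group_test,
    hoeffding_randomized_test,
    monte_carlo_test,
    random_perm_test,
    randomized_random_perm_test,
    representative_random_test,
    sign_flip_group_set,
    subset_shift_test,
    sum_statistic,
    symmetric_group_set,
    two_sample_statistic,
)
from permtest.designs import rotation_subset
from permtest.transform_groups import DrawnVector, Transformation, identity


ALPHAS = (0.01, 0.05, 0.1, 0.2)


# ---------------------------------------------------------------------------
# full_group_test
# ---------------------------------------------------------------------------


def test_alpha_zero_never_rejects(sign_flip_3, rng):
    for _ in range(20):
        x = rng.standard_normal(3)
        assert not full_group_test(x, sign_flip_3, sum_statistic, 0.0).reject


def test_sign_flip_unique_maximum_rejects(sign_flip_3):
    # 8 distinct signed sums; k = ceil(0.875 * 8) = 7; observed 6 is the max
    r = full_group_test(np.array([1.0, 2.0, 3.0]), sign_flip_3, sum_statistic, 0.125)
    assert r.reject
    assert r.k == 7
    assert r.threshold_value == 4.0
    assert r.observed == 6.0


def test_two_sample_rejection_impossible_inside_top_class(s6, rng):
    # k = ceil(0.97 * 720) = 699 lies inside the top class of 36 equal values,
    # so the threshold is the maximum and strict rejection cannot happen
    for _ in range(25):
        x = rng.standard_normal(6)
        r = full_group_test(x, s6, two_sample_statistic, 0.03)
        assert r.k == 699
        assert not r.reject
        stats = np.sort(
            np.array([two_sample_statistic(g.apply(x)) for g in s6])
        )
        assert r.threshold_value == pytest.approx(stats[-1], abs=1e-12)
        assert r.m_zero == 36  # the whole top class sits at the threshold


def test_uncertified_set_rejected_by_default():
    S = TransformationSet(
        [identity(Kind.SIGN_FLIP, 2), Transformation(Kind.SIGN_FLIP, np.array([-1, 1]))]
    )
    with pytest.raises(ValueError, match="not certified"):
        full_group_test(np.array([1.0, 2.0]), S, sum_statistic, 0.1)


def test_allow_nongroup_override_warns(caplog):
    S = TransformationSet(
        [identity(Kind.SIGN_FLIP, 2), Transformation(Kind.SIGN_FLIP, np.array([-1, 1]))]
    )
    with caplog.at_level(logging.WARNING, logger="permtest"):
        full_group_test(np.array([1.0, 2.0]), S, sum_statistic, 0.1, allow_nongroup=True)
    assert any(getattr(r, "code", None) == "NONGROUP_OVERRIDE" for r in caplog.records)


def test_threshold_invariance_under_group_action(sign_flip_3, s3, rng):
    # T^{(k)}(gX) == T^{(k)}(X) for every g in G: the pivotal consequence of Gg = G
    x = rng.standard_normal(3)
    for G, T in ((sign_flip_3, sum_statistic), (s3, lambda v: np.asarray(v)[..., 0] - np.asarray(v)[..., 1])):
        for alpha in ALPHAS:
            base = full_group_test(x, G, T, alpha).threshold_value
            for g in G:
                assert full_group_test(g.apply(x), G, T, alpha).threshold_value == base


def test_fast_path_matches_generic_evaluation(s6, rng):
    # the contrast-matrix evaluation must reproduce per-element statistics
    x = rng.standard_normal(6)
    r = full_group_test(x, s6, two_sample_statistic, 0.05)
    direct = np.sort([two_sample_statistic(g.apply(x)) for g in s6])
    assert r.threshold_value == pytest.approx(direct[r.k - 1], abs=1e-12)
    assert r.observed == pytest.approx(two_sample_statistic(x), abs=1e-12)


# ---------------------------------------------------------------------------
# hoeffding_randomized_test
# ---------------------------------------------------------------------------


def test_hoeffding_a_fraction(sign_flip_3):
    # #G=32, k=31, distinct sums: M+=1, M0=1 -> a = (0.05*32 - 1)/1 = 0.6
    G = sign_flip_group_set(5)
    r = hoeffding_randomized_test(
        np.array([1.0, 2.0, 4.0, 8.0, 16.0]), G, sum_statistic, 0.05, rng=0
    )
    assert r.a == pytest.approx(0.6)
    assert r.m_plus == 1 and r.m_zero == 1
    assert r.reject  # observed is the strict maximum


def test_hoeffding_a_zero_at_exact_boundary(sign_flip_3):
    # alpha * #G = M+ exactly -> a = 0
    r = hoeffding_randomized_test(
        np.array([1.0, 2.0, 3.0]), sign_flip_3, sum_statistic, 0.25, rng=0
    )
    assert r.m_plus == 2  # stats > T^{(6)} = 2 are {4, 6}
    assert r.a == 0.0


def test_hoeffding_boundary_randomization_uses_u(sign_flip_3):
    # tied data: stats are four +1 and four -1; at alpha=0.4 the observed
    # value sits exactly on the threshold with a = (3.2 - 0)/4 = 0.8
    x = np.array([0.0, 0.0, 1.0])
    low = hoeffding_randomized_test(x, sign_flip_3, sum_statistic, 0.4, u=0.5)
    high = hoeffding_randomized_test(x, sign_flip_3, sum_statistic, 0.4, u=0.9)
    assert low.a == pytest.approx(0.8)
    assert low.reject and not high.reject


# ---------------------------------------------------------------------------
# random_perm_test
# ---------------------------------------------------------------------------


def test_random_w1_never_rejects(rng):
    drawn = draw_transformations(SignFlipGroup(4), 1, Scheme.WITH_REPLACEMENT, rng)
    x = rng.standard_normal(4)
    assert not random_perm_test(x, drawn, sum_statistic, 0.2).reject


def test_random_requires_identity_first(rng):
    payloads = (rng.integers(0, 2, size=(5, 4)) * 2 - 1).astype(np.int8)
    payloads[0] = [1, 1, 1, -1]
    with pytest.raises(ValueError, match="identity"):
        DrawnVector(Kind.SIGN_FLIP, payloads, Scheme.WITH_REPLACEMENT)


def test_exhaustive_draw_equals_full_group(sign_flip_4, rng):
    # w = #G without replacement reproduces the full-group decision exactly
    spec = SignFlipGroup(4)
    for _ in range(100):
        x = rng.standard_normal(4)
        drawn = draw_transformations(spec, 16, Scheme.WITHOUT_REPLACEMENT, rng)
        for alpha in ALPHAS:
            got = random_perm_test(x, drawn, sum_statistic, alpha).reject
            want = full_group_test(x, sign_flip_4, sum_statistic, alpha).reject
            assert got == want


def test_monotonicity_in_alpha(rng):
    spec = SignFlipGroup(6)
    for _ in range(50):
        x = rng.standard_normal(6)
        drawn = draw_transformations(spec, 12, Scheme.WITH_REPLACEMENT, rng)
        rejections = [
            random_perm_test(x, drawn, sum_statistic, a).reject
            for a in (0.01, 0.05, 0.1, 0.2, 0.4)
        ]
        # once rejecting, stays rejecting as alpha grows
        assert rejections == sorted(rejections)


def test_shuffle_stability(rng):
    # decision and threshold depend only on the multiset of drawn statistics
    spec = SignFlipGroup(6)
    x = rng.standard_normal(6)
    drawn = draw_transformations(spec, 15, Scheme.WITH_REPLACEMENT, rng)
    base = random_perm_test(x, drawn, sum_statistic, 0.1)
    for _ in range(10):
        shuffled = drawn.payloads.copy()
        shuffled[1:] = shuffled[1:][rng.permutation(14)]
        other = DrawnVector(Kind.SIGN_FLIP, shuffled, Scheme.WITH_REPLACEMENT)
        r = random_perm_test(x, other, sum_statistic, 0.1)
        assert r.reject == base.reject
        assert r.threshold_value == base.threshold_value
        assert (r.m_plus, r.m_zero) == (base.m_plus, base.m_zero)


# ---------------------------------------------------------------------------
# representative_random_test
# ---------------------------------------------------------------------------


def test_representative_alpha_zero(rng):
    d = TwoSampleDesign(3)
    x = rng.standard_normal(6)
    r = representative_random_test(
        x, d, 10, Scheme.WITHOUT_REPLACEMENT, two_sample_statistic, 0.0, rng
    )
    assert not r.reject


def test_representative_exhaustive_equals_full_group(s6, rng):
    # one representative per class yields the same class-rank decision as
    # the full group, for continuous data
    d = TwoSampleDesign(3)
    for _ in range(30):
        x = rng.standard_normal(6)
        for alpha in ALPHAS:
            got = representative_random_test(
                x, d, 20, Scheme.WITHOUT_REPLACEMENT, two_sample_statistic, alpha, rng
            ).reject
            want = full_group_test(x, s6, two_sample_statistic, alpha).reject
            assert got == want


# ---------------------------------------------------------------------------
# randomized_random_perm_test
# ---------------------------------------------------------------------------


def test_randomized_strict_max_rejects_with_certainty(rng):
    spec = SignFlipGroup(8)
    x = np.abs(rng.standard_normal(8)) + 1.0  # all positive: identity sum is the max
    for _ in range(20):
        drawn = draw_transformations(spec, 20, Scheme.WITHOUT_REPLACEMENT, rng)
        r = randomized_random_perm_test(x, drawn, sum_statistic, 0.05, rng)
        assert r.reject


def test_randomized_alpha_zero_never_rejects(rng):
    spec = SignFlipGroup(5)
    for _ in range(50):
        x = rng.standard_normal(5)
        drawn = draw_transformations(spec, 10, Scheme.WITH_REPLACEMENT, rng)
        assert not randomized_random_perm_test(x, drawn, sum_statistic, 0.0, rng).reject


# ---------------------------------------------------------------------------
# subset_shift_test
# ---------------------------------------------------------------------------


def test_subset_shift_group_matches_full_group_for_every_h(sign_flip_3, rng):
    # G* a group: G* h^{-1} = G*, so the decision is the full-group decision
    for _ in range(20):
        x = rng.standard_normal(3)
        for alpha in ALPHAS:
            want = full_group_test(x, sign_flip_3, sum_statistic, alpha).reject
            for h_index in range(8):
                got = subset_shift_test(
                    x, sign_flip_3, sum_statistic, alpha, h_index=h_index
                ).reject
                assert got == want


def test_subset_shift_identity_only_never_rejects(rng):
    design = rotation_subset(2, 1, rng)
    x = rng.standard_normal(2)
    r = subset_shift_test(x, design.g_star, lambda v: np.asarray(v)[..., 0], 0.3, rng)
    assert not r.reject


def test_subset_shift_records_h(rng):
    design = rotation_subset(2, 6, rng)
    r = subset_shift_test(
        np.array([1.0, 0.5]), design.g_star, lambda v: np.asarray(v)[..., 0], 0.1, rng
    )
    assert 0 <= r.seed_record["h_index"] < 6
    assert np.shape(r.seed_record["h"]) == (2, 2)


def test_empty_gstar_unconstructible():
    with pytest.raises(ValueError, match="empty"):
        TransformationSet(kind=Kind.ROTATION, payloads=np.empty((0, 2, 2)))


# ---------------------------------------------------------------------------
# monte_carlo_test
# ---------------------------------------------------------------------------


def test_monte_carlo_w1_never_rejects(rng):
    sampler = lambda r: r.standard_normal(4)
    assert not monte_carlo_test(rng.standard_normal(4), sampler, sum_statistic, 1, 0.3, rng).reject


def test_monte_carlo_bprime_uniform(rng):
    # B' is uniform on {1..w} under the null (chi-square GOF)
    w, reps = 20, 20_000
    sampler = lambda r: r.standard_normal(5)
    counts = np.zeros(w, dtype=int)
    for _ in range(reps):
        x = rng.standard_normal(5)
        r = monte_carlo_test(x, sampler, sum_statistic, w, 0.05, rng)
        counts[r.b_geq - 1] += 1
    assert sps.chisquare(counts).pvalue > 0.01


def test_result_serialization_round_trip(sign_flip_3):
    import json

    r = full_group_test(np.array([1.0, 2.0, 3.0]), sign_flip_3, sum_statistic, 0.125)
    obj = json.loads(r.to_json())
    assert obj["reject"] is True
    assert obj["k"] == 7
    assert obj["method"] == "full_group"
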