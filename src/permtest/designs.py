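"""Concrete experimental designs: data layout + statistic + transformation group.

Includes the two-sample difference-of-sums design with its equal-sized
equivalence-class structure, the one-sample sign-flip design, a finite 2-D
rotation design, and the non-group balanced-permutation set used as a
negative control.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from ._util import as_rng
from .transform_groups import (
    Certificate,
    DrawnVector,
    Kind,
    Scheme,
    SignFlipGroup,
    SymmetricGroup,
    Transformation,
    TransformationSet,
    verify_group,
)

__all__ = [
    "TwoSampleDesign",
    "SignFlipDesign",
    "RotationDesign",
    "Partition",
    "two_sample_statistic",
    "sum_statistic",
    "first_coordinate",
    "class_of_permutation",
    "class_labels",
    "representative_payload",
    "representative_transformation",
    "partition",
    "representatives",
    "balanced_permutation_set",
    "balanced_permutation_multiset",
    "signed_contrast_matrix",
    "rotation_matrix",
    "rotation_subset",
]


# ---------------------------------------------------------------------------
# statistics (batch-aware: reduce the last axis)
# ---------------------------------------------------------------------------


def two_sample_statistic(x: np.ndarray) -> "float | np.ndarray":
    """Difference of sums, cases (first half) minus controls (second half).

    Accepts a single vector of length ``2n`` or a batch with trailing axis
    ``2n``; reduces the last axis. Each arm is sorted before summation so
    that permutations placing the same multiset into an arm yield the same
    floating-point value bit-exactly — summing in permuted order would split
    exact statistic ties by last-ulp rounding differences.
    """
    x = np.asarray(x)
    length = x.shape[-1]
    if length % 2:
        raise ValueError(f"two-sample data must have even length, got {length}")
    n = length // 2
    cases = np.sort(x[..., :n], axis=-1)
    controls = np.sort(x[..., n:], axis=-1)
    out = cases.sum(axis=-1) - controls.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


# marks the statistic as a +/-1 contrast of the original entries, enabling a
# matrix-product evaluation over large permutation sets (see perm_tests)
two_sample_statistic.case_control_contrast = True


def signed_contrast_matrix(payloads: np.ndarray) -> np.ndarray:
    """Per-permutation signed indicator rows ``s_g`` with ``s_g . x = T(gX)``
    for the two-sample difference-of-sums statistic.

    Row ``g`` holds ``+1`` at the original indices the permutation places in
    the case arm and ``-1`` elsewhere. Permutations in the same statistic
    class share a row bit-exactly, so ``S @ x`` ties bit-exactly within
    classes.
    """
    n_el, length = payloads.shape
    half = length // 2
    S = np.full((n_el, length), -1.0)
    rows = np.repeat(np.arange(n_el), half)
    S[rows, payloads[:, :half].ravel()] = 1.0
    return S


def sum_statistic(x: np.ndarray) -> "float | np.ndarray":
    """Sum of entries (one-sample sign-flip statistic).

    Entries are sorted before summation so transformations producing the
    same multiset of signed values tie bit-exactly.
    """
    out = np.sort(np.asarray(x), axis=-1).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def first_coordinate(x: np.ndarray) -> "float | np.ndarray":
    """First coordinate of the data vector (rotation design statistic)."""
    out = np.asarray(x)[..., 0]
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoSampleDesign:
    """Equal-arm two-sample design on vectors of length ``2n``.

    Positions ``0..n-1`` are cases, ``n..2n-1`` controls. The statistic is
    the difference of arm sums, which is constant on each of the
    ``m = C(2n, n)`` equivalence classes of permutations (of size ``n! n!``)
    determined by the set of indices placed into the case arm.
    """

    n_cases: int
    n_controls: int = -1  # -1 means equal to n_cases

    def __post_init__(self) -> None:
        if self.n_controls == -1:
            object.__setattr__(self, "n_controls", self.n_cases)
        if self.n_cases != self.n_controls:
            raise NotImplementedError("only equal case/control arm sizes are supported")
        if self.n_cases < 1:
            raise ValueError("need at least one case")

    @property
    def n(self) -> int:
        return self.n_cases

    @property
    def total(self) -> int:
        return 2 * self.n_cases

    @property
    def m(self) -> int:
        """Number of equivalence classes, ``C(2n, n)``."""
        return math.comb(self.total, self.n_cases)

    def group(self) -> SymmetricGroup:
        return SymmetricGroup(self.total)

    statistic = staticmethod(two_sample_statistic)


@dataclass(frozen=True)
class SignFlipDesign:
    """One-sample design under the group ``{-1,+1}^n`` acting elementwise."""

    n: int

    def group(self) -> SignFlipGroup:
        return SignFlipGroup(self.n)

    statistic = staticmethod(sum_statistic)


@dataclass(frozen=True)
class RotationDesign:
    """A finite subset of 2-D rotations with the first-coordinate statistic."""

    d: int
    g_star: TransformationSet

    def __post_init__(self) -> None:
        if self.g_star.kind is not Kind.ROTATION:
            raise ValueError("g_star must contain rotations")

    statistic = staticmethod(first_coordinate)


# ---------------------------------------------------------------------------
# statistic-equivalence classes of permutations
# ---------------------------------------------------------------------------


def class_of_permutation(g: Transformation, design: TwoSampleDesign) -> tuple:
    """Label of the statistic-equivalence class of a permutation.

    Under the action ``(gX)_i = X_{p[i]}`` the case arm receives original
    indices ``p[0..n-1]``; the sorted tuple of those indices is a canonical
    class label: two permutations share a label iff they give equal
    statistics for generic continuous data.
    """
    if Kind(g.kind) is not Kind.INDEX_PERMUTATION:
        raise ValueError("class labels are defined for index permutations")
    if g.dim != design.total:
        raise ValueError(f"permutation of {g.dim} items does not match design of {design.total}")
    return tuple(sorted(int(i) for i in g.payload[: design.n]))


def class_labels(design: TwoSampleDesign) -> "list[tuple]":
    """All class labels, the identity's label ``(0..n-1)`` first."""
    ident = tuple(range(design.n))
    labels = [ident]
    labels.extend(
        lab
        for lab in itertools.combinations(range(design.total), design.n)
        if lab != ident
    )
    return labels


def representative_payload(label: "tuple | list", total: int) -> np.ndarray:
    """Canonical representative permutation of a class label.

    Moves the chosen case-subset into positions ``0..n-1`` preserving
    relative order, then the complement, also in order.
    """
    label = sorted(int(i) for i in label)
    rest = sorted(set(range(total)) - set(label))
    return np.array(label + rest, dtype=np.intp)


def representative_transformation(label: "tuple | list", total: int) -> Transformation:
    return Transformation(Kind.INDEX_PERMUTATION, representative_payload(label, total))


@dataclass
class Partition:
    """Equal-sized statistic-equivalence classes ``G_1..G_m`` with representatives."""

    m: int
    class_of: "dict[tuple, int]"  # permutation payload key -> class index (1-based)
    representatives: "list[Transformation]" = field(default_factory=list)

    def index_of(self, g: Transformation) -> int:
        return self.class_of[tuple(g.payload.tolist())]


def partition(design: TwoSampleDesign, cap: int = math.factorial(8)) -> Partition:
    """Enumerate the full partition of ``S_2n`` into statistic classes.

    Intended for small designs (oracle/testing use); refuses above ``cap``
    permutations.
    """
    total = design.total
    if math.factorial(total) > cap:
        raise ValueError(f"refusing to enumerate S_{total}")
    labels = class_labels(design)
    label_index = {lab: i + 1 for i, lab in enumerate(labels)}
    class_of = {}
    for perm in itertools.permutations(range(total)):
        lab = tuple(sorted(perm[: design.n]))
        class_of[perm] = label_index[lab]
    reps = [representative_transformation(lab, total) for lab in labels]
    return Partition(m=len(labels), class_of=class_of, representatives=reps)


# ---------------------------------------------------------------------------
# representative sampling
# ---------------------------------------------------------------------------

_LABEL_ENUMERATION_CAP = 200_000


def representatives(
    design: TwoSampleDesign,
    rng: "np.random.Generator | int | None",
    w: int,
    scheme: "Scheme | str" = Scheme.REPRESENTATIVES_WITHOUT_REPLACEMENT,
) -> DrawnVector:
    """Draw ``(id, h_{i_2}, ..., h_{i_w})`` from the canonical class representatives.

    With replacement: ``g_2..g_w`` iid uniform over all ``m`` representatives
    (the identity's class included). Without replacement: representatives of
    distinct non-identity classes; requires ``w <= m``.
    """
    scheme = Scheme(scheme)
    if scheme in (Scheme.WITH_REPLACEMENT, Scheme.REPRESENTATIVES_WITH_REPLACEMENT):
        scheme = Scheme.REPRESENTATIVES_WITH_REPLACEMENT
    elif scheme in (Scheme.WITHOUT_REPLACEMENT, Scheme.REPRESENTATIVES_WITHOUT_REPLACEMENT):
        scheme = Scheme.REPRESENTATIVES_WITHOUT_REPLACEMENT
    if w < 1:
        raise ValueError("w must be at least 1")
    rng = as_rng(rng)
    record = {
        "bit_generator": type(rng.bit_generator).__name__,
        "state": rng.bit_generator.state,
        "scheme": scheme.value,
        "w": w,
    }
    m = design.m
    total = design.total
    without = scheme is Scheme.REPRESENTATIVES_WITHOUT_REPLACEMENT
    if without and w > m:
        raise ValueError(f"w={w} exceeds the number of classes m={m} under without replacement")

    if m <= _LABEL_ENUMERATION_CAP:
        labels = class_labels(design)
        if without:
            idx = rng.choice(m - 1, size=w - 1, replace=False) + 1  # skip identity class
        else:
            idx = rng.integers(0, m, size=w - 1)
        chosen = [labels[i] for i in idx]
    else:  # deduplicated rejection sampling over case-subsets
        ident = tuple(range(design.n))
        chosen = []
        seen = {ident} if without else None
        budget = 1000 * w
        proposed = 0
        while len(chosen) < w - 1:
            if proposed >= budget:
                raise RuntimeError("representative sampling exceeded its proposal budget")
            lab = tuple(sorted(rng.permutation(total)[: design.n].tolist()))
            proposed += 1
            if without:
                if lab in seen:
                    continue
                seen.add(lab)
            chosen.append(lab)

    payloads = np.empty((w, total), dtype=np.intp)
    payloads[0] = np.arange(total)
    for j, lab in enumerate(chosen, start=1):
        payloads[j] = representative_payload(lab, total)
    return DrawnVector(Kind.INDEX_PERMUTATION, payloads, scheme, record)


# ---------------------------------------------------------------------------
# balanced permutations (negative control: not a group)
# ---------------------------------------------------------------------------


def balanced_permutation_set(design: TwoSampleDesign, verify: bool = True) -> TransformationSet:
    """Class representatives whose case arm mixes exactly half of each arm.

    The returned set contains one canonical representative per balanced
    class label (a case-subset with ``n/2`` original cases and ``n/2``
    original controls). It is never a group: it lacks the identity and is
    not closed under composition.
    """
    n = design.n
    if n % 2:
        raise ValueError(f"balanced permutations require an even arm size, got n={n}")
    half = n // 2
    payload_rows = []
    for cases_part in itertools.combinations(range(n), half):
        for controls_part in itertools.combinations(range(n, 2 * n), half):
            label = sorted(cases_part + controls_part)
            payload_rows.append(representative_payload(label, design.total))
    out = TransformationSet(
        kind=Kind.INDEX_PERMUTATION, payloads=np.stack(payload_rows)
    )
    if verify and len(out) <= 10_000:
        out = verify_group(out)
        assert out.group_certificate is Certificate.VERIFIED_NOT_GROUP
    return out


def balanced_permutation_multiset(design: TwoSampleDesign, cap: int = 1_000_000) -> TransformationSet:
    """Every balanced permutation (all within-arm arrangements, not just the
    canonical class representatives): ``C(n, n/2)^2 * n! * n!`` elements.

    This is the set actually warned against in practice; the representative
    set alone does not reproduce the anti-conservativeness because the rank
    threshold of the rejection rule depends on class multiplicities.
    """
    n = design.n
    if n % 2:
        raise ValueError(f"balanced permutations require an even arm size, got n={n}")
    half = n // 2
    total = design.total
    size = math.comb(n, half) ** 2 * math.factorial(n) ** 2
    if size > cap:
        raise ValueError(f"balanced multiset would have {size} elements (cap {cap})")
    rows = []
    for cases_part in itertools.combinations(range(n), half):
        for controls_part in itertools.combinations(range(n, 2 * n), half):
            label = sorted(cases_part + controls_part)
            rest = sorted(set(range(total)) - set(label))
            for front in itertools.permutations(label):
                for back in itertools.permutations(rest):
                    rows.append(front + back)
    return TransformationSet(
        kind=Kind.INDEX_PERMUTATION, payloads=np.array(rows, dtype=np.intp)
    )


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def rotation_subset(
    d: int, size: int, rng: "np.random.Generator | int | None" = None
) -> RotationDesign:
    """A finite subset ``G*`` of 2-D rotations: the identity plus
    ``size - 1`` rotations by iid uniform angles on ``[0, 2*pi)``."""
    if d != 2:
        raise NotImplementedError("only d=2 rotation designs are implemented")
    if size < 1:
        raise ValueError("size must be at least 1")
    rng = as_rng(rng)
    thetas = np.concatenate([[0.0], rng.uniform(0.0, 2.0 * np.pi, size=size - 1)])
    payloads = np.stack([rotation_matrix(t) for t in thetas])
    g_star = TransformationSet(
        kind=Kind.ROTATION, payloads=payloads, identity_index=0
    )
    return RotationDesign(d=2, g_star=g_star)
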