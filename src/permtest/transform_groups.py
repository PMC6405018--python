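"""Transformations, finite transformation sets, and random-draw schemes.

Three kinds of invertible data transformations are supported:

* ``index_permutation`` — an index bijection ``p`` acting by ``(gX)_i = X_{p[i]}``
  (0-based);
* ``sign_flip`` — a vector in ``{-1, +1}^n`` acting elementwise;
* ``rotation`` — an orthogonal ``d x d`` matrix with determinant ``+1``.

A :class:`TransformationSet` is an ordered finite collection of same-kind
transformations carrying a group certificate; :func:`verify_group` checks the
group axioms exhaustively. :func:`draw_transformations` implements the random
sampling schemes in which the identity is always placed first.
"""

from __future__ import annotations

import enum
import itertools
import json
import math
from dataclasses import dataclass

import numpy as np

from ._util import as_rng

__all__ = [
    "Kind",
    "Certificate",
    "Scheme",
    "Transformation",
    "TransformationSet",
    "DrawnVector",
    "SymmetricGroup",
    "SignFlipGroup",
    "identity",
    "compose",
    "inverse",
    "verify_group",
    "orbit",
    "draw_transformations",
    "symmetric_group_set",
    "sign_flip_group_set",
    "apply_payloads",
    "compose_payloads_right",
]

#: Tolerance for the orthogonality / determinant checks on rotation payloads.
#: Rotations are constructed, not measured, so this can be tight.
ORTHOGONALITY_TOL = 1e-10

#: Decimals used when encoding rotation payloads into hashable keys.
KEY_DECIMALS = 12

#: Proposal budget multiplier for deduplicated without-replacement sampling.
REJECTION_FACTOR = 1000

#: Default cap on the O(#S^2) axiom check of :func:`verify_group`.
VERIFY_CAP = 10_000


class Kind(str, enum.Enum):
    INDEX_PERMUTATION = "index_permutation"
    SIGN_FLIP = "sign_flip"
    ROTATION = "rotation"


class Certificate(str, enum.Enum):
    VERIFIED_GROUP = "verified_group"
    VERIFIED_NOT_GROUP = "verified_not_group"
    UNVERIFIED = "unverified"


class Scheme(str, enum.Enum):
    WITH_REPLACEMENT = "with_replacement"
    WITHOUT_REPLACEMENT = "without_replacement"
    REPRESENTATIVES_WITH_REPLACEMENT = "representatives_with_replacement"
    REPRESENTATIVES_WITHOUT_REPLACEMENT = "representatives_without_replacement"


def _validate_payload(kind: Kind, payload: np.ndarray) -> np.ndarray:
    if kind is Kind.INDEX_PERMUTATION:
        payload = np.asarray(payload, dtype=np.intp)
        if payload.ndim != 1:
            raise ValueError("index permutation payload must be 1-D")
        n = payload.size
        if not np.array_equal(np.sort(payload), np.arange(n)):
            raise ValueError("payload is not a bijection of {0..n-1}")
    elif kind is Kind.SIGN_FLIP:
        payload = np.asarray(payload, dtype=np.int8)
        if payload.ndim != 1 or not np.all(np.abs(payload) == 1):
            raise ValueError("sign flip payload entries must be exactly +/-1")
    elif kind is Kind.ROTATION:
        payload = np.asarray(payload, dtype=float)
        if payload.ndim != 2 or payload.shape[0] != payload.shape[1]:
            raise ValueError("rotation payload must be a square matrix")
        d = payload.shape[0]
        if np.max(np.abs(payload.T @ payload - np.eye(d))) > ORTHOGONALITY_TOL:
            raise ValueError("rotation payload is not orthogonal within tolerance")
        if abs(np.linalg.det(payload) - 1.0) > ORTHOGONALITY_TOL:
            raise ValueError("rotation payload must have determinant +1")
    else:  # pragma: no cover - enum exhausts kinds
        raise ValueError(f"unknown kind {kind!r}")
    payload.setflags(write=False)
    return payload


@dataclass(frozen=True, eq=False)
class Transformation:
    """A single invertible map on data vectors."""

    kind: Kind
    payload: np.ndarray

    def __post_init__(self) -> None:
        kind = Kind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "payload", _validate_payload(kind, self.payload))

    @property
    def dim(self) -> int:
        return int(self.payload.shape[0])

    def key(self) -> tuple:
        """Canonical hashable encoding (exact for permutations and signs;
        rotations rounded to :data:`KEY_DECIMALS` decimals)."""
        return payload_key(self.kind, self.payload)

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if self.kind is Kind.INDEX_PERMUTATION:
            return x[self.payload]
        if self.kind is Kind.SIGN_FLIP:
            return self.payload * x
        return self.payload @ x

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.apply(x)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Transformation):
            return NotImplemented
        return self.kind is other.kind and self.key() == other.key()

    def __hash__(self) -> int:
        return hash((self.kind, self.key()))

    def __repr__(self) -> str:
        return f"Transformation({self.kind.value}, {self.payload.tolist()})"

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind.value, "payload": self.payload.tolist()})

    @staticmethod
    def from_json(text: str) -> "Transformation":
        obj = json.loads(text)
        return Transformation(Kind(obj["kind"]), np.asarray(obj["payload"]))


def payload_key(kind: Kind, payload: np.ndarray) -> tuple:
    if kind is Kind.ROTATION:
        return tuple(np.round(payload, KEY_DECIMALS).ravel().tolist())
    return tuple(payload.tolist())


def identity(kind: Kind, n: int) -> Transformation:
    """The identity transformation of the given kind and dimension."""
    kind = Kind(kind)
    if kind is Kind.INDEX_PERMUTATION:
        return Transformation(kind, np.arange(n))
    if kind is Kind.SIGN_FLIP:
        return Transformation(kind, np.ones(n, dtype=np.int8))
    return Transformation(kind, np.eye(n))


def identity_payload(kind: Kind, n: int) -> np.ndarray:
    return identity(kind, n).payload


def _check_compatible(g: Transformation, h: Transformation) -> None:
    if g.kind is not h.kind:
        raise ValueError(f"kind mismatch: {g.kind.value} vs {h.kind.value}")
    if g.dim != h.dim:
        raise ValueError(f"dimension mismatch: {g.dim} vs {h.dim}")


def compose(g: Transformation, h: Transformation) -> Transformation:
    """The composite map ``x -> g(h(x))``.

    For index permutations under the action ``(gX)_i = X_{p_g[i]}`` the
    composite payload is ``q[i] = p_h[p_g[i]]``.
    """
    _check_compatible(g, h)
    if g.kind is Kind.INDEX_PERMUTATION:
        return Transformation(g.kind, h.payload[g.payload])
    if g.kind is Kind.SIGN_FLIP:
        return Transformation(g.kind, g.payload * h.payload)
    return Transformation(g.kind, g.payload @ h.payload)


def inverse(g: Transformation) -> Transformation:
    """The transformation with ``compose(g, inverse(g)) == identity``."""
    if g.kind is Kind.INDEX_PERMUTATION:
        return Transformation(g.kind, np.argsort(g.payload))
    if g.kind is Kind.SIGN_FLIP:
        return g  # sign flips are involutions
    return Transformation(g.kind, g.payload.T.copy())


# ---------------------------------------------------------------------------
# batched payload operations (hot paths avoid per-element objects)
# ---------------------------------------------------------------------------


def apply_payloads(x: np.ndarray, kind: Kind, payloads: np.ndarray) -> np.ndarray:
    """Apply a stack of same-kind payloads to one data vector.

    Returns an array whose row ``j`` is ``g_j(x)``.
    """
    x = np.asarray(x)
    if kind is Kind.INDEX_PERMUTATION:
        return x[payloads]
    if kind is Kind.SIGN_FLIP:
        return payloads * x
    return payloads @ x  # (N, d, d) @ (d,) -> (N, d)


def compose_payloads_right(payloads: np.ndarray, kind: Kind, h: Transformation) -> np.ndarray:
    """Payload stack of ``g ∘ h`` for each row ``g`` of ``payloads``."""
    if kind is not Kind(h.kind):
        raise ValueError("kind mismatch in batched composition")
    if kind is Kind.INDEX_PERMUTATION:
        return h.payload[payloads]
    if kind is Kind.SIGN_FLIP:
        return payloads * h.payload
    return payloads @ h.payload


def _stack_keys(kind: Kind, payloads: np.ndarray) -> "list[tuple]":
    if kind is Kind.ROTATION:
        rounded = np.round(payloads, KEY_DECIMALS)
        return [tuple(m.ravel().tolist()) for m in rounded]
    return [tuple(row.tolist()) for row in payloads]


# ---------------------------------------------------------------------------
# TransformationSet
# ---------------------------------------------------------------------------


class TransformationSet:
    """An ordered finite collection of same-kind transformations.

    May be constructed from a list of :class:`Transformation` or directly
    from a stacked payload array (``kind`` + ``payloads``); elements are then
    materialized lazily, which keeps large enumerated groups cheap.
    """

    def __init__(
        self,
        elements: "list[Transformation] | None" = None,
        group_certificate: Certificate = Certificate.UNVERIFIED,
        identity_index: "int | None" = None,
        *,
        kind: "Kind | None" = None,
        payloads: "np.ndarray | None" = None,
        violation: "tuple | None" = None,
    ) -> None:
        if elements is not None:
            if not elements:
                raise ValueError("a TransformationSet cannot be empty")
            kinds = {Kind(g.kind) for g in elements}
            if len(kinds) > 1:
                raise ValueError("all elements must have the same kind")
            dims = {g.dim for g in elements}
            if len(dims) > 1:
                raise ValueError("all elements must have the same dimension")
            self._elements: "list[Transformation] | None" = list(elements)
            self._kind = kinds.pop()
            self._payloads: "np.ndarray | None" = None
        else:
            if kind is None or payloads is None:
                raise ValueError("provide either elements or (kind, payloads)")
            payloads = np.asarray(payloads)
            if payloads.shape[0] == 0:
                raise ValueError("a TransformationSet cannot be empty")
            self._elements = None
            self._kind = Kind(kind)
            self._payloads = payloads
        self.group_certificate = Certificate(group_certificate)
        self.identity_index = identity_index
        self.violation = violation

    # -- structure -----------------------------------------------------

    @property
    def kind(self) -> Kind:
        return self._kind

    @property
    def elements(self) -> "list[Transformation]":
        if self._elements is None:
            self._elements = [
                Transformation(self._kind, row) for row in self._payloads
            ]
        return self._elements

    @property
    def payloads(self) -> np.ndarray:
        if self._payloads is None:
            self._payloads = np.stack([g.payload for g in self._elements])
        return self._payloads

    @property
    def dim(self) -> int:
        return int(self.payloads.shape[1])

    def __len__(self) -> int:
        if self._payloads is not None:
            return int(self._payloads.shape[0])
        return len(self._elements)

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, i: int) -> Transformation:
        if self._elements is not None:
            return self._elements[i]
        return Transformation(self._kind, self._payloads[i])

    def keys(self) -> "list[tuple]":
        return _stack_keys(self._kind, self.payloads)

    # -- behavior ------------------------------------------------------

    def apply_all(self, x: np.ndarray) -> np.ndarray:
        """Stack of transformed data vectors, one row per element."""
        return apply_payloads(x, self._kind, self.payloads)

    def with_certificate(
        self,
        certificate: Certificate,
        identity_index: "int | None" = None,
        violation: "tuple | None" = None,
    ) -> "TransformationSet":
        out = TransformationSet(
            kind=self._kind,
            payloads=self.payloads,
            group_certificate=certificate,
            identity_index=identity_index,
            violation=violation,
        )
        out._elements = self._elements
        return out

    def __repr__(self) -> str:
        return (
            f"TransformationSet(kind={self._kind.value}, size={len(self)}, "
            f"certificate={self.group_certificate.value})"
        )


def verify_group(S: TransformationSet, cap: int = VERIFY_CAP) -> TransformationSet:
    """Check the group axioms exhaustively and certify the set.

    The axioms are checked in the order identity, closure, inverses; the
    returned set's ``violation`` attribute records the first violated axiom
    and a witness (element indices) when the set is not a group.

    Raises if the set exceeds ``cap`` elements (the check is O(#S^2)); pass
    verified structure explicitly for large groups.
    """
    n_el = len(S)
    if n_el > cap:
        raise ValueError(
            f"verify_group refuses {n_el} > cap={cap} elements; construct the "
            "set with a known certificate instead (e.g. symmetric_group_set)"
        )
    keys = S.keys()
    index = {}
    for i, key in enumerate(keys):
        if key in index:
            raise ValueError(f"elements must be pairwise distinct (rows {index[key]} and {i})")
        index[key] = i

    id_key = payload_key(S.kind, identity_payload(S.kind, S.dim))
    id_idx = index.get(id_key)
    if id_idx is None:
        return S.with_certificate(
            Certificate.VERIFIED_NOT_GROUP, violation=("identity", None)
        )

    payloads = S.payloads
    for j in range(n_el):
        h = S[j]
        composed = compose_payloads_right(payloads, S.kind, h)
        for i, key in enumerate(_stack_keys(S.kind, composed)):
            if key not in index:
                return S.with_certificate(
                    Certificate.VERIFIED_NOT_GROUP,
                    identity_index=id_idx,
                    violation=("closure", (i, j)),
                )
    for i in range(n_el):
        inv_key = payload_key(S.kind, inverse(S[i]).payload)
        if inv_key not in index:  # unreachable for finite closed sets, kept for safety
            return S.with_certificate(
                Certificate.VERIFIED_NOT_GROUP,
                identity_index=id_idx,
                violation=("inverse", (i,)),
            )
    return S.with_certificate(Certificate.VERIFIED_GROUP, identity_index=id_idx)


def orbit(x: np.ndarray, S: TransformationSet) -> "list[np.ndarray]":
    """All distinct images ``{g(x): g in S}`` (small sets; oracle/testing use)."""
    transformed = S.apply_all(np.asarray(x, dtype=float))
    seen = set()
    out = []
    for row in transformed:
        key = tuple(np.round(row, KEY_DECIMALS).tolist())
        if key not in seen:
            seen.add(key)
            out.append(row)
    return out


# ---------------------------------------------------------------------------
# implicit large groups and enumerated small groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymmetricGroup:
    """Implicit representation of all permutations of ``n`` items."""

    n: int

    kind = Kind.INDEX_PERMUTATION

    @property
    def size(self) -> int:
        return math.factorial(self.n)

    def identity_payload(self) -> np.ndarray:
        return np.arange(self.n)

    def sample_payloads(self, count: int, rng: np.random.Generator) -> np.ndarray:
        # argsort of iid uniforms is a uniform random permutation
        return np.argsort(rng.random((count, self.n)), axis=1)


@dataclass(frozen=True)
class SignFlipGroup:
    """Implicit representation of ``{-1, +1}^n`` acting elementwise."""

    n: int

    kind = Kind.SIGN_FLIP

    @property
    def size(self) -> int:
        return 2**self.n

    def identity_payload(self) -> np.ndarray:
        return np.ones(self.n, dtype=np.int8)

    def sample_payloads(self, count: int, rng: np.random.Generator) -> np.ndarray:
        return (rng.integers(0, 2, size=(count, self.n)) * 2 - 1).astype(np.int8)


def symmetric_group_set(n: int, cap: int = math.factorial(8)) -> TransformationSet:
    """All ``n!`` index permutations, certified as a group by construction."""
    if math.factorial(n) > cap:
        raise ValueError(f"refusing to enumerate S_{n} ({math.factorial(n)} elements)")
    payloads = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    return TransformationSet(
        kind=Kind.INDEX_PERMUTATION,
        payloads=payloads,
        group_certificate=Certificate.VERIFIED_GROUP,
        identity_index=0,
    )


def sign_flip_group_set(n: int, cap: int = 2**16) -> TransformationSet:
    """All ``2^n`` sign-flip vectors, certified as a group by construction."""
    if 2**n > cap:
        raise ValueError(f"refusing to enumerate 2^{n} sign flips")
    payloads = np.array(list(itertools.product((1, -1), repeat=n)), dtype=np.int8)
    return TransformationSet(
        kind=Kind.SIGN_FLIP,
        payloads=payloads,
        group_certificate=Certificate.VERIFIED_GROUP,
        identity_index=0,
    )


# ---------------------------------------------------------------------------
# DrawnVector and draw_transformations
# ---------------------------------------------------------------------------


class DrawnVector:
    """An ordered vector ``(g_1, ..., g_w)`` of transformations, ``g_1 = id``.

    Stores the stacked payloads; the ``transformations`` list is materialized
    lazily so that simulation hot loops never build per-element objects.
    """

    def __init__(
        self,
        kind: Kind,
        payloads: np.ndarray,
        scheme: Scheme,
        seed_record: "dict | None" = None,
    ) -> None:
        self.kind = Kind(kind)
        self.payloads = np.asarray(payloads)
        self.scheme = Scheme(scheme)
        self.seed_record = seed_record or {}
        self.w = int(self.payloads.shape[0])
        if self.w < 1:
            raise ValueError("w must be at least 1")
        self.assert_identity_first()

    def assert_identity_first(self) -> None:
        id_payload = identity_payload(self.kind, int(self.payloads.shape[1]))
        if not np.array_equal(self.payloads[0], id_payload):
            raise ValueError("g_1 must be the identity transformation")

    @property
    def transformations(self) -> "list[Transformation]":
        return [Transformation(self.kind, row) for row in self.payloads]

    def apply_all(self, x: np.ndarray) -> np.ndarray:
        return apply_payloads(x, self.kind, self.payloads)

    def __len__(self) -> int:
        return self.w

    def __repr__(self) -> str:
        return f"DrawnVector(kind={self.kind.value}, w={self.w}, scheme={self.scheme.value})"


def _seed_record(rng: np.random.Generator, scheme: Scheme, w: int) -> dict:
    return {
        "bit_generator": type(rng.bit_generator).__name__,
        "state": rng.bit_generator.state,
        "scheme": Scheme(scheme).value,
        "w": w,
    }


def _draw_without_replacement_implicit(
    spec, w: int, rng: np.random.Generator
) -> np.ndarray:
    """Deduplicated rejection sampling from an implicit group, excluding id."""
    n = spec.n
    id_row = spec.identity_payload()
    if w == 1:
        return id_row[None].copy()
    seen = {tuple(id_row.tolist())}
    rows: "list[np.ndarray]" = []
    budget = REJECTION_FACTOR * w
    proposed = 0
    while len(rows) < w - 1:
        batch = max(w - 1 - len(rows), 32)
        if proposed + batch > budget:
            batch = budget - proposed
            if batch <= 0:
                raise RuntimeError(
                    "without-replacement sampling exceeded its proposal budget; "
                    "w is too close to the group size"
                )
        proposals = spec.sample_payloads(batch, rng)
        proposed += batch
        for row in proposals:
            key = tuple(row.tolist())
            if key not in seen:
                seen.add(key)
                rows.append(row)
                if len(rows) == w - 1:
                    break
    out = np.empty((w, n), dtype=id_row.dtype)
    out[0] = id_row
    out[1:] = np.stack(rows)
    return out


def draw_transformations(
    G,
    w: int,
    scheme: "Scheme | str" = Scheme.WITH_REPLACEMENT,
    rng: "np.random.Generator | int | None" = None,
) -> DrawnVector:
    """Draw ``(id, g_2, ..., g_w)`` uniformly from a group.

    ``G`` may be an explicit :class:`TransformationSet` containing the
    identity, or an implicit :class:`SymmetricGroup` / :class:`SignFlipGroup`.
    With replacement, ``g_2..g_w`` are iid uniform on ``G``; without
    replacement they are a uniform sample from ``G \\ {id}`` (for implicit
    groups realized by deduplicated rejection sampling on canonical payload
    encodings).
    """
    scheme = Scheme(scheme)
    if scheme not in (Scheme.WITH_REPLACEMENT, Scheme.WITHOUT_REPLACEMENT):
        raise ValueError("draw_transformations handles only plain (non-representative) schemes")
    if w < 1:
        raise ValueError("w must be at least 1")
    rng = as_rng(rng)
    record = _seed_record(rng, scheme, w)

    if isinstance(G, TransformationSet):
        n_el = len(G)
        keys = G.keys()
        id_key = payload_key(G.kind, identity_payload(G.kind, G.dim))
        try:
            id_idx = keys.index(id_key)
        except ValueError:
            raise ValueError("identity-first sampling requires the identity in G") from None
        if scheme is Scheme.WITH_REPLACEMENT:
            idx = rng.integers(0, n_el, size=w - 1)
        else:
            if w > n_el:
                raise ValueError(f"w={w} exceeds #G={n_el} under without_replacement")
            others = np.delete(np.arange(n_el), id_idx)
            idx = rng.choice(others, size=w - 1, replace=False)
        payloads = np.concatenate(
            [G.payloads[id_idx][None], G.payloads[idx]], axis=0
        )
        return DrawnVector(G.kind, payloads, scheme, record)

    if isinstance(G, (SymmetricGroup, SignFlipGroup)):
        if scheme is Scheme.WITH_REPLACEMENT:
            drawn = G.sample_payloads(w - 1, rng)
            payloads = np.empty((w, G.n), dtype=drawn.dtype)
            payloads[0] = G.identity_payload()
            payloads[1:] = drawn
        else:
            if w > G.size:
                raise ValueError(f"w={w} exceeds #G={G.size} under without_replacement")
            payloads = _draw_without_replacement_implicit(G, w, rng)
        return DrawnVector(G.kind, payloads, scheme, record)

    raise TypeError(f"unsupported group specification: {type(G).__name__}")
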