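"""Secure set-operation protocols over shared presence vectors.

Given two genomes encoded against the same panel as m-bit vectors a and b
(held only as secret shares), each set operation has an elementwise
arithmetization over Z_p whose result vector c contains a 1 exactly where
the operation's set contains the panel variant:

* union            c_i = a_i + b_i - a_i b_i       (c_i = 1 iff a_i or b_i)
* intersection     c_i = a_i b_i                   (both)
* difference A\\B   c_i = a_i - a_i b_i             (a_i and not b_i)
* symmetric diff   c_i = a_i + b_i - 2 a_i b_i     (exactly one)

Each protocol multiplies elementwise (m secure multiplications, one round),
then sums the result shares locally — a communication-free affine step —
and opens the single summed share to the user, who reconstructs the
cardinality. Jaccard similarity J = |A∩B| / |A∪B| opens the two sizes to
the user, who divides in the clear; by default the union size is derived
from the identity |A∪B| = |A| + |B| - |A∩B|, halving the triple cost.

Every protocol also has a vector-producing variant that stops before the
final summation, yielding the shared result vector itself; opening that
vector reveals per-position information and is gated behind an explicit
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

from .config import ProtocolConfig
from .runtime import Handle, MpcSession
from .sharing import InconsistentSharesError, ShareVector

SET_OPS = ("union", "intersect", "difference", "symdifference")


class PanelBindingError(ValueError):
    """Inputs are bound to different panels and must not be compared."""


@dataclass(frozen=True)
class CardinalityResult:
    """The reconstructed size of one set operation, as learned by the user."""

    op: str
    size: int

    def __post_init__(self) -> None:
        if self.op not in SET_OPS:
            raise ValueError(f"unknown set operation {self.op!r}")
        if self.size < 0:
            raise ValueError(f"cardinality cannot be negative: {self.size}")


@dataclass(frozen=True)
class JaccardResult:
    """Intersection and union sizes plus their ratio J = |A∩B| / |A∪B|.

    When the union is empty J is undefined and flagged as such (``jaccard``
    is None), never silently reported as 0.
    """

    intersection_size: int
    union_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.intersection_size <= self.union_size:
            raise ValueError(
                f"need 0 <= intersection <= union, got "
                f"{self.intersection_size} and {self.union_size}"
            )

    @property
    def defined(self) -> bool:
        return self.union_size > 0

    @property
    def jaccard(self) -> Optional[Fraction]:
        if not self.defined:
            return None
        return Fraction(self.intersection_size, self.union_size)


Input = Union[Handle, Sequence[ShareVector]]


def _as_handle(session: MpcSession, x: Input) -> Handle:
    if isinstance(x, Handle):
        return x
    return session.load_shares(list(x))


def _check_pair(a: Handle, b: Handle) -> None:
    if a.length != b.length:
        raise InconsistentSharesError(
            f"vector lengths differ: {a.length} vs {b.length}"
        )
    if a.panel_digest != b.panel_digest:
        raise PanelBindingError(
            "inputs are bound to different panels; re-encode against a "
            "common panel before comparing"
        )


# -- vector-producing variants (shared result vector, no final summation) --


def union_vector(session: MpcSession, a: Input, b: Input) -> Handle:
    ha, hb = _as_handle(session, a), _as_handle(session, b)
    _check_pair(ha, hb)
    ab = session.mul(ha, hb)
    return session.sub(session.add(ha, hb), ab)


def intersection_vector(session: MpcSession, a: Input, b: Input) -> Handle:
    ha, hb = _as_handle(session, a), _as_handle(session, b)
    _check_pair(ha, hb)
    return session.mul(ha, hb)


def difference_vector(session: MpcSession, a: Input, b: Input) -> Handle:
    """Shared indicator of A \\ B — not symmetric in its arguments."""
    ha, hb = _as_handle(session, a), _as_handle(session, b)
    _check_pair(ha, hb)
    return session.sub(ha, session.mul(ha, hb))


def symdifference_vector(session: MpcSession, a: Input, b: Input) -> Handle:
    ha, hb = _as_handle(session, a), _as_handle(session, b)
    _check_pair(ha, hb)
    ab = session.mul(ha, hb)
    return session.sub(session.add(ha, hb), session.scale(ab, 2))


def open_result_vector(
    session: MpcSession, vec: Handle, reveal_positions: bool = False
) -> list[int]:
    """Open a shared result vector to the user.

    This discloses which panel positions are in the result set, far more
    than a cardinality; it therefore requires ``reveal_positions=True``.
    """
    if not reveal_positions:
        raise PermissionError(
            "opening a result vector reveals per-position membership; "
            "pass reveal_positions=True to confirm"
        )
    return session.open_to_user(vec)


_VECTOR_FNS = {
    "union": union_vector,
    "intersect": intersection_vector,
    "difference": difference_vector,
    "symdifference": symdifference_vector,
}


# -- cardinality protocols -------------------------------------------------


def _open_scalar(session: MpcSession, h: Handle) -> int:
    return session.open_to_user(session.sum_components(h))[0]


def secure_union_size(session: MpcSession, a: Input, b: Input) -> CardinalityResult:
    return CardinalityResult("union", _open_scalar(session, union_vector(session, a, b)))


def secure_intersection_size(session: MpcSession, a: Input, b: Input) -> CardinalityResult:
    return CardinalityResult(
        "intersect", _open_scalar(session, intersection_vector(session, a, b))
    )


def secure_difference_size(session: MpcSession, a: Input, b: Input) -> CardinalityResult:
    return CardinalityResult(
        "difference", _open_scalar(session, difference_vector(session, a, b))
    )


def secure_symdifference_size(session: MpcSession, a: Input, b: Input) -> CardinalityResult:
    return CardinalityResult(
        "symdifference", _open_scalar(session, symdifference_vector(session, a, b))
    )


def secure_set_size(session: MpcSession, op: str, a: Input, b: Input) -> CardinalityResult:
    fn = {
        "union": secure_union_size,
        "intersect": secure_intersection_size,
        "difference": secure_difference_size,
        "symdifference": secure_symdifference_size,
    }.get(op)
    if fn is None:
        raise ValueError(f"unknown set operation {op!r}; choose from {SET_OPS}")
    return fn(session, a, b)


def secure_jaccard(
    session: MpcSession,
    a: Input,
    b: Input,
    use_union_identity: bool = True,
) -> JaccardResult:
    """Compute intersection and union sizes securely; the user forms J.

    Only the user learns the two sizes (the opens are directed to the
    user); the compute parties see nothing but uniformly masked values.
    With ``use_union_identity`` (default) the union size is the affine
    combination |A| + |B| - |A∩B| of values already shared, so the whole
    protocol costs m secure multiplications; disabling it runs the direct
    elementwise union protocol as well (2m multiplications).
    """
    ha, hb = _as_handle(session, a), _as_handle(session, b)
    _check_pair(ha, hb)
    inter_sum = session.sum_components(session.mul(ha, hb))
    if use_union_identity:
        pop_sum = session.sum_components(session.add(ha, hb))
        union_sum = session.sub(pop_sum, inter_sum)
    else:
        union_sum = session.sum_components(union_vector(session, ha, hb))
    # one batched open: the user receives shares of both sizes together
    both = _concat_scalars(session, inter_sum, union_sum)
    inter, union = session.open_to_user(both)
    return JaccardResult(intersection_size=inter, union_size=union)


def _concat_scalars(session: MpcSession, x: Handle, y: Handle) -> Handle:
    out = []
    for party in session.parties:
        out.append(list(party.store[x.name]) + list(party.store[y.name]))
    return session._store(out, x.panel_digest)


# -- one-call convenience over plaintext presence vectors ------------------


def secure_compare(
    bits_a: Sequence[int],
    bits_b: Sequence[int],
    config: ProtocolConfig,
    op: str = "jaccard",
    panel_digest: Optional[str] = None,
    session: Optional[MpcSession] = None,
):
    """Share two presence vectors, run one protocol, return the result.

    Deals exactly the preprocessing the chosen protocol needs. Intended for
    simulation and evaluation; in a real deployment sharing happens at the
    two data owners and the session spans distinct machines.
    """
    m = len(bits_a)
    own = session is None
    if session is None:
        session = MpcSession(config)
    try:
        session.preprocess(m)  # every cardinality protocol multiplies once per bit
        rng = session.rng
        ha = session.share_input(list(bits_a), rng)
        hb = session.share_input(list(bits_b), rng)
        ha = Handle(ha.name, ha.length, panel_digest)
        hb = Handle(hb.name, hb.length, panel_digest)
        if op == "jaccard":
            return secure_jaccard(session, ha, hb)
        return secure_set_size(session, op, ha, hb)
    finally:
        if own:
            session.close()


# -- plaintext post-processing of opened sizes -----------------------------


def dice_coefficient(intersection_size: int, union_size: int) -> Optional[Fraction]:
    """Dice coefficient 2|A∩B| / (|A|+|B|), from the same opened sizes
    (|A|+|B| = |A∩B| + |A∪B|). None when both sets are empty."""
    denom = intersection_size + union_size
    if denom == 0:
        return None
    return Fraction(2 * intersection_size, denom)


def overlap_coefficient(
    intersection_size: int, size_a: int, size_b: int
) -> Optional[Fraction]:
    """Overlap coefficient |A∩B| / min(|A|,|B|); needs the set sizes."""
    denom = min(size_a, size_b)
    if denom == 0:
        return None
    return Fraction(intersection_size, denom)
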