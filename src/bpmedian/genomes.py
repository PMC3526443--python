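"""Circular genome models and the breakpoint distance.

A genome is a single circular chromosome carrying the genes ``1..n``, each
exactly once.  In the unsigned model only the cyclic order matters; in the
signed model every gene additionally carries an orientation (``+`` or ``-``),
and a gene has two *extremities* — a tail and a head — that are traversed
tail-to-head when the gene is read forward.

Two circular arrangements that differ only by rotation, or by reading the
circle in the opposite direction (reversing the order and, in the signed
case, flipping every orientation), describe the same genome.  All genome
objects here are canonicalized on construction so that value equality and
hashing coincide with this circular equivalence.

The breakpoint distance between two genomes on the same gene set is
``d(A, B) = n - adj(A, B)`` where ``adj(A, B)`` counts the adjacencies
(unordered neighbour pairs; extremity pairs in the signed case) common to
both.  It is a metric, bounded by ``n``, and ``d/n`` is bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Union

__all__ = [
    "UnsignedGenome",
    "SignedGenome",
    "Genome",
    "Extremity",
    "AdjacencySet",
    "canonical_form",
    "adjacencies",
    "shared_adjacencies",
    "breakpoint_distance",
    "normalized_distance",
    "in_neighborhood",
]

MIN_GENES = 3  # circular genomes with fewer genes have degenerate adjacencies


class GenomeError(ValueError):
    """Raised for invalid genome content or incompatible genome pairs."""


def _validate_labels(labels: Iterable[int]) -> tuple[int, ...]:
    labels = tuple(int(g) for g in labels)
    n = len(labels)
    if n < MIN_GENES:
        raise GenomeError(f"a circular genome needs at least {MIN_GENES} genes, got {n}")
    if sorted(labels) != list(range(1, n + 1)):
        raise GenomeError(f"gene labels must be a permutation of 1..{n}, got {labels}")
    return labels


class Extremity(NamedTuple):
    """One end of a signed gene; ``end`` is ``"tail"`` or ``"head"``."""

    gene: int
    end: Literal["tail", "head"]


@dataclass(frozen=True)
class UnsignedGenome:
    """Circular order of genes ``1..n``, canonical up to rotation/reflection.

    The stored ``order`` is the canonical linearization: gene 1 first, then
    the lexicographically smaller of the two reading directions.
    """

    order: tuple[int, ...]

    def __init__(self, order: Iterable[int]):
        labels = _validate_labels(order)
        object.__setattr__(self, "order", _canonical_unsigned(labels))

    @property
    def n(self) -> int:
        return len(self.order)

    @property
    def signed(self) -> bool:
        return False

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"UnsignedGenome({','.join(map(str, self.order))})"


@dataclass(frozen=True)
class SignedGenome:
    """Circular order of oriented genes, stored as signed integers.

    ``order[i]`` is ``+g`` for gene g read tail-to-head, ``-g`` for the
    reverse orientation.  Reversing the circle and negating every sign gives
    the same genome; canonicalization picks the lexicographically minimal of
    all 2n such linearizations.
    """

    order: tuple[int, ...]

    def __init__(self, order: Iterable[int]):
        signed_order = tuple(int(g) for g in order)
        if any(g == 0 for g in signed_order):
            raise GenomeError("0 is not a valid signed gene label")
        _validate_labels(abs(g) for g in signed_order)
        object.__setattr__(self, "order", _canonical_signed(signed_order))

    @property
    def n(self) -> int:
        return len(self.order)

    @property
    def signed(self) -> bool:
        return True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "SignedGenome(%s)" % ",".join(f"{g:+d}" for g in self.order)


Genome = Union[UnsignedGenome, SignedGenome]


def _canonical_unsigned(order: tuple[int, ...]) -> tuple[int, ...]:
    i = order.index(1)
    fwd = order[i:] + order[:i]
    rev = (1,) + tuple(reversed(fwd[1:]))
    return min(fwd, rev)


def _canonical_signed(order: tuple[int, ...]) -> tuple[int, ...]:
    # minimum over all 2n rotations/reflections under the label-major key
    # (|gene|, sign): every competing linearization starts with a key no
    # smaller than (1, +), and exactly one reading direction shows gene 1
    # forward — so that single rotation is the canonical form, in O(n)
    n = len(order)
    idx = next(i for i, g in enumerate(order) if abs(g) == 1)
    if order[idx] > 0:
        return order[idx:] + order[:idx]
    reflected = tuple(-g for g in reversed(order))
    j = n - 1 - idx
    return reflected[j:] + reflected[:j]


def canonical_form(genome: Genome) -> tuple[int, ...]:
    """Canonical linearization; identical for every rotation/reflection."""
    return genome.order


@dataclass(frozen=True)
class AdjacencySet:
    """The ``n`` unordered neighbour pairs of a circular genome.

    Unsigned pairs are gene pairs; signed pairs are Extremity pairs (the
    trailing extremity of one gene joined to the leading extremity of the
    next), which makes the adjacency ``gh`` equal to ``-h -g`` by
    construction.
    """

    pairs: frozenset[frozenset]
    n: int
    signed: bool = field(default=False)

    def __post_init__(self):
        if len(self.pairs) != self.n:
            raise GenomeError(
                f"adjacency set must have exactly n={self.n} pairs, got {len(self.pairs)}"
            )

    def __and__(self, other: "AdjacencySet") -> frozenset:
        return self.pairs & other.pairs


def _signed_extremity_pair(g: int, h: int) -> frozenset:
    """Adjacency joining the trailing end of signed gene g to the leading end of h."""
    trail = Extremity(abs(g), "head" if g > 0 else "tail")
    lead = Extremity(abs(h), "tail" if h > 0 else "head")
    return frozenset((trail, lead))


def adjacencies(genome: Genome) -> AdjacencySet:
    """All ``n`` adjacencies of a genome, including the wrap-around pair."""
    order = genome.order
    n = len(order)
    if isinstance(genome, SignedGenome):
        pairs = frozenset(
            _signed_extremity_pair(order[i], order[(i + 1) % n]) for i in range(n)
        )
        return AdjacencySet(pairs, n, signed=True)
    pairs = frozenset(frozenset((order[i], order[(i + 1) % n])) for i in range(n))
    return AdjacencySet(pairs, n, signed=False)


def _check_comparable(a: Genome, b: Genome) -> int:
    if a.signed != b.signed:
        raise GenomeError("cannot compare signed with unsigned genomes")
    if a.n != b.n:
        raise GenomeError(f"gene counts differ: {a.n} vs {b.n}")
    return a.n


def shared_adjacencies(a: Genome, b: Genome) -> int:
    """adj(A, B): the number of adjacencies common to both genomes."""
    _check_comparable(a, b)
    return len(adjacencies(a) & adjacencies(b))


def breakpoint_distance(a: Genome, b: Genome) -> int:
    """Breakpoint distance ``d(A, B) = n - adj(A, B)`` (exact integer)."""
    n = _check_comparable(a, b)
    return n - shared_adjacencies(a, b)


def normalized_distance(a: Genome, b: Genome) -> float:
    """``d(A, B) / n`` — in [0, 1]; the metric in which neighbourhoods live."""
    n = _check_comparable(a, b)
    return breakpoint_distance(a, b) / n


def in_neighborhood(a: Genome, b: Genome, eps: float) -> bool:
    """True iff B lies in the open normalized-distance ball of radius eps around A."""
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    return normalized_distance(a, b) < eps
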