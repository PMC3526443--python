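"""Synthetic genome generation: the study's only inputs.

Three generators cover the simulation designs:

* ``identity_genome`` — the identity circular permutation ``1, 2, ..., n``
  (all orientations ``+`` in the signed case), the common ancestor from
  which scrambled genomes are derived.
* ``swap_randomize`` — progressive randomization by repeatedly swapping the
  genes at two random positions.  Each swap touches at most four
  adjacencies, so a single swap moves the breakpoint distance by at most 4.
  In the signed case the orientation of each swapped gene is re-drawn
  uniformly.  This is a deliberately model-agnostic scrambler, not a
  biological rearrangement model.
* ``uniform_random_genome`` — a uniform draw from all circular genomes on
  ``n`` genes, implemented as a uniform random linear permutation read
  circularly (every circular equivalence class has the same number of
  linear representatives, so this is uniform over classes), plus uniform
  orientations when signed.

RNG contract: every function takes a ``numpy.random.Generator`` and
consumes draws in a documented order so trajectories are replayable.
``swap_randomize`` draws, per swap: position ``i = rng.integers(n)``, then
``j = rng.integers(n - 1)`` shifted up by one if ``j >= i`` (so i != j);
signed genomes then re-draw the signs of the two swapped positions in
ascending position order via ``rng.integers(2)`` (0 sets ``+``, 1 sets ``-``).
``uniform_random_genome`` draws ``rng.permutation(n)`` first, then (signed)
``rng.integers(2, size=n)`` sign bits in gene-position order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import (
    Genome,
    SignedGenome,
    UnsignedGenome,
    shared_adjacencies,
)

__all__ = [
    "RandomizationConfig",
    "AdjacencyCountSummary",
    "identity_genome",
    "swap_randomize",
    "uniform_random_genome",
    "shared_adjacency_stats",
    "swaps_for_rate",
]


@dataclass(frozen=True)
class RandomizationConfig:
    """Parameters of one swap-randomization run."""

    n: int
    signed: bool
    swaps: int
    seed: int

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("n must be at least 3")
        if self.swaps < 0:
            raise ValueError("swap count must be non-negative")


@dataclass(frozen=True)
class AdjacencyCountSummary:
    """Sample mean/variance of shared-adjacency counts over random genome pairs."""

    reps: int
    mean: float
    variance: float

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be at least 1")


def identity_genome(n: int, signed: bool = False) -> Genome:
    """The identity circular permutation 1..n (all + when signed)."""
    if n < 3:
        raise ValueError(f"n must be at least 3, got {n}")
    order = range(1, n + 1)
    return SignedGenome(order) if signed else UnsignedGenome(order)


def swaps_for_rate(swaps_per_100: float, n: int) -> int:
    """Convert a per-100-genes swap rate to an absolute swap count."""
    return int(round(swaps_per_100 * n / 100))


def swap_randomize(genome: Genome, swaps: int, rng: np.random.Generator) -> Genome:
    """Apply ``swaps`` random gene-position swaps (see module RNG contract)."""
    if swaps < 0:
        raise ValueError("swap count must be non-negative")
    signed = isinstance(genome, SignedGenome)
    order = list(genome.order)
    n = len(order)
    for _ in range(swaps):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        order[i], order[j] = order[j], order[i]
        if signed:
            for pos in sorted((i, j)):
                flip = int(rng.integers(2))
                if flip:
                    order[pos] = -order[pos]
                else:
                    order[pos] = abs(order[pos])
    return SignedGenome(order) if signed else UnsignedGenome(order)


def uniform_random_genome(
    n: int, signed: bool, rng: np.random.Generator
) -> Genome:
    """One uniform draw from the circular genomes on n genes."""
    if n < 3:
        raise ValueError(f"n must be at least 3, got {n}")
    perm = rng.permutation(n) + 1
    if not signed:
        return UnsignedGenome(perm)
    signs = 1 - 2 * rng.integers(2, size=n)  # 0 -> +1, 1 -> -1
    return SignedGenome(perm * signs)


def shared_adjacency_stats(
    n: int, signed: bool, reps: int, rng: np.random.Generator
) -> AdjacencyCountSummary:
    """Mean/variance of adj(A, B) over ``reps`` independent uniform pairs.

    For large n the count is asymptotically Poisson: parameter 2 in the
    unsigned case, 1/2 in the signed case, which drives the normalized
    distance limit E d/n -> 1.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    counts = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        a = uniform_random_genome(n, signed, rng)
        b = uniform_random_genome(n, signed, rng)
        counts[r] = shared_adjacencies(a, b)
    return AdjacencyCountSummary(
        reps=reps,
        mean=float(counts.mean()),
        variance=float(counts.var(ddof=1)) if reps > 1 else 0.0,
    )
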