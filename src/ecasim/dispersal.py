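"""Offspring dispersal operators over the cell lattice.

Three strategies redistribute a species' offspring each generation.  All of
them conserve the total count exactly; they differ in how much spatial
aggregation (per-cell variance) they produce.

``disperse_n``
    Local neighborhood dispersal.  Each individual in cell *i* independently
    moves to a cell drawn uniformly from the window of radius
    ``round(prefix/100 * m)`` centered on *i* (origin included).  ``0n`` is
    the identity; ``100n`` spreads the pool uniformly over the lattice.
    Repeated application homogenises any initial pattern.

``disperse_r``
    Global aggregated dispersal.  Per-cell weights are the spacings of ``m``
    sorted uniform variates (the first spacing measured from 0), normalised
    to sum to one; these spacings are approximately exponential, so the
    resulting allocation is strongly right-skewed, resembling the negative
    binomial counts used to model overdispersed ecological data.  The prefix
    linearly mixes the spacing weight with the uniform share:
    ``f_i = (1 - p)/m + p * w_i`` with ``p = prefix/100``, so ``0r`` is
    uniform (minimum variance) and ``100r`` maximally aggregated.

``disperse_h``
    Gregarious dispersal: a uniformly chosen ``floor(prefix/100 * m)`` cells
    are forced empty and the occupied remainder receives a maximally
    aggregated ``r`` allocation.  Models organisms that actively seek
    conspecifics, vacating a fixed fraction of the habitat.

The lattice is a ring by default (``wrap=True``) so the n strategy has no
edge effects; a non-wrapping variant truncates the window at the habitat
boundary.  Real-valued target frequencies are converted to integer counts by
largest-remainder rounding, which is conservation-exact.  The r/h weight
draws are iid across cells (the exchangeable form of the sorted-uniform
spacings construction), so the allocation carries no spatial gradient and
every cell is statistically equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DispersalSpec

__all__ = [
    "disperse_n",
    "disperse_r",
    "disperse_h",
    "apply_dispersal",
    "allocation_stats",
    "AllocationStats",
    "largest_remainder",
]


def largest_remainder(total: int, frequencies: np.ndarray) -> np.ndarray:
    """Integerize ``total * frequencies`` so the result sums exactly to ``total``.

    Floors each target and hands the remaining units to the cells with the
    largest fractional remainders (deterministic tie-break — callers that
    need exchangeability permute the result afterwards).
    """
    total = int(total)
    target = total * np.asarray(frequencies, dtype=np.float64)
    base = np.floor(target).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        top = np.argpartition(base - target, short - 1)[:short]
        base[top] += 1
    return base


def _neighborhood_radius(prefix: int, number_of_cells: int) -> int:
    return int(round(prefix / 100.0 * number_of_cells))


def disperse_n(
    source_counts: np.ndarray,
    prefix: int,
    rng: np.random.Generator,
    wrap: bool = True,
) -> np.ndarray:
    """Redistribute each cell's occupants uniformly within its neighborhood.

    Parameters
    ----------
    source_counts : (m,) int array
        Occupants per cell before dispersal.
    prefix : int
        Percentage in [0, 100]; the window radius is
        ``round(prefix/100 * m)``, capped so the window never exceeds the
        lattice.  Prefix 0 leaves every individual in its cell of origin.
    wrap : bool
        Ring topology (default) or truncation at the habitat edge.
    """
    counts = np.asarray(source_counts, dtype=np.int64)
    m = counts.shape[0]
    rho = _neighborhood_radius(int(prefix), m)
    if rho == 0:
        return counts.copy()
    if wrap and 2 * rho + 1 >= m:
        # saturated window: every destination equally likely for every source
        return rng.multinomial(int(counts.sum()), np.full(m, 1.0 / m)).astype(np.int64)
    out = np.zeros(m, dtype=np.int64)
    for i in np.flatnonzero(counts):
        if wrap:
            dests = (np.arange(i - rho, i + rho + 1)) % m
        else:
            dests = np.arange(max(0, i - rho), min(m - 1, i + rho) + 1)
        moved = rng.multinomial(int(counts[i]), np.full(dests.size, 1.0 / dests.size))
        np.add.at(out, dests, moved)
    return out


def _spacing_weights(m: int, rng: np.random.Generator) -> np.ndarray:
    # The spacings of m sorted uniforms (first measured from 0, normalised
    # to their sum) are jointly Dirichlet(1, ..., 1) distributed — exactly
    # the law of m iid standard exponentials divided by their sum.  The
    # exponential form is used because it needs no sort and is manifestly
    # exchangeable across cells, so no post-hoc permutation is required.
    e = rng.standard_exponential(m)
    s = e.sum()
    if s <= 0.0:  # pathological draw; fall back to uniform
        return np.full(m, 1.0 / m)
    return e / s


def disperse_r(
    total: int,
    number_of_cells: int,
    prefix: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allocate a global pool of offspring with tunable aggregation.

    The per-cell weights follow the law of successive differences of ``m``
    sorted uniforms (the first measured from 0), normalised to sum to one —
    sampled directly in their exchangeable exponential-spacings form — then
    mixed with the uniform share according to ``prefix`` and integerized
    with largest-remainder rounding.  Conservation is exact for every
    (total, m, prefix).
    """
    m = int(number_of_cells)
    total = int(total)
    if total == 0:
        return np.zeros(m, dtype=np.int64)
    p = int(prefix) / 100.0
    w = _spacing_weights(m, rng)
    f = (1.0 - p) / m + p * w
    return largest_remainder(total, f)


def disperse_h(
    total: int,
    number_of_cells: int,
    prefix: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gregarious allocation: force a fixed fraction of cells empty.

    Exactly ``floor(prefix/100 * m)`` uniformly chosen cells receive no
    organisms; the occupied remainder gets a maximally aggregated r
    allocation.  ``prefix == 100`` with a positive total is an error (no
    cell left to occupy).
    """
    m = int(number_of_cells)
    total = int(total)
    out = np.zeros(m, dtype=np.int64)
    if total == 0:
        return out
    n_empty = int(np.floor(int(prefix) / 100.0 * m))
    if n_empty >= m:
        raise ValueError(f"h strategy with prefix {prefix} leaves no occupied cell")
    occupied = rng.choice(m, size=m - n_empty, replace=False)
    out[occupied] = disperse_r(total, m - n_empty, 100, rng)
    return out


def apply_dispersal(
    source_counts: np.ndarray,
    spec: DispersalSpec,
    rng: np.random.Generator,
    wrap: bool = True,
) -> np.ndarray:
    """Dispatch a per-cell offspring vector through the strategy in ``spec``.

    The n strategy acts per source cell; r and h act on the pooled total
    without regard to cell of origin.
    """
    counts = np.asarray(source_counts, dtype=np.int64)
    if spec.kind == "n":
        return disperse_n(counts, spec.prefix, rng, wrap=wrap)
    total = int(counts.sum())
    if spec.kind == "r":
        return disperse_r(total, counts.shape[0], spec.prefix, rng)
    return disperse_h(total, counts.shape[0], spec.prefix, rng)


@dataclass(frozen=True)
class AllocationStats:
    """Summary of one allocation against a per-cell carrying capacity."""

    sigma: float  # population standard deviation of per-cell counts
    max_density: int  # most populated cell
    empty_cells: int  # cells with zero occupants
    to_die: int  # organisms beyond capacity, at unit resource need


def allocation_stats(counts: np.ndarray, capacity_per_cell) -> AllocationStats:
    """σ, max density, empty-cell count and over-capacity overflow of an allocation."""
    counts = np.asarray(counts, dtype=np.int64)
    cap = np.broadcast_to(
        np.asarray(capacity_per_cell, dtype=np.int64), counts.shape
    )
    return AllocationStats(
        sigma=float(counts.std()),
        max_density=int(counts.max(initial=0)),
        empty_cells=int(np.count_nonzero(counts == 0)),
        to_die=int(np.maximum(counts - cap, 0).sum()),
    )
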