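"""One generation of the automaton: competition, pairing, reproduction, dispersal.

Generations are discrete and non-overlapping.  Within a generation, each cell
is processed as follows:

1. **Competition** — all occupants of the cell, across species, are processed
   in a uniformly random order; each consumes its species' ``resource_need``
   units if at least that many remain, otherwise it dies.  Only survivors
   reproduce.  With unit needs this reduces to drawing
   ``min(occupants, resources)`` survivors uniformly at random (a
   multivariate hypergeometric draw).  Because a leftover smaller than a
   high-need species' requirement is still usable by lower-need species,
   heterogeneous needs produce the small-portion effect: weak competitors
   feed on scraps the dominant species cannot use.
2. **Pairing** — interaction rules are applied in configuration order; each
   rule forms ``min(remaining_a, remaining_b)`` one-to-one pairs among the
   cell's survivors, and paired individuals are unavailable to later rules.
3. **Reproduction** — an unassociated survivor produces its species'
   ``direct_offspring``; an associated one produces
   ``max(0, direct_offspring + partner_effect)`` where the partner effect
   defaults to the partner species' ``indirect_offspring`` (rules may
   override it).  Brood parasitism, predation, resource feeding and
   inhibition are all expressed through the sign and size of these effects.
4. **Dispersal** — adults die; each species' offspring are redistributed by
   its own strategy (n acts per source cell, r/h on the species' global
   pool).

All randomness flows through one ``numpy.random.Generator``, so a scenario
and seed determine the trajectory bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import InteractionRule, ScenarioConfig, SpeciesSpec
from .dispersal import AllocationStats, allocation_stats, apply_dispersal

try:  # jitted kernel for the heterogeneous-need consumption walk
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    njit = None

__all__ = [
    "PopulationState",
    "GenerationRecord",
    "compete",
    "compete_lattice",
    "form_pairs",
    "realized_offspring",
    "initial_state",
    "step",
]


@dataclass(frozen=True)
class PopulationState:
    """Organism counts per (cell, species) at one generation."""

    counts: np.ndarray  # (number_of_cells, number_of_species) int64
    generation: int = 0

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class GenerationRecord:
    """Diagnostics for one executed generation.

    ``totals`` is the census the time series report: the standing population
    of each species, i.e. the survivors of this generation's resource
    competition (the organisms that lived to reproduce).  ``offspring`` is
    the dispersed pool that forms the next state.
    """

    generation: int  # index of the state this record produced
    totals: np.ndarray  # (S,) survivors of competition this generation
    offspring: np.ndarray  # (S,) post-dispersal offspring totals
    deaths: np.ndarray  # (S,) organisms excluded by competition this generation
    pairs: np.ndarray  # (n_rules,) pairs formed across all cells
    cell_stats: tuple[AllocationStats, ...] | None = None  # per species


# ---------------------------------------------------------------------------
# competition

def compete(
    occupants: np.ndarray,
    resources: int,
    needs: np.ndarray,
    rng: np.random.Generator | None = None,
    order: np.ndarray | None = None,
):
    """Resolve resource competition in one cell.

    Parameters
    ----------
    occupants : (S,) int array
        Occupants per species.
    resources : int
        Resource units available in the cell this generation.
    needs : (S,) int array
        Per-capita resource need of each species.
    rng : Generator, optional
        Source of the random processing order (required unless ``order`` is
        given or no organism can die).
    order : (total,) int array, optional
        Explicit species-index processing sequence; overrides the random
        order (used by tests and sensitivity analyses).

    Returns
    -------
    survivors, deaths : (S,) int arrays
        ``survivors + deaths == occupants`` per species, and the consumed
        resources never exceed ``resources``.
    """
    occ = np.asarray(occupants, dtype=np.int64)
    needs = np.asarray(needs, dtype=np.int64)
    resources = int(resources)
    total = int(occ.sum())
    if total == 0:
        return occ.copy(), np.zeros_like(occ)
    if order is None and np.all(needs[occ > 0] == needs[occ > 0][0]):
        # homogeneous need: min(total, resources // need) survivors, a
        # uniformly random subset — a multivariate hypergeometric draw
        need = int(needs[occ > 0][0])
        k = resources // need
        if total <= k:
            return occ.copy(), np.zeros_like(occ)
        if k == 0:
            return np.zeros_like(occ), occ.copy()
        survivors = np.asarray(
            rng.multivariate_hypergeometric(occ, k), dtype=np.int64
        )
        return survivors, occ - survivors
    if order is None:
        order = rng.permutation(np.repeat(np.arange(occ.size), occ))
    else:
        order = np.asarray(order, dtype=np.int64)
    survivors = _consume_in_order(order, needs, occ.size, resources)
    return survivors, occ - survivors


def _consume_in_order_py(
    order: np.ndarray, needs: np.ndarray, n_species: int, resources: int
) -> np.ndarray:
    """Sequential consumption walk: reference implementation of the kernel."""
    survivors = np.zeros(n_species, dtype=np.int64)
    remaining = resources
    min_need = needs.min() if n_species else 0
    for j in order:
        if remaining < min_need:
            break
        need = needs[j]
        if need <= remaining:
            survivors[j] += 1
            remaining -= need
    return survivors


if njit is not None:
    _consume_in_order = njit(cache=False)(_consume_in_order_py)
else:  # pragma: no cover
    _consume_in_order = _consume_in_order_py


def _compete_cell_seeded_py(counts, needs, resources, seed):
    """Random-order consumption in one cell, driven by a splitmix64 stream.

    Equivalent in distribution to shuffling all occupants and walking the
    shuffled sequence, but O(draws actually made): the walk stops as soon as
    the remaining resource is below the smallest need, when every organism
    still unprocessed is doomed anyway.
    """
    mask = np.uint64(0xFFFFFFFFFFFFFFFF)
    gamma = np.uint64(0x9E3779B97F4A7C15)
    mul1 = np.uint64(0xBF58476D1CE4E5B9)
    mul2 = np.uint64(0x94D049BB133111EB)
    inv53 = 1.0 / 9007199254740992.0
    S = counts.size
    pool = counts.copy()
    survivors = np.zeros(S, dtype=np.int64)
    total_left = np.int64(0)
    min_need = np.int64(2**62)
    for k in range(S):
        total_left += pool[k]
        if pool[k] > 0 and needs[k] < min_need:
            min_need = needs[k]
    remaining = np.int64(resources)
    state = np.uint64(seed)
    while total_left > 0 and remaining >= min_need:
        state = (state + gamma) & mask
        z = state
        z = ((z ^ (z >> np.uint64(30))) * mul1) & mask
        z = ((z ^ (z >> np.uint64(27))) * mul2) & mask
        z = z ^ (z >> np.uint64(31))
        r = float(z >> np.uint64(11)) * inv53
        target = np.int64(r * total_left)
        acc = np.int64(0)
        j = 0
        for k in range(S):
            acc += pool[k]
            if target < acc:
                j = k
                break
        pool[j] -= 1
        total_left -= 1
        if needs[j] <= remaining:
            survivors[j] += 1
            remaining -= needs[j]
    return survivors


if njit is not None:
    _compete_cell_seeded = njit(cache=False)(_compete_cell_seeded_py)
else:  # pragma: no cover
    _compete_cell_seeded = _compete_cell_seeded_py


def compete_lattice(
    counts: np.ndarray,
    resources: np.ndarray,
    needs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized competition across all cells; returns the survivor matrix.

    With homogeneous needs the per-cell multivariate hypergeometric draw is
    decomposed into sequential conditional hypergeometric draws, one
    vectorized call per species; heterogeneous needs fall back to the
    per-cell random-order walk in the cells that are actually contested.
    """
    counts = np.asarray(counts, dtype=np.int64)
    resources = np.asarray(resources, dtype=np.int64)
    needs = np.asarray(needs, dtype=np.int64)
    m, S = counts.shape
    if np.all(needs == needs[0]):
        need = int(needs[0])
        cap = resources // need
        totals = counts.sum(axis=1)
        survivors = counts.copy()
        over = np.flatnonzero(totals > cap)
        if over.size:
            remaining = cap[over].copy()
            tail = counts[over].astype(np.int64)  # occupants not yet drawn
            tail_total = tail.sum(axis=1)
            alive = np.flatnonzero(tail.sum(axis=0) > 0)
            for j in alive:
                ngood = tail[:, j]
                tail_total -= ngood
                drawn = np.zeros_like(ngood)
                mask = (ngood > 0) & (remaining > 0)
                if np.any(mask):
                    nsample = np.minimum(
                        remaining[mask], tail_total[mask] + ngood[mask]
                    )
                    drawn[mask] = rng.hypergeometric(
                        ngood[mask], tail_total[mask], nsample
                    )
                survivors[over, j] = drawn
                remaining -= drawn
        return survivors
    survivors = counts.copy()
    totals_needed = (counts * needs).sum(axis=1)
    contested = np.flatnonzero(totals_needed > resources)
    if contested.size:
        seeds = rng.integers(0, 2**63, size=contested.size)
        for k, i in enumerate(contested):
            survivors[i] = _compete_cell_seeded(
                counts[i], needs, np.int64(resources[i]), np.uint64(seeds[k])
            )
    return survivors


# ---------------------------------------------------------------------------
# pairing and reproduction

def form_pairs(
    survivors: np.ndarray,
    rules: tuple[InteractionRule, ...],
    species_index: dict[str, int],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Form one-to-one within-cell pairs for each rule in order, with depletion.

    ``survivors`` may be a (S,) vector (one cell) or an (m, S) matrix; pairs
    are computed elementwise per cell.  Returns ``(pairs, unpaired)`` where
    ``pairs`` has one row (or scalar per rule) per rule and ``unpaired`` the
    same shape as ``survivors``.
    """
    surv = np.asarray(survivors, dtype=np.int64)
    single = surv.copy()
    one_cell = single.ndim == 1
    if one_cell:
        single = single[None, :]
    pairs = np.zeros((len(rules), single.shape[0]), dtype=np.int64)
    for k, rule in enumerate(rules):
        a = species_index[rule.species_a]
        b = species_index[rule.species_b]
        p = np.minimum(single[:, a], single[:, b])
        if rule.encounter < 1.0:
            p = rng.binomial(p, rule.encounter).astype(np.int64)
        pairs[k] = p
        single[:, a] -= p
        single[:, b] -= p
    if one_cell:
        return pairs[:, 0], single[0]
    return pairs, single


def realized_offspring(species: SpeciesSpec, partner: SpeciesSpec | None) -> int:
    """Offspring of one survivor: direct if alone, direct + partner's indirect if paired.

    In the classic brood-parasitism configuration — cuckoo (0, −2), reed
    warbler (2, 2) — a lone warbler fledges 2 chicks, a parasitized pair
    yields 2 cuckoo chicks (0 + 2) and 0 warbler chicks (2 − 2).  Negative
    sums clamp to zero.
    """
    if partner is None:
        return int(species.direct_offspring)
    return max(0, int(species.direct_offspring) + int(partner.indirect_offspring))


def _rule_effects(
    rule: InteractionRule, species: tuple[SpeciesSpec, ...], index: dict[str, int]
) -> tuple[int, int]:
    """Fecundity effect received by each member of a pair under ``rule``."""
    a = species[index[rule.species_a]]
    b = species[index[rule.species_b]]
    eff_a = rule.effect_on_a if rule.effect_on_a is not None else b.indirect_offspring
    eff_b = rule.effect_on_b if rule.effect_on_b is not None else a.indirect_offspring
    return int(eff_a), int(eff_b)


# ---------------------------------------------------------------------------
# initial placement and the generation step

def initial_state(config: ScenarioConfig, rng: np.random.Generator) -> PopulationState:
    """Place each species' initial population on the lattice.

    Global strategies (r, h) place the founders with their own allocator;
    the local n strategy has no pre-existing pattern to act on, so its
    founders are scattered by a uniform multinomial.
    """
    m = config.habitat.number_of_cells
    counts = np.zeros((m, len(config.species)), dtype=np.int64)
    for j, sp in enumerate(config.species):
        n0 = int(sp.number_of_items)
        if n0 == 0:
            continue
        if sp.dispersal.kind == "n":
            counts[:, j] = rng.multinomial(n0, np.full(m, 1.0 / m))
        else:
            pool = np.zeros(m, dtype=np.int64)
            pool[0] = n0
            counts[:, j] = apply_dispersal(pool, sp.dispersal, rng, config.habitat.wrap)
    return PopulationState(counts=counts, generation=0)


def step(
    state: PopulationState,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[PopulationState, GenerationRecord]:
    """Advance one generation: compete → pair → reproduce → disperse."""
    species = config.species
    index = config.species_index()
    needs = np.array([sp.resource_need for sp in species], dtype=np.int64)
    resources = config.habitat.resources_vector()

    survivors = compete_lattice(state.counts, resources, needs, rng)
    deaths = (state.counts - survivors).sum(axis=0)

    rules = config.interactions
    rule_order = np.arange(len(rules))
    if config.shuffle_rules and len(rules) > 1:
        rule_order = rng.permutation(len(rules))
    ordered = tuple(rules[k] for k in rule_order)
    pairs_ordered, single = form_pairs(survivors, ordered, index, rng)
    pairs = np.empty_like(pairs_ordered)
    pairs[rule_order] = pairs_ordered

    offspring = np.zeros_like(survivors)
    for j, sp in enumerate(species):
        offspring[:, j] = single[:, j] * int(sp.direct_offspring)
    for k, rule in enumerate(config.interactions):
        eff_a, eff_b = _rule_effects(rule, species, index)
        a = index[rule.species_a]
        b = index[rule.species_b]
        sp_a, sp_b = species[a], species[b]
        offspring[:, a] += pairs[k] * max(0, int(sp_a.direct_offspring) + eff_a)
        offspring[:, b] += pairs[k] * max(0, int(sp_b.direct_offspring) + eff_b)

    new_counts = np.zeros_like(offspring)
    for j, sp in enumerate(species):
        new_counts[:, j] = apply_dispersal(
            offspring[:, j], sp.dispersal, rng, config.habitat.wrap
        )

    cell_stats = None
    if config.record_cell_stats:
        cell_stats = tuple(
            allocation_stats(new_counts[:, j], resources // max(1, int(sp.resource_need)))
            for j, sp in enumerate(species)
        )

    next_state = PopulationState(counts=new_counts, generation=state.generation + 1)
    record = GenerationRecord(
        generation=next_state.generation,
        totals=survivors.sum(axis=0),
        offspring=new_counts.sum(axis=0),
        deaths=deaths,
        pairs=pairs.sum(axis=1),
        cell_stats=cell_stats,
    )
    return next_state, record
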