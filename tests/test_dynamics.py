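"""Generation mechanics: competition, pairing, offspring rules, the step.

Includes an individual-based reference implementation of the within-cell
dynamics (explicit organisms, explicit shuffles) used as a distributional
oracle for the vectorized count-based engine on small instances.
"""

import numpy as np
import pytest
from scipy import stats

from ecasim.config import (
    DispersalSpec,
    HabitatSpec,
    InteractionRule,
    ScenarioConfig,
    SpeciesSpec,
    validate,
)
from ecasim.dynamics import (
    PopulationState,
    compete,
    compete_lattice,
    form_pairs,
    initial_state,
    realized_offspring,
    step,
)


@pytest.fixture
def rng():
    return np.random.default_rng(99)


# ---------------------------------------------------------------------------
# competition

def test_compete_unit_needs_caps_at_resources(rng):
    surv, dead = compete(np.array([40]), 25, np.array([1]), rng)
    assert surv.sum() == 25 and dead.sum() == 15


def test_compete_under_capacity_no_deaths(rng):
    occ = np.array([3, 4])
    surv, dead = compete(occ, 10, np.array([1, 1]), rng)
    assert np.array_equal(surv, occ) and dead.sum() == 0


def test_compete_small_portion_order_enumeration():
    """Leftovers below a species' need stay usable by lower-need species."""
    needs = np.array([5, 1])
    # one organism each, high-need processed first: 5 + 1 <= 7, both live
    surv, dead = compete(np.array([1, 1]), 7, needs, order=np.array([0, 1]))
    assert surv.tolist() == [1, 1]
    # low-need first: 1 + 5 <= 7 still fits
    surv, _ = compete(np.array([1, 1]), 7, needs, order=np.array([1, 0]))
    assert surv.tolist() == [1, 1]
    # equal high needs: only the first in order survives on 7 resources
    surv, dead = compete(np.array([1, 1]), 7, np.array([5, 5]),
                         order=np.array([0, 1]))
    assert surv.tolist() == [1, 0] and dead.tolist() == [0, 1]


def test_compete_homogeneous_path_is_hypergeometric(rng):
    """Survivor composition matches the multivariate hypergeometric law."""
    occ = np.array([6, 4])
    reps = 4000
    draws = np.array([compete(occ, 5, np.array([1, 1]), rng)[0][0]
                      for _ in range(reps)])
    support = np.arange(1, 6)
    expected = stats.hypergeom(10, 6, 5).pmf(support) * reps
    observed = np.array([(draws == k).sum() for k in support])
    assert stats.chisquare(observed, expected).pvalue > 0.01


def test_compete_seeded_kernel_matches_shuffled_walk(rng):
    """The splitmix-driven cell kernel agrees with the explicit random-order
    walk in distribution on a heterogeneous-need instance."""
    from ecasim.dynamics import _compete_cell_seeded

    occ = np.array([3, 3])
    needs = np.array([5, 2])
    reps = 3000
    kernel = np.zeros((reps, 2), dtype=int)
    walk = np.zeros((reps, 2), dtype=int)
    seeds = rng.integers(0, 2**63, size=reps)
    for i in range(reps):
        kernel[i] = _compete_cell_seeded(occ, needs, np.int64(12),
                                         np.uint64(seeds[i]))
        walk[i], _ = compete(occ, 12, needs, rng)
    # compare joint outcome frequencies
    combos = {(a, b) for a, b in map(tuple, np.vstack([kernel, walk]))}
    k_counts = np.array([np.sum((kernel == c).all(axis=1)) for c in combos])
    w_counts = np.array([np.sum((walk == c).all(axis=1)) for c in combos])
    table = np.vstack([k_counts, w_counts])
    assert stats.chi2_contingency(table).pvalue > 0.01


def test_compete_lattice_matches_single_cell_semantics(rng):
    counts = np.array([[40, 0], [10, 10], [0, 0], [100, 50]])
    res = np.array([25, 30, 5, 60])
    surv = compete_lattice(counts, res, np.array([1, 1]), rng)
    assert np.array_equal(surv.sum(axis=1),
                          np.minimum(counts.sum(axis=1), res))
    assert np.all(surv <= counts)


# ---------------------------------------------------------------------------
# pairing and offspring

def test_form_pairs_min_rule(rng):
    idx = {"cuckoo": 0, "warbler": 1}
    pairs, single = form_pairs(
        np.array([3, 5]), (InteractionRule("cuckoo", "warbler"),), idx, rng
    )
    assert pairs.tolist() == [3]
    assert single.tolist() == [0, 2]


def test_form_pairs_absent_partner(rng):
    idx = {"pred": 0, "prey": 1}
    pairs, single = form_pairs(
        np.array([0, 7]), (InteractionRule("pred", "prey"),), idx, rng
    )
    assert pairs.tolist() == [0] and single.tolist() == [0, 7]


def test_form_pairs_sequential_depletion(rng):
    """A–B then B–C: B individuals paired by the first rule are unavailable."""
    idx = {"A": 0, "B": 1, "C": 2}
    rules = (InteractionRule("A", "B"), InteractionRule("B", "C"))
    pairs, single = form_pairs(np.array([2, 3, 4]), rules, idx, rng)
    assert pairs.tolist() == [2, 1]
    assert single.tolist() == [0, 0, 3]


def test_realized_offspring_brood_parasitism_worked_example():
    cuckoo = SpeciesSpec("cuckoo", 1, 0, -2)
    warbler = SpeciesSpec("warbler", 1, 2, 2)
    assert realized_offspring(warbler, None) == 2
    assert realized_offspring(cuckoo, warbler) == 2  # 0 + 2
    assert realized_offspring(warbler, cuckoo) == 0  # 2 - 2
    neutral = SpeciesSpec("n", 1, 1, 0)
    assert realized_offspring(warbler, neutral) == 2
    # negative sums clamp at zero
    hostile = SpeciesSpec("h", 1, 0, -9)
    assert realized_offspring(warbler, hostile) == 0


# ---------------------------------------------------------------------------
# the generation step

def _single_species_config(disp="100n", direct=1, cells=10, resources=100,
                           n0=50, generations=5, seed=3):
    return validate(ScenarioConfig(
        habitat=HabitatSpec(cells, resources, DispersalSpec.parse(disp)),
        species=(SpeciesSpec("s", n0, direct, 0),),
        generations=generations,
        seed=seed,
    ))


def test_step_zero_state_is_absorbing(rng):
    cfg = _single_species_config()
    state = PopulationState(np.zeros((10, 1), dtype=np.int64))
    nxt, rec = step(state, cfg, rng)
    assert nxt.counts.sum() == 0
    assert rec.totals.sum() == 0 and rec.deaths.sum() == 0


def test_step_replacement_reproduction_is_constant(rng):
    """direct_offspring 1 under ample capacity keeps the total fixed."""
    cfg = _single_species_config(direct=1, resources=10_000, n0=300)
    state = initial_state(cfg, rng)
    for _ in range(5):
        state, rec = step(state, cfg, rng)
        assert rec.totals.sum() == 300
        assert state.counts.sum() == 300


def test_step_capacity_filling_closed_form(rng):
    """f=3 under 100n fills 100 cells x 120 resources to 12,000 and holds."""
    cfg = validate(ScenarioConfig(
        habitat=HabitatSpec(100, 120, DispersalSpec.parse("100n")),
        species=(SpeciesSpec("s", 6000, 3, 0),),
        generations=8, seed=5,
    ))
    state = initial_state(cfg, rng)
    totals = []
    for _ in range(8):
        state, rec = step(state, cfg, rng)
        totals.append(int(rec.totals.sum()))
    assert totals[-3:] == [12_000, 12_000, 12_000]


def test_step_predator_prey_offspring_semantics(rng):
    """Paired prey yield 0, paired predators g; unpaired prey f, predators 0."""
    f, g = 2, 2
    cfg = validate(ScenarioConfig(
        habitat=HabitatSpec(1, 10_000, DispersalSpec.parse("0n")),
        species=(
            SpeciesSpec("prey", 0, f, g, DispersalSpec.parse("0n")),
            SpeciesSpec("pred", 0, 0, -f, DispersalSpec.parse("0n")),
        ),
        interactions=(InteractionRule("pred", "prey"),),
        generations=1, seed=0,
    ))
    state = PopulationState(np.array([[30, 10]], dtype=np.int64))
    nxt, rec = step(state, cfg, rng)
    # 10 pairs: predators get g each; 20 unpaired prey get f each
    assert nxt.counts[0, 0] == 20 * f
    assert nxt.counts[0, 1] == 10 * g
    assert rec.pairs.tolist() == [10]


def test_step_conservation_within_generation(rng):
    cfg = validate(ScenarioConfig(
        habitat=HabitatSpec(20, 15, DispersalSpec.parse("100r")),
        species=(
            SpeciesSpec("a", 500, 2, 0),
            SpeciesSpec("b", 300, 3, 0),
        ),
        generations=1, seed=0,
    ))
    state = initial_state(cfg, rng)
    occupants = state.counts.sum(axis=0)
    _, rec = step(state, cfg, rng)
    assert np.array_equal(rec.totals + rec.deaths, occupants)


# ---------------------------------------------------------------------------
# individual-based oracle

def _individual_step(counts, config, rng):
    """Per-organism reference for one generation on a tiny lattice.

    Keeps an explicit list of organisms per cell, shuffles them for the
    resource walk, pairs them rule by rule, applies the offspring formula
    per organism, then disperses each species' offspring pool with the
    shared allocators.
    """
    from ecasim.dispersal import apply_dispersal

    species = config.species
    index = config.species_index()
    resources = config.habitat.resources_vector()
    m = config.habitat.number_of_cells
    offspring = np.zeros_like(counts)
    for i in range(m):
        organisms = []
        for j, sp in enumerate(species):
            organisms += [j] * int(counts[i, j])
        rng.shuffle(organisms)
        remaining = int(resources[i])
        alive = []
        for j in organisms:
            need = int(species[j].resource_need)
            if need <= remaining:
                alive.append(j)
                remaining -= need
        paired_partner = {}
        unclaimed = {j: [k for k, sj in enumerate(alive) if sj == j]
                     for j in range(len(species))}
        for rule in config.interactions:
            a, b = index[rule.species_a], index[rule.species_b]
            n_pairs = min(len(unclaimed[a]), len(unclaimed[b]))
            for _ in range(n_pairs):
                ka = unclaimed[a].pop()
                kb = unclaimed[b].pop()
                ea = rule.effect_on_a if rule.effect_on_a is not None \
                    else species[b].indirect_offspring
                eb = rule.effect_on_b if rule.effect_on_b is not None \
                    else species[a].indirect_offspring
                paired_partner[ka] = ea
                paired_partner[kb] = eb
        for k, j in enumerate(alive):
            if k in paired_partner:
                offspring[i, j] += max(
                    0, species[j].direct_offspring + paired_partner[k])
            else:
                offspring[i, j] += species[j].direct_offspring
    out = np.zeros_like(counts)
    for j, sp in enumerate(species):
        out[:, j] = apply_dispersal(offspring[:, j], sp.dispersal, rng,
                                    config.habitat.wrap)
    return out


@pytest.mark.parametrize("disp", ["0n", "100r"])
def test_count_engine_matches_individual_oracle(disp):
    """Next-generation totals agree in distribution with the per-organism
    reference on a crowded 4-cell, 2-species instance."""
    cfg = validate(ScenarioConfig(
        habitat=HabitatSpec(4, 6, DispersalSpec.parse(disp)),
        species=(
            SpeciesSpec("prey", 0, 2, 2),
            SpeciesSpec("pred", 0, 0, -2),
        ),
        interactions=(InteractionRule("pred", "prey"),),
        generations=1, seed=0,
    ))
    start = np.array([[5, 2], [0, 3], [7, 0], [4, 4]], dtype=np.int64)
    reps = 1200
    rng_a = np.random.default_rng(1)
    rng_b = np.random.default_rng(2)
    eng = np.array([
        step(PopulationState(start.copy()), cfg, rng_a)[0].counts.sum(axis=0)
        for _ in range(reps)
    ])
    orc = np.array([
        _individual_step(start.copy(), cfg, rng_b).sum(axis=0)
        for _ in range(reps)
    ])
    for j in range(2):
        ks = stats.ks_2samp(eng[:, j], orc[:, j])
        assert ks.pvalue > 0.01, (j, eng[:, j].mean(), orc[:, j].mean())


def test_step_is_deterministic_under_fixed_seed():
    cfg = _single_species_config(disp="100r", direct=2, n0=400,
                                 resources=30, generations=6)
    from ecasim.engine import run

    a = run(cfg)
    b = run(cfg)
    assert np.array_equal(a.totals, b.totals)
    assert a.extinctions == b.extinctions
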