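"""Reconstructed experiment fixtures.

Each builder returns a :class:`ScenarioFixture`: a runnable
:class:`~ecasim.config.ScenarioConfig` plus a machine-readable expectation
and a provenance note separating parameters that are printed in the source
material from those reconstructed here.  Fixture names follow the original
appendix file naming (``1Pred``, ``1Para``, ``1Plank4``, ``2Planck1``,
``2Plank2``, ``2ResV``, ``2Predat``, ``2SpePred``); these configurations are
reconstructions from the published text, with no claim of byte compatibility
with the unpublished originals.

The recurring species archetypes:

* **prey / host** — positive ``direct_offspring`` f (reproduces when left
  alone) and ``indirect_offspring`` g ≥ 0 handed to an associated predator;
  the predator's ``indirect_offspring`` is −f so an attacked prey fledges
  nothing.
* **predator / brood parasite** — ``direct_offspring`` 0: it reproduces only
  through the association.
* **fitness ladder** — competition-only communities in which species differ
  in ``direct_offspring``; the plankton fixtures also scale
  ``resource_need`` with fecundity, which prices one offspring at one
  resource unit and enables the small-portion effect (leftovers too small
  for a high-need organism remain usable by low-need ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

from .config import (
    DispersalSpec,
    HabitatSpec,
    InteractionRule,
    ScenarioConfig,
    SpeciesSpec,
    save_config,
    validate,
)

__all__ = [
    "ScenarioFixture",
    "predator_prey_equilibrium",
    "brood_parasitism",
    "plankton_ladder",
    "fragmentation_sweep",
    "exclusion_and_rescue",
    "specialized_predators",
    "fixture_names",
    "get_fixture",
    "export_fixture",
]

#: near-extinction threshold: a population is "at the brink" when its total
#: drops below this fraction of the habitat's carrying capacity
BRINK_FRACTION = 0.05

#: fraction of the run over which "stable" population levels are averaged
TAIL_FRACTION = 0.25


@dataclass(frozen=True)
class ScenarioFixture:
    """A named, runnable reconstruction of one published simulation."""

    name: str
    config: ScenarioConfig
    expectation: dict
    provenance_note: str


def _spec(text: str) -> DispersalSpec:
    return text if isinstance(text, DispersalSpec) else DispersalSpec.parse(text)


# ---------------------------------------------------------------------------
# predator–prey capacity filling (1Pred / 2Predat)

def predator_prey_equilibrium(
    dispersal: DispersalSpec | str = "100n",
    capacity_scale: float = 1.0,
    generations: int = 400,
    seed: int = 0,
    prey_benefit: int = 1,
) -> ScenarioFixture:
    """Sawfly-style prey plus a weak specialized predator on 100 × 120 cells.

    Both species carry ``dispersal``.  The prey ("sawfly": direct 2,
    indirect ``prey_benefit`` to the predator) stabilises at the full
    carrying capacity of 12,000 under uniform dispersal and near 9,000 under
    maximal aggregation — the inefficiency of the aggregated distribution —
    while the predator (0 direct, −2 on the prey) fades out.
    ``capacity_scale`` shrinks per-cell resources for scaled checks.
    """
    dispersal = _spec(dispersal)
    cells = 100
    resources = max(1, round(120 * capacity_scale))
    capacity = cells * resources
    config = validate(
        ScenarioConfig(
            habitat=HabitatSpec(cells, resources, dispersal),
            species=(
                SpeciesSpec("sawfly", capacity // 2, 2, prey_benefit, dispersal),
                SpeciesSpec("predator", max(2, capacity // 300), 0, -2, dispersal),
            ),
            interactions=(InteractionRule("predator", "sawfly"),),
            generations=generations,
            seed=seed,
        )
    )
    uniform = dispersal.kind == "n" and dispersal.prefix == 100
    return ScenarioFixture(
        name=f"1Pred.{dispersal}",
        config=config,
        expectation={
            "metric": "prey_tail_mean",
            "species": "sawfly",
            "tail_fraction": TAIL_FRACTION,
            "cmp": "approx",
            "value": capacity if uniform else round(0.75 * capacity),
            "rtol": 0.01 if uniform else 0.15,
        },
        provenance_note=(
            "printed: habitat 100 cells x 120 resources; stable levels 12000 "
            "(100n) and 9000 (100r). reconstructed: prey offspring (2, "
            f"{prey_benefit}), predator (0, -2), initial populations "
            f"{capacity // 2}/{max(2, capacity // 300)}, horizon "
            f"{generations}."
        ),
    )


def predator_prey_cycles(
    dispersal: DispersalSpec | str = "100r",
    generations: int = 500,
    seed: int = 0,
) -> ScenarioFixture:
    """Self-sustaining predator–prey pair (2Predat): aggregation stabilises.

    Prey (2, 2) and predator (0, −2) on 100 × 120 cells.  With both species
    at ``100r`` the interaction persists for the whole horizon; with uniform
    ``100n`` dispersal the oscillation diverges and the pair collapses
    within a few tens of generations.
    """
    dispersal = _spec(dispersal)
    config = validate(
        ScenarioConfig(
            habitat=HabitatSpec(100, 120, dispersal),
            species=(
                SpeciesSpec("prey", 6000, 2, 2, dispersal),
                SpeciesSpec("predator", 400, 0, -2, dispersal),
            ),
            interactions=(InteractionRule("predator", "prey"),),
            generations=generations,
            seed=seed,
        )
    )
    aggregated = dispersal.kind == "r"
    return ScenarioFixture(
        name=f"2Predat.{dispersal}",
        config=config,
        expectation={
            "metric": "coexistence_horizon" if aggregated else "collapse_by",
            "value": generations if aggregated else 60,
        },
        provenance_note=(
            "printed: equilibrium endures with 100r for both, collapses "
            "within ~30 generations with 100n. reconstructed: habitat "
            "100x120, prey (2, 2), predator (0, -2), initials 6000/400."
        ),
    )


# ---------------------------------------------------------------------------
# brood parasitism (1Para)

def brood_parasitism(
    dispersal_cuckoo: DispersalSpec | str = "100r",
    dispersal_warbler: DispersalSpec | str = "100r",
    cells: int = 1000,
    generations: int = 500,
    seed: int = 0,
) -> ScenarioFixture:
    """Cuckoo (0, −2) and reed warbler (2, 2) with one brood-parasitism rule.

    Per-cell resources scale as ``10_000 // cells`` so total carrying
    capacity stays at 10,000 across the 1000/100/10-cell fragmentation
    contrast.  With both species uniform (``100n``) the cuckoo goes extinct;
    with both at ``100r`` on 1000 cells the pair persists; on 10 cells both
    fluctuate to the brink of extinction.
    """
    dispersal_cuckoo = _spec(dispersal_cuckoo)
    dispersal_warbler = _spec(dispersal_warbler)
    resources = max(1, 10_000 // cells)
    capacity = cells * resources
    config = validate(
        ScenarioConfig(
            habitat=HabitatSpec(cells, resources, DispersalSpec(100, "r")),
            species=(
                SpeciesSpec("cuckoo", capacity // 25, 0, -2, dispersal_cuckoo),
                SpeciesSpec("warbler", capacity * 2 // 5, 2, 2, dispersal_warbler),
            ),
            interactions=(InteractionRule("cuckoo", "warbler"),),
            generations=generations,
            seed=seed,
        )
    )
    both_aggregated = (
        dispersal_cuckoo.kind == "r" and dispersal_warbler.kind == "r"
    )
    if not both_aggregated:
        expectation = {"metric": "extinct", "species": "cuckoo",
                       "survivor": "warbler"}
    elif cells >= 1000:
        expectation = {"metric": "coexistence_horizon", "value": generations}
    else:
        expectation = {
            "metric": "brink",
            "value": BRINK_FRACTION,
            "capacity": capacity,
        }
    return ScenarioFixture(
        name=f"1Para.{dispersal_cuckoo}-{dispersal_warbler}-{cells}",
        config=config,
        expectation=expectation,
        provenance_note=(
            "printed: cuckoo (0, -2), warbler (2, 2); habitat of 1000 cells, "
            "reduced to 100 and 10 for the fragmentation contrast. "
            "reconstructed: 10 resources/cell at 1000 cells (capacity "
            "10,000 held constant across cell counts), initial populations "
            "400 cuckoos / 4000 warblers, horizon 500, brink threshold 5% "
            "of capacity."
        ),
    )


# ---------------------------------------------------------------------------
# the paradox of the plankton (1Plank4 / 2Planck1)

def plankton_ladder(
    n_species: int = 10,
    offspring_range: tuple[int, int] | None = None,
    dispersal: DispersalSpec | str = "100r",
    cells: int | None = None,
    resources: int | None = None,
    generations: int = 400,
    seed: int = 0,
    scale_need: bool = True,
) -> ScenarioFixture:
    """Competition-only fitness ladder (no interaction rules).

    The 10-species form uses the printed ladder 3,3,3,4,4,4,5,5,5,6; the
    ``n_species``/``offspring_range`` form assigns fecundities correlatively
    (e.g. 50 species, 10..59).  ``scale_need`` prices one offspring at one
    resource unit (``resource_need = direct_offspring``), the configuration
    under which aggregated dispersal sustains the whole ladder while
    near-uniform dispersal (``1r``) lets the fittest exclude the rest.
    """
    dispersal = _spec(dispersal)
    if offspring_range is None and n_species == 10:
        offspring = [3, 3, 3, 4, 4, 4, 5, 5, 5, 6]
        cells = 500 if cells is None else cells
        resources = 60 if resources is None else resources
        init = 2000
        note = (
            "printed: ladder 3,3,3,4,4,4,5,5,5,6; no exclusions in 400 "
            "generations under 100r. reconstructed: 500 cells x 60 "
            "resources, 2000 founders/species, resource_need = offspring."
        )
    else:
        lo, hi = offspring_range if offspring_range else (10, 59)
        offspring = [lo + round(j * (hi - lo) / max(1, n_species - 1))
                     for j in range(n_species)]
        cells = 6000 if cells is None else cells
        resources = 600 if resources is None else resources
        init = 600
        note = (
            f"printed: {n_species} species, DirectOffspring {lo}..{hi}; "
            "richness preserved at 400 generations under aggregated "
            "dispersal, progressive extinction under 1r. reconstructed "
            "(desk-scaled from the >800-million-organism run): "
            f"{cells} cells x {resources} resources, {init} founders per "
            "species, resource_need = offspring."
        )
    species = tuple(
        SpeciesSpec(
            f"S{j + 1}",
            init,
            offspring[j],
            0,
            dispersal,
            resource_need=offspring[j] if scale_need else 1,
        )
        for j in range(len(offspring))
    )
    config = validate(
        ScenarioConfig(
            habitat=HabitatSpec(cells, resources, dispersal),
            species=species,
            generations=generations,
            seed=seed,
        )
    )
    aggregated = dispersal.kind == "r" and dispersal.prefix >= 40
    name = "1Plank4" if len(offspring) == 10 else "2Planck1"
    return ScenarioFixture(
        name=f"{name}.{dispersal}",
        config=config,
        expectation={
            "metric": "final_richness",
            "cmp": "eq" if aggregated else "lt",
            "value": len(offspring),
        },
        provenance_note=note,
    )


# ---------------------------------------------------------------------------
# habitat fragmentation (2Plank2)

def fragmentation_sweep(
    cells_list: Iterable[int] = (20_000, 12_650),
    generations: int = 700,
    seed: int = 0,
) -> list[ScenarioFixture]:
    """100 aggregated competitors; richness at generation 700 vs cell count.

    The community extends the 50-species ladder: DirectOffspring 10..109
    with resource need priced at one unit per offspring, all species at
    ``100r``.  Fixtures differ only in the cell count.  Species are lost by
    ecological drift of the low-abundance ranks, on a clock that scales
    with habitat size, so the smaller habitat is always the poorer one at
    any fixed generation.
    """
    out = []
    for cells in cells_list:
        config = validate(
            ScenarioConfig(
                habitat=HabitatSpec(int(cells), _FRAG_RESOURCES,
                                    DispersalSpec(100, "r")),
                species=tuple(
                    SpeciesSpec(f"S{j + 1}", _FRAG_INIT, 10 + j, 0,
                                resource_need=10 + j)
                    for j in range(100)
                ),
                generations=generations,
                seed=seed,
            )
        )
        out.append(
            ScenarioFixture(
                name=f"2Plank2.{cells}",
                config=config,
                expectation={
                    "metric": "final_richness",
                    "cmp": "approx",
                    "value": 92 if cells >= 20_000 else 55,
                    "rtol": 0.15,
                },
                provenance_note=(
                    "printed: 100 species, aggregated distribution, 20,000 "
                    "vs 12,650 cells, richness 92 vs 55 at generation 700. "
                    "reconstructed: fecundity ladder 10..109 with "
                    "resource_need = offspring, "
                    f"{_FRAG_RESOURCES} resources/cell, {_FRAG_INIT} "
                    "founders/species. In this reconstruction the "
                    "20,000-cell richness and the per-seed ordering match "
                    "the printed contrast; the 12,650-cell habitat retains "
                    "more species (~88) than the printed 55 — no "
                    "parameterization tried reproduces that much extra "
                    "loss from a 1.6-fold habitat reduction alone."
                ),
            )
        )
    return out


# calibrated once to the printed generation-700 richness regime, then frozen
_FRAG_RESOURCES = 600
_FRAG_INIT = 400


# ---------------------------------------------------------------------------
# exclusion and its breakdown (2ResV)

def exclusion_and_rescue(
    dispersal_a: DispersalSpec | str = "100r",
    dispersal_b: DispersalSpec | str = "100n",
    offspring_a: int = 2,
    offspring_b: int = 2,
    resources_dispersal: DispersalSpec | str = "100r",
    generations: int = 400,
    seed: int = 0,
) -> ScenarioFixture:
    """Two consumers A and B feeding on a shared Resources species.

    A consumer reproduces only when paired with a Resources organism; the
    per-rule effect override sets its fecundity (``offspring_a`` /
    ``offspring_b``) and leaves the Resources organism unaffected, so
    Resources acts as a stationary stock of pairing slots, redistributed
    every generation by its own dispersal strategy (replacement
    reproduction, ample per-cell resources).  Rule order is shuffled each
    generation so neither consumer has a systematic first claim on slots.
    Outcomes: equal dispersal, unequal fecundity → the weaker consumer is
    competitively excluded; equal fecundity, A aggregated vs B uniform →
    the uniform consumer excludes the aggregated one (aggregation wastes
    pairing opportunities in saturated cells); A with more offspring but
    more aggregation than B → the two coexist, breaking the exclusion
    principle.
    """
    dispersal_a = _spec(dispersal_a)
    dispersal_b = _spec(dispersal_b)
    resources_dispersal = _spec(resources_dispersal)
    config = validate(
        ScenarioConfig(
            habitat=HabitatSpec(1000, 10**6, DispersalSpec(100, "r")),
            species=(
                SpeciesSpec("A", 300, 0, 0, dispersal_a),
                SpeciesSpec("B", 300, 0, 0, dispersal_b),
                SpeciesSpec("Resources", 12_000, 1, 0, resources_dispersal),
            ),
            interactions=(
                InteractionRule(
                    "A", "Resources",
                    effect_on_a=int(offspring_a), effect_on_b=0,
                ),
                InteractionRule(
                    "B", "Resources",
                    effect_on_a=int(offspring_b), effect_on_b=0,
                ),
            ),
            generations=generations,
            seed=seed,
            shuffle_rules=True,
        )
    )
    if (offspring_a, dispersal_a) == (offspring_b, dispersal_b):
        expectation = {"metric": "coexistence_horizon", "value": generations}
    elif offspring_a != offspring_b and dispersal_a == dispersal_b:
        loser = "A" if offspring_a < offspring_b else "B"
        expectation = {"metric": "extinct", "species": loser,
                       "survivor": "B" if loser == "A" else "A"}
    elif offspring_a == offspring_b:
        # equal fecundity: the more uniform strategy excludes the other
        loser = "A" if dispersal_a.kind == "r" else "B"
        expectation = {"metric": "extinct", "species": loser,
                       "survivor": "B" if loser == "A" else "A"}
    else:
        expectation = {"metric": "coexistence_horizon", "value": generations}
    return ScenarioFixture(
        name=(
            f"2ResV.{dispersal_a}-{offspring_a}-vs-"
            f"{dispersal_b}-{offspring_b}"
        ),
        config=config,
        expectation=expectation,
        provenance_note=(
            "printed: consumers feed via a third species named Resources; "
            "uniform B excludes aggregated A at equal offspring; lower "
            "offspring excluded at equal dispersal; A (3, 100r) vs B (2, "
            "55r) coexist. reconstructed: 1000 cells, Resources as a "
            "12,000-strong stationary slot stock (replacement "
            "reproduction, unaffected by pairing), consumer fecundity via "
            "per-rule effects, shuffled rule order, 300 founders each."
        ),
    )


# ---------------------------------------------------------------------------
# interdemic competition (2SpePred)

def specialized_predators(
    dispersal_pred1: DispersalSpec | str = "100n",
    dispersal_pred2: DispersalSpec | str = "100r",
    generalist: bool = False,
    generations: int = 500,
    seed: int = 0,
) -> ScenarioFixture:
    """Two predator–prey tandems whose prey inhibit each other.

    Specialist form: predator1 hunts prey1 only, predator2 hunts prey2
    only, and the prey pair carries a mutual-inhibition rule (−1 on each
    member).  The uniformly dispersing tandem over-exploits: its prey is
    competitively excluded and the predator follows, clearing the way for
    the aggregated tandem.  ``generalist=True`` lets both predators hunt
    both prey, which relaxes the coupling to apparent competition: all four
    species persist and the more uniform predator is merely majoritarian.
    """
    dispersal_pred1 = _spec(dispersal_pred1)
    dispersal_pred2 = _spec(dispersal_pred2)
    prey_disp = DispersalSpec(100, "r")
    predation = [
        InteractionRule("predator1", "prey1"),
        InteractionRule("predator2", "prey2"),
    ]
    if generalist:
        predation += [
            InteractionRule("predator1", "prey2", encounter=0.3),
            InteractionRule("predator2", "prey1", encounter=0.3),
        ]
    config = validate(
        ScenarioConfig(
            habitat=HabitatSpec(100, 120, DispersalSpec(100, "r")),
            species=(
                SpeciesSpec("prey1", 6000, 2, 2, prey_disp),
                SpeciesSpec("prey2", 6000, 2, 2, prey_disp),
                SpeciesSpec("predator1", 400, 0, -2, dispersal_pred1),
                SpeciesSpec("predator2", 400, 0, -2, dispersal_pred2),
            ),
            interactions=tuple(
                predation
                + [InteractionRule("prey1", "prey2", effect_on_a=-2,
                                   effect_on_b=-2, encounter=0.3)]
            ),
            generations=generations,
            seed=seed,
            shuffle_rules=True,
        )
    )
    if generalist:
        expectation = {"metric": "coexistence_horizon", "value": generations,
                       "majority": "predator1"}
    else:
        expectation = {"metric": "tandem_exclusion",
                       "losers": ("prey1", "predator1"),
                       "survivors": ("prey2", "predator2")}
    return ScenarioFixture(
        name=(
            f"2SpePred.{'gen' if generalist else 'spe'}."
            f"{dispersal_pred1}-vs-{dispersal_pred2}"
        ),
        config=config,
        expectation=expectation,
        provenance_note=(
            "printed: two specialized predators on two mutually inhibiting "
            "prey; the uniform predator's prey is excluded, then the "
            "predator; generalists persist with the uniform one "
            "majoritarian. reconstructed: 100 cells x 120, prey (2, 2) at "
            "100r, predators (0, -2), inhibition -2/-2 at encounter 0.3, "
            "initials 6000/400; generalist cross-predation at encounter "
            "0.3. In this reconstruction the specialist contrast is robust "
            "(uniform tandem collapses, aggregated tandem persists); the "
            "generalist four-species equilibrium is not recovered."
        ),
    )


# ---------------------------------------------------------------------------
# registry

def _registry() -> dict[str, Callable[[int], ScenarioFixture]]:
    reg: dict[str, Callable[[int], ScenarioFixture]] = {
        "1Pred.sim1": lambda seed: predator_prey_equilibrium("100n", seed=seed),
        "1Pred.sim2": lambda seed: predator_prey_equilibrium("100r", seed=seed),
        "1Para.sim1": lambda seed: brood_parasitism("100n", "100n", 1000, seed=seed),
        "1Para.sim2": lambda seed: brood_parasitism("100n", "100r", 1000, seed=seed),
        "1Para.sim3": lambda seed: brood_parasitism("100r", "100r", 1000, seed=seed),
        "1Para.sim4": lambda seed: brood_parasitism("100r", "100r", 100, seed=seed),
        "1Para.sim5": lambda seed: brood_parasitism("100r", "100r", 10, seed=seed),
        "1Plank4.sim1": lambda seed: plankton_ladder(10, dispersal="100n", seed=seed),
        "1Plank4.sim2": lambda seed: plankton_ladder(10, dispersal="1n", seed=seed),
        "1Plank4.sim3": lambda seed: plankton_ladder(10, dispersal="100r", seed=seed),
        "2Planck1.sim1": lambda seed: plankton_ladder(
            50, (10, 59), dispersal="100r", seed=seed
        ),
        "2Planck1.sim2": lambda seed: plankton_ladder(
            50, (10, 59), dispersal="1r", seed=seed
        ),
        "2Plank2.sim1": lambda seed: fragmentation_sweep((12_650,), seed=seed)[0],
        "2Plank2.sim2": lambda seed: fragmentation_sweep((20_000,), seed=seed)[0],
        "2ResV.sim1": lambda seed: exclusion_and_rescue(
            "100n", "100n", 3, 2, seed=seed
        ),
        "2ResV.sim2": lambda seed: exclusion_and_rescue(
            "100n", "100n", 2, 3, seed=seed
        ),
        "2ResV.sim3": lambda seed: exclusion_and_rescue(
            "100r", "55r", 3, 2, seed=seed
        ),
        "2ResV.sim5": lambda seed: exclusion_and_rescue(
            "100r", "100n", 2, 2, seed=seed
        ),
        "2ResV.sim6": lambda seed: exclusion_and_rescue(
            "100r", "100n", 2, 2, resources_dispersal="100n", seed=seed
        ),
        "2Predat.sim1": lambda seed: predator_prey_cycles("100n", seed=seed),
        "2Predat.sim3": lambda seed: predator_prey_cycles("100r", seed=seed),
        "2SpePred.sim1": lambda seed: specialized_predators(seed=seed),
        "2SpePred.sim6": lambda seed: specialized_predators(
            generalist=True, seed=seed
        ),
    }
    return reg


def fixture_names() -> list[str]:
    """Names accepted by :func:`get_fixture` and the CLI."""
    return sorted(_registry())


def get_fixture(name: str, seed: int = 0) -> ScenarioFixture:
    """Build a registered fixture by name, with the given RNG seed."""
    reg = _registry()
    if name not in reg:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(reg))}"
        )
    return reg[name](seed)


def export_fixture(name: str, outdir: str | Path, seed: int = 0) -> Path:
    """Write a fixture's config as ``<name>.reconstructed.json``."""
    fixture = get_fixture(name, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{name}.reconstructed.json"
    save_config(fixture.config, path)
    return path
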