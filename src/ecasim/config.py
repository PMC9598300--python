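"""Scenario configuration: domain types, validation, JSON input/output.

A scenario describes a habitat (a one-dimensional lattice of cells, each
holding a discrete quantity of resources per generation), a list of digital
species (initial population, direct/indirect offspring numbers, dispersal
strategy, per-capita resource need) and an ordered list of pairwise
interaction rules.  The JSON schema uses snake_case keys but also accepts
the classic ECA variable names (``NumberOfCells``, ``NumberOfRsrcsInEachCell``,
``Distribution``, ``NumberOfItems``, ``DirectOffspring``, ``IndirectOffspring``)
as aliases, so configurations written in that vocabulary load unchanged.

Dispersal strategies are encoded as ``"<prefix><kind>"`` strings, e.g.
``"100r"``, ``"6n"``, ``"40h"``, where the prefix is a percentage in
[0, 100] and the kind is one of

``n``
    local neighborhood dispersal — each offspring moves independently to a
    uniformly chosen cell within a radius set by the prefix;
``r``
    global aggregated dispersal — offspring are allocated to cells with
    weights built from spacings of sorted uniforms, mixed toward the uniform
    share by (100 − prefix)%;
``h``
    gregarious dispersal — a prefix-sized percentage of cells is forced
    empty and the remainder receives a maximally aggregated ``r`` allocation.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "DispersalSpec",
    "HabitatSpec",
    "SpeciesSpec",
    "InteractionRule",
    "ScenarioConfig",
    "ValidationError",
    "load_config",
    "save_config",
    "config_from_dict",
    "config_to_dict",
]


class ValidationError(ValueError):
    """A configuration field violates the schema.

    Attributes
    ----------
    field : str
        Dotted path of the offending field, e.g. ``"species[2].distribution"``.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


_DISPERSAL_RE = re.compile(r"^(\d{1,3})([nrh])$")


@dataclass(frozen=True)
class DispersalSpec:
    """A dispersal strategy: percentage prefix plus kind letter (n, r or h)."""

    prefix: int
    kind: str

    def __post_init__(self):
        if self.kind not in ("n", "r", "h"):
            raise ValidationError("distribution", f"unknown strategy kind {self.kind!r}")
        if not (0 <= int(self.prefix) <= 100):
            raise ValidationError(
                "distribution", f"prefix {self.prefix} outside [0, 100]"
            )

    @classmethod
    def parse(cls, text: str, field_name: str = "distribution") -> "DispersalSpec":
        m = _DISPERSAL_RE.match(str(text).strip())
        if not m:
            raise ValidationError(
                field_name, f"{text!r} is not of the form '<prefix><n|r|h>'"
            )
        prefix, kind = int(m.group(1)), m.group(2)
        if prefix > 100:
            raise ValidationError(field_name, f"prefix {prefix} outside [0, 100]")
        return cls(prefix=prefix, kind=kind)

    def __str__(self) -> str:
        return f"{self.prefix}{self.kind}"


@dataclass(frozen=True)
class HabitatSpec:
    """The lattice: cell count, per-cell resources, default dispersal.

    ``resources_per_cell`` is either a single non-negative integer applied to
    every cell or a tuple of length ``number_of_cells``.  ``wrap`` selects
    ring topology for the n strategy (the default; avoids edge artifacts).
    """

    number_of_cells: int
    resources_per_cell: int | tuple[int, ...]
    default_dispersal: DispersalSpec
    wrap: bool = True

    def resources_vector(self):
        import numpy as np

        if isinstance(self.resources_per_cell, tuple):
            return np.asarray(self.resources_per_cell, dtype=np.int64)
        return np.full(self.number_of_cells, int(self.resources_per_cell), dtype=np.int64)

    @property
    def total_capacity(self) -> int:
        return int(self.resources_vector().sum())


@dataclass(frozen=True)
class SpeciesSpec:
    """One digital species.

    ``direct_offspring`` is the fecundity of an unassociated survivor;
    ``indirect_offspring`` is the fecundity effect this species confers on an
    associated partner (may be negative).  ``resource_need`` is the number of
    resource units one organism must capture in a cell to survive and
    reproduce.  ``dispersal`` of ``None`` means "use the habitat default";
    validation resolves it to an explicit strategy.
    """

    id: str
    number_of_items: int
    direct_offspring: int
    indirect_offspring: int
    dispersal: DispersalSpec | None = None
    resource_need: int = 1


@dataclass(frozen=True)
class InteractionRule:
    """An ordered pairwise association between two species.

    Within each cell, ``min`` one-to-one pairs form between the survivors of
    the two species (rules are applied in list order, with depletion).  The
    fecundity effect each member receives defaults to its partner's
    ``indirect_offspring``; ``effect_on_a`` / ``effect_on_b`` override that
    per rule, which is how mutual inhibition between two species is expressed
    without touching the indirect offspring they use in other interactions.

    ``encounter`` thins the saturated min-matching: each potential pair forms
    independently with this probability (1.0, the default, pairs every
    possible couple).
    """

    species_a: str
    species_b: str
    effect_on_a: int | None = None
    effect_on_b: int | None = None
    encounter: float = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Full simulation specification (habitat + species + interactions + run control)."""

    habitat: HabitatSpec
    species: tuple[SpeciesSpec, ...]
    interactions: tuple[InteractionRule, ...] = ()
    generations: int = 100
    seed: int = 0
    record_cell_stats: bool = False
    #: apply interaction rules in a fresh random order each generation
    #: instead of list order; removes the systematic first-rule advantage
    #: when several rules compete for the same partner species
    shuffle_rules: bool = False

    def species_index(self) -> dict[str, int]:
        return {sp.id: i for i, sp in enumerate(self.species)}

    def digest(self) -> str:
        """Stable hex digest of the canonical JSON form, for provenance."""
        payload = json.dumps(config_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# validation

def validate(config: ScenarioConfig) -> ScenarioConfig:
    """Validate a scenario and return it with species dispersal defaults resolved.

    Raises :class:`ValidationError` naming the first offending field.
    """
    hab = config.habitat
    if int(hab.number_of_cells) < 1:
        raise ValidationError("habitat.number_of_cells", "must be >= 1")
    if isinstance(hab.resources_per_cell, tuple):
        if len(hab.resources_per_cell) != hab.number_of_cells:
            raise ValidationError(
                "habitat.resources_per_cell",
                f"vector length {len(hab.resources_per_cell)} != "
                f"number_of_cells {hab.number_of_cells}",
            )
        if any(int(r) < 0 for r in hab.resources_per_cell):
            raise ValidationError("habitat.resources_per_cell", "entries must be >= 0")
    elif int(hab.resources_per_cell) < 0:
        raise ValidationError("habitat.resources_per_cell", "must be >= 0")

    seen: set[str] = set()
    resolved = []
    for i, sp in enumerate(config.species):
        where = f"species[{i}]"
        if not sp.id:
            raise ValidationError(f"{where}.id", "must be a non-empty string")
        if sp.id in seen:
            raise ValidationError(f"{where}.id", f"duplicate species id {sp.id!r}")
        seen.add(sp.id)
        if int(sp.number_of_items) < 0:
            raise ValidationError(f"{where}.number_of_items", "must be >= 0")
        if int(sp.direct_offspring) < 0:
            raise ValidationError(f"{where}.direct_offspring", "must be >= 0")
        if int(sp.resource_need) < 1:
            raise ValidationError(f"{where}.resource_need", "must be >= 1")
        if sp.dispersal is None:
            sp = replace(sp, dispersal=hab.default_dispersal)
        resolved.append(sp)

    for j, rule in enumerate(config.interactions):
        where = f"interactions[{j}]"
        for attr in ("species_a", "species_b"):
            sid = getattr(rule, attr)
            if sid not in seen:
                raise ValidationError(f"{where}.{attr}", f"unknown species id {sid!r}")
        if rule.species_a == rule.species_b:
            raise ValidationError(
                f"{where}.species_b", "a species cannot associate with itself"
            )
        if not (0.0 <= float(rule.encounter) <= 1.0):
            raise ValidationError(f"{where}.encounter", "must lie in [0, 1]")

    if int(config.generations) < 1:
        raise ValidationError("generations", "must be >= 1")

    return replace(config, species=tuple(resolved))


# ---------------------------------------------------------------------------
# JSON (de)serialisation

_HABITAT_ALIASES = {
    "NumberOfCells": "number_of_cells",
    "NumberOfRsrcsInEachCell": "resources_per_cell",
    "Distribution": "distribution",
}
_SPECIES_ALIASES = {
    "NumberOfItems": "number_of_items",
    "DirectOffspring": "direct_offspring",
    "IndirectOffspring": "indirect_offspring",
    "Distribution": "distribution",
    "ResourceNeed": "resource_need",
}


def _dealias(d: dict, aliases: dict, where: str) -> dict:
    out = {}
    for k, v in d.items():
        canon = aliases.get(k, k)
        if canon in out:
            raise ValidationError(f"{where}.{k}", "duplicates a canonical key")
        out[canon] = v
    return out


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ValidationError(f"{where}.{key}", "missing required field")
    return d[key]


def _as_int(value, where: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValidationError(where, f"expected an integer, got {value!r}")
    if isinstance(value, float) and not value.is_integer():
        raise ValidationError(where, f"expected an integer, got {value!r}")
    return int(value)


def config_from_dict(raw: dict) -> ScenarioConfig:
    """Build and validate a :class:`ScenarioConfig` from a plain dict."""
    if not isinstance(raw, dict):
        raise ValidationError("<root>", "configuration must be a JSON object")
    hraw = _dealias(dict(_require(raw, "habitat", "<root>")), _HABITAT_ALIASES, "habitat")
    rsrc = _require(hraw, "resources_per_cell", "habitat")
    if isinstance(rsrc, list):
        rsrc = tuple(_as_int(r, "habitat.resources_per_cell") for r in rsrc)
    else:
        rsrc = _as_int(rsrc, "habitat.resources_per_cell")
    habitat = HabitatSpec(
        number_of_cells=_as_int(_require(hraw, "number_of_cells", "habitat"),
                                "habitat.number_of_cells"),
        resources_per_cell=rsrc,
        default_dispersal=DispersalSpec.parse(
            _require(hraw, "distribution", "habitat"), "habitat.distribution"
        ),
        wrap=bool(hraw.get("wrap", True)),
    )

    species = []
    for i, sraw in enumerate(_require(raw, "species", "<root>")):
        where = f"species[{i}]"
        sraw = _dealias(dict(sraw), _SPECIES_ALIASES, where)
        disp = None
        if sraw.get("distribution") is not None:
            disp = DispersalSpec.parse(sraw["distribution"], f"{where}.distribution")
        species.append(
            SpeciesSpec(
                id=str(_require(sraw, "id", where)),
                number_of_items=_as_int(
                    _require(sraw, "number_of_items", where), f"{where}.number_of_items"
                ),
                direct_offspring=_as_int(
                    _require(sraw, "direct_offspring", where),
                    f"{where}.direct_offspring",
                ),
                indirect_offspring=_as_int(
                    _require(sraw, "indirect_offspring", where),
                    f"{where}.indirect_offspring",
                ),
                dispersal=disp,
                resource_need=_as_int(
                    sraw.get("resource_need", 1), f"{where}.resource_need"
                ),
            )
        )

    interactions = []
    for j, rraw in enumerate(raw.get("interactions", [])):
        where = f"interactions[{j}]"
        rraw = dict(rraw)
        interactions.append(
            InteractionRule(
                species_a=str(_require(rraw, "species_a", where)),
                species_b=str(_require(rraw, "species_b", where)),
                effect_on_a=None if rraw.get("effect_on_a") is None
                else _as_int(rraw["effect_on_a"], f"{where}.effect_on_a"),
                effect_on_b=None if rraw.get("effect_on_b") is None
                else _as_int(rraw["effect_on_b"], f"{where}.effect_on_b"),
                encounter=float(rraw.get("encounter", 1.0)),
            )
        )

    config = ScenarioConfig(
        habitat=habitat,
        species=tuple(species),
        interactions=tuple(interactions),
        generations=_as_int(raw.get("generations", 100), "generations"),
        seed=_as_int(raw.get("seed", 0), "seed"),
        record_cell_stats=bool(raw.get("record_cell_stats", False)),
        shuffle_rules=bool(raw.get("shuffle_rules", False)),
    )
    return validate(config)


def config_to_dict(config: ScenarioConfig) -> dict:
    """Canonical plain-dict form (snake_case keys, fixed key order)."""
    hab = config.habitat
    rsrc = (
        list(hab.resources_per_cell)
        if isinstance(hab.resources_per_cell, tuple)
        else int(hab.resources_per_cell)
    )
    out = {
        "habitat": {
            "number_of_cells": int(hab.number_of_cells),
            "resources_per_cell": rsrc,
            "distribution": str(hab.default_dispersal),
            "wrap": bool(hab.wrap),
        },
        "species": [
            {
                "id": sp.id,
                "number_of_items": int(sp.number_of_items),
                "direct_offspring": int(sp.direct_offspring),
                "indirect_offspring": int(sp.indirect_offspring),
                **(
                    {"distribution": str(sp.dispersal)}
                    if sp.dispersal is not None
                    else {}
                ),
                "resource_need": int(sp.resource_need),
            }
            for sp in config.species
        ],
        "interactions": [
            {
                "species_a": r.species_a,
                "species_b": r.species_b,
                **({"effect_on_a": r.effect_on_a} if r.effect_on_a is not None else {}),
                **({"effect_on_b": r.effect_on_b} if r.effect_on_b is not None else {}),
                **({"encounter": r.encounter} if r.encounter != 1.0 else {}),
            }
            for r in config.interactions
        ],
        "generations": int(config.generations),
        "seed": int(config.seed),
        "record_cell_stats": bool(config.record_cell_stats),
        **({"shuffle_rules": True} if config.shuffle_rules else {}),
    }
    return out


def load_config(path: str | Path) -> ScenarioConfig:
    """Read, validate and default-resolve a scenario JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: malformed JSON ({exc})") from exc
    return config_from_dict(raw)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario to JSON in canonical key order (round-trip stable)."""
    config = validate(config)
    text = json.dumps(config_to_dict(config), indent=2)
    Path(path).write_text(text + "\n", encoding="utf-8")
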