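"""Whole-simulation driver, time-series accumulation and the exclusion bound.

:func:`run` executes a scenario for its configured number of generations
(stopping early if every species is extinct) and returns a
:class:`SimulationResult` holding per-generation species totals, the
extinction ledger, the richness series and optional per-cell diagnostics.

:func:`chebyshev_bound` is the analytic companion to the simulator: for a
per-cell density distribution with mean μ and variance σ², and an average
per-cell carrying capacity κ, the one-sided skew-corrected Chebyshev
inequality

    P ≤ q σ² / (μ − κ)²

caps the probability that an organism lands where the population exceeds
capacity and is excluded from reproduction.  The factor ``q ≥ 0`` is the
share of the two-sided tail mass that sits on the relevant side; it is 1/2
for a symmetric distribution and is estimated empirically from an allocation
sample by :func:`estimate_q`.  The ceiling is reported unclipped (it may
exceed 1 — it is a bound, not a probability); callers may clip for display.
The bound grows with σ², which is the analytic statement that aggregated
dispersal is less efficient than uniform dispersal at equal capacity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .config import ScenarioConfig, validate
from .dispersal import AllocationStats
from .dynamics import initial_state, step

__all__ = [
    "SimulationResult",
    "run",
    "chebyshev_bound",
    "estimate_q",
    "exclusion_frequency",
    "summarize",
    "write_result",
    "tail_mean",
]


@dataclass(frozen=True)
class SimulationResult:
    """Time series and diagnostics of one simulation run.

    ``totals`` row 0 is the founder census as placed; row t (t ≥ 1) is the
    standing population of generation t: the survivors of that generation's
    resource competition, i.e. the organisms that lived to reproduce.  A
    species whose census reaches 0 can never rebound (no organisms, no
    offspring), so richness is non-increasing after the initial row.
    """

    species_ids: tuple[str, ...]
    totals: np.ndarray  # (n_recorded_generations, S) including generation 0
    deaths: np.ndarray  # (n_recorded_generations, S); zeros in row 0
    pairs: np.ndarray  # (n_recorded_generations, n_rules); zeros in row 0
    extinctions: dict[str, int | None]  # species id -> first generation at 0
    cell_stats: tuple[tuple[AllocationStats, ...], ...] | None
    seed: int
    config_digest: str

    @property
    def n_generations(self) -> int:
        """Number of executed generations (rows minus the initial state)."""
        return self.totals.shape[0] - 1

    def richness(self) -> np.ndarray:
        """Per-generation count of species with a nonzero total."""
        return (self.totals > 0).sum(axis=1)

    def final_totals(self) -> dict[str, int]:
        return dict(zip(self.species_ids, map(int, self.totals[-1])))


def run(
    config: ScenarioConfig,
    seed: int | None = None,
    generations: int | None = None,
) -> SimulationResult:
    """Execute a scenario; ``seed``/``generations`` override the config values."""
    config = validate(config)
    use_seed = int(config.seed if seed is None else seed)
    horizon = int(config.generations if generations is None else generations)
    rng = np.random.default_rng(use_seed)

    state = initial_state(config, rng)
    S = len(config.species)
    n_rules = len(config.interactions)
    totals = [state.totals()]
    deaths = [np.zeros(S, dtype=np.int64)]
    pairs = [np.zeros(n_rules, dtype=np.int64)]
    stats: list[tuple[AllocationStats, ...]] = []
    extinct_at: dict[str, int | None] = {sp.id: None for sp in config.species}
    for sp_id, t0 in zip(extinct_at, totals[0]):
        if t0 == 0:
            extinct_at[sp_id] = 0

    for t in range(1, horizon + 1):
        state, rec = step(state, config, rng)
        totals.append(rec.totals)
        deaths.append(rec.deaths)
        pairs.append(rec.pairs)
        if rec.cell_stats is not None:
            stats.append(rec.cell_stats)
        for j, sp in enumerate(config.species):
            if extinct_at[sp.id] is None and rec.totals[j] == 0:
                extinct_at[sp.id] = t
        if rec.totals.sum() == 0:
            break  # habitat empty: every later census is zero

    return SimulationResult(
        species_ids=tuple(sp.id for sp in config.species),
        totals=np.asarray(totals, dtype=np.int64),
        deaths=np.asarray(deaths, dtype=np.int64),
        pairs=np.asarray(pairs, dtype=np.int64),
        extinctions=extinct_at,
        cell_stats=tuple(stats) if stats else None,
        seed=use_seed,
        config_digest=config.digest(),
    )


def tail_mean(series: np.ndarray, fraction: float = 0.25) -> float:
    """Mean of the trailing ``fraction`` of a per-generation series.

    The convention used to read off a "stable" population level: discard the
    transient and average the last quarter of the run.
    """
    series = np.asarray(series, dtype=np.float64)
    k = max(1, int(round(fraction * series.shape[0])))
    return float(series[-k:].mean())


# ---------------------------------------------------------------------------
# analytic exclusion ceiling

def chebyshev_bound(mu: float, sigma2: float, kappa: float, q: float) -> float:
    """Skew-corrected one-sided Chebyshev ceiling ``q σ² / (μ − κ)²``.

    Raises ``ValueError`` when μ = κ (the bound is undefined there).
    """
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    if q < 0:
        raise ValueError("q must be non-negative")
    if mu == kappa:
        raise ValueError("bound undefined for mu == kappa")
    return float(q) * float(sigma2) / (float(mu) - float(kappa)) ** 2


def estimate_q(sample: np.ndarray, kappa: float) -> float:
    """Estimate the tail-share factor q from a per-cell count sample.

    With α = |μ − κ|, q is the fraction of the two-sided tail mass
    ``P(X ≤ μ − α) + P(X ≥ μ + α)`` that lies in the relevant one-sided
    tail.  This is an empirical proportion in [0, 1] (1/2 for a symmetric
    sample); it is an estimate, not the distribution-level constant.
    """
    x = np.asarray(sample, dtype=np.float64)
    mu = x.mean()
    alpha = abs(mu - float(kappa))
    if alpha == 0:
        raise ValueError("q undefined for mu == kappa")
    lower = np.count_nonzero(x <= mu - alpha)
    upper = np.count_nonzero(x >= mu + alpha)
    if lower + upper == 0:
        return 0.0
    side = lower if float(kappa) < mu else upper
    return side / (lower + upper)


def exclusion_frequency(
    alloc_sampler: Callable[[np.random.Generator], np.ndarray],
    capacity: int,
    replicates: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo fraction of organisms allocated beyond per-cell capacity.

    ``alloc_sampler(rng)`` must return a per-cell count vector; the excluded
    fraction ``Σ max(0, c_i − capacity) / Σ c_i`` is averaged over
    ``replicates`` draws (empty draws contribute 0).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    acc = 0.0
    for _ in range(int(replicates)):
        counts = np.asarray(alloc_sampler(rng), dtype=np.int64)
        total = counts.sum()
        if total > 0:
            acc += float(np.maximum(counts - int(capacity), 0).sum()) / float(total)
    return acc / int(replicates)


# ---------------------------------------------------------------------------
# tidy outputs

def summarize(result: SimulationResult) -> dict[str, pd.DataFrame]:
    """Tidy tables: totals (long), extinction ledger, richness, cell stats."""
    gens = np.arange(result.totals.shape[0])
    totals = pd.DataFrame(
        {
            "generation": np.repeat(gens, len(result.species_ids)),
            "species_id": list(result.species_ids) * len(gens),
            "count": result.totals.ravel(),
        }
    )
    extinctions = pd.DataFrame(
        {
            "species_id": list(result.extinctions),
            "extinct_at": [
                -1 if g is None else g for g in result.extinctions.values()
            ],
        }
    )
    richness = pd.DataFrame({"generation": gens, "richness": result.richness()})
    out = {"totals": totals, "extinctions": extinctions, "richness": richness}
    if result.cell_stats is not None:
        rows = []
        for g, per_species in enumerate(result.cell_stats, start=1):
            for sp_id, st in zip(result.species_ids, per_species):
                rows.append(
                    {
                        "generation": g,
                        "species_id": sp_id,
                        "sigma": st.sigma,
                        "max_density": st.max_density,
                        "empty_cells": st.empty_cells,
                        "to_die": st.to_die,
                    }
                )
        out["cellstats"] = pd.DataFrame(rows)
    return out


def write_result(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write CSV tables plus a JSON manifest (seed, config digest) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, frame in summarize(result).items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path
    manifest = {
        "seed": result.seed,
        "config_digest": result.config_digest,
        "generations": result.n_generations,
        "species": list(result.species_ids),
        "final_totals": result.final_totals(),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    written["manifest"] = path
    return written
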