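# Model and methods

## The automaton

The habitat is a one-dimensional lattice of `m` cells (a ring by default;
`wrap=false` truncates dispersal windows at the boundary).  Each cell holds
`R_i` resource units, renewed every generation.  The state is an integer
matrix of organism counts per (cell, species).  A generation applies four
operators, in this order:

1. **Competition.**  All occupants of a cell, across species, are processed
   in a uniformly random order; an organism consumes its species'
   `resource_need` units if at least that many remain, otherwise it dies.
   With homogeneous needs this is equivalent to drawing
   `min(occupants, ⌊R/need⌋)` survivors as a multivariate hypergeometric
   sample, which is how the engine computes it (vectorized as sequential
   conditional hypergeometric draws).  Heterogeneous needs are simulated
   directly by a jitted random-order consumption walk (a splitmix64-seeded
   kernel; it stops as soon as the remaining stock is below the smallest
   need, which makes its cost proportional to the number of draws that can
   still change the outcome).  The walk produces the *small-portion
   effect*: leftovers smaller than a high-need organism's requirement stay
   available to low-need organisms.
2. **Pairing.**  Interaction rules are applied in list order (or, with
   `shuffle_rules`, in a fresh random order each generation); each rule
   forms `min(remaining_a, remaining_b)` one-to-one pairs per cell, thinned
   binomially when the rule's `encounter` probability is below 1.  Paired
   individuals are unavailable to later rules.
3. **Reproduction.**  Unassociated survivors produce `direct_offspring`;
   associated ones produce `max(0, direct + effect)` where the effect
   defaults to the partner species' `indirect_offspring` and can be
   overridden per rule.  The override exists because a single species-level
   indirect value cannot simultaneously express, say, the gain a prey
   confers on its predator and the penalty it imposes on a competitor it
   inhibits.
4. **Dispersal.**  Adults die (non-overlapping generations).  Each species'
   offspring pool is redistributed by its strategy: `n` moves each
   offspring to a uniform cell within radius `round(prefix/100·m)` of its
   natal cell; `r` allocates the pooled total with per-cell weights
   `(1−p)/m + p·w_i` where `w` follows the law of spacings of `m` sorted
   uniforms (sampled in the equivalent normalised-iid-exponential form,
   which needs no sort and is exchangeable across cells, so no
   permutation step is needed); `h` forces a uniformly chosen
   `⌊prefix/100·m⌋` cells empty and applies the `p=1` allocation to the
   rest.  Real-valued targets become integers by largest-remainder
   rounding, so every operator conserves the total exactly.

All randomness flows through a single `numpy.random.Generator` seeded from
the scenario, so a configuration and seed determine the trajectory
bit-for-bit (the heterogeneous-need kernel consumes per-cell substream
seeds drawn from the same generator).

The per-generation census reported in the time series is the number of
survivors of that generation's competition — the organisms that lived to
reproduce.  Row 0 is the founder placement.  A species whose census reaches
zero can never rebound, so richness is non-increasing after the first row.

## Dispersal-kernel properties

The `r` weights at `p=1` are Dirichlet(1,…,1) marginals, i.e. asymptotically
exponential for large `m`: per-cell counts have coefficient of variation ≈ 1
and sample skewness ≈ 2 (the negative-binomial-like shape used to describe
overdispersed ecological counts).  Variance grows monotonically with the
prefix (`σ ∝ p·μ` at large totals); `0r` distributes the exact mean when the
total divides evenly.  `100n` and `0r` both uniformise; repeated `n` at any
positive prefix converges to the multinomial noise floor.

The one-sided, skew-corrected Chebyshev ceiling
`P ≤ q σ²/(μ−κ)²` (with `q` the share of the two-sided tail mass on the
over-capacity side, 1/2 for a symmetric distribution) bounds the
probability mass in cells beyond capacity.  It is informative only in the
tail regime `κ > μ`; `estimate_q` computes the empirical tail share and the
bound is reported unclipped, because it is a ceiling, not a probability.

## Fixture reconstructions

The published experiments are reconstructed in `ecasim.scenarios`; each
fixture's `provenance_note` separates printed from reconstructed
parameters.  Key reconstruction decisions:

- **Capacity filling / inefficiency (`1Pred`).**  Prey (2, 1) with a weak
  specialized predator (0, −2) on 100 cells × 120 resources.  Under `100n`
  the prey plateau is exactly the capacity, 12,000; under `100r` the
  stationary level solves `s = 2s(1−e^{−60/s})` per cell, ≈ 8,700 — the
  inefficiency of aggregation.  The predator's parameters are unprinted;
  the fixture pins a predator that fades out so the plateau reflects the
  dispersal variance alone, which is what the published comparison varies.
- **Predator–prey stabilisation (`2Predat`).**  Prey (2, 2), predator
  (0, −2), both `100r` → coexistence beyond 500 generations; both `100n` →
  collapse within ~20 generations.
- **Brood parasitism (`1Para`).**  Cuckoo (0, −2), warbler (2, 2); total
  capacity 10,000 held constant while cells vary over 1000/100/10.  Low
  per-cell capacity (10 at 1000 cells) is what lets uniform-dispersal
  troughs reach per-cell densities ≪ 1, where empty-of-cuckoo cells rescue
  the warbler and starve the cuckoo; "brink of extinction" on small
  habitats is operationalised as a total below 5% of capacity.
- **Plankton ladders (`1Plank4`, `2Planck1`).**  Competition-only
  communities (no interaction rules) with `resource_need` priced at one
  unit per offspring (`need = DirectOffspring`).  With unit needs the
  random-order lottery makes per-capita survival composition-independent,
  so the fecundity ladder is under strict selection and no dispersal
  strategy preserves it; the offspring-priced need introduces the
  small-portion niche structure under which maximal aggregation holds the
  full ladder (10 species, 3…6, zero exclusions in 400 generations; 50
  species, 10…59, richness ~49/50 at generation 400 on 6,000 cells × 600
  resources) while `1r` lets the fittest exclude the rest.  The 50-species
  fixture is a desk scaling of a run whose original habitat held hundreds
  of millions of organisms; at this scale a
  drift loss of one species in some seeds is expected and the acceptance
  band accounts for it.
- **Habitat fragmentation (`2Plank2`).**  One hundred competitors with a
  fecundity-and-need ladder (10…109) under maximal aggregation, identical
  except for the cell count.  Extinctions here are ecological drift of the
  low-abundance ranks, on a clock that scales with habitat size, so the
  smaller habitat is reliably the poorer one at any fixed generation and
  the 20,000-cell richness lands near the published level.  The *size* of
  the published gap is not recovered: because drift time scales roughly
  linearly with cells, a 1.6-fold habitat reduction shifts the richness
  curve by a factor ~1.6 in time, which at generation 700 costs this
  community ~10 species, not ~37.  No parameterization we tried (neutral
  equal-fecundity communities, duplicated pairs, compressed ladders,
  milder aggregation prefixes, per-cell resource sweeps) makes the
  generation-700 richness that sensitive to cell count alone; the fixture
  documents this in its provenance note and the corresponding regression
  test is expected to fail on the small-habitat value.
- **Exclusion and rescue (`2ResV`).**  Two consumers pair with a
  stationary "Resources" species (replacement reproduction, unaffected by
  pairing, ample cell resources) so that pairing slots are the only
  limiting factor.  Aggregation then carries only its cost — wasted
  pairing opportunities in saturated cells — which is why the uniform
  consumer excludes the aggregated one at equal fecundity, while an extra
  offspring can compensate the cost and produce stable coexistence.
- **Interdemic competition (`2SpePred`).**  Two specialist tandems whose
  prey inhibit each other (−2 at encounter 0.3).  The uniform predator
  over-exploits: its prey is excluded, then it starves, and the aggregated
  tandem persists.  The generalist four-species equilibrium is not
  recovered by this reconstruction (apparent competition keeps either
  predator fed through either prey's trough, so the oscillation diverges);
  the fixture builds the generalist variant but no claim is attached to it.

## Parameters that matter

- `prefix` (0–100, %): aggregation level; the single variable behind every
  contrast above.
- `resources_per_cell` (resource units): with unit needs, the per-cell
  carrying capacity; per-cell capacities of order 10 make demographic
  discreteness (empty cells, Poisson troughs) ecologically active, which
  the exploitation scenarios depend on.
- `resource_need` (units/organism, default 1): pricing need by fecundity
  converts the lottery into a size-structured niche (small-portion effect).
- `generations`: horizons follow the published figures (400–700); "stable"
  levels are read as the mean of the trailing 25% of the series
  (`tail_mean`).

## What the generator does and does not emulate

Fixtures generate all data; nothing is fitted to field observations.  The
automaton has no explicit space beyond the cell index (the `r`/`h`
strategies ignore distance entirely), no genetics or mutation, no
overlapping generations, no energy storage, and interaction pairing is
saturated rather than mass-action unless an `encounter` probability is set.
Passing tests therefore demonstrate the internal consistency of the
variance-mediated mechanisms, not their quantitative transfer to any real
plankton or vertebrate system.

## Numerical choices

- Largest-remainder integerization; ties go to arbitrary-but-deterministic
  cells (the weights are exchangeable, so no spatial bias results).
- The homogeneous-need survivor draw is decomposed into vectorized
  conditional hypergeometric draws, one per species, which is exact.
- Competition in a cell whose occupants fit its resources never kills;
  those cells are skipped wholesale.
- Simulations stop early once the habitat is empty; the extinction ledger
  records the first zero-census generation per species.
- Tail means use the trailing 25% of the recorded series.

## Known limitations

- The generalist-predator equilibrium (above) and the uniform-Resources
  variant of the rescue scenario are not reproduced; both are documented
  in the fixture notes.
- Chebyshev ceilings are weak (often ≫ 1) away from the `κ > μ` tail
  regime.
- The heterogeneous-need competition walk is O(successful draws) per cell
  per generation; community fixtures with tens of distinct needs and
  ≥ 10⁴ cells run in minutes, not seconds.
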