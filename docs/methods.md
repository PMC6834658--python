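# Methods

This note documents the models, parameters and numerical choices behind
`n2kprior`, and what the synthetic data can and cannot say about real
protected-area networks.

## Problem statement

Given a network of m sites, each with a declared list of target
species, a binary site × species occurrence matrix, IUCN Red List
statuses, directive-annex listing flags and a species–habitat
association table, the pipeline identifies the minimal set of sites
whose target lists should be extended so that every threatened species
(CR, EN, VU or NT — the categories that roughly correspond to an
unfavourable conservation status and hence to management need) is a
managed target in at least t sites. Robustness is summarised by
re-running the optimisation over bootstrap replicates of the candidate
pools and counting selection frequencies.

## Gap analysis

`gap.summarize` cross-tabulates species by taxon × status with
annex-listed counts per cell, and derives threatened totals, the
threatened-but-unlisted set and (given a site table) the threatened
species declared in no site. Integer percentages use round-half-up by
default with a truncation mode exposed, because published coverage
figures mix the two conventions (e.g. 21/156 = 13.46 prints as 13
either way, but 40/49 = 81.6 prints as 81 only under truncation).

The module embeds the published 2019 cross-tabulation of the 1282
European terrestrial and freshwater vertebrates as a reference fixture.
Its printed totals row is internally inconsistent with the per-taxon
cells for directive-listed counts (the LC row prints 277 where the
cells sum to 281, so the directive total prints 400 vs 404 from cells).
Both are kept verbatim: per-taxon cells drive taxon-level checks, the
totals row drives network-level checks, and no reconciliation is
attempted. The headline share of listed species that are threatened is
28% under either denominator.

## Candidate pools

A site's pool in one replicate is its declared list plus at most
`threshold` additions drawn from the eligible species occurring there
(eligibility per scenario: policy = threatened ∧ annex-listed;
conservation = all threatened, with a flag to restrict to unlisted
only). "Habitat-sharing" is operationalised as non-empty intersection
between a candidate's preferred ∪ suitable habitats and the union of
habitats of the site's declared targets — a deliberately transparent
binary overlap, since no graded similarity metric is defined by the
source linkage tables. All declared targets contribute managed
habitats, threatened or not: management effort follows the declared
list. When candidates fit within the threshold the pool is
deterministic; otherwise habitat-sharing candidates are exhausted first
(uniformly without replacement), then others. Sites with empty declared
lists have no managed habitats, so all their candidates are drawn from
the "other" stratum. The threshold caps only additions; declared
targets ride free.

## Objective and solvers

The objective is the linear normalised-shortfall form

    total(x) = Σ_i c_i x_i + Σ_j SPF_j · H(s_j) · s_j / t_j

with s_j = max(0, t_j − r_j) and H the Heaviside step. Targets count
as met at r_j ≥ t_j. This is implemented exactly as written, not as the
cost-to-fix penalty of classic Marxan implementations. Defaults follow
the standard analysis constants: t = 10, SPF = 10, c = 1.

**Simulated annealing** proposes uniformly random single-site flips,
accepts when Δtotal ≤ 0 or with probability exp(−Δtotal/T), and cools
geometrically from T₀ to 10⁻⁴·T₀. T₀ is calibrated so the median
|Δtotal| of 100 probe flips from the initial (empty) state is accepted
with probability 0.8. Δtotal is evaluated incrementally (only the
species present at the flipped site are touched) and a test asserts it
equals the from-scratch recomputation. The default of 10⁵ iterations is
a desk-scale setting chosen so a full bootstrap experiment runs in
minutes on one core; production-scale runs (millions of iterations,
hundreds of restarts) are plain configuration values.

**Tie-breaking.** With the standard constants the marginal penalty of
one unit of shortfall (SPF/t = 1) exactly equals one unit-cost site, so
a solution one site smaller but one representation short ties the
full-representation solution on the total. Since the analysis treats
the targets as the binding requirement, equal-total states are ordered
by lower penalty first, then fewer selected sites, then lexicographic
selection vector — in the annealer's best-state tracking and in
best-of-runs selection. The exhaustive oracle keeps the plain
(total, fewer sites, lexicographic) order, as a deliberately
independent convention. Floats are compared with a 10⁻⁹ tolerance.

**Greedy** adds the site with the largest objective decrease per unit
cost until no addition strictly helps (ties to the lowest index);
**exact** enumerates all 2^m subsets for m ≤ 20. Greedy is a fast
baseline, exact the test oracle; on 50 random penalty-dominant
instances the best-of-10 annealer attains the enumerated optimum in at
least 45.

**Feasibility.** Targets are clamped per bootstrap to each species'
availability (number of pools containing it), with a logged warning;
species that entered no pool at all in a replicate are dropped from
that replicate's instance rather than carried with an unmeetable
target. Unclamped behaviour is available via `clamp_targets=False`. A
config switch `count_declared_as_locked` (off by default) credits sites
where a species is already declared toward its representation without
selecting them; the default is the pure objective on the pool
availability matrix.

## Bootstrap orchestration and assignment

For bootstrap b, pools are drawn from the sub-stream
SeedSequence(master_seed, spawn_key=(b, 0)) and annealer run k from the
k-th spawn of spawn_key=(b, 1); everything downstream is deterministic
given the master seed, and run k is identical whether 10 or 100 runs
are requested. Desk-scale defaults are 50 bootstraps × best-of-10 ×
10⁵ iterations.

Translating a selection back into list updates: every selected site is
initially assigned all non-declared pool members, then additions are
trimmed greedily wherever a species' representation exceeds its target
without them, processing sites in descending count of droppable
additions so redundant sites are emptied first. Declared contributions
are never trimmed. "Updated sites" counts sites with at least one
surviving addition; the raw selected-site count is reported alongside.

## Aggregation

Site selection frequency is the count of best solutions containing the
site (reported as count and proportion); species-site frequency counts
the bootstraps in which a species was assigned to a selected site
(declared-and-eligible members plus kept additions), so it is bounded
by the site's own frequency. The richness diagnostic is a Spearman rank
correlation between per-site richness (optionally restricted to a
species subset) and selection frequency — rank-based because the
frequency distribution is strongly skewed; it is reported with its
two-sided p-value, never thresholded, and returns NaN with a warning on
constant input. Concentration is the Gini coefficient of the site
frequency vector (0 = even, (k−1)/k for all mass on one of k sites),
computed from the sorted-vector formula and cross-checked in tests
against the O(k²) pairwise-difference definition. Aggregation is always
per (scenario, threshold) run; frequencies are never pooled across
thresholds implicitly.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs,
not their geography:

- **Sites** sit on a 1-D latitude axis (35–70 °N, uniform, sorted so
  site index equals latitude rank). No polygons, no 2-D geometry.
- **Species** come in five taxa; per-taxon counts default to the
  published checklist totals (85 amphibians, 477 birds, 396 fish, 186
  mammals, 138 reptiles). Red List status is categorical with the
  published marginals (threatened fraction 322/1282 ≈ 0.25); annex
  listing is Bernoulli with P(listed | status) from the published
  totals row, which makes listing imperfectly correlated with threat by
  construction.
- **Ranges** are contiguous latitude intervals — the simplest structure
  that makes rarity and endemism controllable by two parameters. Sizes
  are log-normal (default log-mean ln 30, log-sd 1.5 at 1000 sites:
  median range 3% of the network, heavy right tail, a few percent of
  narrow-range endemics), rounded and clipped to [1, n_sites]. Centres
  of threatened species' ranges are drawn from Beta(1, 1+g) over the
  latitude rank (southward-skewed); g defaults to 4, placing the mean
  threatened range centre at rank fraction 1/6. No quantitative
  calibration of the real gradient exists, so g is an explicitly free
  parameter.
- **Habitats**: a 12-type typology (the order of magnitude of the MAES
  ecosystem classification); each species gets one preferred habitat
  plus 0–2 suitable ones, uniformly without replacement.
- **Declared lists** include each annex-listed occupant of a site with
  probability 0.5; empty lists are allowed and occur, emulating sites
  designated for habitats only.

Per-stage RNG sub-streams (sites, statuses, ranges, habitats, declared
lists) are derived from the master seed by fixed spawn keys, so
changing a later stage never reshuffles earlier draws.

What passing tests on this generator do **not** show: real occurrence
matrices have 2-D spatial autocorrelation, nested community structure
and range-size/latitude interactions far richer than contiguous 1-D
intervals; real declared lists reflect population-level designation
criteria, not Bernoulli sampling of occupants; and real networks are
~30× larger than the desk-scale instances used in tests. Conclusions
about the pipeline's correctness transfer; conclusions about effect
sizes (how many lists need updating, how concentrated frequencies are)
do not.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on 40–150-site datasets with thousands of
annealing iterations. The end-to-end checks use: 50 random instances of
≤ 12 sites for the oracle-equivalence harness (best-of-10 × 50 000
iterations); a 200-site, 70-species dataset with generous ranges
(log-normal ln 80, sd 0.4 — every threatened species occupies ≥ 10
sites with probability ≈ 1) for the feasibility and stability checks
(5–30 bootstraps); and a 150-site dataset for the threshold sweep
{2, 5, 10, 20, 50} × 5 seeds. The acceptance script reuses the 200-site
configuration with 5 bootstraps × best-of-10 × 30 000 iterations per
scenario. These sizes were chosen so the full experiment suite
completes in minutes on a single core while keeping every qualitative
property (feasibility, concentration trend, stability) comfortably
resolvable.

## Known limitations

- The annealer's quality depends on the iteration budget; at the desk
  defaults it matches exhaustive optima on small instances but carries
  no optimality guarantee at scale (none exists for this problem class).
- The habitat-priority rule is binary; graded habitat similarity or
  management-cost heterogeneity among additions is out of scope, as are
  boundary-length/clumping terms and locked-in/locked-out site statuses
  beyond pass-through.
- Real-data ingestion expects a precomputed occurrence matrix; GIS
  overlap of range polygons with site boundaries is out of scope
  (`geopandas`-based preprocessing can produce the required CSVs).
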