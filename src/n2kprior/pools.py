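"""Per-site candidate pools of species offered to the optimiser.

A site's *candidate pool* in one bootstrap replicate is its declared
target list (always retained: species already being managed are never
dropped) plus at most ``threshold`` additional species drawn from the
eligible species occurring there.  Additions are drawn habitat-sharing
species first: a candidate shares habitat with the site when its
preferred ∪ suitable habitats intersect the union of habitats of the
site's declared targets — those habitats are assumed to be under active
management already, so co-occurring species that depend on them can be
added at least extra effort.  Only when habitat-sharing candidates do
not fill the quota is the draw widened to the remaining eligible
species.  Re-drawing the pools across bootstrap replicates is what turns
a single optimisation into a selection-frequency analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from n2kprior.datatypes import Dataset, Site, SpeciesRecord, ValidationError


@dataclass
class CandidatePool:
    """Species made available to the optimiser at one site in one replicate.

    ``available`` is ordered: declared targets first, then habitat-sharing
    additions, then other additions.  ``n_added`` counts the non-declared
    members and never exceeds the threshold used to build the pool.
    """

    site_id: str
    available: list[str]
    n_added: int

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.available


def managed_habitats(site: Site, species_by_id: dict[str, SpeciesRecord]) -> frozenset[str]:
    """Habitats assumed to be under management at a site.

    The union of preferred and suitable habitats over the site's declared
    targets; empty for sites with no declared targets.  All declared
    targets contribute, threatened or not — management effort follows the
    declared list, not the Red List.
    """
    out: set[str] = set()
    for sid in site.declared_targets:
        rec = species_by_id.get(sid)
        if rec is not None:
            out |= rec.habitats
    return frozenset(out)


def build_pool(
    site: Site,
    eligible: frozenset[str] | set[str],
    threshold: int,
    rng: np.random.Generator,
    species_by_id: dict[str, SpeciesRecord],
) -> CandidatePool:
    """Build one site's candidate pool.

    ``eligible`` must already be restricted to species occurring in the
    site (intersected with the scenario's species filter by the caller).
    If the number of non-declared eligible candidates is at or below
    ``threshold`` the pool is deterministic (all of them enter);
    otherwise a random subset of size ``threshold`` is drawn, exhausting
    habitat-sharing candidates before any other candidate is considered.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    declared = sorted(site.declared_targets)
    candidates = set(eligible) - site.declared_targets
    managed = managed_habitats(site, species_by_id)
    sharing = sorted(
        c for c in candidates if species_by_id[c].habitats & managed
    )
    other = sorted(candidates - set(sharing))

    if len(candidates) <= threshold:
        added = sharing + other
    else:
        n_share = min(threshold, len(sharing))
        picked_h = sorted(rng.choice(len(sharing), size=n_share, replace=False)) if n_share else []
        added = [sharing[k] for k in picked_h]
        n_fill = threshold - n_share
        if n_fill > 0:
            picked_o = sorted(rng.choice(len(other), size=n_fill, replace=False))
            added += [other[k] for k in picked_o]

    return CandidatePool(site_id=site.site_id, available=declared + added, n_added=len(added))


def build_all_pools(
    dataset: Dataset,
    scenario_species: frozenset[str] | set[str],
    threshold: int,
    rng: np.random.Generator,
) -> dict[str, CandidatePool]:
    """One candidate pool per site, in site-table order.

    ``rng`` is consumed site by site in a fixed order, so a fixed
    generator state yields identical pool maps; callers running several
    bootstrap replicates pass independently sub-seeded generators.
    """
    species_by_id = {sp.species_id: sp for sp in dataset.species}
    unknown = set(scenario_species) - set(species_by_id)
    if unknown:
        raise ValidationError(f"scenario species not in species table: {sorted(unknown)}")
    pools: dict[str, CandidatePool] = {}
    for site in dataset.sites:
        present = dataset.occurrence.species_in_site(site.site_id)
        eligible = present & set(scenario_species)
        pools[site.site_id] = build_pool(site, eligible, threshold, rng, species_by_id)
    return pools


def pools_to_rows(pools: dict[str, CandidatePool], dataset: Dataset, bootstrap_id: int) -> list[dict]:
    """Long-form export rows (bootstrap_id, site_id, species_id, origin)."""
    species_by_id = {sp.species_id: sp for sp in dataset.species}
    rows = []
    for site_id in sorted(pools):
        pool = pools[site_id]
        site = dataset.site(site_id)
        managed = managed_habitats(site, species_by_id)
        for sid in pool.available:
            if sid in site.declared_targets:
                origin = "declared"
            elif species_by_id[sid].habitats & managed:
                origin = "habitat"
            else:
                origin = "other"
            rows.append(
                {"bootstrap_id": bootstrap_id, "site_id": site_id,
                 "species_id": sid, "origin": origin}
            )
    return rows
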