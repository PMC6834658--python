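"""Core containers shared across the pipeline.

Species records, sites with declared target-species lists, the binary
site × species occurrence matrix, and the bundle of all four (a
:class:`Dataset`).  Identifiers are opaque strings everywhere at this
level; dense integer indices live inside :class:`OccurrenceMatrix` and
the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The five vertebrate groups the analysis covers.
TAXA = ("amphibian", "bird", "fish", "mammal", "reptile")

#: IUCN Red List categories handled by the pipeline.
IUCN_STATUSES = ("CR", "EN", "VU", "NT", "LC", "NE", "DD")

#: Categories counted as "threatened" (those that roughly correspond to
#: an unfavourable conservation status and hence to management need).
THREATENED_STATUSES = frozenset({"CR", "EN", "VU", "NT"})


class ValidationError(ValueError):
    """An input violated a structural contract (bad status, duplicate id, ...)."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: taxonomy, Red List status, annex listing and habitat links.

    Parameters
    ----------
    species_id
        Unique identifier.
    taxon
        One of :data:`TAXA`.
    iucn_status
        One of :data:`IUCN_STATUSES`.
    annex_listed
        Whether the species is listed in the annexes of the Birds/Habitats
        Directives (or the analogous legal instrument of the network).
    habitats_preferred, habitats_suitable
        Habitat identifiers linked to the species, split by preference
        class; the two sets are disjoint.
    """

    species_id: str
    taxon: str
    iucn_status: str
    annex_listed: bool
    habitats_preferred: frozenset[str] = frozenset()
    habitats_suitable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.iucn_status not in IUCN_STATUSES:
            raise ValidationError(
                f"species {self.species_id!r}: unknown IUCN status {self.iucn_status!r}"
            )
        if self.taxon not in TAXA:
            raise ValidationError(
                f"species {self.species_id!r}: unknown taxon {self.taxon!r}"
            )
        overlap = self.habitats_preferred & self.habitats_suitable
        if overlap:
            raise ValidationError(
                f"species {self.species_id!r}: habitats both preferred and "
                f"suitable: {sorted(overlap)}"
            )

    @property
    def threatened(self) -> bool:
        return self.iucn_status in THREATENED_STATUSES

    @property
    def habitats(self) -> frozenset[str]:
        """All linked habitats, preferred and suitable together."""
        return self.habitats_preferred | self.habitats_suitable


@dataclass(frozen=True)
class Site:
    """One planning unit: a protected-area site with its declared target list.

    ``declared_targets`` may be empty — sites designated for habitats only
    carry no target species.
    """

    site_id: str
    declared_targets: frozenset[str] = frozenset()
    latitude: float | None = None


@dataclass
class OccurrenceMatrix:
    """Binary site × species incidence with stable orderings.

    ``matrix[i, j]`` is True iff species ``species_ids[j]`` occurs in site
    ``site_ids[i]``.
    """

    site_ids: list[str]
    species_ids: list[str]
    matrix: np.ndarray

    _site_index: dict[str, int] = field(init=False, repr=False)
    _species_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValidationError(
                f"occurrence matrix shape {self.matrix.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        self._site_index = {s: i for i, s in enumerate(self.site_ids)}
        self._species_index = {s: j for j, s in enumerate(self.species_ids)}
        if len(self._site_index) != len(self.site_ids):
            raise ValidationError("duplicate site_id in occurrence matrix")
        if len(self._species_index) != len(self.species_ids):
            raise ValidationError("duplicate species_id in occurrence matrix")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def site_index(self, site_id: str) -> int:
        return self._site_index[site_id]

    def species_index(self, species_id: str) -> int:
        return self._species_index[species_id]

    def occurs(self, site_id: str, species_id: str) -> bool:
        return bool(self.matrix[self._site_index[site_id], self._species_index[species_id]])

    def species_in_site(self, site_id: str) -> frozenset[str]:
        row = self.matrix[self._site_index[site_id]]
        return frozenset(self.species_ids[j] for j in np.flatnonzero(row))

    def range_sizes(self) -> np.ndarray:
        """Occupied-site count per species (column sums)."""
        return self.matrix.sum(axis=0)

    def site_richness(self) -> np.ndarray:
        """Species count per site (row sums)."""
        return self.matrix.sum(axis=1)


@dataclass
class Dataset:
    """Species table, site table and occurrence matrix, kept consistent.

    Invariants enforced by :meth:`validate` (strict mode):

    * every declared target of every site occurs in that site;
    * every species occupies at least one site;
    * every species has at least one habitat link.
    """

    species: list[SpeciesRecord]
    sites: list[Site]
    occurrence: OccurrenceMatrix

    def __post_init__(self) -> None:
        self._species_by_id = {sp.species_id: sp for sp in self.species}
        if len(self._species_by_id) != len(self.species):
            raise ValidationError("duplicate species_id in species table")
        self._sites_by_id = {s.site_id: s for s in self.sites}
        if len(self._sites_by_id) != len(self.sites):
            raise ValidationError("duplicate site_id in site table")

    def species_record(self, species_id: str) -> SpeciesRecord:
        return self._species_by_id[species_id]

    def site(self, site_id: str) -> Site:
        return self._sites_by_id[site_id]

    @property
    def species_ids(self) -> list[str]:
        return [sp.species_id for sp in self.species]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def validate(self, lenient: bool = False) -> list[str]:
        """Check cross-table invariants.

        Returns the list of problems found.  In strict mode (default) any
        problem raises :class:`ValidationError`; with ``lenient=True``
        declared-target inconsistencies are reported but tolerated, which
        accommodates real-world inputs where a site may declare a species
        the occurrence layer does not record.
        """
        problems: list[str] = []
        hard: list[str] = []
        occ_species = set(self.occurrence.species_ids)
        occ_sites = set(self.occurrence.site_ids)
        if occ_species != set(self._species_by_id):
            hard.append("occurrence matrix species do not match species table")
        if occ_sites != set(self._sites_by_id):
            hard.append("occurrence matrix sites do not match site table")
        if not hard:
            sizes = self.occurrence.range_sizes()
            for j, n in enumerate(sizes):
                if n == 0:
                    problems.append(
                        f"species {self.occurrence.species_ids[j]!r} occupies no site"
                    )
            for sp in self.species:
                if not sp.habitats:
                    problems.append(f"species {sp.species_id!r} has no habitat link")
            for site in self.sites:
                unknown = site.declared_targets - occ_species
                if unknown:
                    hard.append(
                        f"site {site.site_id!r} declares unknown species {sorted(unknown)}"
                    )
                    continue
                present = self.occurrence.species_in_site(site.site_id)
                missing = site.declared_targets - present
                if missing:
                    problems.append(
                        f"site {site.site_id!r} declares non-occurring targets "
                        f"{sorted(missing)}"
                    )
        if hard:
            raise ValidationError("; ".join(hard))
        if problems and not lenient:
            raise ValidationError("; ".join(problems))
        return problems
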