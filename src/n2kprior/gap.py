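"""Gap analysis: taxon × IUCN-status × annex-listing cross-tabulation.

A *gap analysis* asks how well the legal instruments behind a
protected-area network (here, the annexes of the EU Birds and Habitats
Directives) cover the species that actually need conservation action
(here, species in the IUCN Red List threat categories CR, EN, VU and
NT), and which threatened species are a declared management target of no
site at all.

The module also ships, as plain data, the published 2019 cross-tabulation
of the 1282 European terrestrial and freshwater vertebrate species by
taxonomic group, Red List category and directive-annex listing, which
serves as a reference fixture for the arithmetic
(:func:`eu_vertebrate_reference_counts`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from n2kprior.datatypes import (
    IUCN_STATUSES,
    Site,
    SpeciesRecord,
    THREATENED_STATUSES,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Published reference cross-tabulation (European terrestrial & freshwater
# vertebrates, IUCN Red List 2019 vs Birds Directive annexes I-II and
# Habitats Directive annexes II & IV).  Each cell is (total, annex-listed).
# ---------------------------------------------------------------------------

_REFERENCE_CELLS: dict[str, dict[str, tuple[int, int]]] = {
    "amphibian": {"CR": (2, 0), "EN": (5, 1), "VU": (11, 4), "NT": (15, 6),
                  "LC": (49, 26), "NE": (2, 0), "DD": (1, 0)},
    "bird":      {"CR": (2, 1), "EN": (8, 7), "VU": (15, 11), "NT": (24, 21),
                  "LC": (428, 173), "NE": (0, 0), "DD": (0, 0)},
    "fish":      {"CR": (45, 7), "EN": (38, 6), "VU": (57, 6), "NT": (16, 2),
                  "LC": (172, 27), "NE": (45, 0), "DD": (23, 1)},
    "mammal":    {"CR": (2, 2), "EN": (5, 2), "VU": (14, 8), "NT": (19, 14),
                  "LC": (125, 31), "NE": (10, 5), "DD": (11, 3)},
    "reptile":   {"CR": (6, 2), "EN": (12, 5), "VU": (8, 3), "NT": (18, 5),
                  "LC": (79, 24), "NE": (12, 1), "DD": (3, 0)},
}

#: The totals row as printed in the published checklist summary.  Its LC
#: listed count (277) is not the sum of the per-taxon LC cells (281); the
#: row is kept verbatim for network-level checks while per-taxon cells are
#: used for taxon-level checks, without attempting to reconcile the two.
REFERENCE_TOTALS_ROW: dict[str, tuple[int, int]] = {
    "CR": (57, 12), "EN": (68, 21), "VU": (105, 32), "NT": (92, 48),
    "LC": (853, 277), "NE": (69, 6), "DD": (38, 4),
}


def eu_vertebrate_reference_counts() -> pd.DataFrame:
    """The published per-taxon reference counts as a tidy DataFrame.

    Columns: ``taxon``, ``status``, ``total``, ``listed`` — one row per
    (taxon, Red List category) cell, 35 rows in total.
    """
    rows = [
        {"taxon": taxon, "status": status, "total": tot, "listed": lst}
        for taxon, by_status in _REFERENCE_CELLS.items()
        for status, (tot, lst) in by_status.items()
    ]
    return pd.DataFrame(rows)


def reference_directive_total() -> int:
    """Number of annex-listed species per the printed totals row (400)."""
    return sum(lst for _tot, lst in REFERENCE_TOTALS_ROW.values())


def expand_reference_to_species(counts: pd.DataFrame | None = None) -> list[SpeciesRecord]:
    """Expand a (taxon, status, total, listed) count table to pseudo-species.

    Each cell becomes ``total`` records, of which the first ``listed`` are
    annex-listed.  Every record gets one synthetic habitat link so the
    resulting table is valid.  Used to feed aggregate counts through the
    same code path as a real species table.
    """
    if counts is None:
        counts = eu_vertebrate_reference_counts()
    records: list[SpeciesRecord] = []
    for row in counts.itertuples(index=False):
        for k in range(int(row.total)):
            records.append(
                SpeciesRecord(
                    species_id=f"{row.taxon}_{row.status}_{k:04d}",
                    taxon=row.taxon,
                    iucn_status=row.status,
                    annex_listed=k < int(row.listed),
                    habitats_preferred=frozenset({"h0"}),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Gap summary
# ---------------------------------------------------------------------------


def is_threatened(status: str) -> bool:
    """Whether a Red List category counts as threatened (CR/EN/VU/NT).

    NT is included because these four categories are the ones that
    roughly correspond to an unfavourable conservation status, i.e. to
    species for which management action would be required; LC, NE and DD
    never count.
    """
    if status not in IUCN_STATUSES:
        raise ValidationError(f"unknown IUCN status {status!r}")
    return status in THREATENED_STATUSES


@dataclass
class GapSummary:
    """Cross-tabulated species counts plus the derived coverage totals.

    ``counts`` maps ``(taxon, status)`` to ``(total, listed)``;
    ``undeclared_threatened_ids`` is only populated when a site table was
    supplied (threatened species that are a declared target of no site).
    """

    counts: dict[tuple[str, str], tuple[int, int]]
    threatened_total: int
    threatened_listed: int
    unlisted_threatened_ids: frozenset[str]
    undeclared_threatened_ids: frozenset[str] = frozenset()

    taxa: tuple[str, ...] = field(default=())

    @property
    def grand_total(self) -> int:
        return sum(tot for tot, _ in self.counts.values())

    @property
    def listed_total(self) -> int:
        return sum(lst for _, lst in self.counts.values())

    def taxon_threatened(self, taxon: str) -> tuple[int, int]:
        """(total, listed) threatened counts for one taxon."""
        tot = sum(self.counts.get((taxon, s), (0, 0))[0] for s in THREATENED_STATUSES)
        lst = sum(self.counts.get((taxon, s), (0, 0))[1] for s in THREATENED_STATUSES)
        return tot, lst

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon": taxon, "status": status, "total": tot, "listed": lst}
            for (taxon, status), (tot, lst) in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["taxon", "status", "total", "listed"])


def summarize(species_table: list[SpeciesRecord]) -> GapSummary:
    """Cross-tabulate a species table by taxon and Red List category.

    Raises :class:`ValidationError` on duplicate species identifiers.
    """
    seen: set[str] = set()
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    threatened_total = 0
    threatened_listed = 0
    unlisted_threatened: set[str] = set()
    taxa: list[str] = []
    for rec in species_table:
        if rec.species_id in seen:
            raise ValidationError(f"duplicate species_id {rec.species_id!r}")
        seen.add(rec.species_id)
        if rec.taxon not in taxa:
            taxa.append(rec.taxon)
        tot, lst = counts.get((rec.taxon, rec.iucn_status), (0, 0))
        counts[(rec.taxon, rec.iucn_status)] = (tot + 1, lst + int(rec.annex_listed))
        if rec.threatened:
            threatened_total += 1
            if rec.annex_listed:
                threatened_listed += 1
            else:
                unlisted_threatened.add(rec.species_id)
    return GapSummary(
        counts=counts,
        threatened_total=threatened_total,
        threatened_listed=threatened_listed,
        unlisted_threatened_ids=frozenset(unlisted_threatened),
        taxa=tuple(taxa),
    )


def _percent(numerator: int, denominator: int, rounding: str) -> int:
    if denominator == 0:
        raise ValidationError("undefined ratio: zero denominator")
    value = 100.0 * numerator / denominator
    if rounding == "round":
        # round half up, not banker's rounding
        return int(math.floor(value + 0.5))
    if rounding == "truncate":
        return int(math.floor(value))
    raise ValidationError(f"unknown rounding mode {rounding!r}")


def coverage_percent(summary: GapSummary, taxon: str, rounding: str = "round") -> int:
    """Integer percentage of a taxon's threatened species that are annex-listed.

    ``rounding`` selects between round-half-up (default) and truncation;
    published coverage figures mix the two conventions, so both are exposed.
    """
    tot, lst = summary.taxon_threatened(taxon)
    if tot == 0:
        raise ValidationError(f"taxon {taxon!r} has no threatened species")
    return _percent(lst, tot, rounding)


def threatened_share_of_listed(
    summary: GapSummary, listed_total: int | None = None, rounding: str = "round"
) -> int:
    """Integer percentage of annex-listed species that are threatened.

    ``listed_total`` overrides the denominator, e.g. to use a published
    network-level total instead of the cell sum.
    """
    denom = summary.listed_total if listed_total is None else listed_total
    return _percent(summary.threatened_listed, denom, rounding)


def undeclared_threatened(
    species_table: list[SpeciesRecord], site_table: list[Site]
) -> frozenset[str]:
    """Threatened species that appear on no site's declared target list."""
    declared: set[str] = set()
    for site in site_table:
        declared |= site.declared_targets
    return frozenset(
        rec.species_id
        for rec in species_table
        if rec.threatened and rec.species_id not in declared
    )


def gap_report(summary: GapSummary, rounding: str = "round") -> str:
    """Human-readable text block summarising the gap analysis."""
    lines = [
        f"species total:            {summary.grand_total}",
        f"annex-listed total:       {summary.listed_total}",
        f"threatened (CR/EN/VU/NT): {summary.threatened_total}",
        f"threatened and listed:    {summary.threatened_listed}",
    ]
    for taxon in summary.taxa:
        tot, lst = summary.taxon_threatened(taxon)
        if tot:
            pct = _percent(lst, tot, rounding)
            lines.append(f"  {taxon}: {lst}/{tot} threatened listed ({pct}%)")
        else:
            lines.append(f"  {taxon}: 0 threatened")
    if summary.undeclared_threatened_ids:
        lines.append(
            f"threatened species declared in no site: "
            f"{len(summary.undeclared_threatened_ids)}"
        )
    return "\n".join(lines)
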