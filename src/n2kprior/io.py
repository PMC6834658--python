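"""Readers and writers for all on-disk formats.

Four CSV tables carry a dataset (``species.csv``, ``sites.csv``,
``occurrence.csv`` in long form, ``habitat_links.csv``); solver
instances round-trip through the classic Marxan input dialect
(``pu.dat``, ``spec.dat``, ``puvspr.dat``, tab- or comma-separated,
auto-detected); experiment outputs land as long-form CSVs plus one JSON
run manifest per output directory.  All writers order rows by identifier
so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from n2kprior.aggregation import SelectionFrequencyTable
from n2kprior.datatypes import (
    Dataset,
    OccurrenceMatrix,
    Site,
    SpeciesRecord,
    ValidationError,
)
from n2kprior.scenarios import ScenarioResult

_DECL_SEP = ";"


class ParseError(ValidationError):
    """A file failed to parse; the message carries file and line number."""


# ---------------------------------------------------------------------------
# Dataset CSV tables
# ---------------------------------------------------------------------------


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    """Write species.csv, sites.csv, occurrence.csv and habitat_links.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    species_rows = [
        {
            "species_id": sp.species_id,
            "taxon": sp.taxon,
            "iucn_status": sp.iucn_status,
            "annex_listed": int(sp.annex_listed),
        }
        for sp in sorted(dataset.species, key=lambda s: s.species_id)
    ]
    pd.DataFrame(species_rows).to_csv(outdir / "species.csv", index=False)

    site_rows = [
        {
            "site_id": s.site_id,
            "latitude": "" if s.latitude is None else repr(float(s.latitude)),
            "declared_targets": _DECL_SEP.join(sorted(s.declared_targets)),
        }
        for s in sorted(dataset.sites, key=lambda s: s.site_id)
    ]
    pd.DataFrame(site_rows).to_csv(outdir / "sites.csv", index=False)

    occ = dataset.occurrence
    rows_i, cols_j = np.nonzero(occ.matrix)
    occ_rows = sorted(
        (occ.site_ids[i], occ.species_ids[j]) for i, j in zip(rows_i, cols_j)
    )
    pd.DataFrame(occ_rows, columns=["site_id", "species_id"]).to_csv(
        outdir / "occurrence.csv", index=False
    )

    link_rows = []
    for sp in sorted(dataset.species, key=lambda s: s.species_id):
        for h in sorted(sp.habitats_preferred):
            link_rows.append(
                {"species_id": sp.species_id, "habitat_id": h, "preference": "preferred"}
            )
        for h in sorted(sp.habitats_suitable):
            link_rows.append(
                {"species_id": sp.species_id, "habitat_id": h, "preference": "suitable"}
            )
    pd.DataFrame(
        link_rows, columns=["species_id", "habitat_id", "preference"]
    ).to_csv(outdir / "habitat_links.csv", index=False)


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def read_dataset(indir: str | Path, lenient: bool = False) -> Dataset:
    """Read the four dataset tables and validate cross-table invariants.

    With ``lenient=True`` declared-target inconsistencies (a site
    declaring a species the occurrence table does not place there) are
    downgraded to warnings, which real-world inputs may need.
    """
    indir = Path(indir)
    for name in ("species.csv", "sites.csv", "occurrence.csv", "habitat_links.csv"):
        if not (indir / name).exists():
            raise ParseError(f"{indir / name}: file not found")

    species_df = pd.read_csv(indir / "species.csv", dtype=str)
    _require_columns(
        species_df, ["species_id", "taxon", "iucn_status", "annex_listed"],
        indir / "species.csv",
    )
    links_df = pd.read_csv(indir / "habitat_links.csv", dtype=str)
    _require_columns(
        links_df, ["species_id", "habitat_id", "preference"], indir / "habitat_links.csv"
    )
    preferred: dict[str, set[str]] = {}
    suitable: dict[str, set[str]] = {}
    for ln, row in enumerate(links_df.itertuples(index=False), start=2):
        if row.preference not in ("preferred", "suitable"):
            raise ParseError(
                f"{indir / 'habitat_links.csv'}:{ln}: unknown preference "
                f"{row.preference!r}"
            )
        bucket = preferred if row.preference == "preferred" else suitable
        bucket.setdefault(row.species_id, set()).add(row.habitat_id)

    species = [
        SpeciesRecord(
            species_id=row.species_id,
            taxon=row.taxon,
            iucn_status=row.iucn_status,
            annex_listed=row.annex_listed in ("1", "True", "true"),
            habitats_preferred=frozenset(preferred.get(row.species_id, set())),
            habitats_suitable=frozenset(suitable.get(row.species_id, set())),
        )
        for row in species_df.itertuples(index=False)
    ]

    sites_df = pd.read_csv(
        indir / "sites.csv", dtype=str, keep_default_na=False
    )
    _require_columns(sites_df, ["site_id", "declared_targets"], indir / "sites.csv")
    sites = []
    for row in sites_df.itertuples(index=False):
        declared = frozenset(
            s for s in str(row.declared_targets).split(_DECL_SEP) if s
        )
        lat = getattr(row, "latitude", "")
        sites.append(
            Site(
                site_id=row.site_id,
                declared_targets=declared,
                latitude=float(lat) if lat not in ("", "nan") else None,
            )
        )

    occ_df = pd.read_csv(indir / "occurrence.csv", dtype=str)
    _require_columns(occ_df, ["site_id", "species_id"], indir / "occurrence.csv")
    site_ids = [s.site_id for s in sites]
    species_ids = [sp.species_id for sp in species]
    site_index = {s: i for i, s in enumerate(site_ids)}
    species_index = {s: j for j, s in enumerate(species_ids)}
    matrix = np.zeros((len(site_ids), len(species_ids)), dtype=bool)
    for ln, row in enumerate(occ_df.itertuples(index=False), start=2):
        i = site_index.get(row.site_id)
        j = species_index.get(row.species_id)
        if i is None:
            raise ParseError(
                f"{indir / 'occurrence.csv'}:{ln}: unknown site {row.site_id!r}"
            )
        if j is None:
            raise ParseError(
                f"{indir / 'occurrence.csv'}:{ln}: unknown species {row.species_id!r}"
            )
        matrix[i, j] = True

    dataset = Dataset(
        species=species,
        sites=sites,
        occurrence=OccurrenceMatrix(
            site_ids=site_ids, species_ids=species_ids, matrix=matrix
        ),
    )
    problems = dataset.validate(lenient=lenient)
    for p in problems:
        import warnings

        warnings.warn(p, stacklevel=2)
    return dataset


# ---------------------------------------------------------------------------
# Marxan input dialect
# ---------------------------------------------------------------------------


def _read_dat(path: Path, required: list[str]) -> list[dict[str, str]]:
    """Read a Marxan .dat table, auto-detecting tab vs comma separation."""
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    text = path.read_text().splitlines()
    if not text:
        raise ParseError(f"{path}: empty file")
    sep = "\t" if "\t" in text[0] else ","
    header = [c.strip() for c in text[0].split(sep)]
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path}:1: missing column(s) {missing}")
    rows = []
    for ln, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        fields = [c.strip() for c in line.split(sep)]
        if len(fields) != len(header):
            raise ParseError(f"{path}:{ln}: expected {len(header)} fields")
        rows.append({"_line": str(ln), **dict(zip(header, fields))})
    return rows


def _to_number(value: str, path: Path, line: str, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{line}: non-numeric {column} value {value!r}") from None


def read_marxan_inputs(indir: str | Path) -> "Problem":
    """Build a solver instance from pu.dat, spec.dat and puvspr.dat.

    External integer identifiers are remapped to dense indices in file
    order; any positive puvspr amount becomes a binary availability of 1.
    """
    from n2kprior.solver import Problem

    indir = Path(indir)
    pu_rows = _read_dat(indir / "pu.dat", ["id", "cost"])
    spec_rows = _read_dat(indir / "spec.dat", ["id", "target", "spf"])
    link_rows = _read_dat(indir / "puvspr.dat", ["species", "pu", "amount"])

    pu_ids: list[str] = []
    cost = []
    for row in pu_rows:
        if row["id"] in pu_ids:
            raise ParseError(f"{indir / 'pu.dat'}:{row['_line']}: duplicate id {row['id']}")
        pu_ids.append(row["id"])
        cost.append(_to_number(row["cost"], indir / "pu.dat", row["_line"], "cost"))

    sp_ids: list[str] = []
    names: list[str] = []
    target = []
    spf = []
    for row in spec_rows:
        if row["id"] in sp_ids:
            raise ParseError(
                f"{indir / 'spec.dat'}:{row['_line']}: duplicate id {row['id']}"
            )
        sp_ids.append(row["id"])
        names.append(row.get("name", row["id"]))
        target.append(
            int(_to_number(row["target"], indir / "spec.dat", row["_line"], "target"))
        )
        spf.append(_to_number(row["spf"], indir / "spec.dat", row["_line"], "spf"))

    pu_index = {p: i for i, p in enumerate(pu_ids)}
    sp_index = {s: j for j, s in enumerate(sp_ids)}
    benefit = np.zeros((len(pu_ids), len(sp_ids)), dtype=bool)
    for row in link_rows:
        i = pu_index.get(row["pu"])
        j = sp_index.get(row["species"])
        if i is None:
            raise ParseError(
                f"{indir / 'puvspr.dat'}:{row['_line']}: unknown pu id {row['pu']!r}"
            )
        if j is None:
            raise ParseError(
                f"{indir / 'puvspr.dat'}:{row['_line']}: unknown species id "
                f"{row['species']!r}"
            )
        amount = _to_number(
            row["amount"], indir / "puvspr.dat", row["_line"], "amount"
        )
        if amount > 0:
            benefit[i, j] = True

    return Problem(
        site_ids=pu_ids,
        species_ids=names,
        cost=np.array(cost),
        benefit=benefit,
        target=np.array(target),
        spf=np.array(spf),
    )


def write_marxan_inputs(problem: "Problem", outdir: str | Path, sep: str = "\t") -> None:
    """Write pu.dat, spec.dat and puvspr.dat for a solver instance.

    Identifiers become 1-based dense integers in table order; the species
    name column preserves the external species identifier.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nl = "\n"

    with open(outdir / "pu.dat", "w", newline="") as fh:
        fh.write(sep.join(["id", "cost", "status"]) + nl)
        for i, _sid in enumerate(problem.site_ids, start=1):
            fh.write(sep.join([str(i), _fmt(problem.cost[i - 1]), "0"]) + nl)

    with open(outdir / "spec.dat", "w", newline="") as fh:
        fh.write(sep.join(["id", "target", "spf", "name"]) + nl)
        for j, name in enumerate(problem.species_ids, start=1):
            fh.write(
                sep.join(
                    [str(j), str(int(problem.target[j - 1])),
                     _fmt(problem.spf[j - 1]), name]
                )
                + nl
            )

    rows_i, cols_j = np.nonzero(problem.benefit)
    links = sorted((j + 1, i + 1) for i, j in zip(rows_i, cols_j))
    with open(outdir / "puvspr.dat", "w", newline="") as fh:
        fh.write(sep.join(["species", "pu", "amount"]) + nl)
        for j, i in links:
            fh.write(sep.join([str(j), str(i), "1"]) + nl)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


# ---------------------------------------------------------------------------
# Experiment outputs
# ---------------------------------------------------------------------------


def write_scenario_result(result: ScenarioResult, outdir: str | Path) -> None:
    """Write per-bootstrap solution membership, additions and summaries."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sol_rows = []
    for b, sol in enumerate(result.best_solutions):
        for i in np.flatnonzero(sol.x):
            sol_rows.append({"bootstrap_id": b, "site_id": result.site_ids[i]})
    pd.DataFrame(sol_rows, columns=["bootstrap_id", "site_id"]).to_csv(
        outdir / "solutions.csv", index=False
    )

    add_rows = [
        {"bootstrap_id": b, "site_id": site_id, "species_id": sp}
        for b, additions in enumerate(result.additions)
        for site_id in sorted(additions)
        for sp in sorted(additions[site_id])
    ]
    pd.DataFrame(
        add_rows, columns=["bootstrap_id", "site_id", "species_id"]
    ).to_csv(outdir / "additions.csv", index=False)

    asg_rows = [
        {"bootstrap_id": b, "site_id": site_id, "species_id": sp}
        for b, assignment in enumerate(result.assignments)
        for site_id in sorted(assignment)
        for sp in sorted(assignment[site_id])
    ]
    pd.DataFrame(
        asg_rows, columns=["bootstrap_id", "site_id", "species_id"]
    ).to_csv(outdir / "assignments.csv", index=False)

    summary_rows = [
        {
            "bootstrap_id": b,
            "n_selected": result.selected_site_counts[b],
            "n_updated": result.updated_site_counts[b],
            "objective_total": round(sol.objective.total, 9),
            "cost_term": round(sol.objective.cost_term, 9),
            "penalty_term": round(sol.objective.penalty_term, 9),
        }
        for b, sol in enumerate(result.best_solutions)
    ]
    pd.DataFrame(summary_rows).to_csv(outdir / "bootstrap_summary.csv", index=False)


def write_frequency_tables(
    freq: SelectionFrequencyTable,
    outdir: str | Path,
    occurrence: OccurrenceMatrix | None = None,
    richness_listed: dict[str, int] | None = None,
    richness_threatened: dict[str, int] | None = None,
) -> None:
    """Write site_frequencies.csv and species_site_frequencies.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    site_df = freq.site_frame()
    if richness_listed is not None:
        site_df["richness_listed"] = site_df["site_id"].map(richness_listed)
    if richness_threatened is not None:
        site_df["richness_threatened"] = site_df["site_id"].map(richness_threatened)
    site_df.to_csv(outdir / "site_frequencies.csv", index=False)
    freq.species_site_frame().to_csv(
        outdir / "species_site_frequencies.csv", index=False
    )


def write_manifest(
    outdir: str | Path,
    stage: str,
    config: dict,
    seeds: dict | None = None,
    counts: dict | None = None,
) -> None:
    """Write the run manifest (exactly one per output directory)."""
    from n2kprior import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "n2kprior",
        "version": __version__,
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "config": config,
        "seeds": seeds or {},
        "counts": counts or {},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
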