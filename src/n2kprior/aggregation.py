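"""Selection frequencies and robustness diagnostics over bootstraps.

The frequency with which a site enters the best solution across
bootstrap replicates is a Monte-Carlo proxy for its irreplaceability:
sites that appear regardless of which random species subset was offered
are hard to substitute.  The per-(species, site) frequency likewise
ranks the sites most adequate for managing each species.  Two
diagnostics accompany the tables: a rank correlation between site
richness and selection frequency (the analysis expects selection to be
driven by species identity, not by raw richness) and a Gini coefficient
measuring how concentrated the frequency mass is on few sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from n2kprior.datatypes import OccurrenceMatrix, ValidationError
from n2kprior.scenarios import ScenarioResult


@dataclass
class SelectionFrequencyTable:
    """Counts of appearances in best solutions, per site and per (species, site)."""

    site_freq: dict[str, int]
    species_site_freq: dict[tuple[str, str], int]
    n_bootstraps: int

    def site_frame(self) -> pd.DataFrame:
        rows = [
            {"site_id": s, "count": c, "proportion": c / self.n_bootstraps}
            for s, c in sorted(self.site_freq.items())
        ]
        return pd.DataFrame(rows, columns=["site_id", "count", "proportion"])

    def species_site_frame(self) -> pd.DataFrame:
        rows = [
            {"species_id": sp, "site_id": si, "count": c,
             "proportion": c / self.n_bootstraps}
            for (sp, si), c in sorted(self.species_site_freq.items())
        ]
        return pd.DataFrame(
            rows, columns=["species_id", "site_id", "count", "proportion"]
        )


def selection_frequencies(result: ScenarioResult) -> SelectionFrequencyTable:
    """Tally best-solution membership across bootstraps.

    Every site of the problem appears in ``site_freq`` (with 0 when never
    selected); ``species_site_freq`` counts the bootstraps in which a
    species was assigned to a given selected site (declared eligible
    species and kept additions alike), so it is bounded above by the
    site's own frequency.
    """
    if result.n_bootstraps == 0:
        raise ValidationError("empty scenario result")
    site_freq = {s: 0 for s in result.site_ids}
    for sol in result.best_solutions:
        for i in np.flatnonzero(sol.x):
            site_freq[result.site_ids[i]] += 1
    species_site: dict[tuple[str, str], int] = {}
    for assignment in result.assignments:
        for site_id, members in assignment.items():
            for sp in members:
                key = (sp, site_id)
                species_site[key] = species_site.get(key, 0) + 1
    return SelectionFrequencyTable(
        site_freq=site_freq,
        species_site_freq=species_site,
        n_bootstraps=result.n_bootstraps,
    )


def richness_frequency_association(
    freq_table: SelectionFrequencyTable,
    occurrence: OccurrenceMatrix,
    species_subset: set[str] | frozenset[str] | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation between site richness and selection frequency.

    Richness is restricted to ``species_subset`` when given (e.g. the
    threatened species, or the threatened annex-listed species).  Returns
    ``(rho, p_value)``; both are NaN, with a warning, when either vector
    is constant and the correlation is undefined.  The statistic is
    reported, never thresholded.
    """
    if len(freq_table.site_freq) < 3:
        raise ValidationError("need at least 3 sites for a correlation")
    if species_subset is None:
        cols = np.ones(occurrence.n_species, dtype=bool)
    else:
        cols = np.array([s in species_subset for s in occurrence.species_ids])
    richness = occurrence.matrix[:, cols].sum(axis=1)
    freq = np.array([freq_table.site_freq[s] for s in occurrence.site_ids])
    if np.all(richness == richness[0]) or np.all(freq == freq[0]):
        warnings.warn(
            "richness or frequency vector is constant; correlation undefined",
            stacklevel=2,
        )
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(richness, freq)
    return float(rho), float(p)


def concentration_index(freq_table: SelectionFrequencyTable) -> float:
    """Gini coefficient of the site selection frequencies.

    0 when every site has the same frequency; approaches (k−1)/k → 1 as
    the mass concentrates on a single site among k.
    """
    freq = np.array(sorted(freq_table.site_freq.values()), dtype=float)
    total = freq.sum()
    if total <= 0:
        raise ValidationError("all selection frequencies are zero")
    k = freq.size
    # Gini from the sorted vector: 2·Σ i·f_i / (k·Σ f) − (k+1)/k
    i = np.arange(1, k + 1)
    return float(2.0 * (i * freq).sum() / (k * total) - (k + 1) / k)
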