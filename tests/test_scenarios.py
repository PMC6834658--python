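"""Scenario filters, bootstrap orchestration and species-to-site assignment."""

import numpy as np
import pytest

from n2kprior.datatypes import Dataset, OccurrenceMatrix, Site, ValidationError
from n2kprior.gap import expand_reference_to_species
from n2kprior.scenarios import (
    ScenarioConfig,
    assign_new_species,
    run_scenario,
    scenario_species,
)
from n2kprior.solver import Problem, objective, Solution


@pytest.fixture(scope="module")
def reference_dataset():
    """The published checklist as pseudo-species, all placed in one site."""
    species = expand_reference_to_species()
    ids = [sp.species_id for sp in species]
    return Dataset(
        species=species,
        sites=[Site("s0")],
        occurrence=OccurrenceMatrix(
            ["s0"], ids, np.ones((1, len(ids)), dtype=bool)
        ),
    )


class TestScenarioSpecies:
    def test_policy_set_is_threatened_and_listed(self, reference_dataset):
        assert len(scenario_species(reference_dataset, "policy")) == 113

    def test_conservation_set_is_all_threatened(self, reference_dataset):
        assert len(scenario_species(reference_dataset, "conservation")) == 322

    def test_conservation_unlisted_only_flag(self, reference_dataset):
        assert len(
            scenario_species(reference_dataset, "conservation", unlisted_only=True)
        ) == 322 - 113

    def test_no_threatened_species_gives_empty_sets(self, reference_dataset):
        safe = [sp for sp in reference_dataset.species if not sp.threatened]
        ds = Dataset(
            species=safe,
            sites=[Site("s0")],
            occurrence=OccurrenceMatrix(
                ["s0"], [sp.species_id for sp in safe],
                np.ones((1, len(safe)), dtype=bool),
            ),
        )
        assert scenario_species(ds, "policy") == frozenset()
        assert scenario_species(ds, "conservation") == frozenset()

    def test_unknown_scenario_rejected(self, reference_dataset):
        with pytest.raises(ValidationError):
            scenario_species(reference_dataset, "wishful")


class TestRunScenario:
    CONFIG = ScenarioConfig(
        scenario="conservation", threshold=10, n_bootstraps=3, n_runs=2,
        iterations=4000, master_seed=21,
    )

    def test_deterministic_for_fixed_master_seed(self, small_dataset):
        a = run_scenario(small_dataset, self.CONFIG)
        b = run_scenario(small_dataset, self.CONFIG)
        for sa, sb in zip(a.best_solutions, b.best_solutions):
            assert np.array_equal(sa.x, sb.x)
        assert a.additions == b.additions
        assert a.updated_site_counts == b.updated_site_counts

    def test_all_targets_met_with_exhaustive_threshold(self, small_dataset):
        config = self.CONFIG.replace(
            threshold=small_dataset.occurrence.n_species, n_bootstraps=1,
            iterations=20_000, n_runs=4,
        )
        result = run_scenario(small_dataset, config)
        sol = result.best_solutions[0]
        assert sol.objective.penalty_term == 0
        assert (sol.representation >= result.bootstrap_targets[0]).all()

    def test_counts_are_bounded_by_selection(self, small_dataset):
        result = run_scenario(small_dataset, self.CONFIG)
        m = len(small_dataset.sites)
        for updated, selected in zip(
            result.updated_site_counts, result.selected_site_counts
        ):
            assert updated <= selected <= m

    def test_config_validation(self, small_dataset):
        with pytest.raises(ValidationError):
            run_scenario(small_dataset, self.CONFIG.replace(n_bootstraps=0))
        with pytest.raises(ValidationError):
            run_scenario(small_dataset, self.CONFIG.replace(scenario="x"))

    def test_locked_declared_mode_reduces_or_keeps_workload(self, small_dataset):
        # crediting already-declared sites can only make targets easier
        plain = run_scenario(small_dataset, self.CONFIG)
        locked = run_scenario(
            small_dataset, self.CONFIG.replace(count_declared_as_locked=True)
        )
        assert np.mean(locked.selected_site_counts) <= np.mean(
            plain.selected_site_counts
        ) + 2.0


class TestAssignNewSpecies:
    def _toy(self):
        # sites s0..s2; species p0 needs 1 site, available in all three
        benefit = np.array([[1], [1], [1]], dtype=bool)
        problem = Problem(
            site_ids=["s0", "s1", "s2"], species_ids=["p0"],
            cost=np.ones(3), benefit=benefit,
            target=np.array([1]), spf=np.array([10.0]),
        )
        return problem

    def _solution(self, problem, x):
        x = np.asarray(x, dtype=bool)
        r = problem.locked_rep + x.astype(int) @ problem.benefit.astype(int)
        return Solution(x=x, objective=objective(x, problem), representation=r)

    def _pools_and_dataset(self, tiny=False):
        from n2kprior.pools import CandidatePool

        pools = {
            s: CandidatePool(site_id=s, available=["p0"], n_added=1)
            for s in ("s0", "s1", "s2")
        }
        species = expand_reference_to_species()[:1]
        import dataclasses

        sp = dataclasses.replace(species[0], species_id="p0")
        dataset = Dataset(
            species=[sp],
            sites=[Site("s0"), Site("s1"), Site("s2")],
            occurrence=OccurrenceMatrix(
                ["s0", "s1", "s2"], ["p0"], np.ones((3, 1), dtype=bool)
            ),
        )
        return pools, dataset

    def test_empty_selection_gives_empty_map(self):
        problem = self._toy()
        pools, dataset = self._pools_and_dataset()
        sol = self._solution(problem, [0, 0, 0])
        assert assign_new_species(sol, problem, pools, dataset) == {}

    def test_single_selected_site_gets_the_addition(self):
        problem = self._toy()
        pools, dataset = self._pools_and_dataset()
        sol = self._solution(problem, [1, 0, 0])
        assert assign_new_species(sol, problem, pools, dataset) == {
            "s0": frozenset({"p0"})
        }

    def test_redundant_site_additions_are_trimmed(self):
        # all three sites selected but the species needs only one:
        # exhaustive minimal assignment keeps exactly one addition
        problem = self._toy()
        pools, dataset = self._pools_and_dataset()
        sol = self._solution(problem, [1, 1, 1])
        additions = assign_new_species(sol, problem, pools, dataset)
        assert sum(len(v) for v in additions.values()) == 1

    def test_declared_contributions_never_trimmed(self):
        from n2kprior.pools import CandidatePool
        import dataclasses

        problem = self._toy()
        pools, dataset = self._pools_and_dataset()
        # declare p0 at s0: additions only possible at s1/s2 and all vacuous
        sites = [Site("s0", frozenset({"p0"})), Site("s1"), Site("s2")]
        dataset = Dataset(
            species=dataset.species, sites=sites,
            occurrence=dataset.occurrence,
        )
        sol = self._solution(problem, [1, 1, 1])
        additions = assign_new_species(sol, problem, pools, dataset)
        assert additions == {}
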