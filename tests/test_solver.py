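"""Objective arithmetic and the three solver back-ends against each other."""

import numpy as np
import pytest

from n2kprior.datatypes import ValidationError
from n2kprior.solver import (
    AnnealingParams,
    Problem,
    best_of_runs,
    flip_delta,
    objective,
    solve_exact,
    solve_greedy,
    solve_sa,
)


def _problem(benefit, target, spf, cost=None, locked=None):
    benefit = np.asarray(benefit)
    m, n = benefit.shape
    return Problem(
        site_ids=[f"s{i}" for i in range(m)],
        species_ids=[f"p{j}" for j in range(n)],
        cost=np.ones(m) if cost is None else np.asarray(cost, float),
        benefit=benefit,
        target=np.asarray(target, int),
        spf=np.asarray(spf, float),
        locked_rep=locked,
    )


def random_instance(seed, m=10, n=6, spf=50.0):
    """A random feasible instance (every species available somewhere)."""
    rng = np.random.default_rng(seed)
    benefit = rng.random((m, n)) < 0.4
    empty = ~benefit.any(axis=0)
    benefit[0, empty] = True
    avail = benefit.sum(axis=0)
    target = np.minimum(rng.integers(1, 4, size=n), avail)
    return _problem(benefit, target, np.full(n, spf))


class TestObjective:
    def test_empty_selection_pays_full_penalty(self):
        n = 7
        p = _problem(np.zeros((4, n), dtype=bool) | True, [10] * n, [10.0] * n)
        o = objective(np.zeros(4, dtype=bool), p)
        assert o.cost_term == 0
        assert o.penalty_term == pytest.approx(10 * n)
        assert o.total == pytest.approx(10 * n)
        assert (o.shortfalls == 10).all()

    def test_full_selection_meeting_targets_has_zero_penalty(self):
        p = _problem(np.ones((5, 3), dtype=bool), [2, 3, 5], [10.0] * 3)
        o = objective(np.ones(5, dtype=bool), p)
        assert o.penalty_term == 0
        assert o.total == pytest.approx(5)

    def test_hand_built_four_site_toy(self):
        # x = (1,1,0,0): r = (2,1), total = 2 + 10·(1/2) = 7
        benefit = np.array([[1, 1], [1, 0], [0, 1], [0, 1]])
        p = _problem(benefit, [2, 2], [10.0, 10.0])
        o = objective(np.array([1, 1, 0, 0], dtype=bool), p)
        assert o.total == pytest.approx(7.0)
        assert o.cost_term == pytest.approx(2.0)
        assert o.penalty_term == pytest.approx(5.0)

    def test_total_decomposes_exactly(self):
        rng = np.random.default_rng(4)
        p = random_instance(4)
        for _ in range(50):
            x = rng.random(p.n_sites) < 0.5
            o = objective(x, p)
            assert o.total == o.cost_term + o.penalty_term

    def test_dimension_mismatch_rejected(self):
        p = random_instance(0)
        with pytest.raises(ValidationError):
            objective(np.zeros(3, dtype=bool), p)

    def test_locked_representation_counts_without_selection(self):
        p = _problem(np.zeros((2, 1), dtype=bool), [1], [10.0],
                     locked=np.array([1]))
        o = objective(np.zeros(2, dtype=bool), p)
        assert o.penalty_term == 0


class TestIncrementalEvaluation:
    def test_flip_delta_matches_scratch_recomputation(self):
        rng = np.random.default_rng(99)
        for seed in range(5):
            p = random_instance(200 + seed, m=12, n=8)
            for _ in range(200):
                x = rng.random(p.n_sites) < 0.5
                r = p.locked_rep + x.astype(int) @ p.benefit.astype(int)
                i = int(rng.integers(p.n_sites))
                x2 = x.copy()
                x2[i] = not x2[i]
                expected = objective(x2, p).total - objective(x, p).total
                assert flip_delta(p, x, r, i) == pytest.approx(expected, abs=1e-9)


class TestSolveExact:
    def test_empty_problem(self):
        p = _problem(np.zeros((0, 0), dtype=bool), [], [])
        sol = solve_exact(p)
        assert sol.n_selected == 0

    def test_two_disjoint_species_need_both_sites(self):
        p = _problem(np.array([[1, 0], [0, 1]]), [1, 1], [10.0, 10.0])
        sol = solve_exact(p)
        assert sol.x.all()
        assert sol.objective.total == pytest.approx(2.0)

    def test_penalty_dominant_optimum_meets_all_targets(self):
        for seed in range(10):
            p = random_instance(seed, m=8, n=5, spf=100.0)
            sol = solve_exact(p)
            assert sol.objective.penalty_term == 0

    def test_size_limit(self):
        p = _problem(np.ones((21, 1), dtype=bool), [1], [10.0])
        with pytest.raises(ValidationError, match="20"):
            solve_exact(p)


class TestSolveGreedy:
    def test_nothing_to_gain_selects_nothing(self):
        p = _problem(np.zeros((3, 2), dtype=bool), [1, 1], [0.0, 0.0])
        assert solve_greedy(p).n_selected == 0

    def test_prefers_single_site_covering_both_species(self):
        # site 0 covers both; sites 1 and 2 cover one each
        p = _problem(np.array([[1, 1], [1, 0], [0, 1]]), [1, 1], [10.0, 10.0])
        sol = solve_greedy(p)
        assert sol.x.tolist() == [True, False, False]

    def test_never_beats_the_exhaustive_optimum(self):
        for seed in range(20):
            p = random_instance(seed, m=12, n=7)
            assert (
                solve_greedy(p).objective.total
                >= solve_exact(p).objective.total - 1e-9
            )


class TestSolveSA:
    def test_single_covering_site(self):
        p = _problem(np.array([[1, 1, 1]]), [1, 1, 1], [10.0] * 3)
        sol = solve_sa(p, AnnealingParams(iterations=500), np.random.default_rng(0))
        assert sol.x.tolist() == [True]
        assert sol.objective.total == pytest.approx(1.0)

    def test_deterministic_for_fixed_seed(self):
        p = random_instance(5, m=12, n=8)
        params = AnnealingParams(iterations=5000)
        a = solve_sa(p, params, np.random.default_rng(77))
        b = solve_sa(p, params, np.random.default_rng(77))
        assert np.array_equal(a.x, b.x)
        assert a.objective.total == b.objective.total

    def test_at_least_as_good_as_greedy_usually_and_never_below_optimum(self):
        wins = 0
        for seed in range(20):
            p = random_instance(300 + seed, m=12, n=8)
            sa = best_of_runs(p, 3, AnnealingParams(iterations=10_000), seed=seed)
            greedy = solve_greedy(p)
            exact = solve_exact(p)
            assert sa.objective.total >= exact.objective.total - 1e-9
            if sa.objective.total <= greedy.objective.total + 1e-9:
                wins += 1
        assert wins >= 10


class TestBestOfRuns:
    def test_single_run_equals_first_subseed_run(self):
        p = random_instance(8)
        params = AnnealingParams(iterations=2000)
        seq = np.random.SeedSequence(123)
        direct = solve_sa(
            p, params, np.random.Generator(np.random.PCG64(seq.spawn(1)[0]))
        )
        best = best_of_runs(p, 1, params, seed=np.random.SeedSequence(123))
        assert np.array_equal(direct.x, best.x)

    def test_returns_minimum_over_individual_runs(self):
        p = random_instance(9, m=14, n=8)
        params = AnnealingParams(iterations=2000)
        seq = np.random.SeedSequence(55)
        totals = [
            solve_sa(p, params, np.random.Generator(np.random.PCG64(c))).objective.total
            for c in seq.spawn(10)
        ]
        best = best_of_runs(p, 10, params, seed=np.random.SeedSequence(55))
        assert best.objective.total == pytest.approx(min(totals))

    def test_monotone_in_number_of_runs(self):
        p = random_instance(10, m=14, n=8)
        params = AnnealingParams(iterations=2000)
        prev = np.inf
        for n_runs in (1, 3, 6, 10):
            total = best_of_runs(
                p, n_runs, params, seed=np.random.SeedSequence(7)
            ).objective.total
            assert total <= prev + 1e-12
            prev = total

    def test_rejects_zero_runs(self):
        with pytest.raises(ValidationError):
            best_of_runs(random_instance(1), 0)
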