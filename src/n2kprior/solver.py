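"""Minimum-set site selection with a species-penalty objective.

The problem: choose a binary vector x over m sites minimising

    total(x) = Σ_i c_i x_i  +  Σ_j SPF_j · H(s_j) · s_j / t_j

where c_i is the site cost, t_j the representation target of species j
(the number of selected sites where j must be available), r_j = Σ_i
x_i a_ij its achieved representation given the binary availability
matrix a, s_j = max(0, t_j − r_j) the shortfall, H the Heaviside step
(1 when s_j > 0) and SPF_j a dimensionless species penalty factor.  The
normalised shortfall s_j/t_j runs from 1 (species absent from the
selection) to 0 (target met), so a species' maximum penalty is SPF_j.
Targets are satisfied at r_j ≥ t_j.

Three back-ends share this objective: simulated annealing with
single-site bit flips and a geometric cooling schedule (the workhorse),
a greedy best-improvement-per-unit-cost heuristic (fast baseline), and
exhaustive enumeration for ≤ 20 sites (the oracle used in tests).

Ties between equal-total states are broken toward lower penalty (i.e.
toward meeting targets) and then fewer selected sites: with unit costs
and SPF/t equal to the site cost, trading one site for one unit of
shortfall leaves the total unchanged, and the target-meeting state is
the one the analysis wants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from n2kprior.datatypes import ValidationError

#: float tolerance when comparing objective totals for tie-breaking
_TIE_TOL = 1e-9

_EXACT_MAX_SITES = 20


@dataclass
class Problem:
    """A minimum-set instance: costs, availability, targets and penalties.

    ``benefit[i, j]`` is 1 iff species j is available at site i (in the
    candidate-pool workflow: iff j is in site i's pool).  ``locked_rep``
    is an optional per-species baseline representation counted regardless
    of the selection, used to credit sites where a species is already a
    declared target without selecting them.
    """

    site_ids: list[str]
    species_ids: list[str]
    cost: np.ndarray
    benefit: np.ndarray
    target: np.ndarray
    spf: np.ndarray
    locked_rep: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cost = np.asarray(self.cost, dtype=float)
        self.benefit = np.asarray(self.benefit, dtype=bool)
        self.target = np.asarray(self.target, dtype=int)
        self.spf = np.asarray(self.spf, dtype=float)
        m, n = len(self.site_ids), len(self.species_ids)
        if self.benefit.shape != (m, n):
            raise ValidationError(
                f"benefit matrix shape {self.benefit.shape}, expected {(m, n)}"
            )
        if self.cost.shape != (m,):
            raise ValidationError("cost vector length does not match site count")
        if self.target.shape != (n,) or self.spf.shape != (n,):
            raise ValidationError("target/spf length does not match species count")
        if np.any(self.cost <= 0):
            raise ValidationError("site costs must be positive")
        if np.any(self.target < 1):
            raise ValidationError("targets must be >= 1")
        if np.any(self.spf < 0):
            raise ValidationError("penalty factors must be >= 0")
        if self.locked_rep is None:
            self.locked_rep = np.zeros(n, dtype=int)
        else:
            self.locked_rep = np.asarray(self.locked_rep, dtype=int)
            if self.locked_rep.shape != (n,):
                raise ValidationError("locked_rep length does not match species count")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


@dataclass(frozen=True)
class ObjectiveValue:
    """Decomposed objective: total = cost_term + penalty_term exactly."""

    cost_term: float
    penalty_term: float
    total: float
    shortfalls: np.ndarray


@dataclass
class Solution:
    """A selection vector with its objective and achieved representation."""

    x: np.ndarray
    objective: ObjectiveValue
    representation: np.ndarray

    @property
    def n_selected(self) -> int:
        return int(self.x.sum())

    def selected_ids(self, problem: Problem) -> list[str]:
        return [problem.site_ids[i] for i in np.flatnonzero(self.x)]


def objective(x: np.ndarray, problem: Problem) -> ObjectiveValue:
    """Evaluate the objective from scratch for a selection vector."""
    x = np.asarray(x, dtype=bool)
    if x.shape != (problem.n_sites,):
        raise ValidationError(
            f"selection vector length {x.shape}, expected ({problem.n_sites},)"
        )
    r = problem.locked_rep + x.astype(np.int64) @ problem.benefit.astype(np.int64)
    shortfall = np.maximum(problem.target - r, 0)
    cost_term = float(problem.cost[x].sum())
    with np.errstate(invalid="ignore"):
        penalty_term = float((problem.spf * shortfall / problem.target).sum())
    return ObjectiveValue(
        cost_term=cost_term,
        penalty_term=penalty_term,
        total=cost_term + penalty_term,
        shortfalls=shortfall,
    )


def flip_delta(problem: Problem, x: np.ndarray, r: np.ndarray, i: int) -> float:
    """Change in total objective from flipping site ``i`` of state ``x``.

    ``r`` must be the representation vector of ``x`` (locked baseline
    plus selected availability).  This is the incremental evaluation the
    annealer relies on; it must equal ``objective(x') − objective(x)``
    recomputed from scratch.
    """
    sign = -1.0 if x[i] else 1.0
    ids = np.flatnonzero(problem.benefit[i])
    t = problem.target[ids].astype(float)
    w = problem.spf[ids] / t
    r_ids = r[ids].astype(float)
    old = w @ np.maximum(t - r_ids, 0.0)
    new = w @ np.maximum(t - (r_ids + sign), 0.0)
    return float(sign * problem.cost[i] + (new - old))


def _make_solution(x: np.ndarray, problem: Problem) -> Solution:
    x = np.asarray(x, dtype=bool)
    obj = objective(x, problem)
    r = problem.locked_rep + x.astype(np.int64) @ problem.benefit.astype(np.int64)
    return Solution(x=x.copy(), objective=obj, representation=r)


def _solution_key(sol: Solution) -> tuple:
    """Ordering key: total, then penalty (prefer met targets), then size,
    then lexicographic selection vector — all floats rounded to absorb
    accumulation noise."""
    return (
        round(sol.objective.total, 9),
        round(sol.objective.penalty_term, 9),
        sol.n_selected,
        tuple(sol.x.astype(int)),
    )


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnealingParams:
    """Cooling schedule for :func:`solve_sa`.

    ``t_initial=None`` calibrates the start temperature so the median
    |Δtotal| of ``n_probe`` random single-site flips from the initial
    (empty) state is accepted with probability ``accept_prob``; cooling
    is geometric down to ``t_final_ratio`` times the start temperature.
    The default 100 000 iterations is a desk-scale setting; production
    runs at millions of iterations are reached through this parameter.
    """

    iterations: int = 100_000
    t_initial: float | None = None
    t_final_ratio: float = 1e-4
    n_probe: int = 100
    accept_prob: float = 0.8

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not 0 < self.accept_prob < 1:
            raise ValidationError("accept_prob must be in (0, 1)")


def solve_sa(
    problem: Problem,
    schedule: AnnealingParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> Solution:
    """Simulated annealing over single-site bit flips.

    Starts from the empty selection, proposes a uniformly random site
    flip each iteration, accepts when Δtotal ≤ 0 or with probability
    exp(−Δtotal/T), and returns the best state visited (by the tie
    ordering described in the module docstring).  Deterministic for a
    fixed generator state.
    """
    schedule = schedule or AnnealingParams()
    rng = np.random.default_rng(rng)
    m, n = problem.n_sites, problem.n_species
    if m == 0:
        return _make_solution(np.zeros(0, dtype=bool), problem)

    cost = problem.cost
    t = problem.target.astype(float)
    weight = problem.spf / t  # penalty per unit shortfall, per species
    site_species = [np.flatnonzero(problem.benefit[i]) for i in range(m)]

    x = np.zeros(m, dtype=bool)
    r = problem.locked_rep.astype(float).copy()
    pen_vec = weight * np.maximum(t - r, 0.0)
    cost_cur = 0.0
    penalty_cur = float(pen_vec.sum())

    # calibrate the start temperature from probe flips off the initial state
    if schedule.t_initial is not None:
        t0 = float(schedule.t_initial)
    else:
        probes = rng.integers(0, m, size=schedule.n_probe)
        deltas = np.abs([flip_delta(problem, x, r, int(i)) for i in probes])
        med = float(np.median(deltas))
        t0 = med / math.log(1.0 / schedule.accept_prob) if med > 0 else 1.0
    t_final = max(schedule.t_final_ratio * t0, 1e-300)
    n_iter = schedule.iterations
    alpha = (t_final / t0) ** (1.0 / max(n_iter - 1, 1))

    best_x = x.copy()
    best_total = cost_cur + penalty_cur
    best_penalty = penalty_cur
    best_nsel = 0
    nsel = 0

    temp = t0
    block = 8192
    done = 0
    while done < n_iter:
        k = min(block, n_iter - done)
        sites = rng.integers(0, m, size=k)
        unif = rng.random(k)
        for b in range(k):
            i = int(sites[b])
            sign = -1.0 if x[i] else 1.0
            ids = site_species[i]
            if ids.size:
                r_ids = r[ids]
                t_ids = t[ids]
                w_ids = weight[ids]
                old = w_ids @ np.maximum(t_ids - r_ids, 0.0)
                new_pen = w_ids @ np.maximum(t_ids - (r_ids + sign), 0.0)
                dpen = new_pen - old
            else:
                dpen = 0.0
            delta = sign * cost[i] + dpen
            if delta <= 0.0 or unif[b] < math.exp(-delta / temp):
                x[i] = not x[i]
                if ids.size:
                    r[ids] += sign
                cost_cur += sign * cost[i]
                penalty_cur += dpen
                nsel += 1 if sign > 0 else -1
                total = cost_cur + penalty_cur
                if total < best_total - _TIE_TOL:
                    better = True
                elif total <= best_total + _TIE_TOL:
                    better = penalty_cur < best_penalty - _TIE_TOL or (
                        abs(penalty_cur - best_penalty) <= _TIE_TOL
                        and nsel < best_nsel
                    )
                else:
                    better = False
                if better:
                    best_x = x.copy()
                    best_total = total
                    best_penalty = penalty_cur
                    best_nsel = nsel
            temp *= alpha
        done += k

    return _make_solution(best_x, problem)


# ---------------------------------------------------------------------------
# Greedy baseline
# ---------------------------------------------------------------------------


def solve_greedy(problem: Problem) -> Solution:
    """Iteratively add the site with the best objective decrease per unit cost.

    Stops as soon as no single addition strictly decreases the total;
    ties go to the lowest site index.  Purely deterministic.
    """
    m = problem.n_sites
    x = np.zeros(m, dtype=bool)
    r = problem.locked_rep.astype(float).copy()
    t = problem.target.astype(float)
    weight = problem.spf / t
    benefit = problem.benefit.astype(float)

    while True:
        # penalty reduction of adding one copy of each unmet species
        gain = np.where(r < t, weight, 0.0)
        reduction = benefit @ gain
        decrease = reduction - problem.cost
        decrease[x] = -np.inf
        score = decrease / problem.cost
        i = int(np.argmax(score))  # argmax takes the first (lowest) index on ties
        if decrease[i] <= _TIE_TOL:
            break
        x[i] = True
        r += benefit[i]
    return _make_solution(x, problem)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------


def solve_exact(problem: Problem) -> Solution:
    """Enumerate all 2^m selections (m ≤ 20) and return the minimum.

    Ties are broken by fewer selected sites, then lexicographically
    smallest selection vector.  Intended as a test oracle on small
    instances.
    """
    m = problem.n_sites
    if m > _EXACT_MAX_SITES:
        raise ValidationError(
            f"exhaustive enumeration limited to {_EXACT_MAX_SITES} sites (got {m})"
        )
    if m == 0:
        return _make_solution(np.zeros(0, dtype=bool), problem)

    benefit = problem.benefit.astype(float)
    t = problem.target.astype(float)
    weight = problem.spf / t
    best: Solution | None = None
    best_key: tuple | None = None
    chunk = 1 << 14
    bits = np.arange(m)
    for start in range(0, 1 << m, chunk):
        stop = min(start + chunk, 1 << m)
        codes = np.arange(start, stop, dtype=np.int64)
        sel = ((codes[:, None] >> bits[None, :]) & 1).astype(bool)
        r = problem.locked_rep + sel @ benefit
        penalty = (np.maximum(t - r, 0.0) * weight).sum(axis=1)
        cost = sel @ problem.cost
        total = cost + penalty
        lo = float(total.min())
        if best is not None and lo > best.objective.total + _TIE_TOL:
            continue
        for k in np.flatnonzero(total <= lo + _TIE_TOL):
            cand = _make_solution(sel[k], problem)
            key = (
                round(cand.objective.total, 9),
                cand.n_selected,
                tuple(cand.x.astype(int)),
            )
            if best_key is None or key < best_key:
                best, best_key = cand, key
    assert best is not None
    return best


def best_of_runs(
    problem: Problem,
    n_runs: int,
    schedule: AnnealingParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> Solution:
    """Run the annealer ``n_runs`` times with independent sub-seeds.

    Sub-seeds are spawned from a single seed sequence, so run k is the
    same whether 10 or 100 runs are requested (nested determinism).
    Returns the best solution by the shared tie ordering.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seq.spawn(n_runs)
    best: Solution | None = None
    best_key: tuple | None = None
    for child in children:
        sol = solve_sa(problem, schedule, np.random.Generator(np.random.PCG64(child)))
        key = _solution_key(sol)
        if best_key is None or key < best_key:
            best, best_key = sol, key
    assert best is not None
    return best
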