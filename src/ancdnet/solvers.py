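"""Stochastic solvers over the discretised allocation space.

Three interchangeable metaheuristics search the same genotype space — an
integer vector of per-edge volume-option indices of length E = W * R:

* **ACO** — a Max–Min Ant System: each ant picks, per edge, an option with
  probability proportional to ``tau^alpha * eta^beta`` where the heuristic
  information eta is the option's marginal contribution to the cost index;
  after each iteration pheromone persists by a factor rho and the
  iteration-best feasible ant deposits on its chosen cells; trails are
  clamped to [tau_min, tau_max].
* **GA** — integer-encoded genetic algorithm with tournament (or rank)
  selection, uniform crossover on a configurable fraction of offspring,
  per-gene resampling mutation and elitism.
* **PSO** — particles move in the continuous cube [0, 1]^E with a linearly
  decaying inertia weight and clamped velocities; positions are mapped to
  the nearest discrete option for evaluation.

All three decode genotypes through the same volume-repair step (scale-down
to the per-source and per-receptor volume caps, snap to the option grid)
before evaluation; the remaining blend constraints (C/N, alkalinity,
toxicity) are handled by a death or linear penalty.  Campaigns run N
independent repetitions with derived seeds and keep the best feasible run.
A brute-force oracle exhaustively scores small instances for testing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .errors import ConfigurationError, ValidationError
from .evaluator import VectorEvaluator
from .network import Allocation, CaseNetwork
from .objective import check_feasibility, cost_index

__all__ = [
    "SolverConfig",
    "RunRecord",
    "CampaignResult",
    "OracleResult",
    "fitness",
    "aco_solve",
    "ga_solve",
    "pso_solve",
    "solve",
    "run_campaign",
    "brute_force_oracle",
]

ALGORITHMS = ("aco", "ga", "pso")


@dataclass
class SolverConfig:
    """Hyper-parameters shared by the campaign harness and the three solvers.

    Defaults follow the trimmed values used on the case study: population
    100, 500 iterations, best of 10 repetitions; ACO alpha=1, beta=2,
    pheromone persistence rho=0.98; GA crossover fraction 0.8 and 5% elite
    children; PSO cognitive attraction 0.8 and social attraction 1.25.
    """

    algorithm: str = "aco"
    population: int = 100
    iterations: int = 500
    repetitions: int = 10
    seed: int = 0
    penalty: str = "death"
    penalty_lambda: float = 1.0
    repair_volumes: bool = True
    # ACO
    aco_alpha: float = 1.0
    aco_beta: float = 2.0
    aco_rho: float = 0.98
    aco_tau_bounds: tuple[float, float] = (0.01, 10.0)
    # relative heuristic floor: this fraction of the edge's largest marginal
    # term is added to every option's eta, keeping zero/low-volume options
    # genuinely selectable under beta = 2
    aco_eta_floor: float = 0.1
    # per-edge uniform exploration rate; until a run constructs its first
    # feasible solution ants sample options uniformly (pheromone carries no
    # information before the first deposit, and the heuristic alone is too
    # greedy to discover blend-feasible corners of the space)
    aco_explore: float = 0.1
    # GA
    ga_crossover_fraction: float = 0.8
    ga_elite_fraction: float = 0.05
    ga_mutation_rate: float | None = None   # default 1/E
    ga_selection: str = "tournament"
    # PSO
    pso_cognitive: float = 0.8
    pso_social: float = 1.25
    pso_inertia: tuple[float, float] = (0.9, 0.4)
    pso_velocity_clamp: float = 0.2

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if min(self.population, self.iterations, self.repetitions) < 1:
            raise ConfigurationError("population, iterations and repetitions must be >= 1")
        if self.penalty not in ("death", "linear"):
            raise ConfigurationError(f"penalty must be 'death' or 'linear', got {self.penalty!r}")
        if not 0 < self.aco_rho < 1:
            raise ConfigurationError("aco_rho must lie in (0, 1)")
        for name in ("ga_crossover_fraction", "ga_elite_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.ga_mutation_rate is not None and not 0 <= self.ga_mutation_rate <= 1:
            raise ConfigurationError("ga_mutation_rate must lie in [0, 1]")
        if self.ga_selection not in ("tournament", "rank"):
            raise ConfigurationError(f"ga_selection must be 'tournament' or 'rank'")
        tmin, tmax = self.aco_tau_bounds
        if not 0 < tmin < tmax:
            raise ConfigurationError("aco_tau_bounds must satisfy 0 < tau_min < tau_max")
        if not 0 < self.pso_velocity_clamp <= 1:
            raise ConfigurationError("pso_velocity_clamp must lie in (0, 1]")
        if not 0 <= self.aco_explore <= 1:
            raise ConfigurationError("aco_explore must lie in [0, 1]")


@dataclass
class RunRecord:
    """Outcome of one solver run: best solution found and its history."""

    best_allocation: Allocation
    best_b: float
    iteration_trace: list[tuple[int, float, float]]  # (iteration, best_b so far, mean fitness)
    seed: int
    feasible_found: bool


@dataclass
class CampaignResult:
    """Best-of-N campaign: independent repetitions, feasibility-then-B selection."""

    runs: list[RunRecord]
    best: RunRecord
    mean_best_b: float
    feasible: bool


def fitness(a: Allocation, net: CaseNetwork, penalty: str = "death", lam: float = 1.0) -> float:
    """Penalty-adjusted scalar fitness of one allocation.

    Feasible allocations score their cost index B.  Under the death penalty
    any violation zeroes the fitness; under the linear penalty the sum of
    bound-normalised violation magnitudes is subtracted (floored at 0).
    """
    if penalty not in ("death", "linear"):
        raise ConfigurationError(f"penalty must be 'death' or 'linear', got {penalty!r}")
    _, b_abs = cost_index(a, net)
    feasible, violations = check_feasibility(a, net)
    if feasible:
        return b_abs
    if penalty == "death":
        return 0.0
    return max(0.0, b_abs - lam * sum(v.magnitude for v in violations))


# ---------------------------------------------------------------------------
# Shared run machinery
# ---------------------------------------------------------------------------

class _BestTracker:
    """Best-ever bookkeeping with feasibility-then-fitness ordering.

    A candidate only counts as *feasible* when it satisfies every restriction
    AND ships a positive volume; the all-zero allocation is "no solution".
    First-encountered wins at equal fitness.
    """

    def __init__(self) -> None:
        self.best_vol: np.ndarray | None = None
        self.best_fit = -math.inf
        self.best_feasible = False

    def update(self, vols: np.ndarray, res: dict[str, np.ndarray], fit: np.ndarray) -> None:
        ok = res["feasible"] & (res["total_volume"] > 0)
        if ok.any():
            cand = np.where(ok, fit, -np.inf)
            i = int(np.argmax(cand))
            if (not self.best_feasible) or cand[i] > self.best_fit:
                self.best_vol = vols[i].copy()
                self.best_fit = float(cand[i])
                self.best_feasible = True
            return
        if self.best_feasible:
            return
        i = int(np.argmax(fit))
        if fit[i] > self.best_fit:
            self.best_vol = vols[i].copy()
            self.best_fit = float(fit[i])
            self.best_feasible = False

    @property
    def trace_value(self) -> float:
        return self.best_fit if self.best_vol is not None else 0.0


def _finish(ev: VectorEvaluator, tracker: _BestTracker, trace: list, seed: int) -> RunRecord:
    if tracker.best_vol is None:
        alloc = Allocation({})
        best_b = 0.0
    else:
        alloc = ev.to_allocation(tracker.best_vol)
        best_b = tracker.best_fit
    return RunRecord(
        best_allocation=alloc,
        best_b=best_b,
        iteration_trace=trace,
        seed=seed,
        feasible_found=tracker.best_feasible,
    )


def _prepare(ev: VectorEvaluator, idx: np.ndarray, cfg: SolverConfig) -> np.ndarray:
    vol = ev.decode(idx)
    if cfg.repair_volumes:
        vol = ev.repair(vol)
    return vol


# ---------------------------------------------------------------------------
# ACO (Max-Min Ant System)
# ---------------------------------------------------------------------------

def aco_solve(net: CaseNetwork, cfg: SolverConfig, _debug: dict | None = None) -> RunRecord:
    """Max–Min Ant System over the per-edge option choices.

    ``_debug``, when a dict, receives the pheromone extremes observed after
    every update (keys ``tau_min_seen`` / ``tau_max_seen``); test hook only.
    """
    if cfg.algorithm != "aco":
        raise ConfigurationError("cfg.algorithm must be 'aco'")
    rng = np.random.default_rng(cfg.seed)
    ev = VectorEvaluator(net)
    E, P = ev.E, cfg.population
    tau_min, tau_max = cfg.aco_tau_bounds
    smax = ev.edge_options.shape[1]
    valid = np.arange(smax)[None, :] < ev.n_options[:, None]          # (E, smax)
    # heuristic information: marginal cost-index term of each option, floored
    # at a fraction of the edge's largest term (absolute floor would make
    # zero options unselectable once raised to beta)
    term = ev.edge_options * ev.edge_weight.reshape(ev.E, 1)
    t_max = np.where(valid, term, 0.0).max(axis=1, keepdims=True)
    eta = term + cfg.aco_eta_floor * np.where(t_max > 0, t_max, 1.0)
    eta = np.where(valid, eta, 0.0)
    tau = np.where(valid, tau_max, 0.0)

    tracker = _BestTracker()
    trace: list[tuple[int, float, float]] = []
    edge_ids = np.arange(E)
    found_feasible = False
    for it in range(cfg.iterations):
        weight = np.where(valid, tau**cfg.aco_alpha * eta**cfg.aco_beta, 0.0)
        cdf = np.cumsum(weight, axis=1)
        total = cdf[:, -1]
        u = rng.random((P, E)) * total[None, :]
        idx = np.empty((P, E), dtype=np.int64)
        for e in range(E):
            idx[:, e] = np.searchsorted(cdf[e], u[:, e], side="right")
        np.minimum(idx, ev.n_options - 1, out=idx)
        explore = cfg.aco_explore if found_feasible else 1.0
        if explore > 0:
            mask = rng.random((P, E)) < explore
            uniform = (rng.random((P, E)) * ev.n_options).astype(np.int64)
            idx = np.where(mask, uniform, idx)

        vols = _prepare(ev, idx, cfg)
        res = ev.evaluate(vols)
        fit = ev.fitness(res, cfg.penalty, cfg.penalty_lambda)
        tracker.update(vols, res, fit)

        # evaporation (persistence rho), then iteration-best feasible deposit
        tau *= cfg.aco_rho
        ok = res["feasible"] & (res["total_volume"] > 0)
        if ok.any():
            found_feasible = True
            cand = np.where(ok, fit, -np.inf)
            ib = int(np.argmax(cand))
            dep_idx = ev.volumes_to_indices(vols[ib])
            tau[edge_ids, dep_idx] += float(fit[ib])
        np.clip(tau, tau_min, tau_max, out=tau)
        tau = np.where(valid, tau, 0.0)
        if _debug is not None:
            seen = tau[valid]
            _debug["tau_min_seen"] = min(_debug.get("tau_min_seen", np.inf), float(seen.min()))
            _debug["tau_max_seen"] = max(_debug.get("tau_max_seen", -np.inf), float(seen.max()))
        trace.append((it, tracker.trace_value, float(fit.mean())))
    return _finish(ev, tracker, trace, cfg.seed)


# ---------------------------------------------------------------------------
# GA (integer encoding, elitism)
# ---------------------------------------------------------------------------

def ga_solve(net: CaseNetwork, cfg: SolverConfig) -> RunRecord:
    """Elitist genetic algorithm on integer option-index chromosomes."""
    if cfg.algorithm != "ga":
        raise ConfigurationError("cfg.algorithm must be 'ga'")
    rng = np.random.default_rng(cfg.seed)
    ev = VectorEvaluator(net)
    E, P = ev.E, cfg.population
    mut_rate = cfg.ga_mutation_rate if cfg.ga_mutation_rate is not None else 1.0 / E
    elite_n = min(P, int(round(cfg.ga_elite_fraction * P)))

    pop = ev.random_indices(rng, P)
    tracker = _BestTracker()
    trace: list[tuple[int, float, float]] = []
    for it in range(cfg.iterations):
        vols = _prepare(ev, pop, cfg)
        res = ev.evaluate(vols)
        fit = ev.fitness(res, cfg.penalty, cfg.penalty_lambda)
        tracker.update(vols, res, fit)
        trace.append((it, tracker.trace_value, float(fit.mean())))
        if it == cfg.iterations - 1:
            break

        order = np.argsort(-fit, kind="stable")
        elites = pop[order[:elite_n]].copy()
        n_off = P - elite_n
        if n_off > 0:
            if cfg.ga_selection == "tournament":
                cand = rng.integers(0, P, size=(2, 2 * n_off))
                win = np.where(fit[cand[0]] >= fit[cand[1]], cand[0], cand[1])
                pa, pb = win[:n_off], win[n_off:]
            else:  # rank-proportional selection
                ranks = np.empty(P)
                ranks[order] = np.arange(P, 0, -1)
                prob = ranks / ranks.sum()
                pa = rng.choice(P, size=n_off, p=prob)
                pb = rng.choice(P, size=n_off, p=prob)
            off = pop[pa].copy()
            n_cross = int(round(cfg.ga_crossover_fraction * n_off))
            if n_cross > 0:
                mask = rng.random((n_cross, E)) < 0.5
                off[:n_cross] = np.where(mask, pop[pa[:n_cross]], pop[pb[:n_cross]])
            mut = rng.random((n_off, E)) < mut_rate
            resample = (rng.random((n_off, E)) * ev.n_options).astype(np.int64)
            off = np.where(mut, resample, off)
            pop = np.concatenate([elites, off]) if elite_n else off
        else:
            pop = elites
    return _finish(ev, tracker, trace, cfg.seed)


# ---------------------------------------------------------------------------
# PSO (continuous relaxation with nearest-option mapping)
# ---------------------------------------------------------------------------

def pso_solve(net: CaseNetwork, cfg: SolverConfig) -> RunRecord:
    """Particle swarm in [0, 1]^E mapped to the nearest discrete option."""
    if cfg.algorithm != "pso":
        raise ConfigurationError("cfg.algorithm must be 'pso'")
    rng = np.random.default_rng(cfg.seed)
    ev = VectorEvaluator(net)
    E, P = ev.E, cfg.population
    w0, w1 = cfg.pso_inertia
    vmax = cfg.pso_velocity_clamp

    def to_idx(x: np.ndarray) -> np.ndarray:
        return np.rint(x * (ev.n_options - 1)).astype(np.int64)

    x = rng.random((P, E))
    v = np.zeros((P, E))
    tracker = _BestTracker()
    trace: list[tuple[int, float, float]] = []
    pbest_x = x.copy()
    pbest_fit = np.full(P, -np.inf)
    gbest_x = x[0].copy()
    gbest_fit = -np.inf
    for it in range(cfg.iterations):
        vols = _prepare(ev, to_idx(x), cfg)
        res = ev.evaluate(vols)
        fit = ev.fitness(res, cfg.penalty, cfg.penalty_lambda)
        tracker.update(vols, res, fit)
        trace.append((it, tracker.trace_value, float(fit.mean())))

        improved = fit > pbest_fit
        pbest_x[improved] = x[improved]
        pbest_fit[improved] = fit[improved]
        gi = int(np.argmax(pbest_fit))
        if pbest_fit[gi] > gbest_fit:
            gbest_fit = float(pbest_fit[gi])
            gbest_x = pbest_x[gi].copy()
        if it == cfg.iterations - 1:
            break

        frac = it / (cfg.iterations - 1) if cfg.iterations > 1 else 0.0
        w = w0 + (w1 - w0) * frac
        r1 = rng.random((P, E))
        r2 = rng.random((P, E))
        v = w * v + cfg.pso_cognitive * r1 * (pbest_x - x) + cfg.pso_social * r2 * (gbest_x - x)
        np.clip(v, -vmax, vmax, out=v)
        x = np.clip(x + v, 0.0, 1.0)
    return _finish(ev, tracker, trace, cfg.seed)


_SOLVERS: dict[str, Callable[[CaseNetwork, SolverConfig], RunRecord]] = {
    "aco": aco_solve,
    "ga": ga_solve,
    "pso": pso_solve,
}


def solve(net: CaseNetwork, cfg: SolverConfig) -> RunRecord:
    """Dispatch to the configured solver."""
    return _SOLVERS[cfg.algorithm](net, cfg)


def run_campaign(net: CaseNetwork, cfg: SolverConfig) -> CampaignResult:
    """Run ``cfg.repetitions`` independent solves and keep the best.

    Per-repetition seeds are ``cfg.seed + repetition_index`` so a campaign is
    reproducible while its repetitions stay independent.  The winner is the
    feasible run with the highest index B (first wins on ties); when no run
    finds a feasible solution the campaign is marked infeasible and the
    highest-B run is reported for inspection.
    """
    runs = [solve(net, replace(cfg, seed=cfg.seed + rep)) for rep in range(cfg.repetitions)]
    feasible_runs = [r for r in runs if r.feasible_found]
    pool = feasible_runs or runs
    best = max(pool, key=lambda r: r.best_b)
    return CampaignResult(
        runs=runs,
        best=best,
        mean_best_b=sum(r.best_b for r in runs) / len(runs),
        feasible=bool(feasible_runs),
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    allocation: Allocation
    b_abs: float
    feasible: bool


def brute_force_oracle(net: CaseNetwork, cap: int = 10**6) -> OracleResult:
    """Exhaustively enumerate every option combination on a small instance.

    Refuses (with the combination count) when the search space exceeds
    ``cap``.  Returns the feasible maximiser of the index B among allocations
    with positive volume; ties break to the lexicographically smallest
    option vector.  When no such allocation exists the instance is reported
    infeasible (with the empty allocation).
    """
    ev = VectorEvaluator(net)
    n_opts = ev.n_options
    count = int(np.prod(n_opts.astype(object)))
    if count > cap:
        raise ValidationError(f"search space has {count} combinations, above the cap of {cap}")

    best_idx: np.ndarray | None = None
    best_b = -math.inf
    chunk = 65536
    it = itertools.product(*[range(int(n)) for n in n_opts])
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        idx = np.array(block, dtype=np.int64)
        vols = ev.decode(idx)
        res = ev.evaluate(vols)
        ok = res["feasible"] & (res["total_volume"] > 0)
        if ok.any():
            cand = np.where(ok, res["b_abs"], -np.inf)
            i = int(np.argmax(cand))
            if cand[i] > best_b:  # strict: earlier (lexicographically smaller) wins ties
                best_b = float(cand[i])
                best_idx = idx[i]
    if best_idx is None:
        return OracleResult(Allocation({}), 0.0, False)
    return OracleResult(Allocation.from_indices(net, best_idx), best_b, True)
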