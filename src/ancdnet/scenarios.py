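"""Scenario transformations, benchmark runner, reports and parameter sweeps.

Scenarios are reproducible transformations of a base network used to stress
the solvers: scaling COD concentrations (high organic load), scaling or
square-rooting route distances (logistics pressure, receptor dispersion),
scaling available volumes (larger search space) and re-sampling the C/N
ratio of selected generators (restriction pressure).  The module also
provides the per-receptor blending-profile report, the truck logistics
schedule implied by an allocation, and hyper-parameter trimming sweeps.
"""

from __future__ import annotations

import copy
import math
import time
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .network import Allocation, CaseNetwork
from .objective import evaluate, performance_summary
from .solvers import SolverConfig, run_campaign

__all__ = [
    "CnOverride",
    "ScenarioSpec",
    "standard_scenarios",
    "apply_scenario",
    "BenchmarkTable",
    "run_benchmark",
    "blending_profile_report",
    "TruckSchedule",
    "ScheduleEntry",
    "logistics_schedule",
    "parameter_sweep",
]


@dataclass(frozen=True)
class CnOverride:
    """Re-sample the C/N ratio of the named sources uniformly in [lo, hi]."""

    source_ids: tuple[str, ...]
    lo: float
    hi: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lo <= self.hi:
            raise ValidationError("cn override range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class ScenarioSpec:
    """One transformation of a base network."""

    id: str
    cod_multiplier: float = 1.0
    distance_mode: str = "identity"     # identity | linear | sqrt
    distance_factor: float = 1.0
    volume_multiplier: float = 1.0
    cn_override: CnOverride | None = None

    def __post_init__(self) -> None:
        if not self.cod_multiplier > 0 or not self.volume_multiplier > 0:
            raise ValidationError("scenario multipliers must be > 0")
        if self.distance_mode not in ("identity", "linear", "sqrt"):
            raise ValidationError(f"unknown distance_mode {self.distance_mode!r}")
        if self.distance_mode == "linear" and not self.distance_factor > 0:
            raise ValidationError("distance_factor must be > 0")


def standard_scenarios(cn_seed: int = 0) -> list[ScenarioSpec]:
    """The five stress scenarios used on the case study, plus the baseline.

    Scenario 1 multiplies COD by 10; 2a multiplies distances by 10; 2b
    replaces each distance with its square root (in km); 3 triples volumes;
    4 re-samples the C/N ratio of the twelve sludge generators W1–W12
    uniformly in [50, 60].
    """
    w = tuple(f"W{i}" for i in range(1, 13))
    return [
        ScenarioSpec(id="baseline"),
        ScenarioSpec(id="scenario1", cod_multiplier=10.0),
        ScenarioSpec(id="scenario2a", distance_mode="linear", distance_factor=10.0),
        ScenarioSpec(id="scenario2b", distance_mode="sqrt"),
        ScenarioSpec(id="scenario3", volume_multiplier=3.0),
        ScenarioSpec(id="scenario4", cn_override=CnOverride(w, 50.0, 60.0, seed=cn_seed)),
    ]


def apply_scenario(net: CaseNetwork, spec: ScenarioSpec) -> CaseNetwork:
    """Return a transformed deep copy of ``net``; the input is not mutated."""
    out = copy.deepcopy(net)
    if spec.cn_override is not None:
        known = set(out.source_ids)
        missing = [sid for sid in spec.cn_override.source_ids if sid not in known]
        if missing:
            raise ValidationError(f"cn_override names unknown source(s): {missing}")
        rng = np.random.default_rng(spec.cn_override.seed)
        targets = set(spec.cn_override.source_ids)
        for s in out.sources:  # network order, so draws are reproducible
            if s.id in targets:
                s.cn_ratio = float(rng.uniform(spec.cn_override.lo, spec.cn_override.hi))
    for s in out.sources:
        s.cod *= spec.cod_multiplier
        s.daily_volume *= spec.volume_multiplier
        if spec.distance_mode == "linear":
            s.distance_km = {r: d * spec.distance_factor for r, d in s.distance_km.items()}
        elif spec.distance_mode == "sqrt":
            s.distance_km = {r: math.sqrt(d) for r, d in s.distance_km.items()}
    return out


@dataclass
class BenchmarkTable:
    """One row per (scenario, algorithm) with the performance-metric set."""

    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def run_benchmark(
    net: CaseNetwork,
    scenarios: Sequence[ScenarioSpec],
    algorithms: Sequence[str],
    cfg: SolverConfig,
) -> BenchmarkTable:
    """Campaign every (scenario, algorithm) pair and tabulate the metrics.

    Infeasible campaigns emit a marked row with empty metric cells.  Elapsed
    wall time is informative only.
    """
    table = BenchmarkTable()
    for spec in scenarios:
        s_net = apply_scenario(net, spec)
        for algo in algorithms:
            t0 = time.perf_counter()
            result = run_campaign(s_net, replace(cfg, algorithm=algo))
            elapsed = time.perf_counter() - t0
            row: dict = {"scenario": spec.id, "algorithm": algo, "elapsed_s": elapsed}
            if result.feasible:
                ev = evaluate(result.best.best_allocation, s_net)
                row.update(performance_summary(ev, s_net))
            else:
                row.update({"best_index_b": float("nan"), "feasible": False})
            table.rows.append(row)
    return table


def blending_profile_report(a: Allocation, net: CaseNetwork) -> pd.DataFrame:
    """Per-receptor contribution table: source, volume, fraction of intake.

    Fractions sum to 1 for every receptor with non-zero intake; receptors
    with empty blends are omitted.  Sources appear in network order.
    """
    rows = []
    for r in net.receptors:
        total = a.total_to_receptor(r.id)
        if total == 0.0:
            continue
        for s in net.sources:
            v = a.get(s.id, r.id)
            if v != 0.0:
                rows.append(
                    {"receptor": r.id, "source": s.id, "volume_l_per_day": v, "fraction": v / total}
                )
    return pd.DataFrame(rows, columns=["receptor", "source", "volume_l_per_day", "fraction"])


@dataclass(frozen=True)
class ScheduleEntry:
    loads_per_cycle: int
    load_volume_l: float
    cycle_days: float


@dataclass
class TruckSchedule:
    """Truck loads needed per route over one retention-time cycle."""

    entries: dict[tuple[str, str], ScheduleEntry]
    feasible_within_hrt: bool


def logistics_schedule(
    a: Allocation,
    net: CaseNetwork,
    truck_capacity_t: float = 20.0,
    density_kg_per_l: float = 1.0,
    hrt_days: float = 20.0,
) -> TruckSchedule:
    """Convert an allocation into a per-route truck schedule.

    Substrate is stocked at the generator and moved in full 20-tonne loads;
    one cycle spans the digester's hydraulic retention time, so each active
    route must move ``v * density * hrt`` kilograms per cycle, i.e.
    ``ceil(cycle mass / truck capacity)`` loads.  Zero-volume routes are
    pruned.
    """
    if min(truck_capacity_t, density_kg_per_l, hrt_days) <= 0:
        raise ValidationError("truck capacity, density and HRT must all be > 0")
    cap_kg = truck_capacity_t * 1000.0
    entries: dict[tuple[str, str], ScheduleEntry] = {}
    for (sid, rid), v in sorted(a.nonzero().items()):
        cycle_mass = v * density_kg_per_l * hrt_days
        loads = math.ceil(cycle_mass / cap_kg - 1e-12)
        entries[(sid, rid)] = ScheduleEntry(
            loads_per_cycle=loads,
            load_volume_l=cap_kg / density_kg_per_l,
            cycle_days=hrt_days,
        )
    # one load or more always fits a cycle under this stocking model; the
    # flag exists for future refinements (e.g. fleet limits)
    return TruckSchedule(entries=entries, feasible_within_hrt=True)


def parameter_sweep(
    net: CaseNetwork,
    algorithm: str,
    grid: Mapping[str, Iterable],
    cfg: SolverConfig,
) -> pd.DataFrame:
    """Trimming sweep: one campaign per (parameter, value), all else fixed.

    Mirrors the one-at-a-time trimming procedure used to pick solver
    hyper-parameters: each listed value of each parameter is campaigned with
    every other setting at its configured value, and the argmax per
    parameter is marked ``best``.
    """
    valid = {f.name for f in fields(SolverConfig)}
    for name in grid:
        if name not in valid:
            raise ConfigurationError(f"unknown solver parameter {name!r}")
    rows = []
    for name, values in grid.items():
        for value in values:
            t0 = time.perf_counter()
            result = run_campaign(net, replace(cfg, algorithm=algorithm, **{name: value}))
            rows.append(
                {
                    "parameter": name,
                    "value": value,
                    "best_b": result.best.best_b if result.feasible else float("nan"),
                    "feasible": result.feasible,
                    "elapsed_s": time.perf_counter() - t0,
                    "best": False,
                }
            )
    df = pd.DataFrame(rows)
    for name in grid:
        sub = df[df["parameter"] == name]
        if sub["best_b"].notna().any():
            df.loc[sub["best_b"].idxmax(), "best"] = True
    return df
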