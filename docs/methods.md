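# Methods

This note documents the model implemented by `ancdnet`, the numerical and
design choices behind it, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Problem statement

A centralised anaerobic co-digestion network couples `W` substrate
generators to `R` receptor digesters over a complete bipartite graph. The
decision variable is the quantised daily volume shipped along each edge; per
edge exactly one option from `{0, q, 2q, …, ⌊V_w/q⌋·q, V_w}` is selected.
Because real source volumes are rarely exact multiples of the quantum, the
exact available volume `V_w` is always appended as a final partial step, so
full utilisation of a generator stays representable. Volumes from one
generator may be split across receptors; the per-source conservation
`Σ_r v(w,r) ≤ V_w` couples the edges. A single-receptor-style assignment
can be recovered by inspection or by restricting datasets to one receptor;
the per-edge model is the more general reading and matches observed blending
profiles in which the same generator feeds several plants.

## Quality coefficients

Each substrate carries four dimensionless coefficients: `F_w1` for biogas
potential, `F_w2` for COD/TN adequacy, `F_w3` for alkalinity adequacy and a
toxicity attenuation factor `T_w`. The package ships a transparent
*fallback* family:

* `F_w1 = COD_w / COD_ref`, with `COD_ref` the largest COD in the network
  (configurable) — biogas potential scales with organic content;
* `F_w2`, `F_w3`: trapezoidal membership of the substrate's C/N ratio
  (resp. alkalinity) on the operational window [20, 60] (resp.
  [2500, 6000] mg CaCO₃/L): 1 on the window, falling linearly to 0 over
  shoulders of width 0.25 × the window width. The shoulder fraction is a
  parameter; 0.25 keeps near-window substrates partially attractive (they
  are valuable in blends) without rewarding extreme compositions;
* `T_w = max(0, 1 − tox_w / 2.1)`: substrates at or above the 2.1 mg Pb/L
  ceiling contribute nothing, so toxicity needs no separate hard
  constraint on the substrate side (the blend-level ceiling is still
  enforced).

A `figure2` coefficient mode accepts user-supplied equation callables for
all four coefficients and refuses to run without them; the fallback family
is the shipped default and makes no claim to reproduce any particular
published coefficient curves, so index magnitudes are comparable between
runs of this package only.

## Cost index

An allocation is scored as

    B′ = K Σ_w Σ_r (v_wr / V_w) · T_w · combine(quality_w, logistics_wr),
    B  = |B′|,

with `quality_w = (F_w1 + F_w2 + F_w3)^ρq` (the exponent reading of the
weight; a plain-multiplier mode is switchable) and `ρq = ρx = 0.5`. The raw
logistics cost of an edge is `X_w · d_wr · I_w` (transport rate × route
length × social-impact class). Two combination modes exist:

* **penalty** (default): `combine = max(0, quality − ρx · raw / L_ref)`
  with a fixed reference scale `L_ref = 100` (the cost of a 100 km
  unit-rate, low-impact route). Long routes reduce an edge's worth, never
  increase it, and uniformly stretching a network's geography genuinely
  degrades the index — the behaviour the distance-stress scenario is meant
  to probe. Setting `logistics_ref=None` switches to normalising by the
  network's own largest edge cost, which is scale-free (a uniform ×10 on
  all distances would then change nothing); this variant is kept because it
  needs no exogenous scale.
* **literal**: `combine = quality + ρx · raw`, the additive form. It
  rewards distance and is retained only for comparison.

`K ∈ {−1, +1}` encodes whether the surrounding solver maximises or
minimises; all solvers in this package maximise `B`, so `K` only affects the
sign of the reported `B′`. Every per-edge factor is volume-independent, so
batch evaluation reduces to one matrix product; a vectorised evaluator
(`ancdnet.evaluator`) mirrors the readable public functions and the test
suite asserts the two routes agree.

## Feasibility and mass balance

Receptor blends are volume-weighted mass balances: COD mass is
`Σ v·COD·10⁻⁶` kg/d; nitrogen is derived per source as `COD/(C/N)` *before*
mixing and the blend C/N is the COD-mass over TN-mass ratio (never an
average of ratios — the blend C/N therefore always lies between the
constituent ratios, a property the tests enforce). Alkalinity and toxicity
mix as volume-weighted concentrations. Constraints per receptor with
non-zero intake: intake ≤ acceptance cap, C/N ∈ [20, 60], alkalinity ∈
[2500, 6000] mg CaCO₃/L, toxicity ≤ 2.1 mg Pb/L, all bounds inclusive with
a 10⁻⁹ relative tolerance against floating-point edge effects. By default
constraints are evaluated on the external substrates only; a `with_base`
mixing mode co-mixes the receptor's own sludge stream when its flow is
known. Biogas is `0.268 m³ per kg COD` fed. Organic loading rates divide
COD mass by the digester working volume; when a receptor does not state
one, it is approximated as 20 days (the hydraulic retention time) times the
plant's daily feed and flagged as approximate in all outputs.

## Constraint handling in the solvers

Random option vectors on a realistic network violate the volume caps almost
surely (total available substrate is ~3× total acceptance capacity), so a
bare death penalty would leave every population member at zero fitness and
the search would never start. All three solvers therefore decode genotypes
through a *volume repair* step before evaluation: volumes are scaled down
per source to `V_w`, snapped down onto the option grid, then scaled down
per receptor to the acceptance cap and snapped again. Repair is
deterministic, never increases a volume, and leaves volume-feasible
candidates untouched; repaired phenotypes are always on the option grid.
The remaining blend constraints (C/N, alkalinity, toxicity) are handled by
the penalty: *death* (default — any violation zeroes the fitness) or
*linear* (`max(0, B − λ Σ` bound-normalised violation magnitudes`)`,
λ = 1). Repair can be disabled (`repair_volumes=False`) to study the bare
formulations. A solution only counts as *found* when it is feasible **and**
ships a positive volume; the all-zero allocation trivially satisfies every
constraint but is reported as "no solution".

Under the linear penalty the best-so-far trace may step down once when the
first feasible solution displaces a higher-scoring infeasible incumbent;
under the default death penalty the trace is non-decreasing.

## Solvers

Shared campaign protocol: population 100, 500 iterations, 10 independent
repetitions with derived seeds (`seed + repetition index`), best feasible
repetition kept (first wins on ties). All randomness flows through one
`numpy` generator per run, so identical (configuration, seed, network)
triples give bit-identical results.

**ACO (Max–Min Ant System).** Construction graph = per-edge option choices.
Each ant picks, per edge, option `s` with probability ∝ `τ(e,s)^α η(e,s)^β`
(`α = 1, β = 2`); after each iteration pheromone persists by `ρ = 0.98` and
the iteration-best feasible ant deposits its fitness on its chosen cells;
trails are clamped to `[τ_min, τ_max] = [0.01, 10]` and initialised at
`τ_max`. The heuristic information `η` is the option's marginal index term,
floored at 0.1 × the edge's largest term: an absolute micro-floor would
make the zero option unselectable once raised to `β = 2`, and a solver that
cannot *exclude* a substrate cannot reach blends that require leaving
high-C/N sources out. For the same reason each edge choice is replaced with
a uniformly random option at rate 0.1, and until a run constructs its first
feasible solution ants sample options uniformly — before the first deposit
the pheromone matrix carries no information and the heuristic alone is too
greedy to discover the feasible region's corners. Both rates are
configurable.

**GA.** Chromosome = integer option-index vector of length `E`. Tournament
selection of size 2 (rank-proportional selection switchable), uniform
crossover applied to a 0.8 fraction of offspring, per-gene mutation at rate
`1/E` resampling a uniform option, top 5 % copied unchanged (elitism).

**PSO.** Particles move in `[0, 1]^E`; positions map to the nearest
discrete option for evaluation. Velocity update uses cognitive attraction
0.8, social attraction 1.25, inertia decaying linearly 0.9 → 0.4 over the
iterations, velocities clamped to 0.2 of the position range, zero initial
velocities, positions clipped to the cube.

**Exhaustive oracle.** For instances whose option-combination count is
below a cap (default 10⁶) the feasible space is enumerated outright; ties
break to the lexicographically smallest option vector. The oracle is the
reference in the solver-quality tests: on twenty seeded synthetic instances
(3 sludge + 2 industrial sources, one receptor, 10,000 L quantum, ≤ 600
combinations) each solver's full-budget campaign must reach ≥ 99 % of the
exhaustive optimum — or agree the instance is infeasible — in ≥ 95 % of
instances.

## Scenario engine

Scenarios transform a copy of the network, never the input: COD ×
multiplier, distances × factor or per-edge `√d` (in km), volumes ×
multiplier with option sets recomputed, and seeded uniform re-sampling of
selected sources' C/N into a target range (the standard stress set uses
[50, 60] for the twelve sludge generators; sampling rather than a fixed
value is assumed, with the seed part of the scenario so runs are
reproducible). Composing identity scenarios is a no-op; COD scaling is
exactly linear in biogas for a fixed allocation.

## Logistics schedule

The winning allocation converts to a per-route truck plan: substrate is
stocked at the generator and moved in full 20-tonne loads (density 1 kg/L
by default, configurable — sludge and most liquid substrates are
water-like); one supply cycle spans the 20-day retention time, so a route
shipping `v` L/day needs `⌈v · density · HRT / 20,000 kg⌉` loads per cycle.
Start times within the day, fleet limits and queuing are out of scope.

## Synthetic data

The generator draws instances whose *marginals* match the bundled
case-study dataset: sludge sources with COD 16.9–23.4 g/L, C/N 14–21,
alkalinity 1.8–10.1 g/L and volumes 4,400–47,000 L/d; industrial sources
with fixed 9,000 L/d volume, COD 156–667 g/L and C/N 32–33,000 (COD and C/N
log-uniform, matching their orders-of-magnitude spread); toxicity
0.01–2.30 mg Pb/L; distances 5–67 km. Receptor acceptance capacities are
drawn so total supply exceeds total capacity by a uniform factor in [1, 4],
keeping the volume constraints active. The generator does **not** emulate
spatial correlation between routes (distances are i.i.d., so there is no
geographic clustering), correlations between composition fields, temporal
variability of substrate production, or receptor base-stream
characteristics beyond ranges — passing tests on synthetic instances
therefore demonstrate solver correctness and constraint soundness, not
calibration to any particular basin.

## Numerical choices

Inclusive constraint bounds use a 10⁻⁹ relative slack. Option-grid
snapping guards against representation error with a 10⁻¹² relative epsilon.
The blend C/N of a nitrogen-free blend is reported as +∞ and treated as a
C/N-ceiling violation of unit normalised magnitude. Zero-intake receptors
are skipped by all blend constraints and excluded from volume-weighted
averages; an evaluation with no intake anywhere reports NaN averages and
zero biogas. Ties in selection, deposits and best-tracking always resolve
to the first-encountered candidate. CSV output is written at 17
significant digits and read back with round-trip float parsing, so network
and allocation serialisation is lossless.

## Limitations

* The shipped quality-coefficient family is a documented stand-in; absolute
  index values are not comparable to other implementations of the same
  blending problem, only to other runs of this package.
* The transport cost rates `X_w` and social impacts `I_w` of the bundled
  case study are not part of the public dataset; they default to 1 and are
  overridable per source.
* Static, single-day formulation: no digestion kinetics (no ADM1-style
  process model), no substrate stock dynamics, no routing on road networks.
* Campaign wall-clock times are recorded for information only and are
  hardware-dependent.
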