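# ancdnet

Optimiser for **centralised anaerobic co-digestion (AnCD) networks**: given a
set of organic-waste generators (undigested sewage sludge from wastewater
treatment plants, plus industrial substrates) and a set of receptor plants
operating anaerobic digesters with spare capacity, `ancdnet` decides how many
litres per day each generator should ship to each receptor so that every
digester receives a biochemically safe, energetically valuable blend at a
reasonable transport cost. It is aimed at water-administration engineers and
researchers who manage digester networks and today blend substrates by hand.

## The model

The network is a complete bipartite graph between `W` generators and `R`
receptors (`E = W·R` edges). Shipped volumes are quantised: generator *w*
with daily volume `V_w` may ship, per edge, one of
`{0, q, 2q, …, ⌊V_w/q⌋·q, V_w}` litres (quantum `q` = 1000 L by default).
A candidate allocation `x = {V_ws}` is scored by the normalised
quality-plus-logistics cost index

    B′ = K · Σ_edges (V_ws / V_w) · T_w · max(0, (F_w1 + F_w2 + F_w3)^ρq − ρx · X_w d_wr I_w / L_ref)
    B  = |B′|

where `F_w1` (biogas potential from COD), `F_w2` (COD/TN adequacy), `F_w3`
(alkalinity adequacy) and `T_w` (toxicity attenuation) are dimensionless
per-substrate quality coefficients, `ρq = ρx = 0.5` balance quality against
logistics, `X_w` is the transport cost rate (currency/km), `d_wr` the route
length, `I_w ∈ {1,2,3}` a social-impact class, `L_ref` a fixed logistics
reference scale, and `K ∈ {−1, +1}` a solver sign convention (the comparable
index is always `B`). Feasibility `g(x)` is checked per receptor on the
volume-weighted blend mass balance: intake ≤ the acceptance cap, COD/TN
ratio in [20, 60], alkalinity in [2500, 6000] mg CaCO₃/L, lead toxicity
≤ 2.1 mg Pb/L, plus per-generator volume conservation.

This discrete, multi-constraint selection problem is a multidimensional
knapsack, solved by three interchangeable metaheuristics sharing one
evaluation contract:

* **ACO** — Max–Min Ant System over per-edge option choices,
  `α = 1, β = 2, ρ = 0.98`, pheromone clamped to `[τ_min, τ_max]`;
* **GA** — integer-encoded genetic algorithm, tournament selection, uniform
  crossover (fraction 0.8), 5 % elitism, per-gene mutation `1/E`;
* **PSO** — particle swarm in `[0,1]^E` with nearest-option decoding,
  cognitive 0.8, social 1.25, linearly decaying inertia.

Campaigns run 10 independent repetitions (population 100, 500 iterations
each, derived seeds) and keep the best feasible run. A scenario engine
applies stress transformations (COD ×10, distances ×10 or √d, volumes ×3,
C/N re-sampling into [50, 60]), and reporting utilities produce per-receptor
blending profiles, 20-tonne truck schedules over the 20-day retention time,
and hyper-parameter trimming sweeps. The Besòs river-basin case study
(19 generators, 3 receptors) ships with the package; a seeded synthetic
generator produces structurally similar instances for testing.

## Worked example

```bash
ancdnet optimise --data besos --algorithm pso \
    --population 100 --iterations 500 --repetitions 10 --seed 7 --out run/
```

prints (and writes to `run/summary.json`, with the winning allocation in
`run/allocation.json`):

```json
{
  "algorithm": "pso",
  "seed": 7,
  "feasible": true,
  "mean_best_b": 8.154474385358824,
  "best_index_b": 8.3338258682484,
  "total_biogas_nm3_d": 7713.281200000001,
  "avg_organic_load_kg_cod_m3_d": 3.8507854542168487,
  "avg_cn_ratio": 59.423119342544744,
  "avg_alkalinity_mg_l": 4244.523076923077,
  "organic_load_approximate": true,
  "organic_load_R1": 4.051639344262295,
  "organic_load_R2": 3.20472602739726,
  "organic_load_R3": 4.295990990990991
}
```

Reading: the best of ten PSO repetitions scored `B = 8.33` (mean 8.15 across
repetitions — index magnitudes depend on the shipped coefficient family and
are comparable between runs of this package, not across other
implementations). The blend ships roughly 7,700 Nm³ of biogas per day, every
receptor's feed sits inside the safe windows (network C/N 59.4, alkalinity
4,245 mg CaCO₃/L), and organic loading rates are 3.2–4.3 kg COD/(m³·d)
against digester volumes approximated from the 20-day retention time
(`organic_load_approximate`). Post-process the allocation with
`ancdnet profile` (per-receptor blend fractions) and `ancdnet schedule`
(truck loads per route and cycle); `ancdnet benchmark` runs the scenario ×
algorithm battery and `ancdnet synth` generates synthetic datasets.

The same pipeline is available as a library:

```python
import ancdnet as an

net = an.load_baseline()
campaign = an.run_campaign(net, an.SolverConfig(algorithm="aco", seed=1))
result = an.evaluate(campaign.best.best_allocation, net)
print(result.b_abs, result.biogas_total, result.avg_cn)
```

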