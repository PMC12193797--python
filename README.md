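# luces

Coupled land-use scenario simulation and ecosystem-service trade-off
analysis on raster landscapes, written for landscape ecologists and
ecosystem-service modellers who need a fully scripted, seed-reproducible
version of the common MOP → patch-CA → InVEST-style → Spearman/GWR
workflow — including a synthetic-landscape generator so every stage can
be exercised and tested without proprietary regional rasters.

## What it computes

**Land-use demand (structure).** Per-class 2030 areas come from either a
Markov projection of the observed decadal transition matrix (natural
increase, NIS) or a linear program over areas x₁..x₆ (ha: cropland,
woodland, grassland, water, built-up, unused) and population P (10⁴
persons):

- ecological protection (EPS): max f₁(x) = 0.5x₁ + 2.72x₂ + 1.55x₃ + 16.12x₄ − 1.58x₅ + 0.08x₆
- economic development (EDS): max f₂(x) = 12.88x₁ + 0.79x₂ + 7.74x₃ + 7.10x₄ + 785.85x₅ + 0.001x₆

subject to Σxᵢ = S_total, a population bracket, a food-security constraint
(P·10⁴·141.2·1.1411 ≤ x₁·4316.24·1.11·0.67), per-class planning brackets,
per-capita built-up demand (P·10⁴·0.0109 ≤ x₅), and ecological land
(x₂+x₃+x₄) ≥ 0.75·S_total. Solved exactly with HiGHS.

**Spatial allocation (pattern).** A two-stage patch-generating procedure:
expansion cells per class are mined from a dated map pair and a random
forest on driver rasters yields growth-suitability surfaces; a cellular
automaton with roulette competition over suitability × neighbourhood ×
adaptive inertia, plus random patch seeding with a decaying threshold,
converts cells until class counts meet demand. Map agreement is scored by
overall accuracy and Cohen's kappa.

**Ecosystem services (per cell).** Water yield Y = (1 − AET/P)·P;
carbon stock C = C_above + C_below + C_soil + C_dead by class lookup;
habitat quality Q = H_j·(1 − Dᶻ/(Dᶻ + kᶻ)) with distance-decayed threat
degradation D; soil retention A = R·K·LS·(1 − C·P) with helpers for
rainfall erosivity (R = a·P^b) and the LS factor (D8 flow accumulation).

**Trade-offs/synergies.** Spearman rank correlation between services over
grid sample units (ρ > 0 synergy, ρ < 0 trade-off) and geographically
weighted regression Y_i = β₀(U_i,V_i) + Σ β_k(U_i,V_i)X_ik + ε_i with
AICc-optimised bandwidth; local slopes are classified into strong/weak
synergy/trade-off maps.

Six scenarios cross the three demand pathways with two climate forcings
(RCP4.5/RCP8.5); climate enters only the service stage.

## Worked example

```bash
python examples/02_demand_optimization.py
```

prints the two demand optima side by side (ha):

```
                  EPS         EDS
cropland   2126060.65  2277958.84
woodland   5522431.16  5413076.08
grassland  2979666.28  2920662.98
water       164919.00   146419.93
built_up    332112.95   367072.21
unused       15849.30    15849.30

EPS: objective 22,837,549.6 million CNY, P = 2127 x10^4 persons
  binding: woodland_upper, grassland_upper, water_upper, built_up_lower, ...
```

Under ecological protection the ecological classes sit at their upper
planning bounds and built-up at its lower bound, with cropland absorbing
the residual area; economic development reverses the pattern, pushing
built-up (the highest-value class) to its ceiling. The remaining examples
(`examples/01…06`) walk through landscape generation, allocation,
services, trade-off mapping, and the full six-scenario pipeline; each
prints its results with a line on how to read them. A thin CLI mirrors
the pipeline (`luces synth|demand|run|report`).

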