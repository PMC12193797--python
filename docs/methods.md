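# Methods

This note documents the models implemented in `luces`, the defaults they
ship with, and what the synthetic landscapes do and do not establish.

## Demand stage

**Markov projection.** The decadal transition matrix is cross-tabulated
from two dated categorical maps (entries in hectares, diagonal =
persistence). Its row-stochastic form `P` projects areas forward,
`a_{t+1} = a_t P`; rows with zero source area are treated as identity
rows, and projecting demand out of a class never observed as a source is
an error. Total area is conserved to machine precision by construction.

**Linear programs.** Decision variables are the six class areas (ha) and
population (10⁴ persons). The policy constraint table is a dataclass
(`ConstraintParams`) whose defaults encode the study region's 2030
planning envelope; bound pairs are treated as unordered {lo, hi} sets
and sorted, so a table transcribed with reversed brackets still builds a
well-formed program (an error is raised only if a pair cannot be
ordered). Per-capita coefficients (food demand 141.2 kg·person⁻¹·yr⁻¹,
built-up 0.0109 ha·person⁻¹) apply to P·10⁴ since P is measured in
10⁴ persons — with P applied raw, the built-up bracket (~332,000 ha)
could never bind, so the scaled form is the only consistent reading.
The ecological-land constraint is implemented as x₂+x₃+x₄ ≥ 0.75·S_total
("at least 75%"); with ≤ the ecological-protection program would be
infeasible against its own class brackets. The LP is solved with HiGHS
(exact simplex); the returned vertex is machine-checked against every
constraint at 10⁻⁶ relative tolerance and binding constraints are
labelled. Infeasibility triggers a greedy deletion filter that reports
an irreducible infeasible constraint subset.

The woodland bracket anchors to the current woodland area ±1% and the
grassland bracket to the Markov-projected grassland area ±1%
(`ConstraintParams.from_projection`). Optima are reported at 2-decimal
precision; no integer variables are used.

## Allocation stage

**Expansion mining.** For class k, positives are cells with `t0 ≠ k` and
`t1 = k`; negatives are an equal-sized uniform draw from cells that did
not become k (balanced sampling keeps the classifier's probability scale
comparable across classes). Classes without expansion cells are flagged
static and receive a zero suitability surface. Suitability is the
positive-class probability of a random forest (default 100 trees,
unlimited depth, fixed `random_state`) evaluated at every cell; driver
importances are exposed for recovery checks.

**Cellular automaton.** Demand is expressed in cells and must sum to the
number of valid cells. Each iteration converts at most
`rate × remaining gap` cells per deficit class (default rate 0.25) so
that neighbourhood effects can propagate between iterations, producing
patch-like growth rather than a single batch paint. Candidate cells are
drawn by weighted sampling without replacement (Gumbel top-k) with
weight = suitability × neighbourhood fraction × inertia, where the
neighbourhood fraction is the share of same-class cells in the Moore
window (default 3×3, centre excluded, border-normalised). Cells with no
same-class neighbour may enter only as random patch seeds: each
iteration a 10% Bernoulli mask of cells with suitability above the seed
threshold τ becomes seed-eligible, and τ decays geometrically (τ₀ = 0.5,
δ = 0.9). Inertia starts at 1 per class and, whenever a class's absolute
demand gap fails to shrink between iterations, is multiplied by the
successive gap ratio (boosting deficit classes, damping surplus ones),
clipped to [10⁻³, 10³]. Donor cells must belong to a surplus class and
the 6×6 allowed-transition matrix must permit the conversion (default:
everything allowed except water → unused). Two pragmatic rules keep the
top-down demand authoritative: a static deficit class (all-zero
suitability) falls back to a uniform suitability of 0.5, and if no
positively weighted donor remains for a deficit class the draw falls
back to an unweighted one over convertible donors. Convergence means
every class is within max(1 cell, 0.1%) of demand; non-convergence at
`max_iter` (default 200) returns the best map with a warning flag.

**Agreement.** Overall accuracy and Cohen's kappa are computed from the
6×6 confusion matrix; the implementation is cross-checked against
scikit-learn's independent computation in the test suite.

## Ecosystem services

**Water yield** is the annual balance P − AET in mm, floored at zero
(negative annual yield is physically meaningless); cells with P = 0
yield 0 without division. The full Budyko-type curve is out of scope
because AET rasters are inputs here.

**Carbon stock** sums four pools per class (t/hm²) with an optional
per-class multiplicative climate-correction factor (default 1) as a
hook for precipitation/temperature density adjustment. The shipped
table (`SYNTHETIC_CARBON_TABLE`) is a synthetic placeholder with
field-typical magnitudes for subtropical plateau systems, not a
calibrated dataset.

**Habitat quality** uses the half-saturation form
Q = H_j·(1 − Dᶻ/(Dᶻ + kᶻ)), the canonical monotone-decreasing response
of quality to degradation (z default 2.5; k defaults to half the
observed maximum degradation of the run, both configurable).
Degradation accumulates over *all* threat-source cells with a linear
(1 − d/d_max) or exponential (e^(−2.99·d/d_max), truncated at d_max)
distance decay, weight-normalised across threats and scaled by the
exposed cell's sensitivity and accessibility β (default 1). The
implementation is an FFT convolution of the source indicator with the
sampled decay kernel; a brute-force O(N²) pairwise oracle is kept in
the package for verification and agrees to < 10⁻⁹ on small grids.
Default threats are cropland (weight 0.6, 2 km, linear) and built-up
(weight 1.0, 5 km, exponential) with placeholder sensitivities.

**Soil retention** is RUSLE potential retention A = R·K·LS·(1 − C·P);
C·P > 1 anywhere is rejected. Erosivity defaults to the annual power
law R = 0.0534·P^1.6548 (a common annual-scale regression for humid
subtropical monsoon climates; both coefficients configurable). The LS
factor uses steepest-descent (D8) flow accumulation with
LS = (A_s/22.13)^0.4·(sin θ/0.0896)^1.3 and a small slope floor
(0.057°) so flat terrain yields a minimal positive constant instead of
zero.

## Trade-off analysis

Services are averaged over square sample units (units with < 50% valid
cells dropped; centroids recorded). Spearman ρ is computed as the
Pearson correlation of average ranks — exactly the tie-averaged rank
formulation — with a two-sided t-approximation for p-values and no
multiple-testing correction; zero-variance columns are flagged
undefined rather than silently dropped.

GWR solves a weighted least-squares problem at every sample with
adaptive bisquare (default), fixed Gaussian, or uniform kernel weights.
`bandwidth="auto"` minimises the corrected AIC
(n·ln(σ̂²) + n·ln 2π + n(n + tr S)/(n − 2 − tr S)) by golden-section
search over neighbour counts (adaptive) or distance (fixed). Singular
local designs are flagged and their coefficients set missing; with a
uniform kernel and unbounded bandwidth the estimator reproduces global
OLS exactly, which serves as the oracle in tests. Local slopes are
classified into strong/weak synergy (≥ 0) and trade-off (< 0) with the
strong/weak split at the median absolute slope; for each pair the
second-named service is the response by convention (configurable). A
zero slope is binned as weak synergy, which makes the classification
antisymmetric under response negation for nonzero slopes.

## Synthetic landscapes

The generator emulates a plateau mountain–basin region: terrain is
standardised spectral (Fourier) noise with power-law falloff — the
autocorrelation length maps to the spectral cutoff — scaled to a base
elevation of 1500 m and 1200 m of relief; slope is the central-difference
gradient in degrees. Precipitation combines the regional mean, a
north→south trend (300 mm amplitude), an orographic lapse
(0.25 mm·m⁻¹), and autocorrelated noise (σ = 60 mm), clipped at zero
with a log message; temperature uses a −6.5 °C·km⁻¹ lapse; AET is a
smooth fraction field of precipitation (mean 0.6, σ 0.1, clipped to
[0, 1]) so AET ≤ P holds cellwise by construction. Population density
and GDP are lognormal-like surfaces concentrated in low, flat terrain.
Climate means default to 851.55 mm / 16.55 °C (moderate forcing) and
1080.60 mm / 16.47 °C (high forcing).

The initial land-cover map is built by sequential rank-thresholding of
driver-weighted latent fields (rarest, most driver-bound classes claim
cells first), which hits the target class fractions exactly up to
integer rounding; defaults follow the regional composition (woodland
0.4908, grassland 0.2684, cropland 0.2023, built-up 0.0234, water
0.0131, unused 0.0020). The later map applies ordered change rules —
by default built-up grows 30% along population density, water 8%
toward low elevation, cropland 2% toward low slope — each selecting its
top-scoring convertible cells by driver value plus a neighbourhood
bonus and a small seeded noise term. The rules are returned as ground
truth, so expansion mining and allocation can be tested for recovering
the generating driver ordering.

One integer seed determines everything; per-artifact sub-streams
(terrain, climate, socio-economic, land-cover, change) are derived
deterministically so regenerating one artifact never perturbs another.

What the synthetic landscapes do *not* emulate: hydrologically
consistent drainage (terrain is spectral noise, not fluvially carved),
real CRS reprojection chains, anisotropic urban form, multi-date
climate trends, or calibrated biophysical parameters. Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms — demand satisfied, oracles matched, invariants held — not
the realism of any particular regional magnitude.

## Orchestration and problem sizes

The pipeline default grid is 200×200 cells at 30 m with a 300 m
trade-off sampling unit — chosen so the synthetic domain (6×6 km)
yields ~400 GWR samples, since a kilometre-scale unit appropriate for a
111,400 km² region would leave too few units on a synthetic extent.
Expansion sampling uses fraction 0.5 and 50 trees in pipeline runs.
Scenario reports serialise with sorted keys and are byte-identical
across reruns with the same configuration and seed; the config hash in
each report fingerprints the generating settings. Climate scenarios
modify only the service stage inputs, so the allocated land-use map is
shared between the two forcings of a land pathway by construction.

## Known limitations

- The CA is a single-resolution, single-thread implementation; it is
  not a bit-level reproduction of any published patch-generating tool.
- GWR is plain (single-bandwidth); multiscale variants are out of scope.
- Carbon, habitat and RUSLE lookup tables are placeholders labelled
  synthetic; regional studies must supply calibrated biophysical tables.
- The demand LP treats coefficients as certain; no goal programming or
  Pareto enumeration is attempted.
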