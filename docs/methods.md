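# Methods

## Model

The dispersal is modelled as a front that leaves one origin cell at time `t₀`
(cal BP) and propagates over a friction surface. The surface is a projected
raster (square cells, km) of K terrain classes; class `k` has a dimensionless
cost `c_k ≥ ε` and local front speed `v_k = v₀ / c_k` for base speed `v₀`
(1 km yr⁻¹ by default). Accumulated weighted distance `D` from the origin is
the single-source shortest path on the 16-direction grid graph — orthogonal,
diagonal and knight's moves with geometric lengths 1, √2 and √5 cells — with
edge weight `euclid · cellsize · (c_a + c_b)/2` between adjacent cells. The
knight's-move edge uses the mean of its two endpoint frictions only; GIS
implementations that average over the cells swept by the move differ at
second order at per-biome cost granularity, and the simple rule is exactly
reproducible by an independent edge-list oracle. Simulated arrival at a site
is `t = t₀ − D/v₀`; predictions beyond the present (t ≤ 0) are kept, with a
warning, so the fitness surface stays continuous.

Assumptions worth keeping in mind: the front is purely terrestrial (no sea
legs), friction is constant in time, class geometry is static, and `t₀` and
the origin are treated as known (configurable) rather than fitted.

## Observations

A ¹⁴C determination `a ± σ` is calibrated with the Gaussian-combination
likelihood `p(t) ∝ exp(−(a − μ(t))² / 2(σ² + σ_curve(t)²))` on a 1-calendar-
year grid spanning the curve; 1 yr is far below dating noise, so finer grids
change medians by well under a year (checked against 0.1-yr quadrature). The
summary statistic is the median, defined as the smallest grid age with
cumulative probability ≥ 0.5 — a deterministic tie-break on plateaus. Sites
contribute, by default, their earliest (largest median) included date; the
`all_dates` mode keeps every included determination. Determinations outside
the curve support are errors, sites outside the raster or on unreachable
cells are excluded from the fitness and counted, never imputed.

## Optimisation

The fitness of a cost vector is the RMSE (years) between simulated arrivals
and observed medians over usable sites. The genetic algorithm uses the
published settings throughout: population 500 initialised gene-wise from
N(1, 1); truncation selection of the best 250; elitism of the best 50 (so the
best-RMSE trace is non-increasing by construction, and elites are not
re-scored — their fitness is deterministic); uniform crossover (each gene
from either parent with probability ½) between parent pairs drawn uniformly
without replacement per pairing; with probability 0.2 a child gets one
uniformly chosen gene perturbed by a standard-normal draw; 20 generations
after the initial evaluation (≈ 9 500 evaluations). Genes are clamped to
ε = 0.01 after initialisation and mutation: N(1,1) puts ~16 % of initial mass
at or below zero, and non-positive friction has no shortest-path meaning
(it would be infinite local speed). Fitness ties break by stable insertion
order; one seeded `numpy` Generator is threaded through every stochastic
step, so a fixed seed gives a bit-identical trace and result.

Design choices that were genuinely open: mutation probability is interpreted
per child (not per gene), matching the wording "one of the parameters is
changed"; crossover is uniform as the simplest scheme in which each parent
contributes a subset of its genes; parent pairing is uniform over the
selected pool so the selection pressure is purely truncation-based.

## Synthetic worlds and what they show

The generator builds a banded raster traversed west→east — K vertical bands,
by default four bands of 50 columns on a 100×200 grid of 20 km cells,
matching the ~4 000 km west–east extent of the real corridor — with true
band speeds 0.4, 0.8, 1.5, 2.0 km yr⁻¹ spanning mountain-slow to
tropical-fast. Sites (default 60) are drawn uniformly over cells; observed
dates are `t₀ − D/v₀` plus Gaussian dating noise (default σ = 100 yr), and
can be back-converted to ¹⁴C ages through an invertible toy curve
(μ(t) = t + 20·sin(t/300), monotone) so the whole calibrate→median→fit path
is exercised. Crucially, the generator computes D with a separate
networkx shortest-path implementation over an explicitly enumerated edge
list, sharing no code with the production numba kernel: recovering the true
speeds therefore cross-checks the production distance computation, not just
the optimiser.

What the synthetic worlds do **not** emulate: realistic biome geometry
(bands, not polygons), clustered site discovery, taphonomic loss,
plateau-ridden real calibration curves, or origin-date uncertainty. Passing
recovery tests shows the machinery is correct and the design identifiable
under those idealisations — not that the real-data speeds are correct.

## Numerical choices and problem sizes

The production Dijkstra is a numba-compiled binary-heap implementation
(~2.5 ms for a 100×200 grid), verified against the networkx oracle to 1e-9
relative error over hundreds of random rasters including nodata holes.
Site→cell lookup is nearest-cell, not interpolated: D is a path quantity and
interpolation across class boundaries is ill-defined. Recovery experiments
use the 100×200 design with five seeds each for the noiseless and noisy
conditions (~5 min total on one CPU); unit tests use a 20×40 world.

Observed behaviour at those conditions: seed-averaged class speeds recover
within 10 % without noise (worst class ≈ 7 %) and within 25 % with 100-yr
noise (worst single run ≈ 20 %). The final noiseless RMSE settles around
10–25 yr (seed-average ≈ 15 yr) rather than collapsing to 0: with
unit-variance single-gene mutations spread over K genes and 20 generations,
the per-gene error floor is a few hundredths of a cost unit, which over
~1 000-km bands translates to tens of years. This is a precision floor of
the published GA scheme itself, not of the distance or scoring code (the
true cost vector scores RMSE 0 exactly).

## Limitations

Latitude-dependent cell areas are out of scope (rasters must be projected to
square km cells; an equirectangular helper covers the synthetic world).
Uncertainty is not propagated from calibration densities into the fit — the
median is the observation, as in the underlying design. The GA returns a
point estimate; rerunning across seeds is the only spread measure provided.
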