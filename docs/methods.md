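# Methods

## The self-avoiding (trail) sampler

The core sampler is a Metropolis–Hastings walker on a 2D lattice with
periodic boundaries.  Proposals add an independent uniform draw from
{−1, 0, +1} to each coordinate, so the nine outcomes of the Moore
neighbourhood (including staying put) are equiprobable and the proposal is
symmetric.  The walker carries no internal memory; instead it maintains an
*externalized* memory M — a per-cell count field initialized to a uniform
Dirichlet prior of `alpha` pseudo-counts per cell and incremented by one at
the walker's cell after every step, accepted or rejected alike.  (The
deposit-after-rejection rule is a deliberate, literal reading of the
update order: decide, then mark the cell you are on.)

The plain variant accepts with probability min(1, P(prop)/P(curr)).  The
trail variant multiplies that ratio by (P(prop)/M(prop)) / (P(curr)/M(curr)),
which makes the chain target P×P/M.  The P² factor sharpens the pull toward
high-probability cells (a cell of mass 0.2 is 4× as attractive as one of
mass 0.1, not 2×); the M divisor repels the walker from ground it has
already marked.  As deposits accumulate where the walker has been, M → P
and the objective relaxes back to P: early steps prioritize discovery,
late steps sample faithfully.

Numerical choices:

- **Lazy normalization.**  M is kept as raw counts.  Any global scale of M
  cancels in the acceptance ratio, so normalizing M to a probability
  distribution every step would change nothing while costing O(cells).
  This is asserted exactly in the tests (a power-of-two rescale of M leaves
  every ratio bit-identical).
- **Zero-mass target cells.**  Sparse gamma targets may contain cells of
  (numerically) zero mass.  Rules: positive → zero proposals are never
  accepted; zero → positive proposals always are; zero → zero is treated
  as ratio 1 (free diffusion on null support).  This keeps a chain started
  on null support from stalling without distorting the kernel elsewhere,
  since a positive-support chain never enters the null region.
- **Tie rule.**  ratio = 1 is accepted through the `ratio > u` branch with
  probability 1 (u is drawn from [0, 1)); acceptance probability is exactly
  min(1, ratio).
- **Cleaning.**  The cleaning condition resets the deposit field to the
  pure prior at given step indices, at the *end* of the named step.  For
  the 60,000-step benchmark the schedule is every 10,000 steps — five
  resets, one after each simulated "ant".  Deposits accumulate normally
  between resets.
- **Decay.**  An optional per-step factor e^(−λ) multiplies the deposit
  excess, modelling marker evaporation.  The prior floor `alpha` never
  decays, so M stays strictly positive; as λ → ∞ the memory collapses to
  the prior each step and the trail kernel reduces exactly to M–H on P²
  (asserted against the enumeration oracle).  Internally the decay is a
  lazy global scale folded into the array before it overflows;
  mathematically identical to per-step multiplication.
- **Reproducibility.**  One seeded generator per chain; proposal offsets
  and acceptance uniforms are pre-drawn indexed by step, so traces replay
  bit-identically from (target, config).

Convergence is tracked by the cross-entropy CE(P, Q) = −Σ P ln Q in nats
(natural logs throughout; the base only rescales curves).  By Gibbs'
inequality CE ≥ H(P) with equality iff Q matches P on its support, so H(P)
is the floor every curve is measured against.  The default estimate Q is
the chain's visit histogram with a Dirichlet pseudo-count of 1 per cell
(`smoothing_alpha`); the normalized memory is available as an alternative
estimator (`ce_estimator="memory"`).  With λ = 0 and no cleaning the two
coincide for the trail variant; they differ under cleaning, where the
memory forgets and the histogram does not.  Cross-entropy itself refuses
zero-mass estimates on the reference's support rather than imputing —
smoothing is always the caller's explicit, visible choice.

## From trajectories to a target distribution

A cohort of tracked exploration bouts (one walker at a time, 0.1 s
sampling, 90 × 90 cm arena, nest at the centre) becomes an empirical target
distribution as follows:

1. **Mask removal.**  Points with max(|x|, |y|) < 75 mm fall under the
   central 15 × 15 cm mask, where walkers linger and edge-follow; they are
   removed.  Boundary points are kept (closed outward).
2. **Log-polar transform.**  (x, y) → (θ, ln r) about the nest, θ ∈ (−π, π],
   ln r in ln-mm.  Points with ln r outside the open interval (4.3, 6.5)
   are dropped and counted (zero-radius points included).  The log-radial
   axis roughly equalizes visit density across radii, which evens out the
   statistical power of later comparisons.  Note the mask cut and the lower
   ln r cut overlap (75 mm ≈ ln r 4.32); both are applied as two explicit
   steps.
3. **Periodic padding.**  Every point is duplicated 2π away in θ (θ ≤ 0
   shifts up, θ > 0 shifts down), extending the space to ≈(−2π, 2π] so the
   blur sees no artificial edge at ±π.
4. **Histogram, blur, truncate, normalize.**  Points are binned to the
   nearest node of a regular lattice — θ nodes at integer multiples of 0.01
   rad (1257 padded nodes), ln r nodes at 4.3 + k·0.0025 (881 nodes) —
   blurred with an isotropic Gaussian of σ = 30 cells, truncated back to
   |θ| ≤ π (629 nodes), and normalized to unit mass.  In physical terms the
   blur widens from ~6 mm near the nest to ~40 mm at the arena edge.  The
   kernel is cut at 4σ and the histogram boundary is zero-padded — the
   periodic θ padding, not the filter mode, is what protects the seam.

Cells beyond 4σ of every data point are exactly zero, so a cumulative
estimate can miss support the final target has.  `cumulative_ce_curves`
therefore mixes each estimate with a uniform floor of mass 1e-9 before the
cross-entropy.  The floor changes CE by far less than 1e-6 nats wherever
the estimate has real mass, and it is a parameter (`smoothing_epsilon`),
set to 0 in the identity tests.

Convergence by release order: for each treatment and colony, walkers
1..k are pooled, the density rebuilt on the same lattice, and compared to
the final (full-cohort) target by CE; per-treatment curves are the
arithmetic mean over colonies with the standard error over colonies.  The
treatment comparison excludes order 1 (the first walker out sees a clean
arena in both treatments) and runs a paired sign-flip permutation test on
the (colony, order) cells of orders 2–6.

### The Markov-ant null

A memoryless benchmark walker is built by resampling: all trajectories are
chopped into non-overlapping 1 s runs of 10 consecutive displacement
vectors, and a null trajectory concatenates uniformly drawn segments from
the nest outward, rejecting and redrawing any segment that would leave the
arena (bounded retries).  The resulting walker preserves the cohort's
short-time movement statistics but has neither internal nor externalized
memory; null "colonies" group six such walkers.

### Exit sides

The first segment crossing a nest-centred square (inside = max-norm ≤ half
width) is interpolated linearly; the side whose boundary is reached at the
smallest interpolation parameter is assigned, with corner ties broken in
the fixed order right, left, top, bottom.  Trajectories that never leave
the square are reported separately, not dropped.  Counts are tested against
uniformity with the chi-square goodness-of-fit statistic Σ(O−E)²/E on k−1
df, and — for the small samples where the χ² approximation is poor — an
exact multinomial test that enumerates all compositions of N into k parts
and sums the probability of every outcome at most as probable as the
observed one (point-probability ordering, with a 1e-12 relative tie
tolerance and an enumeration budget guard).

### Permutation scheme

The design pairs the two treatments by (colony, order) cell, so the test is
a paired sign-flip: statistic = mean within-pair difference, null built by
independently flipping each pair's sign.  All 2^n patterns are enumerated
when 2^n ≤ 2^20 (15 pairs → 32,768 patterns, Monte-Carlo noise eliminated);
otherwise Monte Carlo with the add-one correction p = (1+extreme)/(1+draws).
Two-sided by default.  The scheme, sidedness and count are package choices:
the underlying experimental design is paired by construction, and
exhaustive enumeration is cheap at this n.

## The synthetic cohort generator

The generator exists so every pipeline stage and the treatment contrast are
testable without tracked animal data.  Each walker is a correlated random
walk from the nest: heading persists with von Mises concentration
`turning_kappa` (default 8 per 0.1 s step), speeds are normal
(7 ± 4.5 mm/s, truncated at 0 — a 45 min bout then walks ≈ 19 m, matching
real bout path lengths of ~18 m), walls reflect, and a drift term
`bias_gain · sin(ψ − φ)` pulls headings toward the resultant ψ of the
`quadrant_bias` weights.  The default bias (1, 3, 1, 1) favours the
upper-left quadrant, mirroring the heterogeneous exploration preference
observed in real cohorts.  This shared bias is load-bearing: it is what
makes *uninformed* walkers overlap each other, so that footprint avoidance
has redundancy to remove.  With uniform bias, independent walkers already
decorrelate and the treatment contrast all but vanishes.

Avoidance is stigmergic and sequential: after each walker finishes, its
path is binned onto a 30 mm field grid, blurred with a 60 mm Gaussian
footprint, normalized to mean cell value 1, and added to the colony field.
The next walker's heading is steered down the local field gradient with
torque `avoidance_strength · tanh(|∇F|) · sin(ψ_away − φ)` — bounded,
strongest where the field changes fastest.  The field is static during a
walker's own bout (no self-avoidance), so the coupling is purely
between successive walkers.  Treatment NC lets the field accumulate over a
colony's six releases; treatment C wipes it before every release.  Each
walker's intrinsic randomness comes from a substream keyed by
(seed, colony, order), so matched NC/C cohorts share random numbers and
differ only through the coupling — order-1 walkers are identical across
treatments by construction.

`avoidance_strength = 0.5` (radians/step, max torque) together with the
60 mm footprint is the calibrated planted effect size, chosen once by a
sweep over strengths and footprint widths: at these defaults the paired
permutation test on orders 2–6 rejects in essentially every replicate
cohort pair.

What the generator does *not* emulate: stop-and-go movement events, speed
autocorrelation, thigmotaxis along the mask and walls, returns to the nest
within a bout, pheromone decay, and any self-avoidance within a walker's
own path.  Passing tests therefore show that the pipeline and tests recover
a planted avoidance effect of realistic geometry and magnitude — not that
real ants behave like the generator.

## Problem sizes used in the test suite

Sizes are chosen so the whole suite runs in minutes on one core:

- Sampler convergence checks use 10×10 targets at 2×10⁵ steps; the
  three-way sparse comparison uses the benchmark conditions themselves
  (50×50, gamma shape 0.1, T = 60,000, 20 seeds).
- Synthetic-cohort studies keep the full experimental regime (3 colonies ×
  6 walkers × 45 min at 0.1 s) but evaluate densities on a lattice
  coarsened ×5 (θ step 0.05, ln r step 0.0125, σ = 6 cells — the same
  physical blur width; 125 × 177 truncated nodes).  Treatment power is
  estimated over 20 replicate cohort pairs; type-I error over 1,000
  light exchangeable paired datasets.
- Exact-multinomial oracles enumerate all N ≤ 6, k ≤ 4 cases and one
  N = 200 spot-check against the χ² approximation.

## Known limitations

- At T = 60,000 local-proposal steps on a 50×50 sparse target both
  samplers are still far from convergence (CE ≈ 9–10 nats vs H ≈ 6); the
  trail sampler's advantage is clear in the mean (≈ 0.5 nats) but the
  per-seed win rate against plain M–H is ≈ 0.85, not ≈ 1. Longer runs
  (T = 6×10⁵) separate the methods decisively.  On smaller lattices the
  same budget converges much further and the ordering is sharper.
- The trail kernel is not reversible with respect to a fixed distribution
  while M evolves; all convergence statements here are empirical
  (cross-entropy curves), not spectral.
- The exact multinomial test is O(C(N+k−1, k−1)) and guarded by a budget;
  use the χ² test for large N.
- `markov_ant_resample` can in principle exhaust its retry budget if the
  segment pool contains only outward-bound segments near a wall; the
  bounded-retry error names the stuck position.
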