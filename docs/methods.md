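# Methods

## Model and procedure

The object of inference is a joint confidence region for a pair of
parameters, estimated from an empirical point cloud of n paired values
(xᵢ, yᵢ) — in the intended workflow, bootstrap replicates of the two
estimates. No distributional form is assumed; the only primitive is the
empirical quantile.

**Directional quantile bands.** A reference line through the origin at
angle θ ∈ [0, π) induces the signed perpendicular distances
dᵢ(θ) = yᵢ cos θ − xᵢ sin θ (lines are represented by their unit normal
(−sin θ, cos θ) and an offset, so θ = π/2 needs no special case; θ and
θ + π index the same line, hence the half-open range). The two-sided band
at per-direction level α_t is the slab between the α_t/2 and 1 − α_t/2
empirical quantiles of d(θ). By construction the fraction of points outside
any single band approximates α_t to within the quantile granularity
(enforced in tests at ±2/n).

**Region.** The confidence region is the intersection of the K slabs of an
equally spaced direction grid θ_k = kπ/K — a convex polygon with at most 2K
vertices. It is constructed by Sutherland–Hodgman clipping of a generous
bounding square by each of the 2K half-planes in turn, which is robust to
redundant (inactive) boundaries; the analytic crossover point of two
adjacent active boundary lines (`adjacent_crossover`, a 2×2 linear solve)
is kept as a verification identity rather than used as the constructor,
because adjacent intersections alone generate spurious vertices when a
boundary is inactive.

**Calibration.** The polygon is a conjunction of K simultaneous two-sided
tests, so at α_t = α_d the realized exclusion rate
α_e = #{points outside}/n exceeds α_d (verified across designs in tests).
Since α_t ↦ α_e is non-decreasing, the per-direction level is solved by
bisection on (0, α_d], stopping when |α_e − α_d| ≤ max(tol, 1/n). The
realized rate is a step function of α_t; on the terminal plateau the solver
returns the largest α_t whose realized level does not exceed α_d + tol —
the widest region consistent with the nominal level (conservative
tie-break). Realized α is computed in-sample, on the same points the region
was built from, which is the method's definition of adequacy; the
`coverage_discrepancy` harness records exactly this quantity.

## Numerical choices

- **Quantile convention.** Ascending sort, target rank p(n−1)+1, linear
  interpolation between the bracketing order statistics (identical to
  numpy's default `linear` method; all standard conventions converge for
  large n). Points exactly on a band boundary count as inside, keeping the
  realized level at or below the intended one under ties.
- **Rank stagger in the calibration solver.** With the same interpolated
  rank in every direction, all 2K band boundaries cross data points at the
  same discrete values of α_t (the crossings depend on rank only, not on
  the data), so the realized-α step function jumps by several points at
  once and bisection cannot land within 1/n of the target. The solver
  therefore offsets each direction's quantile rank by a fixed, centred
  sub-rank amount (|offset| < 0.5 rank, i.e. < 1/n in level, drawn from
  golden-ratio and √2 low-discrepancy sequences, one per tail). This
  de-synchronizes the crossings, restoring 1/n granularity, while each
  band's level moves by less than the quantile-definition ambiguity itself;
  runs remain bit-reproducible. The stagger is disabled for K = 1, and the
  user-facing `directional_band` uses the plain convention.
- **Solver constants.** Bisection on [α_d/1000, α_d], default
  tol = max(10⁻⁴, 0.25/n), at most 60 iterations; failure to bracket
  (realized level above target even at the smallest per-direction level)
  raises with diagnostics.
- **Degenerate inputs.** Region construction requires n ≥ 3; calibration
  warns below n = max(20, 4/α_d), where an empirical proportion is too
  coarse for the target. Collinear data yield zero-width bands and a
  zero-area region, reported with a warning rather than an error. An empty
  band intersection (only possible with pathological hand-built bands)
  raises.
- **Canonical output.** Vertices are ordered counter-clockwise starting
  from the smallest angle about the centroid, so outputs are diffable;
  consecutive vertices closer than 10⁻¹² of the coordinate scale are
  merged.

## Baselines

- **Ellipse.** {p : (p − x̄)ᵀ S⁻¹ (p − x̄) ≤ χ²₂(1 − α)} with S the sample
  covariance, discretized to 360 vertices. The χ² (large-sample) scaling is
  used rather than the small-sample F scaling: at the n ≥ 200 of the study
  designs the two are practically identical, and the choice is recorded in
  the CLI report.
- **Convex hull peeling.** Hull layers are removed outside-in
  (scipy's ConvexHull per layer; points on a hull's boundary, including
  non-vertex collinear ones, belong to that layer), stopping before the
  layer whose removal would push the cumulative removed fraction above α.
  Exclusion rates are therefore quantized to whole-layer jumps and never
  exceed α — the structural reason peeling under-covers.

## Simulated designs

The generators define the study conditions under which the method is
validated; all are seeded and bit-reproducible.

- **Design I — bivariate normal.** Means (0, 0), unit variances,
  off-diagonal correlation r_xy ∈ {0, 0.5, 0.9}; configurable.
- **Design II — bivariate noncentral F.** Margins exactly
  F(df1 = 5, df2 = 10, λ = 3) through the exact `scipy.stats.ncf` inverse
  CDF applied to Gaussian-copula uniforms. The latent normal correlation is
  solved with Brent's method so the *output* Pearson correlation hits r_xy;
  the objective is evaluated by 64-node Gauss–Hermite quadrature of
  E[h(z₁)h(z₂)] with h = F⁻¹∘Φ approximated on a 3001-point monotone
  interpolant (the interpolant is used only inside the solver, never for
  sampling). Unattainable r_xy raises with the feasible range.
- **Design III — normal mixture.** Equal-weight mixture of components at
  (0, 0) and (4, 4) with per-component correlation r_xy. Note the *overall*
  correlation exceeds r_xy because the component separation lies along the
  diagonal.
- **AR(1) variant.** Any design's iid standard-normal innovations are
  replaced by a stationary AR(1) recursion z_t = φz_{t−1} + √(1−φ²)e_t, so
  marginal distributions are preserved while draws become serially
  dependent (emulating, e.g., MCMC output); φ = 0 reproduces the base
  sampler draw-for-draw.

What the generators do *not* emulate: real bootstrap clouds' discreteness
(atoms from resampling small data sets), heavy ties, or non-stationary
dependence. Passing tests therefore demonstrate correct behaviour for
continuous, at-most-AR(1)-dependent clouds; very small or heavily tied
inputs trigger the warnings above instead of silent miscoverage.

## Study scale and defaults

Default direction count K = 100 (K ≥ 8 already shows full multiplicity
inflation; calibrated realized levels are stable in K — asserted in tests
for K ∈ {4, 16, 100}). The built-in coverage study defaults to reps = 3,
n = 2,000, K = 72 over the seven-level grid
α ∈ {0.005, 0.01, 0.025, 0.05, 0.1, 0.2, 0.5}, which keeps a full
three-design run in the minutes range; the headline realized-α checks run
at n = 10,000. Larger grids are a config-file edit away
(`distfreecr evaluate --config study.yaml`).

## Known limitations

- Two dimensions only; the directional-band idea extends to d ≥ 3
  (half-spaces replacing half-planes) but is not implemented.
- The region is convex by construction: strongly concave clouds (e.g.
  ring-shaped densities) are covered but not tightly described; kernel-
  density or data-depth regions are out of scope.
- Realized α is an in-sample quantity. It validates the construction, not
  out-of-sample coverage of a future draw; for that, the study harness can
  be pointed at fresh samples from the same design.
- Calibration on heavily tied data may not reach the 1/n contract; the
  solver then warns and returns the conservative plateau end.
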