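# distfreecr

Distribution-free joint confidence regions for two parameters, built from a
point cloud — typically bootstrap replicates of two estimates — with no
assumption about the sampling distribution.

## Who this is for

Joint inference about a parameter *pair* (two regression coefficients, two
principal-component scores, two genotype effects, …) needs a confidence
*region*, not two marginal intervals. The classical region is the
normal-theory ellipse, which misrepresents skewed or multimodal clouds and
realizes the wrong exclusion rate on them. `distfreecr` constructs a region
from the data's own shape using only empirical quantiles and convex
geometry.

## The method

Given n points (xᵢ, yᵢ) and a desired significance level α_d:

1. **Directional projection.** For each of K reference-line directions
   θ_k ∈ [0, π), compute the signed perpendicular distances
   dᵢ = yᵢ·cos θ − xᵢ·sin θ of all points to the line through the origin at
   angle θ.
2. **Quantile band.** Cut the two-sided empirical band between the α_t/2
   and 1 − α_t/2 distance quantiles — a slab bounded by two lines parallel
   to the reference line, leaving ≈ α_t of the points outside in that
   direction.
3. **Polygon.** Intersect the K slabs: a convex polygon with at most 2K
   vertices (the crossover points of adjacent boundary lines).
4. **Calibration.** The polygon is a conjunction of K simultaneous tests,
   so its realized exclusion rate α_e (the fraction of points outside)
   exceeds α_t. Solve α_t by bisection so that α_e matches α_d to within
   max(tol, 1/n).

Baselines for comparison (the normal-theory ellipse scaled by the χ²₂
quantile, and convex-hull peeling), seeded samplers for three bivariate
study designs (normal, noncentral F via a Gaussian copula, normal mixture,
each with an AR(1) variant), and a coverage-discrepancy study harness are
included.

## Worked example

`examples/02_compare_region_methods.py` draws 5,000 points from a skewed
bivariate noncentral-F distribution and builds a 95% region with each
method:

```
nominal alpha = 0.05, n = 5000 (noncentral F, r_xy = 0.5)
distfree  realized alpha = 0.0500  area =   58.409  chi2(1) =    0.00  p = 1
ellipse   realized alpha = 0.0612  area =   50.750  chi2(1) =   13.20  p = 0.000279
peel      realized alpha = 0.0452  area =   60.155  chi2(1) =    2.43  p = 0.119
```

The calibrated polygon leaves exactly 5.00% of points outside (the
chi-square coverage test finds no deviation from nominal); the ellipse
excludes 6.12% — significantly off — because it cannot follow the skewed
shape; hull peeling under-covers because it can only remove whole hull
layers. The other scripts in `examples/` show the bootstrap workflow for
regression coefficients, a scaled-down coverage study over all three
designs, and the simulators themselves.

A thin CLI mirrors the library:

```sh
distfreecr simulate --design II --n 5000 --r 0.5 --seed 3 --out pts.csv
distfreecr region --in pts.csv --alpha 0.05 --directions 100 \
    --out polygon.csv --wkt --report report.json
distfreecr test-coverage --outside 306 --n 5000 --alpha 0.05
```

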