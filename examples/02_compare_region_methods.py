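"""Distribution-free polygon vs ellipse vs hull peeling on skewed data.

Draws a right-skewed bivariate noncentral-F sample, builds a 95% region
with each method, and compares realized exclusion rates.  The chi-square
coverage test quantifies how far each realized rate is from nominal.
"""

from distfreecr import (
    SimDesign,
    chisq_coverage_test,
    confidence_region,
    convex_hull_peeling_region,
    ellipse_region,
    realized_alpha,
    sample_bvf,
)

alpha = 0.05
pts = sample_bvf(SimDesign(design="noncentral_F", n=5000, r_xy=0.5, seed=3))

regions = {
    "distfree": confidence_region(pts, alpha_d=alpha, K=100),
    "ellipse": ellipse_region(pts, alpha=alpha),
    "peel": convex_hull_peeling_region(pts, alpha=alpha),
}
print(f"nominal alpha = {alpha}, n = {pts.n} (noncentral F, r_xy = 0.5)")
for name, reg in regions.items():
    ra = realized_alpha(pts, reg)
    m = round(ra * pts.n)
    stat, p = chisq_coverage_test(m, pts.n, alpha)
    print(f"{name:9s} realized alpha = {ra:.4f}  area = {reg.area:8.3f}  "
          f"chi2(1) = {stat:7.2f}  p = {p:.3g}")
# the polygon tracks the skewed shape and hits the nominal rate; the
# normal-theory ellipse misses both the shape and (slightly) the rate
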