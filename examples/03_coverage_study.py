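"""A scaled-down coverage-discrepancy study across the three designs.

For each design and nominal level, draws replicates, builds regions with
each method and records realized-minus-nominal discrepancies — the
adequacy metric for comparing region constructions.
"""

from distfreecr import SimDesign, coverage_discrepancy

designs = [
    SimDesign(design="normal", n=2000, r_xy=0.5, seed=1),
    SimDesign(design="noncentral_F", n=2000, r_xy=0.5, seed=1),
    SimDesign(design="normal_mixture", n=2000, r_xy=0.5, seed=1),
]
df = coverage_discrepancy(
    designs, methods=("distfree", "ellipse", "peel"),
    alphas=(0.005, 0.05, 0.2, 0.5), reps=3, K=72,
)
table = (
    df.groupby(["design", "method", "alpha_nominal"]).discrepancy.mean()
    .unstack().round(4)
)
print("mean coverage discrepancy (realized - nominal), 3 replicates, n=2000")
print(table)
# distfree stays within 1/n of zero everywhere; the ellipse over-covers
# skewed data at small alpha and under-covers at large alpha; peeling is
# always <= 0 because whole hull layers are excluded at a time
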