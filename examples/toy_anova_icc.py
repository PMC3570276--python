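"""Hand-checkable ANOVA ICC and design effect on three tiny clusters.

Three clusters of three subjects each — {1,1,1}, {1,0,0}, {0,0,0} — give a
one-way ANOVA with MSB = 7/9 and MSW = 1/9, hence F = 7 and an intraclass
correlation of 2/3; the unweighted cluster proportions (1, 1/3, 0) around
the pooled prevalence 4/9 give a design effect of 2.8.
"""

from clustericc import ClusterSummary, anova_icc, design_effect, ratio_estimator

groups = [[1, 1, 1], [1, 0, 0], [0, 0, 0]]
summaries = [ClusterSummary(str(i), len(g), sum(g)) for i, g in enumerate(groups)]

icc = anova_icc(groups)
deff = design_effect(summaries)

print(f"pooled prevalence r = {ratio_estimator(summaries):.4f}")
print(f"F = {icc.F:.1f}  (MSB = {icc.msb:.4f}, MSW = {icc.msw:.4f})")
print(f"ICC = {icc.rho:.3f}  95% CI [{icc.ci_low:.3f}, {icc.ci_high:.3f}]")
print(f"DEFF = {deff.deff:.1f}  (var_actual = {deff.var_actual:.5f}, var_SRS = {deff.var_srs:.5f})")
print()
print("An ICC of 0.667 means two-thirds of the outcome variance sits between")
print("clusters; DEFF = 2.8 means this cluster sample is as informative as a")
print("simple random sample 2.8x smaller.")
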