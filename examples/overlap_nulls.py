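"""The overlap null models on a small worked instance.

Computes the probability that fixed-size random subsets of a finite pool
intersect at least as much as observed — the null for clonal sharing —
three ways: hypergeometric closed form (2 sets), exact fold (any number
of sets), and Monte-Carlo random draws.
"""

import clonetrace as ct

# two sets: 4-subset vs 5-subset of a 10-element pool, 3 shared
res = ct.hypergeom_overlap_p(N=10, nA=4, nB=5, k=3)
print(f"2-way: P(|A∩B| >= 3) = {res.p_value:.5f}  (= 66/252)")

# three sets: the exact fold and the Monte-Carlo estimate agree
exact = ct.multiway_overlap_p_exact(12, (5, 6, 7), 2)
mc = ct.multiway_overlap_p_mc(12, (5, 6, 7), 2, M=200_000, seed=0)
print(f"3-way exact: P = {exact.p_value:.5f}")
print(f"3-way Monte-Carlo: P = {mc.p_value:.5f} +/- {mc.mc_se:.5f} "
      f"(M={mc.iterations:,})")

# the tail is monotone in the observed overlap
for k in (0, 1, 2, 3, 4, 5):
    p = ct.multiway_overlap_p_exact(12, (5, 6, 7), k).p_value
    print(f"  k={k}: p = {p:.3g}")
print("-> larger observed intersections are ever less likely by chance.")
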