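"""Clonal barcode tracking on a simulated transplantation.

Simulates 400 barcoded clones (30% tripotent) sampled into three sorted
populations at 50k reads each with 0.5% sequencing error, recovers the
barcodes, and tests whether the three populations share more clones than
chance. A small 3-way p-value means single clones feed all three
compartments — the bipotency signature.
"""

import clonetrace as ct

whitelist = ct.make_whitelist(n=725, seed=1)
cfg = ct.CloneSimConfig(seed=2)
clones = ct.simulate_clones(cfg, whitelist)
reads = ct.simulate_reads(clones, cfg.depths, cfg.error_rate, seed=3)

table = ct.count_barcodes(reads, whitelist=whitelist)
print(table.qc_summary(), end="\n\n")

sets = {s.sample: s.barcodes for s in ct.depth_floor_filter(table)}
union = frozenset().union(*sets.values())
print("barcodes per population:", {k: len(v) for k, v in sets.items()})
print("Venn regions:", ct.venn_counts(sets), end="\n\n")

two_way = ct.hypergeom_overlap_p(
    N=725, nA=len(sets["MB"]), nB=len(sets["EB"]),
    k=len(sets["MB"] & sets["EB"]), labels=("MB", "EB"),
)
print(f"2-way MB/EB overlap: k={two_way.k} of pool 725, "
      f"p = {two_way.p_value:.3g} (hypergeometric)")

k3 = len(sets["NMP"] & sets["MB"] & sets["EB"])
mc = ct.multiway_overlap_p_mc(
    len(union), [len(sets[p]) for p in ("NMP", "MB", "EB")], k3,
    M=1_000_000, seed=4,
)
exact = ct.multiway_overlap_p_exact(
    len(union), [len(sets[p]) for p in ("NMP", "MB", "EB")], k3)
print(f"3-way overlap: k={k3} of union pool {len(union)}, "
      f"Monte-Carlo p = {mc.p_value:.3g} (M={mc.iterations:,}), "
      f"exact p = {exact.p_value:.3g}")
print("-> p far below 0.001: the three compartments share clones, "
      "i.e. single barcoded cells are multipotent.")
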