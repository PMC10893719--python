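"""Simulate a planted case/control cohort and inspect its ground truth.

The generator emulates a merged two-batch microarray cohort on the log2
scale: a global disease signature shared by every case, plus one disjoint
differentially-expressed gene block per molecular subtype.
"""

import igansub as ig

cfg = ig.SimConfig(n_case=90, n_ctrl=12, n_genes=2000, seed=1)
expr, ann, truth = ig.generate_cohort(cfg)

print(f"expression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples")
print(ann.groupby(["group", "batch"]).size().rename("n").to_string())
print("planted subtype sizes:",
      truth.true_subtype.value_counts().sort_index().to_dict())
print("global DE block:", len(truth.true_global_de), "genes;",
      "per-subtype blocks:",
      {s: len(g) for s, g in truth.true_de_genes.items()})
# Each subtype block is shifted by the full effect in its own subtype and
# by half the effect case-wide, so subtype markers also surface in the
# global case-vs-control screen -- the structure the intersection rule
# for subtype-specific genes relies on.
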