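"""Expression-bias pathway activity scores per subtype.

For each gene in a pathway, |case mean - control mean| / control SD; the
pathway's score in a subtype is the mean over its genes, and a one-way
ANOVA on the per-gene values tests for score differences across subtypes.
"""

import igansub as ig

expr, ann, truth = ig.generate_cohort(ig.SimConfig(n_case=90, n_ctrl=12,
                                                   seed=1))
adjusted = ig.adjust_batches(expr, ann)
cases = ann.loc[ann.group == "case", "sample_id"].tolist()

sets = ig.generate_gene_sets(truth, n_null_sets=3, set_size=50, seed=0)
tab = ig.subtype_pathway_table(adjusted, ann, truth.true_subtype.loc[cases],
                               sets)
for name in sets:
    sub = tab[tab.pathway == name].set_index("subtype")
    scores = {s: round(v, 2) for s, v in sub["score"].items()}
    print(f"{name:18s} scores {scores}  ANOVA p = {sub['p'].iloc[0]:.2e}")
# Each signal pathway scores highest in its own subtype (the planted
# dysregulation); null pathways sit near the noise floor with flat ANOVA.
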