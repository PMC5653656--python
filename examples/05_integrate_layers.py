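"""Relate site-level regulatory classes to gene-level expression classes.

Builds a genome context where cis-class genes receive extra cis-class sites
in their TSS window (20 kb upstream / 10 kb downstream), then runs the
logistic enrichment regression and the per-gene Shannon diversity of
mechanisms.
"""

from cistrans import integrate as integ
from cistrans.simdata import SimConfig, simulate_genome_context

fs = simulate_genome_context(SimConfig(seed=51), n_genes=300, n_sites=1500,
                             planted_extra={"cis": 3})
genes = integ.assign_sites_to_genes(fs.sites, fs.genes)

res = integ.logistic_enrichment(genes, "cis").set_index("predictor")
print("logistic regression: gene-expression class 'cis' on per-class "
      "site counts")
for pred, row in res.iterrows():
    flag = " *" if row["significant"] else ""
    print(f"  {pred:13s} OR = {row['odds_ratio']:.2f}  Z = {row['z']:+.2f}{flag}")

div = integ.diversity_by_expression_class(genes)
print("\nmedian Shannon diversity of site mechanisms per gene class:")
print(div["diversity"].groupby("class")["H"].median().round(3).to_string())
print()
print("An odds ratio > 1 with |Z| > 2 on the cis-count predictor recovers "
      "the planted association: genes whose expression is cis-driven carry "
      "more cis-class sites near their TSS.")
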