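"""Integrate methylation with expression: clusters, GSEA, tiered overlap.

Genes carrying >5 intragenic DMRs form "DMR clusters"; in the
simulation those clusters are hypomethylated and coupled to induction
(probability 0.8 vs a 0.1 background rate).  The integration recovers
that coupling three ways: cluster detection, a GSEA running sum of
induced genes along the DMR-count ranking, and overlap fractions that
sharpen as the DMR threshold tightens.
"""

from methnet.annotate import annotate_dmrs
from methnet.dmr import call_dmcs, call_dmrs
from methnet.integrate import (
    de_gene_sets,
    define_de_genes,
    detect_dmr_clusters,
    expression_methylation_overlap,
    gsea_enrichment,
    profile_gene_dmrs,
    rank_genes_by_dmr_count,
)
from methnet.sim import (
    SimConfig,
    simulate_expression,
    simulate_gene_models,
    simulate_methylome,
)

cfg = SimConfig(rng_seed=0)
genes = simulate_gene_models(cfg)
matrix, truth = simulate_methylome(cfg, genes)
table, _ = simulate_expression(cfg, genes, truth)

records = define_de_genes(table)
sets = de_gene_sets(records)
print(f"expression: {len(sets['induced'])} induced, {len(sets['repressed'])} "
      f"repressed of {len(table)} genes (>1.75-fold, p<0.05, floor RPKM 1)")

dmrs = call_dmrs(call_dmcs(matrix, cfg.design()))
annotated = annotate_dmrs(dmrs, genes)
profiles = profile_gene_dmrs(annotated, genes)
clusters = detect_dmr_clusters(profiles)
print(f"DMR clusters: {clusters['n_cluster_genes']} genes capture "
      f"{clusters['fraction_dmrs_captured']:.0%} of intragenic DMRs "
      f"({clusters['hypo_fraction_in_clusters']:.0%} hypomethylated)")

ranked = rank_genes_by_dmr_count(profiles)
gsea = gsea_enrichment(ranked, sets["induced"], n_perm=1000, seed=0)
print(f"GSEA of induced genes on the DMR-count ranking: ES {gsea.es:+.3f}, "
      f"permutation p {gsea.p:.3f}")
# Positive ES: induced genes concentrate near the top (many-DMR) end.

for o in expression_methylation_overlap(records, profiles, annotated):
    print(f"tier {o.tier}: {o.n_overlap}/{o.n_methylated} methylated genes are DE "
          f"({o.overlap_fraction:.0%}; Fisher OR {o.enrichment.odds_ratio:.2f})")
# The fraction rises from 'any assigned DMR' to 'intragenic' to
# 'clustered' - tighter methylation criteria select the coupled genes.
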