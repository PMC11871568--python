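"""Local hypergeometric pathway enrichment with the amalgamated score (AES).

Builds a synthetic GMT collection over the contrast universe, spikes one
pathway with receptor-dependent genes, and tests the top-100 dependence
genes for over-representation.
"""

import kinomeflow as kf

a, b, _ = kf.simulate_contrast_tables(
    n_genes=1000, n_unique_each=50, effect_log2fc=2.0, null_sd=0.25, seed=4
)
ranking = kf.dependence_scores(a, b, top_n=100)
universe = sorted(set(a["gene_id"]))

gene_sets = kf.simulate_pathways(universe, n_pathways=9, genes_per_pathway=(20, 40), seed=4)
gene_sets["PATH_SPIKED"] = ranking.top[:15] + universe[:10]  # planted signal pathway

res = kf.enrich(ranking.top, gene_sets, universe)
print(res.head(4).to_string(index=False, float_format=lambda x: f"{x:.3g}"))
# p_value: hypergeometric upper tail for the overlap; padj: BH-adjusted;
# aes = n_overlap * (-log10 padj) combines overlap size with significance —
# the spiked pathway should lead the table by a wide margin.
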