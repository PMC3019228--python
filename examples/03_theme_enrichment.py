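"""Biological-theme enrichment of a gene list.

Generates annotation tables over eight theme categories with one planted
enriched term, runs the hypergeometric test with Bonferroni correction, and
clusters the query genes by significant theme.
"""

import warnings

from bionetkit import cluster_by_theme, enrich, synth

annotations, query, truth = synth.gen_annotations(
    n_genes=500, n_terms=40, planted_hits=8, query_size=10, seed=1,
)
print(f"query: {len(query)} genes; "
      f"{len(annotations)} terms over 8 categories; "
      f"planted term: {truth.planted_enriched_terms[0]['term']}")

with warnings.catch_warnings():
    # unannotated query genes fall outside the default background
    warnings.simplefilter("ignore", UserWarning)
    results = enrich(query, annotations)
print("\ntop enriched themes (k of n query genes, term size M, background N):")
for r in results[:3]:
    print(f"  {r.category:<9} {r.term_id:<10} k={r.k}/{r.n} M={r.M} N={r.N} "
          f"p_raw={r.p_raw:.2e} p_corrected={r.p_corrected:.2e}")

clusters = cluster_by_theme(results, cutoff=0.05)
print(f"\nsignificant theme clusters at corrected p <= 0.05: {len(clusters)}")
for (category, term), genes in clusters.items():
    print(f"  {category}/{term}: {sorted(genes)}")
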