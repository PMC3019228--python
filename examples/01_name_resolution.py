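"""Resolve gene names across disagreeing sources.

Builds a registry from three mock source databases, shows how name support
is counted, how a shared synonym is reported as a conflict, and how the four
search modes behave. Weighted names mirror how a search result should rank
the most widely supported identifier first.
"""

from bionetkit import EntityRegistry, SourceRecord

registry = EntityRegistry()
registry.register_source([
    SourceRecord("uniprot", "P04637", ("TP53", "p53"), "human", "gene"),
    SourceRecord("ensembl", "ENSG141510", ("TP53",), "human", "gene"),
    SourceRecord("refseq", "NM_000546", ("TP53", "LFS1"), "human", "gene"),
    # a protein-level record re-using the synonym "p53" -> shared-name conflict
    SourceRecord("pdb", "1TUP", ("p53",), "human", "protein"),
    SourceRecord("genbank", "EGFR1", ("EGFR", "ERBB1"), "human", "gene"),
])

gene = registry.find_by_name("TP53")[0]
print("weighted names for", gene.canonical_id)
for nw in registry.rank_names(gene):
    print(f"  {nw.name:<6} supported by {nw.support_count} source(s)")
# TP53 leads: three sources assert it; conflicted 'p53' sinks in ties.

print("\nconflicts:")
for c in registry.conflicts():
    print(f"  {c.kind}: {c.name_or_entity} -> {c.implicated}")

print("\nwildcard search 'TP*':",
      [e.canonical_id for e in registry.search("TP*", mode="wildcard")])

registry.set_properties(gene.canonical_id, {"disease": "Li-Fraumeni syndrome"})
print("keyword search 'fraumeni':",
      [e.canonical_id for e in registry.search("fraumeni", mode="keyword")])
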