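"""Interval-tree annotation queries and TSS-relative promoter windows.

Indexes a handful of typed sequence elements on one chromosome, then runs
the three elementary operators — overlap query, next-element navigation,
intersection — and recalibrates TSS-relative coordinates to genomic ones.
Coordinates are 0-based half-open.
"""

from bionetkit import (
    GenomicInterval,
    SequenceElement,
    build_index,
    intersect,
    next_element,
    promoter_region,
    query_overlaps,
    recalibrate,
)

elements = [
    SequenceElement("geneA", GenomicInterval("chr1", 12_000, 20_000, "+"), "gene"),
    SequenceElement("tata1", GenomicInterval("chr1", 11_950, 11_980, "+"), "TATA_box"),
    SequenceElement("site1", GenomicInterval("chr1", 9_500, 9_512, "+"), "TFBS"),
    SequenceElement("geneB", GenomicInterval("chr1", 40_000, 52_000, "-"), "gene"),
    SequenceElement("site2", GenomicInterval("chr1", 53_100, 53_112, "-"), "TFBS"),
]
index = build_index(elements)

# the default promoter window is -6 kb .. +500 bp around the TSS
prom = promoter_region(tss=12_000, strand="+")
print(f"promoter of geneA: [{prom.start}, {prom.end})")
hits = query_overlaps(index, prom)
print("elements in that window:",
      [(e.element_id, e.element_type) for e in hits])

nxt = next_element(elements[0].interval, index, type_filter="gene")
print("next gene downstream of geneA:", nxt.element_id)

both = intersect(GenomicInterval("chr1", 9_000, 12_500),
                 GenomicInterval("chr1", 9_400, 9_600))
print(f"intersection: [{both.start}, {both.end})")

# a site reported 100..50 bp upstream of a minus-strand TSS at 52,000
iv = recalibrate(-100, -50, gene_tss=52_000, strand="-")
print(f"minus-strand recalibration of (-100, -50): [{iv.start}, {iv.end})")
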