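"""Per-chromosome interval index over annotated sequence elements.

Genomic annotations (genes, promoters, binding sites, TATA boxes, ...) are
typed intervals, one interval tree per chromosome. The three elementary
interval operators — overlap test, next-in-ordering, and intersection — are
the primitives behind upstream/downstream navigation and the annotation of
multiply overlapping regulatory regions. Coordinates are 0-based half-open
internally; BED is read natively and GFF3 (1-based closed) is converted on
read/write. TSS-relative coordinates (negative = upstream) are recalibrated
to global coordinates per strand.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

ELEMENT_TYPES = (
    "gene", "exon", "intron", "TSS", "promoter", "TFBS", "TATA_box",
    "operon", "composite_element", "repeat", "conserved_region", "other",
)

#: promoter window of the comparative case study: −6 kb to +500 bp around TSS
DEFAULT_UPSTREAM = 6000
DEFAULT_DOWNSTREAM = 500


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome strand."""

    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self):
        return self.end - self.start


@dataclass
class SequenceElement:
    """A typed, attributed genomic interval, optionally linked to an entity."""

    element_id: str
    interval: GenomicInterval
    element_type: str = "other"
    attributes: dict[str, str] = field(default_factory=dict)
    linked_entity: str | None = None

    def __post_init__(self):
        if self.element_type not in ELEMENT_TYPES:
            raise ValueError(
                f"element {self.element_id}: unknown element_type {self.element_type!r}"
            )


class IntervalIndex:
    """One interval tree per chromosome plus a (start, end) sorted view."""

    def __init__(self):
        self._trees: dict[str, IntervalTree] = {}
        self._sorted: dict[str, list[SequenceElement]] = {}
        self._keys: dict[str, list[tuple[int, int]]] = {}
        self._ids: set[str] = set()
        self.n_elements = 0

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def add(self, element: SequenceElement) -> None:
        if element.element_id in self._ids:
            raise ValueError(f"duplicate element_id {element.element_id!r}")
        iv = element.interval
        self._trees.setdefault(iv.chromosome, IntervalTree()) \
            .addi(iv.start, iv.end, element)
        lst = self._sorted.setdefault(iv.chromosome, [])
        keys = self._keys.setdefault(iv.chromosome, [])
        pos = bisect.bisect(keys, (iv.start, iv.end))
        keys.insert(pos, (iv.start, iv.end))
        lst.insert(pos, element)
        self._ids.add(element.element_id)
        self.n_elements += 1

    def elements(self, chromosome: str | None = None) -> list[SequenceElement]:
        if chromosome is not None:
            return list(self._sorted.get(chromosome, ()))
        return [e for c in self.chromosomes for e in self._sorted[c]]


def build_index(elements: list[SequenceElement]) -> IntervalIndex:
    """Index a collection of elements for sublinear overlap/next queries."""
    index = IntervalIndex()
    for el in elements:
        index.add(el)
    return index


def if_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base (half-open)."""
    return (
        a.chromosome == b.chromosome and a.start < b.end and b.start < a.end
    )


def intersect(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval | None:
    """The overlap of two intervals, or None when they do not overlap."""
    if not if_overlap(a, b):
        return None
    return GenomicInterval(
        a.chromosome, max(a.start, b.start), min(a.end, b.end), a.strand
    )


def next_element(
    from_interval: GenomicInterval,
    index: IntervalIndex,
    type_filter: str | None = None,
) -> SequenceElement | None:
    """The next element downstream in (start, end) order on the chromosome.

    Returns the first element with start >= from_interval.end matching the
    type filter, or None at the chromosome end. The genomic (start, end)
    ordering realises the next-in-ordering operator for sequence data.
    """
    chrom = from_interval.chromosome
    if chrom not in index._sorted:
        raise KeyError(f"unknown chromosome {chrom!r}")
    keys = index._keys[chrom]
    pos = bisect.bisect_left(keys, (from_interval.end, -1))
    for el in index._sorted[chrom][pos:]:
        if type_filter is None or el.element_type == type_filter:
            return el
    return None


def query_overlaps(
    index: IntervalIndex,
    probe: GenomicInterval,
    type_filter: str | None = None,
) -> list[SequenceElement]:
    """All indexed elements overlapping a probe, in (start, end, id) order."""
    tree = index._trees.get(probe.chromosome)
    if tree is None:
        return []
    hits = [iv.data for iv in tree.overlap(probe.start, probe.end)]
    if type_filter is not None:
        hits = [e for e in hits if e.element_type == type_filter]
    hits.sort(key=lambda e: (e.interval.start, e.interval.end, e.element_id))
    return hits


def recalibrate(
    rel_start: int,
    rel_end: int,
    gene_tss: int,
    strand: str = "+",
    chromosome: str = "chr1",
) -> GenomicInterval:
    """Convert TSS-relative coordinates to a global genomic interval.

    Negative relative coordinates are upstream of the transcription start in
    transcription direction: on '+', [tss+rel_start, tss+rel_end); on '−' the
    window reflects to [tss−rel_end, tss−rel_start). A '.' strand is treated
    as '+' with a warning. Windows reaching past the chromosome origin are
    clipped at 0; a window entirely below 0 is an error.
    """
    if rel_start >= rel_end:
        raise ValueError("rel_start must be < rel_end")
    if strand == ".":
        warnings.warn("strand '.' treated as '+' for recalibration")
        strand = "+"
    if strand == "+":
        start, end = gene_tss + rel_start, gene_tss + rel_end
    else:
        start, end = gene_tss - rel_end, gene_tss - rel_start
    if end <= 0:
        raise ValueError(
            f"recalibrated interval [{start}, {end}) lies entirely before the origin"
        )
    if start < 0:
        warnings.warn(f"interval [{start}, {end}) clipped at the chromosome origin")
        start = 0
    return GenomicInterval(chromosome, start, end, strand)


def promoter_region(
    tss: int,
    strand: str = "+",
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    chromosome: str = "chr1",
) -> GenomicInterval:
    """Promoter window around a TSS (default −6 kb to +500 bp)."""
    if tss < 0:
        raise ValueError("tss must be >= 0")
    return recalibrate(-upstream, downstream, tss, strand, chromosome)


# ---------------------------------------------------------------------------
# BED / GFF3 round-trip


def write_bed(elements: list[SequenceElement], path) -> None:
    """Write 6-column BED; the name field is ``element_type|element_id``.

    BED carries no attribute column, so attributes and entity links do not
    survive a BED round-trip; use GFF3 for a lossless one.
    """
    with open(path, "w") as fh:
        for el in elements:
            iv = el.interval
            fh.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t"
                f"{el.element_type}|{el.element_id}\t0\t{iv.strand}\n"
            )


def read_bed(path) -> list[SequenceElement]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{line_no}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            etype, _, eid = name.partition("|")
            if etype not in ELEMENT_TYPES:
                etype, eid = "other", name
            out.append(SequenceElement(
                element_id=eid or name,
                interval=GenomicInterval(chrom, int(start), int(end), strand),
                element_type=etype,
            ))
    return out


def _gff_escape(value: str) -> str:
    return (
        str(value).replace("%", "%25").replace(";", "%3B")
        .replace("=", "%3D").replace(",", "%2C").replace("\t", "%09")
    )


def _gff_unescape(value: str) -> str:
    return (
        value.replace("%09", "\t").replace("%2C", ",").replace("%3D", "=")
        .replace("%3B", ";").replace("%25", "%")
    )


def write_gff3(elements: list[SequenceElement], path, source: str = "bionetkit") -> None:
    """Write GFF3 (1-based closed coordinates on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            iv = el.interval
            attrs = [f"ID={_gff_escape(el.element_id)}"]
            if el.linked_entity:
                attrs.append(f"linked_entity={_gff_escape(el.linked_entity)}")
            for k in sorted(el.attributes):
                attrs.append(f"{_gff_escape(k)}={_gff_escape(el.attributes[k])}")
            fh.write(
                f"{iv.chromosome}\t{source}\t{el.element_type}\t"
                f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{';'.join(attrs)}\n"
            )


def read_gff3(path) -> list[SequenceElement]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{line_no}: expected 9 GFF3 columns")
            chrom, _src, etype, start, end, _score, strand, _phase, attr_col = parts
            attrs: dict[str, str] = {}
            for item in attr_col.split(";"):
                if not item:
                    continue
                k, _, v = item.partition("=")
                attrs[_gff_unescape(k)] = _gff_unescape(v)
            eid = attrs.pop("ID", f"element_{line_no}")
            linked = attrs.pop("linked_entity", None)
            out.append(SequenceElement(
                element_id=eid,
                interval=GenomicInterval(chrom, int(start) - 1, int(end), strand),
                element_type=etype if etype in ELEMENT_TYPES else "other",
                attributes=attrs,
                linked_entity=linked,
            ))
    return out
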