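"""Biological-theme enrichment for gene lists.

Annotations are grouped into eight theme categories (three Gene Ontology
branches, curated pathways, diseases, cell types, tissue expression, and
phenotype/anatomy). For a query gene list, each term's over-representation
is scored with the hypergeometric upper tail and Bonferroni-corrected over
all terms tested in the run; significant terms become gene clusters by theme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
from scipy.stats import hypergeom

CATEGORIES = (
    "GO_BP", "GO_MF", "GO_CC", "pathway", "disease",
    "cell_type", "tissue", "phenotype_anatomy",
)


@dataclass
class AnnotationSet:
    """One term of one theme category with its annotated genes."""

    category: str
    term_id: str
    term_label: str
    genes: frozenset[str]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown theme category: {self.category}")
        self.genes = frozenset(self.genes)


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one term in one query list.

    k hits out of a query of n, against a term of size M in a background of
    N genes; p_corrected = min(1, p_raw · m) for m terms tested in the run.
    """

    term_id: str
    category: str
    term_label: str
    k: int
    n: int
    M: int
    N: int
    p_raw: float
    p_corrected: float
    member_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.k > min(self.n, self.M):
            raise ValueError("hit count exceeds query or term size")


def hypergeom_tail(k: int, n: int, M: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, M marked, n drawn)."""
    if not (0 <= k <= n <= N) or not (0 <= M <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} M={M} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, M, n))


def enrich(
    query_genes,
    annotations: list[AnnotationSet],
    background: set[str] | None = None,
    min_term_size: int = 2,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in a gene list.

    The background defaults to the union of all annotated genes. Query genes
    outside the background are dropped with a warning. Terms annotating fewer
    than ``min_term_size`` background genes are skipped as uninformative; the
    Bonferroni family is all remaining terms across all categories in this
    invocation. Results (one per term with >= 1 hit) are sorted by corrected
    p ascending, then term id.
    """
    if background is None:
        background = set().union(*(a.genes for a in annotations)) if annotations else set()
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes)
    outside = query - background
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background were dropped"
        )
        query &= background
    N, n = len(background), len(query)
    tested = [
        a for a in annotations if len(a.genes & background) >= min_term_size
    ]
    m = len(tested)
    results = []
    for a in tested:
        term_genes = a.genes & background
        hit = query & term_genes
        if not hit:
            continue
        p = hypergeom_tail(len(hit), n, len(term_genes), N)
        results.append(EnrichmentResult(
            term_id=a.term_id, category=a.category, term_label=a.term_label,
            k=len(hit), n=n, M=len(term_genes), N=N,
            p_raw=p, p_corrected=min(1.0, p * m), member_genes=frozenset(hit),
        ))
    results.sort(key=lambda r: (r.p_corrected, r.p_raw, r.term_id))
    return results


def cluster_by_theme(
    results: list[EnrichmentResult], cutoff: float = 0.05
) -> dict[tuple[str, str], frozenset[str]]:
    """Gene clusters for the significant themes.

    Keeps terms with corrected p <= ``cutoff``; each cluster is the term's
    query hit set, keyed by (category, term_id). A gene may belong to several
    clusters; nested significant terms are both kept (no pruning).
    """
    return {
        (r.category, r.term_id): r.member_genes
        for r in results if r.p_corrected <= cutoff
    }


def read_annotations(path) -> list[AnnotationSet]:
    """Read a tab-delimited annotation table.

    Columns: category, term_id, term_label, gene_id (one row per gene-term
    link); a header row matching the column names is tolerated.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                     names=["category", "term_id", "term_label", "gene_id"])
    if len(df) and list(df.iloc[0]) == ["category", "term_id", "term_label", "gene_id"]:
        df = df.iloc[1:]
    out = []
    for (cat, tid, label), grp in df.groupby(
        ["category", "term_id", "term_label"], sort=True
    ):
        out.append(AnnotationSet(cat, tid, label, frozenset(grp["gene_id"])))
    return out


def write_annotations(annotations: list[AnnotationSet], path) -> None:
    rows = [
        (a.category, a.term_id, a.term_label, g)
        for a in sorted(annotations, key=lambda a: (a.category, a.term_id))
        for g in sorted(a.genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
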