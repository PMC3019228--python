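"""Conservation-filtered TF → gene regulatory network construction.

Predicted transcription-factor binding sites carry high false-positive
rates. Three composable filters suppress them: a p-value cutoff on the
binding call (default: keep p < 1e-3), phylogenetic-footprint conservation —
a site must recur, for the same TF, in the orthologous promoters of enough
species, optionally with identical 5'→3' site order — and tissue/cell-type
context. Surviving predictions become TF → target edges; supplied
interactions among the included nodes complete the network, and candidate
TFs left without any surviving edge are dropped.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd

from bionetkit.netquery import InteractionRecord, Network

DEFAULT_PMAX = 1e-3


@dataclass(frozen=True)
class TFBSPrediction:
    """One predicted binding site of a TF in a target gene's promoter.

    ``rel_start``/``rel_end`` are TSS-relative (negative = upstream) in
    transcription direction, so ascending rel_start is 5'→3' site order.
    An empty ``tissues`` set means the call is not tissue-restricted.
    """

    tf_id: str
    target_gene_id: str
    species: str
    rel_start: int
    rel_end: int
    p_value: float
    tissues: frozenset[str] = frozenset()
    source: str = ""

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")
        if self.rel_start >= self.rel_end:
            raise ValueError("rel_start must be < rel_end")
        object.__setattr__(self, "tissues", frozenset(self.tissues))


@dataclass(frozen=True)
class OrthologGroup:
    """A cross-species group of corresponding genes (one gene per species)."""

    group_id: str
    members: tuple[tuple[str, str], ...]  # (species, gene_id)

    def __post_init__(self):
        species = [s for s, _ in self.members]
        if len(species) != len(set(species)):
            raise ValueError(f"group {self.group_id}: one gene per species")
        if len(species) < 2:
            raise ValueError(f"group {self.group_id}: needs >= 2 species")
        object.__setattr__(self, "members", tuple(sorted(self.members)))

    @property
    def species(self) -> set[str]:
        return {s for s, _ in self.members}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.members}

    def gene_of(self, species: str) -> str | None:
        return dict(self.members).get(species)


@dataclass
class RegulatoryEdge:
    """A TF → target edge with its surviving binding-site evidence."""

    tf_id: str
    target_gene_id: str
    evidence: list = field(default_factory=list)
    conserved: bool = False

    def __post_init__(self):
        if not self.evidence:
            raise ValueError("a regulatory edge requires evidence")

    @property
    def best_p(self) -> float:
        ps = [e.p_value for e in self.evidence if getattr(e, "p_value", None) is not None]
        return min(ps) if ps else 1.0


# ---------------------------------------------------------------------------
# filters (order-independent and composable)


def filter_by_pvalue(
    predictions: list[TFBSPrediction], threshold: float = DEFAULT_PMAX
) -> list[TFBSPrediction]:
    """Keep exactly the predictions with binding p-value below ``threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    return [p for p in predictions if p.p_value < threshold]


def filter_by_tissue(items, tissue_labels) -> list:
    """Keep tissue-unrestricted items and items matching any requested label."""
    labels = set(tissue_labels)
    return [
        it for it in items
        if not it.tissues or (set(it.tissues) & labels)
    ]


def _order_consistent_tfs(
    sites_by_species: dict[str, list[TFBSPrediction]], candidates: set[str]
) -> set[str]:
    """Candidates whose pairwise 5'→3' order agrees across all species.

    Each species' promoter induces an order of the candidate TFs by the
    position of the TF's first (5'-most) site. For every TF pair present
    together in >= 2 species, the order must be the same in all of them;
    an inconsistent pair removes both TFs.
    """
    first_pos: dict[str, dict[str, int]] = {}
    for sp, sites in sites_by_species.items():
        pos: dict[str, int] = {}
        for s in sorted(sites, key=lambda s: (s.rel_start, s.rel_end, s.tf_id)):
            if s.tf_id in candidates and s.tf_id not in pos:
                pos[s.tf_id] = s.rel_start
        first_pos[sp] = pos
    dropped: set[str] = set()
    for t1, t2 in itertools.combinations(sorted(candidates), 2):
        orders = set()
        for pos in first_pos.values():
            if t1 in pos and t2 in pos and pos[t1] != pos[t2]:
                orders.add(pos[t1] < pos[t2])
        if len(orders) > 1:
            dropped.update((t1, t2))
    return candidates - dropped


def conserved_tfbs(
    predictions: list[TFBSPrediction],
    ortholog_groups: list[OrthologGroup],
    min_species: int | None = None,
    check_order: bool = True,
) -> list[TFBSPrediction]:
    """Phylogenetic-footprint filter: keep sites conserved across orthologs.

    A (TF, ortholog group) combination is conserved when the TF has a site in
    the promoters of at least ``min_species`` member genes (default: every
    species in the group — strict footprinting). With ``check_order``, the
    relative 5'→3' order of the conserved TFs along each orthologous promoter
    must also be identical across species. Only predictions belonging to
    conserved combinations are returned; predictions whose target maps to no
    group are dropped with a warning.
    """
    gene_to_group: dict[str, OrthologGroup] = {}
    for grp in ortholog_groups:
        for _, gene in grp.members:
            gene_to_group[gene] = grp

    by_group: dict[str, list[TFBSPrediction]] = {}
    unmapped = 0
    for p in predictions:
        grp = gene_to_group.get(p.target_gene_id)
        if grp is None:
            unmapped += 1
            continue
        by_group.setdefault(grp.group_id, []).append(p)
    if unmapped:
        warnings.warn(f"{unmapped} prediction(s) target genes with no ortholog group")

    groups = {g.group_id: g for g in ortholog_groups}
    kept: list[TFBSPrediction] = []
    any_group_feasible = False
    for gid in sorted(by_group):
        grp = groups[gid]
        need = len(grp.species) if min_species is None else min_species
        if need <= len(grp.species):
            any_group_feasible = True
        sites_by_species: dict[str, list[TFBSPrediction]] = {}
        for p in by_group[gid]:
            sites_by_species.setdefault(p.species, []).append(p)
        tf_species: dict[str, set[str]] = {}
        for sp, sites in sites_by_species.items():
            for s in sites:
                tf_species.setdefault(s.tf_id, set()).add(sp)
        conserved_tfs = {tf for tf, sps in tf_species.items() if len(sps) >= need}
        if check_order and len(conserved_tfs) > 1:
            conserved_tfs = _order_consistent_tfs(sites_by_species, conserved_tfs)
        kept.extend(p for p in by_group[gid] if p.tf_id in conserved_tfs)
    if by_group and not any_group_feasible:
        warnings.warn("min_species exceeds every group's species count")
    order = {id(p): i for i, p in enumerate(predictions)}
    kept.sort(key=lambda p: order[id(p)])
    return kept


# ---------------------------------------------------------------------------
# network construction


def build_tf_gene_network(
    genes,
    predictions: list[TFBSPrediction],
    interactions: list[InteractionRecord] | None = None,
    ortholog_groups: list[OrthologGroup] | None = None,
    pmax: float | None = DEFAULT_PMAX,
    min_species: int | None = None,
    check_order: bool = True,
    tissue_labels=None,
) -> Network:
    """Build the TF → target network for a target gene set.

    Predictions are filtered by p-value, conservation (when ortholog groups
    are supplied) and tissue context; the filters commute. Each surviving
    (TF, target) combination with the target in ``genes`` becomes a directed
    ``tf_dna`` edge annotated with its best evidence p-value and conservation
    flag; supplied interactions whose two endpoints are already included are
    added. Candidate TFs with no surviving edge never enter the network.
    """
    targets = set(genes)
    if not targets:
        raise ValueError("target gene set must be non-empty")
    surviving = list(predictions)
    conserved_ids: set[int] = set()
    if pmax is not None:
        surviving = filter_by_pvalue(surviving, pmax)
    if ortholog_groups:
        surviving = conserved_tfbs(surviving, ortholog_groups, min_species, check_order)
        conserved_ids = {id(p) for p in surviving}
    if tissue_labels is not None:
        surviving = filter_by_tissue(surviving, tissue_labels)

    # orthologous genes map back to the queried targets via their group
    gene_alias: dict[str, str] = {g: g for g in targets}
    for grp in ortholog_groups or []:
        hit = grp.genes & targets
        if len(hit) == 1:
            canonical = next(iter(hit))
            for g in grp.genes:
                gene_alias.setdefault(g, canonical)

    by_edge: dict[tuple[str, str], list[TFBSPrediction]] = {}
    for p in surviving:
        target = gene_alias.get(p.target_gene_id)
        if target is None:
            continue
        by_edge.setdefault((p.tf_id, target), []).append(p)

    net = Network()
    for g in sorted(targets):
        net.add_node(g, role="target")
    for (tf, target), evid in sorted(by_edge.items()):
        edge = RegulatoryEdge(
            tf, target, evid,
            conserved=any(id(p) in conserved_ids for p in evid),
        )
        net.add_node(tf, role="TF")
        net.add_edge(InteractionRecord(
            tf, target, "tf_dna", directed=True, p_value=edge.best_p,
            attributes={
                "conserved": edge.conserved,
                "n_sites": len(evid),
                "species": ",".join(sorted({p.species for p in evid})),
            },
            provenance="tfbs",
        ))
    included = net.nodes
    for rec in interactions or []:
        if rec.source_id in included and rec.target_id in included:
            net.add_edge(rec)
    return net


# ---------------------------------------------------------------------------
# I/O


def read_tfbs(path) -> list[TFBSPrediction]:
    """Read a tab-delimited TFBS table.

    Columns: tf, target, species, rel_start, rel_end, p_value, tissues
    (comma-separated; empty = unrestricted), source.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        tissues = frozenset(t for t in str(row.tissues).split(",") if t)
        out.append(TFBSPrediction(
            tf_id=row.tf, target_gene_id=row.target, species=row.species,
            rel_start=int(row.rel_start), rel_end=int(row.rel_end),
            p_value=float(row.p_value), tissues=tissues, source=row.source,
        ))
    return out


def write_tfbs(predictions: list[TFBSPrediction], path) -> None:
    rows = [{
        "tf": p.tf_id, "target": p.target_gene_id, "species": p.species,
        "rel_start": p.rel_start, "rel_end": p.rel_end,
        "p_value": repr(p.p_value), "tissues": ",".join(sorted(p.tissues)),
        "source": p.source,
    } for p in predictions]
    pd.DataFrame(
        rows,
        columns=["tf", "target", "species", "rel_start", "rel_end",
                 "p_value", "tissues", "source"],
    ).to_csv(path, sep="\t", index=False)


def read_ortholog_groups(path) -> list[OrthologGroup]:
    """Read tab-delimited ortholog groups: group_id, species, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str,
                     names=["group_id", "species", "gene"], header=None)
    if len(df) and list(df.iloc[0]) == ["group_id", "species", "gene"]:
        df = df.iloc[1:]
    out = []
    for gid, grp in df.groupby("group_id", sort=True):
        out.append(OrthologGroup(
            gid, tuple(zip(grp["species"], grp["gene"])),
        ))
    return out


def write_ortholog_groups(groups: list[OrthologGroup], path) -> None:
    rows = [(g.group_id, sp, gene)
            for g in sorted(groups, key=lambda g: g.group_id)
            for sp, gene in g.members]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
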