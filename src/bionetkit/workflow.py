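"""The composed case-study pipeline.

The strategy chains the library's components the way the demonstration
analysis chains them: pick over-expressed genes in an index experiment,
mine the compendium for pairs co-expressed in more than ``min_support``
experiments, take the −6 kb/+500 bp promoter windows of the surviving genes
across species through their ortholog groups, filter binding-site
predictions at p < 1e-3 plus strict cross-species conservation, assemble the
TF → gene network together with any supplied interactions, overlay the
co-expression evidence, and quantify how much more often the network's TFs
carry a disease keyword than background genes do (hypergeometric p).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from bionetkit import expression, regnet
from bionetkit.enrichment import hypergeom_tail
from bionetkit.expression import Compendium, ExperimentMatrix
from bionetkit.intervals import promoter_region, DEFAULT_UPSTREAM, DEFAULT_DOWNSTREAM
from bionetkit.netquery import InteractionRecord, Network, overlay, write_sif
from bionetkit.regnet import OrthologGroup, TFBSPrediction, build_tf_gene_network


class StageError(RuntimeError):
    """A pipeline stage produced no output; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class WorkflowConfig:
    """Thresholds and inputs of the case-study pipeline.

    Defaults follow the demonstration analysis where it states them: pairs
    kept when co-expressed in more than 10 experiments, promoters from −6 kb
    to +500 bp around the TSS, binding sites kept below p = 1e-3, and strict
    conservation (all species of each ortholog group).
    """

    z_cut: float = expression.DEFAULT_Z_CUT
    alpha: float = expression.DEFAULT_ALPHA
    r_min: float = expression.DEFAULT_R_MIN
    min_support: int = 10
    promoter_upstream: int = DEFAULT_UPSTREAM
    promoter_downstream: int = DEFAULT_DOWNSTREAM
    tfbs_pmax: float = 1e-3
    min_species: int | None = None
    check_order: bool = True
    tissue_labels: list[str] | None = None
    disease_keywords: list[str] = field(default_factory=list)
    include_under_expressed: bool = False
    seed: int = 0
    out_dir: str | None = None


@dataclass
class WorkflowReport:
    """Per-stage counts and the keyword-association comparison."""

    config: dict
    selected_genes: list[str] = field(default_factory=list)
    n_over_expressed: int = 0
    n_under_expressed: int = 0
    coexpressed_pairs: list[dict] = field(default_factory=list)
    n_pairs_retained: int = 0
    n_promoters: int = 0
    n_tfbs_after_pvalue: int = 0
    n_tfbs_after_conservation: int = 0
    surviving_tfs: list[str] = field(default_factory=list)
    n_network_nodes: int = 0
    n_network_edges: int = 0
    keyword_fraction_network_tfs: float | None = None
    keyword_fraction_background: float | None = None
    keyword_association_p: float | None = None
    output_files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def run_case_study(
    config: WorkflowConfig,
    index_experiment: ExperimentMatrix,
    compendium: Compendium,
    tss_table: dict[str, tuple[str, int, str]],
    predictions: list[TFBSPrediction],
    ortholog_groups: list[OrthologGroup],
    interactions: list[InteractionRecord] | None = None,
    gene_keywords: dict[str, str] | None = None,
    background_genes: set[str] | None = None,
) -> tuple[WorkflowReport, Network]:
    """Run the composed pipeline; every stage must produce output.

    ``tss_table`` maps gene → (chromosome, tss, strand) for promoter windows;
    ``gene_keywords`` maps gene/TF → free-text annotation searched for the
    configured disease keywords. Returns the report and the final network;
    the report (and, with ``config.out_dir``, all intermediates) is
    deterministic for fixed inputs and configuration.
    """
    report = WorkflowReport(config=asdict(config))
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def emit(name: str, writer) -> None:
        if out_dir:
            path = out_dir / name
            writer(path)
            report.output_files.append(name)

    # stage 1 — differential genes in the index experiment
    diff = expression.find_differential_experiments(
        index_experiment.gene_ids, Compendium([index_experiment]), config.z_cut
    )
    calls = diff.get(index_experiment.experiment_id, {"over": [], "under": []})
    report.n_over_expressed = len(calls["over"])
    report.n_under_expressed = len(calls["under"])
    selected = list(calls["over"])
    if config.include_under_expressed:
        selected += calls["under"]
    if not selected:
        raise StageError("differential_selection",
                         "no gene passed the z-score cut in the index experiment")
    emit("selected_genes.txt",
         lambda p: Path(p).write_text("\n".join(selected) + "\n"))

    # stage 2 — co-expression support across the compendium
    pairs = expression.find_coexpressed_pairs(
        selected, compendium, alpha=config.alpha, r_min=config.r_min,
        min_support=config.min_support,
    )
    if not pairs:
        raise StageError(
            "coexpression",
            f"no pair was co-expressed in more than {config.min_support} experiments",
        )
    report.n_pairs_retained = len(pairs)
    report.coexpressed_pairs = [
        {"members": list(r.members), "support": r.support,
         "mean_abs_r": round(r.mean_abs_r, 4)}
        for r in pairs
    ]
    coexpressed_genes = sorted({g for r in pairs for g in r.members})
    report.selected_genes = coexpressed_genes
    emit("coexpressed_pairs.tsv", lambda p: Path(p).write_text(
        "gene_a\tgene_b\tsupport\tmean_abs_r\n" + "".join(
            f"{r.members[0]}\t{r.members[1]}\t{r.support}\t{r.mean_abs_r:.4f}\n"
            for r in pairs)
    ))

    # stage 3 — promoter windows for the selected genes across species
    gene_alias: dict[str, str] = {}
    for grp in ortholog_groups:
        hit = set(grp.genes) & set(coexpressed_genes)
        if len(hit) == 1:
            canonical = next(iter(hit))
            for g in grp.genes:
                gene_alias[g] = canonical
    promoter_genes = [g for g in sorted(set(gene_alias) | set(coexpressed_genes))
                      if g in tss_table]
    promoters = {}
    for g in promoter_genes:
        chrom, tss, strand = tss_table[g]
        promoters[g] = promoter_region(
            tss, strand, config.promoter_upstream, config.promoter_downstream,
            chromosome=chrom,
        )
    if not promoters:
        raise StageError("promoters", "no selected gene has a TSS entry")
    report.n_promoters = len(promoters)
    emit("promoters.bed", lambda p: Path(p).write_text("".join(
        f"{iv.chromosome}\t{iv.start}\t{iv.end}\tpromoter|{g}\t0\t{iv.strand}\n"
        for g, iv in sorted(promoters.items())
    )))

    # stage 4 — binding-site filters: p-value then conservation
    relevant = [p for p in predictions
                if gene_alias.get(p.target_gene_id, p.target_gene_id)
                in set(coexpressed_genes)]
    passed_p = regnet.filter_by_pvalue(relevant, config.tfbs_pmax)
    report.n_tfbs_after_pvalue = len(passed_p)
    conserved = regnet.conserved_tfbs(
        passed_p, ortholog_groups, config.min_species, config.check_order,
    )
    if config.tissue_labels is not None:
        conserved = regnet.filter_by_tissue(conserved, config.tissue_labels)
    report.n_tfbs_after_conservation = len(conserved)
    if not conserved:
        raise StageError("conservation", "no binding site survived the filters")
    report.surviving_tfs = sorted({p.tf_id for p in conserved})

    # stage 5 — network assembly (filters already applied; groups map the
    # orthologous targets back to the selected genes)
    net = build_tf_gene_network(
        coexpressed_genes, conserved, interactions or [],
        ortholog_groups=ortholog_groups, pmax=None,
        min_species=config.min_species, check_order=config.check_order,
        tissue_labels=None,
    )
    if not net.edges:
        raise StageError("network", "no TF-gene edge survived")

    # stage 6 — overlay the co-expression evidence
    net = overlay(net, coexpression_results=pairs)
    report.n_network_nodes = len(net.nodes)
    report.n_network_edges = len(net.edges)
    emit("network.sif", lambda p: write_sif(
        net, p, Path(p).with_suffix(".edges.tsv")))
    if out_dir and "network.sif" in report.output_files:
        report.output_files.append("network.edges.tsv")

    # stage 7 — disease-keyword association of the network's TFs
    if config.disease_keywords and gene_keywords is not None:
        keywords = [k.lower() for k in config.disease_keywords]

        def has_keyword(g: str) -> bool:
            text = str(gene_keywords.get(g, "")).lower()
            return any(k in text for k in keywords)

        tfs = sorted(set(report.surviving_tfs))
        background = set(background_genes or gene_keywords) - set(coexpressed_genes)
        background -= set(tfs)
        tf_hits = sum(1 for t in tfs if has_keyword(t))
        bg_hits = sum(1 for g in background if has_keyword(g))
        if tfs and background:
            report.keyword_fraction_network_tfs = tf_hits / len(tfs)
            report.keyword_fraction_background = bg_hits / len(background)
            # population = TFs + background; marked = keyword carriers
            report.keyword_association_p = hypergeom_tail(
                tf_hits, len(tfs), tf_hits + bg_hits, len(tfs) + len(background),
            )

    emit("report.json", lambda p: Path(p).write_text(report.to_json()))
    return report, net
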