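"""Synthetic fixtures with planted, recorded ground truth.

Every analysis component gets a closed-loop test partner here: a GEO-like
expression compendium with planted co-expression modules, a multi-species
promoter/TFBS fixture with planted conserved sites among uniform decoys, and
annotation tables with a planted enriched term. Generators are deterministic
per seed, write plain tab-delimited files, and emit a JSON ground-truth
sidecar recording exactly what was planted.

Planted co-expression uses a latent factor: module genes in a designated
experiment are x_g = sqrt(rho)·f + sqrt(1−rho)·ε_g with f and ε standard
normal per condition, giving pairwise correlation rho in expectation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from bionetkit.expression import Compendium, ExperimentMatrix
from bionetkit.regnet import (
    OrthologGroup,
    TFBSPrediction,
    write_ortholog_groups,
    write_tfbs,
)


@dataclass
class GroundTruth:
    """What a generator planted, serialized next to the data it explains."""

    seed: int
    planted_coexpression_modules: list = field(default_factory=list)
    planted_regulators: list = field(default_factory=list)
    planted_conserved_sites: list = field(default_factory=list)
    planted_enriched_terms: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# expression compendium


def gen_compendium(
    n_genes: int = 40,
    n_experiments: int = 40,
    conditions_range: tuple[int, int] = (16, 24),
    modules: list[tuple[int, int, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    out_dir=None,
) -> tuple[Compendium, GroundTruth]:
    """A compendium of Gaussian experiments with planted co-expressed modules.

    ``modules`` lists (size, n_supporting_experiments, rho) triples; module
    genes share a latent factor scaled to pairwise correlation ≈ rho in the
    designated experiments and are independent everywhere else. Condition
    counts are drawn uniformly from ``conditions_range``. When ``out_dir`` is
    given, one TSV per experiment plus a ground-truth JSON are written.
    """
    modules = modules or []
    if sum(size for size, _, _ in modules) > n_genes:
        raise ValueError("modules require more genes than the compendium holds")
    for size, n_sup, rho in modules:
        if not (0 < rho < 1):
            raise ValueError("rho must lie in (0, 1)")
        if n_sup > n_experiments:
            raise ValueError("module supported in more experiments than exist")
    rng = np.random.default_rng(seed)
    genes = [f"g{i+1:04d}" for i in range(n_genes)]
    exp_ids = [f"exp{j+1:03d}" for j in range(n_experiments)]

    truth = GroundTruth(seed=seed)
    assignments: list[tuple[list[str], list[str], float]] = []
    cursor = 0
    for size, n_sup, rho in modules:
        members = genes[cursor:cursor + size]
        cursor += size
        support = [exp_ids[int(i)] for i in
                   rng.choice(n_experiments, size=n_sup, replace=False)]
        support.sort()
        assignments.append((members, support, rho))
        truth.planted_coexpression_modules.append(
            {"genes": members, "experiments": support, "rho": rho}
        )

    comp = Compendium()
    for eid in exp_ids:
        n_cond = int(rng.integers(conditions_range[0], conditions_range[1] + 1))
        values = rng.normal(0.0, noise_sd, size=(n_genes, n_cond))
        for members, support, rho in assignments:
            if eid not in support:
                continue
            f = rng.normal(0.0, 1.0, size=n_cond)
            for g in members:
                i = genes.index(g)
                eps = rng.normal(0.0, 1.0, size=n_cond)
                values[i] = noise_sd * (np.sqrt(rho) * f + np.sqrt(1.0 - rho) * eps)
        comp.add(ExperimentMatrix(experiment_id=eid, gene_ids=list(genes),
                                  values=values))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for exp in comp:
            exp.write_tsv(out_dir / f"{exp.experiment_id}.tsv")
        truth.write(out_dir / "ground_truth.json")
    return comp, truth


def gen_differential_experiment(
    genes: list[str],
    perturbed: dict[str, float],
    n_conditions: int = 16,
    n_case_conditions: int = 2,
    experiment_id: str = "index_experiment",
    seed: int = 0,
) -> ExperimentMatrix:
    """One experiment with designated case conditions and shifted genes.

    ``perturbed`` maps gene → shift (in noise SD units) added to the case
    conditions, emulating the index experiment whose over-/under-expressed
    genes seed a compendium search.
    """
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, 1.0, size=(len(genes), n_conditions))
    case = [f"case{i+1}" for i in range(n_case_conditions)]
    ctrl = [f"ctrl{i+1}" for i in range(n_conditions - n_case_conditions)]
    for g, shift in perturbed.items():
        if g in genes:
            values[genes.index(g), :n_case_conditions] += shift
    return ExperimentMatrix(
        experiment_id=experiment_id, gene_ids=list(genes), values=values,
        condition_labels=case + ctrl,
        metadata={"case_conditions": case},
    )


# ---------------------------------------------------------------------------
# promoters, orthologs, TFBS


def gen_regulatory_fixture(
    n_species: int = 3,
    n_groups: int = 12,
    n_tfs: int = 5,
    targets_per_tf: int = 4,
    site_p_range: tuple[float, float] = (1e-6, 1e-4),
    decoys_per_promoter: int = 10,
    order_violation_groups: int = 0,
    seed: int = 0,
    out_dir=None,
) -> tuple[list[TFBSPrediction], list[OrthologGroup], GroundTruth]:
    """Multi-species promoter TFBS calls with planted conserved regulators.

    Each ortholog group has one gene per species. Planted (TF, target) sites
    appear in every species of the target's group, in the same 5'→3' order,
    with p-values drawn log-uniformly from ``site_p_range``. Decoy sites have
    p ~ Uniform(0, 1), land in a single random species, at random positions.
    ``order_violation_groups`` flips the planted site order in one species of
    that many groups — a constructed control the order check must reject.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    species = [f"sp{i+1}" for i in range(n_species)]
    groups = []
    for g in range(n_groups):
        members = tuple((sp, f"{sp}_gene{g+1:03d}") for sp in species)
        groups.append(OrthologGroup(f"OG{g+1:03d}", members))
    tfs = [f"TF{t+1:02d}" for t in range(n_tfs)]

    truth = GroundTruth(seed=seed)
    predictions: list[TFBSPrediction] = []
    lo, hi = np.log10(site_p_range[0]), np.log10(site_p_range[1])

    # choose distinct target groups per TF, round-robin over groups
    group_cycle = itertools.cycle(range(n_groups))
    planted_by_group: dict[str, list[str]] = {}
    for tf in tfs:
        chosen = [groups[next(group_cycle)] for _ in range(targets_per_tf)]
        for grp in chosen:
            planted_by_group.setdefault(grp.group_id, []).append(tf)
            truth.planted_regulators.append({"tf": tf, "group": grp.group_id,
                                             "targets": sorted(grp.genes)})

    violated = set()
    for k, gid in enumerate(sorted(planted_by_group)):
        if k < order_violation_groups:
            violated.add(gid)

    for grp in groups:
        tf_list = planted_by_group.get(grp.group_id, [])
        # shared 5'→3' layout of planted sites across the group's species
        slots = sorted(rng.choice(np.arange(-5800, 300, 20),
                                  size=max(len(tf_list), 1), replace=False))
        for si, sp in enumerate(species):
            gene = grp.gene_of(sp)
            layout = list(slots[:len(tf_list)])
            if grp.group_id in violated and si == len(species) - 1 and len(layout) > 1:
                layout[0], layout[1] = layout[1], layout[0]
            for tf, pos in zip(tf_list, layout):
                p = float(10 ** rng.uniform(lo, hi))
                predictions.append(TFBSPrediction(
                    tf_id=tf, target_gene_id=gene, species=sp,
                    rel_start=int(pos), rel_end=int(pos) + 12,
                    p_value=p, source="planted",
                ))
                truth.planted_conserved_sites.append(
                    {"tf": tf, "gene": gene, "species": sp,
                     "rel_start": int(pos), "p_value": p,
                     "order_violated": grp.group_id in violated}
                )
            for d in range(decoys_per_promoter):
                pos = int(rng.integers(-6000, 488))
                predictions.append(TFBSPrediction(
                    tf_id=f"decoyTF{rng.integers(1, 200):03d}",
                    target_gene_id=gene, species=sp,
                    rel_start=pos, rel_end=pos + 12,
                    p_value=float(rng.uniform(0.0, 1.0) or 1e-12),
                    source="decoy",
                ))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tfbs(predictions, out_dir / "tfbs.tsv")
        write_ortholog_groups(groups, out_dir / "orthologs.tsv")
        truth.write(out_dir / "ground_truth.json")
    return predictions, groups, truth


# ---------------------------------------------------------------------------
# composed case-study fixture


def gen_case_study_fixture(
    seed: int = 0,
    n_genes: int = 30,
    module: tuple[int, int, float] = (8, 15, 0.9),
    n_tfs: int = 4,
    species: tuple[str, ...] = ("human", "mouse", "rat"),
    decoys_per_promoter: int = 10,
    keyword: str = "hypertension",
) -> dict:
    """Everything the composed pipeline needs, with planted ground truth.

    Returns a dict with: ``index_experiment`` (module genes shifted up in the
    case conditions), ``compendium`` (module co-expressed in its designated
    experiments), ``tss_table``, ``predictions`` (each planted TF binds every
    module gene's promoter in all species, same 5'→3' order, p in
    (1e-6, 1e-4); uniform-p single-species decoys), ``ortholog_groups`` (one
    per gene, across all species), ``interactions`` (a few TF-TF physical
    edges), ``gene_keywords`` (planted TFs carry the disease keyword,
    background genes at a low rate), and ``truth``.
    """
    rng = np.random.default_rng(seed)
    comp, truth = gen_compendium(
        n_genes=n_genes, n_experiments=40, modules=[module], seed=seed,
    )
    genes = next(iter(comp)).gene_ids
    module_genes = truth.planted_coexpression_modules[0]["genes"]
    # after per-gene z-normalization the case-condition mean saturates at
    # sqrt((1-f)/f) for case fraction f, so the case block is kept small and
    # the raw shift large relative to the unit noise
    index_exp = gen_differential_experiment(
        genes, {g: 10.0 for g in module_genes}, seed=seed + 1,
    )

    groups, tss_table = [], {}
    for gi, g in enumerate(genes):
        members = tuple(
            (sp, g if sp == species[0] else f"{sp[:2]}_{g}") for sp in species
        )
        groups.append(OrthologGroup(f"OG_{g}", members))
        for si, (sp, gene) in enumerate(members):
            tss_table[gene] = (f"{sp}_chr1", 100_000 + 10_000 * gi, "+")

    tfs = [f"TF{t+1:02d}" for t in range(n_tfs)]
    predictions: list[TFBSPrediction] = []
    for grp in groups:
        canonical = grp.members[0][1]
        tf_list = tfs if canonical in module_genes else []
        slots = sorted(rng.choice(np.arange(-5800, 300, 25),
                                  size=max(len(tf_list), 1), replace=False))
        for sp, gene in grp.members:
            for tf, pos in zip(tf_list, slots):
                predictions.append(TFBSPrediction(
                    tf_id=tf, target_gene_id=gene, species=sp,
                    rel_start=int(pos), rel_end=int(pos) + 12,
                    p_value=float(10 ** rng.uniform(-6, -4)), source="planted",
                ))
            for _ in range(decoys_per_promoter):
                pos = int(rng.integers(-6000, 488))
                predictions.append(TFBSPrediction(
                    tf_id=f"decoyTF{rng.integers(1, 200):03d}",
                    target_gene_id=gene, species=sp,
                    rel_start=pos, rel_end=pos + 12,
                    p_value=max(float(rng.uniform(0.0, 1.0)), 1e-12),
                    source="decoy",
                ))
    for tf in tfs:
        truth.planted_regulators.append(
            {"tf": tf, "targets": sorted(module_genes)})

    from bionetkit.netquery import InteractionRecord

    interactions = [
        InteractionRecord(tfs[i], tfs[i + 1], "ppi", directed=False,
                          provenance="synthetic_ppi")
        for i in range(len(tfs) - 1)
    ]
    gene_keywords = {tf: f"{keyword} transcription factor" for tf in tfs}
    for g in genes:
        gene_keywords[g] = keyword if rng.random() < 0.016 else "unrelated"
    return {
        "index_experiment": index_exp,
        "compendium": comp,
        "tss_table": tss_table,
        "predictions": predictions,
        "ortholog_groups": groups,
        "interactions": interactions,
        "gene_keywords": gene_keywords,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# annotations


def gen_annotations(
    n_genes: int = 500,
    n_terms: int = 40,
    planted_term: str | None = "T_planted",
    planted_hits: int = 8,
    query_size: int = 10,
    membership_density: float = 0.02,
    term_size: int = 12,
    seed: int = 0,
    out_dir=None,
) -> tuple[list, list[str], GroundTruth]:
    """Annotation tables with one planted enriched term.

    Background genes get random term memberships at ``membership_density``;
    the planted term additionally contains ``planted_hits`` of the
    ``query_size`` query genes. With ``planted_term=None`` the run is a null:
    the query is a uniform draw from the background.
    """
    from bionetkit.enrichment import AnnotationSet, write_annotations

    rng = np.random.default_rng(seed)
    genes = [f"g{i+1:05d}" for i in range(n_genes)]
    categories = ("GO_BP", "GO_MF", "GO_CC", "pathway", "disease",
                  "cell_type", "tissue", "phenotype_anatomy")
    query = [genes[int(i)] for i in
             rng.choice(n_genes, size=query_size, replace=False)]

    annotations = []
    truth = GroundTruth(seed=seed)
    for t in range(n_terms):
        members = {genes[int(i)] for i in
                   rng.choice(n_genes, size=term_size, replace=False)}
        extra = rng.random(n_genes) < membership_density
        members |= {g for g, keep in zip(genes, extra) if keep}
        annotations.append(AnnotationSet(
            category=categories[t % len(categories)],
            term_id=f"T{t+1:03d}", term_label=f"term {t+1}",
            genes=frozenset(members),
        ))
    if planted_term is not None:
        non_query = [g for g in genes if g not in set(query)]
        filler = [non_query[int(i)] for i in
                  rng.choice(len(non_query),
                             size=max(term_size - planted_hits, 0), replace=False)]
        members = frozenset(query[:planted_hits]) | frozenset(filler)
        annotations.append(AnnotationSet(
            category="GO_BP", term_id=planted_term,
            term_label="planted theme", genes=members,
        ))
        truth.planted_enriched_terms.append(
            {"term": planted_term, "genes": sorted(query[:planted_hits])}
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_annotations(annotations, out_dir / "annotations.tsv")
        with open(out_dir / "query_genes.txt", "w") as fh:
            fh.write("\n".join(query) + "\n")
        truth.write(out_dir / "ground_truth.json")
    return annotations, query, truth
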