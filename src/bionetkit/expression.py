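"""Multi-experiment co-expression mining over an expression compendium.

A compendium holds many expression experiments (genes × conditions matrices
of differing widths). Each experiment is z-score normalized per gene; pairwise
Pearson correlations get p-values that account for the number of conditions
(a t-statistic on n−2 degrees of freedom), Benjamini–Hochberg corrected
within each experiment. Three search modes mirror the classic compendium
queries: differential experiments for a gene list, co-expressed pairs, and
co-expressed triples (all three member pairs co-expressed in the same
experiment — the signature of a transcriptional module).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: default thresholds; min_support follows the "co-expressed in more than
#: 10 experiments" retention rule, others are the package defaults
DEFAULT_ALPHA = 0.05
DEFAULT_R_MIN = 0.5
DEFAULT_MIN_SUPPORT = 10
DEFAULT_Z_CUT = 2.0


@dataclass
class ExperimentMatrix:
    """One expression experiment: genes × conditions with metadata.

    ``values`` is a genes × conditions float array; missing measurements are
    NaN (never silently zero). ``metadata`` may carry ``case_conditions``, a
    list of condition labels treated as the perturbed/case columns by the
    differential-experiment search.
    """

    experiment_id: str
    gene_ids: list[str]
    values: np.ndarray
    condition_labels: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    normalized: bool = False
    constant_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes × conditions matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("row count must equal the number of gene ids")
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError(f"duplicate gene ids in {self.experiment_id}")
        if not self.condition_labels:
            self.condition_labels = [f"c{i+1}" for i in range(self.values.shape[1])]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray | None:
        try:
            return self.values[self.gene_ids.index(gene)]
        except ValueError:
            return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.condition_labels)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path, experiment_id: str | None = None,
                 metadata: dict | None = None) -> "ExperimentMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            experiment_id=experiment_id or Path(path).stem,
            gene_ids=[str(g) for g in df.index],
            values=df.to_numpy(dtype=float),
            condition_labels=[str(c) for c in df.columns],
            metadata=metadata or {},
        )


class Compendium:
    """An ordered collection of experiments, queried together."""

    def __init__(self, experiments: list[ExperimentMatrix] | None = None):
        self.experiments: dict[str, ExperimentMatrix] = {}
        for exp in experiments or []:
            self.add(exp)

    def add(self, exp: ExperimentMatrix) -> None:
        if exp.experiment_id in self.experiments:
            raise ValueError(f"duplicate experiment id {exp.experiment_id}")
        self.experiments[exp.experiment_id] = exp

    def __iter__(self):
        return iter(self.experiments.values())

    def __len__(self):
        return len(self.experiments)

    def normalize(self) -> "Compendium":
        out = Compendium()
        for exp in self:
            out.add(normalize_experiment(exp))
        return out

    @classmethod
    def from_dir(cls, directory) -> "Compendium":
        """Load every ``*.tsv`` matrix in a directory (sorted by name).

        A sidecar ``<name>.meta`` of ``key=value`` lines, when present, is
        parsed into the experiment's metadata; a ``case_conditions`` key is
        split on commas.
        """
        directory = Path(directory)
        comp = cls()
        for path in sorted(directory.glob("*.tsv")):
            meta: dict = {}
            sidecar = path.with_suffix(".meta")
            if sidecar.exists():
                for line in sidecar.read_text().splitlines():
                    if "=" in line:
                        k, v = line.split("=", 1)
                        meta[k.strip()] = v.strip()
                if "case_conditions" in meta:
                    meta["case_conditions"] = [
                        c.strip() for c in meta["case_conditions"].split(",") if c.strip()
                    ]
            comp.add(ExperimentMatrix.read_tsv(path, metadata=meta))
        return comp


@dataclass(frozen=True)
class CoexpressionRecord:
    """Per-experiment evidence for one pair (or the pairs of one triple)."""

    members: tuple[str, ...]
    experiment_id: str
    r: float
    p: float
    q: float

    def __post_init__(self):
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


@dataclass
class CoexpressionResult:
    """A pair or triple with the experiments supporting its co-expression."""

    members: tuple[str, ...]
    supporting_experiments: list[str]
    records: list[CoexpressionRecord] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.supporting_experiments)

    @property
    def mean_abs_r(self) -> float:
        if not self.records:
            return 0.0
        return float(np.mean([abs(rec.r) for rec in self.records]))


# ---------------------------------------------------------------------------
# elementary statistics


def normalize_experiment(exp: ExperimentMatrix) -> ExperimentMatrix:
    """Z-score each gene's expression vector (mean 0, unit sample SD).

    Constant vectors cannot be normalized; they are flagged in
    ``constant_genes`` and their rows set to NaN so they are excluded from
    correlation rather than divided by zero. Idempotent up to float error.
    """
    if exp.n_conditions < 2:
        raise ValueError(
            f"{exp.experiment_id}: normalization needs at least 2 conditions"
        )
    values = exp.values.copy()
    constant: set[str] = set(exp.constant_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    for i, gene in enumerate(exp.gene_ids):
        if np.all(np.isnan(values[i])):
            constant.add(gene)
            continue
        if sd[i, 0] == 0 or np.isnan(sd[i, 0]):
            constant.add(gene)
            values[i] = np.nan
        else:
            values[i] = (values[i] - mu[i, 0]) / sd[i, 0]
    return ExperimentMatrix(
        experiment_id=exp.experiment_id,
        gene_ids=list(exp.gene_ids),
        values=values,
        condition_labels=list(exp.condition_labels),
        metadata=dict(exp.metadata),
        normalized=True,
        constant_genes=frozenset(constant),
    )


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        raise ValueError("constant input has no defined correlation")
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    return max(-1.0, min(1.0, r))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation on n observations.

    Uses t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom, so experiments
    with more conditions yield smaller p at the same |r| — the vector-length
    awareness the per-experiment correction relies on.
    """
    if n < 4:
        raise ValueError("p-value needs n >= 4")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (order preserved)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# search modes


def find_differential_experiments(
    genes, compendium: Compendium, z_cut: float = DEFAULT_Z_CUT
) -> dict[str, dict[str, list[str]]]:
    """Experiments where query genes are over- or under-expressed.

    A gene counts as over-expressed in an experiment when the mean of its
    normalized values over the experiment's case conditions is >= ``z_cut``
    (under-expressed: <= −z_cut). Case conditions come from the experiment's
    ``case_conditions`` metadata; without it, all conditions are considered
    and the criterion is applied to the per-condition maximum deviation.
    Experiments with no hits are omitted; unknown genes are skipped.
    """
    genes = list(dict.fromkeys(genes))
    out: dict[str, dict[str, list[str]]] = {}
    for exp in compendium:
        nexp = exp if exp.normalized else normalize_experiment(exp)
        case = nexp.metadata.get("case_conditions")
        if case:
            cols = [i for i, c in enumerate(nexp.condition_labels) if c in set(case)]
        else:
            cols = None
        over, under = [], []
        for gene in genes:
            vec = nexp.row(gene)
            if vec is None or gene in nexp.constant_genes:
                continue
            if cols is not None:
                score = float(np.nanmean(vec[cols]))
            else:
                score = float(vec[np.nanargmax(np.abs(vec))])
            if score >= z_cut:
                over.append(gene)
            elif score <= -z_cut:
                under.append(gene)
        if over or under:
            out[exp.experiment_id] = {"over": over, "under": under}
    return out


def _pair_records(
    exp: ExperimentMatrix, genes: list[str], alpha: float, r_min: float
) -> dict[tuple[str, str], CoexpressionRecord]:
    """All significant pair calls in one experiment.

    Tests every pair of query genes present and non-constant; BH correction
    is applied within the experiment over all tested pairs. Missing values
    use pairwise-complete observations with the effective n in the p-value;
    pairs with effective n < 4 are skipped.
    """
    nexp = exp if exp.normalized else normalize_experiment(exp)
    present = [g for g in genes if nexp.row(g) is not None
               and g not in nexp.constant_genes]
    tested: list[tuple[tuple[str, str], float, float]] = []
    for g1, g2 in itertools.combinations(sorted(present), 2):
        x, y = nexp.row(g1), nexp.row(g2)
        mask = ~(np.isnan(x) | np.isnan(y))
        n_eff = int(mask.sum())
        if n_eff < 4:
            continue
        xs, ys = x[mask], y[mask]
        if np.std(xs) == 0 or np.std(ys) == 0:
            continue
        r = pearson(xs, ys)
        tested.append(((g1, g2), r, correlation_pvalue(r, n_eff)))
    if not tested:
        return {}
    qvals = fdr_adjust([t[2] for t in tested])
    out: dict[tuple[str, str], CoexpressionRecord] = {}
    for (pair, r, p), q in zip(tested, qvals):
        if q <= alpha and abs(r) >= r_min:
            out[pair] = CoexpressionRecord(pair, exp.experiment_id, r, p, float(q))
    return out


def find_coexpressed_pairs(
    genes,
    compendium: Compendium,
    alpha: float = DEFAULT_ALPHA,
    r_min: float = DEFAULT_R_MIN,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[CoexpressionResult]:
    """Gene pairs co-expressed in more than ``min_support`` experiments.

    A pair is co-expressed in an experiment when its BH-adjusted correlation
    q-value is <= ``alpha`` and |r| >= ``r_min`` there. Results are sorted by
    support (descending), then mean |r|, then member ids.
    """
    genes = sorted(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValueError("need at least 2 query genes")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    hits: dict[tuple[str, str], CoexpressionResult] = {}
    for exp in compendium:
        for pair, rec in _pair_records(exp, genes, alpha, r_min).items():
            res = hits.setdefault(pair, CoexpressionResult(pair, []))
            if rec.experiment_id not in res.supporting_experiments:
                res.supporting_experiments.append(rec.experiment_id)
                res.records.append(rec)
    kept = [res for res in hits.values() if res.support > min_support]
    kept.sort(key=lambda r: (-r.support, -r.mean_abs_r, r.members))
    return kept


def find_coexpressed_triples(
    genes,
    compendium: Compendium,
    alpha: float = DEFAULT_ALPHA,
    r_min: float = DEFAULT_R_MIN,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[CoexpressionResult]:
    """Gene triples whose three member pairs are all co-expressed together.

    A triple is co-expressed in an experiment when each of its three pairs
    meets the pair criterion there; support counts experiments, as for pairs.
    Triples of co-expressed genes are the unit of regulatory-module discovery.
    """
    genes = sorted(dict.fromkeys(genes))
    if len(genes) < 3:
        raise ValueError("need at least 3 query genes")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    hits: dict[tuple[str, str, str], CoexpressionResult] = {}
    for exp in compendium:
        pair_calls = _pair_records(exp, genes, alpha, r_min)
        for triple in itertools.combinations(genes, 3):
            pairs = list(itertools.combinations(triple, 2))
            if all(p in pair_calls for p in pairs):
                res = hits.setdefault(triple, CoexpressionResult(triple, []))
                res.supporting_experiments.append(exp.experiment_id)
                res.records.extend(pair_calls[p] for p in pairs)
    kept = [res for res in hits.values() if res.support > min_support]
    kept.sort(key=lambda r: (-r.support, -r.mean_abs_r, r.members))
    return kept
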