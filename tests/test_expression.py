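"""Normalization, correlation statistics, and co-expression mining."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from bionetkit import synth
from bionetkit.expression import (
    Compendium,
    ExperimentMatrix,
    correlation_pvalue,
    fdr_adjust,
    find_coexpressed_pairs,
    find_coexpressed_triples,
    find_differential_experiments,
    normalize_experiment,
    pearson,
)


def make_exp(values, eid="e1", genes=None, **kw):
    values = np.asarray(values, dtype=float)
    return ExperimentMatrix(
        experiment_id=eid,
        gene_ids=genes or [f"g{i}" for i in range(values.shape[0])],
        values=values, **kw,
    )


class TestNormalize:
    def test_simple_vector(self):
        exp = normalize_experiment(make_exp([[1, 2, 3]]))
        assert exp.values[0] == pytest.approx([-1, 0, 1])  # sample SD = 1

    def test_constant_vector_flagged_not_divided(self):
        exp = normalize_experiment(make_exp([[5, 5, 5], [1, 2, 3]]))
        assert "g0" in exp.constant_genes
        assert np.all(np.isnan(exp.values[0]))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        exp = normalize_experiment(make_exp(rng.normal(size=(5, 10))))
        again = normalize_experiment(exp)
        assert np.allclose(exp.values, again.values, atol=1e-12)

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        exp = normalize_experiment(make_exp(rng.normal(2, 7, size=(20, 9))))
        assert np.all(np.abs(exp.values.mean(axis=1)) < 1e-10)
        assert np.all(np.abs(exp.values.std(axis=1, ddof=1) - 1) < 1e-10)

    def test_too_few_conditions_raises(self):
        with pytest.raises(ValueError):
            normalize_experiment(make_exp([[1.0]]))


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        n = 4
        # independent brute-force evaluation of the product-moment formula
        sx, sy = sum(x), sum(y)
        sxy = sum(a * b for a, b in zip(x, y))
        sxx = sum(a * a for a in x)
        syy = sum(b * b for b in y)
        oracle = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx * sx) * (n * syy - sy * sy))
        assert pearson(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r = pearson(x, y)
        assert pearson(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson(3.5 * x + 2, y) == pytest.approx(r, abs=1e-9)
        assert pearson(x, -2.0 * y + 7) == pytest.approx(-r, abs=1e-9)


class TestCorrelationPvalue:
    def test_zero_correlation_p_one(self):
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_matches_numeric_integration_oracle(self):
        # independent oracle: numerically integrate the t density (df = 8)
        r, n = 0.8, 10
        df = n - 2
        t_stat = r * math.sqrt(df / (1 - r * r))
        assert t_stat == pytest.approx(3.7712, abs=1e-3)

        def t_pdf(u):
            c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            return c * (1 + u * u / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(t_pdf, t_stat, np.inf)
        assert correlation_pvalue(r, n) == pytest.approx(2 * tail, rel=1e-8)

    def test_monotone_decreasing_in_n(self):
        assert correlation_pvalue(0.5, 20) < correlation_pvalue(0.5, 6)

    def test_perfect_correlation_p_zero(self):
        assert correlation_pvalue(1.0, 5) == 0.0
        assert correlation_pvalue(-1.0, 5) == 0.0

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 3)


class TestFdrAdjust:
    def test_hand_evaluated_step_up(self):
        # BH by hand: q_(i) = min_{j>=i} p_(j)·m/j = 0.04 for every rank here
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert fdr_adjust([0.3]) == pytest.approx([0.3])
        assert fdr_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_preserving_and_bounded(self, pvals):
        q = fdr_adjust(pvals)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


class TestDifferentialSearch:
    def test_planted_genes_recovered_exactly(self):
        genes = [f"g{i}" for i in range(20)]
        perturbed = {"g3": 10.0, "g7": 10.0, "g11": -10.0}
        exp = synth.gen_differential_experiment(genes, perturbed, seed=4)
        hits = find_differential_experiments(genes, Compendium([exp]), z_cut=2.0)
        assert set(hits[exp.experiment_id]["over"]) == {"g3", "g7"}
        assert set(hits[exp.experiment_id]["under"]) == {"g11"}

    def test_gene_absent_from_experiment_skipped(self):
        exp = synth.gen_differential_experiment(["a", "b"], {"a": 10.0}, seed=0)
        hits = find_differential_experiments(["a", "zzz"], Compendium([exp]))
        assert hits[exp.experiment_id]["over"] == ["a"]


def brute_force_pairs(genes, compendium, alpha, r_min, min_support):
    """Independent oracle: scipy.stats.pearsonr + statsmodels BH, exhaustive."""
    support = {}
    for exp in compendium:
        nexp = normalize_experiment(exp)
        present = sorted(g for g in genes if nexp.row(g) is not None
                         and g not in nexp.constant_genes)
        tested = []
        for pair in itertools.combinations(present, 2):
            x, y = nexp.row(pair[0]), nexp.row(pair[1])
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 4 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
                continue
            r, p = stats.pearsonr(x[mask], y[mask])
            tested.append((pair, r, p))
        if not tested:
            continue
        q = multipletests([t[2] for t in tested], method="fdr_bh")[1]
        for (pair, r, _p), qv in zip(tested, q):
            if qv <= alpha and abs(r) >= r_min:
                support.setdefault(pair, []).append(exp.experiment_id)
    return {pair: exps for pair, exps in support.items()
            if len(exps) > min_support}


def brute_force_triples(genes, compendium, alpha, r_min, min_support):
    pair_support = brute_force_pairs(genes, compendium, alpha, r_min, -1)
    per_exp = {}
    for pair, exps in pair_support.items():
        for e in exps:
            per_exp.setdefault(e, set()).add(pair)
    support = {}
    for triple in itertools.combinations(sorted(set(genes)), 3):
        pairs = set(itertools.combinations(triple, 2))
        for e, called in per_exp.items():
            if pairs <= called:
                support.setdefault(triple, []).append(e)
    return {t: sorted(e) for t, e in support.items() if len(e) > min_support}


@pytest.fixture(scope="module")
def small_compendium():
    comp, _ = synth.gen_compendium(
        n_genes=10, n_experiments=5, conditions_range=(8, 14),
        modules=[(4, 3, 0.95)], seed=21,
    )
    return comp


class TestPairMining:
    def test_equals_brute_force_enumeration(self, small_compendium):
        genes = next(iter(small_compendium)).gene_ids
        mined = find_coexpressed_pairs(genes, small_compendium,
                                       alpha=0.05, r_min=0.5, min_support=1)
        oracle = brute_force_pairs(genes, small_compendium, 0.05, 0.5, 1)
        assert {r.members: sorted(r.supporting_experiments) for r in mined} \
            == {p: sorted(e) for p, e in oracle.items()}

    def test_identical_vectors_supported_everywhere(self):
        rng = np.random.default_rng(3)
        exps = []
        for j in range(12):
            v = rng.normal(size=10)
            noise = rng.normal(size=(1, 10)) * 0.0
            exps.append(make_exp(np.vstack([v, v + noise]), eid=f"e{j}",
                                 genes=["a", "b"]))
        res = find_coexpressed_pairs(["a", "b"], Compendium(exps),
                                     alpha=0.05, r_min=0.5, min_support=10)
        assert len(res) == 1
        assert res[0].support == 12

    def test_independent_genes_yield_nothing(self):
        comp, _ = synth.gen_compendium(n_genes=8, n_experiments=12,
                                       modules=[], seed=9)
        res = find_coexpressed_pairs(next(iter(comp)).gene_ids, comp,
                                     alpha=0.01, r_min=0.5, min_support=10)
        assert res == []

    def test_needs_two_genes(self, small_compendium):
        with pytest.raises(ValueError):
            find_coexpressed_pairs(["g0001"], small_compendium)

    def test_result_ordering_deterministic(self, small_compendium):
        genes = next(iter(small_compendium)).gene_ids
        a = find_coexpressed_pairs(genes, small_compendium, min_support=1)
        b = find_coexpressed_pairs(list(reversed(genes)), small_compendium,
                                   min_support=1)
        assert [r.members for r in a] == [r.members for r in b]


class TestTripleMining:
    def test_equals_brute_force_enumeration(self):
        comp, _ = synth.gen_compendium(
            n_genes=6, n_experiments=4, conditions_range=(10, 12),
            modules=[(3, 3, 0.95)], seed=5,
        )
        genes = next(iter(comp)).gene_ids
        mined = find_coexpressed_triples(genes, comp, alpha=0.05,
                                         r_min=0.5, min_support=0)
        oracle = brute_force_triples(genes, comp, 0.05, 0.5, 0)
        assert {r.members: sorted(r.supporting_experiments) for r in mined} \
            == oracle

    def test_identical_vectors_form_triple(self):
        v = np.sin(np.arange(10))
        exp = make_exp(np.vstack([v, v, v]), genes=["a", "b", "c"])
        res = find_coexpressed_triples(["a", "b", "c"], Compendium([exp]),
                                       alpha=0.05, r_min=0.5, min_support=0)
        assert len(res) == 1 and res[0].members == ("a", "b", "c")

    def test_one_failing_pair_excludes_triple(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=12)
        w = rng.normal(size=12)  # independent of v
        exp = make_exp(np.vstack([v, v, w]), genes=["a", "b", "c"])
        res = find_coexpressed_triples(["a", "b", "c"], Compendium([exp]),
                                       alpha=0.05, r_min=0.9, min_support=0)
        assert res == []


class TestMissingValues:
    def test_pairwise_complete_with_effective_n(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan])
        y = np.array([2.0, 4, 6.2, 7.9, 10.1, 3.0])
        exp = make_exp(np.vstack([x, y]), genes=["a", "b"])
        res = find_coexpressed_pairs(["a", "b"], Compendium([exp]),
                                     alpha=0.05, r_min=0.5, min_support=0)
        assert len(res) == 1
        rec = res[0].records[0]
        # oracle on the 5 complete observations
        r_o, p_o = stats.pearsonr(
            stats.zscore(x[:5], ddof=1), stats.zscore(y[:5], ddof=1))
        assert rec.r == pytest.approx(r_o, abs=1e-12)
        assert rec.p == pytest.approx(p_o, rel=1e-9)

    def test_insufficient_overlap_skipped(self):
        x = np.array([1.0, 2, 3, np.nan, np.nan, np.nan])
        y = np.array([np.nan, 4, 6, 8, 1, 2])
        exp = make_exp(np.vstack([x, y]), genes=["a", "b"])
        res = find_coexpressed_pairs(["a", "b"], Compendium([exp]),
                                     alpha=1 - 1e-9, r_min=0.0, min_support=0)
        assert res == []


class TestPlantedModuleRecovery:
    def test_module_recovered_with_high_support(self):
        comp, truth = synth.gen_compendium(
            n_genes=40, n_experiments=40, conditions_range=(30, 30),
            modules=[(8, 15, 0.9)], seed=0,
        )
        module = truth.planted_coexpression_modules[0]
        res = find_coexpressed_pairs(
            next(iter(comp)).gene_ids, comp,
            alpha=0.001, r_min=0.7, min_support=10,
        )
        planted = set(itertools.combinations(sorted(module["genes"]), 2))
        assert {r.members for r in res} == planted
        assert min(r.support for r in res) >= 15 * 0.9
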