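import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psymeta import (
    aw_fisher,
    combine_databases,
    combine_logfc,
    fisher_stat,
    impute_missing_pvalues,
    select_common_degs,
)
from psymeta.concordance import ConcordanceRecord
from psymeta.dge import DGETable
from psymeta.meta import _weight_matrix, build_null_table
from psymeta.io_core import spawn_rng


def brute_force_aw(pvals):
    """Independent enumeration oracle: explicit loop over all nonzero weights.

    Returns (min candidate p, best weight) with the most-inclusive-then-
    lexicographic tie-break, computed with plain Python loops.
    """
    k = len(pvals)
    best_p, best_w = None, None
    candidates = [w for w in itertools.product((0, 1), repeat=k) if any(w)]
    candidates.sort(key=lambda w: (-sum(w), w))
    for w in candidates:
        t = sum(-2.0 * np.log(max(p, 1e-300)) for p, wi in zip(pvals, w) if wi)
        cand = stats.chi2.sf(t, 2 * sum(w))
        if best_p is None or cand < best_p:
            best_p, best_w = cand, w
    return best_p, best_w


def table_of(study_id, genes, ps, logfcs=None, reporting="full", threshold=None):
    df = pd.DataFrame(
        {
            "gene": genes,
            "logFC": logfcs if logfcs is not None else np.nan,
            "p": ps,
        }
    )
    return DGETable(study_id=study_id, table=df, reporting=reporting, threshold=threshold)


class TestImputation:
    def test_censored_mean_for_missing_gene(self):
        full = table_of("F", ["a", "b", "c"], [0.5, 0.6, 0.7])
        part = table_of("P", ["a"], [0.01], reporting="partial", threshold=0.05)
        out = impute_missing_pvalues([full, part])
        completed = out[1].table.set_index("gene")
        assert completed.loc["b", "p"] == pytest.approx(0.525)
        assert bool(completed.loc["b", "imputed"]) is True

    def test_degenerate_threshold_one_imputes_one(self):
        full = table_of("F", ["a", "b"], [0.5, 0.6])
        part = table_of("P", ["a"], [0.9], reporting="partial", threshold=1.0)
        out = impute_missing_pvalues([full, part])
        assert out[1].table.set_index("gene").loc["b", "p"] == pytest.approx(1.0)

    def test_present_genes_untouched_and_full_tables_passthrough(self):
        full = table_of("F", ["a", "b"], [0.5, 0.6])
        part = table_of("P", ["a"], [0.01], reporting="partial", threshold=0.05)
        out = impute_missing_pvalues([full, part])
        assert out[1].table.set_index("gene").loc["a", "p"] == pytest.approx(0.01)
        np.testing.assert_allclose(out[0].table["p"], [0.5, 0.6])

    def test_grand_mean_alternative(self):
        full = table_of("F", ["a", "b"], [0.5, 0.6])
        part = table_of("P", ["a"], [0.02], reporting="partial", threshold=0.05)
        out = impute_missing_pvalues([full, part], method="grand_mean")
        assert out[1].table.set_index("gene").loc["b", "p"] == pytest.approx(0.02)

    def test_partial_without_threshold_rejected(self):
        part = table_of("P", ["a"], [0.01])
        part.reporting = "partial"  # bypass constructor check deliberately
        with pytest.raises(ValueError, match="threshold"):
            impute_missing_pvalues([part])


class TestFisherStat:
    def test_worked_value(self):
        t, p = fisher_stat(np.array([0.5, 0.5]), np.array([1, 1]))
        assert t == pytest.approx(2.7726, abs=1e-4)
        assert p == pytest.approx(0.5966, abs=1e-4)

    def test_single_study_reduction(self):
        t, _ = fisher_stat(np.array([0.2, 0.3]), np.array([0, 1]))
        assert t == pytest.approx(-2 * np.log(0.3))

    def test_all_ones_input_gives_p_one(self):
        t, p = fisher_stat(np.array([1.0, 1.0]), np.array([1, 1]))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            fisher_stat(np.array([0.5]), np.array([0]))

    def test_classical_fisher_closed_form(self):
        rng = np.random.default_rng(4)
        for k in (2, 3, 5):
            p = rng.uniform(size=k)
            t, cand = fisher_stat(p, np.ones(k, dtype=int))
            ref = stats.chi2.sf(-2 * np.log(p).sum(), 2 * k)
            assert cand == pytest.approx(ref, abs=1e-12)


class TestAWFisher:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_brute_force_enumeration(self, k):
        rng = np.random.default_rng(100 + k)
        pmat = rng.uniform(size=(1000, k))
        rng_null = spawn_rng(1, "null")
        results = aw_fisher(pmat, B=200, rng=rng_null)
        for row, res in zip(pmat, results):
            ref_p, ref_w = brute_force_aw(list(row))
            assert res.observed_min_candidate_p == pytest.approx(ref_p, rel=1e-12)
            assert res.weights == ref_w

    def test_single_study_combined_p_near_input(self):
        pmat = np.array([[0.3], [0.04], [0.9]])
        rng = spawn_rng(2, "null")
        results = aw_fisher(pmat, B=20_000, rng=rng)
        for row, res in zip(pmat, results):
            assert res.weights == (1,)
            assert res.p_combined == pytest.approx(row[0], abs=0.02)

    def test_informative_study_selected(self):
        rng = spawn_rng(3, "null")
        (r,) = aw_fisher(np.array([[0.001, 0.9]]), B=1000, rng=rng)
        assert r.weights == (1, 0)

    def test_two_concordant_studies_jointly_selected(self):
        rng = spawn_rng(3, "null")
        (r,) = aw_fisher(np.array([[0.01, 0.01]]), B=1000, rng=rng)
        assert r.weights == (1, 1)

    def test_monotone_in_each_study_p(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(size=3)
            base, _ = brute_force_aw(list(p))
            j = rng.integers(3)
            q = p.copy()
            q[j] *= rng.uniform()
            better, _ = brute_force_aw(list(q))
            assert better <= base + 1e-15

    def test_null_calibration(self):
        rng_data = np.random.default_rng(9)
        pmat = rng_data.uniform(size=(2000, 3))
        rng_null = spawn_rng(9, "null")
        results = aw_fisher(pmat, B=10_000, rng=rng_null)
        frac = np.mean([r.p_combined < 0.05 for r in results])
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_combined_p_floored_at_inverse_table_size(self):
        rng = spawn_rng(10, "null")
        (r,) = aw_fisher(np.array([[1e-50, 1e-50]]), B=500, rng=rng)
        assert r.p_combined == pytest.approx(1 / 501)

    def test_weight_enumeration_bounds(self):
        with pytest.raises(ValueError):
            _weight_matrix(0)
        with pytest.raises(ValueError):
            _weight_matrix(21)
        assert len(_weight_matrix(4)) == 15


class TestCombineDatabases:
    def test_joint_signal_gets_full_weight(self):
        a = aw_fisher(np.array([[0.001]]), genes=["g"], B=500, rng=spawn_rng(1, "a"))
        b = aw_fisher(np.array([[0.001]]), genes=["g"], B=500, rng=spawn_rng(1, "b"))
        cross, dropped = combine_databases(a, b, B=5000, rng=spawn_rng(1, "x"))
        assert dropped == []
        assert cross[0].weights == (1, 1)
        assert cross[0].p_combined < 0.05

    def test_one_sided_signal_weighted_to_one_database(self):
        a = aw_fisher(np.array([[0.001]]), genes=["g"], B=500, rng=spawn_rng(2, "a"))
        b = aw_fisher(np.array([[0.99]]), genes=["g"], B=500, rng=spawn_rng(2, "b"))
        cross, _ = combine_databases(a, b, B=5000, rng=spawn_rng(2, "x"))
        assert cross[0].weights == (1, 0)

    def test_unshared_genes_dropped_and_logged(self):
        a = aw_fisher(np.array([[0.5], [0.2]]), genes=["g", "only_a"], B=200, rng=spawn_rng(3, "a"))
        b = aw_fisher(np.array([[0.5]]), genes=["g"], B=200, rng=spawn_rng(3, "b"))
        cross, dropped = combine_databases(a, b, B=500, rng=spawn_rng(3, "x"))
        assert [r.gene for r in cross] == ["g"]
        assert dropped == ["only_a"]

    def test_empty_intersection_rejected(self):
        a = aw_fisher(np.array([[0.5]]), genes=["x"], B=200, rng=spawn_rng(4, "a"))
        b = aw_fisher(np.array([[0.5]]), genes=["y"], B=200, rng=spawn_rng(4, "b"))
        with pytest.raises(ValueError):
            combine_databases(a, b, B=200, rng=spawn_rng(4, "x"))


class TestCombineLogFC:
    def test_inverse_p_weighting_arithmetic(self):
        t1 = table_of("S1", ["g"], [0.01], logfcs=[1.0])
        t2 = table_of("S2", ["g"], [0.1], logfcs=[0.0])
        pooled = combine_logfc([t1, t2])
        assert pooled["g"] == pytest.approx((100 * 1 + 10 * 0) / 110)

    def test_single_study_passthrough(self):
        t1 = table_of("S1", ["g"], [0.3], logfcs=[0.7])
        assert combine_logfc([t1])["g"] == pytest.approx(0.7)

    def test_equal_pvalues_give_arithmetic_mean(self):
        t1 = table_of("S1", ["g"], [0.2], logfcs=[1.0])
        t2 = table_of("S2", ["g"], [0.2], logfcs=[3.0])
        assert combine_logfc([t1, t2])["g"] == pytest.approx(2.0)

    def test_no_logfc_anywhere_marked_unavailable(self):
        t1 = table_of("S1", ["g"], [0.2])
        assert np.isnan(combine_logfc([t1])["g"])


class TestSelectCommonDEGs:
    def _inputs(self, p_cross, weights, status_a, status_b):
        a = aw_fisher(np.array([[0.01]]), genes=["g"], B=200, rng=spawn_rng(5, "a"))
        b = aw_fisher(np.array([[0.01]]), genes=["g"], B=200, rng=spawn_rng(5, "b"))
        cross = aw_fisher(np.array([[0.01, 0.01]]), genes=["g"], B=200, rng=spawn_rng(5, "x"))
        cross[0].p_combined = p_cross
        cross[0].weights = weights
        ca = [ConcordanceRecord("g", "A", status_a, 2, 1)]
        cb = [ConcordanceRecord("g", "B", status_b, 2, 1)]
        lfc = pd.Series({"g": 0.5})
        return cross, a, b, ca, cb, lfc, lfc

    @pytest.mark.parametrize(
        "p,w,sa,sb,expected",
        [
            (0.01, (1, 1), "C", "S", True),
            (0.01, (1, 0), "C", "C", False),
            (0.01, (1, 1), "C", "D", False),
            (0.2, (1, 1), "C", "C", False),
        ],
    )
    def test_common_deg_definition(self, p, w, sa, sb, expected):
        results = select_common_degs(*self._inputs(p, w, sa, sb), alpha=0.05)
        assert results[0].is_common_deg is expected

    def test_direction_labels(self):
        cross, a, b, ca, cb, _, _ = self._inputs(0.01, (1, 1), "C", "C")
        up = select_common_degs(cross, a, b, ca, cb, pd.Series({"g": 0.5}), pd.Series({"g": 0.3}))
        mixed = select_common_degs(cross, a, b, ca, cb, pd.Series({"g": 0.5}), pd.Series({"g": -0.3}))
        down = select_common_degs(cross, a, b, ca, cb, pd.Series({"g": -0.5}), pd.Series({"g": -0.3}))
        assert up[0].direction == "up"
        assert mixed[0].direction == "mixed"
        assert down[0].direction == "down"


class TestNullTableSharing:
    def test_null_table_is_deterministic_given_stream(self):
        t1 = build_null_table(3, 500, spawn_rng(1, "null"))
        t2 = build_null_table(3, 500, spawn_rng(1, "null"))
        np.testing.assert_array_equal(t1, t2)
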