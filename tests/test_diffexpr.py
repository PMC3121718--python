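"""Factorial models, laboratory-consistency filter, BH, significance calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lesionlink.diffexpr import (DEGeneSet, FactorialDE, benjamini_hochberg,
                                 call_de, combine_analyses, consistency_filter,
                                 design_matrices, fit_full_model, fold_change)
from lesionlink.normalize import ExpressionMatrix

from conftest import make_balanced_sheet


def _noise_matrix(sheet, n_probesets, rng, sd=0.25):
    vals = rng.normal(8.0, 0.0, size=(n_probesets, len(sheet))) + \
        rng.normal(0.0, sd, size=(n_probesets, len(sheet)))
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"PS{i:04d}" for i in range(n_probesets)],
                     columns=sheet["sample_id"].tolist()), scale="log2")


class TestFullModel:
    def test_noiseless_treatment_recovery(self, balanced_sheet):
        y = np.where(balanced_sheet["treatment"] == "MAM", 9.0, 8.0)
        fit = fit_full_model(y, balanced_sheet)
        assert fit.coef["treatment"] == pytest.approx(1.0, abs=1e-10)
        assert fit.pvalues["treatment"] < 1e-12

    def test_matches_normal_equations_oracle(self, balanced_sheet, rng):
        """Coefficients agree with a brute-force normal-equations solve."""
        y = rng.normal(8.0, 0.5, size=len(balanced_sheet))
        fit = fit_full_model(y, balanced_sheet)
        X, _ = design_matrices(balanced_sheet)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coef.to_numpy(), beta, atol=1e-8)

    def test_matches_statsmodels(self, balanced_sheet, rng):
        sm = pytest.importorskip("statsmodels.api")
        y = rng.normal(8.0, 0.5, size=len(balanced_sheet))
        fit = fit_full_model(y, balanced_sheet)
        X, _ = design_matrices(balanced_sheet)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coef.to_numpy(), ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), ref.pvalues, atol=1e-10)

    def test_null_pvalues_uniform(self, balanced_sheet, rng):
        """Pure-noise responses give uniform p-values per term (KS, alpha=.01)."""
        pvals = {t: [] for t in ("treatment", "genotype", "interaction")}
        for _ in range(600):
            y = rng.normal(0.0, 1.0, size=len(balanced_sheet))
            fit = fit_full_model(y, balanced_sheet)
            for t in pvals:
                pvals[t].append(fit.pvalues[t])
        for t, p in pvals.items():
            assert stats.kstest(p, "uniform").pvalue > 0.01, t

    def test_rank_deficient_design_rejected(self, balanced_sheet, rng):
        broken = balanced_sheet.copy()
        broken.loc[broken["site"] == "siteB", "treatment"] = "MAM"  # empty cell
        with pytest.raises(np.linalg.LinAlgError):
            fit_full_model(rng.normal(size=len(broken)), broken)


class TestConsistencyFilter:
    def test_nonsignificant_lab_interactions_reduce(self, balanced_sheet, rng):
        y = rng.normal(8.0, 0.25, size=len(balanced_sheet))
        fit = fit_full_model(y, balanced_sheet)
        if (fit.lab_interaction_pvalues > 0.15).all():
            status, reduced = consistency_filter(fit)
            assert status == "reduced"
            assert list(reduced.coef.index) == ["intercept", "treatment",
                                                "genotype", "interaction", "lab"]

    def test_planted_lab_interaction_excluded(self, balanced_sheet, rng):
        """A 2.0-log2 site x treatment interaction is caught >= 95% of the time."""
        excluded = 0
        n = 120
        mam_b = ((balanced_sheet["treatment"] == "MAM")
                 & (balanced_sheet["site"] == "siteB")).to_numpy()
        for _ in range(n):
            y = rng.normal(8.0, 0.25, size=len(balanced_sheet))
            y[mam_b] += 2.0
            status, _ = consistency_filter(fit_full_model(y, balanced_sheet))
            excluded += status == "excluded"
        assert excluded / n >= 0.95

    def test_zero_alpha_always_reduces(self, balanced_sheet, rng):
        for _ in range(10):
            y = rng.normal(8.0, 0.25, size=len(balanced_sheet))
            status, _ = consistency_filter(fit_full_model(y, balanced_sheet),
                                           alpha_lab=0.0)
            assert status == "reduced"

    def test_joint_variant_runs(self, balanced_sheet, rng):
        y = rng.normal(8.0, 0.25, size=len(balanced_sheet))
        status, _ = consistency_filter(fit_full_model(y, balanced_sheet), joint=True)
        assert status in ("reduced", "excluded")

    def test_reduced_treatment_equals_cell_means_oracle(self, balanced_sheet, rng):
        """On a balanced design the reduced-model treatment coefficient is the
        MAM-minus-vehicle difference of log2 means (lab-adjusted)."""
        y = rng.normal(8.0, 0.25, size=len(balanced_sheet))
        status, reduced = consistency_filter(fit_full_model(y, balanced_sheet),
                                             alpha_lab=0.0)
        mam = y[(balanced_sheet["treatment"] == "MAM").to_numpy()]
        veh = y[(balanced_sheet["treatment"] == "vehicle").to_numpy()]
        assert reduced.coef["treatment"] == pytest.approx(mam.mean() - veh.mean(),
                                                          abs=1e-10)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.9]),
                                   [0.03, 0.03, 0.9])

    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_single_p(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=200)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_order_invariance(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(size=50)
        perm = r.permutation(50)
        q = benjamini_hochberg(p)
        q_perm = benjamini_hochberg(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=100)
        np.testing.assert_allclose(benjamini_hochberg(p),
                                   sm.multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)


def _results_frame(rows):
    return pd.DataFrame(rows)


class TestCallDE:
    def _frame(self, p, est, status=None):
        n = len(p)
        return pd.DataFrame({
            "probeset_id": [f"PS{i}" for i in range(n)],
            "timepoint_h": [6] * n,
            "status": status or ["reduced"] * n,
            "p_treatment": p,
            "estimate_treatment": est,
        })

    def test_both_gates_required(self):
        # q = 0.04 but |fc| = 1.25 < 1.3: not significant
        res = self._frame([0.04], [np.log2(1.25)])
        de = call_de(res, "treatment")
        assert len(de.union) == 0

    def test_fold_change_gate_is_sign_blind(self):
        res = self._frame([0.04], [-np.log2(1.5)])
        de = call_de(res, "treatment")
        assert de.union == frozenset({"PS0"})

    def test_excluded_never_significant(self):
        res = self._frame([1e-9, 1e-9], [2.0, 2.0], status=["reduced", "excluded"])
        de = call_de(res, "treatment")
        assert de.union == frozenset({"PS0"})

    def test_empty_family_warns(self):
        res = self._frame([0.01], [2.0], status=["excluded"])
        with pytest.warns(UserWarning):
            de = call_de(res, "treatment")
        assert len(de.union) == 0

    def test_fold_change_definition(self):
        np.testing.assert_allclose(fold_change([1.0, -1.0, 0.378511623]),
                                   [2.0, -2.0, 1.3], rtol=1e-6)

    def test_null_calls_controlled(self, rng):
        """No planted effects: BH plus the fold-change gate yields ~no calls."""
        sheet = make_balanced_sheet(3, timepoints=(6, 24, 48, 168))
        total_calls = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            norm = _noise_matrix(sheet, 500, r, sd=0.25)
            model = FactorialDE().fit(norm, sheet)
            total_calls += len(model.de_set("treatment").union)
        assert total_calls <= 0.05 * 500 * 5


class TestCombine:
    def test_disjoint_union(self):
        a = DEGeneSet("a", {6: frozenset({"g1", "g2", "g3"})})
        b = DEGeneSet("b", {6: frozenset({"g4", "g5", "g6", "g7"})})
        assert len(combine_analyses(a, b)) == 7

    def test_identical_sets(self):
        a = DEGeneSet("a", {6: frozenset({"g1", "g2"})})
        assert len(combine_analyses(a, a)) == 2

    def test_published_count_arithmetic(self):
        """362- and 153-gene analyses sharing 72 genes combine to 443."""
        first = frozenset(f"x{i}" for i in range(362))
        shared = sorted(first)[:72]
        second = frozenset(shared) | frozenset(f"y{i}" for i in range(153 - 72))
        a = DEGeneSet("mgmt-null MAM response", {6: first})
        b = DEGeneSet("genotype difference", {6: second})
        assert len(combine_analyses(a, b)) == 443


class TestFactorialDEEstimator:
    def test_power_on_planted_effects(self, rng):
        """Planted 1-log2 treatment effects at probeset level are recovered."""
        sheet = make_balanced_sheet(3, timepoints=(6, 24, 48, 168))
        norm = _noise_matrix(sheet, 300, rng, sd=0.25)
        vals = norm.values.copy()
        planted = vals.index[:30]
        vals.loc[planted, (sheet["treatment"] == "MAM").to_numpy()] += 1.0
        norm = ExpressionMatrix(vals, scale="log2")
        model = FactorialDE().fit(norm, sheet)
        de = model.de_set("treatment")
        sens = len(de.union & set(planted)) / len(planted)
        fdp = len(de.union - set(planted)) / max(len(de.union), 1)
        assert sens >= 0.90
        assert fdp <= 0.10

    def test_single_status_per_probeset_timepoint(self, small_study_norm, small_study):
        model = FactorialDE().fit(small_study_norm, small_study.sample_sheet)
        counts = model.results_.groupby(["probeset_id", "timepoint_h"]).size()
        assert (counts == 1).all()

    def test_params_round_trip(self):
        m = FactorialDE(fdr=0.1, min_fc=1.5)
        assert FactorialDE(**m.get_params()).get_params() == m.get_params()
        with pytest.raises(ValueError):
            m.set_params(bogus=1)
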