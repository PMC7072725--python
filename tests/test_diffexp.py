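"""ANOVA, BH adjustment, post-hoc contrasts, fold changes and tiered calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mpsprofiler as mp
from mpsprofiler.diffexp import (
    DifferentialExpressionModel,
    anova_oneway,
    bh_adjust,
    call_significance,
    log2_fold_change,
    posthoc_contrast,
)


def bh_bruteforce(p):
    """Step-up by direct evaluation: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(ps[j] * m / (j + 1) for j in range(i, m))
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestAnova:
    def test_hand_computed_toy(self):
        # SS_between = 16, SS_within = 1.5, df (2, 3) -> F = (16/2)/(1.5/3)
        F, p = anova_oneway([[0, 1], [2, 3], [4, 5]])
        assert F == pytest.approx(16.0, abs=1e-12)
        assert p == pytest.approx(float(stats.f.sf(16.0, 2, 3)), rel=1e-12)

    def test_equal_group_means_give_zero_F(self):
        F, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_F_equals_t_squared(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            F, p_f = anova_oneway([a, b])
            t, p_t, _ = posthoc_contrast(a, b, m=1)
            assert F == pytest.approx(t ** 2, rel=1e-9)
            assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            groups = [rng.normal(size=4) for _ in range(5)]
            F, p = anova_oneway(groups)
            ref = stats.f_oneway(*groups)
            assert F == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_shift_and_permutation_invariance(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=4) for _ in range(3)]
        F0, _ = anova_oneway(groups)
        F_shift, _ = anova_oneway([g + 11.5 for g in groups])
        F_perm, _ = anova_oneway([np.flip(g) for g in groups])
        assert F_shift == pytest.approx(F0, rel=1e-9)
        assert F_perm == pytest.approx(F0, rel=1e-9)

    def test_degenerate_inputs(self):
        F, p = anova_oneway([[1, 1], [2, 2]])  # zero within, unequal means
        assert np.isinf(F) and p == 0.0
        with pytest.raises(ValueError, match="untestable"):
            anova_oneway([[1, 1], [1, 1]])


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.3] * 7), [0.3] * 7)

    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.9])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.9], atol=1e-15)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert q.min() >= p.min() - 1e-15  # q >= p elementwise holds too
        assert (q >= p - 1e-15).all()

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_equals_bruteforce(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestPosthoc:
    def test_hand_example(self):
        # pooled s^2 = 5/3, t = -2 / sqrt((5/3)(1/2)), df = 6
        t, p_t, p_bonf = posthoc_contrast([1, 2, 3, 4], [3, 4, 5, 6], m=11)
        assert t == pytest.approx(-2 / np.sqrt(5 / 3 * 0.5), rel=1e-12)
        assert p_t == pytest.approx(0.0712, abs=5e-4)
        assert p_bonf == pytest.approx(min(1.0, 11 * p_t), rel=1e-12)

    def test_identical_samples(self):
        t, p_t, p_bonf = posthoc_contrast([2, 2, 2], [2, 2, 2], m=11)
        assert (t, p_t, p_bonf) == (0.0, 1.0, 1.0)

    def test_zero_variance_unequal_means(self):
        t, p_t, p_bonf = posthoc_contrast([1, 1], [0, 0], m=11)
        assert np.isinf(t) and p_t == 0.0 and p_bonf == 0.0

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a, b = rng.normal(size=5), rng.normal(size=4)
            t, p_t, _ = posthoc_contrast(a, b, m=1)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p_t == pytest.approx(ref.pvalue, rel=1e-10)


class TestLog2FoldChange:
    @pytest.mark.parametrize("grp,ctrl,expected", [
        (5.0, 5.0, 0.0),
        (7.0, 1.0, 2.0),
        (127.0, 1.0, 6.0),
    ])
    def test_reference_points(self, grp, ctrl, expected):
        assert log2_fold_change(grp, ctrl, 1.0) == pytest.approx(expected)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            log2_fold_change(1.0, 1.0, 0.0)


class TestCalls:
    def test_gate_logic(self, toy_de_table, full_sheet):
        groups = full_sheet.noncontrol_groups
        calls = call_significance(toy_de_table, mp.TIER1, groups)
        got = set(zip(calls["feature"], calls["group"], calls["direction"]))
        assert ("f_extreme", "I", "up") in got
        assert ("f_extreme", "IX", "down") in got
        assert ("f_weak", "I", "up") in got
        assert not any(f == "f_null" for f, _, _ in got)

    def test_p_gate_blocks(self, toy_de_table, full_sheet):
        toy_de_table.loc["f_weak", "p_bonf_I"] = 0.5
        calls = call_significance(toy_de_table, mp.TIER1,
                                 full_sheet.noncontrol_groups)
        assert "f_weak" not in set(calls["feature"])

    def test_lfc_gate_strict(self, toy_de_table, full_sheet):
        calls = call_significance(toy_de_table, mp.TIER3,
                                 full_sheet.noncontrol_groups)
        feats = set(calls["feature"])
        assert "f_extreme" in feats
        assert "f_boundary" not in feats  # exactly 2.5 fails the strict gate


class TestModelFit:
    def test_matches_per_feature_loop(self, small_sheet):
        """Vectorised fit equals the scalar operations feature by feature."""
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.integers(1, 2000, size=(30, len(small_sheet))),
            index=[f"g{i}" for i in range(30)],
            columns=small_sheet.sample_ids,
        )
        lengths = {f: int(l) for f, l in zip(
            counts.index, rng.integers(200, 5000, size=30))}
        model = DifferentialExpressionModel.from_counts(
            counts, lengths, small_sheet)
        res = model.fit()
        log_vals = model.expr.log_fpkm
        fpkm_vals = model.expr.fpkm
        groups = small_sheet.noncontrol_groups
        m = len(groups)
        ctrl_samples = small_sheet.samples_of("HDFa")
        pvals = []
        for f in counts.index:
            by_group = [log_vals.loc[f, small_sheet.samples_of(g)].to_numpy()
                        for g in small_sheet.groups]
            F, p = anova_oneway(by_group)
            assert res.table.loc[f, "F"] == pytest.approx(F, rel=1e-9)
            pvals.append(p)
            for g in groups:
                t, p_t, p_bonf = posthoc_contrast(
                    log_vals.loc[f, small_sheet.samples_of(g)].to_numpy(),
                    log_vals.loc[f, ctrl_samples].to_numpy(), m)
                assert res.table.loc[f, f"t_{g}"] == pytest.approx(t, rel=1e-9)
                assert res.table.loc[f, f"p_bonf_{g}"] == pytest.approx(
                    p_bonf, rel=1e-9)
                lfc = log2_fold_change(
                    fpkm_vals.loc[f, small_sheet.samples_of(g)].mean(),
                    fpkm_vals.loc[f, ctrl_samples].mean(), 1.0)
                assert res.table.loc[f, f"log2fc_{g}"] == pytest.approx(
                    lfc, rel=1e-9)
        np.testing.assert_allclose(res.table["q_bh"], bh_adjust(pvals),
                                   atol=1e-12)

    def test_untestable_features_skipped(self, small_sheet):
        counts = pd.DataFrame(
            [[10, 20, 30, 40, 50, 60, 70, 80, 90],
             [0, 0, 0, 0, 0, 0, 0, 0, 0],
             [5, 6, 7, 8, 9, 10, 11, 12, 13]],
            index=["ok1", "allzero", "ok2"],
            columns=small_sheet.sample_ids,
        )
        lengths = {"ok1": 1000, "allzero": 1000, "ok2": 1000}
        res = DifferentialExpressionModel.from_counts(
            counts, lengths, small_sheet).fit()
        assert "allzero" not in res.table.index
        assert set(res.skipped["feature"]) == {"allzero"}
        assert res.skipped["reason"].iloc[0] == "all_zero_counts"
        assert len(res.table) == 2  # BH denominator excludes the skipped one

    def test_invariants_on_fitted_table(self, recovery_results):
        res, _ = recovery_results
        tab = res.table
        assert (tab["q_bh"] >= tab["p_anova"] - 1e-15).all()
        assert ((tab["q_bh"] >= 0) & (tab["q_bh"] <= 1)).all()
        assert (tab["F"] >= 0).all()
        for g in res.groups:
            np.testing.assert_allclose(
                tab[f"p_bonf_{g}"],
                np.minimum(1.0, len(res.groups) * tab[f"p_t_{g}"]),
                atol=1e-12,
            )

    def test_summary_mentions_design(self, recovery_results):
        res, _ = recovery_results
        text = res.summary()
        assert "HDFa" in text and "tier1" in text and "tier3" in text
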