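"""Tests for the statistical layer: ANOVA/Tukey, exact WMW, cohort tests."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import dtci
from dtci.stats import REFERENCE_COHORT


def _auc_table(n_groups=7, n_rep=100, seed=0, spread=0.02):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        vals = 0.8 + 0.02 * g + spread * rng.standard_normal(n_rep)
        rows += [{"K": 4 + 2 * g, "auc": v} for v in vals]
    return pd.DataFrame(rows)


class TestAnovaTukey:
    def test_seven_by_hundred_degrees_of_freedom(self):
        anova, _ = dtci.anova_tukey(_auc_table())
        assert anova.df_between == 6
        assert anova.df_within == 693

    def test_degenerate_constant_input_flagged(self):
        table = pd.DataFrame({"K": [4] * 3 + [6] * 3, "auc": [0.5] * 6})
        anova, _ = dtci.anova_tukey(table)
        assert anova.degenerate

    def test_single_group_rejected(self):
        table = pd.DataFrame({"K": [4] * 5, "auc": np.arange(5.0)})
        with pytest.raises(ValueError):
            dtci.anova_tukey(table)

    def test_two_groups_tukey_equals_t_test(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        table = pd.DataFrame(
            {"K": [4] * 30 + [6] * 30, "auc": np.r_[x, y]}
        )
        _, tukey = dtci.anova_tukey(table)
        p_t = sps.ttest_ind(x, y, equal_var=True).pvalue
        assert np.isclose(float(tukey.table["p_adj"].iloc[0]), p_t, atol=1e-4)

    def test_f_invariant_to_location_eta_to_affine(self):
        table = _auc_table(n_groups=4, n_rep=20, seed=2)
        a1, _ = dtci.anova_tukey(table)
        t2 = table.assign(auc=table.auc + 5.0)
        a2, _ = dtci.anova_tukey(t2)
        assert np.isclose(a1.F, a2.F)
        t3 = table.assign(auc=3.0 * table.auc - 1.0)
        a3, _ = dtci.anova_tukey(t3)
        assert np.isclose(a1.partial_eta_sq, a3.partial_eta_sq)

    def test_tukey_adjusted_at_least_unadjusted(self):
        """Family-wise Tukey p is never below the unadjusted pairwise p
        computed from the same pooled within-group variance."""
        table = _auc_table(n_groups=4, n_rep=15, seed=3, spread=0.05)
        anova, tukey = dtci.anova_tukey(table)
        by_k = {k: g["auc"].to_numpy() for k, g in table.groupby("K")}
        mse = (
            sum(((v - v.mean()) ** 2).sum() for v in by_k.values())
            / anova.df_within
        )
        for _, row in tukey.table.iterrows():
            a, b = by_k[row["a"]], by_k[row["b"]]
            t = abs(a.mean() - b.mean()) / np.sqrt(
                mse * (1 / len(a) + 1 / len(b))
            )
            p_raw = 2 * sps.t.sf(t, anova.df_within)
            assert float(row["p_adj"]) >= p_raw - 1e-6


class TestWmwExact:
    def test_tiny_case_enumerated(self):
        res = dtci.wmw_exact([1, 2], [3, 4])
        assert np.isclose(res.p, 1 / 3)
        assert res.method == "enumeration"
        assert res.n_assignments == 6

    def test_identical_groups_null_symmetry(self):
        res = dtci.wmw_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.U == 4.5
        assert res.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dtci.wmw_exact([], [1.0])

    @pytest.mark.parametrize("trial", range(6))
    def test_dp_matches_brute_force_enumeration_with_ties(self, trial):
        """The subset-sum convolution equals literal enumeration of all
        C(n1+n2, n1) assignments, including tied data."""
        rng = np.random.default_rng(trial)
        x = rng.choice([0.0, 1.0, 2.0, 3.0], size=5)
        y = rng.choice([0.0, 1.0, 2.0, 3.0], size=4)
        allv = np.r_[x, y]
        n1, n = 5, 9

        def u_of(ix):
            xs = allv[list(ix)]
            ys = np.delete(allv, list(ix))
            return (xs[:, None] > ys[None, :]).sum() + 0.5 * (
                xs[:, None] == ys[None, :]
            ).sum()

        mid = n1 * (n - n1) / 2
        obs = abs(u_of(range(n1)) - mid)
        devs = [abs(u_of(c) - mid) for c in itertools.combinations(range(n), n1)]
        brute = np.mean([d >= obs - 1e-9 for d in devs])
        assert np.isclose(dtci.wmw_exact(x, y).p, brute, atol=1e-12)

    def test_cohort_split_enumeration_vs_monte_carlo(self):
        """19 vs 8 values: full-enumeration p agrees with a Monte Carlo
        permutation estimate within 3 Monte Carlo SEs."""
        rng = np.random.default_rng(7)
        x = rng.normal(0.4, 1, 19)
        y = rng.normal(0.0, 1, 8)
        en = dtci.wmw_exact(x, y)
        assert en.method == "enumeration"
        assert en.n_assignments == comb(27, 8) == 2220075
        n_mc = 100_000
        mc = dtci.wmw_exact(x, y, enumeration_cap=10, n_mc=n_mc, seed=3)
        se = np.sqrt(en.p * (1 - en.p) / n_mc)
        assert abs(en.p - mc.p) <= 3 * se

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(1, 1, 9), rng.normal(0, 1, 7)
        a = dtci.wmw_exact(x, y)
        b = dtci.wmw_exact(y, x)
        assert np.isclose(a.p, b.p)
        assert np.isclose(a.hl_shift, -b.hl_shift)
        assert np.isclose(a.U + b.U, 63)  # U + U' = n1*n2

    def test_ci_brackets_hodges_lehmann(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(1, 1, 12), rng.normal(0, 1, 9)
        res = dtci.wmw_exact(x, y)
        assert res.ci_lower <= res.hl_shift <= res.ci_upper

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        x=st.lists(st.floats(-5, 5), min_size=2, max_size=7),
        y=st.lists(st.floats(-5, 5), min_size=2, max_size=7),
    )
    def test_p_in_unit_interval_r_bounded(self, x, y):
        res = dtci.wmw_exact(x, y)
        assert 0.0 < res.p <= 1.0
        assert 0.0 <= res.r <= 1.0
        assert 0.0 <= res.U <= len(x) * len(y)


class TestCohortTests:
    def test_sex_ratio_by_grade_reproduces_reference(self):
        _, df, p = dtci.chi_squared(REFERENCE_COHORT["sex_by_grade"])
        assert df == 1
        assert abs(p - 0.33) < 0.005

    def test_sex_ratio_by_mib1_reproduces_reference(self):
        _, _, p = dtci.chi_squared(REFERENCE_COHORT["sex_by_mib1"])
        assert abs(p - 0.78) < 0.006

    def test_independent_table_statistic_zero(self):
        stat, _, p = dtci.chi_squared([[10, 20], [5, 10]])
        assert np.isclose(stat, 0.0)
        assert np.isclose(p, 1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            dtci.chi_squared([[0, 0], [3, 4]])

    def test_t_identical_groups(self):
        res = dtci.students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_t_matches_permutation_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0.8, 1, 12)
        y = rng.normal(0.0, 1, 12)
        res = dtci.students_t(x, y)
        pooled = np.r_[x, y]
        n_perm = 20000
        obs = abs(res.t)
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            t = sps.ttest_ind(pooled[:12], pooled[12:], equal_var=True).statistic
            hits += abs(t) >= obs
        p_perm = hits / n_perm
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert abs(res.p - p_perm) <= 4 * se + 0.005

    def test_single_element_group_rejected(self):
        with pytest.raises(ValueError):
            dtci.students_t([1.0], [1.0, 2.0])

    def test_degenerate_constant_groups_flagged(self):
        res = dtci.students_t([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p == 1.0


class TestGroupMeanReconstruction:
    def test_low_grade_reference_rows(self):
        rows = REFERENCE_COHORT["grade_subtype_mib1"]["low"]
        assert dtci.reconstruct_group_means(rows) == 3.4

    def test_high_grade_reference_rows(self):
        rows = REFERENCE_COHORT["grade_subtype_mib1"]["high"]
        assert dtci.reconstruct_group_means(rows) == 14.1

    def test_single_row_identity(self):
        assert dtci.reconstruct_group_means([(7, 2.5)]) == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtci.reconstruct_group_means([])


class TestPerClassComparison:
    def test_label_flip_flips_shift_sign(self, log_ratio_features, grade_labels):
        F, _ = log_ratio_features
        a = dtci.per_class_group_comparison(F, grade_labels)
        b = dtci.per_class_group_comparison(F, 1 - grade_labels)
        assert np.allclose(a["p"], b["p"])
        assert np.allclose(a["hl_shift"], -b["hl_shift"])

    def test_necrosis_enriched_classes_shift_positive(
        self, log_ratio_features, grade_labels
    ):
        """Top-ordered (necrosis-like) classes are over-occupied in the
        high-grade group of the shifted synthetic cohort."""
        F, _ = log_ratio_features
        res = dtci.per_class_group_comparison(F, grade_labels)
        top = res.iloc[-1]  # highest class number
        assert top["hl_shift"] > 0

    def test_holm_correction_monotone(self, log_ratio_features, grade_labels):
        F, _ = log_ratio_features
        res = dtci.per_class_group_comparison(F, grade_labels, correction="holm")
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_validate_cohort_rejects_inconsistent_grouping(self, small_cohort):
        _, cohort, _ = small_cohort
        bad = cohort.copy()
        bad.loc[0, "mib1_group"] = (
            "lt5" if bad.loc[0, "mib1_group"] == "ge5" else "ge5"
        )
        with pytest.raises(ValueError):
            dtci.validate_cohort(bad)
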