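import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from nbackerp.stats import (
    aicc,
    bh_fdr,
    chi_square,
    correlate_and_compare,
    evidence_p,
    km_logrank,
    lin_vs_quad_aicc,
    mixed_ancova,
    partial_eta_sq,
    two_sample_t,
)


class TestSimpleComparisons:
    def test_pooled_t_toy_samples(self):
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4

    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_summary_mode_matches_sample_mode(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.2, 15)
        full = two_sample_t(a, b)
        summ = two_sample_t(mean1=a.mean(), sd1=a.std(ddof=1), n1=12,
                            mean2=b.mean(), sd2=b.std(ddof=1), n2=15)
        assert summ.t == pytest.approx(full.t, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_chi_square_diagonal_table(self):
        stat, df, p = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_chi_square_equal_split_is_null(self):
        stat, df, p = chi_square([[9, 7], [9, 7]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_chi_square_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [3, 4]])

    def test_partial_eta_sq_identity(self):
        assert partial_eta_sq(0.0, 1, 20) == 0.0
        F = 7.3
        assert partial_eta_sq(F, 1, 28) == pytest.approx(F / (F + 28))
        with pytest.raises(ValueError):
            partial_eta_sq(-1.0, 1, 10)


class TestMixedAncova:
    def _data(self, rng, n=16, group_shift=0.0, within_shift=0.0, age_slope=0.0):
        rows = []
        for i in range(2 * n):
            g = "a" if i < n else "b"
            age = rng.uniform(11, 17)
            base = rng.normal(0, 1) + age_slope * age + (group_shift if g == "a" else 0)
            for w in ("w1", "w2"):
                y = base + (within_shift if w == "w1" else 0) + rng.normal(0, 1)
                rows.append(dict(subject=f"s{i}", group=g, w=w, age=age, y=y))
        return pd.DataFrame(rows)

    def test_matches_independent_mixed_anova_oracle(self, rng):
        """All three effects agree exactly with pingouin's mixed ANOVA."""
        pg = pytest.importorskip("pingouin")
        df = self._data(rng, within_shift=0.8, group_shift=0.4)
        res = mixed_ancova(df, dv="y", subject="subject", between="group",
                           within=["w"], covariate=None)
        oracle = pg.mixed_anova(df, dv="y", within="w", subject="subject",
                                between="group").set_index("Source")
        assert res["group"].F == pytest.approx(oracle.loc["group", "F"], rel=1e-9)
        assert res["w"].F == pytest.approx(oracle.loc["w", "F"], rel=1e-9)
        assert res["group:w"].F == pytest.approx(oracle.loc["Interaction", "F"], rel=1e-9)

    def test_constant_within_difference_is_detected_at_tiny_p(self, rng):
        """A fixed +d within-condition difference for every subject drives the
        within-effect p toward zero."""
        df = self._data(rng, within_shift=0.0)
        df.loc[df["w"] == "w1", "y"] += 5.0
        res = mixed_ancova(df, dv="y", subject="subject", between="group",
                           within=["w"], covariate=None)
        assert res["w"].p < 1e-10

    def test_type_one_error_calibrated_under_null(self):
        hits = 0
        n_sims = 100
        for seed in range(n_sims):
            df = self._data(np.random.default_rng(seed))
            res = mixed_ancova(df, dv="y", subject="subject", between="group",
                               within=["w"], covariate="age", force_covariate=True)
            hits += res["group"].p < 0.05
        assert hits <= 10  # ~alpha with binomial slack

    def test_orthogonal_covariate_rescales_f_by_df_only(self, rng):
        """A covariate with exactly zero fitted slope leaves SS untouched, so
        the group F changes only through the error df."""
        df = self._data(rng, group_shift=0.7)
        wide = df.pivot_table(index="subject", columns="w", values="y")
        ymean = wide.to_numpy().mean(axis=1)
        g = np.where([s.startswith("s0") or int(s[1:]) < 16 for s in wide.index], 1.0, -1.0)
        z = np.random.default_rng(0).normal(size=len(ymean))
        X = np.column_stack([np.ones_like(g), g, ymean])
        z = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]  # orthogonal covariate
        cov_map = dict(zip(wide.index, z))
        df["age2"] = df["subject"].map(cov_map)
        with_cov = mixed_ancova(df, dv="y", subject="subject", between="group",
                                within=["w"], covariate="age2", force_covariate=True)
        without = mixed_ancova(df, dv="y", subject="subject", between="group",
                               within=["w"], covariate=None)
        n = with_cov.n_subjects
        expect = without["group"].F * (n - 3) / (n - 2)
        assert with_cov["group"].F == pytest.approx(expect, rel=1e-9)

    def test_homogeneity_gate_downgrades(self, rng):
        df = self._data(rng)
        # build a covariate whose slope differs strongly by group
        wide = df.pivot_table(index="subject", columns="w", values="y")
        subj = df.drop_duplicates("subject").set_index("subject").loc[wide.index]
        y = wide.to_numpy().mean(axis=1)
        cov = np.where(subj["group"] == "a", y, -y) + rng.normal(0, 0.05, len(y))
        df["cov"] = df["subject"].map(dict(zip(wide.index, cov)))
        res = mixed_ancova(df, dv="y", subject="subject", between="group",
                           within=["w"], covariate="cov")
        assert res.downgraded and not res.covariate_used
        assert res.homogeneity_p < 0.05

    def test_unbalanced_design_rejected(self, rng):
        df = self._data(rng).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_ancova(df, dv="y", subject="subject", between="group", within=["w"])

    def test_effect_size_identity_on_all_effects(self, rng):
        df = self._data(rng, within_shift=0.4, group_shift=0.3)
        res = mixed_ancova(df, dv="y", subject="subject", between="group",
                           within=["w"], covariate="age", force_covariate=True)
        for e in res.effects:
            assert e.eta_p_sq == pytest.approx(e.F / (e.F + e.df2), abs=1e-12)


class TestCorrelations:
    def test_equal_correlations_give_zero_z(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(0, 1, 40)
        g = ["a"] * 20 + ["b"] * 20
        x2 = np.concatenate([x[:20], x[:20]])
        y2 = np.concatenate([y[:20], y[:20]])
        res = correlate_and_compare(x2, y2, g)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_fisher_z_closed_form(self):
        rng = np.random.default_rng(5)
        # construct samples with exact r = 0.8 and r = 0.0
        def sample_with_r(r, n):
            x = rng.normal(size=n)
            e = rng.normal(size=n)
            e -= e.mean()
            x -= x.mean()
            e -= x * (x @ e) / (x @ x)  # exactly orthogonal
            y = r * x / x.std() + np.sqrt(1 - r**2) * e / e.std()
            return x, y

        x1, y1 = sample_with_r(0.8, 20)
        x2, y2 = sample_with_r(0.0, 20)
        res = correlate_and_compare(np.concatenate([x1, x2]), np.concatenate([y1, y2]),
                                    ["a"] * 20 + ["b"] * 20)
        expect = (np.arctanh(0.8) - 0.0) / np.sqrt(2.0 / 17.0)
        assert res.z == pytest.approx(expect, abs=1e-6)

    def test_boundary_correlation_flagged(self):
        x = np.arange(8.0)
        res = correlate_and_compare(np.concatenate([x, x]), np.concatenate([x, x]),
                                    ["a"] * 8 + ["b"] * 8)
        assert res.z is None and res.flag == "boundary-correlation"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_and_compare([1, 2, 3, 4, 5], [1, 2, 1, 2, 3],
                                  ["a", "a", "a", "b", "b"])


class TestBhFdr:
    def test_single_small_p_survives(self):
        assert bh_fdr([0.001], 0.10).tolist() == [True]

    def test_large_ps_do_not_survive(self):
        assert not bh_fdr([0.5, 0.6, 0.7], 0.10).any()

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=10)
            flags = bh_fdr(p, 0.10)
            order = np.argsort(p)
            m = len(p)
            k = 0
            for i in range(1, m + 1):
                if p[order[i - 1]] <= i * 0.10 / m:
                    k = i
            expect = np.zeros(m, dtype=bool)
            expect[order[:k]] = True
            assert np.array_equal(flags, expect)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
           st.floats(0.01, 0.2), st.floats(0.0, 0.3))
    def test_order_invariant_and_monotone_in_q(self, ps, q, dq):
        base = bh_fdr(ps, q)
        shuffled = list(reversed(ps))
        assert np.array_equal(bh_fdr(shuffled, q), base[::-1])
        assert bh_fdr(ps, q + dq).sum() >= base.sum()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([], 0.10)


class TestModelComparison:
    def test_evidence_p_is_exponential_of_half_delta(self):
        assert evidence_p(100.0, 100.0) == 1.0
        assert evidence_p(98.0, 104.0) == pytest.approx(np.exp(-3.0))

    def test_noiseless_linear_prefers_linear(self):
        x = np.linspace(0, 10, 16)
        res = lin_vs_quad_aicc(x, 2.0 + 3.0 * x)
        assert abs(res.coef_quadratic[2]) < 1e-6
        assert res.p_quadratic_better >= 1.0
        assert res.flag == "linear preferred"

    def test_inverted_u_detected(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(-2, 2, 16)
        y = (x - x.mean()) ** 2 + rng.normal(0, 0.1, 16)
        res = lin_vs_quad_aicc(x, y)
        assert res.p_quadratic_better < 0.05
        assert res.r2_quadratic > res.r2_linear

    def test_nested_r2_ordering_and_aicc_formula(self, rng):
        x = rng.normal(size=30)
        y = 0.3 * x + rng.normal(size=30)
        res = lin_vs_quad_aicc(x, y)
        assert res.r2_quadratic >= res.r2_linear
        # AICc formula spot check
        assert aicc(30, 10.0, 3) == pytest.approx(
            30 * np.log(10.0 / 30) + 6 + 24 / 26
        )

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            lin_vs_quad_aicc(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            lin_vs_quad_aicc(np.arange(4.0), np.arange(4.0))


class TestKmLogrank:
    def test_identical_groups_null(self):
        res = km_logrank({"a": [1, 2, 2, 3], "b": [1, 2, 2, 3]})
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_worked_two_group_table(self):
        """Groups {1,1,2,2} vs {3,3,4,4}: chi-square from the worked log-rank
        table over the 4 distinct event levels is 1715/247."""
        res = km_logrank({"a": [1, 1, 2, 2], "b": [3, 3, 4, 4]})
        assert res.chi_square == pytest.approx(1715.0 / 247.0, rel=1e-6)
        assert res.df == 1

    def test_km_curve_product_limit(self):
        res = km_logrank({"a": [2, 2, 3], "b": [2, 2, 3]})
        curve = res.curves["a"]
        s = dict(zip(curve["level"], curve["survival"]))
        assert s[2.0] == pytest.approx(1.0 / 3.0)
        assert s[3.0] == pytest.approx(0.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank({"a": [1, 2, 3]})
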