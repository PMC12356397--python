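"""Group statistics: RM-ANOVA, FDR post-hocs, Bayes factors, power."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from srbias.inference import (fdr_bh, jzs_bf_correlation, jzs_bf_one_sample,
                              one_sample_t, posthoc_vs_baseline,
                              power_sample_size, rm_anova_oneway)


def brute_force_rm_anova(m):
    """Sum-of-squares oracle written directly from the decomposition."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    ss_level = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_err = sum((m[i, j] - m[:, j].mean() - m[i].mean() + grand) ** 2
                 for i in range(n) for j in range(k))
    return (ss_level / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestRmAnova:
    def test_constant_rows_give_zero_f(self):
        m = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 4))
        assert rm_anova_oneway(m).value == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_matrix_matches_ss_oracle(self):
        m = np.array([[3.0, 5.0, 4.0], [2.0, 6.0, 7.0], [1.0, 4.0, 4.0]])
        res = rm_anova_oneway(m)
        assert res.value == pytest.approx(brute_force_rm_anova(m), rel=1e-12)
        assert res.df == (2.0, 4.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(6, 4))
        assert rm_anova_oneway(m).value == \
            pytest.approx(rm_anova_oneway(m + 17.3).value, rel=1e-9)

    @given(hnp.arrays(np.float64, st.tuples(st.integers(2, 6),
                                            st.integers(2, 6)),
                      elements=st.floats(-10, 10, allow_nan=False)))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_on_random_matrices(self, m):
        n, k = m.shape
        grand = m.mean()
        ss_err = sum((m[i, j] - m[:, j].mean() - m[i].mean() + grand) ** 2
                     for i in range(n) for j in range(k))
        if ss_err < 1e-9 * max(1.0, np.abs(m).max() ** 2):
            return  # degenerate: error term at float-noise level
        oracle = brute_force_rm_anova(m)
        assert rm_anova_oneway(m).value == pytest.approx(oracle, rel=1e-8,
                                                         abs=1e-8)

    def test_cross_check_against_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(3)
        m = rng.normal(size=(8, 5)) + rng.normal(size=(1, 5))
        long = pd.DataFrame({
            "y": m.ravel(),
            "subj": np.repeat(np.arange(8), 5),
            "level": np.tile(np.arange(5), 8)})
        ours = rm_anova_oneway(m)
        theirs = pg.rm_anova(data=long, dv="y", within="level",
                             subject="subj")
        assert ours.value == pytest.approx(theirs["F"].iloc[0], rel=1e-6)
        assert ours.p_raw == pytest.approx(theirs["p_unc"].iloc[0], rel=1e-6)

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_oneway(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestPosthoc:
    def test_identical_level_gives_half_p(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = np.column_stack([base, base + np.array([0.1, -0.1, 0.1, -0.1])])
        res = posthoc_vs_baseline(m, 0, "greater")
        assert res[0].value == pytest.approx(0.0)
        assert res[0].p_raw == pytest.approx(0.5)

    def test_degenerate_variance_raises(self):
        m = np.column_stack([np.zeros(4), np.ones(4)])
        with pytest.raises(ValueError):
            posthoc_vs_baseline(m, 0, "greater")

    def test_direction_less_flips_p(self):
        rng = np.random.default_rng(5)
        m = np.column_stack([rng.normal(size=10),
                             rng.normal(size=10) - 1.0])
        g = posthoc_vs_baseline(m, 0, "greater")[0]
        l = posthoc_vs_baseline(m, 0, "less")[0]
        assert g.p_raw == pytest.approx(1.0 - l.p_raw)
        assert l.p_raw < 0.2

    def test_cohens_d_is_mean_over_sd_of_diffs(self):
        m = np.column_stack([np.array([0.0, 0.0, 0.0, 0.0]),
                             np.array([1.0, 2.0, 3.0, 2.0])])
        r = posthoc_vs_baseline(m, 0, "greater")[0]
        diff = m[:, 1] - m[:, 0]
        assert r.cohens_d == pytest.approx(diff.mean() / diff.std(ddof=1))


class TestFdrBH:
    def brute_force(self, p):
        """Step-up oracle straight from the definition."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            adj[order[rank - 1]] = running
        return np.minimum(adj, 1.0)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.037]) == pytest.approx([0.037])

    def test_textbook_example(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_inflates(self, p):
        ours = fdr_bh(p)
        assert ours == pytest.approx(self.brute_force(p), abs=1e-12)
        assert (ours >= np.asarray(p) - 1e-12).all()

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2,
                    max_size=10), st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_order_invariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        ours = fdr_bh(p)
        permuted = fdr_bh([p[i] for i in perm])
        assert permuted == pytest.approx([ours[i] for i in perm], abs=1e-12)

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.uniform(size=9)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert fdr_bh(p) == pytest.approx(theirs, abs=1e-12)


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        r = one_sample_t([-1.0, 1.0, -2.0, 2.0], 0.0)
        assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_summary_statistics_arithmetic(self):
        """n=22 values with mean 0.52, sd 0.40 give t near 6.10 (the study's
        printed 6.46 used unrounded data)."""
        x = np.array([0.52 - 0.40, 0.52 + 0.40] * 11)
        sd = x.std(ddof=1)
        x = 0.52 + (x - 0.52) * 0.40 / sd   # exact sd 0.40
        r = one_sample_t(x, 0.0)
        assert r.value == pytest.approx(0.52 / (0.40 / np.sqrt(22)), rel=1e-9)
        assert r.value == pytest.approx(6.0979, abs=1e-3)
        assert r.cohens_d == pytest.approx(1.3, abs=1e-9)

    def test_scaling_deviations_doubles_d(self):
        x = np.array([0.1, 0.5, 0.9, 0.2])
        d1 = one_sample_t(x, 0.0).cohens_d
        d2 = one_sample_t(2 * x, 0.0).cohens_d
        assert d2 == pytest.approx(d1)          # scale-free
        y = 0.3 + (x - x.mean())
        d3 = one_sample_t(y, 0.0).cohens_d
        d4 = one_sample_t(0.3 + 2 * (x - x.mean()), 0.0).cohens_d
        assert d4 == pytest.approx(d3 / 2)      # doubling spread halves d

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0], 0.0)


class TestJzsOneSample:
    def test_printed_group_test_value(self):
        """t = 6.46 with n = 22 and r = 0.707 gives ln BF10 of about 9.11."""
        bf = jzs_bf_one_sample(6.46, 22, 0.707)
        assert bf.ln_bf10 == pytest.approx(9.11, abs=0.15)

    def test_null_favoured_at_t_zero(self):
        for n in (5, 22, 80):
            assert jzs_bf_one_sample(0.0, n).ln_bf10 < 0.0

    def test_monotone_in_t(self):
        bfs = [jzs_bf_one_sample(t, 20).ln_bf10 for t in (0.0, 1.0, 2.5, 5.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_matches_importance_sampling_oracle(self):
        """Monte-Carlo marginal likelihood over the g mixture (inverse-
        chi-square draws) agrees with the quadrature within 2%."""
        t, n, r = 2.0, 20, 0.707
        rng = np.random.default_rng(0)
        v = n - 1
        g = 1.0 / rng.chisquare(1, size=400_000)   # g ~ inv-chi2(1)
        a = 1.0 + n * g * r * r
        like = a ** -0.5 * (1 + t * t / (a * v)) ** (-(v + 1) / 2)
        bf_mc = np.log(like.mean()) - (-(v + 1) / 2) * np.log1p(t * t / v)
        ours = jzs_bf_one_sample(t, n, r).ln_bf10
        assert ours == pytest.approx(bf_mc, abs=0.02)

    def test_cross_check_against_pingouin(self):
        import pingouin as pg
        for t, n in ((1.3, 12), (3.2, 25)):
            theirs = float(pg.bayesfactor_ttest(t, n, r=0.707))
            assert jzs_bf_one_sample(t, n, 0.707).ln_bf10 == \
                pytest.approx(np.log(theirs), rel=1e-4)


class TestJzsCorrelation:
    def test_perfect_correlation_overwhelms(self):
        x = np.linspace(0, 1, 20)
        assert jzs_bf_correlation(x, 0.99 * x + 0.01).ln_bf10 > 3.0

    def test_independent_gaussians_mostly_favour_null(self):
        rng = np.random.default_rng(11)
        low = sum(jzs_bf_correlation(rng.normal(size=22),
                                     rng.normal(size=22)).ln_bf10 < 1.0
                  for _ in range(20))
        assert low >= 15

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        a = jzs_bf_correlation(x, y).ln_bf10
        b = jzs_bf_correlation(3.0 * x - 1.0, -2.0 * y + 5.0).ln_bf10
        assert a == pytest.approx(abs(b), rel=1e-6) or \
            a == pytest.approx(b, rel=1e-6)

    def test_cross_check_against_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        r = float(np.corrcoef(x, y)[0, 1])
        theirs = float(pg.bayesfactor_pearson(r, 25))
        assert jzs_bf_correlation(x, y).ln_bf10 == \
            pytest.approx(np.log(theirs), abs=0.02)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_correlation(np.ones(10), np.arange(10.0))


class TestPower:
    def test_study_sample_size(self):
        """Medium effect 0.6 at alpha .05, power .80, one-tailed: n = 19."""
        assert power_sample_size(0.6, 0.05, 0.80, tails=1).required_n == 19

    def test_two_tailed_needs_more(self):
        assert power_sample_size(0.6, 0.05, 0.80, tails=2).required_n == 24

    def test_minimality_contract(self):
        from srbias.inference import _t_power
        spec = power_sample_size(0.45, 0.05, 0.9, tails=2)
        assert spec.achieved_power >= 0.9
        assert _t_power(spec.required_n - 1, 0.45, 0.05, 2) < 0.9

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            power_sample_size(-0.2, 0.05, 0.8)
        with pytest.raises(ValueError):
            power_sample_size(0.6, 0.05, 1.5)
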