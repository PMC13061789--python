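"""RT filtering, condition summaries, RM-ANOVA with GG correction, Holm tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multitact.rte_pipeline import (
    apply_rt_filters,
    condition_summary,
    holm_pairwise,
    means_matrix,
    rm_anova_gg,
)


def _trials(rows):
    return pd.DataFrame(rows, columns=["participant", "condition", "rt", "responded"])


class TestFilters:
    def test_range_filter_bounds(self):
        t = _trials([("p1", "V", rt, True) for rt in (0.05, 0.3, 0.95, 1.2)])
        retained, report = apply_rt_filters(t)
        assert sorted(retained["rt"]) == [0.3, 0.95]
        assert report.n_removed_fast == 1 and report.n_removed_slow == 1

    def test_sd_filter_removes_constructed_outlier(self):
        rts = [0.30] * 10 + [0.90]
        t = _trials([("p1", "A", rt, True) for rt in rts])
        retained, report = apply_rt_filters(t)
        assert report.n_removed_sd == 1
        assert 0.90 not in retained["rt"].values
        # oracle arithmetic with the sample SD
        sd = np.std(rts, ddof=1)
        assert abs(0.90 - np.mean(rts)) > 2.5 * sd

    def test_identical_rts_nothing_removed(self):
        t = _trials([("p1", "T", 0.4, True)] * 12)
        retained, report = apply_rt_filters(t)
        assert report.n_removed_sd == 0 and len(retained) == 12

    def test_range_filter_idempotent(self):
        rng = np.random.default_rng(0)
        t = _trials([("p1", "V", r, True) for r in rng.uniform(0, 1.5, 200)])
        retained, _ = apply_rt_filters(t)
        again, report2 = apply_rt_filters(retained)
        assert report2.n_removed_fast == 0 and report2.n_removed_slow == 0

    def test_misses_and_catch_trials_excluded_but_counted(self):
        t = _trials(
            [("p1", "V", 0.4, True), ("p1", "V", np.nan, False), ("p1", "none", np.nan, False)]
        )
        retained, report = apply_rt_filters(t)
        assert len(retained) == 1
        assert report.n_no_response == 1 and report.n_no_target == 1

    def test_counts_additive(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"p{i}", c, rng.normal(0.45, 0.2), True)
            for i in range(4)
            for c in ("V", "A", "T")
            for _ in range(30)
        ]
        retained, rep = apply_rt_filters(_trials(rows))
        assert (
            rep.n_retained + rep.n_removed_fast + rep.n_removed_slow + rep.n_removed_sd
            == len(rows)
        )


class TestConditionSummary:
    def test_group_level_arithmetic(self):
        t = _trials([("p1", "V", 0.4, True), ("p2", "V", 0.5, True)])
        (s,) = condition_summary(t, conditions=("V",))
        assert s.n == 2
        assert s.mean == pytest.approx(0.45)
        assert s.sd == pytest.approx(np.std([0.4, 0.5], ddof=1))
        assert s.se == pytest.approx(s.sd / np.sqrt(2))

    def test_single_participant_sd_missing(self):
        t = _trials([("p1", "V", 0.4, True)])
        (s,) = condition_summary(t, conditions=("V",))
        assert np.isnan(s.sd) and np.isnan(s.se)

    def test_participant_means_computed_first(self):
        # p1 has many trials, p2 one; the group mean weights participants equally
        t = _trials([("p1", "V", 0.3, True)] * 9 + [("p2", "V", 0.6, True)])
        (s,) = condition_summary(t, conditions=("V",))
        assert s.mean == pytest.approx(0.45)


def _oracle_rm_anova(x):
    """Loop-based sums-of-squares + explicit GG epsilon (independent route)."""
    n, k = x.shape
    grand = x.mean()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (x[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    # epsilon from the raw covariance entries (Greenhouse & Geisser's form)
    s = np.cov(x, rowvar=False, ddof=1)
    sbar = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (np.trace(s) / k - sbar)) ** 2
    den = (k - 1) * (
        np.sum(s**2) - 2 * k * np.sum(row_means**2) + k**2 * sbar**2
    )
    eps = num / den
    p_gg = stats.f.sf(f, eps * (k - 1), eps * (k - 1) * (n - 1))
    return f, eps, p_gg, ss_cond / ss_tot


class TestRmAnova:
    def test_zero_effect_gives_zero_f(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=8)
        x = np.tile(col[:, None], (1, 7))
        res = rm_anova_gg(x, include_pairwise=False)
        assert res.f_value == pytest.approx(0.0, abs=1e-20)

    def test_two_conditions_epsilon_is_one(self):
        rng = np.random.default_rng(2)
        res = rm_anova_gg(rng.normal(size=(6, 2)), include_pairwise=False)
        assert res.epsilon_gg == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(5, 3)) + rng.normal(size=(5, 1))
        res = rm_anova_gg(x, include_pairwise=False)
        f, eps, p_gg, eta2 = _oracle_rm_anova(x)
        assert res.f_value == pytest.approx(f, abs=1e-10)
        assert res.epsilon_gg == pytest.approx(eps, abs=1e-10)
        assert res.p_value_gg == pytest.approx(p_gg, abs=1e-10)
        assert res.eta_squared == pytest.approx(eta2, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1))
        res = rm_anova_gg(x, include_pairwise=False)
        long = pd.DataFrame(x).reset_index().melt("index", var_name="c", value_name="y")
        aov = pg.rm_anova(data=long, dv="y", within="c", subject="index",
                          correction=True, detailed=True)
        assert res.f_value == pytest.approx(float(aov.loc[0, "F"]))
        assert res.epsilon_gg == pytest.approx(float(aov.loc[0, "eps"]))
        assert res.p_value_gg == pytest.approx(float(aov.loc[0, "p_GG_corr"]))
        sph = pg.sphericity(data=long, dv="y", within="c", subject="index")
        assert res.mauchly_w == pytest.approx(float(sph.W))
        assert res.mauchly_chi2 == pytest.approx(float(sph.chi2))

    def test_f_invariant_to_constant_shifts(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 5))
        base = rm_anova_gg(x, include_pairwise=False).f_value
        shifted = rm_anova_gg(x + 3.7, include_pairwise=False).f_value
        subj = rm_anova_gg(x + rng.normal(size=(6, 1)), include_pairwise=False).f_value
        assert shifted == pytest.approx(base, rel=1e-9)
        assert subj == pytest.approx(base, rel=1e-9)

    def test_epsilon_within_theoretical_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            k = rng.integers(3, 8)
            x = rng.normal(size=(9, k)) * rng.uniform(0.5, 2.0, size=k)
            eps = rm_anova_gg(x, include_pairwise=False).epsilon_gg
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_missing_cells_rejected(self):
        x = np.full((5, 3), 0.4)
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="listwise"):
            rm_anova_gg(x)

    def test_null_false_positive_rate_calibrated(self):
        # no condition effect: GG-corrected test rejects at ~alpha
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=(10, 1)) + rng.normal(size=(10, 4)) * 0.3
            if rm_anova_gg(x, include_pairwise=False).p_value_gg < 0.05:
                rejections += 1
        rate = rejections / reps
        # GG correction is mildly conservative under sphericity
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


def _oracle_holm(praw):
    """Step-down enumeration of the Holm adjustment."""
    m = len(praw)
    order = np.argsort(praw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * praw[idx])
        running = max(running, val)
        adj[idx] = running
    return adj


class TestHolm:
    def test_identical_raw_ps_all_scaled_by_m(self):
        # b = a + d and c = b + d: all three paired t-tests share the same t
        # (a-c doubles the differences, which leaves t unchanged), so Holm
        # with full ties adjusts every p to min(1, m*p)
        a = np.array([0.10, 0.20, 0.35, 0.15])
        d = np.array([0.10, 0.15, 0.05, 0.12])
        x = pd.DataFrame({"a": a, "b": a + d, "c": a + 2 * d})
        table = holm_pairwise(x)
        np.testing.assert_allclose(table["p_raw"], table["p_raw"].iloc[0])
        np.testing.assert_allclose(
            table["p_holm"], np.minimum(1.0, 3 * table["p_raw"]), atol=1e-12
        )

    def test_smallest_p_scaled_by_number_of_tests(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame(rng.normal(size=(12, 7)), columns=list("abcdefg"))
        table = holm_pairwise(x)
        assert len(table) == 21
        i = table["p_raw"].idxmin()
        assert table.loc[i, "p_holm"] == pytest.approx(min(1.0, 21 * table.loc[i, "p_raw"]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_stepdown_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(8, 5)) + rng.normal(size=(8, 1)))
        table = holm_pairwise(x)
        np.testing.assert_allclose(
            table["p_holm"].to_numpy(), _oracle_holm(table["p_raw"].to_numpy()), atol=1e-12
        )

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(7)
        x = pd.DataFrame(rng.normal(size=(9, 6)))
        table = holm_pairwise(x).sort_values("p_raw")
        assert np.all(np.diff(table["p_holm"].to_numpy()) >= -1e-15)
        assert np.all(table["p_holm"] >= table["p_raw"] - 1e-15)


class TestEndToEnd:
    def test_generated_effect_detected(self):
        from multitact.synthetic_data import RTEGenConfig, gen_rte_trials

        trials, _ = gen_rte_trials(RTEGenConfig(seed=5))
        retained, _ = apply_rt_filters(trials)
        res = rm_anova_gg(means_matrix(retained))
        assert res.p_value_gg < 0.001
        assert res.pairwise is not None and len(res.pairwise) == 21
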