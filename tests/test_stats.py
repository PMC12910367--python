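"""Tukey-fence outliers, split-plot ANOVA, protected LSD, Shapiro-Wilk."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from clgrow.stats import (
    protected_lsd,
    shapiro_wilk,
    split_plot_anova,
    tukey_fences,
    tukey_outliers,
)


def _table(values_by_group):
    rows = []
    for (blk, tr, cv), vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append((blk, tr, cv, i, v))
    return pd.DataFrame(rows, columns=["block", "treatment", "cultivar",
                                       "plant_id", "value"])


class TestTukeyOutliers:
    def test_single_extreme_value_flagged(self):
        vals = list(range(1, 11)) + [100]
        tab = _table({(1, "18h", "Danstar"): vals})
        flags = tukey_outliers(tab)
        # independent quartile computation as oracle
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        expect = [(v < lo) or (v > hi) for v in vals]
        assert expect == [False] * 10 + [True]
        assert list(flags) == expect

    def test_all_equal_group_has_no_flags(self):
        tab = _table({(1, "18h", "Danstar"): [5.0] * 8})
        assert not tukey_outliers(tab).any()

    def test_small_group_skipped_with_warning(self):
        tab = _table({(1, "18h", "Danstar"): [1.0, 2.0, 50.0]})
        with pytest.warns(RuntimeWarning):
            flags = tukey_outliers(tab)
        assert not flags.any()

    def test_planted_outliers_in_full_cohort(self, grid_cohort):
        """A 168-plant cohort (4 blocks x 2 x 2 cells of 10-11) with four
        planted extremes at +-6 IQR flags exactly those four.

        Plant values spread on a bounded within-group grid (ground truth
        free of natural extremes) around the study's cell means.
        """
        tab = grid_cohort
        assert len(tab) == 168
        planted = []
        for blk, tr, cv, sign in [(2, "CL", "Danstar", +1), (3, "18h", "Jagger", -1),
                                  (4, "18h", "Danstar", +1), (4, "18h", "Danstar", -1)]:
            grp = tab[(tab.block == blk) & (tab.treatment == tr) & (tab.cultivar == cv)]
            q1, q3 = np.quantile(grp.value, [0.25, 0.75])
            iqr = q3 - q1
            idx = grp.index[0 if sign > 0 else 1]
            tab.loc[idx, "value"] = (q3 + 6 * iqr) if sign > 0 else (q1 - 6 * iqr)
            planted.append(idx)
        flags = tukey_outliers(tab)
        assert sorted(tab.index[flags]) == sorted(planted)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_fences_invariant_under_affine_maps(self, shift, scale):
        vals = np.array([1.0, 2.0, 3.0, 8.0, 9.0, 30.0])
        lo, hi = tukey_fences(vals)
        lo2, hi2 = tukey_fences(vals * scale + shift)
        assert lo2 == pytest.approx(lo * scale + shift, rel=1e-9, abs=1e-9)
        assert hi2 == pytest.approx(hi * scale + shift, rel=1e-9, abs=1e-9)
        flags = (vals < lo) | (vals > hi)
        flags2 = (vals * scale + shift < lo2) | (vals * scale + shift > hi2)
        assert (flags == flags2).all()


def _balanced_random_table(rng, b=4, n=10):
    rows = {}
    for blk, tr, cv in itertools.product(range(1, b + 1), ["18h", "CL"],
                                         ["Danstar", "Jagger"]):
        mu = 40 + 5 * (tr == "CL") + 8 * (cv == "Jagger") + 1.5 * blk
        rows[(blk, tr, cv)] = mu + rng.normal(0, 3, n)
    return _table(rows)


def _oracle_ss(tab):
    """Classical balanced split-plot sums of squares from cell means."""
    y = tab.value
    g = y.mean()
    n = len(tab)
    b = tab.block.nunique()
    t = tab.treatment.nunique()
    c = tab.cultivar.nunique()
    reps = n // (b * t * c)
    ss = {}
    ss["block"] = t * c * reps * sum((y[tab.block == k].mean() - g) ** 2
                                     for k in tab.block.unique())
    ss["treatment"] = b * c * reps * sum((y[tab.treatment == k].mean() - g) ** 2
                                         for k in tab.treatment.unique())
    ss["cultivar"] = b * t * reps * sum((y[tab.cultivar == k].mean() - g) ** 2
                                        for k in tab.cultivar.unique())
    bt = 0.0
    for blk in tab.block.unique():
        for tr in tab.treatment.unique():
            cell = y[(tab.block == blk) & (tab.treatment == tr)].mean()
            bt += (cell - y[tab.block == blk].mean()
                   - y[tab.treatment == tr].mean() + g) ** 2
    ss["block:treatment"] = c * reps * bt
    tc = 0.0
    for tr in tab.treatment.unique():
        for cv in tab.cultivar.unique():
            cell = y[(tab.treatment == tr) & (tab.cultivar == cv)].mean()
            tc += (cell - y[tab.treatment == tr].mean()
                   - y[tab.cultivar == cv].mean() + g) ** 2
    ss["treatment:cultivar"] = b * reps * tc
    return ss


class TestSplitPlotAnova:
    def test_all_equal_data_gives_p_one(self):
        tab = _table({(b, t, c): [7.0] * 5
                      for b, t, c in itertools.product([1, 2, 3], ["18h", "CL"],
                                                       ["Danstar", "Jagger"])})
        res = split_plot_anova(tab)
        assert res.f_prob_main == 1.0
        assert res.f_prob_interaction == 1.0
        assert set(res.letters_main.values()) == {"a"}

    def test_noiseless_cell_means_reproduced_with_infinite_f(self):
        means = {("18h", "Danstar"): 40.0, ("18h", "Jagger"): 50.0,
                 ("CL", "Danstar"): 43.0, ("CL", "Jagger"): 61.0}
        tab = _table({(b, t, c): [means[(t, c)]] * 6
                      for b, t, c in itertools.product([1, 2], ["18h", "CL"],
                                                       ["Danstar", "Jagger"])})
        res = split_plot_anova(tab)
        for (t, c), mu in means.items():
            assert res.means_cell[(t, c)] == pytest.approx(mu, abs=1e-12)
        assert res.f_prob_main == 0.0  # F = inf convention

    def test_ss_partition_matches_projection_oracle(self, rng):
        """Type-III RSS-difference SS equal the classical balanced-design
        projection formulas to 1e-8 and sum to the total SS."""
        tab = _balanced_random_table(rng)
        res = split_plot_anova(tab)
        oracle = _oracle_ss(tab)
        got = dict(zip(res.anova.term, res.anova.ss))
        for term, val in oracle.items():
            assert got[term] == pytest.approx(val, abs=1e-8, rel=1e-10)
        explained = sum(oracle.values()) + got["residual"]
        assert explained == pytest.approx(got["total"], rel=1e-10)

    def test_main_effect_f_uses_wholeplot_stratum(self, rng):
        """The photoperiod p-value comes from F = MS_treat / MS_block:treat
        with (1, (b-1)) dfs, not from the residual stratum."""
        tab = _balanced_random_table(rng, b=4, n=8)
        res = split_plot_anova(tab)
        a = res.anova.set_index("term")
        f = a.loc["treatment", "ms"] / a.loc["block:treatment", "ms"]
        expect = sps.f.sf(f, 1, 3)
        assert res.f_prob_main == pytest.approx(expect, rel=1e-12)

    def test_unbalanced_cells_supported(self, rng):
        tab = _balanced_random_table(rng)
        tab = tab.drop(tab.index[:3])  # 10 vs 11-like unbalance
        res = split_plot_anova(tab)
        assert 0.0 <= res.f_prob_main <= 1.0
        assert res.sem_interaction > 0

    def test_design_errors(self, rng):
        tab = _balanced_random_table(rng)
        with pytest.raises(ValueError):
            split_plot_anova(tab[tab.block == 1])
        with pytest.raises(ValueError):
            split_plot_anova(tab[~((tab.treatment == "CL") & (tab.cultivar == "Jagger"))])


class TestProtectedLSD:
    def test_separated_means_get_distinct_letters(self):
        letters = protected_lsd({"CL": 51.9, "18h": 45.0}, se_diff=1.06,
                                df_error=3, gate_p=0.008)
        assert letters == {"CL": "a", "18h": "b"}

    def test_identical_means_share_letter(self):
        letters = protected_lsd({"A": 10.0, "B": 10.0}, se_diff=1.0,
                                df_error=10, gate_p=0.001)
        assert letters["A"] == letters["B"]

    def test_nonsignificant_gate_suppresses_separation(self):
        letters = protected_lsd({"CL": 51.9, "18h": 45.0}, se_diff=1.06,
                                df_error=3, gate_p=0.11)
        assert set(letters.values()) == {"a"}

    def test_chained_overlap(self):
        # 10 and 8 overlap, 8 and 6.5 overlap, but 10 vs 6.5 differ
        letters = protected_lsd({"x": 10.0, "y": 8.0, "z": 6.5}, se_diff=1.0,
                                df_error=30, gate_p=0.0)
        lsd = sps.t.ppf(0.975, 30) * 1.0  # ~2.04
        assert abs(10.0 - 8.0) < lsd < abs(10.0 - 6.5)
        assert set(letters["x"]) & set(letters["y"])
        assert set(letters["y"]) & set(letters["z"])
        assert not set(letters["x"]) & set(letters["z"])

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=6, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_letters_consistent_with_pairwise_decisions(self, means):
        """Shared letter iff the pair is not separated by the LSD."""
        named = {str(i): m for i, m in enumerate(means)}
        se, df = 2.0, 12
        letters = protected_lsd(named, se_diff=se, df_error=df, gate_p=0.0)
        lsd = sps.t.ppf(0.975, df) * se
        for a in named:
            for b in named:
                if a >= b:
                    continue
                share = bool(set(letters[a]) & set(letters[b]))
                separated = abs(named[a] - named[b]) > lsd
                assert share == (not separated)


class TestShapiroWilk:
    def test_ideal_normal_quantiles_have_high_w(self):
        q = sps.norm.ppf((np.arange(1, 51) - 0.375) / (50 + 0.25))
        w, p = shapiro_wilk(q)
        assert w > 0.99

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.zeros(10))

    def test_two_point_mixture_detected(self, rng):
        x = np.where(rng.random(50) < 0.5, -3.0, 3.0) + rng.normal(0, 0.1, 50)
        w, p = shapiro_wilk(x)
        assert p < 0.05

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
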