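"""Mixed-design ANOVA, GG correction, t tests, multiplicity control.

Hand-worked oracles: the 2 x 2 mixed-design fixture is solved from raw
sums of squares in the test itself; Sidak and BH are checked against their
closed-form / step-up definitions; pingouin serves as an independent
cross-check of the ANOVA implementation.
"""

import numpy as np
import pandas as pd
import pytest

from socoh.stats import (bh_fdr, gg_epsilon, mixed_anova,
                         per_frequency_contrast, rm_anova_gg, sidak,
                         t_test_ind, t_test_paired)


def _long(x, groups, chambers=("social", "nonsocial")):
    rows = []
    for s in range(x.shape[0]):
        for j, ch in enumerate(chambers):
            rows.append({"animal_id": f"s{s}", "group": groups[s],
                         "chamber": ch, "value": x[s, j]})
    return pd.DataFrame(rows)


def _effect(df, name):
    return df.loc[df.effect == name].iloc[0]


class TestMixedAnova:
    def test_all_equal_gives_zero_f(self):
        x = np.full((8, 2), 3.0)
        df = mixed_anova(_long(x, ["a"] * 4 + ["b"] * 4))
        assert (df.statistic == 0).all()

    def test_hand_worked_2x2_fixture(self):
        # 6 subjects, 3 per group; sums of squares worked from cell means
        x = np.array([[3.0, 5.0], [4.0, 7.0], [5.0, 6.0],
                      [7.0, 7.0], [8.0, 9.0], [9.0, 8.0]])
        g = ["a"] * 3 + ["b"] * 3
        grand = x.mean()
        m_s = x.mean(1)
        ss_subj = 2 * ((m_s - grand) ** 2).sum()
        ss_g = 2 * 3 * ((np.array([x[:3].mean(), x[3:].mean()]) - grand) ** 2).sum()
        ss_err_b = ss_subj - ss_g
        ss_ch = 6 * ((x.mean(0) - grand) ** 2).sum()
        cells = np.array([x[:3].mean(0), x[3:].mean(0)])
        ss_cells = 3 * ((cells - grand) ** 2).sum()
        ss_int = ss_cells - ss_g - ss_ch
        ss_err_w = ((x - m_s[:, None]
                     - np.repeat(cells, 3, 0)
                     + np.repeat(cells.mean(1), 3)[:, None]) ** 2).sum()
        want_fg = (ss_g / 1) / (ss_err_b / 4)
        want_fc = (ss_ch / 1) / (ss_err_w / 4)
        want_fi = (ss_int / 1) / (ss_err_w / 4)
        df = mixed_anova(_long(x, g))
        assert _effect(df, "group").statistic == pytest.approx(want_fg, abs=1e-8)
        assert _effect(df, "chamber").statistic == pytest.approx(want_fc, abs=1e-8)
        assert _effect(df, "group x chamber").statistic == \
            pytest.approx(want_fi, abs=1e-8)
        assert _effect(df, "group").df2 == 4

    def test_unbalanced_df_match_design(self, rng):
        x = rng.standard_normal((21, 2))
        df = mixed_anova(_long(x, ["a"] * 9 + ["b"] * 12))
        assert _effect(df, "group").df2 == 19
        assert _effect(df, "group x chamber").df2 == 19

    def test_group_f_equals_squared_pooled_t_on_means(self, rng):
        from scipy import stats as ss
        x = rng.standard_normal((15, 2)) + [0.2, 0.0]
        g = ["a"] * 7 + ["b"] * 8
        df = mixed_anova(_long(x, g))
        m = x.mean(1)
        t = ss.ttest_ind(m[:7], m[7:], equal_var=True).statistic
        assert _effect(df, "group").statistic == pytest.approx(t ** 2, rel=1e-10)

    def test_matches_pingouin_unbalanced(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.standard_normal((13, 3)) + [0.5, 0.0, 0.2]
        g = ["a"] * 5 + ["b"] * 8
        long = _long(x, g, chambers=("c1", "c2", "c3"))
        long = long.rename(columns={"chamber": "within"})
        ours = mixed_anova(long, within="within")
        theirs = pg.mixed_anova(data=long, dv="value", within="within",
                                subject="animal_id", between="group",
                                correction=False)
        for eff, key in (("group", "group"), ("within", "within"),
                         ("group x within", "Interaction")):
            assert _effect(ours, eff).statistic == pytest.approx(
                float(theirs.loc[theirs.Source == key, "F"].iloc[0]), rel=1e-9)

    def test_missing_cell_lists_subject(self):
        x = np.ones((4, 2))
        long = _long(x, ["a", "a", "b", "b"])
        long = long.drop(long[(long.animal_id == "s2")
                              & (long.chamber == "social")].index)
        with pytest.raises(ValueError, match="s2"):
            mixed_anova(long)


class TestRMAnovaGG:
    def test_spherical_data_epsilon_near_one(self, rng):
        x = rng.standard_normal((60, 4))
        assert gg_epsilon(x) > 0.85

    def test_perfectly_correlated_hits_lower_bound(self, rng):
        base = rng.standard_normal(10)
        x = np.column_stack([base, base * 1.0, base + 0.0, base])
        x = x + np.arange(4)  # distinct level means, identical shapes
        assert gg_epsilon(x) == pytest.approx(1 / 3)

    def test_oracle_epsilon_on_small_fixture(self):
        # direct evaluation of the epsilon formula on a 5-subject,
        # 4-level fixture
        x = np.array([[2.0, 3.0, 5.0, 4.0],
                      [4.0, 4.0, 6.0, 7.0],
                      [1.0, 2.0, 2.0, 3.0],
                      [5.0, 6.0, 9.0, 7.0],
                      [3.0, 5.0, 5.0, 6.0]])
        s = np.cov(x, rowvar=False)
        k = 4
        mean_all = s.mean()
        row_means = s.mean(1)
        num = (k * (np.trace(s) / k - mean_all)) ** 2
        den = (k - 1) * ((s ** 2).sum() - 2 * k * (row_means ** 2).sum()
                         + k ** 2 * mean_all ** 2)
        assert gg_epsilon(x) == pytest.approx(num / den, rel=1e-10)

    def test_corrected_df_scale_with_epsilon(self, rng):
        x = rng.standard_normal((12, 4)) + [0.0, 0.3, 0.6, 0.1]
        out = rm_anova_gg(x)
        eps = out.attrs["epsilon"]
        unc = out[out.effect == "within"].iloc[0]
        gg = out[out.effect == "within (GG)"].iloc[0]
        assert gg.df1 == pytest.approx(eps * unc.df1)
        assert gg.df2 == pytest.approx(eps * unc.df2)
        assert gg.statistic == unc.statistic  # only the df change

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.standard_normal((9, 4)) + [0.0, 0.5, 0.2, 0.8]
        long = pd.DataFrame({
            "y": x.ravel(),
            "subj": np.repeat(np.arange(9), 4),
            "lvl": list(range(4)) * 9,
        })
        theirs = pg.rm_anova(data=long, dv="y", within="lvl", subject="subj",
                             correction=True)
        ours = rm_anova_gg(x)
        assert ours[ours.effect == "within"].statistic.iloc[0] == \
            pytest.approx(float(theirs["F"].iloc[0]), rel=1e-9)
        assert ours.attrs["epsilon"] == \
            pytest.approx(float(theirs["eps"].iloc[0]), rel=1e-6)

    def test_needs_three_levels(self, rng):
        with pytest.raises(ValueError):
            rm_anova_gg(rng.standard_normal((5, 2)))


class TestTTests:
    def test_identical_groups(self):
        r = t_test_ind([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["statistic"] == 0.0 and r["p"] == pytest.approx(1.0)

    def test_hand_computed_pooled_fixture(self):
        # {1,2,3} vs {4,5,6}: pooled sd 1, se = sqrt(2/3), t = -3/se
        r = t_test_ind([1, 2, 3], [4, 5, 6])
        assert r["statistic"] == pytest.approx(-3.674, abs=1e-3)
        assert r["df2"] == 4

    def test_paired_constant_shift_flagged(self):
        x = np.array([1.0, 2.0, 3.0])
        r = t_test_paired(x, x + 2.0)
        assert np.isnan(r["statistic"]) and "zero-variance" in r["method"]

    def test_paired_identical_is_null(self):
        x = np.array([1.0, 2.0, 3.0])
        r = t_test_paired(x, x)
        assert r["statistic"] == 0.0 and r["p"] == 1.0


class TestCorrections:
    def test_sidak_closed_form(self):
        assert sidak(0.01, 5) == pytest.approx(1 - 0.99 ** 5)
        assert sidak(0.01, 5) == pytest.approx(0.04901, abs=1e-5)

    def test_sidak_identity_and_cap(self):
        assert sidak(0.2, 1) == pytest.approx(0.2)
        assert sidak(0.9, 50) == 1.0

    def test_sidak_monotone(self, rng):
        p = rng.uniform(size=100)
        assert np.all(sidak(p, 7) >= p)

    def test_bh_stepup_fixture(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_bh_single_p_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_bh_matches_brute_force_definition(self, rng):
        p = rng.uniform(size=25)
        m = p.size
        order = np.argsort(p)
        want = np.empty(m)
        # step-up: min over the tail of m * p_(i) / i, capped at 1
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, m * p[order[rank - 1]] / rank)
            want[order[rank - 1]] = running
        assert np.allclose(bh_fdr(p), want, atol=1e-12)
        # order preservation
        assert np.all(np.diff(bh_fdr(np.sort(p))) >= -1e-12)


class TestPerFrequencyContrast:
    def test_null_flags_about_alpha(self, rng):
        freqs = np.arange(0.5, 150.5, 0.5)
        a = rng.standard_normal((20, freqs.size))
        b = rng.standard_normal((20, freqs.size))
        out = per_frequency_contrast(a, b, freqs)
        assert 0.01 < out["sig_uncorrected"].mean() < 0.12

    def test_programmed_band_effect_recovered(self, rng):
        freqs = np.arange(0.5, 150.5, 0.5)
        band = (freqs >= 25) & (freqs <= 60)
        a = rng.standard_normal((12, freqs.size)) + band * 2.0
        b = rng.standard_normal((9, freqs.size))
        out = per_frequency_contrast(a, b, freqs)
        assert out.loc[band, "sig_fdr"].mean() > 0.8
        assert out.loc[~band, "sig_uncorrected"].mean() < 0.2

    def test_fdr_mask_is_subset(self, rng):
        freqs = np.arange(0.5, 50.5, 0.5)
        a = rng.standard_normal((8, freqs.size)) + 0.5
        b = rng.standard_normal((8, freqs.size))
        out = per_frequency_contrast(a, b, freqs)
        assert not (out["sig_fdr"] & ~out["sig_uncorrected"]).any()
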