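import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sprintcoord.errors import ValidationError
from sprintcoord.inference import (
    bin_frequency_report,
    bonferroni,
    discrete_kinematics_report,
    extract_event_angles,
    friedman,
    gg_epsilon,
    mauchly,
    rm_anova,
    wilcoxon_signed_rank,
)
from sprintcoord.preprocessing import StepWindow, segment_steps


class TestExtractEventAngles:
    def test_ramp_interpolation(self, ramp_trial):
        """TD at 0.42 s on a 10 deg/s trunk ramp -> 4.2 degrees."""
        windows = segment_steps(ramp_trial)
        df = extract_event_angles(ramp_trial, windows)
        row = df[(df.step == 1) & (df.event == "touchdown") & (df.variable == "trunk")]
        assert row["angle_deg"].iloc[0] == pytest.approx(4.2, abs=1e-6)

    def test_toe_off_uses_window_end(self, ramp_trial):
        windows = segment_steps(ramp_trial)
        df = extract_event_angles(ramp_trial, windows)
        row = df[(df.step == 1) & (df.event == "toe_off") & (df.variable == "trunk")]
        assert row["angle_deg"].iloc[0] == pytest.approx(6.2, abs=1e-6)

    def test_joint_angles_are_segment_differences(self, ramp_trial):
        windows = segment_steps(ramp_trial)
        df = extract_event_angles(ramp_trial, windows)
        sub = df[(df.step == 1) & (df.event == "touchdown")].set_index("variable")
        assert sub.loc["ankle", "angle_deg"] == pytest.approx(
            sub.loc["shank", "angle_deg"] - sub.loc["foot", "angle_deg"]
        )

    def test_variables_present(self, ramp_trial):
        windows = segment_steps(ramp_trial)
        df = extract_event_angles(ramp_trial, windows)
        assert set(df["variable"]) == {"trunk", "thigh", "shank", "foot", "hip", "knee", "ankle"}


class TestRMAnova:
    def test_no_effect_when_identical_columns(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 4))
        res = rm_anova(x)
        assert res.F == pytest.approx(0.0)
        assert res.eta_sq == pytest.approx(0.0)

    def test_df_21_participants_4_steps(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(21, 4))
        res = rm_anova(x)
        if not res.gg_applied:
            assert (res.df_num, res.df_den) == (3.0, 60.0)

    def test_two_steps_equals_paired_t_squared(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=15)
        b = a + rng.normal(0.4, 1.0, size=15)
        res = rm_anova(np.column_stack([a, b]))
        t = sps.ttest_rel(a, b)
        assert res.F == pytest.approx(t.statistic**2, abs=1e-6)
        assert res.p == pytest.approx(t.pvalue, abs=1e-9)

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (12, 4)) + np.array([0, 0.5, 1.0, 0.2])
        x[:, 3] *= 2.5  # break sphericity
        res = rm_anova(x)
        long = pd.DataFrame(
            {
                "y": x.ravel(),
                "subj": np.repeat(np.arange(12), 4),
                "cond": np.tile(np.arange(4), 12),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                          correction=True, detailed=True).iloc[0]
        assert res.F == pytest.approx(ref["F"], rel=1e-9)
        assert res.epsilon == pytest.approx(ref["eps"], rel=1e-9)
        assert res.gg_applied  # pingouin flags sphericity False here
        assert res.p == pytest.approx(ref["p_GG_corr"], rel=1e-6)
        # partial eta squared from pingouin's SS decomposition
        ss_effect = ref["SS"]
        full = pg.rm_anova(data=long, dv="y", within="cond", subject="subj", detailed=True)
        ss_error = full.iloc[1]["SS"]
        assert res.eta_sq == pytest.approx(ss_effect / (ss_effect + ss_error), rel=1e-9)

    def test_mauchly_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        x = rng.normal(size=(14, 4)) * np.array([1.0, 1.0, 2.0, 3.0])
        w, chi2, df, p = mauchly(x)
        long = pd.DataFrame(
            {
                "y": x.ravel(),
                "subj": np.repeat(np.arange(14), 4),
                "cond": np.tile(np.arange(4), 14),
            }
        )
        ref = pg.sphericity(data=long, dv="y", within="cond", subject="subj")
        assert w == pytest.approx(ref.W, rel=1e-9)
        assert chi2 == pytest.approx(ref.chi2, rel=1e-9)
        # pingouin adds a second-order Box term to the p-value
        assert p == pytest.approx(ref.pval, abs=0.01)

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=(10, 4))
            eps = gg_epsilon(x)
            assert 1.0 / 3.0 - 1e-12 <= eps <= 1.0

    def test_incomplete_matrix_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValidationError):
            rm_anova(x)


class TestFriedman:
    def test_identical_columns(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        chi2, df, p = friedman(x)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_strictly_increasing_rows(self):
        """3 participants x 3 steps, each row increasing -> chi2 = 6, df = 2."""
        x = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.1, 0.5, 0.9]])
        chi2, df, p = friedman(x)
        assert chi2 == pytest.approx(6.0)
        assert df == 2.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(size=(9, 4))
            chi2, df, p = friedman(x)
            ref = sps.friedmanchisquare(*x.T)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_permutation_vs_asymptotic(self):
        """The chi-square approximation is crude at n=6; it should still sit
        in the neighbourhood of the exact permutation p (and the exact p is
        the more conservative of the two for mid-range statistics)."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=(6, 3))
        chi2, df, p_asym = friedman(x)
        _, _, p_exact = friedman(x, exact=True)
        assert abs(p_asym - p_exact) < 0.15
        assert 0.0 < p_exact <= 1.0

    def test_exact_on_increasing_rows(self):
        x = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.1, 0.5, 0.9]])
        _, _, p_exact = friedman(x, exact=True)
        # chi2 = 6 is attained only when all three rows share one ordering:
        # 6 concordant assignments out of 6^3 equally likely ones
        assert p_exact == pytest.approx(6 / 6**3, abs=1e-12)

    def test_exact_matches_monte_carlo(self):
        """Independent check of the exact enumeration via random sampling of
        within-row permutations."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=(5, 3))
        chi2, _, p_exact = friedman(x, exact=True)
        from sprintcoord.inference import friedman_statistic

        hits = 0
        n_mc = 4000
        for _ in range(n_mc):
            xp = np.vstack([row[rng.permutation(3)] for row in x])
            stat, _ = friedman_statistic(xp)
            if stat >= chi2 - 1e-9:
                hits += 1
        assert hits / n_mc == pytest.approx(p_exact, abs=0.03)


def _exact_wilcoxon_enumeration(d):
    """Two-sided p by enumerating all sign patterns of |d| ranks."""
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[np.asarray(d) > 0].sum()
    n = len(d)
    total = 2**n
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    mean_w = ranks.sum() / 2.0
    p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return p


class TestWilcoxon:
    def test_degenerate_all_zero(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_all_positive_n6_exact(self):
        """All six differences positive: W = 21, exact two-sided p = 2/64."""
        a = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        b = a - np.array([1.0, 2.0, 0.5, 1.5, 2.5, 0.7])
        w, p = wilcoxon_signed_rank(a, b)
        assert w == pytest.approx(21.0)
        assert p == pytest.approx(0.03125)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=8)
        d = d[d != 0]
        a = np.abs(d) + 5.0 + rng.normal(size=d.size) * 0  # construct pairs
        b = a - d
        w, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(_exact_wilcoxon_enumeration(d), abs=1e-9)

    def test_symmetric_differences(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + np.array([0.5, -0.5, 1.5, -1.5])
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(1.0)


class TestBonferroni:
    def test_simple_scaling(self):
        assert bonferroni([0.01], m=6)[0] == pytest.approx(0.06)

    def test_capped_at_one(self):
        assert bonferroni([0.5], m=6)[0] == 1.0

    def test_identity_for_single(self):
        assert bonferroni([0.2], m=1)[0] == pytest.approx(0.2)

    def test_default_m(self):
        out = bonferroni([0.01, 0.02, 0.03])
        np.testing.assert_allclose(out, [0.03, 0.06, 0.09])

    def test_rejects_invalid(self):
        with pytest.raises(ValidationError):
            bonferroni([1.5])


class TestReports:
    def test_discrete_report_runs(self, sim_config, analysis_config):
        from sprintcoord import analyze_cohort, generate_cohort

        cfg = sim_config
        result = analyze_cohort(generate_cohort(cfg), analysis_config, ["thigh_thigh"])
        report = discrete_kinematics_report(result.discrete_kinematics)
        assert len(report) == 7 * 2  # variables x events
        assert np.all(report["F"] >= 0)
        assert np.all((report["p"] >= 0) & (report["p"] <= 1))

    def test_bin_report_skips_empty_bins(self, sim_config, analysis_config):
        from sprintcoord import analyze_cohort, generate_cohort

        result = analyze_cohort(generate_cohort(sim_config), analysis_config, ["thigh_thigh"])
        report = bin_frequency_report(result.bin_freq)
        assert not report.empty
        # noise-free asymmetric thighs occupy a small subset of bins
        assert report["bin_index"].nunique() < 8
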