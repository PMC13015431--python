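"""Mixed-design ANOVA: oracles, diagnostics and post-hoc corrections."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from edgecrit.anova import (
    DesignError,
    MixedAnova,
    gg_epsilon,
    holm_correct,
    mauchly_test,
    mixed_anova,
    mixed_anova_arrays,
    posthoc,
    posthoc_between,
)


def long_format(Y, groups, extra=None):
    rows = []
    for i in range(Y.shape[0]):
        for l in range(Y.shape[1]):
            row = dict(subject=f"s{i:03d}", group=groups[i], level=f"L{l}",
                       y=Y[i, l])
            if extra is not None:
                row.update({k: v[i] for k, v in extra.items()})
            rows.append(row)
    return pd.DataFrame(rows)


class TestMixedAnovaCore:
    def test_2x2_interaction_equals_squared_t(self):
        """In the degenerate 2x2 design the interaction F is exactly the
        squared two-sample t on the paired differences."""
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(24, 2))
        groups = np.array(["a"] * 12 + ["b"] * 12)
        out = mixed_anova_arrays(Y, groups)
        d = Y[:, 1] - Y[:, 0]
        t, _ = sstats.ttest_ind(d[:12], d[12:])
        F = out["table"].set_index("source").loc["interaction", "F"]
        assert F == pytest.approx(t ** 2, rel=1e-10)

    def test_hand_computed_sums_of_squares(self):
        """Small integer dataset; oracle = explicit split-plot SS formulas."""
        Y = np.array([[3.0, 5.0], [4.0, 8.0], [2.0, 4.0],
                      [7.0, 7.0], [6.0, 10.0], [5.0, 7.0]])
        groups = np.array(["g1"] * 3 + ["g2"] * 3)
        N, k, G = 6, 2, 2
        grand = Y.mean()
        subj = Y.mean(1)
        ss_bs = k * np.sum((subj - grand) ** 2)
        ss_group = sum(k * 3 * (subj[g].mean() - grand) ** 2
                       for g in (slice(0, 3), slice(3, 6)))
        ss_subj_w = ss_bs - ss_group
        lev_mean = Y.mean(0)
        ss_level = N * np.sum((lev_mean - grand) ** 2)
        cell = np.array([Y[:3].mean(0), Y[3:].mean(0)])
        gmean = np.array([Y[:3].mean(), Y[3:].mean()])
        ss_cells = 3 * np.sum((cell - gmean[:, None] - lev_mean[None, :]
                               + grand) ** 2)
        ss_wtotal = np.sum((Y - subj[:, None]) ** 2)
        ss_err_w = ss_wtotal - ss_level - ss_cells
        out = mixed_anova_arrays(Y, groups)
        tab = out["table"].set_index("source")
        F_group = (ss_group / (G - 1)) / (ss_subj_w / (N - G))
        F_level = (ss_level / (k - 1)) / (ss_err_w / ((N - G) * (k - 1)))
        F_inter = (ss_cells / ((k - 1) * (G - 1))) / (ss_err_w / ((N - G) * (k - 1)))
        assert tab.loc["group", "F"] == pytest.approx(F_group, rel=1e-10)
        assert tab.loc["within", "F"] == pytest.approx(F_level, rel=1e-10)
        assert tab.loc["interaction", "F"] == pytest.approx(F_inter, rel=1e-10)

    def test_balanced_design_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(30, 4)) + rng.normal(size=(30, 1))
        groups = np.array(["a"] * 15 + ["b"] * 15)
        df = long_format(Y, groups)
        mine = MixedAnova(df, dv="y", within="level", between="group",
                          subject="subject").fit()
        ref = pg.mixed_anova(df, dv="y", within="level", between="group",
                             subject="subject").set_index("Source")
        tab = mine.table.set_index("source")
        assert tab.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
        assert tab.loc["within", "F"] == pytest.approx(ref.loc["level", "F"])
        assert tab.loc["interaction", "F"] == pytest.approx(
            ref.loc["Interaction", "F"])

    def test_affine_invariance_of_F(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 4))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        f1 = mixed_anova_arrays(Y, groups)["table"]["F"]
        f2 = mixed_anova_arrays(3.2 * Y - 17.0, groups)["table"]["F"]
        assert np.allclose(f1, f2)

    def test_gg_corrected_p_never_below_uncorrected(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            Y = rng.normal(size=(16, 4)) * np.array([1, 1, 2, 4.0])
            groups = np.array(["a"] * 8 + ["b"] * 8)
            tab = mixed_anova_arrays(Y, groups)["table"]
            w = tab.set_index("source")
            for eff in ("within", "interaction"):
                assert w.loc[eff, "p_gg"] >= w.loc[eff, "p_unc"] - 1e-12

    def test_covariate_absorbs_between_effect(self):
        """A group difference fully explained by age vanishes with the
        covariate and is strong without it."""
        rng = np.random.default_rng(4)
        age = np.concatenate([rng.uniform(20, 30, 15), rng.uniform(40, 50, 15)])
        Y = 0.2 * age[:, None] + rng.normal(scale=0.5, size=(30, 3))
        groups = np.array(["young"] * 15 + ["old"] * 15)
        df = long_format(Y, groups, extra={"age": age})
        without = MixedAnova(df, dv="y", within="level", between="group",
                             subject="subject").fit()
        with_cov = MixedAnova(df, dv="y", within="level", between="group",
                              subject="subject", covariates=["age"]).fit()
        assert without.effect("group")["p"] < 0.001
        assert with_cov.effect("group")["F"] < without.effect("group")["F"] / 5

    def test_type_one_error_calibrated_under_null(self):
        """Balanced null: empirical size of each effect near alpha=0.05."""
        rng = np.random.default_rng(5)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        rej = np.zeros(3)
        reps = 800
        for _ in range(reps):
            Y = rng.normal(size=(40, 4))
            tab = mixed_anova_arrays(Y, groups)["table"]
            rej += (tab["p"].to_numpy() < 0.05)
        rates = rej / reps
        assert np.all(np.abs(rates - 0.05) < 0.017)

    def test_power_for_within_shift(self):
        """0.8 SD within-level shift at n=20/group is detected reliably."""
        rng = np.random.default_rng(6)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        hits = 0
        reps = 120
        for _ in range(reps):
            Y = rng.normal(size=(40, 4))
            Y[:, 3] += 0.8
            tab = mixed_anova_arrays(Y, groups)["table"].set_index("source")
            hits += tab.loc["within", "p"] < 0.05
        assert hits / reps > 0.8

    def test_design_errors(self):
        Y = np.zeros((4, 3))
        with pytest.raises(DesignError):
            mixed_anova_arrays(Y, np.array(["a"] * 4))
        with pytest.raises(DesignError):
            mixed_anova_arrays(Y, np.array(["a", "a", "a", "b"]))

    def test_incomplete_subjects_dropped_listwise(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(10, 3))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        df = long_format(Y, groups)
        df = df[~((df.subject == "s000") & (df.level == "L2"))]
        model = MixedAnova(df, dv="y", within="level", between="group",
                           subject="subject")
        assert model.n_dropped == 1
        assert model.wide.shape[0] == 9


class TestSphericity:
    def test_two_levels_trivially_spherical(self):
        Y = np.random.default_rng(0).normal(size=(12, 2))
        W, p = mauchly_test(Y, np.zeros(12))
        assert (W, p) == (1.0, 1.0)

    def test_mauchly_matches_pingouin_single_group(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(25, 4)) @ np.diag([1.0, 1.5, 2.0, 3.0])
        df = long_format(Y, np.array(["x"] * 25))
        W, p = mauchly_test(Y, np.zeros(25))
        ref = pg.sphericity(df, dv="y", within="level", subject="subject")
        assert W == pytest.approx(ref.W, rel=1e-9)
        assert p == pytest.approx(ref.pval, abs=0.005)

    def test_mauchly_size_under_compound_symmetry(self):
        rng = np.random.default_rng(3)
        rej = 0
        reps = 500
        for _ in range(reps):
            Y = rng.normal(size=(20, 4)) + rng.normal(size=(20, 1))
            _, p = mauchly_test(Y, np.zeros(20))
            rej += p < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.03)

    def test_mauchly_detects_heteroscedastic_levels(self):
        rng = np.random.default_rng(4)
        rej = 0
        for _ in range(100):
            Y = rng.normal(size=(20, 4)) * np.array([0.5, 1.0, 2.0, 5.0])
            _, p = mauchly_test(Y, np.zeros(20))
            rej += p < 0.05
        assert rej > 90

    def test_epsilon_one_for_spherical_covariance(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(4000, 4))
        assert gg_epsilon(Y) > 0.99

    def test_epsilon_lower_bound_for_rank_one_covariance(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(30, 1))
        Y = base * np.array([1.0, 2.0, 3.0, 4.0]) + 1e-9 * rng.normal(
            size=(30, 4))
        assert gg_epsilon(Y) == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_epsilon_matches_trace_formula(self):
        """Brute-force oracle: trace^2 / ((k-1) * trace of square) on the
        double-centered covariance."""
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(40, 5)) @ rng.normal(size=(5, 5))
        S = np.cov(Y, rowvar=False)
        k = 5
        H = np.eye(k) - np.ones((k, k)) / k
        Sc = H @ S @ H
        lam = np.linalg.eigvalsh(Sc)
        oracle = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
        assert gg_epsilon(Y) == pytest.approx(oracle, rel=1e-9)


class TestPosthoc:
    def test_all_unit_pvalues_stay_one(self):
        assert np.allclose(holm_correct([1.0, 1.0, 1.0]), 1.0)

    def test_holm_stepdown_arithmetic(self):
        assert np.allclose(holm_correct([0.01, 0.02, 0.04]),
                           [0.03, 0.04, 0.04])

    def test_tukey_kramer_equal_n_reduces_to_hsd(self):
        """With equal group sizes, the Tukey-Kramer p equals the standard
        studentized-range p computed directly."""
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(20, 3))
        Y[10:] += 0.9
        groups = np.array(["a"] * 10 + ["b"] * 10)
        tab = posthoc_between(pd.DataFrame(Y), groups)
        ybar = Y.mean(1)
        n = 10
        msw = (ybar[:10].var(ddof=1) + ybar[10:].var(ddof=1)) / 2
        q = abs(ybar[:10].mean() - ybar[10:].mean()) / np.sqrt(msw / n)
        p_hsd = sstats.studentized_range.sf(q, 2, 18)
        assert tab["p_corrected"].iloc[0] == pytest.approx(p_hsd, abs=1e-6)

    def test_posthoc_within_pairs_and_correction_order(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(15, 4))
        Y[:, 0] += 2.0
        df = long_format(Y, np.array(["a"] * 8 + ["b"] * 7))
        tab = posthoc(df, dv="y", within="level", between="group",
                      subject="subject", effect="within")
        assert len(tab) == 6
        # Holm-corrected p monotone in raw-p order
        srt = tab.sort_values("p_raw")
        assert srt["p_corrected"].is_monotonic_increasing
        assert np.all(tab["p_corrected"] >= tab["p_raw"] - 1e-12)

    def test_fewer_than_two_levels_empty(self):
        rng = np.random.default_rng(10)
        df = long_format(rng.normal(size=(6, 1)),
                         np.array(["a"] * 3 + ["b"] * 3))
        tab = posthoc(df, dv="y", within="level", between="group",
                      subject="subject", effect="within")
        assert len(tab) == 0


def test_results_summary_and_plot():
    rng = np.random.default_rng(11)
    Y = rng.normal(size=(16, 4))
    df = long_format(Y, np.array(["a"] * 8 + ["b"] * 8))
    res = mixed_anova(df, dv="y", within="level", between="group",
                      subject="subject")
    text = res.summary()
    assert "Mauchly" in text and "group" in text
    import matplotlib

    matplotlib.use("Agg")
    ax = res.plot_means()
    assert ax.get_ylabel() == "y"
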