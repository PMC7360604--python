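"""Stats engine tests against independently coded oracles.

The split-plot oracle below computes every sum of squares from cell means
with explicit textbook formulas (balanced designs), a completely different
route from the package's Type-III projection approach. pingouin and
statsmodels serve as additional third-party cross-checks where their
designs overlap.
"""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sst
from statsmodels.stats.anova import AnovaRM

from pupilstress.stats import (
    StatsError,
    assumption_checks,
    bonferroni_posthoc,
    difference_scores,
    gg_epsilon,
    mauchly_test,
    mixed_anova,
    pearson_corr,
    stressed_male_reappraisal_test,
)

# ---------------------------------------------------------------------------
# oracles


def splitplot_oracle(y: np.ndarray) -> dict:
    """Balanced a x b x (k) split-plot ANOVA from cell means (textbook sums).

    ``y`` has shape (A, B, N, K): between factors A, B; N subjects per cell;
    K within levels.
    """
    A, B, N, K = y.shape
    gm = y.mean()
    m_a = y.mean(axis=(1, 2, 3))
    m_b = y.mean(axis=(0, 2, 3))
    m_ab = y.mean(axis=(2, 3))
    m_w = y.mean(axis=(0, 1, 2))
    m_aw = y.mean(axis=(1, 2))
    m_bw = y.mean(axis=(0, 2))
    m_abw = y.mean(axis=2)
    m_s = y.mean(axis=3)

    ss = {}
    ss["A"] = B * N * K * np.sum((m_a - gm) ** 2)
    ss["B"] = A * N * K * np.sum((m_b - gm) ** 2)
    ss["AB"] = N * K * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss["subj"] = K * np.sum((m_s - m_ab[:, :, None]) ** 2)
    ss["W"] = A * B * N * np.sum((m_w - gm) ** 2)
    ss["AW"] = B * N * np.sum((m_aw - m_a[:, None] - m_w[None, :] + gm) ** 2)
    ss["BW"] = A * N * np.sum((m_bw - m_b[:, None] - m_w[None, :] + gm) ** 2)
    ss["ABW"] = N * np.sum(
        (
            m_abw
            - m_ab[:, :, None]
            - m_aw[:, None, :]
            - m_bw[None, :, :]
            + m_a[:, None, None]
            + m_b[None, :, None]
            + m_w[None, None, :]
            - gm
        )
        ** 2
    )
    ss["total"] = np.sum((y - gm) ** 2)
    ss["err_w"] = ss["total"] - sum(ss[k] for k in ("A", "B", "AB", "subj", "W", "AW", "BW", "ABW"))

    df = {
        "A": A - 1,
        "B": B - 1,
        "AB": (A - 1) * (B - 1),
        "subj": A * B * (N - 1),
        "W": K - 1,
        "AW": (A - 1) * (K - 1),
        "BW": (B - 1) * (K - 1),
        "ABW": (A - 1) * (B - 1) * (K - 1),
        "err_w": A * B * (N - 1) * (K - 1),
    }
    out = {}
    for eff in ("A", "B", "AB"):
        f = (ss[eff] / df[eff]) / (ss["subj"] / df["subj"])
        out[eff] = {
            "ss": ss[eff], "df1": df[eff], "df2": df["subj"], "F": f,
            "p": sst.f.sf(f, df[eff], df["subj"]),
            "pes": ss[eff] / (ss[eff] + ss["subj"]),
        }
    for eff in ("W", "AW", "BW", "ABW"):
        f = (ss[eff] / df[eff]) / (ss["err_w"] / df["err_w"])
        out[eff] = {
            "ss": ss[eff], "df1": df[eff], "df2": df["err_w"], "F": f,
            "p": sst.f.sf(f, df[eff], df["err_w"]),
            "pes": ss[eff] / (ss[eff] + ss["err_w"]),
        }
    return out


def epsilon_eigen_oracle(cov: np.ndarray) -> float:
    """GG epsilon from eigenvalues of the orthonormal-contrast projection."""
    k = cov.shape[0]
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1].T  # orthonormal contrasts
    lam = np.linalg.eigvalsh(c @ cov @ c.T)
    eps = lam.sum() ** 2 / ((k - 1) * np.sum(lam**2))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def to_long(y: np.ndarray) -> pd.DataFrame:
    A, B, N, K = y.shape
    rows = []
    sid = 0
    for a in range(A):
        for b in range(B):
            for s in range(N):
                sid += 1
                for w in range(K):
                    rows.append(
                        {
                            "participant": f"s{sid:03d}",
                            "fa": f"a{a}",
                            "fb": f"b{b}",
                            "cond": f"w{w}",
                            "value": y[a, b, s, w],
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def balanced_2x3x5():
    rng = np.random.default_rng(42)
    y = rng.normal(size=(2, 3, 4, 5))
    y += 0.5 * np.arange(5)  # within effect
    y[0] += 0.3               # between effect
    return y


# ---------------------------------------------------------------------------
# mixed ANOVA


class TestMixedAnovaOracle:
    def _compare(self, y, rtol=1e-8):
        res = mixed_anova(
            to_long(y), dv="value", within="cond", subject="participant", between=["fa", "fb"]
        )
        oracle = splitplot_oracle(y)
        table = res.table.set_index("effect")
        mapping = {
            "fa": "A", "fb": "B", "fa:fb": "AB",
            "cond": "W", "fa:cond": "AW", "fb:cond": "BW", "fa:fb:cond": "ABW",
        }
        for eff, okey in mapping.items():
            row = table.loc[eff]
            exp = oracle[okey]
            assert row.ss == pytest.approx(exp["ss"], rel=rtol), eff
            assert row.df1 == exp["df1"], eff
            assert row.df2 == exp["df2"], eff
            assert row.F == pytest.approx(exp["F"], rel=rtol), eff
            assert row.p_unc == pytest.approx(exp["p"], rel=rtol), eff
            assert row.partial_eta_sq == pytest.approx(exp["pes"], rel=rtol), eff
        return res

    def test_balanced_2x3x5_matches_oracle(self, balanced_2x3x5):
        self._compare(balanced_2x3x5)

    def test_toy_2x2x3_integer_data(self):
        rng = np.random.default_rng(0)
        y = rng.integers(1, 10, size=(2, 2, 3, 3)).astype(float)
        self._compare(y)

    def test_epsilon_matches_eigen_oracle(self, balanced_2x3x5):
        y = balanced_2x3x5
        res = mixed_anova(
            to_long(y), dv="value", within="cond", subject="participant", between=["fa", "fb"]
        )
        # pooled within-cell covariance, independently assembled
        A, B, N, K = y.shape
        pooled = np.zeros((K, K))
        for a in range(A):
            for b in range(B):
                pooled += (N - 1) * np.cov(y[a, b], rowvar=False)
        pooled /= A * B * (N - 1)
        assert res.epsilon_gg == pytest.approx(epsilon_eigen_oracle(pooled), rel=1e-10)

    def test_translation_invariance(self, balanced_2x3x5):
        df = to_long(balanced_2x3x5)
        shifted = df.assign(value=df.value + 1234.5)
        r1 = mixed_anova(df, "value", "cond", "participant", ["fa", "fb"]).table
        r2 = mixed_anova(shifted, "value", "cond", "participant", ["fa", "fb"]).table
        np.testing.assert_allclose(r1.F, r2.F, rtol=1e-8)
        np.testing.assert_allclose(r1.partial_eta_sq, r2.partial_eta_sq, rtol=1e-8)

    def test_scale_invariance(self, balanced_2x3x5):
        df = to_long(balanced_2x3x5)
        scaled = df.assign(value=df.value * 7.25)
        r1 = mixed_anova(df, "value", "cond", "participant", ["fa", "fb"])
        r2 = mixed_anova(scaled, "value", "cond", "participant", ["fa", "fb"])
        np.testing.assert_allclose(r1.table.F, r2.table.F, rtol=1e-8)
        np.testing.assert_allclose(r1.table.p_gg, r2.table.p_gg, rtol=1e-8)
        np.testing.assert_allclose(r1.table.partial_eta_sq, r2.table.partial_eta_sq, rtol=1e-8)
        assert r1.epsilon_gg == pytest.approx(r2.epsilon_gg, rel=1e-10)

    def test_matches_pingouin_one_between(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(2, 1, 6, 4))  # one between factor with 2 levels
        df = to_long(y).drop(columns="fb")
        mine = mixed_anova(df, "value", "cond", "participant", ["fa"]).table.set_index("effect")
        ref = pg.mixed_anova(
            data=df, dv="value", within="cond", subject="participant", between="fa"
        ).set_index("Source")
        assert mine.loc["fa", "F"] == pytest.approx(ref.loc["fa", "F"], rel=1e-8)
        assert mine.loc["cond", "F"] == pytest.approx(ref.loc["cond", "F"], rel=1e-8)
        assert mine.loc["fa:cond", "F"] == pytest.approx(ref.loc["Interaction", "F"], rel=1e-8)
        assert mine.loc["cond", "df2"] == ref.loc["cond", "DF2"]

    def test_matches_statsmodels_pure_within(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(1, 1, 10, 4))
        df = to_long(y).drop(columns=["fa", "fb"])
        mine = mixed_anova(df, "value", "cond", "participant").table.set_index("effect")
        ref = AnovaRM(df, depvar="value", subject="participant", within=["cond"]).fit().anova_table
        assert mine.loc["cond", "F"] == pytest.approx(ref.loc["cond", "F Value"], rel=1e-8)
        assert mine.loc["cond", "df1"] == ref.loc["cond", "Num DF"]
        assert mine.loc["cond", "df2"] == ref.loc["cond", "Den DF"]

    def test_gg_correction_matches_pingouin_pure_within(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(12, 1))
        y = (base + rng.normal(scale=[0.2, 0.5, 2.0, 4.0], size=(12, 4)))[None, None]
        df = to_long(y).drop(columns=["fa", "fb"])
        mine = mixed_anova(df, "value", "cond", "participant")
        ref = pg.rm_anova(data=df, dv="value", within="cond", subject="participant", correction=True)
        assert mine.epsilon_gg == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-8)
        row = mine.table.set_index("effect").loc["cond"]
        assert row.p_gg == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_k2_forces_epsilon_one(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(2, 1, 5, 2))
        df = to_long(y).drop(columns="fb")
        res = mixed_anova(df, "value", "cond", "participant", ["fa"])
        assert res.epsilon_gg == 1.0
        tab = res.table.set_index("effect")
        assert tab.loc["cond", "p_gg"] == pytest.approx(tab.loc["cond", "p_unc"])
        assert np.isnan(res.mauchly_w)

    def test_zero_between_ss_gives_zero_eta(self):
        # identical subject sets in both groups -> group SS exactly 0
        pattern = np.array(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [2.0, 1.0, 5.0]]
        )
        y = np.stack([pattern[None], pattern[None]])  # (2,1,3,3)
        df = to_long(y).drop(columns="fb")
        res = mixed_anova(df, "value", "cond", "participant", ["fa"]).table.set_index("effect")
        assert res.loc["fa", "ss"] == pytest.approx(0.0, abs=1e-10)
        assert res.loc["fa", "partial_eta_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_incomplete_subject_dropped(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(2, 1, 4, 3))
        df = to_long(y).drop(columns="fb")
        df = df[~((df.participant == "s001") & (df.cond == "w2"))]
        res = mixed_anova(df, "value", "cond", "participant", ["fa"])
        assert res.n_subjects == 7
        assert res.dropped_subjects == ["s001"]

    def test_empty_cell_errors(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(2, 1, 3, 3))
        df = to_long(y).drop(columns="fb")
        df = df[~((df.fa == "a0"))]
        with pytest.raises(StatsError):
            mixed_anova(df, "value", "cond", "participant", ["fa"])


class TestEpsilon:
    def test_k2_bound(self):
        assert gg_epsilon(np.array([[1.0, 0.2], [0.2, 1.5]])) == 1.0

    def test_compound_symmetry_gives_one(self):
        k = 5
        s = 0.4 * np.ones((k, k)) + 0.6 * np.eye(k)
        assert gg_epsilon(s) == pytest.approx(1.0, abs=1e-12)
        assert epsilon_eigen_oracle(s) == pytest.approx(1.0, abs=1e-12)

    def test_maximally_nonspherical_lower_bound(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        s = np.outer(v, v)  # rank-1 -> epsilon at 1/(k-1)
        assert gg_epsilon(s) == pytest.approx(0.25)

    def test_random_cov_matches_eigen_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(40, 6))
        s = np.cov(x, rowvar=False)
        assert gg_epsilon(s) == pytest.approx(epsilon_eigen_oracle(s), rel=1e-10)

    def test_degenerate_returns_lower_bound(self):
        s = np.ones((4, 4))
        assert gg_epsilon(s) == pytest.approx(1.0 / 3.0)


class TestMauchly:
    def test_identity_gives_w_one(self):
        w, p = mauchly_test(np.eye(4), 20)
        assert w == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_w_in_unit_interval(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=(25, 4))
            w, p = mauchly_test(np.cov(x, rowvar=False), 25)
            assert 0.0 < w <= 1.0

    def test_k2_not_applicable(self):
        w, p = mauchly_test(np.eye(2), 20)
        assert np.isnan(w) and np.isnan(p)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(30, 4))
        df = pd.DataFrame(x, columns=list("abcd"))
        df["subj"] = range(30)
        long = df.melt(id_vars="subj", var_name="cond", value_name="y")
        ref = pg.sphericity(long, dv="y", within="cond", subject="subj")
        w, p = mauchly_test(np.cov(x, rowvar=False), 30)
        assert w == pytest.approx(float(ref.W), rel=1e-8)
        # classic first-order chi-square approximation; pingouin adds a
        # second-order term, so agreement is to ~1e-3
        assert p == pytest.approx(float(ref.pval), abs=1e-3)

    def test_null_p_roughly_uniform(self):
        # spherical population: p-values should be ~Uniform(0,1)
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(300):
            x = rng.normal(size=(40, 3))
            _, p = mauchly_test(np.cov(x, rowvar=False), 40)
            ps.append(p)
        ks = sst.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestPosthoc:
    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(15)
        cells = {"a": rng.normal(0, 1, 30), "b": rng.normal(1, 1, 30)}
        fam = [("a", "b")] * 1  # single contrast, family size forced to 5
        out = bonferroni_posthoc(cells, fam, family_size=5)
        row = out.iloc[0]
        assert row.p_bonferroni == pytest.approx(min(1.0, 5 * row.p_raw))

    def test_identical_groups(self):
        cells = {"a": np.ones(10), "b": np.ones(10)}
        out = bonferroni_posthoc(cells, [("a", "b")])
        assert out.iloc[0].t == 0.0
        assert out.iloc[0].p_bonferroni == 1.0

    def test_paired_matches_hand_computed_t(self):
        rng = np.random.default_rng(16)
        a = rng.normal(0, 1, 20)
        b = a + rng.normal(0.5, 0.8, 20)
        out = bonferroni_posthoc({"a": a, "b": b}, [("a", "b", "paired")])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert out.iloc[0].t == pytest.approx(t_hand, rel=1e-10)
        assert out.iloc[0].df == d.size - 1

    def test_small_cell_skipped(self):
        cells = {"a": np.array([1.0]), "b": np.ones(10)}
        out = bonferroni_posthoc(cells, [("a", "b")])
        assert out.empty

    def test_p_capped_at_one(self):
        rng = np.random.default_rng(17)
        cells = {"a": rng.normal(size=30), "b": rng.normal(size=30)}
        out = bonferroni_posthoc(cells, [("a", "b")], family_size=1000)
        assert out.iloc[0].p_bonferroni <= 1.0


class TestAssumptionChecks:
    def test_normal_sample_mostly_passes(self):
        rng = np.random.default_rng(18)
        passed = 0
        reps = 40
        for _ in range(reps):
            rep = assumption_checks({"x": rng.normal(size=500)})
            passed += rep["ks_p"]["x"] > 0.05
        assert passed / reps >= 0.9

    def test_equal_cells_levene_zero(self):
        rep = assumption_checks({"a": np.ones(10) * 2, "b": np.ones(10) * 2})
        assert rep["levene_stat"] == pytest.approx(0.0)

    def test_lognormal_triggers_transform_flag(self):
        rng = np.random.default_rng(19)
        flagged = 0
        reps = 20
        for _ in range(reps):
            rep = assumption_checks({"x": np.exp(rng.normal(size=400))})
            flagged += rep["log_transform_recommended"]
        assert flagged / reps >= 0.8

    def test_shift_required_for_nonpositive(self):
        rng = np.random.default_rng(20)
        rep = assumption_checks({"x": np.exp(rng.normal(size=400)) - 5.0})
        if rep["log_transform_recommended"] or rep["shift_required"]:
            assert rep["shift_required"]
            assert not rep["log_transform_recommended"]


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10, dtype=float)
        r, p, n = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_perfect_negative(self):
        x = np.arange(10, dtype=float)
        r, _, _ = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_estimator_consistency(self):
        rng = np.random.default_rng(21)
        rho = 0.3
        cov = [[1.0, rho], [rho, 1.0]]
        rs = []
        for _ in range(2000):
            xy = rng.multivariate_normal([0, 0], cov, size=40)
            r, _, _ = pearson_corr(xy[:, 0], xy[:, 1])
            rs.append(r)
        assert np.mean(rs) == pytest.approx(rho, abs=0.02)

    def test_zero_variance_errors(self):
        with pytest.raises(StatsError):
            pearson_corr(np.ones(10), np.arange(10.0))


class TestDifferenceScores:
    def _df(self):
        rows = []
        for pid, vals in (("p1", {"view_negative": 6.0, "reappraisal": 4.0, "intensify": 7.0}),
                          ("p2", {"view_negative": 5.0, "reappraisal": 5.5, "intensify": 6.0})):
            for cond, v in vals.items():
                rows.append({"participant": pid, "condition": cond, "value": v})
        return pd.DataFrame(rows)

    def test_subtracts_reference(self):
        out = difference_scores(self._df(), "value", "condition", "participant")
        p1 = out[(out.participant == "p1") & (out.condition == "reappraisal")]
        assert p1["value"].iloc[0] == pytest.approx(-2.0)

    def test_reference_removed(self):
        out = difference_scores(self._df(), "value", "condition", "participant")
        assert "view_negative" not in set(out.condition)

    def test_participant_offset_cancels(self):
        # additive per-participant offset leaves difference scores unchanged
        rng = np.random.default_rng(22)
        y = rng.normal(size=(2, 1, 5, 4))
        from test_stats import to_long  # self-import for clarity

        df = to_long(y).drop(columns="fb")
        df["cond"] = df["cond"].map({"w0": "view_negative", "w1": "reappraisal",
                                     "w2": "intensify", "w3": "distraction"})
        offsets = {pid: rng.normal(scale=10) for pid in df.participant.unique()}
        shifted = df.assign(value=df.value + df.participant.map(offsets))
        d1 = difference_scores(df, "value", "cond", "participant")
        d2 = difference_scores(shifted, "value", "cond", "participant")
        r1 = mixed_anova(d1, "value", "cond", "participant", ["fa"]).table
        r2 = mixed_anova(d2, "value", "cond", "participant", ["fa"]).table
        np.testing.assert_allclose(r1.F, r2.F, rtol=1e-8)

    def test_missing_reference_dropped(self):
        df = self._df()
        df = df[~((df.participant == "p2") & (df.condition == "view_negative"))]
        out = difference_scores(df, "value", "condition", "participant")
        assert set(out.participant) == {"p1"}


class TestFocalContrast:
    def test_detects_configured_shift(self):
        from pupilstress import StudyConfig, simulate_study

        cfg = StudyConfig(n_per_cell=25, seed=31)
        ds = simulate_study(cfg, tables=("ratings",))
        t, df, p = stressed_male_reappraisal_test(ds.ratings, ds.roster)
        assert p < 0.05
        assert t > 0  # (control - stress): stressed males rate lower arousal
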