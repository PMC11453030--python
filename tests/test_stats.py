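"""Trend ANOVA machinery: orthogonal polynomials, type-III F tests,
Greenhouse-Geisser correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gcsr.stats import (
    DesignTable,
    format_anova_table,
    gg_anova,
    orth_poly,
    run_study_analyses,
    trend_anova,
)


def make_table(rng, n_per_cell=(4, 4, 5, 5), k=12, effect=None):
    """Random 2x2 design table, optionally with an injected mean structure."""
    rows, ids, ys = [], [], []
    cells = [("GAD", "TR"), ("GAD", "NOT"), ("SAD", "TR"), ("SAD", "NOT")]
    i = 0
    for (diag, res), n in zip(cells, n_per_cell):
        for _ in range(n):
            y = rng.standard_normal(k)
            if effect is not None:
                y = y + effect(diag, res)
            ids.append(f"s{i}")
            rows.append({"diagnosis": diag, "resistance": res})
            ys.append(y)
            i += 1
    return DesignTable(ids, pd.DataFrame(rows), np.array(ys))


class TestOrthPoly:
    def test_quadratic_k3(self):
        P = orth_poly(3)
        expected = np.array([1, -2, 1]) / np.sqrt(6)
        assert np.allclose(P[1], expected)

    @pytest.mark.parametrize("k", [3, 5, 9, 12])
    def test_orthonormal_zero_sum(self, k):
        P = orth_poly(k)
        assert P.shape == (k - 1, k)
        assert np.allclose(P @ P.T, np.eye(k - 1), atol=1e-12)
        assert np.allclose(P.sum(axis=1), 0, atol=1e-12)

    def test_matches_qr_oracle_k12(self):
        # independent construction: Householder QR of the Vandermonde basis
        k = 12
        x = np.arange(k, dtype=float) - (k - 1) / 2
        V = np.vander(x, k, increasing=True)
        Q, _ = np.linalg.qr(V)
        mine = orth_poly(k)
        for j in range(1, k):
            q = Q[:, j] * np.sign(Q[-1, j]) if Q[-1, j] != 0 else Q[:, j]
            assert np.allclose(mine[j - 1], q, atol=1e-10)

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            orth_poly(1)


def brute_force_type3(between, y):
    """Independent type-III oracle via statsmodels formula API (sum coding)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = between.copy()
    df["score"] = y
    terms = [f"C({c}, Sum)" for c in between.columns]
    formula = "score ~ " + " * ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=3)
    return tab, fit


class TestTrendAnova:
    def test_denominator_df_is_14_for_study_cells(self):
        rng = np.random.default_rng(0)
        table = make_table(rng)
        res = trend_anova(table)
        assert all(e.df2 == 14 for e in res.effects)
        orders = sorted({e.order for e in res.effects})
        assert orders == list(range(1, 12))

    def test_hand_computed_one_way_quadratic(self):
        # two groups of 3 subjects, 3 bins: quadratic trend scores reduce the
        # analysis to a one-way ANOVA computed here by explicit sums of squares
        y = np.array([
            [1.0, 2.0, 1.5], [0.5, 1.5, 1.2], [1.2, 2.2, 1.0],
            [2.0, 1.0, 2.5], [1.8, 0.8, 2.0], [2.2, 1.4, 2.8],
        ])
        between = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3})
        table = DesignTable([f"s{i}" for i in range(6)], between, y)
        res = trend_anova(table, orders=[2])

        v = np.array([1, -2, 1]) / np.sqrt(6)
        scores = y @ v
        ga, gb = scores[:3], scores[3:]
        grand = scores.mean()
        ss_between = 3 * (ga.mean() - grand) ** 2 + 3 * (gb.mean() - grand) ** 2
        ss_within = ((ga - ga.mean()) ** 2).sum() + ((gb - gb.mean()) ** 2).sum()
        f_manual = (ss_between / 1) / (ss_within / 4)
        assert res.get("group x frequency", 2).F == pytest.approx(f_manual, rel=1e-10)

        # intercept: unweighted grand-mean test
        f_int = (6 * grand ** 2) / (ss_within / 4)
        assert res.get("frequency", 2).F == pytest.approx(f_int, rel=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_statsmodels_type3_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = make_table(rng)
        res = trend_anova(table)
        P = orth_poly(12)
        for order in (1, 5, 11):
            scores = table.y @ P[order - 1]
            tab, _ = brute_force_type3(table.between, scores)
            mapping = {
                "Intercept": "frequency",
                "C(diagnosis, Sum)": "diagnosis x frequency",
                "C(resistance, Sum)": "resistance x frequency",
                "C(diagnosis, Sum):C(resistance, Sum)":
                    "diagnosis x resistance x frequency",
            }
            for sm_name, mine_name in mapping.items():
                mine = res.get(mine_name, order)
                assert mine.F == pytest.approx(tab.loc[sm_name, "F"], rel=1e-8)
                assert mine.p == pytest.approx(tab.loc[sm_name, "PR(>F)"], abs=1e-10)
                assert mine.df1 == tab.loc[sm_name, "df"]

    def test_single_df_trend_equals_squared_t(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal((12, 5))
        between = pd.DataFrame({"group": ["a"] * 6 + ["b"] * 6})
        table = DesignTable([f"s{i}" for i in range(12)], between, y)
        res = trend_anova(table, orders=[1])
        scores = y @ orth_poly(5)[0]
        t, _ = sps.ttest_ind(scores[:6], scores[6:])
        assert res.get("group x frequency", 1).F == pytest.approx(t ** 2, rel=1e-10)

    def test_variance_partition_reconstructs_profiles(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal((5, 9))
        P = orth_poly(9)
        mean = y.mean(axis=1, keepdims=True)
        recon = mean + (y @ P.T) @ P
        assert np.allclose(recon, y, atol=1e-10)

    def test_flat_identical_profiles_degenerate(self):
        y = np.full((8, 6), 3.14)
        between = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4})
        table = DesignTable([f"s{i}" for i in range(8)], between, y)
        res = trend_anova(table)
        for e in res.effects:
            assert e.F == 0.0 and "degenerate" in e.note


def gg_epsilon_oracle(y, groups):
    """Direct Greenhouse-Geisser epsilon from the double-centred pooled
    covariance of the raw repeated measures."""
    k = y.shape[1]
    levels = sorted(set(groups))
    resid = np.vstack([
        y[[g == lev for g in groups]] - y[[g == lev for g in groups]].mean(axis=0)
        for lev in levels
    ])
    S = resid.T @ resid / (len(y) - len(levels))
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    return float(np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc * Sc)))


class TestGGAnova:
    def _table(self, y, groups):
        between = pd.DataFrame({"group": groups})
        return DesignTable([f"s{i}" for i in range(len(y))], between, y)

    def test_compound_symmetry_gives_epsilon_near_1(self):
        rng = np.random.default_rng(10)
        n, k = 200, 4
        subj = rng.standard_normal((n, 1))
        y = subj + rng.standard_normal((n, k))  # exchangeable levels
        res = gg_anova(self._table(y, ["a"] * (n // 2) + ["b"] * (n // 2)))
        eps = res.get("within").epsilon
        assert eps == pytest.approx(1.0, abs=0.05)

    def test_dominant_component_epsilon_near_lower_bound(self):
        rng = np.random.default_rng(11)
        n, k = 40, 5
        latent = rng.standard_normal(n)
        pattern = np.array([2.0, -1.0, 0.5, -1.0, -0.5])
        y = np.outer(latent, pattern) + 0.01 * rng.standard_normal((n, k))
        res = gg_anova(self._table(y, ["a"] * 20 + ["b"] * 20))
        eps = res.get("within").epsilon
        assert 1 / (k - 1) <= eps <= 0.30

    def test_epsilon_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal((12, 3)) + np.array([0.0, 1.0, 0.5])
        groups = ["a"] * 6 + ["b"] * 6
        res = gg_anova(self._table(y, groups))
        assert res.get("within").epsilon == pytest.approx(
            gg_epsilon_oracle(y, groups), rel=1e-10)

    def test_epsilon_bounds_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            k = rng.integers(3, 7)
            y = rng.standard_normal((15, k))
            res = gg_anova(self._table(y, ["a"] * 7 + ["b"] * 8))
            eps = res.get("within").epsilon
            assert 1 / (k - 1) - 1e-12 <= eps <= 1 + 1e-12

    def test_against_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        n, k = 16, 4
        y = rng.standard_normal((n, k)) + np.array([0.0, 0.4, 0.8, 0.2])
        groups = ["a"] * 8 + ["b"] * 8
        res = gg_anova(self._table(y, groups))

        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "group": np.repeat(groups, k),
            "level": np.tile(np.arange(k), n),
            "value": y.ravel(),
        })
        aov = pg.mixed_anova(long, dv="value", within="level", subject="subject",
                             between="group", correction=True)
        within_row = aov[aov.Source == "level"].iloc[0]
        inter_row = aov[aov.Source == "Interaction"].iloc[0]
        mine_within = res.get("within")
        mine_inter = res.get("group x within")
        assert mine_within.F == pytest.approx(within_row["F"], rel=1e-6)
        assert mine_inter.F == pytest.approx(inter_row["F"], rel=1e-6)
        # epsilon conventions differ: pingouin estimates it from the grand
        # covariance whereas this package pools within cells (the convention
        # of the big commercial packages); both live in the same bounds
        assert 1 / (k - 1) <= mine_within.epsilon <= 1.0


class TestPaperAnalyses:
    def _cohort(self, rng):
        groups = (["GAD_TR"] * 4 + ["GAD_NOT"] * 4 + ["SAD_TR"] * 5 +
                  ["SAD_NOT"] * 5 + ["MDD_TR"] * 11 + ["GMD_NOT"] * 15)
        ids = [f"{g}_{i}" for i, g in enumerate(groups)]
        wide = pd.DataFrame(rng.standard_normal((len(ids), 12)),
                            index=pd.Index(ids, name="subject_id"),
                            columns=[f"{f}Hz" for f in range(2, 14)])
        meta = pd.DataFrame({"subject_id": ids, "group": groups})
        return wide, meta

    def test_order_ranges(self):
        rng = np.random.default_rng(20)
        wide, meta = self._cohort(rng)
        report = run_study_analyses(wide, meta)
        anx = report["analyses"]["anxiety_2x2"]
        dep = report["analyses"]["depression_tr"]
        assert anx["subjects"] == 18 and dep["subjects"] == 26
        assert sorted({e["order"] for e in anx["effects"]}) == list(range(1, 12))
        assert sorted({e["order"] for e in dep["effects"]}) == list(range(1, 9))

    def test_stray_subjects_warned_and_listed(self):
        rng = np.random.default_rng(21)
        wide, meta = self._cohort(rng)
        meta.loc[0, "group"] = "CONTROL"
        with pytest.warns(UserWarning, match="skipped"):
            report = run_study_analyses(wide, meta)
        assert len(report["skipped_subjects"]) == 1

    def test_table_formatting(self):
        rng = np.random.default_rng(22)
        wide, meta = self._cohort(rng)
        text = format_anova_table(run_study_analyses(wide, meta))
        assert "anxiety_2x2" in text and "depression_tr" in text
        assert "diagnosis x resistance x frequency" in text
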