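"""Inferential engine vs. independent brute-force and pingouin oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from drivestress.stats import (
    bonferroni_posthoc,
    gg_epsilon,
    mauchly_test,
    paired_test,
    polynomial_contrast,
    polynomial_weights,
    rm_anova_2x_k,
)


# ---------------------------------------------------------------------------
# brute-force oracles: explicit sums over cells, no shared code paths
# ---------------------------------------------------------------------------

def brute_force_rm_anova(X, Y):
    """Cell-by-cell SS decomposition of a 2 x k within-subject design."""
    n, k = X.shape
    cells = {(i, 0, j): X[i, j] for i in range(n) for j in range(k)}
    cells.update({(i, 1, j): Y[i, j] for i in range(n) for j in range(k)})
    vals = list(cells.values())
    grand = sum(vals) / len(vals)

    def mean(pred):
        sel = [v for key, v in cells.items() if pred(key)]
        return sum(sel) / len(sel)

    ss_a = ss_b = ss_ab = ss_s = ss_sa = ss_sb = 0.0
    m_a = {a: mean(lambda q, a=a: q[1] == a) for a in (0, 1)}
    m_b = {b: mean(lambda q, b=b: q[2] == b) for b in range(k)}
    m_s = {i: mean(lambda q, i=i: q[0] == i) for i in range(n)}
    for a in (0, 1):
        ss_a += n * k * (m_a[a] - grand) ** 2
    for b in range(k):
        ss_b += 2 * n * (m_b[b] - grand) ** 2
    for i in range(n):
        ss_s += 2 * k * (m_s[i] - grand) ** 2
    for a in (0, 1):
        for b in range(k):
            m_ab = mean(lambda q, a=a, b=b: q[1] == a and q[2] == b)
            ss_ab += n * (m_ab - m_a[a] - m_b[b] + grand) ** 2
    for i in range(n):
        for a in (0, 1):
            m_sa = mean(lambda q, i=i, a=a: q[0] == i and q[1] == a)
            ss_sa += k * (m_sa - m_s[i] - m_a[a] + grand) ** 2
    for i in range(n):
        for b in range(k):
            m_sb = mean(lambda q, i=i, b=b: q[0] == i and q[2] == b)
            ss_sb += 2 * (m_sb - m_s[i] - m_b[b] + grand) ** 2
    ss_total = sum((v - grand) ** 2 for v in vals)
    ss_sab = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_sa - ss_sb

    def f_and_p(ss, df, ss_err, df_err):
        F = (ss / df) / (ss_err / df_err)
        return F, float(sps.f.sf(F, df, df_err)), ss / (ss + ss_err)

    out = {}
    out["condition_type"] = f_and_p(ss_a, 1, ss_sa, n - 1)
    out["time"] = f_and_p(ss_b, k - 1, ss_sb, (n - 1) * (k - 1))
    out["interaction"] = f_and_p(ss_ab, k - 1, ss_sab, (n - 1) * (k - 1))
    return out


def brute_force_contrast_t(X, weights):
    scores = [float(np.dot(X[i], weights)) for i in range(X.shape[0])]
    n = len(scores)
    m = sum(scores) / n
    sd = (sum((s - m) ** 2 for s in scores) / (n - 1)) ** 0.5
    t = m / (sd / n**0.5)
    return t, float(2 * sps.t.sf(abs(t), n - 1))


def brute_force_paired(x, y):
    d = [float(a - b) for a, b in zip(x, y)]
    n = len(d)
    m = sum(d) / n
    sd = (sum((v - m) ** 2 for v in d) / (n - 1)) ** 0.5
    t = m / (sd / n**0.5)
    return t, float(2 * sps.t.sf(abs(t), n - 1)), m / sd


# ---------------------------------------------------------------------------


class TestRmAnova:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(3, 7))
            X = rng.standard_normal((n, k))
            Y = rng.standard_normal((n, k)) + rng.normal(0, 0.5)
            res = rm_anova_2x_k(X, Y)
            oracle = brute_force_rm_anova(X, Y)
            for eff in ("condition_type", "time", "interaction"):
                F, p, eta = oracle[eff]
                assert res[eff].F == pytest.approx(F, abs=1e-8)
                assert res[eff].p_uncorrected == pytest.approx(p, abs=1e-8)
                assert res[eff].partial_eta_sq == pytest.approx(eta, abs=1e-8)

    def test_matches_pingouin_two_way_rm(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        n, k = 10, 6
        X = rng.standard_normal((n, k))
        Y = rng.standard_normal((n, k)) + 0.4
        res = rm_anova_2x_k(X, Y)
        rows = [
            (i, a, j, M[i, j])
            for i in range(n)
            for a, M in (("exp", X), ("ctrl", Y))
            for j in range(k)
        ]
        df = pd.DataFrame(rows, columns=["subj", "ctype", "time", "y"])
        aov = pg.rm_anova(
            dv="y", within=["ctype", "time"], subject="subj", data=df, detailed=True
        )
        for eff, src in (
            ("condition_type", "ctype"),
            ("time", "time"),
            ("interaction", "ctype * time"),
        ):
            row = aov[aov.Source == src].iloc[0]
            assert res[eff].F == pytest.approx(row["F"], rel=1e-9)
            assert res[eff].p_uncorrected == pytest.approx(row["p_unc"], rel=1e-9)
            if eff != "condition_type":
                assert res[eff].gg_epsilon == pytest.approx(row["eps"], rel=1e-9)
                assert res[eff].p_gg == pytest.approx(row["p_GG_corr"], rel=1e-9)

    def test_all_cells_equal_yields_zero_f(self):
        X = np.full((5, 4), 3.0)
        res = rm_anova_2x_k(X, X.copy())
        for eff in res.effects.values():
            assert eff.F == 0.0
            assert eff.partial_eta_sq == 0.0
            assert np.isfinite(eff.p_uncorrected)

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(55)
        n, k = 200, 6
        subj = rng.normal(0, 2.0, size=(n, 1))  # equicorrelation
        X = subj + rng.standard_normal((n, k))
        Y = subj + rng.standard_normal((n, k))
        res = rm_anova_2x_k(X, Y)
        assert res["time"].gg_epsilon >= 0.95
        assert res["interaction"].gg_epsilon >= 0.95

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(9)
        for k in (3, 5, 10):
            Z = rng.standard_normal((8, k)) @ np.diag(rng.uniform(0.2, 3.0, k))
            eps = gg_epsilon(Z)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_degenerate_error_with_signal_raises(self):
        X = np.tile(np.arange(4.0), (5, 1))  # no subject variability at all
        with pytest.raises(ZeroDivisionError, match="condition_type"):
            rm_anova_2x_k(X, X + 1.0)

    def test_too_few_subjects_rejected(self):
        X = np.zeros((2, 4))
        with pytest.raises(ValueError, match="3 subjects"):
            rm_anova_2x_k(X, X)

    def test_mauchly_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(31)
        Z = rng.standard_normal((12, 5))
        W, p = mauchly_test(Z)
        long = pd.DataFrame(Z).assign(s=range(12)).melt(id_vars="s", var_name="t")
        ref = pg.sphericity(long, dv="value", subject="s", within="t")
        assert W == pytest.approx(ref.W, rel=1e-9)
        assert p == pytest.approx(ref.pval, rel=1e-9)


class TestBonferroni:
    def test_adjustment_scales_by_k(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((20, 10))
        Y = rng.standard_normal((20, 10))
        rows = bonferroni_posthoc(X, Y)
        for row in rows:
            assert row["p_adj"] == pytest.approx(min(1.0, row["p"] * 10))

    def test_threshold_example(self):
        # p = .004 with 10 comparisons survives; p = .01 does not
        assert min(1.0, 0.004 * 10) < 0.05 < min(1.0, 0.01 * 10)

    def test_identical_matrices_all_nonsignificant(self):
        X = np.random.default_rng(1).standard_normal((10, 6))
        rows = bonferroni_posthoc(X, X.copy())
        assert all(row["p_adj"] == 1.0 and not row["significant"] for row in rows)


class TestPolynomialContrast:
    def test_weights_orthonormal_and_zero_sum(self):
        w = polynomial_weights(10)
        mat = np.vstack([w["linear"], w["quadratic"], w["cubic"]])
        assert np.max(np.abs(mat.sum(axis=1))) < 1e-12
        gram = mat @ mat.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-12)

    def test_flat_curves_give_zero_t(self):
        X = np.full((8, 10), 2.0)
        res = polynomial_contrast(X)
        assert all(c.t == 0.0 and c.p == 1.0 for c in res.values())

    def test_quadratic_construction_dominates(self):
        rng = np.random.default_rng(99)
        k, n = 10, 30
        t = np.arange(k)
        curve = 1.0 * (t - t.mean()) ** 2
        X = curve + 0.5 * rng.standard_normal((n, k))
        res = polynomial_contrast(X)
        assert abs(res["quadratic"].t) > abs(res["linear"].t)
        assert abs(res["quadratic"].t) > abs(res["cubic"].t)
        assert res["quadratic"].p < 0.001
        assert res["quadratic"].t > 0  # U-shape => positive by convention
        # oracle: scores and t recomputed by hand
        t_or, p_or = brute_force_contrast_t(X, res["quadratic"].weights)
        assert res["quadratic"].t == pytest.approx(t_or, abs=1e-10)
        assert res["quadratic"].p == pytest.approx(p_or, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            polynomial_weights(3, max_order=3)


class TestPairedTest:
    def test_identical_vectors(self):
        x = np.arange(5.0)
        r = paired_test(x, x.copy())
        assert (r.t, r.cohens_d, r.p) == (0.0, 0.0, 1.0)

    def test_constant_nonzero_diff_degenerate(self):
        r = paired_test(np.array([2.0, 3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0, 4.0]))
        assert r.sd_diff == 0.0
        assert np.isinf(r.cohens_d) and r.cohens_d > 0
        assert r.p == 0.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(5, 30))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + rng.normal(0, 0.3)
            r = paired_test(x, y)
            t_or, p_or, d_or = brute_force_paired(x, y)
            assert r.t == pytest.approx(t_or, abs=1e-10)
            assert r.p == pytest.approx(p_or, abs=1e-10)
            assert r.cohens_d == pytest.approx(d_or, abs=1e-10)
            assert r.t == pytest.approx(r.cohens_d * np.sqrt(n), abs=1e-10)

    def test_matches_scipy(self):
        rng = np.random.default_rng(18)
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        r = paired_test(x, y)
        ref = sps.ttest_rel(x, y)
        assert r.t == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestEffectScaling:
    def test_eta_sq_monotone_in_template_amplitude(self):
        # doubling the injected effect never shrinks the mean interaction
        # partial eta squared across seeds
        from drivestress.simulate import EcrTemplate, simulate_epoch_pair_cohort

        etas = {1.0: [], 2.0: []}
        for scale in etas:
            tpl = EcrTemplate(-5.0 * scale, 1.0, 6.0 * scale, 3.0, 1.0)
            for seed in range(6):
                rel, exp, ctrl = simulate_epoch_pair_cohort(27, tpl, seed=seed)
                res = rm_anova_2x_k(exp[:, 1:], ctrl[:, 1:])
                etas[scale].append(res["interaction"].partial_eta_sq)
        assert np.mean(etas[2.0]) >= np.mean(etas[1.0])
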