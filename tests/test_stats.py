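import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coregload import stats


def _tidy(data, subjects=None, factor="condition"):
    """(N x k) array -> tidy long table."""
    n, k = data.shape
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append(
                {
                    "subject": f"s{i:02d}" if subjects is None else subjects[i],
                    factor: f"l{j}",
                    "value": data[i, j],
                }
            )
    return pd.DataFrame(rows)


def _oracle_oneway_rm(data):
    """First-principles SS decomposition for the one-way within ANOVA."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    p = sps.f.sf(f, df1, df2)
    eta = ss_cond / (ss_cond + ss_err)
    return f, p, eta


class TestRmAnovaOneWay:
    def test_matches_brute_force_oracle_50_tables(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            k = int(rng.integers(2, 6))
            data = rng.standard_normal((n, k)) + rng.standard_normal((n, 1))
            res = stats.rm_anova(_tidy(data), within=["condition"])[0]
            f, p, eta = _oracle_oneway_rm(data)
            assert res.F == pytest.approx(f, rel=1e-10)
            assert res.p == pytest.approx(p, rel=1e-10)
            assert res.eta_p2 == pytest.approx(eta, rel=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.standard_normal((10, 4)) + rng.standard_normal((10, 1)) * 2
        df = _tidy(data)
        res = stats.rm_anova(df, within=["condition"])[0]
        ref = pg.rm_anova(
            data=df, dv="value", within="condition", subject="subject",
            correction=True, detailed=True,
        )
        assert res.F == pytest.approx(float(ref["F"][0]), rel=1e-8)
        assert res.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-8)
        assert res.gg_epsilon == pytest.approx(float(ref["eps"][0]), rel=1e-6)
        assert res.p_gg == pytest.approx(float(ref["p_GG_corr"][0]), rel=1e-6)

    def test_identical_values_degenerate(self):
        data = np.full((5, 3), 2.0)
        res = stats.rm_anova(_tidy(data), within=["condition"])[0]
        assert res.degenerate
        assert res.F == 0.0

    def test_compound_symmetry_epsilon_near_one(self, rng):
        # equal variances and covariances -> sphericity -> epsilon ~ 1
        n, k = 400, 4
        shared = rng.standard_normal((n, 1))
        data = shared + rng.standard_normal((n, k))
        res = stats.rm_anova(_tidy(data), within=["condition"])[0]
        assert res.gg_epsilon > 0.97

    def test_epsilon_bounds(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 6))
            data = rng.standard_normal((6, k)) * rng.uniform(0.5, 3, size=k)
            res = stats.rm_anova(_tidy(data), within=["condition"])[0]
            assert 1.0 / (k - 1) - 1e-12 <= res.gg_epsilon <= 1.0 + 1e-12

    def test_missing_cell_error(self):
        df = _tidy(np.zeros((4, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            stats.rm_anova(df, within=["condition"])

    def test_too_few_subjects_error(self):
        with pytest.raises(ValueError, match="subjects"):
            stats.rm_anova(_tidy(np.zeros((2, 3))), within=["condition"])


class TestRmAnovaTwoWay:
    @staticmethod
    def _tidy2(cells):
        n, a, b = cells.shape
        rows = []
        for i in range(n):
            for x in range(a):
                for y in range(b):
                    rows.append(
                        {
                            "subject": f"s{i:02d}",
                            "dp": f"a{x}",
                            "load": f"b{y}",
                            "value": cells[i, x, y],
                        }
                    )
        return pd.DataFrame(rows)

    def test_matches_pingouin_two_way(self, rng):
        pg = pytest.importorskip("pingouin")
        cells = rng.standard_normal((12, 4, 2)) + rng.standard_normal((12, 1, 1))
        df = self._tidy2(cells)
        ours = stats.rm_anova(df, within=["dp", "load"])
        ref = pg.rm_anova(
            data=df, dv="value", within=["dp", "load"], subject="subject",
        ).set_index("Source")
        by_effect = {r.effect: r for r in ours}
        assert by_effect["dp"].F == pytest.approx(float(ref.loc["dp", "F"]), rel=1e-6)
        assert by_effect["load"].F == pytest.approx(
            float(ref.loc["load", "F"]), rel=1e-6
        )
        inter = [k for k in ref.index if "*" in k][0]
        assert by_effect["dp:load"].F == pytest.approx(
            float(ref.loc[inter, "F"]), rel=1e-6
        )
        assert by_effect["dp"].p == pytest.approx(
            float(ref.loc["dp", "p_unc"]), rel=1e-6
        )

    def test_dfs(self, rng):
        cells = rng.standard_normal((8, 3, 2))
        ours = {r.effect: r for r in stats.rm_anova(
            self._tidy2(cells), within=["dp", "load"]
        )}
        assert ours["dp"].df == (2, 14)
        assert ours["load"].df == (1, 7)
        assert ours["dp:load"].df == (2, 14)


class TestPosthoc:
    def test_holm_arithmetic(self):
        np.testing.assert_allclose(stats.holm([0.01, 0.04]), [0.02, 0.04])

    def test_holm_monotone_and_geq_raw(self, rng):
        for _ in range(30):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 10)))
            adj = stats.holm(p)
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_holm_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(2, 12)))
            np.testing.assert_allclose(
                stats.holm(p), sm.multipletests(p, method="holm")[1], atol=1e-12
            )

    def test_identical_conditions(self):
        data = np.tile(np.arange(6.0)[:, None], (1, 2))
        res = stats.posthoc_paired_t(_tidy(data))
        assert res[0].t == 0.0
        assert res[0].p_raw == 1.0

    def test_four_levels_six_pairs(self, rng):
        data = rng.standard_normal((6, 4))
        res = stats.posthoc_paired_t(_tidy(data))
        assert len(res) == 6
        assert {(r.level_a, r.level_b) for r in res} == {
            (f"l{i}", f"l{j}") for i, j in itertools.combinations(range(4), 2)
        }

    def test_raw_p_matches_scipy(self, rng):
        data = rng.standard_normal((8, 3))
        res = stats.posthoc_paired_t(_tidy(data))
        for r in res:
            i, j = int(r.level_a[1]), int(r.level_b[1])
            t, p = sps.ttest_rel(data[:, i], data[:, j])
            assert r.t == pytest.approx(float(t))
            assert r.p_raw == pytest.approx(float(p))


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(2, 40)))
            np.testing.assert_allclose(
                stats.benjamini_hochberg(p),
                sm.multipletests(p, method="fdr_bh")[1],
                atol=1e-12,
            )

    def test_q_geq_p(self, rng):
        p = rng.uniform(0, 1, size=30)
        assert np.all(stats.benjamini_hochberg(p) >= p - 1e-15)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0, 1, size=20)
        perm = rng.permutation(20)
        q = stats.benjamini_hochberg(p)
        q_perm = stats.benjamini_hochberg(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-15)


def _oracle_exact_perm_p(d):
    """Exhaustive sign-flip p for one channel, independent loop."""
    n = len(d)
    t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    count = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=n):
        flipped = d * np.array(signs)
        t = flipped.mean() / (flipped.std(ddof=1) / np.sqrt(n))
        total += 1
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    return count / total


class TestPermutationTopoTest:
    def test_identical_inputs_all_p_one(self, rng):
        A = rng.standard_normal((8, 5))
        res = stats.permutation_topo_test(A, A.copy(), n_perm=500, seed=0)
        np.testing.assert_allclose(res.p, 1.0)
        assert not res.significant.any()

    def test_exact_enumeration_matches_oracle(self, rng):
        for _ in range(5):
            d = rng.standard_normal(4) + 0.5
            res = stats.permutation_topo_test(
                d[:, None] + 1e-9, np.zeros((4, 1)), n_perm=1000, seed=0
            )
            assert res.exact and res.n_perm == 16
            assert res.p[0] == pytest.approx(_oracle_exact_perm_p(d + 1e-9))

    def test_shifted_channel_flagged(self, rng):
        A = rng.standard_normal((16, 6))
        B = rng.standard_normal((16, 6))
        A[:, 2] += 3.0  # large paired difference on one channel
        res = stats.permutation_topo_test(A, B, n_perm=999, seed=1)
        assert res.significant[2]
        assert res.q[2] < 0.05

    def test_q_geq_p_and_mask_definition(self, rng):
        A = rng.standard_normal((10, 8))
        B = rng.standard_normal((10, 8))
        res = stats.permutation_topo_test(A, B, n_perm=999, seed=2)
        assert np.all(res.q >= res.p - 1e-12)
        np.testing.assert_array_equal(res.significant, res.q < 0.05)

    def test_null_calibration_small(self, rng):
        flags = 0
        runs = 100
        for i in range(runs):
            A = rng.standard_normal((12, 10))
            B = rng.standard_normal((12, 10))
            res = stats.permutation_topo_test(A, B, n_perm=499, seed=i)
            flags += int(res.significant.any())
        # family-wise false positives bounded near alpha under the null
        assert flags / runs <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / runs)


def _oracle_rmcorr_ancova(subject, x, y):
    """ANCOVA decomposition: r^2 = SS_measure / (SS_measure + SS_error),
    sign from the common within-subject slope."""
    subject = np.asarray(subject)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    subs = np.unique(subject)
    xc = x.copy()
    yc = y.copy()
    for s in subs:
        m = subject == s
        xc[m] -= x[m].mean()
        yc[m] -= y[m].mean()
    slope = np.sum(xc * yc) / np.sum(xc**2)
    ss_measure = slope**2 * np.sum(xc**2)
    ss_error = np.sum((yc - slope * xc) ** 2)
    r = np.sign(slope) * np.sqrt(ss_measure / (ss_measure + ss_error))
    return r


class TestRmcorr:
    def test_perfect_within_subject_relation(self):
        subject = np.repeat(["a", "b", "c"], 4)
        x = np.tile(np.arange(4.0), 3)
        y = 2 * x + np.repeat([0.0, 10.0, -5.0], 4)
        res = stats.rmcorr(subject, x, y)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_df_balanced(self):
        subject = np.repeat(np.arange(10), 4)
        rng = np.random.default_rng(0)
        res = stats.rmcorr(subject, rng.normal(size=40), rng.normal(size=40))
        assert res.df == 10 * (4 - 1) - 1

    def test_matches_ancova_oracle(self, rng):
        for _ in range(50):
            n_sub = int(rng.integers(3, 8))
            k = int(rng.integers(2, 6))
            subject = np.repeat(np.arange(n_sub), k)
            x = rng.standard_normal(n_sub * k)
            y = rng.standard_normal(n_sub * k) + 0.5 * x
            res = stats.rmcorr(subject, x, y)
            assert res.r == pytest.approx(_oracle_rmcorr_ancova(subject, x, y), abs=1e-10)
            assert -1.0 <= res.r <= 1.0

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        subject = np.repeat(np.arange(8), 5)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40) + 0.4 * x
        df = pd.DataFrame({"subject": subject, "x": x, "y": y})
        ref = pg.rm_corr(data=df, x="x", y="y", subject="subject")
        res = stats.rmcorr(subject, x, y)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_null_r_small(self, rng):
        subject = np.repeat(np.arange(32), 4)
        res = stats.rmcorr(
            subject, rng.standard_normal(128), rng.standard_normal(128)
        )
        assert abs(res.r) < 0.3

    def test_zero_variance_error(self):
        subject = np.repeat(["a", "b"], 3)
        with pytest.raises(ValueError, match="variance"):
            stats.rmcorr(subject, np.ones(6), np.arange(6.0))

    def test_ci_contains_r(self, rng):
        subject = np.repeat(np.arange(6), 4)
        res = stats.rmcorr(
            subject, rng.standard_normal(24), rng.standard_normal(24)
        )
        assert res.ci95[0] <= res.r <= res.ci95[1]


def _oracle_sem(data):
    n, m = data.shape
    norm = np.empty_like(data)
    grand = data.mean()
    for i in range(n):
        for j in range(m):
            norm[i, j] = data[i, j] - data[i].mean() + grand
    sems = []
    for j in range(m):
        sems.append(np.std(norm[:, j], ddof=1) / np.sqrt(n) * np.sqrt(m / (m - 1)))
    return np.array(sems)


class TestWithinSubjectSem:
    def test_pure_offsets_zero_sem(self):
        profile = np.array([1.0, 3.0, 2.0])
        data = profile[None, :] + np.array([[0.0], [10.0], [-4.0], [7.0]])
        np.testing.assert_allclose(stats.within_subject_sem(data), 0.0, atol=1e-12)

    def test_two_condition_formula(self, rng):
        data = rng.standard_normal((12, 2))
        sem = stats.within_subject_sem(data)
        norm = data - data.mean(axis=1, keepdims=True) + data.mean()
        s = norm.std(axis=0, ddof=1)
        np.testing.assert_allclose(sem, s / np.sqrt(12) * np.sqrt(2.0))

    def test_matches_loop_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            m = int(rng.integers(2, 6))
            data = rng.standard_normal((n, m)) * 3 + rng.standard_normal((n, 1)) * 5
            np.testing.assert_allclose(
                stats.within_subject_sem(data), _oracle_sem(data), atol=1e-12
            )

    def test_single_condition_error(self):
        with pytest.raises(ValueError):
            stats.within_subject_sem(np.zeros((5, 1)))
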