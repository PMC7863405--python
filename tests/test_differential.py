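import numpy as np
import pytest
from scipy import stats

from spikewin.differential import (
    bh_adjust,
    build_design,
    classify_trend,
    cluster_windows,
    combine_simes,
    estimate_dispersions,
    fit_window_glms,
    simes_combine,
)
from spikewin.differential import test_windows as run_window_tests
from spikewin.synthetic_data import simulate_null_matrix

CONDS6 = ["solvent", "solvent", "t8", "t8", "t18", "t18"]


def _null_setup(n_windows=2000, phi=0.05, seed=0, mean=50):
    cm = simulate_null_matrix(n_windows, 6, nb_mean=mean, nb_dispersion=phi, seed=seed)
    design = build_design(cm.samples, CONDS6)
    off = np.log(cm.counts.sum(axis=0).astype(float))
    return cm, design, off


class TestGLMFit:
    def test_intercept_only_equals_sample_mean(self):
        """Poisson intercept-only fit with equal offsets reduces to the
        sample mean (GLM closed form)."""
        y = np.array([[3, 5, 7, 9], [0, 1, 2, 3]], dtype=np.int64)
        design = build_design(list("abcd"), ["x"] * 4, reference="x")
        off = np.zeros(4)
        fit = fit_window_glms(y, design, off, dispersion=0.0)
        np.testing.assert_allclose(fit.mu[0], np.full(4, 6.0), rtol=1e-6)
        np.testing.assert_allclose(fit.mu[1], np.full(4, 1.5), rtol=1e-6)

    def test_logfc_consistency_on_planted_fold(self):
        """A planted 4-fold difference at large counts is recovered as
        log2FC ~ 2."""
        rng = np.random.default_rng(0)
        mu = np.where(np.arange(8) < 4, 1000, 4000)
        y = rng.poisson(mu, size=(300, 8))
        design = build_design(
            [f"s{i}" for i in range(8)], ["solvent"] * 4 + ["t18"] * 4
        )
        fit = fit_window_glms(y, design, np.zeros(8), dispersion=0.0)
        logfc = fit.beta[:, design.condition_cols[0]] / np.log(2)
        assert np.mean(logfc) == pytest.approx(2.0, abs=0.01)
        assert np.std(logfc) < 0.1

    def test_matches_statsmodels_nb_glm(self):
        """Coefficients agree with an independent NB GLM fit at the same
        fixed dispersion."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        y = rng.negative_binomial(10, 10 / (10 + 60.0), size=(3, 6))
        design = build_design([f"s{i}" for i in range(6)], CONDS6)
        off = np.log(np.full(6, 100.0))
        phi = 0.1
        ours = fit_window_glms(y, design, off, dispersion=phi)
        for g in range(3):
            ref = sm.GLM(
                y[g], design.X, family=sm.families.NegativeBinomial(alpha=phi),
                offset=off,
            ).fit()
            np.testing.assert_allclose(ours.beta[g], ref.params, atol=1e-4)

    def test_all_zero_window_flagged(self):
        y = np.array([[0, 0, 0, 0, 0, 0]], dtype=np.int64)
        design = build_design([f"s{i}" for i in range(6)], CONDS6)
        fit = fit_window_glms(y, design, np.zeros(6))
        assert not fit.converged[0]

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            build_design(
                ["a", "b", "c", "d"],
                ["x", "x", "y", "y"],
                covariates=np.array([0.0, 0.0, 1.0, 1.0]),  # aliases condition
                reference="x",
            )


class TestDispersions:
    def test_recovery_and_null(self):
        cm, design, off = _null_setup(n_windows=3000, phi=0.1, seed=2)
        disp = estimate_dispersions(cm.counts, design, off)
        assert 0.07 <= np.median(disp.phi_raw) <= 0.13
        cm0, design0, off0 = _null_setup(n_windows=3000, phi=0.0, seed=2)
        disp0 = estimate_dispersions(cm0.counts, design0, off0)
        assert np.median(disp0.phi_raw) < 0.02

    def test_shrinkage_reduces_spread(self):
        cm, design, off = _null_setup(n_windows=2000, phi=0.05, seed=3)
        disp = estimate_dispersions(cm.counts, design, off)
        assert np.var(disp.s2_post) < np.var(disp.s2_raw)


class TestWindowTest:
    def test_null_calibration_and_uniformity(self):
        cm, design, off = _null_setup(n_windows=2000, phi=0.05, seed=4)
        disp = estimate_dispersions(cm.counts, design, off)
        wt = run_window_tests(cm.counts, design, off, disp)
        p = wt.pvalue[wt.tested]
        assert 0.03 <= np.mean(p < 0.05) <= 0.07
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_power_on_planted_threefold(self):
        """3-fold planted windows at mean ~50 are detected with power > 0.8
        at p < 0.05."""
        rng = np.random.default_rng(6)
        G = 400
        mu = np.tile([50.0] * 3 + [150.0] * 3, (G, 1))
        lam = rng.gamma(1 / 0.05, 0.05 * mu)
        y = rng.poisson(lam)
        null = simulate_null_matrix(1600, 6, nb_mean=50, nb_dispersion=0.05, seed=7).counts
        counts = np.vstack([y, null])
        design = build_design(
            [f"s{i}" for i in range(6)], ["solvent"] * 3 + ["t18"] * 3
        )
        off = np.zeros(6)
        disp = estimate_dispersions(counts, design, off)
        wt = run_window_tests(counts, design, off, disp)
        assert np.mean(wt.pvalue[:G] < 0.05) > 0.8

    def test_single_contrast_vector(self):
        cm, design, off = _null_setup(n_windows=500, phi=0.05, seed=8)
        disp = estimate_dispersions(cm.counts, design, off)
        c = np.zeros(design.X.shape[1])
        c[design.condition_cols[0]] = 1.0
        wt = run_window_tests(cm.counts, design, off, disp, contrast=c)
        assert wt.df_num == 1
        assert np.all((wt.pvalue >= 0) & (wt.pvalue <= 1))
        with pytest.raises(ValueError, match="contrast"):
            run_window_tests(cm.counts, design, off, disp, contrast=np.ones(2))


class TestSimes:
    def test_forced_examples(self):
        assert simes_combine(np.array([0.01, 0.02, 0.5])) == pytest.approx(0.03)
        assert simes_combine(np.array([0.2])) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            simes_combine(np.array([]))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 12))
            p = rng.uniform(size=m)
            srt = np.sort(p)
            oracle = min(1.0, min(len(p) * srt[i] / (i + 1) for i in range(m)))
            assert simes_combine(p) == pytest.approx(oracle, rel=1e-12)


class TestBH:
    def test_forced_examples(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))

    def test_matches_oracle_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 50)))
            q = bh_adjust(p)
            # brute-force step-up oracle
            m = len(p)
            order = np.argsort(p)
            oracle = np.empty(m)
            for rank, i in enumerate(order, start=1):
                oracle[i] = min(
                    min(1.0, m * p[j] / (list(order).index(j) + 1))
                    for j in order[rank - 1 :]
                )
            np.testing.assert_allclose(q, oracle, rtol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], rtol=1e-10
            )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestClustering:
    def test_overlap_chain(self):
        chroms = np.array(["c"] * 3, dtype=object)
        ids = cluster_windows(chroms, np.array([0, 50, 100]), np.array([150, 200, 250]))
        assert len(set(ids)) == 1

    def test_gap_splits(self):
        chroms = np.array(["c", "c"], dtype=object)
        ids = cluster_windows(chroms, np.array([0, 350]), np.array([150, 500]), max_gap=100)
        assert len(set(ids)) == 2
        ids2 = cluster_windows(chroms, np.array([0, 250]), np.array([150, 400]), max_gap=100)
        assert len(set(ids2)) == 1

    def test_max_width_split(self):
        n = 200
        starts = np.arange(n) * 50
        ends = starts + 150
        chroms = np.array(["c"] * n, dtype=object)
        ids = cluster_windows(chroms, starts, ends, max_width=5000)
        assert len(set(ids)) >= 2
        for cid in set(ids):
            sel = ids == cid
            assert ends[sel].max() - starts[sel].min() <= 5000

    def test_deterministic_and_contiguous(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.integers(0, 100_000, size=300))
        ends = starts + 150
        chroms = np.array(["c"] * 300, dtype=object)
        a = cluster_windows(chroms, starts, ends)
        b = cluster_windows(chroms, starts, ends)
        np.testing.assert_array_equal(a, b)
        # members of each cluster are a contiguous run in sorted order
        for cid in set(a):
            idx = np.flatnonzero(a == cid)
            assert np.all(np.diff(idx) == 1)


class TestTrendClassification:
    def _frame(self, q, f8, f18):
        import pandas as pd

        return pd.DataFrame(
            {"qvalue": q, "logfc_cond_t8": f8, "logfc_cond_t18": f18}
        )

    def test_rule_arithmetic(self):
        df = self._frame(
            [0.001, 0.001, 0.2, 0.001],
            [0.2, 0.1, 1.0, -0.3],
            [0.9, 0.5, 2.0, -0.9],
        )
        out = classify_trend(df)
        # 0.9 >= log2(1.5)=0.585 and q<0.05 and f8>=0 -> up
        # 0.5 < 0.585 -> none; q=0.2 -> none; mirrored negative -> down
        assert out["trend"].tolist() == ["up", "none", "none", "down"]

    def test_18h_only_mode(self):
        df = self._frame([0.001], [-0.2], [0.9])
        assert classify_trend(df)["trend"].tolist() == ["none"]
        assert classify_trend(df, require_same_sign_8h=False)["trend"].tolist() == ["up"]


class TestClusterCombination:
    def test_cluster_table_uses_simes_and_bh(self):
        cm, design, off = _null_setup(n_windows=300, phi=0.05, seed=9)
        disp = estimate_dispersions(cm.counts, design, off)
        wt = run_window_tests(cm.counts, design, off, disp)
        ids = cluster_windows(cm.chroms, cm.starts, cm.ends)
        table = combine_simes(wt, ids, cm.chroms, cm.starts, cm.ends)
        for _, row in table.iterrows():
            members = wt.pvalue[(ids == row.cluster_id) & wt.tested]
            assert row.pvalue == pytest.approx(simes_combine(members))
        np.testing.assert_allclose(
            table["qvalue"], bh_adjust(table["pvalue"].to_numpy())
        )
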