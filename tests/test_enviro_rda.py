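import numpy as np
import pandas as pd
import pytest

from haploscan import enviro_rda
from haploscan.enviro_rda import MISSING
from haploscan.gtio import GLDataset, RegionRecord


def _make_ds(gl, depth):
    S, N, _ = gl.shape
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, S + 1) * 100, "major": "A",
         "minor": "C"}
    )
    return GLDataset(sites=sites, individuals=[f"i{k}" for k in range(N)],
                     gl=gl, depth=np.asarray(depth))


class TestHardCall:
    def test_argmax_inside_depth_gate(self):
        gl = np.array([[[0.7, 0.2, 0.1]]])
        for depth, expect in [(3, 0), (1, MISSING), (6, MISSING)]:
            ds = _make_ds(gl, [[depth]])
            assert enviro_rda.hard_call(ds)[0, 0] == expect

    def test_tie_is_missing(self):
        gl = np.array([[[0.45, 0.45, 0.10]]])
        ds = _make_ds(gl, [[3]])
        assert enviro_rda.hard_call(ds)[0, 0] == MISSING

    def test_requires_depth_layer(self):
        gl = np.ones((1, 1, 3)) / 3
        ds = _make_ds(gl, [[1]])
        ds.depth = None
        with pytest.raises(ValueError, match="depth"):
            enviro_rda.hard_call(ds)


class TestFilterImpute:
    def test_mode_fill(self):
        G = np.array([[0], [0], [1], [MISSING]], dtype=np.int8)
        out, report = enviro_rda.filter_impute(G, min_maf=0.1, min_ind=0.5)
        assert out[3, 0] == 0
        assert report.missing_fraction == pytest.approx(0.25)

    def test_mode_tie_takes_lower_genotype(self):
        G = np.array([[0], [0], [2], [2], [MISSING]], dtype=np.int8)
        out, _r = enviro_rda.filter_impute(G, min_maf=0.1, min_ind=0.5)
        assert out[4, 0] == 0

    def test_call_rate_threshold(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(100, 2)).astype(np.int8)
        G[:15, 0] = MISSING  # 85% called < 90%
        out, report = enviro_rda.filter_impute(G, min_maf=0.0, min_ind=0.90)
        assert list(report.kept) == [1]

    def test_constructed_missingness_reported(self):
        rng = np.random.default_rng(1)
        n, m = 100, 400
        G = rng.binomial(2, 0.4, size=(n, m)).astype(np.int8)
        drop = rng.uniform(size=(n, m)) < 0.09
        G[drop] = MISSING
        out, report = enviro_rda.filter_impute(G, min_maf=0.05, min_ind=0.80)
        assert report.missing_fraction == pytest.approx(0.09, abs=0.005)
        assert not np.any(out == MISSING)

    def test_all_dropped_is_error(self):
        G = np.full((10, 3), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="dropped"):
            enviro_rda.filter_impute(G)


def _random_env(rng, n, p=3):
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"e{k}" for k in range(p)]
    )


class TestRdaFit:
    def test_perfect_fit(self):
        rng = np.random.default_rng(2)
        n, m, p = 30, 50, 3
        X = rng.normal(size=(n, p))
        B = rng.normal(size=(p, m))
        Y = X @ B
        env = pd.DataFrame(X, columns=list("abc"))
        fit = enviro_rda.rda_fit(Y, env)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_linear_algebra_oracle(self):
        rng = np.random.default_rng(3)
        n, m, p = 60, 500, 3
        G = rng.integers(0, 3, size=(n, m)).astype(float)
        env = _random_env(rng, n)
        fit = enviro_rda.rda_fit(G, env)
        # independent direct computation
        X = env.to_numpy()
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = G - G.mean(0)
        Yhat = X @ np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.max(np.abs(fit.fitted - Yhat)) <= 1e-8
        r2 = np.sum(Yhat**2) / np.sum(Y**2)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(
            1 - (1 - r2) * (n - 1) / (n - p - 1), abs=1e-10
        )
        d = np.linalg.svd(Yhat, compute_uv=False)[:p]
        assert np.allclose(fit.singular_values, d, atol=1e-8)
        # loadings span: projections of Yhat onto loadings reproduce Yhat
        recon = fit.scores @ fit.loadings.T
        assert np.max(np.abs(recon - Yhat)) <= 1e-8

    def test_null_adjusted_r2_centered_on_zero(self):
        rng = np.random.default_rng(4)
        n, m = 40, 80
        adjs = []
        for _ in range(200):
            G = rng.integers(0, 3, size=(n, m)).astype(float)
            fit = enviro_rda.rda_fit(G, _random_env(rng, n))
            adjs.append(fit.adj_r2)
        assert -0.05 <= np.mean(adjs) <= 0.05

    def test_collinear_env_rejected_naming_pair(self):
        rng = np.random.default_rng(5)
        n = 30
        x = rng.normal(size=n)
        env = pd.DataFrame(
            {"temp": x, "ph": 0.95 * x + 0.05 * rng.normal(size=n),
             "flow": rng.normal(size=n)}
        )
        G = rng.integers(0, 3, size=(n, 20)).astype(float)
        with pytest.raises(ValueError, match="temp.*ph"):
            enviro_rda.rda_fit(G, env)

    def test_env_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        n, m = 40, 60
        G = rng.integers(0, 3, size=(n, m)).astype(float)
        env = _random_env(rng, n)
        fit1 = enviro_rda.rda_fit(G, env)
        env2 = env.copy()
        env2["e0"] = env2["e0"] * 1000 + 7
        fit2 = enviro_rda.rda_fit(G, env2)
        assert fit1.adj_r2 == pytest.approx(fit2.adj_r2, abs=1e-12)
        assert np.allclose(fit1.fitted, fit2.fitted, atol=1e-9)


class TestRdaSignificance:
    def test_perfect_fit_attains_minimum_p(self):
        rng = np.random.default_rng(7)
        n, m, p = 30, 40, 3
        X = rng.normal(size=(n, p))
        Y = X @ rng.normal(size=(p, m))
        fit = enviro_rda.rda_fit(Y, pd.DataFrame(X, columns=list("abc")))
        sig = enviro_rda.rda_significance(fit, n_perm=99, seed=0)
        assert sig["overall"] == pytest.approx(1 / 100)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        G = rng.integers(0, 3, size=(30, 40)).astype(float)
        fit = enviro_rda.rda_fit(G, _random_env(rng, 30))
        s1 = enviro_rda.rda_significance(fit, n_perm=199, seed=5)
        s2 = enviro_rda.rda_significance(fit, n_perm=199, seed=5)
        assert s1["overall"] == s2["overall"]
        assert np.array_equal(s1["axes"], s2["axes"])

    def test_null_pvalues_approximately_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(9)
        n, m = 30, 30
        pvals = []
        for r in range(120):
            G = rng.integers(0, 3, size=(n, m)).astype(float)
            fit = enviro_rda.rda_fit(G, _random_env(rng, n))
            pvals.append(
                enviro_rda.rda_significance(fit, n_perm=99, seed=r,
                                            axes=False)["overall"]
            )
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestRdaOutliers:
    def _fit_with_loadings(self, loadings):
        m, k = loadings.shape
        return enviro_rda.RdaFit(
            Y=np.zeros((5, m)), X=np.zeros((5, k)), fitted=np.zeros((5, m)),
            singular_values=np.ones(k), loadings=loadings,
            scores=np.zeros((5, k)), r2=0.5, adj_r2=0.4,
            axis_proportion=np.ones(k) / k, env_names=list("abc")[:k],
            coef=np.zeros((k, m)),
        )

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(10)
        load = rng.normal(0, 1, size=(500, 1))
        load[123, 0] = 10.0
        fit = self._fit_with_loadings(load)
        table, _pb = enviro_rda.rda_outliers(fit, np.arange(500))
        assert 123 in set(table["snp_index"])
        # only the expected ~0.3% two-sided tail besides the plant
        assert len(table) <= 1 + int(0.01 * 500)

    def test_degenerate_equal_loadings_flag_nothing(self):
        fit = self._fit_with_loadings(np.full((100, 2), 0.3))
        table, _pb = enviro_rda.rda_outliers(fit, np.arange(100))
        assert len(table) == 0

    def test_counts_nonincreasing_in_k_sd(self):
        rng = np.random.default_rng(11)
        load = rng.standard_t(df=3, size=(800, 3))
        fit = self._fit_with_loadings(load)
        pos = np.arange(800) * 1000
        blocks = [RegionRecord("chr1", 0, 400_000, "b1")]
        counts = []
        for k_sd in (2.0, 2.5, 3.0, 4.0):
            _t, pb = enviro_rda.rda_outliers(
                fit, pos, np.full(800, "chr1", dtype=object), k_sd=k_sd,
                blocks=blocks,
            )
            counts.append(pb["b1"])
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_env_annotation_picks_strongest_correlate(self):
        rng = np.random.default_rng(12)
        n, m = 60, 40
        env = _random_env(rng, n)
        G = rng.integers(0, 3, size=(n, m)).astype(float)
        G[:, 7] = 2 * (env["e1"] > 0)  # strongly coupled to e1
        fit = enviro_rda.rda_fit(G, env)
        table, _pb = enviro_rda.rda_outliers(
            fit, np.arange(m), G=G, env=env
        )
        if 7 in set(table["snp_index"]):
            row = table.set_index("snp_index").loc[7]
            assert row["env_variable"] == "e1"


class TestPowerSimulation:
    def test_env_associated_snps_recovered(self):
        # SNPs coupled to an environmental gradient with per-SNP r^2 >= 0.15
        # are flagged at >= 80% power by the 3-SD loading rule
        rng = np.random.default_rng(13)
        n, m, n_true = 80, 400, 10
        powers = []
        for _rep in range(4):
            env = _random_env(rng, n)
            G = rng.integers(0, 3, size=(n, m)).astype(float)
            grad = env["e0"].to_numpy()
            grad = (grad - grad.mean()) / grad.std()
            p = np.clip(0.5 + 0.22 * grad, 0.02, 0.98)
            for j in range(n_true):
                G[:, j] = rng.binomial(2, p)
            fit = enviro_rda.rda_fit(G, env)
            table, _pb = enviro_rda.rda_outliers(fit, np.arange(m), G=G, env=env)
            flagged = set(table["snp_index"])
            powers.append(len(flagged & set(range(n_true))) / n_true)
        assert np.mean(powers) >= 0.8
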