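"""GLS with phylogenetic covariance: estimation, dredging, averaging."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.stats import multivariate_normal

from ecodensity import pgls, phylo
from ecodensity.pgls import ModelSpec, Term, PGLSFit
from ecodensity.synth import yule_tree


def make_data(n, p, rng, beta=None, V=None, sigma=1.0):
    idx = pd.Index([f"s{i:02d}" for i in range(n)], name="species")
    X = rng.normal(size=(n, p))
    beta = np.zeros(p + 1) if beta is None else np.asarray(beta, dtype=float)
    mu = beta[0] + X @ beta[1:]
    if V is None:
        eps = rng.normal(size=n) * sigma
        Vdf = pd.DataFrame(np.eye(n), index=idx, columns=idx)
    else:
        L = np.linalg.cholesky(V)
        eps = L @ rng.normal(size=n) * sigma
        Vdf = pd.DataFrame(V, index=idx, columns=idx)
    data = pd.DataFrame(X, index=idx, columns=[f"x{i}" for i in range(p)])
    data["y"] = mu + eps
    return data, Vdf


def random_spd_vcv(n, rng):
    """Random Brownian-like covariance from a random ultrametric tree."""
    tree = yule_tree(n, 1.0, rng)
    labels = sorted(f"sp{i}" for i in range(1, n + 1))
    V = phylo.brownian_vcv(tree, labels).to_numpy()
    return V + 1e-8 * np.eye(n)


def whitening_oracle(y, X, V):
    """Eigendecomposition whitening + OLS; returns beta and ML log-lik."""
    w, U = np.linalg.eigh(V)
    W = U @ np.diag(w**-0.5) @ U.T  # V^(-1/2)
    yw, Xw = W @ y, W @ X
    beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
    resid = yw - Xw @ beta
    n = len(y)
    sigma2 = resid @ resid / n
    loglik = -0.5 * (
        n * math.log(2 * math.pi * sigma2) + np.linalg.slogdet(V)[1] + n
    )
    return beta, loglik, sigma2


def spec_for(p, response="y"):
    return ModelSpec(response, tuple(Term.single(f"x{i}") for i in range(p)))


class TestFitPGLS:
    def test_identity_vcv_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        data, V = make_data(25, 2, rng, beta=[1.0, 0.5, -0.2])
        fit = pgls.fit_pgls(spec_for(2), data, V)
        ols = sm.OLS(data["y"], sm.add_constant(data[["x0", "x1"]])).fit()
        assert np.allclose(fit.params, ols.params, atol=1e-12)
        assert np.allclose(fit.bse, ols.bse, atol=1e-12)
        assert np.allclose(fit.tvalues, ols.tvalues, atol=1e-10)
        assert np.allclose(fit.pvalues, ols.pvalues, atol=1e-12)
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-10)

    def test_exact_linear_response_recovered(self):
        rng = np.random.default_rng(2)
        data, V = make_data(15, 2, rng, beta=[2.0, 1.0, -3.0], sigma=0.0)
        fit = pgls.fit_pgls(spec_for(2), data, V)
        assert np.allclose(fit.params, [2.0, 1.0, -3.0], atol=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_matches_whitening_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for i in range(100):
            n = int(rng.integers(6, 13))
            p = int(rng.integers(1, min(3, n - 3) + 1))
            V = random_spd_vcv(n, rng)
            data, Vdf = make_data(n, p, rng, V=V)
            fit = pgls.fit_pgls(spec_for(p), data, Vdf)
            X = np.column_stack([np.ones(n), data[[f"x{i}" for i in range(p)]]])
            beta, loglik, _ = whitening_oracle(data["y"].to_numpy(), X, V)
            assert np.allclose(fit.params, beta, atol=1e-8)
            assert fit.loglik == pytest.approx(loglik, abs=1e-8)

    def test_loglik_is_gaussian_density_at_mle(self):
        """Independent check: logLik equals the multivariate normal logpdf
        of y at (X beta_hat, sigma2_hat V)."""
        rng = np.random.default_rng(4)
        V = random_spd_vcv(10, rng)
        data, Vdf = make_data(10, 2, rng, V=V)
        fit = pgls.fit_pgls(spec_for(2), data, Vdf)
        X = np.column_stack([np.ones(10), data[["x0", "x1"]]])
        mu = X @ fit.params.to_numpy()
        ref = multivariate_normal.logpdf(
            data["y"].to_numpy(), mean=mu, cov=fit.sigma2 * V
        )
        assert fit.loglik == pytest.approx(ref, abs=1e-8)

    def test_statsmodels_gls_agreement(self):
        rng = np.random.default_rng(5)
        V = random_spd_vcv(12, rng)
        data, Vdf = make_data(12, 1, rng, V=V)
        fit = pgls.fit_pgls(spec_for(1), data, Vdf)
        gls = sm.GLS(
            data["y"], sm.add_constant(data["x0"]), sigma=V
        ).fit()
        assert np.allclose(fit.params, gls.params, atol=1e-10)
        assert np.allclose(fit.bse, gls.bse, atol=1e-10)

    def test_aic_identity_and_k(self):
        rng = np.random.default_rng(6)
        data, V = make_data(20, 2, rng)
        fit = pgls.fit_pgls(spec_for(2), data, V)
        assert fit.k == 4  # 3 betas + sigma2
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        V = random_spd_vcv(12, rng)
        data, Vdf = make_data(12, 2, rng, V=V)
        fit = pgls.fit_pgls(spec_for(2), data, Vdf)
        perm = rng.permutation(data.index)
        fit_p = pgls.fit_pgls(spec_for(2), data.loc[perm], Vdf)
        assert np.allclose(fit.params, fit_p.params, atol=1e-10)
        assert fit.loglik == pytest.approx(fit_p.loglik, abs=1e-10)

    def test_star_phylogeny_equals_ols(self):
        import dendropy

        tree = dendropy.Tree.get(
            data="(" + ",".join(f"s{i:02d}:2.5" for i in range(14)) + ");",
            schema="newick",
        )
        rng = np.random.default_rng(8)
        data, _ = make_data(14, 2, rng, beta=[0.5, 1.0, 0.0])
        V = phylo.brownian_vcv(tree, list(data.index))
        fit = pgls.fit_pgls(spec_for(2), data, V)
        ols = sm.OLS(data["y"], sm.add_constant(data[["x0", "x1"]])).fit()
        assert np.allclose(fit.params, ols.params, atol=1e-10)
        assert np.allclose(fit.bse, ols.bse, atol=1e-10)

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(9)
        data, V = make_data(15, 2, rng)
        data["x1"] = 2.0 * data["x0"]
        with pytest.raises(ValueError, match="x1|x0"):
            pgls.fit_pgls(spec_for(2), data, V)

    def test_non_psd_vcv_rejected(self):
        rng = np.random.default_rng(10)
        data, V = make_data(8, 1, rng)
        V.iloc[:, :] = -np.eye(8)
        with pytest.raises(ValueError, match="positive definite"):
            pgls.fit_pgls(spec_for(1), data, V)

    def test_nesting_never_decreases_loglik(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            V = random_spd_vcv(12, rng)
            data, Vdf = make_data(12, 3, rng, V=V, beta=[1, 0.5, 0, 0])
            small = pgls.fit_pgls(spec_for(2), data, Vdf)
            big = pgls.fit_pgls(spec_for(3), data, Vdf)
            assert big.loglik >= small.loglik - 1e-9

    def test_reml_identity_vcv_matches_ols_sigma2(self):
        rng = np.random.default_rng(12)
        data, V = make_data(20, 2, rng)
        fit = pgls.fit_pgls(spec_for(2), data, V, method="REML")
        ols = sm.OLS(data["y"], sm.add_constant(data[["x0", "x1"]])).fit()
        assert fit.sigma2 == pytest.approx(ols.mse_resid)
        assert np.allclose(fit.params, ols.params, atol=1e-12)


class TestCalibration:
    def test_ci_coverage_under_generating_model(self):
        """95% CIs cover the true slope ~95% of the time when data are
        simulated under the fitted model."""
        rng = np.random.default_rng(13)
        n, beta1 = 25, 0.7
        V = random_spd_vcv(n, rng)
        L = np.linalg.cholesky(V)
        idx = [f"s{i:02d}" for i in range(n)]
        Vdf = pd.DataFrame(V, index=idx, columns=idx)
        x = rng.normal(size=n)
        covered = 0
        n_rep = 400
        for _ in range(n_rep):
            y = 1.0 + beta1 * x + L @ rng.normal(size=n)
            data = pd.DataFrame({"x0": x, "y": y}, index=idx)
            fit = pgls.fit_pgls(spec_for(1), data, Vdf)
            tcrit = stats.t.ppf(0.975, fit.df_resid)
            lo = fit.params["x0"] - tcrit * fit.bse["x0"]
            hi = fit.params["x0"] + tcrit * fit.bse["x0"]
            covered += lo <= beta1 <= hi
        assert 0.92 <= covered / n_rep <= 0.975

    def test_type_one_error_under_model_null(self):
        """Slope test rejects ~5% when the response is pure Brownian noise."""
        rng = np.random.default_rng(14)
        n = 30
        V = random_spd_vcv(n, rng)
        L = np.linalg.cholesky(V)
        idx = [f"s{i:02d}" for i in range(n)]
        Vdf = pd.DataFrame(V, index=idx, columns=idx)
        x = rng.normal(size=n)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            y = L @ rng.normal(size=n)
            data = pd.DataFrame({"x0": x, "y": y}, index=idx)
            fit = pgls.fit_pgls(spec_for(1), data, Vdf)
            rejections += fit.pvalues["x0"] < 0.05
        rate = rejections / n_rep
        assert 0.05 - 2.5 * math.sqrt(0.05 * 0.95 / n_rep) <= rate \
            <= 0.05 + 2.5 * math.sqrt(0.05 * 0.95 / n_rep)


@pytest.fixture(scope="module")
def dredged():
    rng = np.random.default_rng(15)
    V = random_spd_vcv(40, rng)
    data, Vdf = make_data(40, 5, rng, V=V, beta=[1, 0.8, 0, 0.3, 0, 0])
    spec = spec_for(5)
    return spec, data, Vdf, pgls.dredge(spec, data, Vdf)


class TestDredge:
    def test_all_subsets_fitted(self, dredged):
        _, _, _, fits = dredged
        assert len(fits) == 32  # 2^5
        assert len({f.term_names for f in fits}) == 32

    def test_sorted_with_best_delta_zero(self, dredged):
        _, _, _, fits = dredged
        aics = [f.aic for f in fits]
        assert aics == sorted(aics)
        assert fits[0].aic - min(aics) == 0.0

    def test_each_subset_matches_direct_refit(self, dredged):
        spec, data, Vdf, fits = dredged
        for fit in fits[:8]:
            terms = tuple(Term.single(nm) for nm in fit.term_names)
            direct = pgls.fit_pgls(ModelSpec("y", terms), data, Vdf)
            assert fit.aic == pytest.approx(direct.aic, abs=1e-9)
            assert np.allclose(fit.params, direct.params, atol=1e-9)

    def test_combinatorial_guard(self):
        spec = spec_for(21)
        with pytest.raises(ValueError, match="refus"):
            pgls.dredge(spec, pd.DataFrame(), pd.DataFrame())


def make_fit(term_names, params, bse, aic, n=20, response="y"):
    names = list(params.keys())
    p = len(names)
    return PGLSFit(
        response=response,
        term_names=tuple(term_names),
        params=pd.Series(params),
        bse=pd.Series(bse),
        tvalues=pd.Series(0.0, index=names),
        pvalues=pd.Series(1.0, index=names),
        sigma2=1.0,
        loglik=-(aic - 2 * (p + 1)) / 2,
        aic=aic,
        n=n,
        k=p + 1,
        df_resid=n - p,
    )


def averaging_oracle(fits, delta_cut=2.0):
    """Independent implementation of full averaging (plain loops)."""
    best = min(f.aic for f in fits)
    kept = [f for f in fits if f.aic - best < delta_cut]
    w = [math.exp(-(f.aic - best) / 2) for f in kept]
    w = [x / sum(w) for x in w]
    names = []
    for f in fits:
        for nm in f.params.index:
            if nm not in names:
                names.append(nm)
    out = {}
    for nm in names:
        betas = [float(f.params.get(nm, 0.0)) for f in kept]
        ses = [float(f.bse.get(nm, 0.0)) for f in kept]
        bbar = sum(wi * bi for wi, bi in zip(w, betas))
        se = sum(
            wi * math.sqrt(si**2 + (bi - bbar) ** 2)
            for wi, bi, si in zip(w, betas, ses)
        )
        out[nm] = (bbar, se)
    return out


class TestAveraging:
    def test_single_retained_model_passthrough(self):
        f1 = make_fit(["x0"], {"(Intercept)": 1.0, "x0": 2.0},
                      {"(Intercept)": 0.1, "x0": 0.2}, aic=10.0)
        f2 = make_fit([], {"(Intercept)": 1.5}, {"(Intercept)": 0.1}, aic=20.0)
        avg = pgls.select_and_average([f1, f2])
        assert avg.coef.loc["x0", "estimate"] == pytest.approx(2.0)
        assert avg.coef.loc["x0", "se"] == pytest.approx(0.2)
        assert avg.models["retained"].sum() == 1

    def test_two_equal_models_hand_example(self):
        """Equal AIC, term with betas 1 and 3 and zero SEs: average 2, SE 1."""
        f1 = make_fit(["x0"], {"(Intercept)": 0.0, "x0": 1.0},
                      {"(Intercept)": 0.0, "x0": 0.0}, aic=10.0)
        f2 = make_fit(["x0"], {"(Intercept)": 0.0, "x0": 3.0},
                      {"(Intercept)": 0.0, "x0": 0.0}, aic=10.0)
        avg = pgls.select_and_average([f1, f2])
        assert avg.coef.loc["x0", "estimate"] == pytest.approx(2.0)
        assert avg.coef.loc["x0", "se"] == pytest.approx(1.0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(16)
        V = random_spd_vcv(30, rng)
        data, Vdf = make_data(30, 3, rng, V=V)
        avg = pgls.select_and_average(pgls.dredge(spec_for(3), data, Vdf))
        w = avg.models.loc[avg.models["retained"], "weight"]
        assert w.sum() == pytest.approx(1.0)

    def test_matches_independent_implementation_on_random_fit_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            fits = []
            n_terms = int(rng.integers(1, 4))
            terms = [f"x{i}" for i in range(n_terms)]
            for mask in range(2**n_terms):
                sub = [t for i, t in enumerate(terms) if mask >> i & 1]
                params = {"(Intercept)": float(rng.normal())}
                bse = {"(Intercept)": float(rng.uniform(0.05, 1))}
                for t in sub:
                    params[t] = float(rng.normal())
                    bse[t] = float(rng.uniform(0.05, 1))
                fits.append(make_fit(sub, params, bse, aic=float(rng.uniform(0, 6))))
            avg = pgls.select_and_average(fits)
            oracle = averaging_oracle(fits)
            for nm, (bbar, se) in oracle.items():
                assert avg.coef.loc[nm, "estimate"] == pytest.approx(bbar, abs=1e-10)
                assert avg.coef.loc[nm, "se"] == pytest.approx(se, abs=1e-10)

    def test_adjusted_se_shrinks_to_se_at_large_df(self):
        f = make_fit(["x0"], {"(Intercept)": 1.0, "x0": 2.0},
                     {"(Intercept)": 0.1, "x0": 0.2}, aic=10.0, n=5000)
        avg = pgls.select_and_average([f])
        assert avg.coef.loc["x0", "adjusted_se"] == pytest.approx(0.2, rel=1e-3)
        assert avg.coef.loc["x0", "adjusted_se"] >= avg.coef.loc["x0", "se"]


class TestDredgeOverTrees:
    def test_identical_trees_zero_spread_and_full_agreement(self):
        rng = np.random.default_rng(18)
        tree = yule_tree(20, 1.0, rng)
        labels = sorted(f"sp{i}" for i in range(1, 21))
        V = phylo.brownian_vcv(tree, labels)
        idx = pd.Index(labels, name="species")
        L = np.linalg.cholesky(V.to_numpy())
        x = rng.normal(size=20)
        data = pd.DataFrame({"x0": x}, index=idx)
        data["y"] = 1.0 + 2.0 * x + 0.3 * (L @ rng.normal(size=20))
        spec = spec_for(1)
        report = pgls.dredge_over_trees(spec, data, [tree, tree, tree])
        assert list(report.index) == ["(Intercept)", "x0"]
        assert report["sd"].max() == pytest.approx(0.0, abs=1e-12)
        assert report.loc["x0", "sign_agreement"] == 1.0
        assert report.loc["x0", "mean"] == pytest.approx(
            report.loc["x0", "consensus_estimate"]
        )
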