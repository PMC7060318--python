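"""ORM algebra, REML against a brute-force likelihood oracle, and BLUP."""

import numpy as np
import pandas as pd
import pytest

import methwas as mw
from methwas.mixed_model import blup_probe_effects, compute_orm, reml, reml_fit
from conftest import prepared_cohort


def reml_loglik_oracle(y, X, V):
    """Independent textbook evaluation of the restricted log-likelihood
    (up to the constant), via explicit inverses and determinants."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return -0.5 * (ld_v + ld_x + y @ P @ y)


class TestORM:
    def test_single_probe_orm_is_outer_product(self):
        w = np.array([[-1.224744871], [0.0], [1.224744871]])
        W = mw.StandardizedMethylation(values=w, sample_ids=pd.Index(list("abc")),
                                       probe_ids=pd.Index(["p0"]),
                                       means=np.zeros(1), sds=np.ones(1))
        A = compute_orm(W).A
        assert np.allclose(A, np.outer(w[:, 0], w[:, 0]))

    def test_diagonal_mean_is_one(self, small_cohort):
        *_, W = small_cohort
        A = compute_orm(W).A
        assert np.mean(np.diag(A)) == pytest.approx(1.0, abs=1e-8)

    def test_duplicating_probes_leaves_orm_unchanged(self, small_cohort):
        *_, W = small_cohort
        A1 = compute_orm(W).A
        W2 = mw.StandardizedMethylation(
            values=np.hstack([W.values, W.values]),
            sample_ids=W.sample_ids,
            probe_ids=W.probe_ids.append(W.probe_ids.map(lambda s: s + "_dup")),
            means=np.tile(W.means, 2), sds=np.tile(W.sds, 2))
        assert np.allclose(A1, compute_orm(W2).A, atol=1e-12)

    def test_empty_orm_rejected(self):
        W = mw.StandardizedMethylation(values=np.empty((3, 0)),
                                       sample_ids=pd.Index(list("abc")),
                                       probe_ids=pd.Index([]),
                                       means=np.empty(0), sds=np.empty(0))
        with pytest.raises(ValueError):
            compute_orm(W)


class TestREML:
    @pytest.fixture(scope="class")
    @staticmethod
    def toy():
        rng = np.random.default_rng(0)
        n = 8
        G = rng.normal(size=(n, 4))
        A = G @ G.T / 4
        A /= np.mean(np.diag(A))
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        return y, X, A

    def test_loglik_matches_grid_search_oracle(self, toy):
        y, X, A = toy
        n = len(y)
        fit = reml(y, X, [A, np.eye(n)])
        at_optimum = reml_loglik_oracle(y, X, fit.sigmas[0] * A
                                        + fit.sigmas[1] * np.eye(n))
        assert fit.loglik == pytest.approx(at_optimum, abs=1e-6)
        grid = np.linspace(0.01, 3.0, 40)
        best = max(reml_loglik_oracle(y, X, so * A + se * np.eye(n))
                   for so in grid for se in grid)
        assert fit.loglik >= best - 1e-6

    def test_em_iterations_do_not_decrease_loglik(self, toy):
        from methwas.mixed_model import REMLError
        y, X, A = toy
        try:
            fit = reml(y, X, [A, np.eye(len(y))], method="em", tol=0.0,
                       max_iter=80)
            lls = [h["loglik"] for h in fit.history]
        except REMLError as err:     # boundary creep: property still holds
            lls = [h["loglik"] for h in err.history]
        assert len(lls) >= 50
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_null_phenotype_gives_rho2_near_zero(self, null_cohort):
        _, design, _, _, W = null_cohort
        fit = reml_fit(design, compute_orm(W))
        assert abs(fit.rho2) < 2 * max(fit.se_rho2, 1e-3)
        assert fit.p_rho2 > 0.01

    def test_rho2_invariant_to_rescaling_W(self, small_cohort):
        _, design, _, _, W = small_cohort
        f1 = reml_fit(design, compute_orm(W), lrt=False)
        W2 = mw.StandardizedMethylation(values=3.0 * W.values,
                                        sample_ids=W.sample_ids,
                                        probe_ids=W.probe_ids,
                                        means=W.means, sds=W.sds)
        f2 = reml_fit(design, compute_orm(W2), lrt=False)
        assert f1.rho2 == pytest.approx(f2.rho2, abs=1e-4)

    def test_interval_coverage_on_model_simulated_data(self):
        # y drawn directly from N(0, sigma_o A + sigma_e I): the 95% interval
        # for rho2 should cover the truth about 95% of the time
        rng = np.random.default_rng(1)
        n, m, so, se = 80, 60, 0.4, 0.6
        rho_true = so / (so + se)
        covered = 0
        reps = 100
        G = rng.normal(size=(n, m))
        G = (G - G.mean(0)) / G.std(0)
        A = G @ G.T / m
        L = np.linalg.cholesky(so * A + se * np.eye(n) + 1e-10 * np.eye(n))
        X = np.ones((n, 1))
        cov_df = pd.DataFrame(index=range(n))
        for _ in range(reps):
            y = L @ rng.normal(size=n)
            fit = reml(y, X, [A, np.eye(n)])
            s = fit.sigmas
            rho = s[0] / (s[0] + s[1])
            g = np.array([s[1], -s[0]]) / (s[0] + s[1]) ** 2
            se_rho = np.sqrt(max(g @ fit.cov_sigmas @ g, 0))
            covered += abs(rho - rho_true) < 1.96 * se_rho
        assert 0.86 <= covered / reps <= 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= p"):
            reml(np.zeros(3), np.ones((3, 2)), [np.eye(3)])


class TestBLUP:
    def test_zero_methylomic_variance_gives_zero_effects(self, small_cohort):
        _, design, _, _, W = small_cohort
        var = mw.VarianceEstimate(sigma_o=0.0, sigma_e=0.25, rho2=0.0,
                                  se_sigma_o=0, se_sigma_e=0, se_rho2=0,
                                  loglik=0, n_iter=1, converged=True,
                                  clamped=False)
        blup = blup_probe_effects(design, W, var)
        assert np.allclose(blup.u.to_numpy(), 0.0)

    def test_single_probe_matches_scalar_formula(self):
        rng = np.random.default_rng(4)
        n = 10
        w = rng.normal(size=n)
        w = (w - w.mean()) / w.std()
        y = 0.3 * w + rng.normal(size=n) * 0.5
        y = (y > np.median(y)).astype(float)
        design = mw.CohortDesign(y=y, covariates=pd.DataFrame(index=range(n)),
                                 sample_ids=pd.Index(range(n)))
        W = mw.StandardizedMethylation(values=w[:, None],
                                       sample_ids=pd.Index(range(n)),
                                       probe_ids=pd.Index(["p0"]),
                                       means=np.zeros(1), sds=np.ones(1))
        so, se = 0.2, 0.8
        var = mw.VarianceEstimate(sigma_o=so, sigma_e=se, rho2=so / (so + se),
                                  se_sigma_o=0, se_sigma_e=0, se_rho2=0,
                                  loglik=0, n_iter=1, converged=True,
                                  clamped=False)
        blup = blup_probe_effects(design, W, var)
        V = so * np.outer(w, w) + se * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        expected = so * (w @ (Vi @ (y - X @ beta)))
        assert blup.u.iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_blup_solves_mixed_model_equations(self):
        # MME identity on n=10, m=6: [X'X  X'W; W'X  W'W + I*se/su] solves
        # the same u_hat as the V-inverse closed form
        rng = np.random.default_rng(6)
        n, m = 10, 6
        Wv = rng.normal(size=(n, m))
        Wv = (Wv - Wv.mean(0)) / Wv.std(0)
        y = (rng.normal(size=n) > 0).astype(float)
        design = mw.CohortDesign(y=y, covariates=pd.DataFrame(index=range(n)),
                                 sample_ids=pd.Index(range(n)))
        W = mw.StandardizedMethylation(values=Wv, sample_ids=pd.Index(range(n)),
                                       probe_ids=pd.Index([f"p{i}" for i in range(m)]),
                                       means=np.zeros(m), sds=np.ones(m))
        so, se = 0.3, 0.7
        var = mw.VarianceEstimate(sigma_o=so, sigma_e=se, rho2=so / (so + se),
                                  se_sigma_o=0, se_sigma_e=0, se_rho2=0,
                                  loglik=0, n_iter=1, converged=True,
                                  clamped=False)
        u_hat = blup_probe_effects(design, W, var).u.to_numpy()
        su = so / m
        X = np.ones((n, 1))
        top = np.hstack([X.T @ X, X.T @ Wv])
        bottom = np.hstack([Wv.T @ X, Wv.T @ Wv + np.eye(m) * se / su])
        sol = np.linalg.solve(np.vstack([top, bottom]),
                              np.concatenate([X.T @ y, Wv.T @ y]))
        assert np.allclose(u_hat, sol[1:], atol=1e-8)

    def test_unconverged_fit_rejected(self, small_cohort):
        _, design, _, _, W = small_cohort
        var = mw.VarianceEstimate(sigma_o=0.1, sigma_e=0.1, rho2=0.5,
                                  se_sigma_o=0, se_sigma_e=0, se_rho2=0,
                                  loglik=0, n_iter=1, converged=False,
                                  clamped=False)
        with pytest.raises(ValueError, match="converge"):
            blup_probe_effects(design, W, var)
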