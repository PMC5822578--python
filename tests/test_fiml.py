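"""FIML engine: pattern likelihood, estimation, references, standardization."""

import copy

import numpy as np
import pandas as pd
import pytest

from hippolcs import (
    build_model_spec,
    default_calibration,
    fit_baseline,
    fit_saturated,
    generate_cohort,
    generating_parameters,
    residualize_table,
)
from hippolcs import fiml
from hippolcs.fiml import compute_patterns, fiml_loglik, loglik_moments

from conftest import small_spec


def closed_form_loglik(Y, mu, Sigma):
    """Independent oracle: complete-data Gaussian log-likelihood via the
    textbook sufficient-statistics formula."""
    n, p = Y.shape
    xbar = Y.mean(axis=0)
    S = (Y - xbar).T @ (Y - xbar) / n
    Sinv = np.linalg.inv(Sigma)
    d = xbar - mu
    _, logdet = np.linalg.slogdet(Sigma)
    return -0.5 * n * (
        p * np.log(2 * np.pi) + logdet + np.trace(S @ Sinv) + d @ Sinv @ d
    )


class TestPatternLikelihood:
    def test_standard_normal_single_point(self):
        pat = compute_patterns(np.array([[0.0]]))
        ll = loglik_moments(np.array([0.0]), np.array([[1.0]]), pat)
        assert np.isclose(ll, -0.5 * np.log(2 * np.pi))  # -0.91894

    def test_complete_data_equals_closed_form(self, rng):
        n, p = 60, 5
        A = rng.normal(size=(p, p))
        Sigma = A @ A.T + p * np.eye(p)
        mu = rng.normal(size=p)
        Y = rng.multivariate_normal(mu, Sigma, size=n)
        pat = compute_patterns(Y)
        ll = loglik_moments(mu + 0.1, Sigma * 1.2, pat)
        oracle = closed_form_loglik(Y, mu + 0.1, Sigma * 1.2)
        assert np.isclose(ll, oracle, atol=1e-8)

    def test_all_missing_row_contributes_zero(self, rng):
        Y = rng.normal(size=(10, 3))
        Yx = np.vstack([Y, np.full((1, 3), np.nan)])
        mu, Sigma = np.zeros(3), np.eye(3)
        assert np.isclose(
            loglik_moments(mu, Sigma, compute_patterns(Y)),
            loglik_moments(mu, Sigma, compute_patterns(Yx)),
        )
        assert compute_patterns(Yx).n_dropped == 1

    def test_row_order_invariance(self, rng):
        Y = rng.normal(size=(50, 4))
        Y[rng.random((50, 4)) < 0.3] = np.nan
        mu, Sigma = np.zeros(4), np.eye(4) * 2
        lls = []
        for _ in range(3):
            perm = rng.permutation(50)
            lls.append(loglik_moments(mu, Sigma, compute_patterns(Y[perm])))
        assert np.allclose(lls, lls[0])

    def test_inadmissible_theta_returns_sentinel(self):
        spec = small_spec()
        theta = np.full(spec.n_free, np.nan)
        pat = compute_patterns(np.zeros((3, spec.n_observed)))
        assert fiml_loglik(theta, pat, spec) <= -1e14  # optimizer-safe, no crash


class TestGradient:
    def test_analytic_chain_gradient_matches_finite_differences(self):
        cfg = default_calibration()
        cfg = copy.deepcopy(cfg)
        cfg.n_wave2, cfg.n_wave3 = 120, 90
        spec = small_spec("fa")
        df = residualize_table(generate_cohort(cfg, seed=8))
        Y = df[list(spec.observed)].to_numpy()
        Y = Y / np.nanstd(Y, axis=0)  # keep finite differences well-scaled
        pat = compute_patterns(Y)
        theta = fiml.start_values(spec, pd.DataFrame(Y, columns=list(spec.observed)))
        g = fiml.fiml_gradient(theta, pat, spec)
        for j in [0, 5, len(theta) // 2, len(theta) - 1]:
            h = 1e-6 * max(1, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (fiml_loglik(tp, pat, spec) - fiml_loglik(tm, pat, spec)) / (2 * h)
            assert np.isclose(g[j], fd, rtol=1e-4, atol=1e-6)


class TestFit:
    def test_loglik_never_below_start(self, md_model, residualized):
        res = md_model.result_
        pat = compute_patterns(residualized[list(res.spec.observed)].to_numpy(dtype=float))
        ll_start = fiml_loglik(res.start_theta, pat, res.spec)
        assert res.loglik >= ll_start - 1e-6

    def test_estimates_invariant_to_row_shuffling(self, config, rng):
        cfg = copy.deepcopy(config)
        cfg.n_wave2, cfg.n_wave3 = 250, 180
        from hippolcs import apply_attrition

        df = residualize_table(apply_attrition(generate_cohort(cfg, 5), cfg, 6))
        spec = small_spec("fa")
        f1 = fiml.fit(spec, df, compute_se=False)
        shuffled = df.sample(frac=1.0, random_state=1)
        f2 = fiml.fit(spec, shuffled, compute_se=False)
        assert np.isclose(f1.loglik, f2.loglik, atol=1e-5)
        scale = np.maximum(1.0, np.abs(f1.theta))
        assert (np.abs(f1.theta - f2.theta) / scale).max() < 1e-5

    def test_parameter_recovery_complete_data(self, config):
        """Structural correlations recovered within +/-0.05 at n=2000 with no
        missingness (averaged over three replicates to separate recovery from
        single-draw noise)."""
        cfg = copy.deepcopy(config)
        cfg.n_wave2, cfg.n_wave3 = 2000, 2000
        spec = small_spec("md")
        R = cfg.structural_correlation("md")
        order = cfg.structural_order("md")
        ests = {}
        for seed in (13, 14, 15):
            df = residualize_table(generate_cohort(cfg, seed=seed))
            fm = fiml.fit(spec, df, compute_se=False)
            assert fm.converged
            std = fiml.standardize(fm)
            for row in std[std.kind == "correlation"].itertuples():
                ests.setdefault((row.var1, row.var2), []).append(row.estimate)
        for (a, b), vals in ests.items():
            i, j = order.index(a), order.index(b)
            assert abs(np.mean(vals) - R[i, j]) < 0.05, (a, b, np.mean(vals), R[i, j])

    def test_too_sparse_column_raises(self, config):
        cfg = copy.deepcopy(config)
        cfg.n_wave2, cfg.n_wave3 = 50, 40
        df = residualize_table(generate_cohort(cfg, 3))
        df["md_w3"] = np.nan
        with pytest.raises(ValueError, match="observed values"):
            fiml.fit(small_spec("md"), df)


class TestReferenceFits:
    def test_saturated_equals_sample_moments_on_complete_data(self, rng):
        n, p = 120, 4
        Y = rng.multivariate_normal(np.arange(p, dtype=float), np.eye(p) + 0.5, size=n)
        df = pd.DataFrame(Y, columns=[f"v{j}" for j in range(p)])
        sat = fit_saturated(df)
        assert np.allclose(sat.mu, Y.mean(axis=0), atol=1e-6)
        S = np.cov(Y.T, ddof=0)
        assert np.abs(sat.Sigma - S).max() < 1e-6
        assert np.isclose(sat.loglik, closed_form_loglik(Y, sat.mu, sat.Sigma), atol=1e-6)

    def test_saturated_em_matches_monotone_factorization_oracle(self, rng):
        """With monotone missingness the saturated MLE has a closed form:
        baseline moments from everyone, follow-up given baseline from the
        completers' regression (likelihood factorization)."""
        n = 400
        rho = 0.6
        X = rng.normal(size=n)
        Y = rho * X + np.sqrt(1 - rho**2) * rng.normal(size=n) + 1.0
        Y[200:] = np.nan  # second half drops out
        df = pd.DataFrame({"x": X, "y": Y})
        sat = fit_saturated(df, tol=1e-13)
        # oracle
        mu_x, var_x = X.mean(), X.var()
        xc, yc = X[:200], Y[:200]
        b = np.cov(xc, yc, ddof=0)[0, 1] / xc.var()
        a = yc.mean() - b * xc.mean()
        s2 = np.mean((yc - a - b * xc) ** 2)
        mu_y = a + b * mu_x
        var_y = s2 + b**2 * var_x
        cov_xy = b * var_x
        assert np.isclose(sat.mu[0], mu_x, atol=1e-6)
        assert np.isclose(sat.mu[1], mu_y, atol=1e-5)
        assert np.isclose(sat.Sigma[0, 0], var_x, atol=1e-6)
        assert np.isclose(sat.Sigma[0, 1], cov_xy, atol=1e-5)
        assert np.isclose(sat.Sigma[1, 1], var_y, atol=1e-4)

    def test_manifest_change_mean_is_sample_mean_difference(self, rng):
        w2 = rng.normal(10, 2, 300)
        w3 = w2 + rng.normal(-1.5, 1, 300)
        sat = fit_saturated(pd.DataFrame({"b_w2": w2, "b_w3": w3}))
        assert np.isclose(sat.mu[1] - sat.mu[0], (w3 - w2).mean(), atol=1e-10)

    def test_nesting_order_of_logliks(self, residualized, md_model):
        sub = residualized[list(md_model.spec_.observed)]
        sat = fit_saturated(sub)
        base = fit_baseline(sub)
        assert base.loglik <= md_model.loglik_ <= sat.loglik

    def test_pattern_fiml_equals_complete_ml_when_nothing_missing(self, config):
        cfg = copy.deepcopy(config)
        cfg.n_wave2, cfg.n_wave3 = 150, 150
        spec = small_spec("t1")
        df = residualize_table(generate_cohort(cfg, 17))
        Y = df[list(spec.observed)].to_numpy()
        theta = generating_parameters(cfg, spec)
        mom = spec.implied_moments(theta)
        ll_pat = loglik_moments(mom.mu, mom.Sigma, compute_patterns(Y))
        assert np.isclose(ll_pat, closed_form_loglik(Y, mom.mu, mom.Sigma), atol=1e-8)


class TestStandardize:
    def test_closed_form_values(self):
        spec = small_spec()
        k = spec.n_latent
        Psi = np.eye(k)
        i, j = spec.structural_index("bio_level"), spec.structural_index("verbal_memory_level")
        Psi[j, j] = 4.0
        Psi[i, j] = Psi[j, i] = 0.5
        lo = {n: 1.0 for n in spec.indicator_list}
        theta = spec.pack(
            lo,
            {n: 0.0 for n in spec.indicator_list},
            {(n, w): 1.0 for n in spec.indicator_list for w in (2, 3)},
            np.zeros(k),
            Psi,
        )
        from hippolcs.fiml import _standardized_vector

        labels, vals = _standardized_vector(spec, theta)
        lookup = dict(zip([(a, b) for _, a, b in labels], vals))
        assert np.isclose(lookup[("bio_level", "verbal_memory_level")], 0.25)
        assert np.isclose(lookup[("bio_level", "bio_change")], 0.0)

    def test_correlations_bounded(self, md_model):
        std = md_model.standardized_
        corr = std[std.kind == "correlation"].estimate
        assert ((corr >= -1) & (corr <= 1)).all()

    def test_zero_covariance_standardizes_to_zero(self):
        # part of test_closed_form_values; kept for the level-change pair
        spec = small_spec()
        theta = spec.pack(
            {n: 1.0 for n in spec.indicator_list},
            {n: 0.0 for n in spec.indicator_list},
            {(n, w): 1.0 for n in spec.indicator_list for w in (2, 3)},
            np.zeros(spec.n_latent),
            np.eye(spec.n_latent),
        )
        from hippolcs.fiml import _standardized_vector

        _, vals = _standardized_vector(spec, theta)
        assert np.allclose(vals, 0.0)
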