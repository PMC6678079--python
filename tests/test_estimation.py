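"""Estimation machinery: Halton draws, simulated likelihood against a
Gauss-Hermite oracle, starting-value fits, standard errors, pruning."""

import math

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import multivariate_normal, norm

from bivop import (CrashRecord, DegenerateDataError, FitConfig, ModelSpec,
                   Parameters, fit_bivariate_fixed, fit_rpbop,
                   fit_univariate_op, halton_draws, halton_sequence,
                   loglik_fixed, prune_random_params, simulated_loglik,
                   standard_errors)
from bivop.estimation import (DrawSet, HessianError, _natural, _pack,
                              _unpack, param_labels)
from bivop.model import SpecError, design_matrices
from bivop.synthetic import recovery_truth_fixture, simulate_dataset


class TestHalton:
    def test_base2_raw_sequence(self):
        np.testing.assert_allclose(halton_sequence(4, 2),
                                   [0.5, 0.25, 0.75, 0.125])

    def test_deterministic_given_seed(self):
        d1 = halton_draws(50, 2, 20, seed=3)
        d2 = halton_draws(50, 2, 20, seed=3)
        np.testing.assert_array_equal(d1.draws, d2.draws)
        d3 = halton_draws(50, 2, 20, seed=4)
        assert not np.array_equal(d1.draws, d3.draws)

    def test_moments_of_transformed_draws(self):
        ds = halton_draws(1, 2, 500, seed=0)
        for m in range(2):
            z = ds.draws[0, m, :]
            assert abs(z.mean()) < 0.02
            assert abs(z.var() - 1.0) < 0.05

    def test_prefix_is_leading_slice(self):
        ds = halton_draws(10, 1, 40, seed=1)
        pre = ds.prefix(15)
        assert pre.R == 15
        np.testing.assert_array_equal(pre.draws, ds.draws[:, :, :15])


class TestPacking:
    def test_roundtrip_preserves_parameters(self):
        spec = ModelSpec(covariates=(("a", "b"), ("c",)),
                         random_flags=((False, True, False),
                                       (True, False)))
        params = Parameters(
            beta=(np.array([-0.5, 0.3, -0.2]), np.array([0.1, 0.7])),
            thresholds=(np.array([0.0, 0.4, 1.1]), np.array([0.0, 0.8, 1.9])),
            rho=-0.35,
            sigma=(np.array([0.0, 0.6, 0.0]), np.array([0.2, 0.0])))
        back = _unpack(_pack(params, spec), spec)
        for j in range(2):
            np.testing.assert_allclose(back.beta[j], params.beta[j], atol=1e-12)
            np.testing.assert_allclose(back.thresholds[j],
                                       params.thresholds[j], atol=1e-12)
            np.testing.assert_allclose(back.sigma[j], params.sigma[j],
                                       atol=1e-12)
        assert back.rho == pytest.approx(params.rho, abs=1e-12)
        assert len(param_labels(spec)) == len(_natural(_pack(params, spec),
                                                       spec))

    def test_rho_always_inside_unit_interval(self):
        spec = ModelSpec(covariates=((), ()))
        for t in (-50.0, -1.0, 0.0, 4.0, 80.0):
            theta = _pack(Parameters(beta=(np.zeros(1), np.zeros(1)),
                                     thresholds=(np.array([0.0, 1.0, 2.0]),) * 2,
                                     rho=0.0), spec)
            theta[-1] = t
            assert abs(_unpack(theta, spec).rho) < 1.0


class TestSimulatedLoglik:
    def _toy(self):
        spec = ModelSpec(covariates=(("x",), ()),
                         random_flags=((False, True), (False,)))
        params = Parameters(
            beta=(np.array([-0.2, 0.5]), np.array([0.1])),
            thresholds=(np.array([0.0, 0.7, 1.4]), np.array([0.0, 0.6, 1.2])),
            rho=0.3,
            sigma=(np.array([0.0, 0.4]), np.zeros(1)))
        data = [CrashRecord(0, 1, 2, np.array([1.0]), np.array([])),
                CrashRecord(1, 0, 0, np.array([1.0]), np.array([]))]
        return spec, params, data

    def test_zero_sigma_reduces_to_fixed_loglik(self, toy_spec, toy_params):
        spec = ModelSpec(covariates=((), ()),
                         random_flags=((True,), (False,)))
        params = Parameters(beta=toy_params.beta,
                            thresholds=toy_params.thresholds,
                            rho=toy_params.rho,
                            sigma=(np.zeros(1), np.zeros(1)))
        data = [CrashRecord(i, k, l, np.array([]), np.array([]))
                for i, (k, l) in enumerate([(0, 0), (2, 1), (3, 3)])]
        # sigma is zero but the coefficient is still flagged random, so the
        # simulated path runs and must agree with the fixed path exactly
        draws = halton_draws(len(data), 1, 64, seed=2)
        ll_sim = simulated_loglik(params, data, spec, draws)
        ll_fix = loglik_fixed(Parameters(beta=params.beta,
                                         thresholds=params.thresholds,
                                         rho=params.rho), data, toy_spec)
        assert ll_sim == pytest.approx(ll_fix, abs=1e-12)

    def test_gauss_hermite_oracle(self):
        """One random coefficient: SML at R=2000 vs 64-node quadrature."""
        spec, params, data = self._toy()
        draws = halton_draws(len(data), 1, 2000, seed=4)
        ll_sim = simulated_loglik(params, data, spec, draws)

        nodes, weights = hermegauss(64)  # exp(-x^2/2) weight
        weights = weights / math.sqrt(2 * math.pi)
        cov = [[1.0, params.rho], [params.rho, 1.0]]
        mvn = multivariate_normal(mean=[0, 0], cov=cov)

        def F2(a, b):
            if a == -np.inf or b == -np.inf:
                return 0.0
            return mvn.cdf([min(a, 9.0), min(b, 9.0)])

        thr1 = np.concatenate(([-np.inf], params.thresholds[0], [np.inf]))
        thr2 = np.concatenate(([-np.inf], params.thresholds[1], [np.inf]))
        expected = 0.0
        for rec in data:
            k, l = rec.outcome_rear, rec.outcome_front
            cell = 0.0
            for t, w in zip(nodes, weights):
                b1 = params.beta[0] + np.array([0.0, params.sigma[0][1] * t])
                e1 = b1[0] + b1[1] * rec.x_rear[0]
                e2 = params.beta[1][0]
                cell += w * (F2(thr1[k + 1] - e1, thr2[l + 1] - e2)
                             - F2(thr1[k] - e1, thr2[l + 1] - e2)
                             - F2(thr1[k + 1] - e1, thr2[l] - e2)
                             + F2(thr1[k] - e1, thr2[l] - e2))
            expected += math.log(cell)
        assert abs(ll_sim - expected) / abs(expected) < 1e-3

    def test_invariant_to_draw_permutation(self):
        spec, params, data = self._toy()
        draws = halton_draws(len(data), 1, 100, seed=6)
        ll = simulated_loglik(params, data, spec, draws)
        rng = np.random.default_rng(0)
        shuffled = draws.draws.copy()
        for i in range(shuffled.shape[0]):
            rng.shuffle(shuffled[i, 0, :])
        ds2 = DrawSet(shuffled, draws.R, draws.primes, draws.seed)
        assert simulated_loglik(params, data, spec, ds2) == pytest.approx(
            ll, abs=1e-10)

    def test_missing_draws_rejected(self):
        spec, params, data = self._toy()
        bad = halton_draws(len(data) + 3, 1, 10, seed=0)
        with pytest.raises(SpecError):
            simulated_loglik(params, data, spec, bad)


class TestUnivariateFit:
    def test_intercept_only_reproduces_cumulative_proportions(self):
        """Saturated intercept-only fit: Phi(mu_c - b0) equals the empirical
        cumulative shares (the published rear-margin shares)."""
        counts = np.array([12217, 1372, 1128, 442])
        y = np.repeat(np.arange(4), counts)
        spec = ModelSpec(covariates=((), ()))
        data = [CrashRecord(i, yi, 0, np.array([]), np.array([]))
                for i, yi in enumerate(y)]
        fit = fit_univariate_op(data, "rear", spec)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        fitted = norm.cdf(fit.thresholds[0] - fit.beta[0][0])
        np.testing.assert_allclose(fitted, cum, atol=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(12)
        n = 20000
        x = rng.binomial(1, 0.4, n).astype(float)
        beta0, b1 = -0.3, 0.6
        thr = np.array([0.0, 0.7, 1.5])
        ystar = beta0 + b1 * x + rng.standard_normal(n)
        y = np.searchsorted(thr, ystar, side="left")
        spec = ModelSpec(covariates=(("x",), ()))
        data = [CrashRecord(i, int(y[i]), 0, np.array([x[i]]), np.array([]))
                for i in range(n)]
        fit = fit_univariate_op(data, "rear", spec)
        assert fit.beta[0][0] == pytest.approx(beta0, abs=0.05)
        assert fit.beta[0][1] == pytest.approx(b1, abs=0.06)
        np.testing.assert_allclose(fit.thresholds[0], thr, atol=0.06)

    def test_empty_category_named_in_error(self):
        spec = ModelSpec(covariates=((), ()))
        data = [CrashRecord(i, yi, 0, np.array([]), np.array([]))
                for i, yi in enumerate([0, 0, 1, 3, 3])]
        with pytest.raises(DegenerateDataError, match="category 2"):
            fit_univariate_op(data, "rear", spec)

    def test_constant_covariate_rejected(self):
        spec = ModelSpec(covariates=(("dead",), ()))
        data = [CrashRecord(i, yi, 0, np.array([0.0]), np.array([]))
                for i, yi in enumerate([0, 1, 2, 3] * 10)]
        with pytest.raises(DegenerateDataError, match="dead"):
            fit_univariate_op(data, "rear", spec)


class TestStandardErrors:
    def test_quadratic_objective_exact(self):
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        f = lambda th: -0.5 * th @ A @ th
        se = standard_errors(f, np.zeros(2))
        np.testing.assert_allclose(se, np.sqrt(np.diag(np.linalg.inv(A))),
                                   atol=1e-5)

    def test_scaling_objective_scales_se(self):
        A = np.diag([1.5, 4.0])
        f = lambda th: -0.5 * th @ A @ th
        g = lambda th: 2.0 * f(th)
        se_f = standard_errors(f, np.zeros(2))
        se_g = standard_errors(g, np.zeros(2))
        np.testing.assert_allclose(se_g, se_f / math.sqrt(2.0), atol=1e-6)

    def test_indefinite_hessian_fails_loudly(self):
        f = lambda th: 0.5 * th @ th  # convex -> not a maximum
        with pytest.raises(HessianError, match="eigenvalue"):
            standard_errors(f, np.zeros(2))

    def test_se_close_to_monte_carlo_replication_sd(self):
        """Univariate ordered probit: reported SE vs the spread of the
        estimate across independent replications."""
        spec = ModelSpec(covariates=(("x",), ()))
        beta0, b1 = -0.2, 0.5
        thr = np.array([0.0, 0.8, 1.6])
        n = 5000
        ests = []
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            x = rng.binomial(1, 0.5, n).astype(float)
            ystar = beta0 + b1 * x + rng.standard_normal(n)
            y = np.searchsorted(thr, ystar, side="left")
            data = [CrashRecord(i, int(y[i]), 0, np.array([x[i]]),
                                np.array([])) for i in range(n)]
            fit = fit_univariate_op(data, "rear", spec)
            ests.append(fit.beta[0][1])
        mc_sd = np.std(ests, ddof=1)
        # analytic SE for the slope at the truth, via the information of
        # one replication's likelihood
        rng = np.random.default_rng(100)
        x = rng.binomial(1, 0.5, n).astype(float)
        ystar = beta0 + b1 * x + rng.standard_normal(n)
        y = np.searchsorted(thr, ystar, side="left")
        data = [CrashRecord(i, int(y[i]), 0, np.array([x[i]]), np.array([]))
                for i in range(n)]

        def ll(theta):
            eta = theta[0] + theta[1] * x
            t = np.concatenate(([-np.inf], [0.0, theta[2], theta[3]],
                                [np.inf]))
            return np.sum(np.log(norm.cdf(t[y + 1] - eta)
                                 - norm.cdf(t[y] - eta)))

        se = standard_errors(ll, np.array([beta0, b1, thr[1], thr[2]]))
        assert abs(se[1] - mc_sd) / mc_sd < 0.25


@pytest.fixture(scope="module")
def fixed_fit_pair():
    """Fixed-parameter bivariate fit plus an independent re-optimisation."""
    spec, params, scheme = recovery_truth_fixture(rho=0.3)
    fixed = Parameters(beta=params.beta, thresholds=params.thresholds,
                       rho=0.3)
    plain_spec = ModelSpec(covariates=spec.covariates)
    df, records, _ = simulate_dataset(4000, plain_spec, fixed, scheme,
                                      seed=21)
    fit = fit_bivariate_fixed(records, plain_spec,
                              FitConfig(compute_se=True))
    return plain_spec, fixed, records, fit


class TestBivariateFixedFit:
    def test_recovers_truth_within_three_se(self, fixed_fit_pair):
        plain_spec, truth, records, fit = fixed_fit_pair
        assert fit.converged
        truth_nat = _natural(_pack(truth, plain_spec), plain_spec)
        err = np.abs(fit.estimates - truth_nat) / fit.se
        assert np.all(err < 3.0), dict(zip(fit.names, err))

    def test_matches_independent_optimiser(self, fixed_fit_pair):
        """Same optimum as directly maximising a scipy-based fixed
        log-likelihood (independent of the compiled kernel path)."""
        from scipy.optimize import minimize

        plain_spec, _, records, fit = fixed_fit_pair
        X1, X2, y1, y2 = design_matrices(records, plain_spec)

        def nll(theta):
            p = _unpack(theta, plain_spec)
            r = p.rho
            total = 0.0
            for X, y, j in ((X1, y1, 0), (X2, y2, 1)):
                pass
            eta1 = X1 @ p.beta[0]
            eta2 = X2 @ p.beta[1]
            t1 = np.concatenate(([-np.inf], p.thresholds[0], [np.inf]))
            t2 = np.concatenate(([-np.inf], p.thresholds[1], [np.inf]))
            cov = np.array([[1.0, r], [r, 1.0]])
            mvn = multivariate_normal(mean=[0, 0], cov=cov)

            def F2(a, b):
                fin = np.isfinite(a) & np.isfinite(b)
                out = np.zeros(len(a))
                neg = (a == -np.inf) | (b == -np.inf)
                ainf = (a == np.inf) & np.isfinite(b)
                binf = (b == np.inf) & np.isfinite(a)
                both = (a == np.inf) & (b == np.inf)
                out[ainf] = norm.cdf(b[ainf])
                out[binf] = norm.cdf(a[binf])
                out[both] = 1.0
                if fin.any():
                    pts = np.column_stack([a[fin], b[fin]])
                    out[fin] = mvn.cdf(pts)
                out[neg] = 0.0
                return out

            pr = (F2(t1[y1 + 1] - eta1, t2[y2 + 1] - eta2)
                  - F2(t1[y1] - eta1, t2[y2 + 1] - eta2)
                  - F2(t1[y1 + 1] - eta1, t2[y2] - eta2)
                  + F2(t1[y1] - eta1, t2[y2] - eta2))
            return -np.sum(np.log(np.maximum(pr, 1e-300))) / len(y1)

        res = minimize(nll, fit.theta, method="Nelder-Mead",
                       options=dict(maxiter=400, fatol=1e-10, xatol=1e-6))
        # independent optimiser cannot improve on the reported optimum
        assert res.fun >= -fit.loglik / fit.n_obs - 1e-4

    def test_intercept_only_fit_to_published_table(self):
        """Polychoric-style fit to the published 4x4 joint severity
        counts: fitted marginal category shares within 0.5 pp of the
        observed margins, and positive latent correlation."""
        from bivop import table1_fixture

        t = table1_fixture()
        y_rear, y_front = t.expand_to_outcome_pairs()
        records = [CrashRecord(i, int(k), int(l), np.empty(0), np.empty(0))
                   for i, (k, l) in enumerate(zip(y_rear, y_front))]
        spec = ModelSpec(covariates=((), ()))
        fit = fit_bivariate_fixed(records, spec, FitConfig(compute_se=False))
        assert fit.converged
        assert fit.rho > 0
        for j, totals in ((0, t.rear_totals()), (1, t.front_totals())):
            thr = np.concatenate(([-np.inf], fit.params.thresholds[j],
                                  [np.inf]))
            fitted = np.diff(norm.cdf(thr - fit.params.beta[j][0]))
            np.testing.assert_allclose(fitted, totals / totals.sum(),
                                       atol=0.005)

    def test_null_correlation_recovery(self):
        spec, params, scheme = recovery_truth_fixture(rho=0.0)
        fixed = Parameters(beta=params.beta, thresholds=params.thresholds,
                           rho=0.0)
        plain = ModelSpec(covariates=spec.covariates)
        _, records, _ = simulate_dataset(4000, plain, fixed, scheme, seed=31)
        fit = fit_bivariate_fixed(records, plain, FitConfig(compute_se=True))
        i = fit.names.index("rho")
        assert abs(fit.estimates[i]) < 3.0 * fit.se[i]


class TestRandomParameterFit:
    def test_loglik_not_worse_when_R_doubles(self, small_recovery_data):
        spec, params, scheme, df, records, _ = small_recovery_data
        data = records[:400]
        lls = []
        for R in (25, 50):
            cfg = FitConfig(R=R, seed=5, compute_se=False, warm_start=False)
            lls.append(fit_rpbop(data, spec, cfg).loglik)
        assert lls[1] >= lls[0] - 0.1

    def test_all_flags_off_equals_fixed_fit(self, small_recovery_data):
        spec, params, scheme, df, records, _ = small_recovery_data
        data = records[:800]
        plain = ModelSpec(covariates=spec.covariates)
        cfg = FitConfig(compute_se=False)
        f1 = fit_rpbop(data, plain, cfg)
        f2 = fit_bivariate_fixed(data, spec, cfg)
        np.testing.assert_allclose(f1.estimates, f2.estimates, atol=1e-6)

    def test_consistency_bias_shrinks_with_n(self):
        """Mean absolute bias of (beta, rho) falls from n=1,000 to
        n=10,000 over 20 replications (fixed-parameter model)."""
        spec, params, scheme = recovery_truth_fixture(rho=0.3)
        truth = Parameters(beta=params.beta, thresholds=params.thresholds,
                           rho=0.3)
        plain = ModelSpec(covariates=spec.covariates)
        truth_nat = _natural(_pack(truth, plain), plain)
        cfg = FitConfig(compute_se=False)
        bias = {}
        for n in (1000, 10000):
            errs = []
            for rep in range(20):
                _, records, _ = simulate_dataset(n, plain, truth, scheme,
                                                 seed=1000 * n + rep)
                fit = fit_bivariate_fixed(records, plain, cfg)
                errs.append(np.abs(fit.estimates - truth_nat))
            bias[n] = np.mean(errs)
        assert bias[10000] < bias[1000]


@pytest.fixture(scope="module")
def pruning_world():
    """One truly random coefficient (rear age, sd 1.0) and one flagged
    random but truly fixed (front age)."""
    spec = ModelSpec(
        covariates=(("age_le24", "sex_male"), ("age_le24", "sex_male")),
        random_flags=((False, True, False), (False, True, False)))
    _, base, scheme = recovery_truth_fixture()
    params = Parameters(
        beta=base.beta, thresholds=base.thresholds, rho=0.25,
        sigma=(np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 0.0])))
    return spec, params, scheme


class TestPruning:
    def test_truly_fixed_coefficient_is_pruned(self, pruning_world):
        spec, params, scheme = pruning_world
        cfg = FitConfig(R=50, seed=5, compute_se=True)
        kept_true, dropped_false = 0, 0
        reps = 5
        for rep in range(reps):
            _, records, _ = simulate_dataset(4000, spec, params, scheme,
                                             seed=500 + rep)
            fit = fit_rpbop(records, spec, cfg)
            pruned = prune_random_params(fit, records, spec, cfg)
            flags = pruned.spec.random_flags
            kept_true += flags[0][1]       # rear age: truly random
            dropped_false += not flags[1][1]  # front age: truly fixed
        assert kept_true >= reps - 1
        assert dropped_false >= reps - 1

    def test_all_significant_returned_unchanged(self, pruning_world):
        # random flags on the well-identified dummies of each equation
        # (rear age, front sex), both with strong heterogeneity
        base_spec, base_params, scheme = pruning_world
        spec = ModelSpec(covariates=base_spec.covariates,
                         random_flags=((False, True, False),
                                       (False, False, True)))
        params = Parameters(
            beta=base_params.beta, thresholds=base_params.thresholds,
            rho=0.25,
            sigma=(np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])))
        _, records, _ = simulate_dataset(4000, spec, params, scheme, seed=91)
        cfg = FitConfig(R=50, seed=5, compute_se=True)
        fit = fit_rpbop(records, spec, cfg)
        sd_idx = [i for i, n in enumerate(fit.names) if ":sd(" in n]
        assert all(fit.p[i] < cfg.prune_alpha for i in sd_idx)
        assert prune_random_params(fit, records, spec, cfg) is fit

    def test_full_pruning_equals_fixed_fit(self, pruning_world):
        spec, base_params, scheme = pruning_world
        fixed_truth = Parameters(beta=base_params.beta,
                                 thresholds=base_params.thresholds, rho=0.25)
        _, records, _ = simulate_dataset(1200, spec, fixed_truth, scheme,
                                         seed=77)
        cfg = FitConfig(R=40, seed=5, compute_se=True)
        fit = fit_rpbop(records, spec, cfg)
        pruned = prune_random_params(fit, records, spec, cfg)
        if not any(any(f) for f in pruned.spec.random_flags):
            ref = fit_bivariate_fixed(records, spec, cfg)
            np.testing.assert_allclose(pruned.estimates, ref.estimates,
                                       atol=1e-8)
        else:
            # sampling noise can leave one SD marginally significant; the
            # retained SD must then be small
            for j in range(2):
                assert np.all(pruned.params.sigma[j] < 0.2)
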