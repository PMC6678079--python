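"""Estimation of the random-parameters bivariate ordered probit.

The workflow mirrors standard practice for mixed ordinal models:

1. two independent univariate ordered probits provide starting values for
   the coefficient means and thresholds;
2. the mixing integral over the normally distributed coefficient
   heterogeneity is approximated by averaging the conditional joint
   probability over R quasi-random (Halton) draws per crash, shared across
   all likelihood evaluations of one fit;
3. the simulated log-likelihood is maximised by a quasi-Newton optimiser
   over an unconstrained parameterisation (log SDs, log threshold
   increments, atanh of the correlation);
4. standard errors come from the inverse numerical Hessian at the optimum,
   mapped to the natural scale with the delta method;
5. random-coefficient SDs that are not significant are iteratively
   converted back to fixed coefficients and the model refitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtri
from scipy.stats import norm

from . import _kernels
from .model import (FRONT, REAR, EQUATION_NAMES, CrashRecord, ModelSpec,
                    Parameters, SpecError, design_matrices,
                    extended_thresholds, percent_observations, z_and_p)

__all__ = [
    "DrawSet",
    "FitConfig",
    "FitResult",
    "halton_sequence",
    "halton_draws",
    "simulated_loglik",
    "fit_univariate_op",
    "fit_rpbop",
    "fit_bivariate_fixed",
    "prune_random_params",
    "standard_errors",
]

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47,
           53, 59, 61, 67, 71, 73, 79, 83, 89, 97)

PROB_FLOOR = 1e-300


class DegenerateDataError(ValueError):
    """Raised when the data cannot identify the requested model."""


# ---------------------------------------------------------------------------
# quasi-random draws


def halton_sequence(n_points: int, base: int, start: int = 1) -> np.ndarray:
    """Raw Halton (van der Corput) sequence in the given prime base.

    With ``start=1`` the base-2 sequence begins 1/2, 1/4, 3/4, 1/8, ...
    """
    idx = np.arange(start, start + n_points, dtype=np.int64)
    out = np.zeros(n_points)
    f = 1.0 / base
    while idx.any():
        out += f * (idx % base)
        idx //= base
        f /= base
    return out


@dataclass(frozen=True)
class DrawSet:
    """Standard-normal quasi-random draws indexed (crash, random coef, draw).

    The same draw set is reused for every likelihood evaluation within one
    fit so that the simulated objective is a smooth deterministic function
    of the parameters.
    """

    draws: np.ndarray  # (n_crashes, n_random, R)
    R: int
    primes: tuple[int, ...]
    seed: int
    burn: int = 50

    def prefix(self, R0: int) -> "DrawSet":
        """The first ``R0`` draws of every crash (a coarser approximation
        of the same integral, used for warm starts)."""
        if R0 >= self.R:
            return self
        return DrawSet(np.ascontiguousarray(self.draws[:, :, :R0]), R0,
                       self.primes, self.seed, self.burn)


def halton_draws(n_crashes: int, n_random: int, R: int, seed: int,
                 burn: int = 50) -> DrawSet:
    """Scrambled-Halton standard normal draws for the simulated likelihood.

    One Halton dimension (consecutive prime bases) per random coefficient;
    the first ``burn`` points are dropped, a uniform random shift (mod 1)
    scrambles each dimension, and the inverse normal CDF maps to draws.
    Deterministic given ``(n_crashes, n_random, R, seed)``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if n_random > len(_PRIMES):
        raise ValueError(f"at most {len(_PRIMES)} random coefficients supported")
    rng = np.random.default_rng(seed)
    shifts = rng.random(max(n_random, 1))
    draws = np.empty((n_crashes, n_random, R))
    for m in range(n_random):
        u = halton_sequence(n_crashes * R, _PRIMES[m], start=burn + 1)
        u = (u + shifts[m]) % 1.0
        np.clip(u, 1e-12, 1.0 - 1e-12, out=u)
        draws[:, m, :] = ndtri(u).reshape(n_crashes, R)
    return DrawSet(draws, R, _PRIMES[:n_random], seed, burn)


# ---------------------------------------------------------------------------
# parameter packing

def _random_map(spec: ModelSpec) -> list[tuple[int, int, int]]:
    """(equation, coefficient index, Halton dimension) per random coefficient."""
    out = []
    dim = 0
    for j in (REAR, FRONT):
        for c, flag in enumerate(spec.random_flags[j]):
            if flag:
                out.append((j, c, dim))
                dim += 1
    return out


def _n_free_cuts(spec: ModelSpec, j: int) -> int:
    # interior cutoffs: K-1; one pinned at 0 when a constant is estimated
    return spec.n_categories[j] - 1 - int(spec.include_constant[j])


def _pack(params: Parameters, spec: ModelSpec,
          sigma_floor: float = 1e-8) -> np.ndarray:
    parts = [params.beta[REAR], params.beta[FRONT]]
    for j in (REAR, FRONT):
        thr = params.thresholds[j]
        if spec.include_constant[j]:
            incr = np.diff(np.concatenate(([0.0], thr[1:])))
            parts.append(np.log(incr))
        else:
            parts.append(np.concatenate(([thr[0]], np.log(np.diff(thr)))))
    sig = np.array([max(params.sigma[j][c], sigma_floor)
                    for j, c, _ in _random_map(spec)])
    parts.append(np.log(sig))
    parts.append(np.array([np.arctanh(params.rho)]))
    return np.concatenate([np.atleast_1d(p) for p in parts])


def _unpack(theta: np.ndarray, spec: ModelSpec) -> Parameters:
    pos = 0
    beta = []
    for j in (REAR, FRONT):
        p = spec.n_coefs(j)
        beta.append(np.asarray(theta[pos:pos + p]))
        pos += p
    thrs = []
    for j in (REAR, FRONT):
        nf = _n_free_cuts(spec, j)
        block = theta[pos:pos + nf]
        pos += nf
        if spec.include_constant[j]:
            thr = np.concatenate(([0.0], np.cumsum(np.exp(block))))
        else:
            thr = np.concatenate(([block[0]],
                                  block[0] + np.cumsum(np.exp(block[1:]))))
        thrs.append(thr)
    rmap = _random_map(spec)
    sigma = [np.zeros(spec.n_coefs(REAR)), np.zeros(spec.n_coefs(FRONT))]
    for (j, c, _), s in zip(rmap, theta[pos:pos + len(rmap)]):
        sigma[j][c] = math.exp(s)
    pos += len(rmap)
    # tanh rounds to +-1.0 beyond |t| ~ 19; keep rho strictly inside (-1, 1)
    rho = max(-1.0 + 1e-12, min(1.0 - 1e-12, math.tanh(theta[pos])))
    return Parameters(beta=tuple(beta), thresholds=tuple(thrs), rho=rho,
                      sigma=tuple(sigma))


def _natural(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Map the packed vector to the reported (natural) scale, same layout."""
    p = _unpack(theta, spec)
    parts = [p.beta[REAR], p.beta[FRONT]]
    for j in (REAR, FRONT):
        if spec.include_constant[j]:
            parts.append(p.thresholds[j][1:])
        else:
            parts.append(p.thresholds[j])
    rmap = _random_map(spec)
    parts.append(np.array([p.sigma[j][c] for j, c, _ in rmap]))
    parts.append(np.array([p.rho]))
    return np.concatenate([np.atleast_1d(x) for x in parts])


def param_labels(spec: ModelSpec) -> tuple[str, ...]:
    """Labels for the natural parameter vector, in packing order."""
    labels = []
    for j in (REAR, FRONT):
        eq = EQUATION_NAMES[j]
        labels.extend(f"{eq}:{name}" for name in spec.coef_names(j))
    for j in (REAR, FRONT):
        eq = EQUATION_NAMES[j]
        first = 1 if spec.include_constant[j] else 0
        labels.extend(f"{eq}:mu_{c}" for c in
                      range(first, spec.n_categories[j] - 1))
    names = [spec.coef_names(j) for j in (REAR, FRONT)]
    for j, c, _ in _random_map(spec):
        labels.append(f"{EQUATION_NAMES[j]}:sd({names[j][c]})")
    labels.append("rho")
    return tuple(labels)


# ---------------------------------------------------------------------------
# simulated likelihood


class _Objective:
    """Negative mean simulated log-likelihood over packed parameters.

    Precomputes design matrices and caches the draw array; each call
    rebuilds the per-draw linear indices and evaluates the compiled
    rectangle kernel.
    """

    def __init__(self, data, spec: ModelSpec, draws: DrawSet | None):
        self.spec = spec
        X1, X2, y1, y2 = design_matrices(data, spec)
        self.X = (X1, X2)
        self.y = (np.ascontiguousarray(y1), np.ascontiguousarray(y2))
        self.n = len(y1)
        self.rmap = _random_map(spec)
        if self.rmap and (draws is None or draws.draws.shape[:2] !=
                          (self.n, len(self.rmap))):
            raise SpecError("draw set does not cover every (crash, random "
                            "coefficient) pair")
        self.draws = draws
        self.last_clamped = 0

    def _etas(self, params: Parameters):
        R = self.draws.R if (self.rmap and self.draws is not None) else 1
        etas = []
        for j in (REAR, FRONT):
            base = self.X[j] @ params.beta[j]
            eq_terms = [(c, dim) for (jj, c, dim) in self.rmap if jj == j]
            if eq_terms:
                eta = np.repeat(base[:, None], R, axis=1)
                for c, dim in eq_terms:
                    s = params.sigma[j][c]
                    if s != 0.0:
                        eta += s * self.draws.draws[:, dim, :] * self.X[j][:, c, None]
            else:
                eta = np.broadcast_to(base[:, None], (self.n, R)).copy()
            etas.append(eta)
        return etas

    def loglik(self, params: Parameters) -> float:
        eta1, eta2 = self._etas(params)
        thr1 = extended_thresholds(params.thresholds[REAR])
        thr2 = extended_thresholds(params.thresholds[FRONT])
        ll, clamped = _kernels.loglik_kernel(
            np.ascontiguousarray(eta1), np.ascontiguousarray(eta2),
            self.y[0], self.y[1], thr1, thr2, params.rho, PROB_FLOOR)
        self.last_clamped = clamped
        return ll

    def neg_mean(self, theta: np.ndarray) -> float:
        return -self.loglik(_unpack(theta, self.spec)) / self.n

    def total(self, theta: np.ndarray) -> float:
        return self.loglik(_unpack(theta, self.spec))


def simulated_loglik(params: Parameters, data: Sequence[CrashRecord],
                     spec: ModelSpec, draws: DrawSet) -> float:
    """Simulated log-likelihood: per crash, the joint probability is
    averaged over R realisations ``beta + sigma * draw`` of the random
    coefficients before taking the log.  Reduces exactly to the fixed
    log-likelihood when every sigma is zero.
    """
    params.validate(spec)
    obj = _Objective(data, spec, draws)
    return obj.loglik(params)


# ---------------------------------------------------------------------------
# univariate ordered probit (starting values)


def _check_identified(y: np.ndarray, X: np.ndarray, K: int, j: int,
                      spec: ModelSpec) -> None:
    counts = np.bincount(y, minlength=K)
    for c in np.flatnonzero(counts == 0):
        raise DegenerateDataError(
            f"{EQUATION_NAMES[j]} equation: outcome category {c} has no "
            "observations")
    names = spec.coef_names(j)
    start = 1 if spec.include_constant[j] else 0
    for c in range(start, X.shape[1]):
        if np.ptp(X[:, c]) == 0.0:
            raise DegenerateDataError(
                f"{EQUATION_NAMES[j]} equation: covariate "
                f"'{names[c]}' is constant and not identified")


def _fit_univariate(y: np.ndarray, X: np.ndarray, K: int,
                    include_constant: bool) -> tuple[np.ndarray, np.ndarray, float]:
    """MLE of one ordered probit equation.

    Returns ``(beta, interior thresholds, loglik)`` in the package's
    parameterisation (constant estimated, first cutoff pinned at 0).
    Intercept-only models use the closed form through the empirical
    cumulative proportions; otherwise the fit is delegated to statsmodels'
    ``OrderedModel``.
    """
    n = len(y)
    n_exog = X.shape[1] - int(include_constant)
    if include_constant and n_exog == 0:
        cum = np.cumsum(np.bincount(y, minlength=K))[:-1] / n
        alpha = ndtri(cum)
        beta = np.array([-alpha[0]])
        thr = alpha - alpha[0]
        probs = np.diff(np.concatenate(([0.0], cum, [1.0])))
        ll = float(n * np.sum(probs * np.log(probs)))
        return beta, thr, ll
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    exog = X[:, 1:] if include_constant else X
    endog = pd.Series(y).astype("category").cat.as_ordered()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = OrderedModel(endog, exog, distr="probit")
        res = m.fit(method="bfgs", maxiter=300, disp=0)
    alpha = m.transform_threshold_params(res.params.to_numpy())[1:-1]
    slopes = res.params.to_numpy()[:n_exog]
    if include_constant:
        beta = np.concatenate(([-alpha[0]], slopes))
        thr = alpha - alpha[0]
    else:
        beta = slopes
        thr = alpha
    return beta, thr, float(res.llf)


def fit_univariate_op(data: Sequence[CrashRecord], equation: str,
                      spec: ModelSpec) -> Parameters:
    """Maximum-likelihood univariate ordered probit for one equation.

    ``equation`` is ``"rear"`` or ``"front"``.  The returned
    :class:`Parameters` carry the fitted coefficients and thresholds in
    the requested equation; the other equation is left at neutral defaults
    (zero coefficients, unit-spaced thresholds) and ``rho`` is 0.  Used to
    seed the bivariate fit.
    """
    if equation not in EQUATION_NAMES:
        raise ValueError(f"equation must be one of {EQUATION_NAMES}")
    j = EQUATION_NAMES.index(equation)
    X1, X2, y1, y2 = design_matrices(data, spec)
    X, y = (X1, y1) if j == REAR else (X2, y2)
    K = spec.n_categories[j]
    _check_identified(y, X, K, j, spec)
    beta, thr, _ = _fit_univariate(y, X, K, spec.include_constant[j])
    other = 1 - j
    beta_out = [None, None]
    thr_out = [None, None]
    beta_out[j] = beta
    thr_out[j] = thr
    beta_out[other] = np.zeros(spec.n_coefs(other))
    thr_out[other] = np.arange(spec.n_categories[other] - 1, dtype=float)
    return Parameters(beta=tuple(beta_out), thresholds=tuple(thr_out), rho=0.0)


# ---------------------------------------------------------------------------
# numerical derivatives / standard errors


def _hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
             rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with steps ``rel_step * max(1, |x_i|)``."""
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for jj in range(i + 1, p):
            ej = np.zeros(p)
            ej[jj] = h[jj]
            H[i, jj] = H[jj, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                + f(x - ei - ej)) / (4.0 * h[i] * h[jj])
    return H


def _jacobian(g: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
              rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = rel_step * np.maximum(1.0, np.abs(x))
    cols = []
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = h[i]
        cols.append((g(x + e) - g(x - e)) / (2.0 * h[i]))
    return np.column_stack(cols)


class HessianError(RuntimeError):
    pass


def _embed(theta: np.ndarray, free: np.ndarray, sub: np.ndarray) -> np.ndarray:
    full = theta.copy()
    full[free] = sub
    return full


def standard_errors(loglik_fn: Callable[[np.ndarray], float],
                    theta_hat: np.ndarray,
                    rel_step: float = 1e-4) -> np.ndarray:
    """SEs as the square root of the diagonal of the inverse negative
    Hessian of ``loglik_fn`` at ``theta_hat`` (central differences).

    Raises :class:`HessianError` naming the offending eigenvalue when the
    negative Hessian is not positive definite, rather than returning NaNs.
    """
    H = _hessian(loglik_fn, np.asarray(theta_hat, dtype=float), rel_step)
    A = -H
    eigs = np.linalg.eigvalsh(A)
    if eigs[0] <= 0:
        raise HessianError(
            "negative Hessian is not positive definite at the optimum "
            f"(smallest eigenvalue {eigs[0]:.3e})")
    return np.sqrt(np.diag(np.linalg.inv(A)))


# ---------------------------------------------------------------------------
# the full fit


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the maximum simulated likelihood fit.

    R is the number of Halton draws per crash and random coefficient;
    ``tol`` is the convergence threshold on the max-norm of the gradient
    of the per-crash mean log-likelihood; ``sigma_init`` seeds every
    random-coefficient SD; ``warm_R`` optimises first on a draw prefix to
    cut the cost of early iterations.  ``prune_alpha`` is the two-sided
    significance level of the SD pruning rule; ``screen_alpha`` the level
    used when screening candidate covariates in univariate models.
    """

    R: int = 200
    seed: int = 1
    max_iter: int = 500
    tol: float = 1e-5
    sigma_init: float = 0.1
    compute_se: bool = True
    warm_start: bool = True
    warm_R: int = 20
    maxcor: int = 30
    prune_alpha: float = 0.05
    screen_alpha: float = 0.10
    log_sigma_bounds: tuple[float, float] = (-6.0, 2.5)


@dataclass
class FitResult:
    """Estimates and diagnostics of one bivariate ordered probit fit."""

    spec: ModelSpec
    params: Parameters
    theta: np.ndarray
    names: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray | None
    z: np.ndarray | None
    p: np.ndarray | None
    percent_obs: dict[str, tuple[float, float]]
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    clamp_count: int
    draw_config: dict
    message: str = ""

    def __getitem__(self, label: str) -> dict:
        i = self.names.index(label)
        return {
            "estimate": float(self.estimates[i]),
            "se": None if self.se is None else float(self.se[i]),
            "z": None if self.z is None else float(self.z[i]),
            "p": None if self.p is None else float(self.p[i]),
        }

    @property
    def rho(self) -> float:
        return self.params.rho


def _start_theta(data, spec: ModelSpec, config: FitConfig) -> np.ndarray:
    p_rear = fit_univariate_op(data, "rear", spec)
    p_front = fit_univariate_op(data, "front", spec)
    sigma = [np.zeros(spec.n_coefs(REAR)), np.zeros(spec.n_coefs(FRONT))]
    for j, c, _ in _random_map(spec):
        sigma[j][c] = config.sigma_init
    start = Parameters(
        beta=(p_rear.beta[REAR], p_front.beta[FRONT]),
        thresholds=(p_rear.thresholds[REAR], p_front.thresholds[FRONT]),
        rho=0.0, sigma=tuple(sigma))
    return _pack(start, spec)


def _bounds(spec: ModelSpec, config: FitConfig):
    nb = spec.n_coefs(REAR) + spec.n_coefs(FRONT)
    nc = _n_free_cuts(spec, REAR) + _n_free_cuts(spec, FRONT)
    nr = len(_random_map(spec))
    bounds = [(None, None)] * nb
    bounds += [(-10.0, 5.0)] * nc
    bounds += [config.log_sigma_bounds] * nr
    bounds += [(-6.0, 6.0)]  # atanh(rho)
    return bounds


def fit_rpbop(data: Sequence[CrashRecord], spec: ModelSpec,
              config: FitConfig | None = None) -> FitResult:
    """Maximum simulated likelihood fit of the random-parameters bivariate
    ordered probit.

    Starts from the two univariate ordered probit fits (SDs at
    ``sigma_init``, rho at 0), maximises the simulated log-likelihood with
    L-BFGS-B over the unconstrained parameterisation, and reports
    delta-method standard errors from the inverse numerical Hessian.
    Non-convergence is reported through ``converged=False`` and
    ``message``, never as an exception.
    """
    config = config or FitConfig()
    theta0 = _start_theta(data, spec, config)
    rmap = _random_map(spec)
    n = len(data)
    draws = (halton_draws(n, len(rmap), config.R, config.seed)
             if rmap else None)
    obj = _Objective(data, spec, draws)
    bounds = _bounds(spec, config)
    n_iter = 0
    theta = theta0
    if (config.warm_start and rmap and draws is not None
            and config.warm_R < config.R):
        warm_obj = _Objective(data, spec, draws.prefix(config.warm_R))
        res_w = minimize(warm_obj.neg_mean, theta, method="L-BFGS-B",
                         bounds=bounds,
                         options=dict(maxiter=min(config.max_iter, 300),
                                      ftol=1e-12, gtol=config.tol,
                                      maxcor=config.maxcor))
        theta = res_w.x.copy()
        n_iter += res_w.nit
        # coarse-draw noise can push a mixing SD to its bound prematurely;
        # reset such SDs so the full-draw stage re-evaluates them
        nb = spec.n_coefs(REAR) + spec.n_coefs(FRONT)
        nc = _n_free_cuts(spec, REAR) + _n_free_cuts(spec, FRONT)
        for i in range(nb + nc, nb + nc + len(rmap)):
            if theta[i] <= config.log_sigma_bounds[0] + 1e-3:
                theta[i] = math.log(config.sigma_init)
    res = minimize(obj.neg_mean, theta, method="L-BFGS-B", bounds=bounds,
                   options=dict(maxiter=config.max_iter, ftol=1e-12,
                                gtol=config.tol, maxcor=config.maxcor))
    n_iter += res.nit
    theta_hat = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = grad_norm < config.tol or bool(res.success)
    loglik = obj.total(theta_hat)
    clamp_count = obj.last_clamped
    params = _unpack(theta_hat, spec)
    names = param_labels(spec)
    estimates = _natural(theta_hat, spec)
    se = z = pvals = None
    message = str(res.message)
    if config.compute_se:
        # A mixing SD driven to its lower bound leaves the likelihood flat
        # in that direction (the model degenerates to a fixed coefficient),
        # which would make the Hessian singular.  Such SDs are excluded
        # from the Hessian and reported with z = NaN, p = 1 so the pruning
        # rule treats them as non-significant.
        nb = spec.n_coefs(REAR) + spec.n_coefs(FRONT)
        nc = _n_free_cuts(spec, REAR) + _n_free_cuts(spec, FRONT)
        sigma_slice = range(nb + nc, nb + nc + len(rmap))
        lb = config.log_sigma_bounds[0]
        at_bound = np.zeros(len(theta_hat), dtype=bool)
        for i in sigma_slice:
            at_bound[i] = theta_hat[i] <= lb + 1e-3
        free = ~at_bound
        try:
            H = _hessian(lambda sub: obj.total(_embed(theta_hat, free, sub)),
                         theta_hat[free])
            A = -H
            eigs = np.linalg.eigvalsh(A)
            if eigs[0] <= 0:
                raise HessianError(
                    "negative Hessian not positive definite "
                    f"(smallest eigenvalue {eigs[0]:.3e})")
            cov_sub = np.linalg.inv(A)
            cov_theta = np.zeros((len(theta_hat), len(theta_hat)))
            cov_theta[np.ix_(free, free)] = cov_sub
            J = _jacobian(lambda t: _natural(t, spec), theta_hat)
            cov_nat = J @ cov_theta @ J.T
            se = np.sqrt(np.maximum(np.diag(cov_nat), 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = estimates / se
            pvals = 2.0 * norm.sf(np.abs(z))
            # natural vector shares the theta layout, so bounded sigma
            # positions coincide
            for i in np.flatnonzero(at_bound):
                se[i] = np.nan
                z[i] = np.nan
                pvals[i] = 1.0
        except HessianError as exc:
            message = f"{message}; SEs unavailable: {exc}"
            converged = False
    percent = {}
    coef_names = [spec.coef_names(j) for j in (REAR, FRONT)]
    for j, c, _ in rmap:
        label = f"{EQUATION_NAMES[j]}:{coef_names[j][c]}"
        percent[label] = percent_observations(params.beta[j][c],
                                              params.sigma[j][c])
    return FitResult(
        spec=spec, params=params, theta=theta_hat, names=names,
        estimates=estimates, se=se, z=z, p=pvals, percent_obs=percent,
        loglik=loglik, converged=converged, n_iter=n_iter, n_obs=n,
        clamp_count=clamp_count,
        draw_config=dict(R=config.R if rmap else 0, seed=config.seed,
                         burn=50, primes=[p for p in _PRIMES[:len(rmap)]]),
        message=message)


def fit_bivariate_fixed(data: Sequence[CrashRecord], spec: ModelSpec,
                        config: FitConfig | None = None) -> FitResult:
    """Fixed-parameter bivariate ordered probit (every coefficient fixed)."""
    flags = tuple(tuple(False for _ in range(spec.n_coefs(j)))
                  for j in (REAR, FRONT))
    return fit_rpbop(data, spec.with_random_flags(flags), config)


def _sd_entries(fit: FitResult) -> list[tuple[int, str]]:
    return [(i, name) for i, name in enumerate(fit.names) if ":sd(" in name]


def prune_random_params(fit: FitResult, data: Sequence[CrashRecord],
                        spec: ModelSpec, config: FitConfig | None = None
                        ) -> FitResult:
    """Iteratively convert non-significant random coefficients to fixed.

    While any random-coefficient SD has a two-sided p-value above
    ``config.prune_alpha``, the least significant one is set to fixed and
    the model refitted; the final refit is returned.  A fit whose SDs are
    all significant is returned unchanged.
    """
    config = config or FitConfig()
    current = fit
    current_spec = fit.spec
    while True:
        if not current.converged:
            return current
        if current.p is None:
            raise HessianError("pruning needs standard errors; refit with "
                               "compute_se=True")
        entries = _sd_entries(current)
        insig = [(i, name) for i, name in entries
                 if current.p[i] > config.prune_alpha]
        if not insig:
            return current
        worst_i, worst_name = max(insig, key=lambda t: current.p[t[0]])
        eq_name, inner = worst_name.split(":sd(")
        cname = inner[:-1]
        j = EQUATION_NAMES.index(eq_name)
        c = current_spec.coef_names(j).index(cname)
        flags = [list(f) for f in current_spec.random_flags]
        flags[j][c] = False
        current_spec = current_spec.with_random_flags(flags)
        current = fit_rpbop(data, current_spec, config)
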