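"""Data model and probability core of the bivariate ordered probit.

Two ordered probit equations describe the injury severity of the two
drivers in the same rear-end crash: equation 1 for the driver of the rear
(striking) vehicle and equation 2 for the driver of the front (struck)
vehicle.  Each driver's latent injury propensity is a linear index
``eta = beta' x`` plus a standard normal error; the two errors are jointly
standard bivariate normal with correlation ``rho``, and increasing
thresholds censor the latent propensity into K ordered severity levels
(here the regrouped KABCO levels L1-L4, coded 0..K-1).

The probability that a crash lands in cell (k, l) is the bivariate normal
mass of the rectangle between consecutive thresholds, expressed as a
four-term combination of :func:`std_biv_norm_cdf` values.  Everything in
this module treats coefficients as fixed; the mixing over random
coefficients lives in :mod:`bivop.estimation`.

Identification follows the usual ordered-probit convention: error
variances are 1 and, when an equation includes a constant, its first
interior threshold is pinned at 0 so the remaining cutoffs and the
constant are free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from . import _kernels
from .bvn import _bvn_cdf_scalar, std_biv_norm_cdf

__all__ = [
    "CrashRecord",
    "ModelSpec",
    "Parameters",
    "JointProbTable",
    "std_biv_norm_cdf",
    "rectangle_prob",
    "joint_outcome_probs",
    "loglik_fixed",
    "percent_observations",
    "z_and_p",
    "design_matrices",
]

REAR, FRONT = 0, 1
EQUATION_NAMES = ("rear", "front")

PROB_FLOOR = 1e-300


class SpecError(ValueError):
    """Raised when data, parameters and model specification disagree."""


@dataclass(frozen=True)
class CrashRecord:
    """One crash: the two drivers' ordinal outcomes and covariate vectors.

    Outcomes are 0-based severity levels (0 = L1 no injury ... K-1 = L4
    incapacitating/fatal).  Covariate vectors exclude the constant; their
    order must match the covariate lists of the :class:`ModelSpec` in use.
    """

    crash_id: object
    outcome_rear: int
    outcome_front: int
    x_rear: np.ndarray
    x_front: np.ndarray


@dataclass(frozen=True)
class ModelSpec:
    """Equation layout: categories, covariates and random-coefficient flags.

    Per-equation tuples are ordered ``(rear, front)``.  ``random_flags``
    align with the full coefficient vector of an equation, i.e. the
    constant first (when present) followed by the covariates, so a random
    constant is expressible.
    """

    covariates: tuple[tuple[str, ...], tuple[str, ...]]
    n_categories: tuple[int, int] = (4, 4)
    random_flags: tuple[tuple[bool, ...], tuple[bool, ...]] | None = None
    include_constant: tuple[bool, bool] = (True, True)

    def __post_init__(self):
        if len(self.covariates) != 2:
            raise SpecError("covariates must be a (rear, front) pair of name lists")
        covs = tuple(tuple(c) for c in self.covariates)
        object.__setattr__(self, "covariates", covs)
        for j, names in enumerate(covs):
            if len(set(names)) != len(names):
                raise SpecError(f"duplicate covariate names in {EQUATION_NAMES[j]} equation")
        for K in self.n_categories:
            if K < 2:
                raise SpecError("each equation needs at least 2 outcome categories")
        if self.random_flags is None:
            flags = tuple(tuple(False for _ in range(self.n_coefs(j))) for j in (REAR, FRONT))
            object.__setattr__(self, "random_flags", flags)
        else:
            flags = tuple(tuple(bool(f) for f in fl) for fl in self.random_flags)
            object.__setattr__(self, "random_flags", flags)
            for j in (REAR, FRONT):
                if len(flags[j]) != self.n_coefs(j):
                    raise SpecError(
                        f"random_flags for {EQUATION_NAMES[j]} equation must have "
                        f"length {self.n_coefs(j)} (constant first), got {len(flags[j])}")

    def n_coefs(self, j: int) -> int:
        return len(self.covariates[j]) + int(self.include_constant[j])

    def coef_names(self, j: int) -> tuple[str, ...]:
        base = ("const",) if self.include_constant[j] else ()
        return base + self.covariates[j]

    def n_random(self, j: int) -> int:
        return sum(self.random_flags[j])

    @property
    def n_random_total(self) -> int:
        return self.n_random(REAR) + self.n_random(FRONT)

    def with_random_flags(self, flags) -> "ModelSpec":
        return ModelSpec(self.covariates, self.n_categories,
                         tuple(tuple(f) for f in flags), self.include_constant)


@dataclass
class Parameters:
    """Coefficients, random-coefficient SDs, thresholds and correlation.

    ``thresholds`` hold the full interior cutoff vectors (length K-1); with
    an estimated constant the first entry is fixed at 0.  ``sigma`` entries
    are standard deviations of the normally distributed coefficient
    heterogeneity and must be 0 exactly where the spec flags a coefficient
    as fixed.
    """

    beta: tuple[np.ndarray, np.ndarray]
    thresholds: tuple[np.ndarray, np.ndarray]
    rho: float
    sigma: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        self.beta = tuple(np.asarray(b, dtype=float) for b in self.beta)
        self.thresholds = tuple(np.asarray(t, dtype=float) for t in self.thresholds)
        self.rho = float(self.rho)
        if self.sigma is None:
            self.sigma = tuple(np.zeros_like(b) for b in self.beta)
        else:
            self.sigma = tuple(np.asarray(s, dtype=float) for s in self.sigma)

    def validate(self, spec: ModelSpec) -> None:
        for j in (REAR, FRONT):
            name = EQUATION_NAMES[j]
            if self.beta[j].shape != (spec.n_coefs(j),):
                raise SpecError(f"beta[{name}] has wrong length")
            if self.sigma[j].shape != (spec.n_coefs(j),):
                raise SpecError(f"sigma[{name}] has wrong length")
            if np.any(self.sigma[j] < 0):
                raise SpecError(f"sigma[{name}] must be nonnegative")
            fixed = ~np.asarray(spec.random_flags[j], dtype=bool)
            if np.any(self.sigma[j][fixed] != 0.0):
                raise SpecError(f"sigma[{name}] must be 0 for fixed coefficients")
            thr = self.thresholds[j]
            if thr.shape != (spec.n_categories[j] - 1,):
                raise SpecError(f"thresholds[{name}] must have K-1 interior cutoffs")
            if np.any(np.diff(thr) <= 0):
                raise SpecError(f"thresholds[{name}] must be strictly increasing")
            if spec.include_constant[j] and thr[0] != 0.0:
                raise SpecError(
                    f"first interior threshold of {name} equation must be 0 "
                    "when a constant is estimated")
        if not abs(self.rho) < 1:
            raise SpecError(f"|rho| must be < 1, got {self.rho}")

    @property
    def has_random(self) -> bool:
        return any(np.any(s > 0) for s in self.sigma)


@dataclass
class JointProbTable:
    """K x L table of joint outcome probabilities for one crash (rear rows)."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)

    def validate(self, atol: float = 1e-10) -> None:
        if np.any(self.probs < -atol) or np.any(self.probs > 1 + atol):
            raise ValueError("joint probabilities outside [0, 1]")
        if abs(self.probs.sum() - 1.0) > atol:
            raise ValueError(f"joint probabilities sum to {self.probs.sum()}, not 1")

    def marginal_rear(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def marginal_front(self) -> np.ndarray:
        return self.probs.sum(axis=0)


def extended_thresholds(interior: np.ndarray) -> np.ndarray:
    """Pad interior cutoffs with the -inf / +inf boundary thresholds."""
    return np.concatenate(([-np.inf], np.asarray(interior, dtype=float), [np.inf]))


def rectangle_prob(k: int, l: int, eta_rear: float, eta_front: float,
                   params: Parameters) -> float:
    """Joint probability that the rear driver is at level ``k`` and the
    front driver at level ``l`` given the linear indices of both equations.

    Evaluates the four-term bivariate normal rectangle between consecutive
    thresholds, with the boundary cutoffs at -inf and +inf.
    """
    thr1 = extended_thresholds(params.thresholds[REAR])
    thr2 = extended_thresholds(params.thresholds[FRONT])
    K, L = len(thr1) - 1, len(thr2) - 1
    if not (0 <= k < K):
        raise IndexError(f"rear level {k} outside 0..{K - 1}")
    if not (0 <= l < L):
        raise IndexError(f"front level {l} outside 0..{L - 1}")
    rho = params.rho
    p = (_bvn_cdf_scalar(thr1[k + 1] - eta_rear, thr2[l + 1] - eta_front, rho)
         - _bvn_cdf_scalar(thr1[k] - eta_rear, thr2[l + 1] - eta_front, rho)
         - _bvn_cdf_scalar(thr1[k + 1] - eta_rear, thr2[l] - eta_front, rho)
         + _bvn_cdf_scalar(thr1[k] - eta_rear, thr2[l] - eta_front, rho))
    return max(p, 0.0)


def linear_indices(record: CrashRecord, params: Parameters,
                   spec: ModelSpec) -> tuple[float, float]:
    """Linear indices ``eta_j = beta_j' x_j`` (constant included) for one crash."""
    etas = []
    for j, x in ((REAR, record.x_rear), (FRONT, record.x_front)):
        x = np.asarray(x, dtype=float)
        if x.shape != (len(spec.covariates[j]),):
            raise SpecError(
                f"covariate vector for {EQUATION_NAMES[j]} equation has length "
                f"{x.shape}, spec expects {len(spec.covariates[j])}")
        beta = params.beta[j]
        if spec.include_constant[j]:
            etas.append(beta[0] + float(x @ beta[1:]))
        else:
            etas.append(float(x @ beta))
    return etas[0], etas[1]


def joint_outcome_probs(record: CrashRecord, params: Parameters,
                        spec: ModelSpec) -> JointProbTable:
    """Full K x L joint outcome probability table for one crash.

    Rows marginalise to the rear equation's univariate ordered probit
    probabilities and columns to the front equation's.
    """
    params.validate(spec)
    eta1, eta2 = linear_indices(record, params, spec)
    K, L = spec.n_categories
    table = np.empty((K, L))
    for k in range(K):
        for l in range(L):
            table[k, l] = rectangle_prob(k, l, eta1, eta2, params)
    return JointProbTable(table)


def design_matrices(data: Sequence[CrashRecord], spec: ModelSpec):
    """Stack records into per-equation design matrices and outcome vectors.

    Returns ``(X_rear, X_front, y_rear, y_front)`` where the design
    matrices carry the constant column first when the equation includes
    one.  Validates outcome ranges and covariate lengths.
    """
    if len(data) == 0:
        raise SpecError("no crash records supplied")
    n = len(data)
    Xs, ys = [], []
    for j, (x_attr, y_attr) in enumerate(
            (("x_rear", "outcome_rear"), ("x_front", "outcome_front"))):
        p = len(spec.covariates[j])
        X = np.empty((n, p))
        y = np.empty(n, dtype=np.int64)
        for i, rec in enumerate(data):
            x = np.asarray(getattr(rec, x_attr), dtype=float)
            if x.shape != (p,):
                raise SpecError(
                    f"record {rec.crash_id}: {EQUATION_NAMES[j]} covariates have "
                    f"length {x.shape[0]}, spec expects {p}")
            X[i] = x
            y[i] = getattr(rec, y_attr)
        K = spec.n_categories[j]
        if np.any((y < 0) | (y >= K)):
            bad = data[int(np.argmax((y < 0) | (y >= K)))].crash_id
            raise SpecError(
                f"record {bad}: {EQUATION_NAMES[j]} outcome outside 0..{K - 1}")
        if spec.include_constant[j]:
            X = np.column_stack([np.ones(n), X])
        Xs.append(X)
        ys.append(y)
    return Xs[REAR], Xs[FRONT], ys[REAR], ys[FRONT]


def _loglik_arrays(eta1: np.ndarray, eta2: np.ndarray, y1: np.ndarray,
                   y2: np.ndarray, params: Parameters) -> tuple[float, int]:
    """Sum of log mean-over-draws rectangle probabilities; (loglik, n clamped)."""
    thr1 = extended_thresholds(params.thresholds[REAR])
    thr2 = extended_thresholds(params.thresholds[FRONT])
    return _kernels.loglik_kernel(
        np.ascontiguousarray(eta1), np.ascontiguousarray(eta2),
        np.ascontiguousarray(y1), np.ascontiguousarray(y2),
        thr1, thr2, float(params.rho), PROB_FLOOR)


def loglik_fixed(params: Parameters, data: Sequence[CrashRecord],
                 spec: ModelSpec) -> float:
    """Log-likelihood of the fixed-parameter bivariate ordered probit.

    Requires all random-coefficient SDs to be zero.  Cell probabilities are
    floored at ``PROB_FLOOR`` before the log; a ``RuntimeWarning`` reports
    how many cells were clamped instead of silently returning -inf.
    """
    params.validate(spec)
    if params.has_random:
        raise SpecError("loglik_fixed requires all sigma == 0; "
                        "use simulated_loglik for random coefficients")
    X1, X2, y1, y2 = design_matrices(data, spec)
    eta1 = (X1 @ params.beta[REAR])[:, None]
    eta2 = (X2 @ params.beta[FRONT])[:, None]
    ll, clamped = _loglik_arrays(eta1, eta2, y1, y2, params)
    if clamped:
        warnings.warn(f"{clamped} crash cell probabilities clamped at "
                      f"{PROB_FLOOR:g} before log", RuntimeWarning, stacklevel=2)
    return ll


def percent_observations(mean: float, sd: float) -> tuple[float, float]:
    """Share of the population with a positive / negative coefficient.

    For a normally distributed random coefficient with the given mean and
    SD, returns ``(100 * Phi(mean/sd), 100 * (1 - Phi(mean/sd)))``; a zero
    SD degenerates to a point mass at the mean.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if sd == 0:
        if mean > 0:
            above = 100.0
        elif mean < 0:
            above = 0.0
        else:
            above = 50.0
    else:
        above = 100.0 * float(norm.cdf(mean / sd))
    return above, 100.0 - above


def z_and_p(coef: float, se: float) -> tuple[float, float]:
    """Wald z statistic and two-sided normal p-value for one estimate."""
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    z = coef / se
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p
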