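"""Numba likelihood kernels.

The simulated likelihood averages, per crash, the joint rectangle
probability over R realisations of the random coefficients; the fixed
model is the R = 1 special case.  Two structural shortcuts keep the cost
down: the correlation is constant within one likelihood evaluation, so
the Gauss-Legendre nodes of the Phi2 quadrature are precomputed once per
call; and crashes whose random-coefficient covariates are all zero have
draw-invariant linear indices, so their rectangle probability is
evaluated once instead of R times.
"""

import math

import numpy as np
from numba import njit

from .bvn import (_W6, _W12, _W20, _X6, _X12, _X20, _TWOPI, _bvn_cdf_scalar,
                  _phid)


@njit(cache=True)
def rect_scalar(a_lo, a_hi, b_lo, b_hi, rho):
    """Rectangle probability from four Phi2 corner terms (general path)."""
    p = (_bvn_cdf_scalar(a_hi, b_hi, rho)
         - _bvn_cdf_scalar(a_lo, b_hi, rho)
         - _bvn_cdf_scalar(a_hi, b_lo, rho)
         + _bvn_cdf_scalar(a_lo, b_lo, rho))
    return p if p > 0.0 else 0.0


@njit(cache=True)
def _gl_nodes(rho):
    """Half-angle sine nodes and weights of the Phi2 quadrature for a
    fixed correlation (valid for |rho| < 0.925)."""
    ar = abs(rho)
    if ar < 0.3:
        x = _X6
        w = _W6
    elif ar < 0.75:
        x = _X12
        w = _W12
    else:
        x = _X20
        w = _W20
    nn = x.shape[0]
    asr = math.asin(rho) / 2.0
    sn = np.empty(2 * nn)
    csinv = np.empty(2 * nn)
    ww = np.empty(2 * nn)
    for i in range(nn):
        for s in range(2):
            v = math.sin(asr * (1.0 + (2.0 * s - 1.0) * x[i]))
            sn[2 * i + s] = v
            csinv[2 * i + s] = 1.0 / (1.0 - v * v)
            ww[2 * i + s] = w[i]
    return sn, csinv, ww, asr


@njit(cache=True)
def _f2_pre(a, b, rho, sn, csinv, ww, asr):
    """P(Z1 <= a, Z2 <= b) with precomputed nodes; a, b may be +-inf."""
    if a == -np.inf or b == -np.inf:
        return 0.0
    if a == np.inf:
        if b == np.inf:
            return 1.0
        return _phid(b)
    if b == np.inf:
        return _phid(a)
    h = -a
    k = -b
    hk = h * k
    hs = (h * h + k * k) / 2.0
    bvn = 0.0
    for m in range(sn.shape[0]):
        bvn += ww[m] * math.exp((sn[m] * hk - hs) * csinv[m])
    bvn = bvn * asr / _TWOPI + _phid(a) * _phid(b)
    if bvn < 0.0:
        return 0.0
    if bvn > 1.0:
        return 1.0
    return bvn


@njit(cache=True)
def _quad_term(a, b, sn, csinv, ww, asr):
    """Quadrature part of Phi2(a, b): Phi2 = T + Phi(a)Phi(b), T = 0 when
    either argument is infinite."""
    if a == np.inf or a == -np.inf or b == np.inf or b == -np.inf:
        return 0.0
    hk = a * b
    hs = (a * a + b * b) / 2.0
    t = 0.0
    for m in range(sn.shape[0]):
        t += ww[m] * math.exp((sn[m] * hk - hs) * csinv[m])
    return t * asr / _TWOPI


@njit(cache=True)
def _phi_ext(a):
    if a == np.inf:
        return 1.0
    if a == -np.inf:
        return 0.0
    return _phid(a)


@njit(cache=True)
def _rect_pre(a_lo, a_hi, b_lo, b_hi, rho, sn, csinv, ww, asr):
    # Phi2 = T + Phi*Phi per corner; the Phi*Phi parts telescope into a
    # product of marginal differences.
    t = (_quad_term(a_hi, b_hi, sn, csinv, ww, asr)
         - _quad_term(a_lo, b_hi, sn, csinv, ww, asr)
         - _quad_term(a_hi, b_lo, sn, csinv, ww, asr)
         + _quad_term(a_lo, b_lo, sn, csinv, ww, asr))
    p = t + ((_phi_ext(a_hi) - _phi_ext(a_lo))
             * (_phi_ext(b_hi) - _phi_ext(b_lo)))
    return p if p > 0.0 else 0.0


@njit(cache=True)
def loglik_kernel(eta1, eta2, y1, y2, thr1, thr2, rho, floor):
    """Sum over crashes of log mean-over-draws rectangle probability.

    eta1, eta2 : (n, R) linear indices per crash and draw
    y1, y2     : (n,) observed levels
    thr1, thr2 : extended thresholds (K+1,) with -inf / +inf boundaries
    Returns (loglik, number of clamped cells).
    """
    n, R = eta1.shape
    fast = abs(rho) < 0.925
    if fast:
        sn, csinv, ww, asr = _gl_nodes(rho)
    else:
        sn = np.empty(0)
        csinv = np.empty(0)
        ww = np.empty(0)
        asr = 0.0
    total = 0.0
    clamped = 0
    for i in range(n):
        a_lo = thr1[y1[i]]
        a_hi = thr1[y1[i] + 1]
        b_lo = thr2[y2[i]]
        b_hi = thr2[y2[i] + 1]
        # draw-invariant linear indices: average collapses to one term
        if R == 1 or (eta1[i, 0] == eta1[i, R - 1]
                      and eta2[i, 0] == eta2[i, R - 1]):
            e1 = eta1[i, 0]
            e2 = eta2[i, 0]
            if fast:
                p = _rect_pre(a_lo - e1, a_hi - e1, b_lo - e2, b_hi - e2,
                              rho, sn, csinv, ww, asr)
            else:
                p = rect_scalar(a_lo - e1, a_hi - e1, b_lo - e2, b_hi - e2,
                                rho)
        else:
            acc = 0.0
            if fast:
                for r in range(R):
                    acc += _rect_pre(a_lo - eta1[i, r], a_hi - eta1[i, r],
                                     b_lo - eta2[i, r], b_hi - eta2[i, r],
                                     rho, sn, csinv, ww, asr)
            else:
                for r in range(R):
                    acc += rect_scalar(a_lo - eta1[i, r], a_hi - eta1[i, r],
                                       b_lo - eta2[i, r], b_hi - eta2[i, r],
                                       rho)
            p = acc / R
        if p < floor:
            p = floor
            clamped += 1
        total += math.log(p)
    return total, clamped
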