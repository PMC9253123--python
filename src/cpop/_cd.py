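"""Cyclic coordinate-descent kernel for penalised weighted least squares.

This is the inner engine behind every penalised fit in the package.  All
GLM families are reduced to iteratively reweighted least squares; each
quadratic subproblem

    minimise_{b0, beta}  0.5 * sum_i v_i (z_i - b0 - x_i . beta)^2
                         + lam * sum_j f_j * (a*|beta_j| + 0.5*(1-a)*beta_j^2)

is solved here by cyclic coordinate descent with an active-set strategy:
full sweeps over all features alternate with sweeps restricted to the
currently non-zero set until the largest coefficient update falls below
`tol` (on the standardised scale).  Columns of X are expected to be
standardised by the caller; `excluded` marks columns that must stay at
exactly zero (constant columns, or penalty factors so large the feature is
effectively banned).
"""

import numpy as np
from numba import njit

__all__ = ["cd_wls"]


@njit(cache=True, fastmath=False)
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True, fastmath=False)
def cd_wls(X, v, z, beta, b0_box, lam, alpha, pf, excluded, fit_intercept,
           tol, max_passes, obj_hist):
    """Solve one penalised weighted least-squares problem in place.

    Parameters
    ----------
    X : (n, q) standardised design
    v : (n,) observation weights (not renormalised here)
    z : (n,) working response
    beta : (q,) warm-start coefficients, overwritten with the solution
    b0_box : (1,) intercept in a length-1 array, overwritten
    lam, alpha : penalty level and elastic-net mixing
    pf : (q,) penalty factors (already rescaled to mean one by the caller)
    excluded : (q,) boolean, features pinned to zero
    fit_intercept : boolean
    tol : convergence threshold on the largest coefficient update
    max_passes : cap on coordinate sweeps
    obj_hist : (max_passes,) array; filled with the objective after each
        sweep (unused tail stays at NaN)

    Returns
    -------
    (n_passes, converged_flag)
    """
    n, q = X.shape
    b0 = b0_box[0]

    vsum = 0.0
    for i in range(n):
        vsum += v[i]

    xv = np.empty(q)
    for j in range(q):
        s = 0.0
        for i in range(n):
            s += v[i] * X[i, j] * X[i, j]
        xv[j] = s

    # residual r_i = z_i - b0 - X_i . beta
    r = np.empty(n)
    for i in range(n):
        s = z[i] - b0
        for j in range(q):
            if beta[j] != 0.0:
                s -= X[i, j] * beta[j]
        r[i] = s

    obj_hist[:] = np.nan
    npass = 0
    converged = False
    while npass < max_passes:
        # --- full sweep over all features ---
        npass += 1
        dmax = 0.0
        for j in range(q):
            if excluded[j]:
                continue
            bj = beta[j]
            g = 0.0
            for i in range(n):
                g += v[i] * X[i, j] * r[i]
            num = g + xv[j] * bj
            denom = xv[j] + lam * (1.0 - alpha) * pf[j]
            if denom <= 0.0:
                continue
            bnew = _soft(num, lam * alpha * pf[j]) / denom
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * X[i, j]
                beta[j] = bnew
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
        if fit_intercept and vsum > 0.0:
            g = 0.0
            for i in range(n):
                g += v[i] * r[i]
            d = g / vsum
            if d != 0.0:
                b0 += d
                for i in range(n):
                    r[i] -= d
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
        obj_hist[npass - 1] = _objective(v, r, beta, lam, alpha, pf)
        if dmax < tol:
            converged = True
            break

        # --- inner sweeps over the active set ---
        while npass < max_passes:
            npass += 1
            dmax = 0.0
            for j in range(q):
                if excluded[j] or beta[j] == 0.0:
                    continue
                bj = beta[j]
                g = 0.0
                for i in range(n):
                    g += v[i] * X[i, j] * r[i]
                num = g + xv[j] * bj
                denom = xv[j] + lam * (1.0 - alpha) * pf[j]
                if denom <= 0.0:
                    continue
                bnew = _soft(num, lam * alpha * pf[j]) / denom
                d = bnew - bj
                if d != 0.0:
                    for i in range(n):
                        r[i] -= d * X[i, j]
                    beta[j] = bnew
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            if fit_intercept and vsum > 0.0:
                g = 0.0
                for i in range(n):
                    g += v[i] * r[i]
                d = g / vsum
                if d != 0.0:
                    b0 += d
                    for i in range(n):
                        r[i] -= d
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            obj_hist[npass - 1] = _objective(v, r, beta, lam, alpha, pf)
            if dmax < tol:
                break

    b0_box[0] = b0
    return npass, converged


@njit(cache=True, fastmath=False)
def _objective(v, r, beta, lam, alpha, pf):
    n = r.shape[0]
    q = beta.shape[0]
    loss = 0.0
    for i in range(n):
        loss += 0.5 * v[i] * r[i] * r[i]
    pen = 0.0
    for j in range(q):
        b = beta[j]
        pen += pf[j] * (alpha * abs(b) + 0.5 * (1.0 - alpha) * b * b)
    return loss + lam * pen
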