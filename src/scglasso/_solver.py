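"""Numba kernel for the element-wise weighted graphical lasso.

Block coordinate descent in the style of Friedman/Hastie/Tibshirani:
the current working covariance ``W`` starts at ``S`` (the diagonal is
never penalized, so ``W_jj = S_jj`` throughout) and each column update
solves a lasso subproblem by cyclic coordinate descent with per-entry
penalties ``Pen_ij``.  The precision matrix is reassembled from the
column regression coefficients after every sweep so that convergence
can be monitored directly on ``Theta``.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def cd_glasso(S, Pen, tol, max_iter, W, B):
    """Solve max_Theta logdet(Theta) - tr(S Theta) - sum_ij Pen_ij |Theta_ij|.

    ``Pen`` must be symmetric with a zero diagonal.  ``W`` (working
    covariance, start at a copy of ``S``) and ``B`` ((p-1) x p column
    regression coefficients, start at zero) are updated in place, which
    allows warm starts along a lambda path.  Returns
    ``(Theta, n_sweeps, converged)``.
    """
    p = S.shape[0]
    Theta = np.zeros((p, p))
    for j in range(p):
        Theta[j, j] = 1.0 / S[j, j]
    Theta_old = Theta.copy()

    # off-diagonal scale of S sets the absolute tolerance of the lasso loop
    smax = 0.0
    for a in range(p):
        for b in range(p):
            if a != b and abs(S[a, b]) > smax:
                smax = abs(S[a, b])
    if smax <= 0.0:
        smax = 1.0
    inner_tol = tol * smax

    idx = np.empty(p - 1, np.int64)
    V = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    r12 = np.empty(p - 1)

    converged = False
    n_sweeps = 0
    for _sweep in range(max_iter):
        n_sweeps += 1
        for j in range(p):
            k = 0
            for i in range(p):
                if i != j:
                    idx[k] = i
                    k += 1
            for a in range(p - 1):
                ia = idx[a]
                s12[a] = S[ia, j]
                r12[a] = Pen[ia, j]
                for b in range(p - 1):
                    V[a, b] = W[ia, idx[b]]

            beta = B[:, j].copy()
            u = V @ beta
            for _it in range(200):
                dmax = 0.0
                for i in range(p - 1):
                    z = s12[i] - u[i] + V[i, i] * beta[i]
                    az = abs(z) - r12[i]
                    if az > 0.0:
                        bnew = np.sign(z) * az / V[i, i]
                    else:
                        bnew = 0.0
                    d = bnew - beta[i]
                    if d != 0.0:
                        for a in range(p - 1):
                            u[a] += V[a, i] * d
                        beta[i] = bnew
                        if abs(d) > dmax:
                            dmax = abs(d)
                if dmax <= inner_tol:
                    break
            for a in range(p - 1):
                B[a, j] = beta[a]
                W[idx[a], j] = u[a]
                W[j, idx[a]] = u[a]

        # rebuild Theta from the column regressions
        for j in range(p):
            k = 0
            dot = 0.0
            for i in range(p):
                if i != j:
                    dot += W[i, j] * B[k, j]
                    k += 1
            tjj = 1.0 / (W[j, j] - dot)
            Theta[j, j] = tjj
            k = 0
            for i in range(p):
                if i != j:
                    Theta[i, j] = -B[k, j] * tjj
                    k += 1

        tmax = 0.0
        dmax = 0.0
        for a in range(p):
            for b in range(p):
                if abs(Theta[a, b]) > tmax:
                    tmax = abs(Theta[a, b])
                if abs(Theta[a, b] - Theta_old[a, b]) > dmax:
                    dmax = abs(Theta[a, b] - Theta_old[a, b])
        Theta_old[:, :] = Theta
        if dmax <= tol * max(tmax, 1e-300):
            converged = True
            break

    # exact symmetrization; keep exact zeros (both halves share support)
    for a in range(p):
        for b in range(a + 1, p):
            if Theta[a, b] == 0.0 or Theta[b, a] == 0.0:
                m = 0.0
            else:
                m = 0.5 * (Theta[a, b] + Theta[b, a])
            Theta[a, b] = m
            Theta[b, a] = m
    return Theta, n_sweeps, converged
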