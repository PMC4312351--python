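"""Slow reference solver for the weighted graphical lasso.

Proximal-gradient ascent on the penalized log-likelihood with a
positive-definiteness-preserving backtracking line search.  This is an
algorithmically independent route to the same optimum as the
coordinate-descent solver in :mod:`scglasso.glasso` and exists purely
for verification; it is orders of magnitude slower and should only be
run on small problems.
"""

from __future__ import annotations

import numpy as np

__all__ = ["prox_gradient_glasso"]


def _soft(x: np.ndarray, thr: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.clip(np.abs(x) - thr, 0.0, None)


def _is_pd(A: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(A)
        return True
    except np.linalg.LinAlgError:
        return False


def prox_gradient_glasso(
    S: np.ndarray,
    lam: float,
    W: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Minimise ``-logdet(Theta) + tr(S Theta) + lam * sum W_ij |Theta_ij|``.

    ``W`` defaults to ones off the diagonal; the diagonal is never
    penalized.  Returns the estimated precision matrix.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if W is None:
        W = np.ones((p, p))
        np.fill_diagonal(W, 0.0)
    thr_base = lam * np.asarray(W, dtype=float)

    Theta = np.diag(1.0 / np.diag(S))
    step = 1.0 / max(np.linalg.eigvalsh(S)[-1] ** 2, 1e-12)
    for _ in range(max_iter):
        Sigma = np.linalg.inv(Theta)
        grad = S - Sigma  # gradient of the smooth part
        t = step
        while True:
            cand = _soft(Theta - t * grad, t * thr_base)
            cand = (cand + cand.T) / 2.0
            if _is_pd(cand):
                break
            t /= 2.0
            if t < 1e-18:
                raise RuntimeError("line search failed to find a PD iterate")
        delta = np.max(np.abs(cand - Theta))
        Theta = cand
        if delta <= tol * max(np.max(np.abs(Theta)), 1e-300):
            break
    return Theta
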