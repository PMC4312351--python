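"""Penalized Gaussian precision-matrix estimation.

Implements the three flavours of the graphical lasso used for
envelope-connectivity estimation:

``GL``
    the plain graphical lasso — a single regularisation parameter
    ``lam`` applied uniformly to all off-diagonal precision entries;
``GLa``
    the functionally adaptive variant — per-entry penalty weights
    ``W_ij = 1 / |S_ij|`` derived from the sample covariance, so weakly
    covarying pairs are penalized more strongly;
``GLd``
    the structurally adaptive variant — weights ``W_ij = 1 / FD_ij``
    derived from tractography fiber densities, so connections without
    anatomical support are penalized more strongly (guided, but not
    hard-constrained, by the structural network).

All variants maximise ``logdet(Theta) - tr(S Theta) - lam * sum_{i!=j}
W_ij |Theta_ij|`` over positive-definite ``Theta``; the diagonal is not
penalized.  Weight matrices are rescaled to unit mean off-diagonal
weight so that ``lam`` is comparable across variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._solver import cd_glasso
from .matrices import ConnectivityMatrix

__all__ = [
    "GlassoSolution",
    "sample_covariance",
    "glasso_objective",
    "uniform_weights",
    "functional_weights",
    "structural_weights",
    "weights_for_mode",
    "glasso_fit",
    "precision_density",
    "kkt_residual",
]

#: Raw penalty weight assigned to a zero denominator (absent tract or zero
#: covariance), as a multiple of the largest finite raw weight.  Large but
#: finite: absent connections are strongly discouraged, never forbidden.
ZERO_DENOM_CAP_FACTOR = 10.0


@dataclass(frozen=True)
class GlassoSolution:
    """A fitted sparse precision matrix with its diagnostics."""

    theta: ConnectivityMatrix
    lam: float
    weight_mode: str
    objective: float
    density: float
    n_iter: int
    converged: bool


def sample_covariance(X, labels=None) -> ConnectivityMatrix:
    """Maximum-likelihood sample covariance ``S = X'X / T``.

    ``X`` is a T x p matrix of envelope samples (rows = time points).
    Columns are mean-centered first; the ML denominator ``T`` matches
    the Gaussian log-likelihood used downstream for BIC.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D time-by-region matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    T = X.shape[0]
    if T < 2:
        raise ValueError("need at least two time points")
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / T
    S = (S + S.T) / 2.0
    return ConnectivityMatrix(S, labels or (), "covariance")


def glasso_objective(
    theta: ConnectivityMatrix,
    S: ConnectivityMatrix,
    lam: float,
    W: ConnectivityMatrix | None = None,
) -> float:
    """Penalized log-likelihood criterion (up to constants).

    ``logdet(Theta) - tr(S Theta) - lam * sum_{i!=j} W_ij |Theta_ij|``.
    With ``W=None`` all off-diagonal weights are 1 (the GL case).
    """
    Th = theta.values
    sign, logdet = np.linalg.slogdet(Th)
    if sign <= 0:
        raise ValueError("theta must be positive definite")
    penalty_weights = _weight_values(W, theta.p)
    penalty = lam * float(np.sum(penalty_weights * np.abs(Th)))
    return float(logdet - np.trace(S.values @ Th) - penalty)


def _weight_values(W: ConnectivityMatrix | None, p: int) -> np.ndarray:
    if W is None:
        vals = np.ones((p, p))
        np.fill_diagonal(vals, 0.0)
        return vals
    if W.p != p:
        raise ValueError("weight matrix size mismatch")
    return W.values


def _capped_inverse_weights(denom: np.ndarray, labels) -> ConnectivityMatrix:
    """1/denom off-diagonal weights with the zero-denominator cap and
    mean-1 rescaling shared by GLa and GLd."""
    p = denom.shape[0]
    off = ~np.eye(p, dtype=bool)
    raw = np.zeros((p, p))
    with np.errstate(divide="ignore"):
        raw[off] = 1.0 / np.abs(denom[off])
    finite = np.isfinite(raw) & off
    if not finite.any():
        raw[off] = 1.0
    else:
        cap = ZERO_DENOM_CAP_FACTOR * raw[finite].max()
        raw[off & ~np.isfinite(raw)] = cap
    raw[off] /= raw[off].mean()
    np.fill_diagonal(raw, 0.0)
    raw = (raw + raw.T) / 2.0
    return ConnectivityMatrix(raw, labels, "weights")


def uniform_weights(p: int, labels=()) -> ConnectivityMatrix:
    """Constant off-diagonal weights (the non-adaptive GL penalty)."""
    vals = np.ones((p, p))
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(vals, labels, "weights")


def functional_weights(S: ConnectivityMatrix) -> ConnectivityMatrix:
    """GLa weights ``W_ij = 1/|S_ij|`` from the sample covariance.

    Zero covariances receive a large finite cap; weights are rescaled
    to unit mean off-diagonal weight.
    """
    if S.role != "covariance":
        raise ValueError("functional weights require a covariance matrix")
    return _capped_inverse_weights(S.values, S.labels)


def structural_weights(FD: ConnectivityMatrix) -> ConnectivityMatrix:
    """GLd weights ``W_ij = 1/FD_ij`` from tractography fiber densities.

    Absent tracts (``FD_ij = 0``) receive a large finite cap so the
    structural network guides, but does not hard-constrain, the
    estimated support.  Weights are rescaled to unit mean.
    """
    if FD.role != "fiber_density":
        raise ValueError("structural weights require a fiber-density matrix")
    off = ~np.eye(FD.p, dtype=bool)
    if not np.any(FD.values[off] > 0):
        raise ValueError("fiber-density matrix is all zero: no structural information")
    return _capped_inverse_weights(FD.values, FD.labels)


def weights_for_mode(
    mode: str,
    S: ConnectivityMatrix,
    fd: ConnectivityMatrix | None = None,
) -> ConnectivityMatrix:
    """Penalty weights for ``mode`` in {"GL", "GLa", "GLd"}."""
    if mode == "GL":
        return uniform_weights(S.p, S.labels)
    if mode == "GLa":
        return functional_weights(S)
    if mode == "GLd":
        if fd is None:
            raise ValueError("GLd requires a fiber-density matrix")
        return structural_weights(fd)
    raise ValueError(f"unknown weight mode {mode!r}")


def precision_density(theta_values: np.ndarray) -> float:
    """Fraction of strictly-upper-triangular entries that are nonzero.

    Entries with ``|Theta_ij| <= 1e-8 * max_i Theta_ii`` count as zero,
    guarding against round-off on top of the solver's exact zeros.
    """
    p = theta_values.shape[0]
    if p < 2:
        return 0.0
    zero_tol = 1e-8 * np.max(np.diag(theta_values))
    iu = np.triu_indices(p, k=1)
    return float(np.mean(np.abs(theta_values[iu]) > zero_tol))


def glasso_fit(
    S: ConnectivityMatrix,
    lam: float,
    W: ConnectivityMatrix | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    weight_mode: str | None = None,
    state: tuple[np.ndarray, np.ndarray] | None = None,
) -> GlassoSolution:
    """Fit the (adaptive) graphical lasso by block coordinate descent.

    Parameters
    ----------
    S
        Sample covariance.
    lam
        Non-negative regularisation parameter.  ``lam = 0`` requires an
        invertible ``S`` and returns the unpenalized MLE ``S^{-1}``.
    W
        Per-entry penalty weights (zero diagonal).  ``None`` means the
        uniform GL penalty.
    tol
        Convergence threshold on the relative max-norm change of
        ``Theta`` between sweeps.
    max_iter
        Maximum number of coordinate-descent sweeps; on exhaustion the
        current iterate is returned with ``converged=False`` and a
        warning.
    state
        Optional warm-start state ``(working_covariance, coefficients)``
        from a previous fit on the same ``S`` (updated in place); used
        to accelerate lambda paths.
    """
    if S.role != "covariance":
        raise ValueError("glasso_fit requires a covariance matrix")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    penalty_weights = _weight_values(W, S.p)
    if np.any(np.diag(penalty_weights) != 0):
        raise ValueError("penalty weights must have a zero diagonal")
    if lam == 0.0:
        eigvals = np.linalg.eigvalsh(S.values)
        if eigvals[0] <= 1e-12 * max(eigvals[-1], 1e-300):
            raise ValueError("lam=0 requires an invertible covariance matrix")

    Pen = np.ascontiguousarray(lam * penalty_weights)
    if state is None:
        state = (np.array(S.values), np.zeros((S.p - 1, S.p)))
    theta_vals, n_iter, converged = cd_glasso(
        np.ascontiguousarray(S.values), Pen, tol, max_iter, state[0], state[1]
    )
    if not converged:
        warnings.warn(
            f"glasso did not converge in {max_iter} sweeps (lam={lam:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    theta = ConnectivityMatrix(theta_vals, S.labels, "precision")
    mode = weight_mode or ("GL" if W is None else "custom")
    return GlassoSolution(
        theta=theta,
        lam=float(lam),
        weight_mode=mode,
        objective=glasso_objective(theta, S, lam, W),
        density=precision_density(theta_vals),
        n_iter=int(n_iter),
        converged=bool(converged),
    )


def kkt_residual(
    theta: ConnectivityMatrix,
    S: ConnectivityMatrix,
    lam: float,
    W: ConnectivityMatrix | None = None,
) -> float:
    """Maximum violation of the stationarity conditions at ``theta``.

    For nonzero off-diagonal entries the subgradient condition is
    ``S_ij - [Theta^{-1}]_ij + lam W_ij sign(Theta_ij) = 0``; for zero
    entries ``|S_ij - [Theta^{-1}]_ij| <= lam W_ij``.  The diagonal is
    unpenalized, so ``S_ii = [Theta^{-1}]_ii`` at the optimum.
    """
    Th = theta.values
    Sigma = np.linalg.inv(Th)
    Wv = lam * _weight_values(W, theta.p)
    G = S.values - Sigma
    zero_tol = 1e-8 * np.max(np.diag(Th))
    nz = np.abs(Th) > zero_tol
    res_nz = np.abs(G + Wv * np.sign(Th))[nz]
    res_z = np.clip(np.abs(G) - Wv, 0.0, None)[~nz]
    out = 0.0
    if res_nz.size:
        out = max(out, float(res_nz.max()))
    if res_z.size:
        out = max(out, float(res_z.max()))
    return out
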