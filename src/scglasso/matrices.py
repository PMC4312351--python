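"""Labelled symmetric connectivity matrices.

A :class:`ConnectivityMatrix` is the common container for every square
region-by-region quantity in the pipeline: sample covariances ``S``,
precision (inverse covariance) matrices ``Theta``, tractography-derived
fiber-density matrices ``FD`` and penalty-weight matrices ``W``.  The
``role`` field records which of these the values represent and drives
role-specific validation (positive definiteness for precisions,
non-negativity and a zero diagonal for fiber densities and weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ConnectivityMatrix", "default_labels"]

#: Relative tolerance for the symmetry check.
SYMMETRY_RTOL = 1e-10

_ROLES = ("covariance", "precision", "fiber_density", "weights")


def default_labels(p: int) -> tuple[str, ...]:
    """Generate placeholder region labels ``region_01 .. region_p``."""
    width = max(2, len(str(p)))
    return tuple(f"region_{i + 1:0{width}d}" for i in range(p))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ``p x p`` matrix with ordered region labels and a role.

    Parameters
    ----------
    values
        Square real matrix.  Must be symmetric to within a relative
        tolerance of ``1e-10``; it is symmetrized exactly on construction.
    labels
        Ordered region names, one per row/column.
    role
        One of ``"covariance"`` (positive semidefinite), ``"precision"``
        (positive definite), ``"fiber_density"`` or ``"weights"`` (both
        non-negative with zero diagonal).
    """

    values: np.ndarray
    labels: tuple[str, ...] = field(default=())
    role: str = "covariance"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"expected a square matrix, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(f"non-finite entry at ({i}, {j})")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {_ROLES}")

        scale = np.max(np.abs(values)) or 1.0
        if np.max(np.abs(values - values.T)) > SYMMETRY_RTOL * scale:
            raise ValueError("matrix is not symmetric within tolerance")
        values = (values + values.T) / 2.0

        labels = tuple(self.labels) if self.labels else default_labels(values.shape[0])
        if len(labels) != values.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for a {values.shape[0]}-region matrix"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")

        if self.role == "covariance":
            eigvals = np.linalg.eigvalsh(values)
            if eigvals[0] < -1e-8 * max(eigvals[-1], 0.0):
                raise ValueError("covariance matrix is not positive semidefinite")
        elif self.role == "precision":
            try:
                np.linalg.cholesky(values)
            except np.linalg.LinAlgError:
                raise ValueError("precision matrix is not positive definite") from None
        else:  # fiber_density / weights
            if np.any(values < 0):
                raise ValueError(f"{self.role} matrix must be non-negative")
            if np.any(np.diag(values) != 0):
                raise ValueError(f"{self.role} matrix must have a zero diagonal")

        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def p(self) -> int:
        """Number of regions."""
        return self.values.shape[0]

    def with_role(self, role: str) -> "ConnectivityMatrix":
        """Return the same matrix re-validated under a different role."""
        return ConnectivityMatrix(np.array(self.values), self.labels, role)

    def reordered(self, labels: Sequence[str]) -> "ConnectivityMatrix":
        """Return a copy with rows/columns permuted into ``labels`` order."""
        labels = tuple(labels)
        if set(labels) != set(self.labels):
            raise ValueError("label sets do not match")
        idx = [self.labels.index(lab) for lab in labels]
        return ConnectivityMatrix(self.values[np.ix_(idx, idx)], labels, self.role)

    def upper_triangle(self) -> np.ndarray:
        """Strictly upper-triangular entries in row-major order."""
        iu = np.triu_indices(self.p, k=1)
        return self.values[iu]
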