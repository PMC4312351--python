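"""Fiber-density matrices from tractography tract counts.

The structural connection between regions *i* and *j* is quantified as
the fiber density ``FD_ij = (n_ij / N) * 2 / (V_i + V_j)``: the share of
all streamlines touching both regions, normalized by the average volume
of the two regions to control for differences in node size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrices import ConnectivityMatrix

__all__ = ["TractCountTable", "fiber_density", "group_density_threshold"]


@dataclass(frozen=True)
class TractCountTable:
    """Streamline counts between region pairs plus region volumes.

    ``counts[i, j]`` is the number of streamlines touching both regions
    *i* and *j*; ``total`` is the total streamline count ``N`` of the
    tractography; ``volumes`` are region volumes in mm^3.
    """

    counts: np.ndarray
    total: int
    volumes: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        volumes = np.asarray(self.volumes, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        if not np.array_equal(counts, counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(counts) != 0):
            raise ValueError("counts must have a zero diagonal")
        if self.total <= 0:
            raise ValueError("total streamline count must be positive")
        iu = np.triu_indices(counts.shape[0], k=1)
        if counts[iu].sum() > self.total:
            raise ValueError("upper-triangle count sum exceeds the total")
        if volumes.shape != (counts.shape[0],) or np.any(volumes <= 0):
            raise ValueError("volumes must be positive, one per region")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "volumes", volumes)


def fiber_density(table: TractCountTable) -> ConnectivityMatrix:
    """``FD_ij = (n_ij / N) * 2 / (V_i + V_j)``, zero diagonal.

    The support of FD equals the support of the raw counts: a pair is
    structurally connected exactly when at least one streamline touches
    both regions.
    """
    V = table.volumes
    fd = (table.counts / table.total) * (2.0 / (V[:, None] + V[None, :]))
    np.fill_diagonal(fd, 0.0)
    return ConnectivityMatrix(fd, table.labels, "fiber_density")


def group_density_threshold(fd_list: Sequence[ConnectivityMatrix]) -> float:
    """Density of the group-average structural network.

    Returns the fraction of strictly-upper-triangular entries of the
    elementwise mean fiber-density matrix that are nonzero — the
    data-driven cap on functional network density (about 20 % for
    cortical connectomes).
    """
    if len(fd_list) == 0:
        raise ValueError("need at least one fiber-density matrix")
    labels = fd_list[0].labels
    for fd in fd_list:
        if fd.labels != labels:
            raise ValueError("fiber-density matrices have mismatched labels")
    mean_fd = np.mean([fd.values for fd in fd_list], axis=0)
    iu = np.triu_indices(mean_fd.shape[0], k=1)
    return float(np.mean(mean_fd[iu] != 0))
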