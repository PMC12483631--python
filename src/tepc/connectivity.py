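"""Kernel connectivity matrices and the multiscale Laplacian filtration.

A network of N nodes (atoms, cells, signals, images) is encoded as a
symmetric, zero-row-sum connectivity matrix A whose off-diagonal entries
decay with inter-node distance (cutoff / generalized-exponential /
power-law kernels) or are given by absolute Pearson correlations.  A
filtration of the weighted Laplacian at p evenly spaced thresholds then
yields an ordered family of binarized graph Laplacians L_1 … L_p, the
multiscale couplings that drive the coupled chaotic systems downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PointCloud",
    "KernelSpec",
    "ConnectivityMatrix",
    "LaplacianFamily",
    "pairwise_distances",
    "build_connectivity",
    "correlation_connectivity",
    "laplacian_filtration",
]

KernelFamily = Literal["cutoff", "exponential", "power"]


@dataclass
class PointCloud:
    """N points in R^n with node identifiers.

    Parameters
    ----------
    coords
        (N, n) array of coordinates; arbitrary length units.
    ids
        Node identifiers; defaults to ``0 … N-1``.
    """

    coords: np.ndarray
    ids: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 1:
            self.coords = self.coords[:, None]
        if self.coords.ndim != 2 or self.coords.shape[0] < 1:
            raise ValueError("coords must be a non-empty (N, n) array")
        bad = ~np.isfinite(self.coords).all(axis=1)
        if bad.any():
            raise ValueError(
                f"non-finite coordinates at node(s) {np.flatnonzero(bad).tolist()}"
            )
        if self.ids is None:
            self.ids = list(range(self.coords.shape[0]))
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("ids length must match number of coordinate rows")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class KernelSpec:
    """Radial connectivity kernel.

    family
        ``cutoff`` (1 inside sigma, 0 outside), ``exponential``
        (exp(−d^κ / (κ σ^κ))) or ``power`` ((d/σ)^(−ν)).
    sigma
        Characteristic distance σ > 0, shared by all node pairs.
    kappa
        Positive integer order of the generalized exponential.
    nu
        Power-law exponent, ν > 1.
    """

    family: KernelFamily = "exponential"
    sigma: float = 3.0
    kappa: int = 1
    nu: float = 2.0

    def __post_init__(self) -> None:
        if self.family not in ("cutoff", "exponential", "power"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")
        if self.family == "exponential" and (
            int(self.kappa) != self.kappa or self.kappa < 1
        ):
            raise ValueError("kappa must be a positive integer")
        if self.family == "power" and not (self.nu > 1):
            raise ValueError("nu must exceed 1 for the power kernel")


@dataclass
class ConnectivityMatrix:
    """Symmetric zero-row-sum coupling matrix A.

    Off-diagonal entries are non-negative coupling weights; each diagonal
    entry equals minus the sum of its row's off-diagonal entries, so rows
    sum to zero (the diffusive-coupling convention).
    """

    a: np.ndarray
    kernel: Union[KernelSpec, str]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = self.a.shape[0]
        if self.a.shape != (n, n):
            raise ValueError("connectivity matrix must be square")

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Off-diagonal weights with a zeroed diagonal."""
        w = self.a.copy()
        np.fill_diagonal(w, 0.0)
        return w


@dataclass
class LaplacianFamily:
    """Ordered multiscale family of binarized graph Laplacians.

    ``laplacians[k-1]`` is L_k: off-diagonals in {0, −1}, diagonal equal
    to the node degree, rows summing to zero.  Edge sets nest: scale k+1
    retains a subset of scale k's edges, and L_p is always empty (the
    final threshold equals the largest weight and the comparison is a
    non-strict ``≤``).
    """

    laplacians: list
    p: int
    thresholds: list
    lmin: float
    lmax: float
    d_range: float

    def __iter__(self):
        return iter(self.laplacians)

    def __len__(self) -> int:
        return len(self.laplacians)

    def edge_sets(self) -> list:
        """Retained undirected edges per scale as sets of (i, j), i < j."""
        out = []
        for lk in self.laplacians:
            ii, jj = np.nonzero(np.triu(lk, 1))
            out.append(set(zip(ii.tolist(), jj.tolist())))
        return out


def pairwise_distances(cloud: PointCloud) -> np.ndarray:
    """Euclidean distance matrix between all node pairs.

    Returns a symmetric (N, N) array with zero diagonal.
    """
    if cloud.n_nodes == 1:
        return np.zeros((1, 1))
    return squareform(pdist(cloud.coords, metric="euclidean"))


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite entries")
    if (d < 0).any():
        raise ValueError("distance matrix contains negative entries")
    return d


def build_connectivity(d: np.ndarray, kernel: KernelSpec) -> ConnectivityMatrix:
    """Kernel connectivity matrix from a distance matrix.

    Off-diagonal entries follow the selected kernel family evaluated at
    d_ij; the diagonal is set to minus the row sum of off-diagonals.

    Raises
    ------
    ZeroDivisionError
        For the power kernel when any off-diagonal distance is zero.
    """
    d = _check_distance_matrix(d)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    a = np.zeros((n, n))
    if kernel.family == "cutoff":
        a[off] = (d[off] <= kernel.sigma).astype(float)
    elif kernel.family == "exponential":
        k = float(kernel.kappa)
        a[off] = np.exp(-(d[off] ** k) / (k * kernel.sigma**k))
    else:  # power
        if n > 1 and (d[off] == 0).any():
            raise ZeroDivisionError(
                "power kernel undefined at zero off-diagonal distance"
            )
        a[off] = (d[off] / kernel.sigma) ** (-kernel.nu)
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(a, -a.sum(axis=1))
    return ConnectivityMatrix(a=a, kernel=kernel)


def correlation_connectivity(
    signals: np.ndarray, signed: bool = False
) -> ConnectivityMatrix:
    """Connectivity from pairwise Pearson correlations of signal channels.

    Parameters
    ----------
    signals
        (N, T) array, one channel per row, T ≥ 3 samples.
    signed
        If False (default) the coupling weight is |r_ij|; if True the raw
        signed correlation is kept (sensitivity analyses only).
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("signals must be an (N, T) array with T >= 3")
    var = x.var(axis=1)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        raise ValueError(
            f"correlation undefined: zero-variance channel(s) {dead.tolist()}"
        )
    r = np.corrcoef(x)
    a = r if signed else np.abs(r)
    a = np.array(a, dtype=float)
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(a, -a.sum(axis=1))
    return ConnectivityMatrix(a=a, kernel="correlation")


def laplacian_filtration(
    a: Union[ConnectivityMatrix, np.ndarray], p: int
) -> LaplacianFamily:
    """Threshold the weighted Laplacian at p evenly spaced levels.

    With off-diagonal weights l_ij (= A_ij), lmin/lmax their extremes and
    d = lmax − lmin, scale k ∈ {1…p} drops every edge whose weight
    satisfies l_ij ≤ (k/p)·d + lmin and keeps the rest with entry −1;
    the diagonal is the resulting node degree.  Ties at a threshold drop
    the edge (the comparison is exactly ``≤``), so scale p is empty.
    """
    if p < 1:
        raise ValueError("p must be a positive integer")
    w = a.off_diagonal() if isinstance(a, ConnectivityMatrix) else np.asarray(a, float)
    n = w.shape[0]
    if n < 2:
        raise ValueError("Laplacian filtration needs at least 2 nodes")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    off = ~np.eye(n, dtype=bool)
    lmax = float(w[off].max())
    lmin = float(w[off].min())
    d_range = lmax - lmin
    if d_range == 0.0:
        warnings.warn(
            "all off-diagonal weights identical; filtration is degenerate "
            "(every scale is empty)",
            RuntimeWarning,
            stacklevel=2,
        )
    laplacians = []
    thresholds = []
    for k in range(1, p + 1):
        # at k = p the threshold is lmax by definition; computing it as
        # lmin + d_range can round one ulp low and retain a spurious edge
        thr = lmax if k == p else (k / p) * d_range + lmin
        keep = off & (w > thr)
        lk = np.zeros((n, n), dtype=int)
        lk[keep] = -1
        np.fill_diagonal(lk, -lk.sum(axis=1))
        laplacians.append(lk)
        thresholds.append(thr)
    return LaplacianFamily(
        laplacians=laplacians,
        p=p,
        thresholds=thresholds,
        lmin=lmin,
        lmax=lmax,
        d_range=d_range,
    )
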