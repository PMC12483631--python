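"""Vietoris–Rips filtrations and simplicial persistent Laplacians.

A Vietoris–Rips filtration over a point cloud yields nested complexes
K_t (all simplices whose vertex set has pairwise distances within the
scale).  For a pair of scales t ≤ t+p the p-persistent q-boundary
operator restricts the boundary map of K_{t+p} to those q-chains whose
boundary already lies in K_t; the persistent Laplacian

    L_q^{t,p} = B_{q+1}^{t,p} (B_{q+1}^{t,p})^T + (B_q^t)^T B_q^t

is symmetric positive semidefinite.  Its kernel dimension equals the
persistent Betti number β_q^{t,p} (features of K_t still alive in
K_{t+p}), while its smallest nonzero eigenvalue tracks the geometric
("homotopic shape") evolution that homology alone cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "SimplicialFiltration",
    "PersistentLaplacianResult",
    "vietoris_rips",
    "boundary_matrix",
    "persistent_boundary",
    "persistent_laplacian",
    "persistent_betti",
    "spectral_curves",
]


@dataclass
class SimplicialFiltration:
    """A filtered simplicial complex.

    simplices is a list of ``(vertex_tuple, birth)`` with every face
    present at a birth no later than the simplex itself.  Simplices sort
    by (birth, dimension, lexicographic tuple).
    """

    vertices: list
    simplices: list
    max_dim: int

    def __post_init__(self) -> None:
        self.simplices = sorted(
            ((tuple(sorted(s)), float(b)) for s, b in self.simplices),
            key=lambda sb: (sb[1], len(sb[0]), sb[0]),
        )
        births = {s: b for s, b in self.simplices}
        for s, b in self.simplices:
            for face in combinations(s, len(s) - 1):
                if len(face) == 0:
                    continue
                if face not in births or births[face] > b:
                    raise ValueError(
                        f"face {face} of simplex {s} missing or born later"
                    )

    def simplices_at(self, t: float, q: int) -> list:
        """Sorted q-simplices of K_t (birth ≤ t)."""
        return sorted(s for s, b in self.simplices if len(s) == q + 1 and b <= t)

    def birth_values(self) -> np.ndarray:
        """Sorted distinct birth values in the filtration."""
        return np.unique([b for _, b in self.simplices])

    def to_text(self) -> str:
        """Plain-text export, one simplex per line: ``dim birth v0 v1 …``."""
        lines = [f"{len(s) - 1} {b:.17g} " + " ".join(map(str, s)) for s, b in self.simplices]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SimplicialFiltration":
        simplices = []
        max_dim = 0
        for line in text.strip().splitlines():
            parts = line.split()
            dim, birth = int(parts[0]), float(parts[1])
            verts = tuple(int(v) for v in parts[2 : 3 + dim])
            simplices.append((verts, birth))
            max_dim = max(max_dim, dim)
        vertices = sorted({v for s, _ in simplices for v in s})
        return cls(vertices=vertices, simplices=simplices, max_dim=max_dim)


@dataclass
class PersistentLaplacianResult:
    """Persistent Laplacian matrix, spectrum, and derived quantities."""

    matrix: np.ndarray
    eigenvalues: np.ndarray
    betti: int
    lambda_min_nonzero: float
    q: int
    t: float
    t_plus_p: float


def vietoris_rips(
    d: np.ndarray,
    alpha_max: float,
    max_dim: int = 2,
    diameter_convention: bool = False,
    allow_high_dim: bool = False,
) -> SimplicialFiltration:
    """Vietoris–Rips filtration of a finite metric space.

    A simplex on vertex set S is born at half the maximal pairwise
    distance within S (growing-balls radius convention; pass
    ``diameter_convention=True`` for birth at the distance itself).
    Only simplices with birth ≤ alpha_max and dim ≤ max_dim are kept.

    ``max_dim`` beyond 3 is refused unless ``allow_high_dim`` is set —
    the subset enumeration grows combinatorially.
    """
    if max_dim > 3 and not allow_high_dim:
        raise ValueError("max_dim > 3 unsupported (set allow_high_dim to override)")
    if not (alpha_max > 0):
        raise ValueError("alpha_max must be positive")
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    scale = 1.0 if diameter_convention else 0.5
    simplices = [((v,), 0.0) for v in range(n)]
    for dim in range(1, max_dim + 1):
        for s in combinations(range(n), dim + 1):
            idx = np.array(s)
            birth = scale * d[np.ix_(idx, idx)].max()
            if birth <= alpha_max:
                simplices.append((s, float(birth)))
    return SimplicialFiltration(
        vertices=list(range(n)), simplices=simplices, max_dim=max_dim
    )


def boundary_matrix(f: SimplicialFiltration, t: float, q: int) -> np.ndarray:
    """Matrix of the q-boundary operator of K_t.

    Rows are indexed by the sorted (q−1)-simplices of K_t, columns by
    the sorted q-simplices; the entry for (face, simplex) is (−1)^i
    where i is the position of the removed vertex.  B_0 maps to the
    zero space and is returned as a (0, #vertices) matrix.
    """
    if q < 0:
        raise ValueError("q must be nonnegative")
    if q > f.max_dim + 1:
        raise ValueError(f"q={q} exceeds max_dim+1={f.max_dim + 1}")
    cols = f.simplices_at(t, q)
    if q == 0:
        return np.zeros((0, len(cols)), dtype=int)
    rows = f.simplices_at(t, q - 1)
    row_index = {s: i for i, s in enumerate(rows)}
    b = np.zeros((len(rows), len(cols)), dtype=int)
    for j, s in enumerate(cols):
        for i in range(q + 1):
            face = s[:i] + s[i + 1 :]
            b[row_index[face], j] = (-1) ** i
    return b


def persistent_boundary(
    f: SimplicialFiltration, t: float, t_plus_p: float, q: int
) -> np.ndarray:
    """Matrix of the p-persistent q-boundary operator ð_q^{t,p}.

    Restricts ∂_q^{t+p} to the q-chains of K_{t+p} whose boundary lies
    in the span of the (q−1)-simplices of K_t, expressed against those
    simplices.  The restriction subspace is extracted as an orthonormal
    null-space basis of the "outside-K_t" rows, so the returned matrix
    is real-valued; the induced L_q^{t,p} spectrum does not depend on
    the basis choice.
    """
    if t > t_plus_p:
        raise ValueError("t must not exceed t_plus_p")
    b_full = boundary_matrix(f, t_plus_p, q)
    if q == 0:
        return b_full.astype(float)
    rows_tp = f.simplices_at(t_plus_p, q - 1)
    in_t = np.array([s in set(f.simplices_at(t, q - 1)) for s in rows_tp], dtype=bool)
    b_in = b_full[in_t].astype(float)
    b_out = b_full[~in_t].astype(float)
    if b_full.shape[1] == 0:
        return b_in
    if b_out.shape[0] == 0 or b_out.size == 0:
        return b_in
    basis = null_space(b_out)
    return b_in @ basis


def persistent_laplacian(
    f: SimplicialFiltration,
    t: float,
    t_plus_p: float,
    q: int,
    zero_tol_factor: float = 1e-8,
) -> PersistentLaplacianResult:
    """q-order p-persistent Laplacian of the pair K_t ⊆ K_{t+p}.

    betti counts eigenvalues below ``zero_tol_factor × (1 + λ_max)``
    (scale-invariant kernel detection); lambda_min_nonzero is the
    smallest eigenvalue at or above that tolerance, 0 if none.
    """
    n_q = len(f.simplices_at(t, q))
    if n_q == 0:
        return PersistentLaplacianResult(
            matrix=np.zeros((0, 0)),
            eigenvalues=np.zeros(0),
            betti=0,
            lambda_min_nonzero=0.0,
            q=q,
            t=t,
            t_plus_p=t_plus_p,
        )
    d_up = persistent_boundary(f, t, t_plus_p, q + 1)
    lap = d_up @ d_up.T
    if q >= 1:
        b_down = boundary_matrix(f, t, q).astype(float)
        lap = lap + b_down.T @ b_down
    lap = 0.5 * (lap + lap.T)
    eigs = np.linalg.eigvalsh(lap)
    eigs = np.where(np.abs(eigs) < 1e-14, 0.0, eigs)
    tol = zero_tol_factor * (1.0 + float(eigs[-1]))
    betti = int(np.sum(eigs < tol))
    nonzero = eigs[eigs >= tol]
    lam = float(nonzero[0]) if nonzero.size else 0.0
    return PersistentLaplacianResult(
        matrix=lap,
        eigenvalues=eigs,
        betti=betti,
        lambda_min_nonzero=lam,
        q=q,
        t=t,
        t_plus_p=t_plus_p,
    )


def persistent_betti(
    f: SimplicialFiltration, t: float, t_plus_p: float, q: int, exact: bool = False
) -> int:
    """Persistent Betti number via the rank identity.

    β_q^{t,p} = dim ker ∂_q^t − rank ð_{q+1}^{t,p}.  With ``exact=True``
    the two ranks are computed in rational arithmetic (sympy), intended
    for small validation instances.
    """
    b_q = boundary_matrix(f, t, q)
    n_q = b_q.shape[1]
    if n_q == 0:
        return 0
    if exact:
        import sympy

        rank_bq = sympy.Matrix(b_q).rank() if b_q.size else 0
        d_up = _persistent_boundary_exact(f, t, t_plus_p, q + 1)
        rank_up = d_up.rank() if d_up.shape[0] * d_up.shape[1] else 0
    else:
        # absolute tolerance: boundary entries are ±1 and the restriction
        # basis is orthonormal, so genuine singular values are O(1) while
        # a numerically-zero matrix carries only ~1e-16 noise
        rank_bq = np.linalg.matrix_rank(b_q, tol=1e-8) if b_q.size else 0
        d_up = persistent_boundary(f, t, t_plus_p, q + 1)
        rank_up = np.linalg.matrix_rank(d_up, tol=1e-8) if d_up.size else 0
    return int(n_q - rank_bq - rank_up)


def _persistent_boundary_exact(f, t, t_plus_p, q):
    """Rational-arithmetic ð_q^{t,p} (small instances; rank use only)."""
    import sympy

    b_full = boundary_matrix(f, t_plus_p, q)
    if q == 0:
        return sympy.Matrix(b_full)
    rows_tp = f.simplices_at(t_plus_p, q - 1)
    set_t = set(f.simplices_at(t, q - 1))
    in_t = [s in set_t for s in rows_tp]
    m = sympy.Matrix(b_full)
    b_in = m[[i for i, k in enumerate(in_t) if k], :]
    b_out = m[[i for i, k in enumerate(in_t) if not k], :]
    if b_out.rows == 0 or m.cols == 0:
        return b_in
    ns = b_out.nullspace()
    if not ns:
        return sympy.zeros(b_in.rows, 0)
    basis = sympy.Matrix.hstack(*ns)
    return b_in @ basis


def spectral_curves(
    f: SimplicialFiltration,
    q_list: Sequence[int],
    alpha_grid: Sequence[float],
):
    """Per-α table of (β_q^{α,0}, λ_q^{α,0}) across the filtration.

    Returns a pandas DataFrame with columns alpha, q, betti, lam — the
    harmonic (Betti) and first non-harmonic (smallest nonzero
    eigenvalue) spectral summaries at each grid scale.
    """
    import pandas as pd

    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size > 1 and not (np.diff(alpha_grid) > 0).all():
        raise ValueError("alpha_grid must be strictly increasing")
    rows = []
    for alpha in alpha_grid:
        for q in q_list:
            res = persistent_laplacian(f, alpha, alpha, q)
            rows.append(
                {"alpha": float(alpha), "q": int(q), "betti": res.betti,
                 "lam": res.lambda_min_nonzero}
            )
    return pd.DataFrame(rows)
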