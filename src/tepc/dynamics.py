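"""Networks of coupled Lorenz/Rossler oscillators.

Each node carries a 3-variable chaotic oscillator; nodes interact
diffusively through a symmetric zero-row-sum coupling matrix C scaled
by a global strength ε and a 3×3 inner coupling Γ (identity by
default):

    ds_i/dt = F(s_i) + ε Σ_j C_ij Γ s_j .

Because C has zero row sums, identical node states feel no coupling —
the synchronization manifold is invariant.  The coupling term is
evaluated in deviation form (against node 0's state), which is
algebraically identical for zero-row-sum C and keeps the manifold
invariant to the last bit in floating point: once all rows agree they
perform exactly the same arithmetic forever.

Explicit integrators: forward Euler, midpoint RK2, and classical RK4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from tepc.connectivity import ConnectivityMatrix

__all__ = [
    "OscillatorSpec",
    "CoupledSystem",
    "Trajectory",
    "DivergenceError",
    "oscillator_field",
    "coupled_field",
    "integrate",
    "perturbative_trajectory",
    "sync_error",
    "coupling_from_laplacian",
]

#: classical Lorenz parameters used throughout the prediction protocol
LORENZ_DEFAULTS = {"alpha": 10.0, "gamma": 60.0, "beta": 8.0 / 3.0}
#: Rossler parameters (a = b = 0.1, c = 4)
ROSSLER_DEFAULTS = {"a": 0.1, "b": 0.1, "c": 4.0}


class DivergenceError(RuntimeError):
    """Raised when a trajectory exceeds the divergence bound."""

    def __init__(self, step: int, magnitude: float):
        self.step = step
        self.magnitude = magnitude
        super().__init__(
            f"trajectory diverged at step {step} (max |state| = {magnitude:.3g})"
        )


@dataclass(frozen=True)
class OscillatorSpec:
    """Chaotic oscillator choice and parameters.

    Lorenz:  dx = α(y−x), dy = γx − y − xz, dz = xy − βz.
    Rossler: dx = −y−z,   dy = x + a y,     dz = b + z(x−c).
    """

    model: str = "lorenz"
    params: dict = field(default_factory=lambda: dict(LORENZ_DEFAULTS))

    def __post_init__(self) -> None:
        if self.model not in ("lorenz", "rossler"):
            raise ValueError(f"unknown oscillator model {self.model!r}")
        wanted = ("alpha", "gamma", "beta") if self.model == "lorenz" else ("a", "b", "c")
        missing = [k for k in wanted if k not in self.params]
        if missing:
            raise ValueError(f"{self.model} parameters missing: {missing}")
        if not all(np.isfinite(list(self.params.values()))):
            raise ValueError("oscillator parameters must be finite")

    @classmethod
    def lorenz(cls, alpha: float = 10.0, gamma: float = 60.0, beta: float = 8.0 / 3.0):
        return cls("lorenz", {"alpha": alpha, "gamma": gamma, "beta": beta})

    @classmethod
    def rossler(cls, a: float = 0.1, b: float = 0.1, c: float = 4.0):
        return cls("rossler", {"a": a, "b": b, "c": c})


def _vector_field(states: np.ndarray, spec: OscillatorSpec) -> np.ndarray:
    """Oscillator field applied along the last axis (…, 3)."""
    x, y, z = states[..., 0], states[..., 1], states[..., 2]
    out = np.empty_like(states)
    p = spec.params
    if spec.model == "lorenz":
        out[..., 0] = p["alpha"] * (y - x)
        out[..., 1] = p["gamma"] * x - y - x * z
        out[..., 2] = x * y - p["beta"] * z
    else:
        out[..., 0] = -y - z
        out[..., 1] = x + p["a"] * y
        out[..., 2] = p["b"] + z * (x - p["c"])
    return out


def oscillator_field(state: np.ndarray, spec: OscillatorSpec) -> np.ndarray:
    """Right-hand side of a single uncoupled oscillator at ``state``."""
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != 3:
        raise ValueError("state must have 3 components")
    if not np.isfinite(state).all():
        raise ValueError("state must be finite")
    return _vector_field(state, spec)


def coupling_from_laplacian(lk: np.ndarray) -> np.ndarray:
    """Diffusive coupling matrix from a binarized graph Laplacian.

    The filtration stores L_k in the graph-Laplacian sign convention
    (off-diagonal −1, diagonal +degree); the flow needs positive
    off-diagonal conductances with zero row sums, i.e. C = −L_k.
    """
    return -np.asarray(lk, dtype=float)


@dataclass
class CoupledSystem:
    """An oscillator species coupled through a zero-row-sum matrix."""

    spec: OscillatorSpec
    coupling: Union[np.ndarray, ConnectivityMatrix]
    epsilon: float = 1.0
    gamma_inner: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        c = self.coupling.a if isinstance(self.coupling, ConnectivityMatrix) else self.coupling
        c = np.asarray(c, dtype=float)
        n = c.shape[0]
        if c.shape != (n, n):
            raise ValueError("coupling matrix must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("coupling matrix must be symmetric")
        scale = max(1.0, float(np.abs(c).max()))
        if np.abs(c.sum(axis=1)).max() > 1e-9 * scale * n:
            raise ValueError("coupling matrix rows must sum to zero")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        self._c = c
        self._w = c.copy()
        np.fill_diagonal(self._w, 0.0)
        self._rs = -np.diag(c).copy()
        if self.gamma_inner is None:
            self._gamma = None
        else:
            g = np.asarray(self.gamma_inner, dtype=float)
            if g.shape != (3, 3):
                raise ValueError("gamma_inner must be 3x3")
            self._gamma = None if np.array_equal(g, np.eye(3)) else g

    @property
    def n_nodes(self) -> int:
        return self._c.shape[0]

    def field(self, states: np.ndarray) -> np.ndarray:
        """Coupled right-hand side for states shaped (…, N, 3)."""
        f = _vector_field(states, self.spec)
        if self.epsilon == 0.0:
            return f
        dev = states - states[..., :1, :]
        if self._gamma is not None:
            dev = dev @ self._gamma.T
        coup = self._w @ dev - self._rs[:, None] * dev
        return f + self.epsilon * coup


def coupled_field(states: np.ndarray, system: CoupledSystem) -> np.ndarray:
    """Coupled vector field at ``states`` (N, 3)."""
    states = np.asarray(states, dtype=float)
    if states.shape[-2] != system.n_nodes:
        raise ValueError(
            f"states have {states.shape[-2]} nodes, coupling expects {system.n_nodes}"
        )
    return system.field(states)


@dataclass
class Trajectory:
    """Recorded states of N coupled oscillators.

    states has shape (R, N, 3) where R is the number of recorded frames
    (every ``record_every``-th integration step, first and last always
    included); times are the matching integration times.
    """

    times: np.ndarray
    states: np.ndarray
    h: float
    scheme: str
    record_every: int = 1
    seed: Optional[int] = None

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]


_SCHEMES = ("euler", "rk2", "rk4")


def _step(f: Callable, y: np.ndarray, h: float, scheme: str) -> np.ndarray:
    if scheme == "euler":
        return y + h * f(y)
    if scheme == "rk2":  # midpoint rule
        k1 = f(y)
        return y + h * f(y + 0.5 * h * k1)
    k1 = f(y)
    k2 = f(y + 0.5 * h * k1)
    k3 = f(y + 0.5 * h * k2)
    k4 = f(y + h * k3)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _integrate_array(
    f: Callable,
    y0: np.ndarray,
    h: float,
    steps: int,
    scheme: str,
    record_every: int = 1,
    divergence_bound: float = 1e6,
    check_every: int = 25,
) -> tuple:
    """Generic explicit stepping on an arbitrarily shaped state array."""
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}")
    if not (h > 0) or steps < 1:
        raise ValueError("h must be positive and steps >= 1")
    y = np.array(y0, dtype=float)
    rec_idx = list(range(0, steps + 1, record_every))
    if rec_idx[-1] != steps:
        rec_idx.append(steps)
    out = np.empty((len(rec_idx),) + y.shape)
    out[0] = y
    pos = 1
    # overflow en route to the divergence check is expected and handled
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(1, steps + 1):
            y = _step(f, y, h, scheme)
            if step % check_every == 0 or step == steps:
                m = float(np.max(np.abs(y)))
                if not np.isfinite(m) or m > divergence_bound:
                    raise DivergenceError(step, m)
            if pos < len(rec_idx) and step == rec_idx[pos]:
                out[pos] = y
                pos += 1
    times = h * np.asarray(rec_idx, dtype=float)
    return times, out


def integrate(
    system: CoupledSystem,
    initial: np.ndarray,
    h: float,
    steps: int,
    scheme: str = "rk4",
    record_every: int = 1,
    divergence_bound: float = 1e6,
    seed: Optional[int] = None,
) -> Trajectory:
    """Evolve the coupled system from ``initial`` (N, 3) states.

    Raises :class:`DivergenceError` (with the offending step index) if
    any state magnitude exceeds ``divergence_bound``.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (system.n_nodes, 3):
        raise ValueError(f"initial must have shape ({system.n_nodes}, 3)")
    times, states = _integrate_array(
        system.field, initial, h, steps, scheme, record_every, divergence_bound
    )
    return Trajectory(
        times=times, states=states, h=h, scheme=scheme,
        record_every=record_every, seed=seed,
    )


def perturbative_trajectory(
    system: CoupledSystem,
    node: int,
    h: float,
    steps: int,
    scheme: str = "rk4",
    record_every: int = 1,
    first_variable_only: bool = False,
    divergence_bound: float = 1e6,
) -> Trajectory:
    """Perturbative probe of one node's embedded environment.

    The chosen node starts at unit state (all three variables 1, or
    only the first if ``first_variable_only``) while every other node
    rests at the origin equilibrium; the network is then integrated and
    the perturbed node's trajectory reflects its local connectivity.
    """
    n = system.n_nodes
    if not (0 <= node < n):
        raise ValueError(f"node index {node} out of range for {n} nodes")
    y0 = np.zeros((n, 3))
    y0[node] = [1.0, 0.0, 0.0] if first_variable_only else [1.0, 1.0, 1.0]
    return integrate(
        system, y0, h, steps, scheme, record_every, divergence_bound
    )


def sync_error(
    traj: Union[Trajectory, np.ndarray],
    subset: Optional[Sequence[int]] = None,
    subset_b: Optional[Sequence[int]] = None,
    chunk: int = 256,
) -> np.ndarray:
    """Mean pairwise Euclidean state distance at each recorded time.

    With ``subset`` only, averages over pairs within that node subset
    (partial-synchronization diagnosis); with ``subset_b`` as well,
    averages over cross pairs (i ∈ subset, j ∈ subset_b).
    """
    states = traj.states if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if states.ndim != 3:
        raise ValueError("states must have shape (T, N, 3)")
    if subset is not None and subset_b is not None:
        a = states[:, list(subset), :]
        b = states[:, list(subset_b), :]
        out = np.empty(states.shape[0])
        for lo in range(0, states.shape[0], chunk):
            hi = min(lo + chunk, states.shape[0])
            d = np.linalg.norm(a[lo:hi, :, None, :] - b[lo:hi, None, :, :], axis=-1)
            out[lo:hi] = d.mean(axis=(1, 2))
        return out
    if subset is not None:
        states = states[:, list(subset), :]
    n = states.shape[1]
    if n < 2:
        raise ValueError("sync_error needs at least 2 nodes")
    iu, ju = np.triu_indices(n, k=1)
    out = np.empty(states.shape[0])
    for lo in range(0, states.shape[0], chunk):
        hi = min(lo + chunk, states.shape[0])
        d = np.linalg.norm(states[lo:hi, iu, :] - states[lo:hi, ju, :], axis=-1)
        out[lo:hi] = d.mean(axis=1)
    return out
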