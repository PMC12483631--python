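"""Independent brute-force oracles used only by the test suite.

Each oracle is deliberately implemented along a different route from
the library code it checks: Z2 matrix-reduction persistent homology
(vs. persistent-Laplacian kernel counts), naive double loops (vs.
vectorized kernels), a per-node scalar RK4 with the direct coupling sum
(vs. the batched deviation-form integrator), and two-pass streaming
statistics (vs. the feature extractor).
"""

from __future__ import annotations

import numpy as np


def ph_persistence_pairs(filtration):
    """Persistence pairs over Z2 by standard column reduction.

    Returns ``(creators, pairs)`` where creators maps a simplex index
    to its dimension and birth, and pairs maps a creator index to the
    birth value of its destroyer (absent for essential classes).
    """
    sims = filtration.simplices  # sorted by (birth, dim, lex)
    index = {s: i for i, (s, _) in enumerate(sims)}
    cols = []
    for s, _ in sims:
        if len(s) == 1:
            cols.append(set())
        else:
            cols.append({index[s[:i] + s[i + 1:]] for i in range(len(s))})
    reduced = []
    pivot_of = {}
    pairs = {}
    for j, col in enumerate(cols):
        col = set(col)
        while col:
            low = max(col)
            if low not in pivot_of:
                break
            col ^= reduced[pivot_of[low]]
        reduced.append(col)
        if col:
            low = max(col)
            pivot_of[low] = j
            pairs[low] = sims[j][1]  # death value = destroyer's birth
    creators = {
        i: (len(s) - 1, b)
        for i, (s, b) in enumerate(sims)
        if i not in {p for p in pivot_of.values()}
    }
    return creators, pairs


def persistent_betti_oracle(filtration, s: float, u: float, q: int) -> int:
    """β_q^{s,u}: classes of dim q born by s and still alive after u."""
    creators, pairs = ph_persistence_pairs(filtration)
    count = 0
    for idx, (dim, birth) in creators.items():
        if dim != q or birth > s:
            continue
        death = pairs.get(idx)
        if death is None or death > u:
            count += 1
    return count


def cutoff_connectivity_naive(d: np.ndarray, sigma: float) -> np.ndarray:
    """Elementwise double-loop cutoff kernel with the diagonal rule."""
    n = d.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                a[i, j] = 1.0 if d[i, j] <= sigma else 0.0
    for i in range(n):
        a[i, i] = -sum(a[i, j] for j in range(n) if j != i)
    return a


def pearson_naive(x, y) -> float:
    """Textbook PCC formula with explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    sxx = sum((x[i] - mx) ** 2 for i in range(n))
    syy = sum((y[i] - my) ** 2 for i in range(n))
    return sxy / (sxx * syy) ** 0.5


def lorenz_rk4_reference(coupling, epsilon, alpha, gamma, beta, y0, h, steps):
    """Per-node scalar RK4 with the direct coupling sum ε Σ_j C_ij s_j."""
    c = np.asarray(coupling, dtype=float)
    n = c.shape[0]

    def field(y):
        out = np.zeros_like(y)
        for i in range(n):
            x, yy, z = y[i]
            out[i, 0] = alpha * (yy - x)
            out[i, 1] = gamma * x - yy - x * z
            out[i, 2] = x * yy - beta * z
            for j in range(n):
                out[i] += epsilon * c[i, j] * y[j]
        return out

    y = np.array(y0, dtype=float)
    traj = [y.copy()]
    for _ in range(steps):
        k1 = field(y)
        k2 = field(y + 0.5 * h * k1)
        k3 = field(y + 0.5 * h * k2)
        k4 = field(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        traj.append(y.copy())
    return np.asarray(traj)


def statistics_naive(series: np.ndarray) -> dict:
    """Two-pass naive statistics of a 1-D series (population moments)."""
    x = [float(v) for v in series]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = var**0.5
    srt = sorted(x)
    median = (
        srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
    )
    if sd > 0:
        skew = sum((v - mean) ** 3 for v in x) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in x) / n / sd**4 - 3.0
    else:
        skew = kurt = 0.0
    rms = (sum(v * v for v in x) / n) ** 0.5
    return {
        "mean": mean, "std": sd, "min": min(x), "max": max(x),
        "median": median, "skewness": skew, "kurtosis": kurt, "rms": rms,
    }
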