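"""Seeded generators for every input modality the pipelines consume.

These reproduce the statistical and geometric structure of the study
systems at desk scale — regular polygons, folded/partially folded/
unfolded 120-node chains, block-correlated signal bundles, clustered
expression matrices, and elastic-chain pseudo-proteins with a known
flexibility profile — so every pipeline is testable without external
downloads.  Every generator is deterministic in its seed and reports
its full parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from tepc.connectivity import (
    KernelSpec,
    PointCloud,
    build_connectivity,
    pairwise_distances,
)

__all__ = [
    "GeneratorSpec",
    "LabeledDataset",
    "ProteinChain",
    "polygon_cloud",
    "chain_cloud",
    "synthetic_signals",
    "synthetic_expression",
    "synthetic_protein",
]


@dataclass
class GeneratorSpec:
    """Record of a generator call (name, sizes, effects, seed)."""

    name: str
    params: dict
    seed: Optional[int] = None


@dataclass
class LabeledDataset:
    """Samples (or signals) with aligned labels and a modality tag."""

    samples: np.ndarray
    labels: np.ndarray
    modality: str = "generic"
    spec: Optional[GeneratorSpec] = None

    def __post_init__(self) -> None:
        if self.samples.shape[0] != len(self.labels):
            raise ValueError("labels must align with sample rows")


@dataclass
class ProteinChain:
    """Cα trace of a protein chain with experimental B-factors.

    coords are in Å, b_factors in Å²; one Cα per residue.
    """

    residue_ids: list
    coords: np.ndarray
    b_factors: np.ndarray
    source: str = ""
    flexibility: Optional[np.ndarray] = None  # ground truth, synthetic chains only

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        if self.coords.shape[0] != self.b_factors.size:
            raise ValueError("one B-factor per residue required")
        if not np.isfinite(self.b_factors).all() or (self.b_factors < 0).any():
            raise ValueError("B-factors must be finite and nonnegative")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


def polygon_cloud(n: int = 16, circumradius: float = 1.0) -> PointCloud:
    """n equally spaced points on a circle in the z = 0 plane."""
    if n < 3:
        raise ValueError("a polygon needs at least 3 nodes")
    theta = 2.0 * np.pi * np.arange(n) / n
    coords = np.column_stack(
        [circumradius * np.cos(theta), circumradius * np.sin(theta), np.zeros(n)]
    )
    return PointCloud(coords=coords)


def chain_cloud(
    n: int = 120, folded_fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple:
    """Partially folded chain: a compact globule plus a sparse straight tail.

    The folded portion is a compact serpentine (lattice-folded) trace —
    a boustrophedon path through a near-cubic grid with unit spacing, so
    the fold is a genuinely three-dimensional cluster with mean
    nearest-neighbour distance ≈ 1; the unfolded portion extends away
    from the cluster along +z with spacing 3, giving only sparse
    contacts.  A small seeded jitter (sd 0.05) breaks exact symmetry.

    Returns ``(PointCloud, labels)`` with labels in {"folded",
    "unfolded"}.
    """
    if n < 10:
        raise ValueError("chain needs at least 10 nodes")
    if not (0.0 <= folded_fraction <= 1.0):
        raise ValueError("folded_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_folded = int(round(n * folded_fraction))
    coords = np.zeros((n, 3))
    if n_folded:
        side = max(1, int(round(n_folded ** (1.0 / 3.0))))
        pts = []
        row = 0  # global row counter keeps the path continuous across layers
        z = 0
        while len(pts) < n_folded:
            ys = range(side) if z % 2 == 0 else range(side - 1, -1, -1)
            for y in ys:
                xs = range(side) if row % 2 == 0 else range(side - 1, -1, -1)
                for x in xs:
                    pts.append((x, y, z))
                    if len(pts) == n_folded:
                        break
                row += 1
                if len(pts) == n_folded:
                    break
            z += 1
        coords[:n_folded] = np.asarray(pts, dtype=float)
    top = coords[n_folded - 1] if n_folded else np.zeros(3)
    for i in range(n_folded, n):
        coords[i] = top + [0.0, 0.0, 3.0 * (i - n_folded + 1)]
    coords += rng.normal(scale=0.05, size=coords.shape)
    labels = np.array(
        ["folded"] * n_folded + ["unfolded"] * (n - n_folded), dtype=object
    )
    cloud = PointCloud(coords=coords)
    return cloud, labels


def synthetic_signals(
    n_per_class: int = 100,
    classes: int = 3,
    T: int = 10_000,
    within_r: float = 0.8,
    across_r: float = 0.1,
    seed: int = 0,
) -> LabeledDataset:
    """Block-correlated Gaussian signal bundle.

    Realized through shared latent factors: a global factor carrying
    the across-class correlation, one factor per class carrying the
    within-class excess, and independent channel noise.  The implied
    block correlation matrix must be positive semidefinite, which
    requires 0 ≤ across_r ≤ within_r < 1.
    """
    if not (abs(within_r) < 1 and abs(across_r) < 1 and within_r > across_r):
        raise ValueError("need |r| < 1 and within_r > across_r")
    if across_r < 0:
        raise ValueError(
            "across_r < 0 makes the block correlation matrix non-PSD for "
            "more than two classes"
        )
    rng = np.random.default_rng(seed)
    g_global = rng.standard_normal(T)
    signals = np.empty((n_per_class * classes, T))
    labels = np.repeat(np.arange(classes), n_per_class)
    a, w = across_r, within_r
    for c in range(classes):
        g_class = rng.standard_normal(T)
        noise = rng.standard_normal((n_per_class, T))
        block = (
            np.sqrt(a) * g_global
            + np.sqrt(w - a) * g_class
            + np.sqrt(1.0 - w) * noise
        )
        signals[c * n_per_class : (c + 1) * n_per_class] = block
    spec = GeneratorSpec(
        "synthetic_signals",
        dict(n_per_class=n_per_class, classes=classes, T=T,
             within_r=within_r, across_r=across_r),
        seed,
    )
    return LabeledDataset(samples=signals, labels=labels, modality="eeg", spec=spec)


def synthetic_expression(
    cells_per_type: int = 125,
    types: int = 4,
    genes: int = 400,
    marker_fraction: float = 0.1,
    effect_size: float = 4.0,
    seed: int = 0,
) -> LabeledDataset:
    """Clustered count matrix with negative-binomial-like noise.

    Baseline per-gene means are log-normal; each cell type up-regulates
    its own disjoint marker block by ``effect_size`` fold; per-cell
    library sizes vary uniformly over [0.5, 2].  Counts arise from a
    gamma–Poisson mixture (NB dispersion 0.3).
    """
    if types < 2:
        raise ValueError("need at least 2 cell types")
    if not (0.0 < marker_fraction < 1.0):
        raise ValueError("marker_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=1.0, sigma=1.0, size=genes)
    n_markers = max(1, int(round(genes * marker_fraction)))
    n_cells = cells_per_type * types
    labels = np.repeat(np.arange(types), cells_per_type)
    mean = np.tile(base, (n_cells, 1))
    for t in range(types):
        lo = (t * n_markers) % genes
        cols = (np.arange(n_markers) + lo) % genes
        mean[np.ix_(labels == t, cols)] *= effect_size
    libsize = rng.uniform(0.5, 2.0, size=n_cells)
    mean *= libsize[:, None]
    dispersion = 0.3
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    counts = rng.poisson(lam).astype(np.int64)
    spec = GeneratorSpec(
        "synthetic_expression",
        dict(cells_per_type=cells_per_type, types=types, genes=genes,
             marker_fraction=marker_fraction, effect_size=effect_size),
        seed,
    )
    return LabeledDataset(samples=counts, labels=labels, modality="scrna", spec=spec)


def _helical_trace(n_residues: int, rng: np.random.Generator) -> np.ndarray:
    """Compact Cα-like trace: helical segments joined by random turns.

    Successive residues sit 3.8 Å apart; every 12–20 residues the helix
    axis reorients, producing a loosely packed globule rather than a
    straight rod.
    """
    spacing = 3.8
    coords = np.zeros((n_residues, 3))
    # ideal alpha-helix step in a local frame: rise 1.5 Å, radius 2.3 Å
    rise, radius, dtheta = 1.5, 2.3, np.deg2rad(100.0)
    axis = np.array([0.0, 0.0, 1.0])
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, 1.0, 0.0])
    centre = np.zeros(3)
    phase = 0.0
    next_turn = int(rng.integers(12, 21))
    for i in range(1, n_residues):
        if i >= next_turn:
            next_turn = i + int(rng.integers(12, 21))
            # reorient the helix axis toward the origin plus noise: keeps
            # the trace compact (self-attracting random reorientation)
            pull = -coords[i - 1]
            pull = pull / (np.linalg.norm(pull) + 1e-9)
            axis = pull + rng.normal(scale=0.8, size=3)
            axis /= np.linalg.norm(axis)
            u = np.cross(axis, rng.normal(size=3))
            u /= np.linalg.norm(u)
            v = np.cross(axis, u)
            centre = coords[i - 1] - radius * (
                np.cos(phase) * u + np.sin(phase) * v
            )
        phase += dtheta
        centre = centre + rise * axis
        coords[i] = centre + radius * (np.cos(phase) * u + np.sin(phase) * v)
        step = np.linalg.norm(coords[i] - coords[i - 1])
        coords[i] = coords[i - 1] + (coords[i] - coords[i - 1]) * spacing / step
        centre = coords[i] - radius * (np.cos(phase) * u + np.sin(phase) * v)
    # termini dangle outward from the globule (surface-exposed chain ends)
    centroid = coords.mean(axis=0)
    for ends in (range(2, -1, -1), range(n_residues - 3, n_residues)):
        ends = list(ends)
        anchor = ends[0] + (1 if ends[0] < 3 else -1)
        out_dir = coords[anchor] - centroid
        out_dir /= np.linalg.norm(out_dir) + 1e-9
        for i in ends:
            prev = i + 1 if i < 3 else i - 1
            coords[i] = coords[prev] + spacing * out_dir
    return coords


def synthetic_protein(
    n_residues: int = 100, noise_sd: float = 0.05, seed: int = 0
) -> ProteinChain:
    """Elastic-chain pseudo-protein with known flexibility profile.

    Ground-truth flexibility is the diagonal of the pseudo-inverse of
    the cutoff-kernel connectivity Laplacian of the trace (the
    elastic-network construction, cutoff 7.3 Å); the reported B-factor
    is an affine transform of that flexibility plus Gaussian noise with
    sd = ``noise_sd`` × the flexibility signal's sd.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues")
    rng = np.random.default_rng(seed)
    coords = _helical_trace(n_residues, rng)
    cloud = PointCloud(coords=coords)
    d = pairwise_distances(cloud)
    conn = build_connectivity(d, KernelSpec(family="cutoff", sigma=7.3))
    # graph Laplacian (PSD sign convention) of the contact network
    lap = -conn.a
    flex = np.diag(np.linalg.pinv(lap))
    span = flex.max() - flex.min()
    b = 5.0 + 15.0 * (flex - flex.min()) / (span if span > 0 else 1.0)
    b = b + rng.normal(scale=noise_sd * b.std(), size=n_residues)
    b = np.clip(b, 0.01, None)  # guard; inactive at realistic noise levels
    return ProteinChain(
        residue_ids=list(range(1, n_residues + 1)),
        coords=coords,
        b_factors=b,
        source=f"synthetic(seed={seed})",
        flexibility=flex,
    )
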