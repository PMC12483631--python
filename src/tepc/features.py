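"""From multiscale chaotic trajectories to predictive features.

At every filtration scale the network of oscillators is integrated and
per-node statistics of the post-transient trajectory window are
collected; concatenating scales gives each node a feature vector whose
length is (scales × 3 state variables × statistics).  Two trajectory
protocols exist:

* ``perturbative`` — one run per node, started with that node at unit
  state and all others at the origin equilibrium (the protein
  B-factor protocol); only the perturbed node's trajectory is kept.
* ``shared`` — a single seeded random-initial run per scale; every
  node's trajectory is kept (signal / expression / image modalities,
  where each sample is one oscillator in a single networked system).

Evaluation heads: per-protein ordinary least squares with Pearson
correlation against experimental B-factors, balanced-accuracy
cross-validation with pluggable classifiers, and residue–similarity
(R-S) scores for multiclass visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from tepc.connectivity import LaplacianFamily
from tepc.dynamics import (
    CoupledSystem,
    DivergenceError,
    OscillatorSpec,
    Trajectory,
    _integrate_array,
    coupling_from_laplacian,
)

__all__ = [
    "DEFAULT_STATISTICS",
    "FeatureMatrix",
    "RegressionResult",
    "CVReport",
    "RSScores",
    "trajectory_statistics",
    "multiscale_features",
    "pearson_cc",
    "fit_bfactor_regression",
    "balanced_accuracy",
    "cross_validate",
    "rs_scores",
    "reduce_by_variance",
]

#: moment-complete through order 4, plus extremes and RMS
DEFAULT_STATISTICS = (
    "mean", "std", "min", "max", "median", "skewness", "kurtosis", "rms",
)


@dataclass
class FeatureMatrix:
    """Nodes × (scales × variables × statistics) feature table."""

    values: np.ndarray
    feature_names: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


@dataclass
class RegressionResult:
    """Per-protein linear fit of B-factors on chaotic features."""

    coefficients: np.ndarray
    predictions: np.ndarray
    pcc: float
    ridge: Optional[float] = None
    selected_features: Optional[np.ndarray] = None


@dataclass
class CVReport:
    """Cross-validation metrics across folds and seeds."""

    table: pd.DataFrame
    mean_ba: float
    std_ba: float
    mean_accuracy: float
    confusion: np.ndarray
    label_order: list
    mean_sensitivity: Optional[float] = None
    mean_specificity: Optional[float] = None
    fold_assignments: Optional[dict] = None


@dataclass
class RSScores:
    """Per-sample residue (separation) and similarity (cohesion) scores."""

    residue: np.ndarray
    similarity: np.ndarray
    true_labels: np.ndarray
    predicted_labels: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "residue_score": self.residue,
            "similarity_score": self.similarity,
            "true_label": self.true_labels,
        }
        if self.predicted_labels is not None:
            d["predicted_label"] = self.predicted_labels
        return pd.DataFrame(d)


def _window_statistics(window: np.ndarray, stat_names: Sequence[str]) -> np.ndarray:
    """(T, 3) trajectory window → (3, S) statistics array.

    Population moment conventions; skewness and excess kurtosis are 0
    for a constant series.
    """
    out = np.empty((window.shape[1], len(stat_names)))
    mean = window.mean(axis=0)
    centred = window - mean
    std = np.sqrt((centred**2).mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(std > 0, (centred**3).mean(axis=0) / std**3, 0.0)
        kurt = np.where(std > 0, (centred**4).mean(axis=0) / std**4 - 3.0, 0.0)
    for j, name in enumerate(stat_names):
        if name == "mean":
            out[:, j] = mean
        elif name == "std":
            out[:, j] = std
        elif name == "min":
            out[:, j] = window.min(axis=0)
        elif name == "max":
            out[:, j] = window.max(axis=0)
        elif name == "median":
            out[:, j] = np.median(window, axis=0)
        elif name == "skewness":
            out[:, j] = skew
        elif name == "kurtosis":
            out[:, j] = kurt
        elif name == "rms":
            out[:, j] = np.sqrt(np.mean(window**2, axis=0))
        else:
            raise ValueError(f"unknown statistic {name!r}")
    return out


def trajectory_statistics(
    traj: Union[Trajectory, np.ndarray],
    node: int = 0,
    stats: Sequence[str] = DEFAULT_STATISTICS,
    transient_fraction: float = 0.1,
) -> np.ndarray:
    """Statistics of one node's post-transient trajectory.

    Returns a flat vector ordered variable-major: (x stats…, y stats…,
    z stats…).  The first ``transient_fraction`` of recorded frames is
    discarded; the remaining window must hold at least 2 frames.
    """
    if not (0.0 <= transient_fraction < 1.0):
        raise ValueError("transient_fraction must be in [0, 1)")
    series = traj.states[:, node, :] if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if series.ndim != 2 or series.shape[1] != 3:
        raise ValueError("node trajectory must have shape (T, 3)")
    start = int(np.floor(transient_fraction * series.shape[0]))
    window = series[start:]
    if window.shape[0] < 2:
        raise ValueError("post-transient window shorter than 2 frames")
    return _window_statistics(window, stats).ravel()


def _perturbative_node_series(
    system: CoupledSystem, h: float, steps: int, scheme: str,
    first_variable_only: bool, divergence_bound: float,
) -> np.ndarray:
    """All-node perturbative probes in one batched integration.

    Run j starts with node j at unit state; only node j's own series is
    recorded.  Layout is node-first, (N, runs, 3), so the coupling term
    is a single GEMM per stage.  Returns (steps+1, N, 3) where slot i
    holds the perturbed trajectory of node i.
    """
    n = system.n_nodes
    y = np.zeros((n, n, 3))
    unit = [1.0, 0.0, 0.0] if first_variable_only else [1.0, 1.0, 1.0]
    for j in range(n):
        y[j, j] = unit

    w = system._w
    rs = system._rs
    eps = system.epsilon
    gamma = system._gamma
    spec = system.spec

    from tepc.dynamics import _vector_field

    def field(states: np.ndarray) -> np.ndarray:
        f = _vector_field(states, spec)
        if eps == 0.0:
            return f
        dev = states - states[:1]
        if gamma is not None:
            dev = dev @ gamma.T
        coup = (w @ dev.reshape(n, -1)).reshape(n, n, 3) - rs[:, None, None] * dev
        return f + eps * coup

    out = np.empty((steps + 1, n, 3))
    diag = np.arange(n)
    out[0] = y[diag, diag]
    from tepc.dynamics import _step

    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(1, steps + 1):
            y = _step(field, y, h, scheme)
            if step % 25 == 0 or step == steps:
                m = float(np.max(np.abs(y)))
                if not np.isfinite(m) or m > divergence_bound:
                    raise DivergenceError(step, m)
            out[step] = y[diag, diag]
    return out


def multiscale_features(
    family: LaplacianFamily,
    spec: OscillatorSpec,
    epsilon: float = 1.0,
    h: float = 1e-3,
    steps: int = 600,
    scheme: str = "rk4",
    protocol: str = "perturbative",
    stats: Sequence[str] = DEFAULT_STATISTICS,
    transient_fraction: float = 0.1,
    seed: Optional[int] = None,
    gamma_inner: Optional[np.ndarray] = None,
    first_variable_only: bool = False,
    divergence_bound: float = 1e6,
) -> FeatureMatrix:
    """Per-node features across every scale of a Laplacian family.

    Each scale's binarized Laplacian is re-signed into a diffusive
    coupling (C = −L_k) and the network integrated under the chosen
    protocol; per-node statistics are concatenated in scale order.
    Scales whose integration diverges are dropped (never imputed) and
    listed in the provenance.
    """
    if len(family) == 0:
        raise ValueError("Laplacian family is empty")
    if protocol not in ("perturbative", "shared"):
        raise ValueError("protocol must be 'perturbative' or 'shared'")
    if protocol == "shared" and seed is None:
        raise ValueError("shared protocol needs a seed for the initial state")
    n = family.laplacians[0].shape[0]
    blocks, names, dropped = [], [], []
    rng = np.random.default_rng(seed)
    for k, lk in enumerate(family, start=1):
        system = CoupledSystem(
            spec=spec,
            coupling=coupling_from_laplacian(lk),
            epsilon=epsilon,
            gamma_inner=gamma_inner,
        )
        try:
            if protocol == "perturbative":
                series = _perturbative_node_series(
                    system, h, steps, scheme, first_variable_only, divergence_bound
                )
            else:
                y0 = rng.uniform(-1.0, 1.0, size=(n, 3))
                _, series = _integrate_array(
                    system.field, y0, h, steps, scheme,
                    divergence_bound=divergence_bound,
                )
        except DivergenceError as err:
            warnings.warn(
                f"scale {k} diverged ({err}); dropped from the feature matrix",
                RuntimeWarning,
                stacklevel=2,
            )
            dropped.append(k)
            continue
        start = int(np.floor(transient_fraction * series.shape[0]))
        window = series[start:]
        block = np.empty((n, 3 * len(stats)))
        for i in range(n):
            block[i] = _window_statistics(window[:, i, :], stats).ravel()
        blocks.append(block)
        names.extend(
            f"k{k:02d}_{var}_{stat}" for var in "xyz" for stat in stats
        )
    if not blocks:
        raise RuntimeError("every scale diverged; no features produced")
    provenance = {
        "model": spec.model,
        "params": dict(spec.params),
        "epsilon": epsilon,
        "h": h,
        "steps": steps,
        "scheme": scheme,
        "protocol": protocol,
        "stats": list(stats),
        "transient_fraction": transient_fraction,
        "seed": seed,
        "p": family.p,
        "dropped_scales": dropped,
    }
    return FeatureMatrix(
        values=np.hstack(blocks), feature_names=names, provenance=provenance
    )


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient of two sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-D arrays of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined for a constant input")
    return float(np.corrcoef(x, y)[0, 1])


def reduce_by_variance(
    x: np.ndarray, n_features: int, reference: Optional[np.ndarray] = None
) -> np.ndarray:
    """Indices of the ``n_features`` highest-variance columns.

    Variance is measured on ``reference`` rows if given (training folds
    only, to stay leakage-free) and ties break by column order.
    """
    basis = x if reference is None else reference
    var = basis.var(axis=0)
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:n_features])


def fit_bfactor_regression(
    features: Union[FeatureMatrix, np.ndarray],
    b: np.ndarray,
    n_features: Optional[int] = None,
) -> RegressionResult:
    """Per-protein OLS of experimental B-factors on chaotic features.

    Optionally reduces to the ``n_features`` highest-variance columns
    first.  A rank-deficient design falls back to ridge with
    λ = 1e−8 · trace(XᵀX)/F, recorded on the result.  Returns fitted
    coefficients (intercept first), in-sample predictions, and their
    Pearson correlation with the experimental values.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    b = np.asarray(b, dtype=float)
    if not np.isfinite(b).all():
        raise ValueError("B-factors must be finite")
    if x.shape[0] != b.size:
        raise ValueError("feature rows must match the number of B-factors")
    selected = None
    if n_features is not None and n_features < x.shape[1]:
        selected = reduce_by_variance(x, n_features)
        x = x[:, selected]
    n, f = x.shape
    if n <= f + 1:
        raise ValueError(
            f"regression ill-posed: {n} samples for {f} features (+ intercept); "
            "reduce the feature count"
        )
    design = np.hstack([np.ones((n, 1)), x])
    coef, _, rank, _ = np.linalg.lstsq(design, b, rcond=None)
    ridge = None
    if rank < design.shape[1]:
        lam = 1e-8 * float(np.trace(x.T @ x)) / max(f, 1)
        gram = design.T @ design + lam * np.eye(f + 1)
        gram[0, 0] -= lam  # intercept not penalized
        coef = np.linalg.solve(gram, design.T @ b)
        ridge = lam
    pred = design @ coef
    return RegressionResult(
        coefficients=coef,
        predictions=pred,
        pcc=pearson_cc(pred, b),
        ridge=ridge,
        selected_features=selected,
    )


def balanced_accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Mean per-class recall (robust to class imbalance)."""
    from sklearn.metrics import balanced_accuracy_score

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    universe = set(np.unique(y_true).tolist())
    stray = set(np.unique(y_pred).tolist()) - universe
    if stray:
        raise ValueError(f"predicted class(es) absent from the true labels: {sorted(stray)}")
    return float(balanced_accuracy_score(y_true, y_pred))


def _specificity(conf: np.ndarray) -> float:
    """Macro-averaged specificity from a confusion matrix."""
    total = conf.sum()
    specs = []
    for i in range(conf.shape[0]):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        tn = total - tp - fp - fn
        specs.append(tn / (tn + fp) if (tn + fp) > 0 else 0.0)
    return float(np.mean(specs))


def cross_validate(
    features: Union[FeatureMatrix, np.ndarray],
    labels: Sequence,
    folds: int = 5,
    seeds: Sequence[int] = (0,),
    adapter: Optional[Callable] = None,
) -> CVReport:
    """Stratified k-fold cross-validation over several shuffling seeds.

    ``adapter`` is a zero-argument callable returning a fresh
    fit/predict estimator (any scikit-learn classifier works); default
    is a random forest with library defaults.  Folds are stratified by
    class and fully determined by each seed.
    """
    from sklearn.metrics import accuracy_score, confusion_matrix
    from sklearn.model_selection import StratifiedKFold

    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be at least 2")
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < folds]
    if small.size:
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than {folds} members; "
            "use fewer folds"
        )
    if adapter is None:
        from sklearn.ensemble import RandomForestClassifier

        adapter = lambda: RandomForestClassifier(random_state=0)  # noqa: E731

    rows = []
    conf_total = np.zeros((classes.size, classes.size), dtype=int)
    assignments = {}
    for seed in seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
        fold_of = np.empty(y.size, dtype=int)
        for fold, (train, test) in enumerate(skf.split(x, y)):
            fold_of[test] = fold
            clf = adapter()
            clf.fit(x[train], y[train])
            pred = clf.predict(x[test])
            conf = confusion_matrix(y[test], pred, labels=classes)
            conf_total += conf
            rows.append(
                {
                    "seed": seed,
                    "fold": fold,
                    "balanced_accuracy": balanced_accuracy(y[test], pred),
                    "accuracy": float(accuracy_score(y[test], pred)),
                    "sensitivity": balanced_accuracy(y[test], pred),
                    "specificity": _specificity(conf),
                }
            )
        assignments[int(seed)] = fold_of
    table = pd.DataFrame(rows)
    few_classes = classes.size <= 3
    return CVReport(
        table=table,
        mean_ba=float(table["balanced_accuracy"].mean()),
        std_ba=float(table["balanced_accuracy"].std(ddof=0)),
        mean_accuracy=float(table["accuracy"].mean()),
        confusion=conf_total,
        label_order=classes.tolist(),
        mean_sensitivity=float(table["sensitivity"].mean()) if few_classes else None,
        mean_specificity=float(table["specificity"].mean()) if few_classes else None,
        fold_assignments=assignments,
    )


def rs_scores(
    features: Union[FeatureMatrix, np.ndarray],
    labels: Sequence,
    predicted: Optional[Sequence] = None,
) -> RSScores:
    """Residue and similarity scores for multiclass visualization.

    For sample j of class k: similarity = mean over same-class samples
    of (1 − d/d_max) with d_max the dataset-wide maximal pairwise
    distance; residue = (mean distance to out-of-class samples)/r_max
    with r_max the dataset-wide maximal such mean.  Both lie in [0, 1];
    higher is better on both axes.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("rs_scores needs at least 2 classes")
    singles = classes[counts < 2]
    if singles.size:
        raise ValueError(
            f"similarity undefined for singleton class(es) {singles.tolist()}"
        )
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x))
    d_max = float(d.max())
    n = x.shape[0]
    sim = np.empty(n)
    res_raw = np.empty(n)
    for j in range(n):
        same = (y == y[j]) & (np.arange(n) != j)
        other = y != y[j]
        if d_max == 0:
            sim[j] = 1.0
        else:
            sim[j] = float(np.mean(1.0 - d[j, same] / d_max))
        res_raw[j] = float(d[j, other].mean()) if other.any() else 0.0
    r_max = res_raw.max()
    residue = res_raw / r_max if r_max > 0 else np.zeros(n)
    return RSScores(
        residue=residue,
        similarity=sim,
        true_labels=y,
        predicted_labels=None if predicted is None else np.asarray(predicted),
    )
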