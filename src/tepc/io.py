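"""Readers and writers for the plain-text formats the pipelines use.

Point clouds, signal bundles, expression matrices (delimited text or
MatrixMarket), feature tables, and a deterministic ``.npz`` archive for
Laplacian families (fixed zip timestamps, so re-runs are bitwise
identical).
"""

from __future__ import annotations

import io as _io
import zipfile
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from tepc.connectivity import LaplacianFamily, PointCloud

__all__ = [
    "read_point_cloud",
    "read_signals",
    "read_expression",
    "write_matrix",
    "save_family",
    "load_family",
    "savez_deterministic",
]


def read_point_cloud(path: Union[str, Path]) -> PointCloud:
    """Point cloud from delimited text: one node per line, 2–3 coordinate
    columns, optional leading id column (detected as non-numeric or
    integer-index first column when 4 columns are present)."""
    rows = []
    ids = []
    text = Path(path).read_text()
    for line in text.strip().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
            has_id = len(vals) == 4
        except ValueError:
            vals = [float(p) for p in parts[1:]]
            has_id = None  # non-numeric leading id
            ids.append(parts[0])
        if has_id:
            ids.append(str(int(vals[0])))
            vals = vals[1:]
        rows.append(vals)
    coords = np.asarray(rows, dtype=float)
    return PointCloud(coords=coords, ids=ids if ids else None)


def read_signals(path: Union[str, Path], channels_in_columns: bool = True) -> np.ndarray:
    """(N, T) signal array from delimited text (one channel per column)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if not np.issubdtype(np.asarray(df.iloc[0]).dtype, np.number):
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    arr = df.to_numpy(dtype=float)
    return arr.T if channels_in_columns else arr


def read_expression(
    path: Union[str, Path], labels_path: Optional[Union[str, Path]] = None,
    label_column: Optional[str] = None,
):
    """Cell × gene matrix from delimited text or MatrixMarket.

    Labels come either from a ``label_column`` of the delimited file or
    from a separate one-label-per-line file.  Returns ``(matrix,
    labels-or-None)``.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(str(path)).todense(), dtype=float)
        labels = None
    else:
        df = pd.read_csv(path, sep=None, engine="python")
        labels = None
        if label_column is not None:
            labels = df[label_column].to_numpy()
            df = df.drop(columns=[label_column])
        mat = df.to_numpy(dtype=float)
    if labels_path is not None:
        labels = np.array(
            [ln.strip() for ln in Path(labels_path).read_text().strip().splitlines()],
            dtype=object,
        )
    return mat, labels


def write_matrix(path: Union[str, Path], m: np.ndarray, header: str = "") -> None:
    """Delimited-text matrix with an optional ``#`` header line."""
    np.savetxt(path, np.asarray(m), delimiter="\t", header=header, fmt="%.12g")


def savez_deterministic(path: Union[str, Path], **arrays) -> None:
    """Uncompressed ``.npz`` with fixed zip timestamps (bit-reproducible)."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]), allow_pickle=False)
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def save_family(path: Union[str, Path], family: LaplacianFamily) -> None:
    """Laplacian family → deterministic npz archive (shapes and
    threshold metadata preserved bit-exactly)."""
    arrays = {f"L{k:03d}": lk for k, lk in enumerate(family.laplacians, start=1)}
    arrays["thresholds"] = np.asarray(family.thresholds)
    arrays["meta"] = np.asarray([family.p, family.lmin, family.lmax, family.d_range])
    savez_deterministic(path, **arrays)


def load_family(path: Union[str, Path]) -> LaplacianFamily:
    with np.load(path) as z:
        p, lmin, lmax, d_range = z["meta"]
        p = int(p)
        laps = [z[f"L{k:03d}"].astype(int) for k in range(1, p + 1)]
        thresholds = z["thresholds"].tolist()
    return LaplacianFamily(
        laplacians=laps, p=p, thresholds=thresholds,
        lmin=float(lmin), lmax=float(lmax), d_range=float(d_range),
    )
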