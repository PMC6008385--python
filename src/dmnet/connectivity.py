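"""Default-mode-network node definitions and Pearson connectivity.

The network is built on 20 canonical DMN subregions (posterior cingulate,
medial prefrontal, temporo-parietal, retrosplenial, parahippocampal and
hippocampal nodes, with left/right homologues mirrored about the midline).
Regional signals either arrive as ready-made time-series columns or are
extracted from a 4-D volume as the per-volume mean within a 6-mm spherical
seed around each node's MNI coordinate.  Functional connectivity is the
20 x 20 matrix of pairwise Pearson correlations; the diagonal is fixed to
zero and excluded from every edge-level operation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "load_roi_table",
    "extract_sphere_timeseries",
    "fc_matrix",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_node_file",
    "write_edge_file",
]

N_NODES = 20


def load_roi_table() -> pd.DataFrame:
    """The packaged 20-node DMN seed table.

    Columns: ``name`` (e.g. ``PCC.L``), ``region``, ``brodmann``
    (informational), MNI ``x, y, z`` in mm, and ``module``
    (anterior/posterior subsystem assignment used by the cohort
    generator).  Left/right homologues differ only in the sign of x;
    midline nodes (dMPFC, vMPFC) sit at x = 0.
    """
    with resources.files("dmnet.data").joinpath("dmn_rois.csv").open() as fh:
        table = pd.read_csv(fh)
    expected = {"name", "region", "brodmann", "x", "y", "z", "module"}
    if len(table) != N_NODES or not expected.issubset(table.columns):
        raise RuntimeError("packaged ROI table is corrupt")
    return table


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Pearson correlation matrix with zeroed diagonal."""

    values: np.ndarray
    labels: Sequence[str]

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=np.float64)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        V = (V + V.T) / 2.0
        np.fill_diagonal(V, 0.0)
        off = V[~np.eye(V.shape[0], dtype=bool)]
        if np.any(np.abs(off) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = V
        self.labels = list(self.labels)
        if len(self.labels) != V.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def edge(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle correlations in lexicographic (i, j) order."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu, ju]


def fc_matrix(ts, labels: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlation matrix of a T x N time-series array.

    The diagonal is set to zero on construction.  A zero-variance column
    makes the correlation undefined and raises, naming the node.
    """
    X = np.asarray(getattr(ts, "values", ts), dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("time series must be a T x N array")
    T, n = X.shape
    if T < 3:
        raise ValueError("need at least 3 time points")
    if labels is None:
        labels = list(getattr(ts, "columns", [str(i) for i in range(n)]))
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(str(labels[i]) for i in dead)
        raise ValueError(f"zero-variance node(s): {names}")
    R = np.corrcoef(X, rowvar=False)
    return ConnectivityMatrix(R, labels)


def extract_sphere_timeseries(image, center_mm, radius_mm: float = 6.0,
                              affine: np.ndarray | None = None,
                              name: str | None = None) -> np.ndarray:
    """Mean time series over a spherical seed in a 4-D volume.

    ``image`` is a nibabel spatial image or a plain 4-D array (X, Y, Z, T)
    with ``affine`` supplied.  A voxel belongs to the sphere when its
    *center*, mapped to mm through the affine, lies within ``radius_mm``
    (Euclidean, boundary inclusive) of ``center_mm``.  Raises when the
    sphere contains no voxel centers.
    """
    if affine is None:
        data = np.asanyarray(image.dataobj)
        affine = image.affine
    else:
        data = np.asarray(image)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValueError("image must be 3-D or 4-D")
    affine = np.asarray(affine, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    # voxel centers of the full grid in mm
    nx, ny, nz = data.shape[:3]
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = vox @ affine.T
    dist = np.linalg.norm(mm[..., :3] - center, axis=-1)
    mask = dist <= radius_mm
    if not mask.any():
        label = name or f"seed at {tuple(center)}"
        raise ValueError(f"empty sphere: no voxel centers within "
                         f"{radius_mm} mm of {label}")
    return data[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_matrix_tsv(C: ConnectivityMatrix, path) -> None:
    """Labeled TSV (header + index = node names)."""
    df = pd.DataFrame(C.values, index=C.labels, columns=C.labels)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(df.to_numpy(), list(df.columns))


def write_node_file(path, table: pd.DataFrame | None = None,
                    color: int = 1, size: float = 1.0) -> None:
    """BrainNet-style .node file: x y z color size label, one node/row."""
    if table is None:
        table = load_roi_table()
    with open(path, "w") as fh:
        for _, row in table.iterrows():
            fh.write(f"{row.x}\t{row.y}\t{row.z}\t{color}\t{size}\t"
                     f"{row['name']}\n")


def write_edge_file(matrix, path) -> None:
    """Plain N x N numeric matrix (.edge), tab-delimited, no header."""
    values = getattr(matrix, "values", matrix)
    if hasattr(matrix, "adjacency"):
        values = matrix.adjacency
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.10g",
               delimiter="\t")
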