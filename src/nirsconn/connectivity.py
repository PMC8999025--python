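"""Pearson channel-pair connectivity matrices and their binarization.

The functional-connectivity edge weight between channels i and j is the
Pearson correlation of their resting oxy-Hb time courses,

    COR(x_i, x_j) = sum_t (x_i - mean x_i)(x_j - mean x_j)
                    / sqrt(sum_t (x_i - mean x_i)^2 sum_t (x_j - mean x_j)^2).

Negative correlations are retained in the matrix (they carry information)
but can never pass the positive edge threshold; group matrices are plain
element-wise averages across subjects by default, with an optional Fisher-z
average.  Binarization keeps edges with COR strictly above the threshold
(default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import InvalidInputError, InvalidParameterError, UndefinedCorrelationError
from .preprocess import HbTimeSeries


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel Pearson correlation matrix, unit diagonal."""

    values: np.ndarray
    subject_id: str = ""
    session: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidInputError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidInputError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise InvalidInputError("connectivity matrix must have a unit diagonal")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise InvalidInputError("off-diagonal correlations must lie in [-1, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected simple graph as a {0,1} adjacency matrix, zero diagonal."""

    adjacency: np.ndarray
    threshold_used: float
    thresholding_mode: str = "absolute_r"  # or "density"
    degenerate: bool = False  # set by rewiring when no valid swap exists

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidInputError("adjacency must be square")
        a = (a != 0).astype(np.int8)
        if not np.array_equal(a, a.T):
            raise InvalidInputError("adjacency must be symmetric")
        np.fill_diagonal(a, 0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(zip(*np.nonzero(np.triu(self.adjacency, k=1))))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, n_nodes: int, threshold_used: float,
                      mode: str, degenerate: bool = False) -> "BinaryNetwork":
        a = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        for u, v in g.edges():
            a[u, v] = a[v, u] = 1
        return cls(a, threshold_used=threshold_used, thresholding_mode=mode,
                   degenerate=degenerate)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pearson_cor(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length series; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("series must be 1-D and equal length")
    if x.size < 3:
        raise InvalidInputError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise UndefinedCorrelationError("zero-variance series: correlation undefined")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def cor_matrix(hb: HbTimeSeries) -> ConnectivityMatrix:
    """Channel x channel Pearson connectivity of one recording."""
    v = hb.values
    if v.shape[1] < 3:
        raise InvalidInputError("need at least 3 samples")
    sd = v.std(axis=1)
    if np.any(sd == 0):
        ch = int(np.argwhere(sd == 0)[0][0]) + 1
        raise UndefinedCorrelationError(f"channel {ch} is constant: correlation undefined")
    c = np.corrcoef(v)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(c, subject_id=hb.subject_id, session=hb.session)


def group_mean_cor(mats: list[ConnectivityMatrix], fisher_z: bool = False,
                   group_label: str = "", session: str = "") -> ConnectivityMatrix:
    """Element-wise mean connectivity across subjects.

    With ``fisher_z`` the average is taken on arctanh-transformed values and
    mapped back (off by default; the plain average is the reference
    behaviour).
    """
    if not mats:
        raise InvalidInputError("empty list of connectivity matrices")
    shapes = {m.values.shape for m in mats}
    if len(shapes) != 1:
        raise InvalidInputError("matrices differ in shape")
    stack = np.stack([m.values for m in mats])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        mean = np.tanh(z.mean(axis=0))
        np.fill_diagonal(mean, 1.0)
    else:
        mean = stack.mean(axis=0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(mean, session=session, group_label=group_label)


def mean_cor_scalar(mat: ConnectivityMatrix) -> float:
    """Mean of the strict-upper-triangle (231 for 22 channels) entries."""
    iu = np.triu_indices(mat.n_channels, k=1)
    return float(mat.values[iu].mean())


def binarize(mat: ConnectivityMatrix, threshold: float = 0.7,
             fisher_z: bool = False) -> BinaryNetwork:
    """Threshold to an unweighted graph: edge iff COR > threshold (strict).

    With ``fisher_z`` the comparison is |arctanh(COR)| > threshold instead
    (an alternative reading of the display convention); raw-r thresholding is
    the default and reference behaviour.
    """
    if not -1.0 < threshold < 1.0:
        raise InvalidParameterError("threshold must be in (-1, 1)")
    v = mat.values
    if fisher_z:
        z = np.arctanh(np.clip(v, -1 + 1e-15, 1 - 1e-15))
        adj = (np.abs(z) > threshold).astype(np.int8)
    else:
        adj = (v > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adj, threshold_used=threshold, thresholding_mode="absolute_r")
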