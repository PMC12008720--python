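"""Weighted global graph measures on sensor-space connectivity graphs.

Two outcomes: the global clustering coefficient C (network segregation;
Onnela geometric-mean triangle variant with global max-weight
normalization, the Brain Connectivity Toolbox convention) and the
characteristic path length L (network integration; edge length 1/weight,
all-pairs Dijkstra).  Both operate on the dense wPLI adjacency; no
thresholding is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix
from .montage import ElectrodeSubset

__all__ = [
    "GraphMetrics",
    "clustering_coefficient_global",
    "characteristic_path_length",
    "graph_metrics",
    "subset_metrics",
]


@dataclass
class GraphMetrics:
    """The two scalar graph outcomes plus provenance."""

    C: float
    L: float
    unreachable_pairs: int = 0
    electrode_set: int = 0
    band: tuple[float, float] = (8.0, 13.0)
    condition: str = "eyes_closed"
    subject_id: str = ""


def _check_adjacency(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (W < 0).any():
        raise ValueError("adjacency must be nonnegative")
    if np.abs(np.diag(W)).max(initial=0.0) > 0:
        raise ValueError("adjacency must have a zero diagonal")
    return W


def _as_matrix(W: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    return _check_adjacency(W.W if isinstance(W, ConnectivityMatrix) else W)


def clustering_coefficient_global(W: ConnectivityMatrix | np.ndarray,
                                  variant: str = "onnela") -> float:
    """Weighted global clustering coefficient.

    Default ``"onnela"``: weights are scaled by the global maximum and the
    node coefficient is c_i = [ (What^(1/3))^3 ]_ii / (k_i (k_i - 1)) with
    k_i the number of nonzero-weight neighbours.  ``"barrat"`` uses the
    strength-normalized triangle weight average instead.  Either way, C
    averages c_i over nodes with k_i >= 2 (nodes with fewer than two
    neighbours carry no triangle information).
    """
    W = _as_matrix(W)
    wmax = W.max()
    if wmax == 0:
        raise ValueError("empty graph: all weights are zero")
    k = (W > 0).sum(axis=1)
    eligible = k >= 2
    if not eligible.any():
        return 0.0
    c = np.zeros(W.shape[0])
    if variant == "onnela":
        A3 = np.cbrt(W / wmax)
        tri = np.einsum("ij,jh,hi->i", A3, A3, A3)  # 2 x triangle intensity
        c[eligible] = tri[eligible] / (k[eligible] * (k[eligible] - 1))
    elif variant == "barrat":
        A = (W > 0).astype(float)
        s = W.sum(axis=1)
        # sum over triangles of (w_ij + w_ih)/2 = diag(W A A) by symmetry
        tri = np.einsum("ij,jh,hi->i", W, A, A)
        c[eligible] = tri[eligible] / (s[eligible] * (k[eligible] - 1))
    else:
        raise ValueError(f"unknown clustering variant {variant!r}")
    return float(c[eligible].mean())


def characteristic_path_length(
    W: ConnectivityMatrix | np.ndarray, *, length_map: str = "inverse",
    return_unreachable: bool = False,
) -> float | tuple[float, int]:
    """Mean shortest-path distance over reachable ordered node pairs.

    Edge length is 1/weight for positive weights (strong coupling = short
    distance; ``length_map="one_minus"`` uses 1 - w instead, for weights in
    [0, 1]); pairs with no connecting path are excluded from the mean and
    counted.
    """
    W = _as_matrix(W)
    if (W > 0).sum() == 0:
        raise ValueError("graph has no edges")
    if length_map == "inverse":
        with np.errstate(divide="ignore"):
            lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    elif length_map == "one_minus":
        if W.max() > 1:
            raise ValueError("length_map='one_minus' requires weights <= 1")
        lengths = np.where(W > 0, 1.0 - W, np.inf)
    else:
        raise ValueError(f"unknown length_map {length_map!r}")
    D = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(W.shape[0], dtype=bool)
    d = D[off]
    finite = np.isfinite(d)
    unreachable = int((~finite).sum())
    L = float(d[finite].mean())
    if return_unreachable:
        return L, unreachable
    return L


def graph_metrics(W: ConnectivityMatrix, electrode_set: int | None = None,
                  threshold: float = 0.0) -> GraphMetrics:
    """Compute both global outcomes from a subject adjacency.

    ``threshold`` zeroes weights at or below the given value before the
    computation; the default keeps the full dense graph (the estimator's
    contract — no sparsification)."""
    if threshold > 0:
        Wt = W.W.copy()
        Wt[Wt <= threshold] = 0.0
        W = ConnectivityMatrix(W=Wt, channel_labels=W.channel_labels,
                               band=W.band, condition=W.condition,
                               n_epochs=W.n_epochs, subject_id=W.subject_id)
    L, unreachable = characteristic_path_length(W, return_unreachable=True)
    return GraphMetrics(
        C=clustering_coefficient_global(W), L=L,
        unreachable_pairs=unreachable,
        electrode_set=electrode_set or len(W.channel_labels),
        band=W.band, condition=W.condition, subject_id=W.subject_id,
    )


def subset_metrics(W: ConnectivityMatrix, subset: ElectrodeSubset,
                   ) -> GraphMetrics:
    """Restrict the adjacency to an electrode subset and recompute C and L.

    This is a pure sensor-space restriction: wPLI values are unchanged,
    only rows/columns outside the subset are dropped.
    """
    index = {lab: i for i, lab in enumerate(W.channel_labels)}
    missing = [lab for lab in subset.labels if lab not in index]
    if missing:
        raise KeyError(
            f"subset '{subset.name}' labels absent from adjacency: {missing}"
        )
    sel = np.array([index[lab] for lab in subset.labels])
    sub = ConnectivityMatrix(
        W=W.W[np.ix_(sel, sel)],
        channel_labels=[W.channel_labels[i] for i in sel],
        band=W.band, condition=W.condition, n_epochs=W.n_epochs,
        subject_id=W.subject_id,
    )
    return graph_metrics(sub, electrode_set=len(subset.labels))
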