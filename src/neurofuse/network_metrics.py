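"""Graph-theoretic summaries of gated connectivity matrices.

Directed matrices are symmetrized by averaging and treated as weighted
undirected graphs with distance 1/weight; weights are normalized by the
matrix maximum beforehand so all shortest-path metrics are scale-free.
Binary mode applies the strict unweighted formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .gsngc import ConnectivityMatrix

NODAL_METRICS = ("clustering", "path_length", "efficiency", "local_efficiency")
GLOBAL_METRICS = ("CC", "CPL", "GE", "LE")


@dataclass
class BrainGraph:
    adjacency: np.ndarray  # symmetric nonnegative weights, zero diagonal
    mode: str  # "weighted" | "binary"
    labels: list[str]

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def distance(self) -> np.ndarray:
        """1/weight for positive weights, infinity otherwise."""
        with np.errstate(divide="ignore"):
            d = np.where(self.adjacency > 0, 1.0 / self.adjacency, np.inf)
        np.fill_diagonal(d, 0.0)
        return d

    @property
    def degrees(self) -> np.ndarray:
        return (self.adjacency > 0).sum(axis=1)


@dataclass
class GraphMetricSet:
    CC: float
    CPL: float
    GE: float
    LE: float
    nodal: pd.DataFrame  # columns: node, metric, value
    n_unreachable_pairs: int = 0


def to_graph(conn: np.ndarray, mode: str = "weighted", labels: list[str] | None = None,
             normalize: bool = True) -> BrainGraph:
    """Symmetrize a directed nonnegative matrix by averaging and wrap it."""
    W = np.asarray(conn, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if (W < 0).any():
        raise ValueError("negative connectivity entries")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    if mode == "binary":
        W = (W > 0).astype(np.float64)
    elif mode == "weighted":
        mx = W.max()
        if normalize and mx > 0:
            W = W / mx
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if labels is None:
        labels = [str(i) for i in range(W.shape[0])]
    return BrainGraph(adjacency=W, mode=mode, labels=list(labels))


def clustering_coefficient(g: BrainGraph) -> tuple[float, np.ndarray]:
    """Mean and nodal clustering.

    Binary: 2 e_i / (k_i (k_i - 1)). Weighted: geometric-mean triangle
    intensity (cube-root weights, max-normalized), same k_i denominator.
    Nodes with fewer than 2 neighbors score 0.
    """
    W = g.adjacency
    k = g.degrees
    if g.mode == "binary":
        A = (W > 0).astype(np.float64)
        tri = np.diag(A @ A @ A)  # 2 * triangles * ... = number of closed 2-paths
    else:
        mx = W.max()
        Wn = W / mx if mx > 0 else W
        cr = np.cbrt(Wn)
        tri = np.diag(cr @ cr @ cr)
    denom = k * (k - 1)
    nodal = np.zeros(g.n)
    ok = denom > 0
    nodal[ok] = tri[ok] / denom[ok]
    return float(nodal.mean()), nodal


def _shortest_paths(g: BrainGraph) -> np.ndarray:
    # dijkstra treats 0 entries as absent edges; positive-weight edges all
    # have positive distance, so replacing inf with 0 is lossless here.
    dist = g.distance
    finite = np.where(np.isinf(dist), 0.0, dist)
    return dijkstra(finite, directed=False, unweighted=False)


def characteristic_path_length(g: BrainGraph) -> tuple[float, np.ndarray, int]:
    """CPL over reachable ordered pairs, nodal mean path lengths, and the
    count of unreachable ordered pairs."""
    D = _shortest_paths(g)
    off = ~np.eye(g.n, dtype=bool)
    finite = np.isfinite(D) & off
    n_unreach = int((off & ~finite).sum())
    nodal = np.full(g.n, np.nan)
    for i in range(g.n):
        row = D[i][finite[i]]
        if row.size:
            nodal[i] = row.mean()
    cpl = float(D[finite].mean()) if finite.any() else float("nan")
    return cpl, nodal, n_unreach


def global_efficiency(g: BrainGraph) -> tuple[float, np.ndarray]:
    """GE = mean over ordered pairs of 1/d_ij (0 for unreachable pairs)."""
    D = _shortest_paths(g)
    off = ~np.eye(g.n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(D > 0, 1.0 / D, 0.0)
    inv[~off] = 0.0
    inv[np.isinf(D)] = 0.0
    nodal = inv.sum(axis=1) / (g.n - 1)
    return float(inv[off].mean()), nodal


def local_efficiency(g: BrainGraph) -> tuple[float, np.ndarray]:
    """Efficiency of each node's neighbor-induced subgraph (paths restricted
    to that subgraph); nodes with fewer than 2 neighbors score 0."""
    W = g.adjacency
    nodal = np.zeros(g.n)
    for i in range(g.n):
        nbrs = np.flatnonzero(W[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = BrainGraph(W[np.ix_(nbrs, nbrs)], mode=g.mode, labels=[str(j) for j in nbrs])
        D = _shortest_paths(sub)
        off = ~np.eye(k, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
        nodal[i] = inv[off].sum() / (k * (k - 1))
    return float(nodal.mean()), nodal


def graph_metrics(g: BrainGraph) -> GraphMetricSet:
    cc, cc_nodal = clustering_coefficient(g)
    cpl, pl_nodal, n_unreach = characteristic_path_length(g)
    ge, ge_nodal = global_efficiency(g)
    le, le_nodal = local_efficiency(g)
    rows = []
    for metric, vals in zip(NODAL_METRICS, (cc_nodal, pl_nodal, ge_nodal, le_nodal)):
        for node, v in zip(g.labels, vals):
            rows.append(dict(node=node, metric=metric, value=float(v)))
    return GraphMetricSet(
        CC=cc, CPL=cpl, GE=ge, LE=le,
        nodal=pd.DataFrame(rows), n_unreachable_pairs=n_unreach,
    )


def metric_table(
    conn_by_subject: dict[str, ConnectivityMatrix], mode: str = "weighted"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format global and nodal metric tables across subjects and bands."""
    glob_rows, nodal_rows = [], []
    for subject, conn in conn_by_subject.items():
        for band, mat in conn.matrices.items():
            g = to_graph(mat, mode=mode, labels=conn.labels)
            ms = graph_metrics(g)
            for name, val in zip(GLOBAL_METRICS, (ms.CC, ms.CPL, ms.GE, ms.LE)):
                glob_rows.append(dict(subject=subject, band=band, metric=name, value=val))
            nd = ms.nodal.copy()
            nd.insert(0, "subject", subject)
            nd.insert(1, "band", band)
            nodal_rows.append(nd)
    return pd.DataFrame(glob_rows), pd.concat(nodal_rows, ignore_index=True)
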