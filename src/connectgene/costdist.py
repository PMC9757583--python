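"""Least-cost distances and paths over the resistance raster.

The raster is treated as an 8-connected lattice.  The cost of moving between
two neighbouring cells is the mean of their per-cell resistances times the
center-to-center distance (cell size, times sqrt(2) for diagonal moves) —
the convention shared by PATHMATRIX-style least-cost tools and raster
circuit solvers, and the single convention supported here.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .core import DistanceMatrix, PointSet, Raster
from .resistance import ResistanceSurface

__all__ = ["LatticeGraph", "build_lattice", "lcd_matrix", "least_cost_path", "site_nodes"]

log = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)
# moves that enumerate each undirected 8-neighbour edge exactly once
_MOVES = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, _SQRT2), (1, -1, _SQRT2))


@dataclass
class LatticeGraph:
    """Sparse graph over the valid cells of a resistance raster."""

    raster: Raster  # the cost raster the lattice was built from
    node_of_cell: np.ndarray  # (nrows, ncols) int, -1 for nodata cells
    cells: np.ndarray  # (n_nodes, 2) row/col of each node
    matrix: sparse.csr_matrix  # symmetric edge-cost matrix

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    def node_xy(self, nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rc = self.cells[np.asarray(nodes)]
        return self.raster.cell_center(rc[..., 0], rc[..., 1])


def build_lattice(resistance: ResistanceSurface | Raster) -> LatticeGraph:
    """Build the 8-connected lattice graph with averaged-resistance edge costs."""
    raster = resistance.cost if isinstance(resistance, ResistanceSurface) else resistance
    vals = raster.values
    valid = raster.valid_mask
    if not np.any(valid):
        raise ValueError("resistance raster contains no valid cells")
    if np.any(vals[valid] <= 0):
        raise ValueError("resistance values must be strictly positive")
    nrows, ncols = raster.shape
    node_of_cell = np.full((nrows, ncols), -1, dtype=np.int64)
    rr, cc = np.nonzero(valid)
    node_of_cell[rr, cc] = np.arange(len(rr))
    cells = np.column_stack([rr, cc])

    ii, jj, ww = [], [], []
    for dr, dc, mult in _MOVES:
        a = node_of_cell[max(0, -dr): nrows - max(0, dr), max(0, -dc): ncols - max(0, dc)]
        b = node_of_cell[max(0, dr): nrows - max(0, -dr), max(0, dc): ncols - max(0, -dc)]
        va = vals[max(0, -dr): nrows - max(0, dr), max(0, -dc): ncols - max(0, dc)]
        vb = vals[max(0, dr): nrows - max(0, -dr), max(0, dc): ncols - max(0, -dc)]
        ok = (a >= 0) & (b >= 0)
        ii.append(a[ok])
        jj.append(b[ok])
        ww.append(0.5 * (va[ok] + vb[ok]) * raster.cell_size * mult)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    w = np.concatenate(ww)
    n = len(cells)
    m = sparse.coo_matrix((np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n))
    return LatticeGraph(raster, node_of_cell, cells, m.tocsr())


def site_nodes(graph: LatticeGraph, sites: PointSet) -> np.ndarray:
    """Map site coordinates to lattice nodes, snapping to the nearest valid cell."""
    rows, cols = graph.raster.index_of(sites.x, sites.y, clip=True)
    nodes = graph.node_of_cell[rows, cols]
    if np.any(nodes < 0):
        xs, ys = graph.node_xy(np.arange(graph.n_nodes))
        for k in np.nonzero(nodes < 0)[0]:
            d2 = (xs - sites.x[k]) ** 2 + (ys - sites.y[k]) ** 2
            nodes[k] = int(np.argmin(d2))
            log.info(
                "site %s snapped %.1f units to nearest valid cell",
                sites.ids[k], float(np.sqrt(d2[nodes[k]])),
            )
    return nodes


def lcd_matrix(graph: LatticeGraph, sites: PointSet) -> DistanceMatrix:
    """Pairwise least-cost (accumulated-cost) distances between sites.

    Exact Dijkstra over the lattice; disconnected pairs are recorded as
    ``inf`` with a warning.
    """
    nodes = site_nodes(graph, sites)
    d = dijkstra(graph.matrix, directed=False, indices=nodes)
    m = d[:, nodes]
    m = 0.5 * (m + m.T)  # exact symmetry against float jitter
    np.fill_diagonal(m, 0.0)
    if np.any(~np.isfinite(m)):
        warnings.warn("some site pairs are disconnected; recorded as inf")
    return DistanceMatrix(sites.ids, m, kind="LCD")


def least_cost_path(graph: LatticeGraph, a: int, b: int) -> tuple[list[tuple[int, int]], float]:
    """One optimal path between lattice nodes ``a`` and ``b``.

    Returns the ordered (row, col) cell list and its accumulated cost.  Ties
    between equal-cost paths are broken lexicographically by predecessor node
    index, so the result is deterministic.
    """
    n = graph.n_nodes
    if not (0 <= a < n and 0 <= b < n):
        raise ValueError("node index out of range")
    if a == b:
        return [tuple(graph.cells[a])], 0.0
    indptr, indices, data = graph.matrix.indptr, graph.matrix.indices, graph.matrix.data
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=np.int64)
    dist[a] = 0.0
    heap: list[tuple[float, int]] = [(0.0, a)]
    done = np.zeros(n, dtype=bool)
    while heap:
        du, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == b:
            break
        for k in range(indptr[u], indptr[u + 1]):
            v = indices[k]
            nd = du + data[k]
            if nd < dist[v] or (nd == dist[v] and u < pred[v]):
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    if not np.isfinite(dist[b]):
        raise ValueError("nodes are in disconnected components")
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))
    path.reverse()
    return [tuple(graph.cells[v]) for v in path], float(dist[b])


def path_to_geojson(graph: LatticeGraph, path: list[tuple[int, int]]) -> dict:
    """A GeoJSON LineString feature through the cell centers of a path."""
    rc = np.asarray(path)
    x, y = graph.raster.cell_center(rc[:, 0], rc[:, 1])
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": [[float(a), float(b)] for a, b in zip(x, y)]},
        "properties": {},
    }
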