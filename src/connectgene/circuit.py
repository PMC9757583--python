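"""Circuit-theory computations: effective resistance and current throughflow.

The landscape is modelled as a resistor network.  On the raster lattice the
edge resistance equals the least-cost edge cost (average of the two cell
resistances times the center-to-center distance), so the least-cost and
circuit analyses share one conductance model.  Effective resistance between
two nodes — the "resistance distance", the circuit-theory analogue of
isolation by distance — integrates every parallel pathway, so it can never
exceed the least-cost distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .core import DistanceMatrix, PointSet
from .costdist import LatticeGraph, build_lattice, site_nodes
from .resistance import ResistanceSurface

__all__ = ["ResistorNetwork", "effective_resistance", "ibr_matrix", "pair_throughflow"]


@dataclass
class ResistorNetwork:
    """An undirected resistor network with its conductance Laplacian."""

    n: int
    edges: np.ndarray  # (m, 2) int node pairs
    resistance: np.ndarray  # (m,) > 0

    laplacian: sparse.csr_matrix = field(init=False)
    component: np.ndarray = field(init=False)
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.resistance = np.asarray(self.resistance, dtype=float)
        if np.any(self.resistance <= 0):
            raise ValueError("edge resistances must be strictly positive")
        if len(self.edges) != len(self.resistance):
            raise ValueError("edges and resistance length mismatch")
        cond = 1.0 / self.resistance
        i, j = self.edges[:, 0], self.edges[:, 1]
        adj = sparse.coo_matrix(
            (np.concatenate([cond, cond]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n),
        ).tocsr()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        self.laplacian = (sparse.diags(deg) - adj).tocsr()
        self.n_components, self.component = connected_components(adj, directed=False)

    @classmethod
    def from_lattice(cls, graph: LatticeGraph) -> "ResistorNetwork":
        coo = sparse.triu(graph.matrix, k=1).tocoo()
        return cls(graph.n_nodes, np.column_stack([coo.row, coo.col]), coo.data)

    def _grounded_solver(self, comp: int):
        """LU solver for the component's Laplacian with its first node grounded."""
        nodes = np.nonzero(self.component == comp)[0]
        if len(nodes) == 1:
            return nodes, None
        sub = self.laplacian[np.ix_(nodes, nodes)].tocsc()
        lu = splu(sub[1:, 1:].tocsc())
        return nodes, lu

    def solve_potentials(self, injections: np.ndarray) -> np.ndarray:
        """Node potentials for one or more injection vectors (columns).

        Each injection vector must sum to zero within each connected
        component.  The grounded node of each component is held at 0.
        """
        inj = np.atleast_2d(injections.T).T  # (n, k)
        out = np.zeros_like(inj, dtype=float)
        for comp in np.unique(self.component[np.any(inj != 0, axis=1)]):
            nodes, lu = self._grounded_solver(comp)
            if lu is None:
                continue
            sub_inj = inj[nodes[1:], :]
            out[nodes[1:], :] = lu.solve(sub_inj)
        return out if injections.ndim > 1 else out[:, 0]


def effective_resistance(net: ResistorNetwork, a: int, b: int) -> float:
    """Two-point effective resistance R_eff(a, b) via a grounded Laplacian solve."""
    if a == b:
        return 0.0
    if net.component[a] != net.component[b]:
        raise ValueError("nodes lie in different connected components")
    inj = np.zeros(net.n)
    inj[a] = 1.0
    inj[b] = -1.0
    v = net.solve_potentials(inj)
    return float(v[a] - v[b])


def ibr_matrix(resistance: ResistanceSurface | LatticeGraph, sites: PointSet) -> DistanceMatrix:
    """Pairwise resistance distances between sites on the raster lattice.

    Edge resistances reuse the least-cost edge costs so LCD and IBR share a
    single conductance model.  Disconnected pairs are recorded as ``inf``
    with a warning.
    """
    graph = resistance if isinstance(resistance, LatticeGraph) else build_lattice(resistance)
    net = ResistorNetwork.from_lattice(graph)
    nodes = site_nodes(graph, sites)
    k = len(nodes)
    m = np.zeros((k, k))
    # one grounded solve per site against a fixed reference in its component
    solvers: dict[int, tuple[np.ndarray, object, dict[int, int]]] = {}
    pots = {}
    for idx, u in enumerate(nodes):
        comp = int(net.component[u])
        if comp not in solvers:
            cn, lu = net._grounded_solver(comp)
            solvers[comp] = (cn, lu, {int(g): i for i, g in enumerate(cn)})
        cn, lu, pos = solvers[comp]
        if lu is None:
            pots[idx] = None
            continue
        rhs = np.zeros(len(cn) - 1)
        p = pos[int(u)]
        if p > 0:
            rhs[p - 1] = 1.0  # unit injection at u, extraction at the grounded node
        pots[idx] = (np.concatenate([[0.0], lu.solve(rhs)]), pos)
    disconnected = False
    for i in range(k):
        for j in range(i + 1, k):
            if net.component[nodes[i]] != net.component[nodes[j]]:
                m[i, j] = m[j, i] = np.inf
                disconnected = True
                continue
            vi, pos = pots[i]
            vj, _ = pots[j]
            pi, pj = pos[int(nodes[i])], pos[int(nodes[j])]
            # R(a,b) = G_aa + G_bb - 2 G_ab from grounded Green's function columns
            r = vi[pi] + vj[pj] - vi[pj] - vj[pi]
            m[i, j] = m[j, i] = max(r, 0.0)
    if disconnected:
        warnings.warn("some site pairs are disconnected; recorded as inf")
    return DistanceMatrix(sites.ids, m, kind="IBR")


def pair_throughflow(net: ResistorNetwork, s: int, t: int) -> np.ndarray:
    """Per-node current throughflow for a unit s→t injection.

    Interior nodes carry T_v = 0.5 * sum of |edge currents| at v; the source
    and target carry T = 1 by the endpoint convention.  Current is conserved
    at every interior node by construction of the Kirchhoff solve.
    """
    if s == t:
        raise ValueError("source and target must differ")
    if net.component[s] != net.component[t]:
        raise ValueError("nodes lie in different connected components")
    inj = np.zeros(net.n)
    inj[s] = 1.0
    inj[t] = -1.0
    v = net.solve_potentials(inj)
    i, j = net.edges[:, 0], net.edges[:, 1]
    cur = np.abs((v[i] - v[j]) / net.resistance)
    t_v = np.zeros(net.n)
    np.add.at(t_v, i, cur)
    np.add.at(t_v, j, cur)
    t_v *= 0.5
    t_v[s] = 1.0
    t_v[t] = 1.0
    return t_v
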