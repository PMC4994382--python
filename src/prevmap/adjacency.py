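"""Queen-contiguity adjacency between administrative polygons.

The spatial smoothing prior of the small-area model penalises squared
differences between *neighbouring* districts, so the neighbourhood graph is
part of the model specification.  Queen contiguity — two units are
neighbours if their polygons share at least one boundary point, edge or
corner — is the convention in the disease-mapping literature.

Islands (units touching nothing, e.g. an offshore district) leave the
intrinsic autoregressive prior uninformative for that unit.  The default
policy joins each island to its nearest unit by centroid great-circle
distance; a strict policy keeps the island flagged and disconnected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .geometry import haversine_km
from .survey_io import AdminUnit


@dataclass
class AdjacencyGraph:
    """Symmetric neighbour structure over district ids (no self-loops)."""

    ids: list[str]
    neighbors: dict[str, set[str]]
    islands: set[str] = field(default_factory=set)

    def __post_init__(self):
        for i, nbrs in self.neighbors.items():
            if i in nbrs:
                raise ValueError(f"self-loop at node {i!r}")
            for j in nbrs:
                if i not in self.neighbors.get(j, set()):
                    raise ValueError(f"asymmetric adjacency: {i!r}->{j!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as index pairs (i < j)."""
        idx = self.index()
        out = []
        for a, nbrs in self.neighbors.items():
            for b in nbrs:
                i, j = idx[a], idx[b]
                if i < j:
                    out.append((i, j))
        return sorted(out)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        g.add_edges_from((a, b) for a, nbrs in self.neighbors.items()
                         for b in nbrs)
        return g

    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian Q = D - W ordered like ``ids``."""
        q = np.zeros((self.n, self.n))
        for i, j in self.edges():
            q[i, i] += 1.0
            q[j, j] += 1.0
            q[i, j] -= 1.0
            q[j, i] -= 1.0
        return q


def build_adjacency(admin_units: Sequence[AdminUnit],
                    island_policy: str = "join_nearest") -> AdjacencyGraph:
    """Queen-contiguity graph over polygons, with island handling.

    Units whose polygons intersect in at least one point are neighbours.
    ``island_policy``: ``"join_nearest"`` links each isolated unit to its
    nearest unit by centroid distance (keeping it identifiable under the
    spatial prior); ``"strict"`` leaves it disconnected but flagged.
    """
    units = [u for u in admin_units]
    if not units:
        raise ValueError("empty admin unit set")
    if island_policy not in ("join_nearest", "strict"):
        raise ValueError(f"unknown island policy {island_policy!r}")

    ids = [u.unit_id for u in units]
    neighbors: dict[str, set[str]] = {i: set() for i in ids}
    for a in range(len(units)):
        for b in range(a + 1, len(units)):
            if units[a].geometry.intersects(units[b].geometry):
                neighbors[ids[a]].add(ids[b])
                neighbors[ids[b]].add(ids[a])

    islands = {i for i, nbrs in neighbors.items() if not nbrs}
    if islands and island_policy == "join_nearest" and len(units) > 1:
        cent = {u.unit_id: u.geometry.centroid for u in units}
        for isl in islands:
            c = cent[isl]
            other = min((i for i in ids if i != isl),
                        key=lambda i: haversine_km(c.x, c.y,
                                                   cent[i].x, cent[i].y))
            neighbors[isl].add(other)
            neighbors[other].add(isl)
    return AdjacencyGraph(ids=ids, neighbors=neighbors, islands=islands)


def grid_adjacency(ids_grid: np.ndarray, rook: bool = False) -> AdjacencyGraph:
    """Adjacency for a rectangular lattice of unit ids (queen by default)."""
    rows, cols = ids_grid.shape
    neighbors: dict[str, set[str]] = {str(i): set() for i in ids_grid.ravel()}
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if not rook:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for r in range(rows):
        for c in range(cols):
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    neighbors[str(ids_grid[r, c])].add(str(ids_grid[rr, cc]))
    return AdjacencyGraph(ids=[str(i) for i in ids_grid.ravel()],
                          neighbors=neighbors)


def icar_quadratic_form(u: Mapping[str, float] | np.ndarray,
                        graph: AdjacencyGraph) -> float:
    """Pairwise-difference penalty sum_{i~j, i<j} (u_i - u_j)^2.

    Equals u' Q u with Q = D - W; the intrinsic autoregressive log-kernel is
    -(tau_u / 2) times this value.
    """
    if isinstance(u, Mapping):
        vec = np.array([u[i] for i in graph.ids], dtype=float)
    else:
        vec = np.asarray(u, dtype=float)
        if vec.shape != (graph.n,):
            raise ValueError(
                f"u has shape {vec.shape}, expected ({graph.n},)")
    total = 0.0
    for i, j in graph.edges():
        total += (vec[i] - vec[j]) ** 2
    return float(total)
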