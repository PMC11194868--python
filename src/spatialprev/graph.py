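"""Area adjacency graphs.

An :class:`AreaGraph` holds the contiguity structure of a set of small
areas: ordered area identifiers, a symmetric neighbour relation, and
(optionally) one planar polygon per area.  Queen contiguity — two areas
are neighbours if their boundaries share any point, edge or vertex — is
the relation used throughout the package, matching standard practice in
small-area disease mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = ["AreaGraph", "generate_lattice"]


@dataclass(frozen=True)
class AreaGraph:
    """Symmetric adjacency over an ordered set of areas.

    Parameters
    ----------
    area_ids
        Unique identifiers, one per area, in a fixed order.  All other
        per-area arrays in the package follow this order.
    neighbours
        ``neighbours[i]`` is the set of *indices* (not ids) adjacent to
        area ``i``.  Must be symmetric and free of self-loops.
    polygons
        Optional shapely polygons, aligned with ``area_ids``.
    """

    area_ids: tuple
    neighbours: tuple
    polygons: tuple | None = field(default=None, compare=False)

    def __post_init__(self):
        ids = self.area_ids
        if len(set(ids)) != len(ids):
            raise ValueError("area_ids must be unique")
        if len(self.neighbours) != len(ids):
            raise ValueError("neighbours length must match area_ids")
        n = len(ids)
        for i, nbrs in enumerate(self.neighbours):
            if i in nbrs:
                raise ValueError(f"self-adjacency at area index {i}")
            for j in nbrs:
                if not (0 <= j < n):
                    raise ValueError(f"neighbour index {j} out of range")
                if i not in self.neighbours[j]:
                    raise ValueError(f"asymmetric adjacency between {i} and {j}")
        if self.polygons is not None and len(self.polygons) != n:
            raise ValueError("polygons length must match area_ids")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def degrees(self) -> np.ndarray:
        return np.array([len(s) for s in self.neighbours], dtype=np.int64)

    def edge_list(self) -> list[tuple[int, int]]:
        """Undirected edges as (i, j) index pairs with i < j."""
        return [(i, j) for i, s in enumerate(self.neighbours) for j in s if i < j]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edge_list())
        return g

    def is_connected(self) -> bool:
        return self.n_areas > 0 and nx.is_connected(self.to_networkx())

    def subgraph(self, keep: Sequence[int]) -> "AreaGraph":
        """Induced subgraph on the given area indices (order preserved)."""
        keep = list(keep)
        pos = {old: new for new, old in enumerate(keep)}
        nbrs = tuple(
            frozenset(pos[j] for j in self.neighbours[i] if j in pos) for i in keep
        )
        polys = tuple(self.polygons[i] for i in keep) if self.polygons else None
        return AreaGraph(
            area_ids=tuple(self.area_ids[i] for i in keep),
            neighbours=nbrs,
            polygons=polys,
        )


def _queen_grid_neighbours(rows: int, cols: int) -> tuple:
    """Queen adjacency of a rows x cols grid, row-major indexing."""
    nbrs = []
    for r in range(rows):
        for c in range(cols):
            s = set()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        s.add(rr * cols + cc)
            nbrs.append(frozenset(s))
    return tuple(nbrs)


def generate_lattice(rows: int, cols: int) -> AreaGraph:
    """Regular grid of unit squares with queen contiguity.

    Stands in for irregular census geography in simulations: it preserves
    the contiguity statistics (symmetric neighbour relation, corner as
    well as edge adjacency) that the spatial methods depend on.  Interior
    cells have 8 neighbours, edge cells 5, corner cells 3.

    Parameters
    ----------
    rows, cols
        Grid dimensions; both must be >= 1 and ``rows * cols >= 2``.
    """
    from shapely.geometry import box

    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
    if rows * cols < 2:
        raise ValueError("lattice must contain at least 2 areas")
    ids = tuple(f"a{r * cols + c:04d}" for r in range(rows) for c in range(cols))
    polys = tuple(
        box(c, rows - 1 - r, c + 1, rows - r) for r in range(rows) for c in range(cols)
    )
    return AreaGraph(ids, _queen_grid_neighbours(rows, cols), polys)
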