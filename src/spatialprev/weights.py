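"""Spatial weights: queen contiguity from polygons, binary and
row-standardised weight matrices.

Conventions follow GeoDa/CARBayes practice: Moran-type statistics use the
row-standardised matrix, CAR precision matrices use the binary one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .graph import AreaGraph

__all__ = [
    "SpatialWeights",
    "queen_contiguity",
    "build_weights",
    "read_geojson",
    "read_edge_list",
    "write_edge_list",
]

#: snapping tolerance (coordinate units) when testing boundary contact
QUEEN_TOL = 1e-8


class GeometryError(ValueError):
    pass


class IsolatedNodeError(ValueError):
    pass


@dataclass
class SpatialWeights:
    """Sparse spatial weight matrix over an :class:`AreaGraph`.

    ``style`` is ``"binary"`` (w_ij = 1 for neighbours) or
    ``"row_standardised"`` (w_ij = 1/deg(i)); w_ii = 0 always.
    """

    graph: AreaGraph
    style: str
    W: sp.csr_matrix
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.graph.n_areas

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(self.W.sum())

    def degrees(self) -> np.ndarray:
        return self.graph.degrees()

    def lag(self, x: np.ndarray) -> np.ndarray:
        """Spatial lag W @ x."""
        return self.W @ np.asarray(x, dtype=float)

    def laplacian_eigenvalues(self) -> np.ndarray:
        """Eigenvalues of D - W for the *binary* adjacency (cached).

        Used in the Leroux prior normalising constant; independent of
        the standardisation style.
        """
        if self._eigs is None:
            d = self.degrees().astype(float)
            A = _binary_matrix(self.graph).toarray()
            L = np.diag(d) - A
            self._eigs = np.linalg.eigvalsh(L)
        return self._eigs


def _binary_matrix(graph: AreaGraph) -> sp.csr_matrix:
    rows, cols = [], []
    for i, nbrs in enumerate(graph.neighbours):
        for j in nbrs:
            rows.append(i)
            cols.append(j)
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(graph.n_areas, graph.n_areas))


def build_weights(graph: AreaGraph, style: str = "row_standardised") -> SpatialWeights:
    """Build a weight matrix from an adjacency graph.

    Raises
    ------
    IsolatedNodeError
        If any area has no neighbours; rerun the exclusion step, which
        drops spatially disconnected areas.
    """
    if style not in ("binary", "row_standardised"):
        raise ValueError(f"unknown weights style: {style!r}")
    deg = graph.degrees()
    if (deg == 0).any():
        bad = [graph.area_ids[i] for i in np.flatnonzero(deg == 0)]
        raise IsolatedNodeError(
            f"areas with no neighbours: {bad[:5]}{'...' if len(bad) > 5 else ''}; "
            "apply exclusions before building weights"
        )
    W = _binary_matrix(graph)
    if style == "row_standardised":
        W = sp.diags(1.0 / deg) @ W
    return SpatialWeights(graph=graph, style=style, W=sp.csr_matrix(W))


def queen_contiguity(polygons, area_ids=None, tol: float = QUEEN_TOL) -> AreaGraph:
    """Queen-contiguity adjacency from planar polygons.

    Two areas are neighbours iff their boundaries come within ``tol`` of
    one another at at least one point — a shared edge or a single shared
    vertex both count (queen, not rook).

    Raises
    ------
    GeometryError
        For invalid (self-intersecting) geometry, naming the area.
    """
    from shapely import STRtree

    polygons = list(polygons)
    n = len(polygons)
    if area_ids is None:
        area_ids = tuple(f"a{i:04d}" for i in range(n))
    else:
        area_ids = tuple(area_ids)
    for pid, p in zip(area_ids, polygons):
        if p is None or p.is_empty or not p.is_valid:
            raise GeometryError(f"invalid geometry for area {pid!r}")
    tree = STRtree(polygons)
    nbrs = [set() for _ in range(n)]
    for i, p in enumerate(polygons):
        for j in tree.query(p.buffer(tol)):
            j = int(j)
            if j == i:
                continue
            if p.distance(polygons[j]) <= tol:
                nbrs[i].add(j)
                nbrs[j].add(i)
    return AreaGraph(area_ids, tuple(frozenset(s) for s in nbrs), tuple(polygons))


def read_geojson(path) -> tuple[tuple, tuple]:
    """Read a GeoJSON FeatureCollection; returns (area_ids, polygons).

    Each feature must carry an ``area_id`` property.
    """
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        fc = json.load(fh)
    ids, polys = [], []
    for feat in fc["features"]:
        ids.append(feat["properties"]["area_id"])
        polys.append(shape(feat["geometry"]))
    return tuple(ids), tuple(polys)


def read_edge_list(path, area_ids) -> AreaGraph:
    """Adjacency from a two-column edge-list CSV (columns: area_i, area_j)."""
    pos = {a: i for i, a in enumerate(area_ids)}
    nbrs = [set() for _ in area_ids]
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            i, j = pos[row["area_i"]], pos[row["area_j"]]
            if i != j:
                nbrs[i].add(j)
                nbrs[j].add(i)
    return AreaGraph(tuple(area_ids), tuple(frozenset(s) for s in nbrs))


def write_edge_list(graph: AreaGraph, path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["area_i", "area_j"])
        for i, j in graph.edge_list():
            writer.writerow([graph.area_ids[i], graph.area_ids[j]])
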