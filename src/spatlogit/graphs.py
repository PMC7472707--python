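"""Areal adjacency graphs and the sparse precision matrices of the GMRF priors.

Three intrinsic Gaussian Markov random fields appear in the model:

* the intrinsic CAR (Besag) prior over districts, whose unit-precision matrix
  is the graph Laplacian ``Q = D - A`` (rank deficiency 1 on a connected graph,
  null space spanned by the constant vector);
* random-walk priors of order 1 and 2 over the ranked values of a continuous
  covariate, ``Q = D_r' D_r`` with ``D_r`` the order-``r`` difference operator
  (rank deficiency ``r``; null space: constants, resp. constants + linear trend).

All matrices here are *unit* precisions; the precision parameters tau multiply
them inside the model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "AdjacencyGraph",
    "PrecisionStructure",
    "build_icar_precision",
    "build_rw_precision",
    "connected_components",
    "generate_lattice_graph",
]


@dataclass(frozen=True)
class PrecisionStructure:
    """A sparse symmetric PSD unit-precision matrix with known rank deficiency.

    Attributes
    ----------
    matrix : scipy.sparse.csr_array
        The unit precision (tau = 1).
    rank_deficiency : int
        Dimension of the null space (1 for ICAR/RW1, 2 for RW2).
    kind : str
        One of ``"ICAR"``, ``"RW1"``, ``"RW2"``.
    constraint : str
        Human-readable description of the null space.
    """

    matrix: sp.csr_array
    rank_deficiency: int
    kind: str
    constraint: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return self.n - self.rank_deficiency

    def null_basis(self) -> np.ndarray:
        """Orthonormal basis of the declared null space, shape (n, rank_deficiency)."""
        n = self.n
        if self.kind in ("ICAR", "RW1"):
            basis = np.ones((n, 1))
        elif self.kind == "RW2":
            lin = np.arange(1, n + 1, dtype=float)
            basis = np.column_stack([np.ones(n), lin])
        else:  # pragma: no cover - kinds are fixed at construction
            raise ValueError(f"unknown kind {self.kind!r}")
        q, _ = np.linalg.qr(basis)
        return q

    def quad_form(self, x: np.ndarray) -> float:
        """x' Q x, the random-walk / pairwise-difference penalty."""
        return float(x @ (self.matrix @ x))


class AdjacencyGraph:
    """Areal units plus a symmetric shared-boundary neighbour structure.

    Parameters
    ----------
    unit_ids : sequence
        Ordered labels of the areal units (e.g. district codes).
    edges : iterable of pairs
        Undirected neighbour pairs, given as unit ids. Each pair once is
        enough; duplicates and reversed copies are tolerated. Self-loops are
        rejected.
    """

    def __init__(self, unit_ids: Sequence, edges: Iterable[tuple]) -> None:
        self.unit_ids = list(unit_ids)
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit ids")
        self._index = {u: i for i, u in enumerate(self.unit_ids)}
        n = len(self.unit_ids)
        nbr: list[set[int]] = [set() for _ in range(n)]
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on unit {a!r}")
            try:
                i, j = self._index[a], self._index[b]
            except KeyError as exc:
                raise ValueError(f"edge endpoint {exc.args[0]!r} is not a unit id") from None
            nbr[i].add(j)
            nbr[j].add(i)
        self.neighbors = [sorted(s) for s in nbr]
        self.m = np.array([len(s) for s in self.neighbors], dtype=int)

    # -- basic protocol ----------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def index_of(self, unit) -> int:
        return self._index[unit]

    def edge_list(self) -> list[tuple]:
        """Each undirected edge once, as (unit_id_a, unit_id_b) with a before b."""
        out = []
        for i, nbrs in enumerate(self.neighbors):
            for j in nbrs:
                if i < j:
                    out.append((self.unit_ids[i], self.unit_ids[j]))
        return out

    @property
    def n_edges(self) -> int:
        return int(self.m.sum()) // 2

    def is_connected(self) -> bool:
        return len(connected_components(self)) == 1

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_units))
        for i, nbrs in enumerate(self.neighbors):
            g.add_edges_from((i, j) for j in nbrs if i < j)
        return g

    # -- I/O ---------------------------------------------------------------
    def to_edge_csv(self, path) -> None:
        """Write the adjacency as a two-column undirected edge list (each pair once)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["unit_a", "unit_b"])
            for a, b in self.edge_list():
                writer.writerow([a, b])

    @classmethod
    def from_edge_csv(cls, path, unit_ids: Sequence | None = None) -> "AdjacencyGraph":
        """Read a two-column edge-list CSV (header optional).

        If ``unit_ids`` is not given, the units are the sorted set of labels
        appearing in the file.
        """
        edges = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            for row in reader:
                if not row or row[0].strip().lower() in ("unit_a", "from", "source"):
                    continue
                edges.append((row[0].strip(), row[1].strip()))
        if unit_ids is None:
            seen = sorted({u for e in edges for u in e})
            unit_ids = seen
        return cls(unit_ids, edges)

    @classmethod
    def from_geojson(cls, source, id_property: str = "id") -> "AdjacencyGraph":
        """Derive shared-boundary adjacency from a GeoJSON FeatureCollection.

        Two polygons are neighbours when their boundaries intersect in a set of
        positive length (point touching does not count). Requires ``shapely``.
        """
        from shapely.geometry import shape  # optional dependency

        if isinstance(source, (str, bytes)):
            with open(source) as fh:
                collection = json.load(fh)
        else:
            collection = source
        feats = collection["features"]
        ids, geoms = [], []
        for k, feat in enumerate(feats):
            props = feat.get("properties") or {}
            ids.append(props.get(id_property, k))
            geoms.append(shape(feat["geometry"]))
        edges = []
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                inter = geoms[i].boundary.intersection(geoms[j].boundary)
                if inter.length > 0:
                    edges.append((ids[i], ids[j]))
        return cls(ids, edges)


def generate_lattice_graph(n_rows: int, n_cols: int) -> AdjacencyGraph:
    """Rook-adjacency rectangular lattice; the default desk-scale district map.

    Unit ids are strings ``"r{row}c{col}"``. An 8x8 lattice gives 64 units with
    the same cardinality as the Bangladesh district map, 112 edges, and
    neighbour counts in {2, 3, 4}.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be positive")
    if n_rows * n_cols < 2:
        raise ValueError("lattice needs at least 2 cells")
    ids = [f"r{r}c{c}" for r in range(n_rows) for c in range(n_cols)]
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            if c + 1 < n_cols:
                edges.append((f"r{r}c{c}", f"r{r}c{c + 1}"))
            if r + 1 < n_rows:
                edges.append((f"r{r}c{c}", f"r{r + 1}c{c}"))
    return AdjacencyGraph(ids, edges)


def connected_components(graph: AdjacencyGraph) -> list[set]:
    """Partition of the unit ids into connected components."""
    comps = nx.connected_components(graph.to_networkx())
    return [{graph.unit_ids[i] for i in comp} for comp in comps]


def build_icar_precision(graph: AdjacencyGraph) -> PrecisionStructure:
    """Unit precision of the intrinsic CAR prior: Q = D - A.

    The implied full conditionals are b_j | b_{-j} ~ N(mean of neighbours,
    sigma_b^2 / m_j). Row sums are zero; on a connected graph the rank
    deficiency is 1 with null space = constants.
    """
    comps = connected_components(graph)
    if len(comps) != 1:
        raise ValueError(
            f"ICAR prior requires a connected graph; found {len(comps)} components"
        )
    n = graph.n_units
    rows, cols, vals = [], [], []
    for i, nbrs in enumerate(graph.neighbors):
        rows.append(i)
        cols.append(i)
        vals.append(float(graph.m[i]))
        for j in nbrs:
            rows.append(i)
            cols.append(j)
            vals.append(-1.0)
    q = sp.csr_array((vals, (rows, cols)), shape=(n, n))
    return PrecisionStructure(q, 1, "ICAR", "sum-to-zero (constants)")


def difference_operator(K: int, order: int) -> sp.csr_array:
    """Order-``order`` forward-difference operator on 1..K, shape (K-order, K)."""
    d = sp.eye_array(K, format="csr")
    for _ in range(order):
        k = d.shape[0]
        step = sp.csr_array(
            (
                np.concatenate([-np.ones(k - 1), np.ones(k - 1)]),
                (
                    np.concatenate([np.arange(k - 1), np.arange(k - 1)]),
                    np.concatenate([np.arange(k - 1), np.arange(1, k)]),
                ),
            ),
            shape=(k - 1, k),
        )
        d = step @ d
    return d


def build_rw_precision(K: int, order: int) -> PrecisionStructure:
    """Unit precision of the random-walk prior of the given order on 1..K.

    Q = D' D with D the order-th difference operator; knots are taken equally
    spaced (the prior ignores unequal spacing of the ranked values).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if K < order + 1:
        raise ValueError(f"RW{order} needs at least {order + 1} knots, got {K}")
    d = difference_operator(K, order)
    q = (d.T @ d).tocsr()
    kind = f"RW{order}"
    constraint = "sum-to-zero (constants)" if order == 1 else "constants and linear trend"
    return PrecisionStructure(q, order, kind, constraint)
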