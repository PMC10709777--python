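"""County adjacency graphs and the intrinsic-CAR (ICAR) precision pattern.

The spatially structured random effect of the BYM convolution model is an
intrinsic conditional autoregressive prior whose (improper) density penalizes
squared differences between neighboring counties:

    p(u | tau) ∝ tau^((N-C)/2) * exp(-tau/2 * sum_{i~j, i<j} (u_i - u_j)^2)

where C is the number of connected components of the adjacency graph (the
rank deficiency).  This module builds the neighbor structure from an
undirected edge list, validates it against the panel's county set, and
exposes the pairwise-difference quadratic form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "AdjacencyStructure",
    "load_adjacency",
    "lattice_edges",
    "icar_quadratic_form",
]


@dataclass
class AdjacencyStructure:
    """Symmetric county neighbor structure with derived ICAR quantities.

    Attributes
    ----------
    county_ids : list of str
        Ordered county identifiers; index positions are used everywhere
        downstream.
    neighbor_lists : list of list of int
        Per-county neighbor index lists (symmetric, no self-loops).
    """

    county_ids: list
    neighbor_lists: list
    n_neighbors: np.ndarray = field(init=False)
    n_components: int = field(init=False)
    component_labels: np.ndarray = field(init=False)

    def __post_init__(self):
        n = len(self.county_ids)
        if len(self.neighbor_lists) != n:
            raise ValueError("one neighbor list per county required")
        for i, nbrs in enumerate(self.neighbor_lists):
            if i in nbrs:
                raise ValueError(f"self-loop at county {self.county_ids[i]}")
            for j in nbrs:
                if i not in self.neighbor_lists[j]:
                    raise ValueError("asymmetric adjacency")
        self.n_neighbors = np.array([len(nb) for nb in self.neighbor_lists])
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, nbrs in enumerate(self.neighbor_lists):
            g.add_edges_from((i, j) for j in nbrs)
        comps = list(nx.connected_components(g))
        self.n_components = len(comps)
        self.component_labels = np.empty(n, dtype=int)
        for c, members in enumerate(comps):
            self.component_labels[list(members)] = c
        self._graph = g

    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @property
    def n_edges(self) -> int:
        return int(self.n_neighbors.sum()) // 2

    def isolated(self) -> list:
        """County ids with no neighbors (permitted but worth flagging)."""
        return [cid for cid, nb in zip(self.county_ids, self.neighbor_lists) if not nb]

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse 0/1 adjacency matrix W."""
        rows, cols = [], []
        for i, nbrs in enumerate(self.neighbor_lists):
            rows.extend([i] * len(nbrs))
            cols.extend(nbrs)
        data = np.ones(len(rows))
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(self.n_counties, self.n_counties)
        )

    def laplacian(self) -> sp.csr_matrix:
        """ICAR precision pattern D - W (graph Laplacian)."""
        return sp.diags(self.n_neighbors.astype(float)) - self.adjacency_matrix()

    def coloring(self) -> list:
        """Greedy proper coloring: lists of county indices, no two adjacent
        indices share a list.  Enables valid parallel single-site MH updates."""
        colors = nx.greedy_color(self._graph, strategy="largest_first")
        k = max(colors.values(), default=0) + 1
        classes = [[] for _ in range(k)]
        for node, c in colors.items():
            classes[c].append(node)
        return [np.array(sorted(cls)) for cls in classes]

    def edge_index(self) -> tuple:
        """(i_idx, j_idx) arrays with i < j, one entry per undirected edge."""
        ii, jj = [], []
        for i, nbrs in enumerate(self.neighbor_lists):
            for j in nbrs:
                if i < j:
                    ii.append(i)
                    jj.append(j)
        return np.array(ii, dtype=int), np.array(jj, dtype=int)


def lattice_edges(n_rows: int, n_cols: int, county_ids: list) -> list:
    """Rook-adjacency edge list for an n_rows x n_cols lattice of counties
    in row-major order.  Returns (id_a, id_b) pairs."""
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((county_ids[i], county_ids[i + 1]))
            if r + 1 < n_rows:
                edges.append((county_ids[i], county_ids[i + n_cols]))
    return edges


def load_adjacency(edge_file, county_ids: list) -> AdjacencyStructure:
    """Read an undirected edge list (``id_a,id_b`` per line) and build the
    validated structure over ``county_ids``.

    Raises
    ------
    ValueError
        On self-loops or edges referencing counties absent from the panel.
    """
    index = {cid: i for i, cid in enumerate(county_ids)}
    if len(index) != len(county_ids):
        raise ValueError("duplicate county ids")
    neighbor_sets = [set() for _ in county_ids]
    with open(edge_file) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'id_a,id_b'")
            a, b = parts
            if a == b:
                raise ValueError(f"line {lineno}: self-loop on {a}")
            try:
                ia, ib = index[a], index[b]
            except KeyError as exc:
                raise ValueError(
                    f"line {lineno}: county {exc.args[0]} not in panel"
                ) from None
            neighbor_sets[ia].add(ib)
            neighbor_sets[ib].add(ia)
    return AdjacencyStructure(
        county_ids=list(county_ids),
        neighbor_lists=[sorted(s) for s in neighbor_sets],
    )


def structure_from_edges(edges, county_ids: list) -> AdjacencyStructure:
    """Build an AdjacencyStructure from in-memory (id_a, id_b) pairs."""
    index = {cid: i for i, cid in enumerate(county_ids)}
    neighbor_sets = [set() for _ in county_ids]
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop on {a}")
        ia, ib = index[a], index[b]
        neighbor_sets[ia].add(ib)
        neighbor_sets[ib].add(ia)
    return AdjacencyStructure(
        county_ids=list(county_ids),
        neighbor_lists=[sorted(s) for s in neighbor_sets],
    )


def icar_quadratic_form(effects, structure: AdjacencyStructure) -> float:
    """Pairwise-difference penalty sum_{i~j, i<j} (e_i - e_j)^2.

    This is the quadratic form e' (D - W) e of the ICAR prior; it is
    non-negative and invariant under adding a constant to all effects
    within a connected component.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.shape[0] != structure.n_counties:
        raise ValueError(
            f"expected {structure.n_counties} effects, got {effects.shape[0]}"
        )
    ii, jj = structure.edge_index()
    if len(ii) == 0:
        return 0.0
    d = effects[ii] - effects[jj]
    if d.ndim == 1:
        return float(np.sum(d * d))
    return float(np.sum(d * d))
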