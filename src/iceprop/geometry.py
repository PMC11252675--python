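"""Programmatic tissue-construct builders and neighbour rules.

Builds the three packaged constructs — a hexagonally packed disc monolayer,
a close-packed spheroid and a rectangular lattice slab — and computes the
cell contact graph under either a centre-distance ("radius") rule or a
membrane-contact rule.  All constructs are deterministic: identical inputs
give identical coordinates.  Coordinates are Cartesian, in micrometres, with
the origin at the construct centroid.

Spherical agents may overlap by up to 20% of a cell radius; every builder
enforces this bound.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ContactGraph",
    "NeighbourRule",
    "Tissue",
    "build_disc_monolayer",
    "build_slab",
    "build_spheroid",
    "neighbours",
    "automorphisms",
    "MAX_OVERLAP",
]

#: Maximum allowed cell-radius overlap fraction.
MAX_OVERLAP = 0.2

#: Default centre-spacing as a fraction of the cell diameter for the
#: lattice-free packings (within the 20%-radius-overlap bound).
DEFAULT_SPACING_FACTOR = 0.85


class GeometryError(ValueError):
    """Invalid tissue-construction input."""


@dataclass(frozen=True)
class ContactGraph:
    """Undirected cell-contact graph with an optional symmetry group.

    ``edges`` are unordered 0-based id pairs; ``symmetry_group`` is a list of
    permutations (tuples mapping id -> image) that preserve the edge set,
    used for symmetry reduction of the Markov state space.
    """

    N: int
    edges: tuple[tuple[int, int], ...]
    symmetry_group: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        canon = tuple(sorted({(min(i, j), max(i, j)) for i, j in self.edges}))
        for i, j in canon:
            if not (0 <= i < self.N and 0 <= j < self.N) or i == j:
                raise GeometryError(f"invalid edge ({i}, {j}) for N={self.N}")
        object.__setattr__(self, "edges", canon)
        eset = set(canon)
        for perm in self.symmetry_group:
            if sorted(perm) != list(range(self.N)):
                raise GeometryError("symmetry permutation is not a bijection on cell ids")
            mapped = {(min(perm[i], perm[j]), max(perm[i], perm[j])) for i, j in canon}
            if mapped != eset:
                raise GeometryError("symmetry permutation does not preserve the edge set")

    def neighbour_sets(self) -> list[set[int]]:
        out: list[set[int]] = [set() for _ in range(self.N)]
        for i, j in self.edges:
            out[i].add(j)
            out[j].add(i)
        return out

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.N, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def max_degree(self) -> int:
        return int(self.degrees().max()) if self.N else 0

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.N, self.N), dtype=float)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edges)
        return g

    def with_symmetry(self, group: Iterable[Sequence[int]] | None = None) -> "ContactGraph":
        """Return a copy carrying ``group``, or the auto-detected automorphisms."""
        if group is None:
            group = automorphisms(self)
        return ContactGraph(self.N, self.edges, tuple(tuple(p) for p in group))

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for i, j in self.edges:
                fh.write(f"{i} {j}\n")

    @classmethod
    def read_edgelist(cls, path, N: int | None = None) -> "ContactGraph":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                i, j = (int(x) for x in line.split()[:2])
                pairs.append((i, j))
        if N is None:
            N = max((max(p) for p in pairs), default=-1) + 1
        return cls(N, tuple(pairs))


_AUTOMORPHISM_LIMIT = 12


def automorphisms(graph: ContactGraph) -> list[tuple[int, ...]]:
    """Automorphism group of the contact graph (edge-preserving permutations).

    Enumeration via VF2 self-isomorphism; bounded to N <= 12 because the
    group can be factorially large.
    """
    if graph.N > _AUTOMORPHISM_LIMIT:
        raise GeometryError(
            f"automorphism detection limited to N <= {_AUTOMORPHISM_LIMIT}; "
            "supply the symmetry group explicitly"
        )
    g = graph.to_networkx()
    matcher = nx.algorithms.isomorphism.GraphMatcher(g, g)
    return [tuple(m[i] for i in range(graph.N)) for m in matcher.isomorphisms_iter()]


@dataclass(frozen=True)
class NeighbourRule:
    """Neighbourhood definition.

    kind="radius": cells are neighbours iff their centre distance is < R.
    kind="contact": neighbours iff distance <= (1 + contact_slack)(r_i + r_j),
    i.e. the membranes (nearly) touch.
    """

    kind: str = "contact"
    R: float | None = None
    contact_slack: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in ("radius", "contact"):
            raise GeometryError(f"unknown neighbour rule kind {self.kind!r}")
        if self.kind == "radius" and (self.R is None or self.R <= 0):
            raise GeometryError("radius rule requires R > 0")


@dataclass
class Tissue:
    """A collection of spherical cell agents plus contact topology."""

    positions: np.ndarray          # (N, 3) centres [um]
    radii: np.ndarray              # (N,) [um]
    frozen0: np.ndarray            # (N,) bool, pre-frozen seed cells
    graph: ContactGraph | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.radii = np.broadcast_to(np.asarray(self.radii, dtype=float), (n,)).copy()
        if self.frozen0 is None:
            self.frozen0 = np.zeros(n, dtype=bool)
        self.frozen0 = np.asarray(self.frozen0, dtype=bool).reshape(n).copy()
        if np.any(self.radii <= 0):
            raise GeometryError("cell radii must be positive")
        if n > 1:
            d = _pairwise_distances(self.positions)
            s = self.radii[:, None] + self.radii[None, :]
            lower = (1.0 - MAX_OVERLAP) * s
            mask = ~np.eye(n, dtype=bool)
            if np.any(d[mask] < lower[mask] - 1e-9):
                raise GeometryError("construct violates the 20% cell-radius overlap bound")

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    def seed(self, cell_ids: Iterable[int]) -> "Tissue":
        """Return a copy with the given cells pre-frozen."""
        frozen = self.frozen0.copy()
        for c in cell_ids:
            frozen[c] = True
        return Tissue(self.positions.copy(), self.radii.copy(), frozen, self.graph, dict(self.meta))

    def with_graph(self, rule: NeighbourRule) -> "Tissue":
        return Tissue(
            self.positions.copy(), self.radii.copy(), self.frozen0.copy(),
            neighbours(self, rule), dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "radius": self.radii,
                "frozen0": self.frozen0.astype(int),
            }
        )

    def save(self, table_path, edgelist_path=None) -> None:
        self.to_frame().to_csv(table_path, index=False)
        if edgelist_path is not None and self.graph is not None:
            self.graph.write_edgelist(edgelist_path)

    @classmethod
    def load(cls, table_path, edgelist_path=None) -> "Tissue":
        df = pd.read_csv(table_path).sort_values("cell_id")
        graph = None
        if edgelist_path is not None:
            graph = ContactGraph.read_edgelist(edgelist_path, N=len(df))
        return cls(
            positions=df[["x", "y", "z"]].to_numpy(),
            radii=df["radius"].to_numpy(),
            frozen0=df["frozen0"].to_numpy().astype(bool),
            graph=graph,
        )

    def write_vtk(self, path) -> None:
        """Legacy ASCII VTK polydata point cloud (positions + radius + frozen0)."""
        n = self.n_cells
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\niceprop tissue\nASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {n} float\n")
            for p in self.positions:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write(f"VERTICES {n} {2 * n}\n")
            for i in range(n):
                fh.write(f"1 {i}\n")
            fh.write(f"POINT_DATA {n}\nSCALARS radius float 1\nLOOKUP_TABLE default\n")
            for r in self.radii:
                fh.write(f"{r:.6f}\n")
            fh.write("SCALARS frozen0 int 1\nLOOKUP_TABLE default\n")
            for f in self.frozen0:
                fh.write(f"{int(f)}\n")


def _pairwise_distances(pos: np.ndarray) -> np.ndarray:
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def _centre_and_sort(points: np.ndarray, n: int) -> np.ndarray:
    """Keep the n points closest to the origin, deterministic tie-break."""
    d = np.sqrt((points**2).sum(1))
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0], np.round(d, 9)))
    kept = points[order[:n]]
    return kept - kept.mean(axis=0)


def build_disc_monolayer(
    n_cells: int,
    cell_diameter: float = 21.0,
    spacing_factor: float = DEFAULT_SPACING_FACTOR,
    packing: str = "hex",
) -> Tissue:
    """Planar disc monolayer filled ring-by-ring from the centre.

    Cells sit on a hexagonal (default) or square lattice with centre spacing
    ``spacing_factor * cell_diameter`` and are retained in order of distance
    from the centre until exactly ``n_cells`` remain.
    """
    if n_cells < 1:
        raise GeometryError("n_cells must be >= 1")
    if spacing_factor < (1.0 - MAX_OVERLAP):
        raise GeometryError("spacing_factor violates the 20% overlap bound")
    s = spacing_factor * cell_diameter
    # generous lattice patch, trimmed to the n_cells nearest the centre
    m = int(np.ceil(np.sqrt(n_cells))) + 3
    pts = []
    for q in range(-m, m + 1):
        for r in range(-m, m + 1):
            if packing == "hex":
                x = s * (q + 0.5 * r)
                y = s * (np.sqrt(3.0) / 2.0) * r
            elif packing == "square":
                x, y = s * q, s * r
            else:
                raise GeometryError(f"unknown packing {packing!r}")
            pts.append((x, y, 0.0))
    pos = _centre_and_sort(np.array(pts), n_cells)
    return Tissue(
        positions=pos,
        radii=np.full(n_cells, cell_diameter / 2.0),
        frozen0=np.zeros(n_cells, dtype=bool),
        meta={
            "kind": "disc_monolayer", "n_cells": n_cells, "cell_diameter": cell_diameter,
            "spacing_factor": spacing_factor, "packing": packing,
        },
    )


def build_spheroid(
    target_cells: int,
    spheroid_diameter: float = 100.0,
    cell_diameter: float = 21.0,
    spacing_factor: float = DEFAULT_SPACING_FACTOR,
) -> Tissue:
    """Close-packed (FCC) spheroid of exactly ``target_cells`` cells.

    Lattice sites are retained in order of distance from the spheroid centre.
    The achieved bounding diameter (2 max centre distance + cell diameter) is
    reported in ``meta`` and checked against ``spheroid_diameter`` only
    loosely (the packing, not the target, fixes it).
    """
    if target_cells < 1:
        raise GeometryError("target_cells must be >= 1")
    if spacing_factor < (1.0 - MAX_OVERLAP):
        raise GeometryError("spacing_factor violates the 20% overlap bound")
    s = spacing_factor * cell_diameter
    a = s / np.sqrt(2.0)  # cubic sub-lattice constant; even-sum sites are FCC
    m = int(np.ceil((target_cells * 1.5) ** (1.0 / 3.0))) + 3
    pts = [
        (a * i, a * j, a * k)
        for i, j, k in itertools.product(range(-m, m + 1), repeat=3)
        if (i + j + k) % 2 == 0
    ]
    pos = _centre_and_sort(np.array(pts), target_cells)
    bounding = 2.0 * float(np.sqrt((pos**2).sum(1)).max()) + cell_diameter
    if bounding > 3.0 * spheroid_diameter:
        raise GeometryError(
            f"target_cells={target_cells} cannot be packed near diameter "
            f"{spheroid_diameter} um under the overlap bound (got {bounding:.0f} um)"
        )
    return Tissue(
        positions=pos,
        radii=np.full(target_cells, cell_diameter / 2.0),
        frozen0=np.zeros(target_cells, dtype=bool),
        meta={
            "kind": "spheroid", "target_cells": target_cells,
            "spheroid_diameter": spheroid_diameter, "cell_diameter": cell_diameter,
            "spacing_factor": spacing_factor, "bounding_diameter": bounding,
        },
    )


def build_slab(nx_: int, ny: int, nz: int, cell_diameter: float = 21.0) -> Tissue:
    """Rectangular lattice slab of touching cells (spacing = diameter)."""
    if min(nx_, ny, nz) < 1:
        raise GeometryError("all slab counts must be >= 1")
    d = cell_diameter
    grid = np.array(
        [(d * i, d * j, d * k) for i, j, k in itertools.product(range(nx_), range(ny), range(nz))]
    )
    grid = grid - grid.mean(axis=0)
    n = nx_ * ny * nz
    return Tissue(
        positions=grid,
        radii=np.full(n, d / 2.0),
        frozen0=np.zeros(n, dtype=bool),
        meta={
            "kind": "slab", "nx": nx_, "ny": ny, "nz": nz, "cell_diameter": d,
            "extents": (nx_ * d, ny * d, nz * d),
        },
    )


def neighbours(tissue: Tissue, rule: NeighbourRule) -> ContactGraph:
    """Contact graph of a tissue under a neighbourhood rule.

    The relation is symmetric and irreflexive by construction.
    """
    pos = tissue.positions
    n = tissue.n_cells
    if n <= 1:
        return ContactGraph(n, ())
    d = _pairwise_distances(pos)
    if rule.kind == "radius":
        mask = d < rule.R
    else:
        s = tissue.radii[:, None] + tissue.radii[None, :]
        mask = d <= (1.0 + rule.contact_slack) * s
    np.fill_diagonal(mask, False)
    ii, jj = np.nonzero(np.triu(mask, 1))
    return ContactGraph(n, tuple(zip(ii.tolist(), jj.tolist())))
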