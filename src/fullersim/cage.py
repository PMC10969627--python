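"""Construction and graph analysis of the C60-Ih fullerene cage.

The buckminsterfullerene cage is a truncated icosahedron: 60 carbon
vertices, 90 edges, 12 pentagonal and 20 hexagonal faces.  Everything
here is built algorithmically from the canonical vertex orbit of the
truncated icosahedron, so the package needs no external coordinate
files.  The graph machinery (face perception, edge classification,
automorphism counting) also works on small test polyhedra such as the
cube and the dodecahedron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "CageGeometry",
    "CageGraph",
    "build_c60",
    "perceive_faces",
    "classify_edges",
    "count_automorphisms",
]

CARBON_MASS_AMU = 12.011

PHI = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass
class CageGeometry:
    """Cartesian description of a cage: positions (Å) and atomic masses (amu)."""

    positions: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if self.masses.shape != (self.positions.shape[0],):
            raise ValueError("masses must match positions")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def center(self) -> np.ndarray:
        """Center of mass (Å)."""
        return self.masses @ self.positions / self.masses.sum()

    def radii(self) -> np.ndarray:
        """Distance of each atom from the center of mass (Å)."""
        return np.linalg.norm(self.positions - self.center, axis=1)


@dataclass
class CageGraph:
    """Bond graph of a cage with (optionally) perceived faces.

    ``edges`` are canonical: each pair sorted, list sorted
    lexicographically.  ``faces`` are vertex cycles, canonically rotated
    (smallest vertex first, smaller neighbor second) and sorted.
    ``embedding`` carries the coordinates used for geometric face
    tracing when available.
    """

    n_atoms: int
    edges: list[tuple[int, int]]
    faces: list[tuple[int, ...]] | None = None
    edge_class: list[str] | None = None
    embedding: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.edges = sorted(tuple(sorted(e)) for e in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_faces(self) -> int:
        return 0 if self.faces is None else len(self.faces)

    def edge_index(self) -> dict[tuple[int, int], int]:
        return {e: i for i, e in enumerate(self.edges)}

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return [sorted(a) for a in adj]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_atoms, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.edges)
        return g

    def face_sizes(self) -> dict[int, int]:
        """Histogram of face sizes, e.g. {5: 12, 6: 20} for C60."""
        if self.faces is None:
            raise ValueError("faces not perceived")
        sizes: dict[int, int] = {}
        for f in self.faces:
            sizes[len(f)] = sizes.get(len(f), 0) + 1
        return sizes


def _truncated_icosahedron_vertices() -> np.ndarray:
    """The 60 vertices as even (cyclic) permutations of the sign orbits of
    (0, ±1, ±3φ), (±1, ±(2+φ), ±2φ) and (±2, ±(1+2φ), ±φ); edge length 2."""
    seeds = [
        (0.0, 1.0, 3.0 * PHI),
        (1.0, 2.0 + PHI, 2.0 * PHI),
        (2.0, 1.0 + 2.0 * PHI, PHI),
    ]
    pts = set()
    for seed in seeds:
        for sx in (1.0, -1.0):
            for sy in (1.0, -1.0):
                for sz in (1.0, -1.0):
                    a, b, c = seed[0] * sx, seed[1] * sy, seed[2] * sz
                    for p in ((a, b, c), (b, c, a), (c, a, b)):
                        pts.add(tuple(round(x, 12) for x in p))
    arr = np.array(sorted(pts), dtype=float)
    if arr.shape != (60, 3):  # pragma: no cover - construction sanity
        raise RuntimeError(f"vertex orbit produced {arr.shape[0]} points, not 60")
    return arr


def _canonical_order(positions: np.ndarray) -> np.ndarray:
    """Deterministic atom numbering: ascending (z, y, x)."""
    return np.lexsort((positions[:, 0], positions[:, 1], positions[:, 2]))


def _nearest_neighbor_edges(positions: np.ndarray) -> list[tuple[int, int]]:
    # bonded pairs sit at the minimum distance; next shell is >= 1.6x away
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    cutoff = 1.2 * d.min()
    ii, jj = np.nonzero(d < cutoff)
    return sorted((int(i), int(j)) for i, j in zip(ii, jj) if i < j)


def build_c60(target_edge_length: float = 1.44) -> tuple[CageGeometry, CageGraph]:
    """Build the ideal C60-Ih truncated icosahedron.

    Parameters
    ----------
    target_edge_length:
        Desired mean nearest-neighbor (bond) distance in Å.  The ideal
        solid has a single edge length, so every bond gets this length.

    Returns
    -------
    (CageGeometry, CageGraph)
        Geometry in Å with carbon masses, and the bond graph with the
        32 faces perceived and the 90 edges classified 6:6 / 6:5.
    """
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be positive")
    unit = _truncated_icosahedron_vertices()
    unit = unit[_canonical_order(unit)]
    edges = _nearest_neighbor_edges(unit)
    lengths = [np.linalg.norm(unit[i] - unit[j]) for i, j in edges]
    positions = unit * (target_edge_length / np.mean(lengths))
    geometry = CageGeometry(
        positions=positions, masses=np.full(60, CARBON_MASS_AMU)
    )
    graph = CageGraph(n_atoms=60, edges=edges, embedding=positions.copy())
    graph.faces = perceive_faces(graph)
    graph.edge_class = classify_edges(graph)
    return geometry, graph


# ---------------------------------------------------------------------------
# face perception
# ---------------------------------------------------------------------------


def _canonical_face(cycle: list[int]) -> tuple[int, ...]:
    k = cycle.index(min(cycle))
    c = cycle[k:] + cycle[:k]
    if c[-1] < c[1]:
        c = [c[0]] + c[:0:-1]
    return tuple(c)


def _rotation_system_geometric(graph: CageGraph) -> dict[int, list[int]]:
    """Order each vertex's neighbors counterclockwise about the outward
    radial direction (valid for convex, origin-centered cages)."""
    pos = graph.embedding
    center = pos.mean(axis=0)
    adj = graph.adjacency()
    rot: dict[int, list[int]] = {}
    for v in range(graph.n_atoms):
        normal = pos[v] - center
        normal = normal / np.linalg.norm(normal)
        # in-plane basis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ normal) * normal
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        ang = []
        for w in adj[v]:
            d = pos[w] - pos[v]
            ang.append(np.arctan2(d @ e2, d @ e1))
        rot[v] = [w for _, w in sorted(zip(ang, adj[v]))]
    return rot


def _rotation_system_planar(graph: CageGraph) -> dict[int, list[int]]:
    ok, emb = nx.check_planarity(graph.to_networkx())
    if not ok:
        raise ValueError("graph is not planar; cannot perceive faces")
    return {v: list(emb.neighbors_cw_order(v)) for v in emb.nodes()}


def _trace_faces(graph: CageGraph, rot: dict[int, list[int]]) -> list[tuple[int, ...]]:
    faces = []
    seen: set[tuple[int, int]] = set()
    for i, j in graph.edges:
        for u0, v0 in ((i, j), (j, i)):
            if (u0, v0) in seen:
                continue
            cycle = []
            u, v = u0, v0
            while (u, v) not in seen:
                seen.add((u, v))
                cycle.append(u)
                nbrs = rot[v]
                u, v = v, nbrs[(nbrs.index(u) - 1) % len(nbrs)]
                if len(cycle) > graph.n_atoms:
                    raise RuntimeError("face tracing failed to close a cycle")
            if (u, v) != (u0, v0):
                raise RuntimeError("face tracing failed to close a cycle")
            faces.append(_canonical_face(cycle))
    return sorted(set(faces))


def perceive_faces(graph: CageGraph) -> list[tuple[int, ...]]:
    """Perceive the facial cycles of a 3-regular polyhedral graph.

    Uses geometric face tracing (neighbors ordered around the outward
    radial direction) when the graph carries an embedding; otherwise
    falls back to the combinatorial rotation system of a planar
    embedding.  Raises if the graph is not 3-regular or tracing fails.
    """
    deg = graph.degrees()
    if not np.all(deg == 3):
        raise ValueError("face perception requires a 3-regular graph")
    if graph.embedding is not None:
        rot = _rotation_system_geometric(graph)
    else:
        rot = _rotation_system_planar(graph)
    faces = _trace_faces(graph, rot)
    # Euler sanity: V - E + F = 2 for a polyhedral (spherical) graph
    if graph.n_atoms - graph.n_edges + len(faces) != 2:
        raise RuntimeError("face tracing produced a non-spherical face set")
    return faces


def _edge_faces(graph: CageGraph) -> dict[tuple[int, int], list[int]]:
    ef: dict[tuple[int, int], list[int]] = {e: [] for e in graph.edges}
    for fi, face in enumerate(graph.faces):
        m = len(face)
        for k in range(m):
            e = tuple(sorted((face[k], face[(k + 1) % m])))
            ef[e].append(fi)
    return ef


def classify_edges(graph: CageGraph) -> list[str]:
    """Label each edge ``"6:6"`` (between two hexagons) or ``"6:5"``
    (between a hexagon and a pentagon).

    Raises if any edge borders two pentagons — C60-Ih has isolated
    pentagons, so a 5:5 contact signals a broken graph.
    """
    if graph.faces is None:
        raise ValueError("faces must be perceived before classifying edges")
    labels = []
    for e, fis in _edge_faces(graph).items():
        if len(fis) != 2:
            raise ValueError(f"edge {e} borders {len(fis)} faces, expected 2")
        sizes = sorted(len(graph.faces[fi]) for fi in fis)
        if sizes == [6, 6]:
            labels.append("6:6")
        elif sizes == [5, 6]:
            labels.append("6:5")
        elif sizes == [5, 5]:
            raise ValueError(f"edge {e} borders two pentagons (not an IPR cage)")
        else:
            labels.append(f"{sizes[1]}:{sizes[0]}")
    return labels


# ---------------------------------------------------------------------------
# automorphisms
# ---------------------------------------------------------------------------


def count_automorphisms(graph: CageGraph) -> int:
    """Exact order of the graph automorphism group.

    Backtracking over vertices in BFS order: every non-root vertex has a
    previously mapped neighbor, so candidate images are drawn from the
    intersection of the images' neighborhoods, which keeps the search
    tree within degree^2 of the symmetry count for vertex-transitive
    cages.
    """
    n = graph.n_atoms
    adj = [set(a) for a in graph.adjacency()]
    deg = [len(a) for a in adj]
    if n == 0:
        return 1
    order = list(nx.bfs_tree(graph.to_networkx(), 0).nodes()) if graph.edges else list(range(n))
    if len(order) != n:
        raise ValueError("graph must be connected")
    mapping: list[int | None] = [None] * n
    used = [False] * n
    count = 0

    def extend(k: int) -> None:
        nonlocal count
        if k == n:
            count += 1
            return
        u = order[k]
        mapped_nbrs = [mapping[x] for x in adj[u] if mapping[x] is not None]
        if mapped_nbrs:
            cands = set(adj[mapped_nbrs[0]])
            for mn in mapped_nbrs[1:]:
                cands &= adj[mn]
        else:
            cands = set(range(n))
        for w in sorted(cands):
            if used[w] or deg[w] != deg[u]:
                continue
            # bijectivity of adjacency on the mapped prefix, both directions
            ok = True
            for x in adj[u]:
                mx = mapping[x]
                if mx is not None and w not in adj[mx]:
                    ok = False
                    break
            if ok:
                n_back = sum(1 for y in adj[w] if used[y])
                if n_back != len(mapped_nbrs):
                    ok = False
            if not ok:
                continue
            mapping[u] = w
            used[w] = True
            extend(k + 1)
            mapping[u] = None
            used[w] = False

    extend(0)
    return count


def brute_force_automorphisms(graph: CageGraph) -> int:
    """Reference count by exhaustive permutation search (tiny graphs only)."""
    from itertools import permutations

    n = graph.n_atoms
    if n > 9:
        raise ValueError("brute force limited to <= 9 vertices")
    eset = set(graph.edges)
    count = 0
    for perm in permutations(range(n)):
        if all(tuple(sorted((perm[i], perm[j]))) in eset for i, j in eset):
            count += 1
    return count


def graph_distances(graph: CageGraph, sources: list[int]) -> np.ndarray:
    """BFS distance from a vertex set to every vertex."""
    from collections import deque

    adj = graph.adjacency()
    dist = np.full(graph.n_atoms, -1, dtype=int)
    q = deque()
    for s in sources:
        dist[s] = 0
        q.append(s)
    while q:
        v = q.popleft()
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist
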