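"""Bond-order variants of C60, Kekulé combinatorics and formal charges.

Each carbon has valence 4 shared over its 3 bonds, so one bond per atom
is "extra": an integer assignment (single/double) is exactly a perfect
matching of the cage graph (a Kekulé structure), and the fully
delocalized resonance hybrid spreads the valence evenly, giving every
bond the fractional order 4/3.

Five shipped variants:

``C60``
    the resonance hybrid — all 90 bonds of order 4/3 (≈1.33);
``FB1``
    the unique icosahedrally symmetric Kekulé structure: all 30 bonds
    between hexagons (6:6) double, all 60 pentagon-edge (6:5) bonds
    single — every double bond points outward from a pentagon;
``FB2``
    two antipodal pentagons keep the FB1 motif (doubles outward,
    singles inside); every remaining pentagon carries two double bonds
    inside the ring and one pointing outward;
``FB3``
    as FB2, but the two antipodal pentagons hold internal resonance
    bonds of order 3/2 (10 such bonds) with single outward bonds;
``FB4``
    every pentagon has exactly one internal double bond and three
    double bonds pointing outward.

Orders are stored as exact :class:`fractions.Fraction` so the per-atom
valence sums close exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np

from fullersim.cage import CageGraph, graph_distances

__all__ = [
    "VARIANTS",
    "BondOrderAssignment",
    "FormalChargeSet",
    "assign_variant",
    "solve_orders",
    "count_kekule",
    "brute_force_kekule",
    "formal_charges",
]

VARIANTS = ("C60", "FB1", "FB2", "FB3", "FB4")

VALENCE = Fraction(4)


@dataclass
class BondOrderAssignment:
    """Per-edge bond orders for one variant, aligned with ``graph.edges``."""

    variant_name: str
    orders: list[Fraction]
    special_faces: tuple[int, ...] = ()
    edges: list[tuple[int, int]] | None = None

    def orders_float(self) -> np.ndarray:
        return np.array([float(o) for o in self.orders])

    def atom_valences(self, graph: CageGraph) -> list[Fraction]:
        val = [Fraction(0)] * graph.n_atoms
        for (i, j), o in zip(graph.edges, self.orders):
            val[i] += o
            val[j] += o
        return val

    def double_bond_edges(self, graph: CageGraph) -> list[tuple[int, int]]:
        return [e for e, o in zip(graph.edges, self.orders) if o == 2]


@dataclass
class FormalChargeSet:
    """Per-atom charges (e) from a bond-order bookkeeping model."""

    charges: np.ndarray
    model_tag: str

    def net_charge(self) -> float:
        return float(np.sum(self.charges))


class InfeasibleAssignment(ValueError):
    """No bond-order completion satisfies the valence/motif constraints."""


# ---------------------------------------------------------------------------
# constraint solver
# ---------------------------------------------------------------------------


def _backtrack_orders(
    graph: CageGraph,
    fixed: dict[int, Fraction],
    allowed: list[Fraction],
    face_double_counts: dict[int, int] | None = None,
    valence: Fraction = VALENCE,
) -> list[Fraction] | None:
    """Lexicographically smallest completion (by canonical edge index,
    trying allowed orders ascending) in which every atom's incident
    orders sum to 4; optionally constrain the number of order-2 edges
    inside given faces.  Returns None when infeasible."""
    edges = graph.edges
    n_e = len(edges)
    allowed = sorted(set(allowed))
    amin, amax = allowed[0], allowed[-1]

    orders: list[Fraction | None] = [None] * n_e
    atom_sum = [Fraction(0)] * graph.n_atoms
    atom_und = [0] * graph.n_atoms
    for k, (i, j) in enumerate(edges):
        atom_und[i] += 1
        atom_und[j] += 1

    # face bookkeeping for motif constraints
    eidx = graph.edge_index()
    face_edges: dict[int, list[int]] = {}
    edge_faces_c: dict[int, list[int]] = {}
    if face_double_counts:
        for fi in face_double_counts:
            face = graph.faces[fi]
            m = len(face)
            fe = [eidx[tuple(sorted((face[t], face[(t + 1) % m])))] for t in range(m)]
            face_edges[fi] = fe
            for k in fe:
                edge_faces_c.setdefault(k, []).append(fi)
    face_dbl = {fi: 0 for fi in face_edges}
    face_und = {fi: len(fe) for fi, fe in face_edges.items()}

    def atom_ok(a: int) -> bool:
        return (
            atom_sum[a] + amin * atom_und[a] <= valence
            and atom_sum[a] + amax * atom_und[a] >= valence
        )

    def place(k: int, val: Fraction) -> bool:
        """Set edge k to val; return False if any constraint is violated."""
        i, j = edges[k]
        orders[k] = val
        for a in (i, j):
            atom_sum[a] += val
            atom_und[a] -= 1
        ok = atom_ok(i) and atom_ok(j)
        for fi in edge_faces_c.get(k, ()):
            face_und[fi] -= 1
            if val == 2:
                face_dbl[fi] += 1
            tgt = face_double_counts[fi]
            if not (face_dbl[fi] <= tgt <= face_dbl[fi] + face_und[fi]):
                ok = False
        return ok

    def unplace(k: int, val: Fraction) -> None:
        i, j = edges[k]
        orders[k] = None
        for a in (i, j):
            atom_sum[a] -= val
            atom_und[a] += 1
        for fi in edge_faces_c.get(k, ()):
            face_und[fi] += 1
            if val == 2:
                face_dbl[fi] -= 1

    # apply fixed edges first
    for k, val in sorted(fixed.items()):
        if orders[k] is not None:
            raise ValueError(f"edge {k} fixed twice")
        if not place(k, Fraction(val)):
            return None

    free = [k for k in range(n_e) if orders[k] is None]

    def solve(pos: int) -> bool:
        if pos == len(free):
            return True
        k = free[pos]
        for val in allowed:
            if place(k, val):
                if solve(pos + 1):
                    return True
            unplace(k, val)
        return False

    if not solve(0):
        return None
    return [Fraction(o) for o in orders]


def solve_orders(
    graph: CageGraph,
    fixed_edges: dict[tuple[int, int], Fraction] | dict[int, Fraction] | None = None,
    allowed_orders: set = frozenset({1, 2}),
    valence: int = 4,
) -> BondOrderAssignment:
    """Complete a partial bond-order map under the per-atom valence
    constraint (default 4, the carbon value for 3-regular cages; pass
    ``valence=3`` for bare rings where each atom holds one double bond).

    ``fixed_edges`` may be keyed by canonical edge index or by atom
    pair.  Returns the lexicographically smallest completion; raises
    :class:`InfeasibleAssignment` when none exists.
    """
    eidx = graph.edge_index()
    fixed: dict[int, Fraction] = {}
    for key, val in (fixed_edges or {}).items():
        k = eidx[tuple(sorted(key))] if isinstance(key, tuple) else int(key)
        fixed[k] = Fraction(val)
    allowed = [Fraction(a) for a in allowed_orders]
    orders = _backtrack_orders(graph, fixed, allowed, valence=Fraction(valence))
    if orders is None:
        raise InfeasibleAssignment(
            "no bond-order completion satisfies the valence-4 constraint"
        )
    return BondOrderAssignment(
        variant_name="custom", orders=orders, edges=list(graph.edges)
    )


# ---------------------------------------------------------------------------
# variant construction
# ---------------------------------------------------------------------------


def _pentagon_indices(graph: CageGraph) -> list[int]:
    if graph.faces is None:
        raise ValueError("faces must be perceived")
    return [i for i, f in enumerate(graph.faces) if len(f) == 5]


def antipodal_pentagons(graph: CageGraph) -> tuple[int, int]:
    """The antipodal pentagon pair: the lowest-index pentagon and the
    pentagon at maximal graph distance from it (ties to lowest index)."""
    pents = _pentagon_indices(graph)
    p0 = pents[0]
    dist = graph_distances(graph, list(graph.faces[p0]))
    best, best_d = None, -1
    for p in pents[1:]:
        d = min(int(dist[v]) for v in graph.faces[p])
        if d > best_d:
            best, best_d = p, d
    return p0, best


def _face_internal_edges(graph: CageGraph, fi: int) -> list[int]:
    eidx = graph.edge_index()
    face = graph.faces[fi]
    m = len(face)
    return [eidx[tuple(sorted((face[t], face[(t + 1) % m])))] for t in range(m)]


def _face_outward_edges(graph: CageGraph, fi: int) -> list[int]:
    """For each vertex of the face, its third edge (leaving the ring)."""
    eidx = graph.edge_index()
    face = set(graph.faces[fi])
    adj = graph.adjacency()
    out = []
    for v in graph.faces[fi]:
        for w in adj[v]:
            if w not in face:
                out.append(eidx[tuple(sorted((v, w)))])
    return out


def assign_variant(graph: CageGraph, variant_name: str) -> BondOrderAssignment:
    """Build one of the five shipped bond-order variants.

    Deterministic: the distinguished pentagons of FB2/FB3 are the
    canonical antipodal pair, and all remaining choices are resolved by
    the lexicographically smallest solution of the constraint solver.
    """
    if variant_name not in VARIANTS:
        raise ValueError(f"unknown variant {variant_name!r}; pick one of {VARIANTS}")
    if graph.faces is None or graph.edge_class is None:
        raise ValueError("graph must have faces perceived and edges classified")

    if variant_name == "C60":
        orders = [Fraction(4, 3)] * graph.n_edges
        return BondOrderAssignment("C60", orders, (), list(graph.edges))

    if variant_name == "FB1":
        orders = [
            Fraction(2) if c == "6:6" else Fraction(1) for c in graph.edge_class
        ]
        return BondOrderAssignment("FB1", orders, (), list(graph.edges))

    pents = _pentagon_indices(graph)

    if variant_name in ("FB2", "FB3"):
        special = antipodal_pentagons(graph)
        fixed: dict[int, Fraction] = {}
        inner = Fraction(1) if variant_name == "FB2" else Fraction(3, 2)
        outer = Fraction(2) if variant_name == "FB2" else Fraction(1)
        for fi in special:
            for k in _face_internal_edges(graph, fi):
                fixed[k] = inner
            for k in _face_outward_edges(graph, fi):
                fixed[k] = outer
        counts = {fi: 2 for fi in pents if fi not in special}
        orders = _backtrack_orders(graph, fixed, [Fraction(1), Fraction(2)], counts)
        if orders is None:
            raise InfeasibleAssignment(f"{variant_name} motifs admit no assignment")
        return BondOrderAssignment(variant_name, orders, special, list(graph.edges))

    # FB4: every pentagon carries exactly one internal double bond
    counts = {fi: 1 for fi in pents}
    orders = _backtrack_orders(graph, {}, [Fraction(1), Fraction(2)], counts)
    if orders is None:
        raise InfeasibleAssignment("FB4 motifs admit no assignment")
    return BondOrderAssignment("FB4", orders, (), list(graph.edges))


# ---------------------------------------------------------------------------
# Kekulé structure counting (perfect matchings)
# ---------------------------------------------------------------------------


def count_kekule(graph: CageGraph) -> int:
    """Exact number of Kekulé structures (perfect matchings).

    Recursion always matches the lowest-index unmatched vertex, so the
    state is fully described by the matched-vertex bitmask; memoization
    keeps the reachable state count proportional to the graph bandwidth
    of the canonical (z-sorted) vertex order.  C60 completes in well
    under a second.
    """
    n = graph.n_atoms
    if n % 2:
        return 0
    adj_bits = [0] * n
    for i, j in graph.edges:
        adj_bits[i] |= 1 << j
        adj_bits[j] |= 1 << i
    full = (1 << n) - 1
    memo: dict[int, int] = {}

    def count(mask: int) -> int:
        if mask == full:
            return 1
        cached = memo.get(mask)
        if cached is not None:
            return cached
        unmatched = (~mask) & full
        v = (unmatched & -unmatched).bit_length() - 1  # lowest unmatched vertex
        total = 0
        free = adj_bits[v] & ~mask
        mv = mask | (1 << v)
        while free:
            wbit = free & -free
            free ^= wbit
            total += count(mv | wbit)
        memo[mask] = total
        return total

    return count(0)


def brute_force_kekule(graph: CageGraph) -> int:
    """Reference count by enumerating edge subsets (≤ ~16 edges)."""
    if graph.n_edges > 16:
        raise ValueError("brute force limited to small graphs")
    n = graph.n_atoms
    count = 0
    for sub in combinations(graph.edges, n // 2):
        verts = [v for e in sub for v in e]
        if len(set(verts)) == n:
            count += 1
    return count


# ---------------------------------------------------------------------------
# formal charges
# ---------------------------------------------------------------------------


def formal_charges(
    assignment: BondOrderAssignment,
    graph: CageGraph,
    model_tag: str = "formal",
    delta: float = 0.01,
) -> FormalChargeSet:
    """Per-atom charges implied by a bond-order assignment.

    ``"formal"`` (default): charge_i = 4 − Σ incident orders, in e —
    identically zero for every shipped variant since all of them close
    the valence at 4.

    ``"increment"``: a transparent stand-in for force-field charge
    schemes — every bond of order b transfers ``delta·(b − 1)`` e from
    its lower-index to its higher-index endpoint, producing a zero-sum
    charge set that reflects local bond-order asymmetry.
    """
    n = graph.n_atoms
    if model_tag == "formal":
        val = assignment.atom_valences(graph)
        q = np.array([float(VALENCE - v) for v in val])
        return FormalChargeSet(q, "formal")
    if model_tag == "increment":
        q = np.zeros(n)
        for (i, j), o in zip(graph.edges, assignment.orders):
            t = delta * (float(o) - 1.0)
            q[i] -= t
            q[j] += t
        return FormalChargeSet(q, "increment")
    raise ValueError(f"unknown charge model {model_tag!r}")
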