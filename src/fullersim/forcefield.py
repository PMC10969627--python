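"""Molecular-mechanics energy function for bond-order cages.

The potential has four terms:

* harmonic bond stretching with order-dependent constants,
  ``E = Σ ½ k(b) (r0(b) − r)²``;
* a planarity restraint per atom, ``½ l_p R_p²`` with ``R_p`` the
  perpendicular distance of the atom from the plane of its three
  neighbors (sp2 carbon wants to sit in that plane);
* a Born–Mayer van der Waals term, ``A e^(−B r) − C r⁻⁶`` — short-range
  exponential repulsion with an attractive r⁻⁶ tail;
* direct-sum Coulomb electrostatics, ``k_e q_m q_n / r`` (open
  boundaries; 60 atoms need no cutoff or Ewald machinery).

Unit system: Å, fs, amu, kJ/mol, elementary charge e.  With these,
1 amu·Å²/fs² = 1.0e4 kJ/mol and the Coulomb constant is
k_e = 1389.35 kJ·mol⁻¹·Å·e⁻².

Bond parameters interpolate linearly in the bond order between the
single-bond and double-bond anchors.  The equilibrium-length anchors
r0(1) = 1.455 Å and r0(2) = 1.391 Å are the experimental 6:5 / 6:6 bond
lengths of crystalline C60, so the relaxed structures reproduce the
observed short/long bond separation; the stiffness anchors are plausible
C–C values and absolute vibrational frequencies inherit their
uncertainty.  Every constant is overridable via a config file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from fractions import Fraction

import numpy as np
import yaml

from fullersim.cage import CageGraph
from fullersim.bonds import BondOrderAssignment

__all__ = [
    "KB_KJMOL_K",
    "COULOMB_KJMOL_A_E2",
    "KJMOL_PER_AMU_A2_FS2",
    "ForceFieldParams",
    "EnergyBreakdown",
    "MolecularSystem",
    "bond_energy",
    "planarity_energy",
    "nonbonded_energy",
    "total_energy",
]

KB_KJMOL_K = 0.008314462618  # Boltzmann constant, kJ/mol/K
COULOMB_KJMOL_A_E2 = 1389.35  # k_e, kJ/mol·Å/e²
KJMOL_PER_AMU_A2_FS2 = 1.0e4  # energy-unit bridge for the MD integrator


@dataclass
class ForceFieldParams:
    """All tunable constants of the energy function.

    ``k_of`` / ``r0_of`` map a bond order b ∈ [1, 2] to the stretch
    constant (kJ/mol/Å²) and equilibrium length (Å) by linear
    interpolation between the order-1 and order-2 anchors.
    """

    k1: float = 1600.0      # stretch constant of a single bond, kJ/mol/Å²
    k2: float = 3200.0      # stretch constant of a double bond
    r0_1: float = 1.455     # single-bond equilibrium length, Å (6:5 experimental)
    r0_2: float = 1.391     # double-bond equilibrium length, Å (6:6 experimental)
    lp: float = 400.0       # planarity constant, kJ/mol/Å²
    bm_A: float = 3.0e5     # Born–Mayer prefactor, kJ/mol
    bm_B: float = 3.6       # Born–Mayer decay, 1/Å
    bm_C: float = 2.4e3     # dispersion coefficient, kJ/mol·Å⁶
    k_e: float = COULOMB_KJMOL_A_E2
    exclusion_policy: str = "1-3"  # skip nonbonded terms for 1-2 and 1-3 pairs

    def __post_init__(self) -> None:
        if self.k2 < self.k1:
            raise ValueError("k must be nondecreasing in bond order")
        if self.r0_2 > self.r0_1:
            raise ValueError("r0 must be nonincreasing in bond order")
        for name in ("k1", "k2", "lp", "bm_A", "bm_B", "bm_C", "k_e"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")
        if self.exclusion_policy not in ("1-2", "1-3"):
            raise ValueError("exclusion_policy must be '1-2' or '1-3'")

    def k_of(self, order: float | Fraction) -> float:
        return self.k1 + (float(order) - 1.0) * (self.k2 - self.k1)

    def r0_of(self, order: float | Fraction) -> float:
        return self.r0_1 + (float(order) - 1.0) * (self.r0_2 - self.r0_1)

    # -- config round trip ---------------------------------------------------

    def to_sections(self) -> dict:
        return {
            "bonds": {"k1": self.k1, "k2": self.k2, "r0_1": self.r0_1, "r0_2": self.r0_2},
            "planarity": {"lp": self.lp},
            "vdw": {"A": self.bm_A, "B": self.bm_B, "C": self.bm_C,
                    "exclusion_policy": self.exclusion_policy},
            "coulomb": {"k_e": self.k_e},
        }

    @classmethod
    def from_sections(cls, sections: dict) -> "ForceFieldParams":
        kw: dict = {}
        rename = {"A": "bm_A", "B": "bm_B", "C": "bm_C"}
        for sec, vals in sections.items():
            if sec not in ("bonds", "planarity", "vdw", "coulomb"):
                raise ValueError(f"unknown parameter section {sec!r}")
            for key, val in vals.items():
                kw[rename.get(key, key)] = val
        return cls(**kw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_sections(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "ForceFieldParams":
        with open(path) as fh:
            return cls.from_sections(yaml.safe_load(fh))

    def replace(self, **overrides) -> "ForceFieldParams":
        d = asdict(self)
        d.update(overrides)
        return ForceFieldParams(**d)


@dataclass
class EnergyBreakdown:
    """Energy contributions in kJ/mol; ``total`` is their exact sum."""

    bond: float
    planarity: float
    vdw: float
    coulomb: float

    @property
    def total(self) -> float:
        return self.bond + self.planarity + self.vdw + self.coulomb

    def as_dict(self) -> dict[str, float]:
        return {
            "bond": self.bond,
            "planarity": self.planarity,
            "vdw": self.vdw,
            "coulomb": self.coulomb,
            "total": self.total,
        }


# ---------------------------------------------------------------------------
# term implementations (array-level; public wrappers below)
# ---------------------------------------------------------------------------


def _bond_term(x, bi, bj, kk, rr0):
    d = x[bi] - x[bj]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("zero-length bond (coincident bonded atoms)")
    energy = float(np.sum(0.5 * kk * (rr0 - r) ** 2))
    dEdr = kk * (r - rr0)
    gpair = (dEdr / r)[:, None] * d
    grad = np.zeros_like(x)
    np.add.at(grad, bi, gpair)
    np.add.at(grad, bj, -gpair)
    return energy, grad


def _planarity_rows(x, atoms, n1, n2, n3, lp):
    """Energy and the stacked per-site gradient rows [ga | gp | gq | gs]."""
    p, q, s, a = x[n1], x[n2], x[n3], x[atoms]
    u = q - p
    v = s - p
    w = a - p
    nvec = np.cross(u, v)
    nn = np.linalg.norm(nvec, axis=1)
    if np.any(nn < 1e-9 * np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)):
        raise ValueError("collinear neighbor triple: planarity plane degenerate")
    dd = np.einsum("ij,ij->i", nvec, w) / nn
    energy = float(np.sum(0.5 * lp * dd**2))
    f = (lp * dd)[:, None]  # dE/dd
    ga = f * nvec / nn[:, None]
    gq = f * (np.cross(v, w) / nn[:, None]
              - (dd / nn**2)[:, None] * np.cross(v, nvec))
    gs = f * (np.cross(w, u) / nn[:, None]
              - (dd / nn**2)[:, None] * np.cross(nvec, u))
    gp = -(ga + gq + gs)  # translation invariance closes the quadruple
    return energy, np.concatenate([ga, gp, gq, gs], axis=0)


def _planarity_term(x, atoms, n1, n2, n3, lp):
    energy, rows = _planarity_rows(x, atoms, n1, n2, n3, lp)
    m = len(atoms)
    grad = np.zeros_like(x)
    np.add.at(grad, atoms, rows[:m])
    np.add.at(grad, n1, rows[m:2 * m])
    np.add.at(grad, n2, rows[2 * m:3 * m])
    np.add.at(grad, n3, rows[3 * m:])
    return energy, grad


def _nonbonded_term(x, pi, pj, qq, A, B, C, k_e):
    d = x[pi] - x[pj]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 0.1):
        raise ValueError("coincident nonbonded pair")
    e_vdw = float(np.sum(A * np.exp(-B * r) - C / r**6))
    e_cou = float(np.sum(k_e * qq / r))
    dEdr = -A * B * np.exp(-B * r) + 6.0 * C / r**7 - k_e * qq / r**2
    gpair = (dEdr / r)[:, None] * d
    grad = np.zeros_like(x)
    np.add.at(grad, pi, gpair)
    np.add.at(grad, pj, -gpair)
    return e_vdw, e_cou, grad


# ---------------------------------------------------------------------------
# precompiled system for fast repeated evaluation (minimization, MD)
# ---------------------------------------------------------------------------


class MolecularSystem:
    """Graph + bond orders + charges + parameters, with topology-derived
    index arrays precomputed once so energy/gradient evaluation inside
    the MD loop is a handful of vectorized operations."""

    def __init__(
        self,
        graph: CageGraph,
        assignment: BondOrderAssignment,
        charges: np.ndarray | None,
        params: ForceFieldParams | None = None,
        masses: np.ndarray | None = None,
    ):
        self.graph = graph
        self.assignment = assignment
        self.params = params or ForceFieldParams()
        n = graph.n_atoms
        self.charges = np.zeros(n) if charges is None else np.asarray(charges, float)
        from fullersim.cage import CARBON_MASS_AMU

        self.masses = (
            np.full(n, CARBON_MASS_AMU) if masses is None else np.asarray(masses, float)
        )
        p = self.params

        self.bi = np.array([e[0] for e in graph.edges])
        self.bj = np.array([e[1] for e in graph.edges])
        self.kk = np.array([p.k_of(o) for o in assignment.orders])
        self.rr0 = np.array([p.r0_of(o) for o in assignment.orders])

        adj = graph.adjacency()
        if all(len(a) == 3 for a in adj):
            self.pl_atoms = np.arange(n)
            self.pl_n1 = np.array([adj[a][0] for a in range(n)])
            self.pl_n2 = np.array([adj[a][1] for a in range(n)])
            self.pl_n3 = np.array([adj[a][2] for a in range(n)])
        else:
            self.pl_atoms = None

        excl = _excluded_pairs(graph, p.exclusion_policy)
        pi, pj = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) not in excl:
                    pi.append(i)
                    pj.append(j)
        self.pi = np.array(pi, dtype=int)
        self.pj = np.array(pj, dtype=int)
        self.qq = self.charges[self.pi] * self.charges[self.pj]

        # sparse scatter operators: pairwise/per-site gradient rows -> atoms
        # (np.add.at is an order of magnitude slower in the MD loop)
        from scipy.sparse import csr_matrix

        def _scatter(rows_idx, signs):
            ncol = len(rows_idx[0])
            data, ii, jj = [], [], []
            for idx, s in zip(rows_idx, signs):
                data.extend([s] * ncol)
                ii.extend(idx)
                jj.extend(range(ncol))
            return csr_matrix((data, (ii, jj)), shape=(n, ncol))

        self._scat_bond = _scatter((self.bi, self.bj), (1.0, -1.0))
        self._scat_nb = _scatter((self.pi, self.pj), (1.0, -1.0))
        if self.pl_atoms is not None:
            # one column per stacked gradient row [ga | gp | gq | gs]
            self._scat_pl = _scatter(
                (np.concatenate([self.pl_atoms, self.pl_n1, self.pl_n2, self.pl_n3]),),
                (1.0,),
            )

    def energy_grad(self, positions: np.ndarray) -> tuple[EnergyBreakdown, np.ndarray]:
        x = np.asarray(positions, float)
        p = self.params

        # bonds
        d = x[self.bi] - x[self.bj]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-9):
            raise ValueError("zero-length bond (coincident bonded atoms)")
        eb = float(np.sum(0.5 * self.kk * (self.rr0 - r) ** 2))
        grad = self._scat_bond @ ((self.kk * (r - self.rr0) / r)[:, None] * d)

        # planarity
        if self.pl_atoms is not None:
            ep, rows = _planarity_rows(
                x, self.pl_atoms, self.pl_n1, self.pl_n2, self.pl_n3, p.lp
            )
            grad += self._scat_pl @ rows
        else:
            ep = 0.0

        # nonbonded
        d = x[self.pi] - x[self.pj]
        r2 = np.einsum("ij,ij->i", d, d)
        r = np.sqrt(r2)
        if np.any(r < 0.1):
            raise ValueError("coincident nonbonded pair")
        expo = p.bm_A * np.exp(-p.bm_B * r)
        inv6 = 1.0 / (r2 * r2 * r2)
        ev = float(np.sum(expo - p.bm_C * inv6))
        ec = float(np.sum(p.k_e * self.qq / r))
        dEdr = -p.bm_B * expo + 6.0 * p.bm_C * inv6 / r - p.k_e * self.qq / r2
        grad += self._scat_nb @ ((dEdr / r)[:, None] * d)

        return EnergyBreakdown(eb, ep, ev, ec), grad


def _excluded_pairs(graph: CageGraph, policy: str) -> set[tuple[int, int]]:
    adj = graph.adjacency()
    excl: set[tuple[int, int]] = set(graph.edges)  # 1-2
    if policy == "1-3":
        for m in range(graph.n_atoms):
            for a in adj[m]:
                for b in adj[m]:
                    if a < b:
                        excl.add((a, b))
    return excl


# ---------------------------------------------------------------------------
# public per-term operations
# ---------------------------------------------------------------------------


def bond_energy(positions, edges, orders, params: ForceFieldParams):
    """Harmonic stretch energy Σ ½ k(b) (r0(b) − r)² and its gradient."""
    x = np.asarray(positions, float)
    bi = np.array([e[0] for e in edges])
    bj = np.array([e[1] for e in edges])
    kk = np.array([params.k_of(o) for o in orders])
    rr0 = np.array([params.r0_of(o) for o in orders])
    return _bond_term(x, bi, bj, kk, rr0)


def planarity_energy(positions, graph: CageGraph, params: ForceFieldParams):
    """Σ ½ l_p R_p² over atoms, R_p = distance to the neighbor plane."""
    x = np.asarray(positions, float)
    adj = graph.adjacency()
    if not all(len(a) == 3 for a in adj):
        raise ValueError("planarity term requires every atom to have 3 neighbors")
    n = graph.n_atoms
    atoms = np.arange(n)
    n1 = np.array([adj[a][0] for a in range(n)])
    n2 = np.array([adj[a][1] for a in range(n)])
    n3 = np.array([adj[a][2] for a in range(n)])
    return _planarity_term(x, atoms, n1, n2, n3, params.lp)


def nonbonded_energy(positions, graph: CageGraph, charges, params: ForceFieldParams):
    """Born–Mayer vdW + Coulomb over non-excluded pairs.

    Returns ``((E_vdw, E_coulomb), gradient)``.
    """
    x = np.asarray(positions, float)
    q = np.zeros(graph.n_atoms) if charges is None else np.asarray(charges, float)
    excl = _excluded_pairs(graph, params.exclusion_policy)
    pi, pj = [], []
    for i in range(graph.n_atoms):
        for j in range(i + 1, graph.n_atoms):
            if (i, j) not in excl:
                pi.append(i)
                pj.append(j)
    pi = np.array(pi, int)
    pj = np.array(pj, int)
    ev, ec, grad = _nonbonded_term(
        x, pi, pj, q[pi] * q[pj], params.bm_A, params.bm_B, params.bm_C, params.k_e
    )
    return (ev, ec), grad


def total_energy(
    positions,
    graph: CageGraph,
    assignment: BondOrderAssignment,
    charges,
    params: ForceFieldParams | None = None,
):
    """Full energy breakdown and gradient for one configuration."""
    system = MolecularSystem(graph, assignment, charges, params)
    return system.energy_grad(positions)
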