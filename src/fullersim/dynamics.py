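"""Energy minimization and NVT molecular dynamics.

Minimization follows a three-stage protocol: steepest descent with a
backtracking line search, then velocity-damped annealing dynamics with
a 200-step convergence window, then (optionally) an L-BFGS polish with
the analytic gradient to drive the residual gradient norm below tight
tolerances at desk-scale cost.

Dynamics is velocity Verlet with an optional Berendsen weak-coupling
thermostat, λ = sqrt(1 + (dt/τ)(T0/T − 1)).  Initial velocities are
Maxwell–Boltzmann at the target temperature with center-of-mass linear
and angular momentum removed, so the recorded radius-of-gyration signal
carries only internal (vibrational) motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from fullersim.forcefield import (
    EnergyBreakdown,
    KB_KJMOL_K,
    KJMOL_PER_AMU_A2_FS2,
    MolecularSystem,
)
from fullersim.observables import radius_of_gyration

__all__ = ["SimState", "Trajectory", "MinimizeResult", "minimize", "run_md"]

# acceleration in Å/fs² from force in kJ/mol/Å and mass in amu
_ACC = 1.0 / KJMOL_PER_AMU_A2_FS2


@dataclass
class SimState:
    """Instantaneous mechanical state: positions (Å), velocities (Å/fs)."""

    positions: np.ndarray
    velocities: np.ndarray | None = None
    time: float = 0.0  # fs
    step: int = 0

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(),
            None if self.velocities is None else self.velocities.copy(),
            self.time,
            self.step,
        )


@dataclass
class Trajectory:
    """Recorded time series at a fixed stride."""

    stride: int
    dt: float  # fs, integration step
    times: np.ndarray  # fs
    rg_series: np.ndarray  # Å
    bond_length_series: np.ndarray  # (n_records, n_edges), Å
    temperature_series: np.ndarray  # K
    potential_series: np.ndarray  # kJ/mol
    kinetic_series: np.ndarray  # kJ/mol
    total_series: np.ndarray  # kJ/mol
    positions_frames: np.ndarray | None = None

    @property
    def dt_record(self) -> float:
        """Spacing of the recorded samples in fs."""
        return self.stride * self.dt

    @property
    def n_records(self) -> int:
        return len(self.times)


@dataclass
class MinimizeResult:
    state: SimState
    energy: EnergyBreakdown
    grad_norm: float
    n_sd_steps: int
    n_anneal_steps: int


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kJ/mol."""
    return 0.5 * float(np.sum(masses[:, None] * velocities**2)) * KJMOL_PER_AMU_A2_FS2


def instantaneous_temperature(
    velocities: np.ndarray, masses: np.ndarray, n_dof: int | None = None
) -> float:
    """Kinetic temperature in K (default DOF: 3N − 6)."""
    n = len(masses)
    if n_dof is None:
        n_dof = max(3 * n - 6, 1)
    return 2.0 * kinetic_energy(velocities, masses) / (n_dof * KB_KJMOL_K)


def _remove_rigid_motion(x, v, m):
    """Zero the center-of-mass velocity and the total angular momentum."""
    v = v - (m[:, None] * v).sum(axis=0) / m.sum()
    com = m @ x / m.sum()
    r = x - com
    ang = np.sum(m[:, None] * np.cross(r, v), axis=0)
    r2 = np.einsum("ij,ij->i", r, r)
    inertia = (m[:, None, None] * (np.eye(3)[None] * r2[:, None, None]
                                   - np.einsum("ij,ik->ijk", r, r))).sum(axis=0)
    omega = np.linalg.solve(inertia, ang)
    v = v - np.cross(omega, r)
    return v


def maxwell_boltzmann_velocities(
    masses: np.ndarray, T: float, seed: int, positions: np.ndarray | None = None
) -> np.ndarray:
    """Draw velocities at temperature T (K); remove rigid-body motion and
    rescale so the kinetic temperature is exactly T."""
    rng = np.random.default_rng(seed)
    m = np.asarray(masses, float)
    sigma = np.sqrt(KB_KJMOL_K * T / (m * KJMOL_PER_AMU_A2_FS2))
    v = rng.normal(size=(len(m), 3)) * sigma[:, None]
    if positions is not None:
        v = _remove_rigid_motion(np.asarray(positions, float), v, m)
    else:
        v = v - (m[:, None] * v).sum(axis=0) / m.sum()
    t_now = instantaneous_temperature(v, m)
    if t_now > 0:
        v *= np.sqrt(T / t_now)
    return v


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------


def minimize(
    state: SimState,
    system: MolecularSystem,
    max_steps: int = 2000,
    tol: float = 1e-4,
    tol_e: float = 0.05,
    max_displacement: float = 0.01,
    anneal_dt: float = 0.5,
    anneal_max_steps: int = 10000,
    anneal_damping: float = 0.9,
    polish: bool = True,
) -> MinimizeResult:
    """Relax a configuration to the nearest local energy minimum.

    Phase 1: steepest descent, step capped at ``max_displacement`` Å per
    atom, halved on uphill trials.  Phase 2: annealing — velocity Verlet
    with velocities damped by ``anneal_damping`` whenever the power
    −∇E·v is negative, convergence checked every 200 steps (energy
    decrease < ``tol_e`` kJ/mol over the window).  Phase 3 (optional):
    L-BFGS with the analytic gradient until the gradient 2-norm falls
    below ``tol``.
    """
    x = np.asarray(state.positions, float).copy()
    e, g = system.energy_grad(x)
    if not np.isfinite(e.total):
        raise ValueError("non-finite energy at minimization start")
    n_sd = 0
    alpha = max_displacement
    for n_sd in range(1, max_steps + 1):
        gnorm = np.linalg.norm(g)
        if gnorm < tol:
            break
        gmax = np.max(np.linalg.norm(g, axis=1))
        step = -g * (alpha / gmax)
        accepted = False
        for _ in range(30):
            e_trial, g_trial = system.energy_grad(x + step)
            if e_trial.total < e.total:
                x += step
                e, g = e_trial, g_trial
                alpha = min(alpha * 1.2, max_displacement)
                accepted = True
                break
            step *= 0.5
            alpha *= 0.5
        if not accepted:
            break
        if not np.isfinite(e.total):
            raise ValueError(f"non-finite energy at steepest-descent step {n_sd}")

    # phase 2: velocity-damped annealing dynamics
    m = system.masses[:, None]
    v = np.zeros_like(x)
    f = -g
    e_window = e.total
    n_anneal = 0
    while n_anneal < anneal_max_steps:
        v += 0.5 * anneal_dt * f / m * _ACC
        x += v * anneal_dt
        e, g = system.energy_grad(x)
        f = -g
        v += 0.5 * anneal_dt * f / m * _ACC
        if float(np.sum(f * v)) < 0.0:
            v *= anneal_damping
        n_anneal += 1
        if n_anneal % 200 == 0:
            if not np.isfinite(e.total):
                raise ValueError(f"non-finite energy at annealing step {n_anneal}")
            if e_window - e.total < tol_e:
                break
            e_window = e.total

    if polish:
        shape = x.shape

        def fun(flat):
            eb, gr = system.energy_grad(flat.reshape(shape))
            return eb.total, gr.ravel()

        # restart L-BFGS until the 2-norm target is met; its own stopping
        # rules (ftol, projected-gradient max-norm) are looser than tol
        for _ in range(5):
            res = scipy_minimize(
                fun, x.ravel(), jac=True, method="L-BFGS-B",
                options={"maxiter": 5000, "gtol": tol * 1e-3, "ftol": 1e-18},
            )
            x = res.x.reshape(shape)
            e, g = system.energy_grad(x)
            if np.linalg.norm(g) < tol:
                break

    out = SimState(positions=x, velocities=np.zeros_like(x), time=state.time,
                   step=state.step)
    return MinimizeResult(out, e, float(np.linalg.norm(g)), n_sd, n_anneal)


# ---------------------------------------------------------------------------
# molecular dynamics
# ---------------------------------------------------------------------------


def run_md(
    state: SimState,
    system: MolecularSystem,
    dt: float = 1.0,
    n_steps: int = 100_000,
    thermostat: str = "berendsen",
    T_target: float = 298.0,
    tau: float = 100.0,
    stride: int = 10,
    seed: int = 0,
    record_positions: bool = False,
) -> Trajectory:
    """Velocity-Verlet NVT/NVE dynamics recording Rg, bond lengths,
    temperature and energies every ``stride`` steps.

    ``thermostat`` is ``"none"`` (NVE) or ``"berendsen"``; velocities are
    initialized Maxwell–Boltzmann at ``T_target`` with the given seed
    when the state carries none.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if thermostat not in ("none", "berendsen"):
        raise ValueError("thermostat must be 'none' or 'berendsen'")
    m = system.masses
    x = np.asarray(state.positions, float).copy()
    if state.velocities is None:
        v = maxwell_boltzmann_velocities(m, T_target, seed, positions=x)
    else:
        v = np.asarray(state.velocities, float).copy()

    n_dof = max(3 * len(m) - 6, 1)
    bi, bj = system.bi, system.bj
    mcol = m[:, None]

    n_rec = n_steps // stride
    times = np.empty(n_rec)
    rg = np.empty(n_rec)
    bls = np.empty((n_rec, len(bi)))
    temps = np.empty(n_rec)
    epot = np.empty(n_rec)
    ekin = np.empty(n_rec)
    etot = np.empty(n_rec)
    frames = np.empty((n_rec, len(m), 3)) if record_positions else None

    e, g = system.energy_grad(x)
    f = -g
    rec = 0
    for step in range(1, n_steps + 1):
        v += (0.5 * dt * _ACC) * f / mcol
        x += v * dt
        e, g = system.energy_grad(x)
        f = -g
        v += (0.5 * dt * _ACC) * f / mcol
        if thermostat == "berendsen":
            t_inst = instantaneous_temperature(v, m, n_dof)
            lam2 = 1.0 + (dt / tau) * (T_target / max(t_inst, 1e-6) - 1.0)
            # clamp: far-from-target starts would otherwise amplify
            # round-off noise geometrically
            v *= min(max(np.sqrt(max(lam2, 0.0)), 0.5), 2.0)
        # pin the center of mass (internal forces leak tiny net momentum
        # through floating-point round-off; thermostat scaling amplifies it)
        v -= (mcol * v).sum(axis=0) / m.sum()
        if step % stride == 0:
            if not np.all(np.isfinite(x)):
                raise ValueError(f"non-finite coordinates at MD step {step}")
            ke = kinetic_energy(v, m)
            times[rec] = state.time + step * dt
            rg[rec] = radius_of_gyration(x, m)
            d = x[bi] - x[bj]
            bls[rec] = np.linalg.norm(d, axis=1)
            temps[rec] = 2.0 * ke / (n_dof * KB_KJMOL_K)
            epot[rec] = e.total
            ekin[rec] = ke
            etot[rec] = e.total + ke
            if frames is not None:
                frames[rec] = x
            rec += 1

    state.positions = x
    state.velocities = v
    state.time += n_steps * dt
    state.step += n_steps
    return Trajectory(
        stride=stride, dt=dt, times=times, rg_series=rg,
        bond_length_series=bls, temperature_series=temps,
        potential_series=epot, kinetic_series=ekin, total_series=etot,
        positions_frames=frames,
    )
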