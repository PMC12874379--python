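"""Energy/force assembly, FIRE relaxation, Langevin dynamics, replica batches.

A :class:`MMSystem` combines a flexible molecule with one of two
interchangeable substrate backends:

* :class:`GridBackend`   -- tricubic B-spline interpolation of the
  precomputed fields (the production path);
* :class:`DirectBackend` -- exact pairwise sums (Morse over lateral images,
  Coulomb through the converged Ewald solver), the accuracy reference.

The molecule's internal energy is evaluated in real space with no periodic
images: harmonic bonds and angles, cosine torsions, and Morse + Coulomb
nonbonded terms over non-excluded pairs (1-2 and 1-3 excluded, 1-4 full).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ACC_EV_A_AMU, EV_PER_AMU_A2_FS2, K_BOLTZMANN
from .bspline import FieldSet
from .core import (EwaldSum, GlobalParams, Molecule, Substrate, morse_pair,
                   substrate_images)

__all__ = [
    "GridBackend",
    "DirectBackend",
    "MMSystem",
    "FIREState",
    "intramolecular_energy_force",
    "total_energy_force",
    "fire_relax",
    "ReplicaBatch",
    "langevin_step",
]


# ---------------------------------------------------------------------------
# intramolecular terms
# ---------------------------------------------------------------------------

def _bond_terms(mol: Molecule, pos: np.ndarray):
    if len(mol.bonds) == 0:
        return 0.0, np.zeros_like(pos)
    i, j = mol.bonds[:, 0], mol.bonds[:, 1]
    d = pos[j] - pos[i]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("zero bond length")
    dr = r - mol.bond_r0
    e = 0.5 * (mol.bond_k * dr ** 2).sum()
    fmag = (mol.bond_k * dr / r)[:, None] * d  # force on i along +d
    f = np.zeros_like(pos)
    np.add.at(f, i, fmag)
    np.add.at(f, j, -fmag)
    return float(e), f


def _angle_terms(mol: Molecule, pos: np.ndarray):
    if len(mol.angles) == 0:
        return 0.0, np.zeros_like(pos)
    i, j, k = mol.angles[:, 0], mol.angles[:, 1], mol.angles[:, 2]
    u = pos[i] - pos[j]
    v = pos[k] - pos[j]
    ru = np.linalg.norm(u, axis=1)
    rv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (ru * rv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    dtheta = theta - mol.angle_theta0
    e = 0.5 * (mol.angle_k * dtheta ** 2).sum()
    # dE/dtheta, chain rule through cos with a safe sin
    sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-12))
    coef = mol.angle_k * dtheta / sin_t  # = -dE/dcos
    du = (v / (ru * rv)[:, None] - (cos_t / ru ** 2)[:, None] * u)
    dv = (u / (ru * rv)[:, None] - (cos_t / rv ** 2)[:, None] * v)
    f = np.zeros_like(pos)
    np.add.at(f, i, coef[:, None] * du)
    np.add.at(f, k, coef[:, None] * dv)
    np.add.at(f, j, -coef[:, None] * (du + dv))
    return float(e), f


def _torsion_terms(mol: Molecule, pos: np.ndarray):
    if len(mol.torsions) == 0:
        return 0.0, np.zeros_like(pos)
    ii, jj, kk, ll = (mol.torsions[:, c] for c in range(4))
    b1 = pos[jj] - pos[ii]
    b2 = pos[kk] - pos[jj]
    b3 = pos[ll] - pos[kk]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / b2n[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(y, x)
    n = mol.torsion_n
    e = (mol.torsion_v * (1.0 + np.cos(n * phi - mol.torsion_phi0))).sum()
    dedphi = -mol.torsion_v * n * np.sin(n * phi - mol.torsion_phi0)
    # analytic dihedral gradient for b1 = r_j - r_i, b2 = r_k - r_j,
    # b3 = r_l - r_k and phi = atan2(m1.n2, n1.n2):
    #   dphi/dr_i =  |b2|/|n1|^2 n1,   dphi/dr_l = -|b2|/|n2|^2 n2
    #   dphi/dr_j = -(1+c1) g_i + c2 g_l,  dphi/dr_k = c1 g_i - (1+c2) g_l
    # with c1 = b1.b2/|b2|^2, c2 = b3.b2/|b2|^2 (gradients sum to zero).
    n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
    n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
    gi = (b2n / n1sq)[:, None] * n1
    gl = -(b2n / n2sq)[:, None] * n2
    c1 = (np.einsum("ij,ij->i", b1, b2) / b2n ** 2)[:, None]
    c2 = (np.einsum("ij,ij->i", b3, b2) / b2n ** 2)[:, None]
    gj = -(1.0 + c1) * gi + c2 * gl
    gk = c1 * gi - (1.0 + c2) * gl
    f = np.zeros_like(pos)
    np.add.at(f, ii, -dedphi[:, None] * gi)
    np.add.at(f, jj, -dedphi[:, None] * gj)
    np.add.at(f, kk, -dedphi[:, None] * gk)
    np.add.at(f, ll, -dedphi[:, None] * gl)
    return float(e), f


def _intra_nonbonded(mol: Molecule, pos: np.ndarray, params: GlobalParams):
    n = mol.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    if len(iu) == 0:
        return 0.0, np.zeros_like(pos)
    keep = np.array([not mol.is_excluded(int(a), int(b))
                     for a, b in zip(iu, ju)])
    iu, ju = iu[keep], ju[keep]
    if len(iu) == 0:
        return 0.0, np.zeros_like(pos)
    d = pos[iu] - pos[ju]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-6):
        raise ValueError("overlapping atoms in intramolecular nonbonded")
    mask = r <= params.r_cut
    eps_ij = np.sqrt(mol.epsilons[iu] * mol.epsilons[ju])
    r_ij = mol.radii[iu] + mol.radii[ju]
    e_m, dedr = morse_pair(r, eps_ij, r_ij, params.alpha)
    e_m = np.where(mask, e_m, 0.0)
    dedr = np.where(mask, dedr, 0.0)
    qq = params.k_e * mol.charges[iu] * mol.charges[ju]
    e_c = qq / r
    dedr_c = -qq / r ** 2
    dedr_tot = dedr + dedr_c
    e = float(e_m.sum() + e_c.sum())
    fpair = -(dedr_tot / r)[:, None] * d  # force on iu
    f = np.zeros_like(pos)
    np.add.at(f, iu, fpair)
    np.add.at(f, ju, -fpair)
    return e, f


def intramolecular_energy_force(mol: Molecule, params: GlobalParams,
                                positions: np.ndarray | None = None):
    """Internal energy of the molecule and per-atom forces.

    Returns ``(E_bonded, E_intra_nonbonded, F)``.  No periodic images of the
    molecule are ever considered.
    """
    pos = mol.positions if positions is None else np.asarray(positions, float)
    e_b, f_b = _bond_terms(mol, pos)
    e_a, f_a = _angle_terms(mol, pos)
    e_t, f_t = _torsion_terms(mol, pos)
    e_nb, f_nb = _intra_nonbonded(mol, pos, params)
    return e_b + e_a + e_t, e_nb, f_b + f_a + f_t + f_nb


# ---------------------------------------------------------------------------
# substrate backends
# ---------------------------------------------------------------------------

class GridBackend:
    """Molecule-substrate interaction through the fitted B-spline fields."""

    def __init__(self, fieldset: FieldSet, params: GlobalParams):
        if abs(fieldset.alpha - params.alpha) > 1e-12:
            raise ValueError("field set alpha != params alpha")
        self.fieldset = fieldset
        self.params = params

    def surface_energy_force(self, mol: Molecule, pos: np.ndarray):
        e_m, e_c, f = self.fieldset.atoms_energy_force(
            mol.epsilons, mol.radii, mol.charges, pos, above_top="zero")
        return float(e_m.sum()), float(e_c.sum()), f


class DirectBackend:
    """Molecule-substrate interaction by exact pairwise sums (reference).

    Morse is truncated per pair at the cutoff over lateral periodic images;
    Coulomb uses the converged Ewald solver of the rigid substrate (whose
    structure factors are precomputed once).
    """

    def __init__(self, substrate: Substrate, params: GlobalParams,
                 coulomb: str = "ewald", n_images: int | None = None):
        self.substrate = substrate
        self.params = params
        self.coulomb = coulomb
        (self._pos, self._q, self._eps, self._rad) = substrate_images(
            substrate, params.r_cut, n_images)
        self._ewald = EwaldSum(substrate) if coulomb == "ewald" else None

    def surface_energy_force(self, mol: Molecule, pos: np.ndarray):
        params = self.params
        a = params.alpha
        # Morse over all (atom, image) pairs at once
        d = pos[:, None, :] - self._pos[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        near = r2 <= params.r_cut ** 2
        r = np.sqrt(np.where(near, r2, 1.0))
        eps_ij = np.sqrt(mol.epsilons[:, None] * self._eps[None, :])
        arg = r - (mol.radii[:, None] + self._rad[None, :])
        e1 = np.where(near, np.exp(-a * arg), 0.0)
        e2 = e1 * e1
        e_morse = float((eps_ij * (e2 - 2.0 * e1)).sum())
        dedr = eps_ij * (-2.0 * a * e2 + 2.0 * a * e1)
        forces = -np.einsum("ij,ijk->ik", dedr / r, d)
        e_coul = 0.0
        if self._ewald is not None:
            v, efield = self._ewald.potential_and_field(pos)
            e_coul = float(np.dot(mol.charges, v))
            forces += mol.charges[:, None] * efield
        elif np.any(mol.charges != 0.0):
            rall = np.sqrt(r2)
            qq = params.k_e * mol.charges[:, None] * self._q[None, :]
            e_coul = float((qq / rall).sum())
            forces += np.einsum("ij,ijk->ik", qq / rall ** 3, d)
        return e_morse, e_coul, forces


@dataclass
class MMSystem:
    """A molecule over a rigid substrate backend, with optional constraints.

    ``constraints`` maps atom index -> fixed position; constrained atoms are
    pinned (position reset, force zeroed) by every driver.
    """

    molecule: Molecule
    backend: GridBackend | DirectBackend
    params: GlobalParams
    positions: np.ndarray = None
    constraints: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positions is None:
            self.positions = self.molecule.positions.copy()
        self.positions = np.array(self.positions, dtype=float)
        for idx in self.constraints:
            if not 0 <= idx < self.molecule.n_atoms:
                raise ValueError(f"constraint index {idx} out of range")

    def apply_constraints(self) -> None:
        for idx, p in self.constraints.items():
            self.positions[idx] = p

    def copy(self) -> "MMSystem":
        return MMSystem(self.molecule, self.backend, self.params,
                        self.positions.copy(), dict(self.constraints))


def total_energy_force(system: MMSystem, positions: np.ndarray | None = None):
    """Full decomposed energy and constrained per-atom forces.

    Returns ``(decomp, F)`` where decomp has keys ``bonded``, ``intra_nb``,
    ``surf_morse``, ``surf_coul`` and ``total`` (their exact sum).  Forces on
    constrained atoms are projected to zero.
    """
    pos = system.positions if positions is None else positions
    e_b, e_nb, f_intra = intramolecular_energy_force(
        system.molecule, system.params, pos)
    e_m, e_c, f_surf = system.backend.surface_energy_force(
        system.molecule, pos)
    f = f_intra + f_surf
    for idx in system.constraints:
        f[idx] = 0.0
    decomp = {"bonded": e_b, "intra_nb": e_nb, "surf_morse": e_m,
              "surf_coul": e_c}
    decomp["total"] = e_b + e_nb + e_m + e_c
    return decomp, f


# ---------------------------------------------------------------------------
# FIRE relaxation
# ---------------------------------------------------------------------------

@dataclass
class FIREState:
    """FIRE integrator state (velocities are in relaxation units)."""

    velocities: np.ndarray
    dt: float
    alpha_mix: float
    n_pos: int = 0

    ALPHA_START = 0.1
    F_INC = 1.1
    F_DEC = 0.5
    F_ALPHA = 0.99
    N_MIN = 5


def fire_relax(system: MMSystem, f_max: float = 1e-3, max_steps: int = 20000,
               dt_init: float = 0.02, dt_max: float | None = None):
    """FIRE structural relaxation to ``max |F| <= f_max`` [eV/A].

    Damped dynamics with adaptive timestep; all velocities are zeroed
    whenever the system moves against the force (<F|v> < 0).  Constraints
    are held exactly throughout.  Returns ``(system, converged, steps)``;
    hitting ``max_steps`` yields ``converged = False`` rather than an
    exception.  The returned geometry never has higher energy than the
    starting one (the best-seen state is kept).
    """
    if dt_max is None:
        dt_max = 10.0 * dt_init
    st = FIREState(np.zeros_like(system.positions), dt_init,
                   FIREState.ALPHA_START)
    system.apply_constraints()
    decomp, f = total_energy_force(system)
    e_best = decomp["total"]
    x_best = system.positions.copy()
    converged = False
    steps = 0
    for steps in range(1, max_steps + 1):
        fmax_now = np.abs(f).max() if f.size else 0.0
        if fmax_now <= f_max:
            converged = True
            steps -= 1
            break
        p = float(np.vdot(f, st.velocities))
        if p > 0:
            st.n_pos += 1
            if st.n_pos > FIREState.N_MIN:
                st.dt = min(st.dt * FIREState.F_INC, dt_max)
                st.alpha_mix *= FIREState.F_ALPHA
        else:
            st.n_pos = 0
            st.dt *= FIREState.F_DEC
            st.velocities[:] = 0.0
            st.alpha_mix = FIREState.ALPHA_START
        st.velocities += st.dt * f
        vnorm = np.linalg.norm(st.velocities)
        fnorm = np.linalg.norm(f)
        if fnorm > 0 and vnorm > 0:
            st.velocities = ((1.0 - st.alpha_mix) * st.velocities +
                             st.alpha_mix * (f / fnorm) * vnorm)
        for idx in system.constraints:
            st.velocities[idx] = 0.0
        system.positions += st.dt * st.velocities
        system.apply_constraints()
        decomp, f = total_energy_force(system)
        if decomp["total"] < e_best:
            e_best = decomp["total"]
            x_best = system.positions.copy()
    else:
        steps = max_steps
    if not converged:
        system.positions = x_best
        system.apply_constraints()
    return system, converged, steps


# ---------------------------------------------------------------------------
# Langevin dynamics on replica batches
# ---------------------------------------------------------------------------

@dataclass
class ReplicaBatch:
    """Independent replicas of one molecular system.

    Each replica carries its own positions, velocities and a counter-based
    RNG stream (Philox keyed by its seed), so trajectories are bitwise
    reproducible and independent of how many replicas run alongside.  The
    substrate field is shared by reference, never copied.
    """

    positions: np.ndarray  # (R, N, 3)
    velocities: np.ndarray  # (R, N, 3) A/fs
    seeds: list[int]
    rngs: list = None
    alive: np.ndarray = None  # bool (R,)

    def __post_init__(self) -> None:
        self.positions = np.array(self.positions, dtype=float)
        self.velocities = np.array(self.velocities, dtype=float)
        r = len(self.positions)
        if self.rngs is None:
            self.rngs = [np.random.Generator(np.random.Philox(key=s))
                         for s in self.seeds]
        if self.alive is None:
            self.alive = np.ones(r, dtype=bool)

    @classmethod
    def from_system(cls, system: MMSystem, n_replicas: int, seed: int
                    ) -> "ReplicaBatch":
        pos = np.repeat(system.positions[None], n_replicas, axis=0)
        vel = np.zeros_like(pos)
        seeds = [int(seed) + r for r in range(n_replicas)]
        return cls(pos, vel, seeds)

    @property
    def n_replicas(self) -> int:
        return len(self.positions)


def langevin_step(batch: ReplicaBatch, system: MMSystem, temperature: float,
                  gamma: float = 0.01, dt: float = 0.5) -> ReplicaBatch:
    """One leapfrog Langevin step [fs] for every live replica.

    v <- v (1 - gamma dt) + (F/m) dt + sqrt(2 gamma kT/m) sqrt(dt) xi
    x <- x + v dt

    With gamma = 0 and T = 0 this reduces to plain leapfrog NVE.  Replicas
    that develop non-finite coordinates are flagged dead and skipped; the
    others continue.
    """
    m = system.molecule.masses[:, None]
    for r in range(batch.n_replicas):
        if not batch.alive[r]:
            continue
        pos = batch.positions[r]
        if not np.all(np.isfinite(pos)):
            batch.alive[r] = False
            continue
        try:
            _, f = total_energy_force(system, pos)
        except (ValueError, FloatingPointError):
            batch.alive[r] = False
            continue
        acc = f / m * ACC_EV_A_AMU
        v = batch.velocities[r]
        v *= (1.0 - gamma * dt)
        v += acc * dt
        if temperature > 0.0 and gamma > 0.0:
            sigma = np.sqrt(2.0 * gamma * K_BOLTZMANN * temperature *
                            ACC_EV_A_AMU / system.molecule.masses)[:, None]
            v += sigma * math.sqrt(dt) * batch.rngs[r].standard_normal(v.shape)
        for idx in system.constraints:
            v[idx] = 0.0
        pos += v * dt
        for idx, p in system.constraints.items():
            pos[idx] = p
        if not np.all(np.isfinite(pos)):
            batch.alive[r] = False
    return batch


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy [eV] of velocities [A/fs] with masses [amu]."""
    v2 = np.einsum("...ij,...ij->...i", velocities, velocities)
    return float(0.5 * (masses * v2).sum() * EV_PER_AMU_A2_FS2)
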