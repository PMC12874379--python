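"""Domain types, pair laws, reference summations and fixture generators.

This module owns everything the grid pipeline is validated against:

* the Morse pair law with Lorentz-Berthelot mixing (geometric mean for the
  well depth, sum of radii for the equilibrium distance), and its factorized
  form used by the grid builder;
* a brute-force direct pairwise-sum reference for molecule-substrate
  interactions (Morse truncated at the cutoff, Coulomb either image-summed or
  through a converged Ewald summation);
* a full real+reciprocal Ewald solver for the periodic slab potential, used
  as the accuracy oracle for the reciprocal-space Poisson grids;
* deterministic fixture generators: rocksalt (NaCl-type) slabs, a neutral
  surface vacancy pair, and synthetic probe molecules.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfc

from .constants import KE_COULOMB
from .params import MASSES, ElementParams, default_element_table

__all__ = [
    "AtomSpec",
    "Substrate",
    "Molecule",
    "GlobalParams",
    "mix_lb",
    "morse_pair",
    "morse_factor_sums",
    "EwaldSum",
    "ewald_potential",
    "direct_reference",
    "build_rocksalt_slab",
    "introduce_vacancy_pair",
    "make_probe_molecule",
]


class OverlapError(ValueError):
    """Two atoms closer than the numerical overlap threshold."""


@dataclass(frozen=True)
class AtomSpec:
    """One atom: chemical symbol, position [A], charge [e], eps [eV], R [A]."""

    element: str
    position: tuple[float, float, float]
    charge: float = 0.0
    epsilon: float = 0.0
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.radius <= 0:
            raise ValueError("R must be > 0")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")


def _as_array(x, shape, name):
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite values")
    return arr


@dataclass
class Substrate:
    """Rigid periodic substrate: atom arrays + lattice (rows = cell vectors)."""

    elements: list[str]
    positions: np.ndarray  # (N, 3) A
    charges: np.ndarray  # (N,) e
    epsilons: np.ndarray  # (N,) eV
    radii: np.ndarray  # (N,) A
    lattice: np.ndarray  # (3, 3) A
    periodic: tuple[bool, bool, bool] = (True, True, False)

    def __post_init__(self) -> None:
        n = len(self.elements)
        self.positions = _as_array(self.positions, (n, 3), "positions")
        self.charges = _as_array(self.charges, (n,), "charges")
        self.epsilons = _as_array(self.epsilons, (n,), "epsilons")
        self.radii = _as_array(self.radii, (n,), "radii")
        self.lattice = _as_array(self.lattice, (3, 3), "lattice")
        if np.any(self.epsilons < 0):
            raise ValueError("epsilon must be >= 0")
        if np.any(self.radii <= 0):
            raise ValueError("R must be > 0")
        if abs(np.linalg.det(self.lattice)) < 1e-12:
            raise ValueError("lattice rows must be linearly independent")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @classmethod
    def from_atoms(
        cls, atoms: list[AtomSpec], lattice, periodic=(True, True, False)
    ) -> "Substrate":
        return cls(
            elements=[a.element for a in atoms],
            positions=np.array([a.position for a in atoms], dtype=float),
            charges=np.array([a.charge for a in atoms], dtype=float),
            epsilons=np.array([a.epsilon for a in atoms], dtype=float),
            radii=np.array([a.radius for a in atoms], dtype=float),
            lattice=np.asarray(lattice, dtype=float),
            periodic=tuple(periodic),
        )

    def content_hash(self) -> str:
        """Stable hash of the substrate contents (provenance metadata)."""
        h = hashlib.sha256()
        for arr in (self.positions, self.charges, self.epsilons, self.radii,
                    self.lattice):
            h.update(np.round(arr, 10).tobytes())
        h.update(",".join(self.elements).encode())
        h.update(repr(self.periodic).encode())
        return h.hexdigest()[:16]


@dataclass
class Molecule:
    """Flexible adsorbate: atoms, bonded topology and nonbonded exclusions.

    Bonded terms carry their own constants so a molecule is self-contained:
    harmonic bonds 0.5*k*(r-r0)^2, harmonic angles 0.5*k*(theta-theta0)^2 and
    cosine torsions V*(1 + cos(n*phi - phi0)).
    """

    elements: list[str]
    positions: np.ndarray  # (N, 3)
    charges: np.ndarray
    epsilons: np.ndarray
    radii: np.ndarray
    masses: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    torsions: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), int))
    torsion_v: np.ndarray = field(default_factory=lambda: np.zeros(0))
    torsion_n: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    torsion_phi0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    exclusions: frozenset = frozenset()  # frozenset of (i, j) with i < j

    def __post_init__(self) -> None:
        n = len(self.elements)
        self.positions = _as_array(self.positions, (n, 3), "positions")
        self.charges = _as_array(self.charges, (n,), "charges")
        self.epsilons = _as_array(self.epsilons, (n,), "epsilons")
        self.radii = _as_array(self.radii, (n,), "radii")
        self.masses = _as_array(self.masses, (n,), "masses")
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=int).reshape(-1, 3)
        self.torsions = np.asarray(self.torsions, dtype=int).reshape(-1, 4)
        for name, idx in (("bonds", self.bonds), ("angles", self.angles),
                          ("torsions", self.torsions)):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"{name}: atom index out of range")
        for (i, j) in self.exclusions:
            if not (0 <= i < j < n):
                raise ValueError("exclusions must be ordered in-range pairs")
        # topology consistency: each angle's outer pair must be a 1-3 pair,
        # i.e. both its arms are bonds
        bondset = {tuple(sorted(b)) for b in self.bonds.tolist()}
        for (i, j, k) in self.angles.tolist():
            if tuple(sorted((i, j))) not in bondset or \
               tuple(sorted((j, k))) not in bondset:
                raise ValueError(f"angle ({i},{j},{k}) arms are not bonds")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def is_excluded(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.exclusions

    def with_positions(self, positions: np.ndarray) -> "Molecule":
        return replace(self, positions=np.array(positions, dtype=float))


@dataclass(frozen=True)
class GlobalParams:
    """Repo-wide interaction parameters.

    alpha : Morse stiffness [1/A]; one value for all pairs.
    r_cut : real-space cutoff for Morse (and image-summed Coulomb) [A].
    k_e   : Coulomb constant [eV*A/e^2].
    """

    alpha: float = 1.5
    r_cut: float = 17.0
    k_e: float = KE_COULOMB

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.r_cut <= 0:
            raise ValueError("r_cut must be > 0")


# ---------------------------------------------------------------------------
# pair laws
# ---------------------------------------------------------------------------

def mix_lb(eps_i: float, r_i: float, eps_j: float, r_j: float):
    """Lorentz-Berthelot mixing: (sqrt(eps_i*eps_j), R_i + R_j)."""
    if eps_i < 0 or eps_j < 0:
        raise ValueError("epsilon must be >= 0")
    if r_i <= 0 or r_j <= 0:
        raise ValueError("R must be > 0")
    return math.sqrt(eps_i * eps_j), r_i + r_j


def morse_pair(r, eps_ij, r_ij, alpha):
    """Morse energy and radial derivative at separation ``r``.

    E(r) = eps * (exp(-2 a (r - R)) - 2 exp(-a (r - R)))
    Returns ``(E, dE/dr)``; both array-friendly.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    e2 = np.exp(-2.0 * alpha * (r - r_ij))
    e1 = np.exp(-alpha * (r - r_ij))
    energy = eps_ij * (e2 - 2.0 * e1)
    deriv = eps_ij * (-2.0 * alpha * e2 + 2.0 * alpha * e1)
    return energy, deriv


def morse_factor_sums(points, sub_positions, sub_eps, sub_radii, alpha,
                      r_cut=None):
    """Pauli/London factor sums of the factorized Morse law.

    The Morse pair law under Lorentz-Berthelot mixing,
    sqrt(eps_i eps_j) [e^{-2a(r - R_i - R_j)} - 2 e^{-a(r - R_i - R_j)}],
    factorizes because every term in the substrate sum is independent of the
    molecule atom i.  For every query point r this returns the inner sums

      S_P(r) = sum_j sqrt(eps_j) exp(-2 a (|r - r_j| - R_j))
      S_L(r) = sum_j sqrt(eps_j) exp(  -a (|r - r_j| - R_j))

    optionally truncating each pair at ``r_cut``; the energy of a molecule
    atom i is then
    ``sqrt(eps_i) e^{2 a R_i} S_P - 2 sqrt(eps_i) e^{a R_i} S_L``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    sub_positions = np.asarray(sub_positions, dtype=float)
    sqrt_eps = np.sqrt(np.asarray(sub_eps, dtype=float))
    s_p = np.zeros(len(pts))
    s_l = np.zeros(len(pts))
    # chunk over substrate atoms to bound memory
    chunk = max(1, int(4e6 // max(len(pts), 1)))
    for a0 in range(0, len(sub_positions), chunk):
        sl = slice(a0, a0 + chunk)
        d = pts[:, None, :] - sub_positions[None, sl, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        arg = r - sub_radii[None, sl]
        e1 = sqrt_eps[None, sl] * np.exp(-alpha * arg)
        if r_cut is not None:
            e1 = np.where(r <= r_cut, e1, 0.0)
        s_l += e1.sum(axis=1)
        s_p += (e1 * e1 / np.where(sqrt_eps[None, sl] > 0,
                                   sqrt_eps[None, sl], 1.0)).sum(axis=1)
    return s_p, s_l


# ---------------------------------------------------------------------------
# Ewald reference
# ---------------------------------------------------------------------------

class EwaldSum:
    """Converged real+reciprocal Ewald potential of a periodic charge set.

    Slabs (``periodic=(True, True, False)``) are handled as 3D-periodic
    systems with vacuum padding along z; the k = 0 mode is dropped (tin-foil
    convention) which requires a neutral cell.  For the rocksalt fixtures each
    atomic layer is individually neutral, so the laterally averaged potential
    of the padded images vanishes identically and no dipole correction is
    needed.

    Parameters are auto-scaled so that changing the splitting parameter
    ``beta`` inside its stable range moves the potential by far less than
    1e-4 meV.
    """

    def __init__(self, substrate: Substrate, beta: float | None = None,
                 pad_factor: float = 3.0, min_pad: float = 24.0,
                 tail: float = 1e-11):
        if abs(substrate.charges.sum()) > 1e-9:
            raise ValueError("Ewald requires a neutral cell")
        self.substrate = substrate
        lat = substrate.lattice.copy()
        if not substrate.periodic[2]:
            zext = float(np.ptp(substrate.positions[:, 2]))
            pad = max(min_pad, pad_factor * max(zext, 1.0))
            lz = zext + 2.0 * pad
            lat[2] = (0.0, 0.0, lz)
        self.lattice = lat
        self.volume = abs(np.linalg.det(lat))
        if beta is None:
            beta = 0.4
        self.beta = beta
        # real-space cutoff so erfc(beta*rc) ~ tail
        x = 1.0
        while erfc(x) > tail:
            x += 0.05
        self.r_cut = x / beta
        # reciprocal cutoff so exp(-k^2/(4 beta^2)) ~ tail
        self.k_cut = 2.0 * beta * math.sqrt(-math.log(tail))
        self._setup_kspace()
        self._setup_real_images()

    def _setup_kspace(self) -> None:
        recip = 2.0 * np.pi * np.linalg.inv(self.lattice).T  # rows = b_i
        nmax = []
        for i in range(3):
            b = np.linalg.norm(recip[i])
            nmax.append(int(math.ceil(self.k_cut / b)))
        grids = np.meshgrid(*[np.arange(-n, n + 1) for n in nmax],
                            indexing="ij")
        m = np.stack([g.ravel() for g in grids], axis=1)
        kvecs = m @ recip
        k2 = np.einsum("ij,ij->i", kvecs, kvecs)
        mask = (k2 > 1e-12) & (k2 <= self.k_cut ** 2)
        self.kvecs = kvecs[mask]
        self.k2 = k2[mask]
        q = self.substrate.charges
        phases = np.exp(-1j * (self.kvecs @ self.substrate.positions.T))
        self.sk = phases @ q  # structure factor S(k)
        self.kfac = (4.0 * np.pi * KE_COULOMB / self.volume *
                     np.exp(-self.k2 / (4.0 * self.beta ** 2)) / self.k2)

    def _setup_real_images(self) -> None:
        # enumerate lattice images needed to cover r_cut from any cell point
        lat = self.lattice
        nimg = []
        for i in range(3):
            li = np.linalg.norm(lat[i])
            nimg.append(int(math.ceil(self.r_cut / li)) + 1)
        shifts = []
        for a in range(-nimg[0], nimg[0] + 1):
            for b in range(-nimg[1], nimg[1] + 1):
                for c in range(-nimg[2], nimg[2] + 1):
                    shifts.append(a * lat[0] + b * lat[1] + c * lat[2])
        shifts = np.array(shifts)
        pos = self.substrate.positions
        self.image_positions = (pos[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
        self.image_charges = np.tile(self.substrate.charges, len(shifts))

    def _near_images(self, pts: np.ndarray):
        """Image atoms inside the bounding box of ``pts`` padded by r_cut.

        Pure pruning: discarded atoms cannot contribute to the truncated
        real-space sum, so the result is bitwise identical.
        """
        lo = pts.min(axis=0) - self.r_cut
        hi = pts.max(axis=0) + self.r_cut
        m = np.all((self.image_positions >= lo) &
                   (self.image_positions <= hi), axis=1)
        return self.image_positions[m], self.image_charges[m]

    def potential(self, points) -> np.ndarray:
        """Electrostatic potential [eV/e] at the given points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        # reciprocal part
        phases = np.exp(1j * (pts @ self.kvecs.T))
        v = (phases * (self.kfac * self.sk)[None, :]).real.sum(axis=1)
        # real part
        img_pos, img_q = self._near_images(pts)
        chunk = max(1, int(4e6 // max(len(pts), 1)))
        for a0 in range(0, len(img_pos), chunk):
            sl = slice(a0, a0 + chunk)
            d = pts[:, None, :] - img_pos[None, sl, :]
            r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
            if np.any(r < 1e-6):
                raise OverlapError("evaluation point overlaps a charge")
            contrib = np.where(
                r <= self.r_cut,
                img_q[None, sl] * erfc(self.beta * r) / r, 0.0)
            v += KE_COULOMB * contrib.sum(axis=1)
        return v

    def potential_and_field(self, points):
        """Potential [eV/e] and field -grad(V) [eV/(e*A)] in one pass.

        Shares the reciprocal-space phase factors and the real-space
        distance tables between the two quantities; identical numerics to
        calling :meth:`potential` and :meth:`field` separately.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        phases = np.exp(1j * (pts @ self.kvecs.T))
        coef = (self.kfac * self.sk)[None, :] * phases
        v = coef.real.sum(axis=1)
        efield = np.einsum("pk,kd->pd", coef.imag, self.kvecs)
        img_pos, img_q = self._near_images(pts)
        chunk = max(1, int(2e6 // max(len(pts), 1)))
        for a0 in range(0, len(img_pos), chunk):
            sl = slice(a0, a0 + chunk)
            d = pts[:, None, :] - img_pos[None, sl, :]
            r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
            if np.any(r < 1e-6):
                raise OverlapError("evaluation point overlaps a charge")
            q = img_q[None, sl]
            near = r <= self.r_cut
            erfc_term = erfc(self.beta * r) / r
            v += KE_COULOMB * np.where(near, q * erfc_term, 0.0).sum(axis=1)
            dvdr = -q * (erfc_term / r +
                         2.0 * self.beta / math.sqrt(math.pi) *
                         np.exp(-(self.beta * r) ** 2) / r)
            dvdr = np.where(near, dvdr, 0.0)
            efield += -KE_COULOMB * np.einsum("ij,ijk->ik", dvdr / r, d)
        return v, efield

    def field(self, points) -> np.ndarray:
        """Electric field -grad(V) [eV/(e*A)] at the given points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        # reciprocal: V = sum Re[c_k S_k e^{ik r}] -> -grad = sum Im[...]*k
        phases = np.exp(1j * (pts @ self.kvecs.T))
        coef = (self.kfac * self.sk)[None, :] * phases
        efield = np.einsum("pk,kd->pd", coef.imag, self.kvecs)
        # real: -d/dr [q erfc(b r)/r] along r_hat
        img_pos, img_q = self._near_images(pts)
        chunk = max(1, int(2e6 // max(len(pts), 1)))
        for a0 in range(0, len(img_pos), chunk):
            sl = slice(a0, a0 + chunk)
            d = pts[:, None, :] - img_pos[None, sl, :]
            r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
            if np.any(r < 1e-6):
                raise OverlapError("evaluation point overlaps a charge")
            q = img_q[None, sl]
            dvdr = -q * (erfc(self.beta * r) / r ** 2 +
                         2.0 * self.beta / math.sqrt(math.pi) *
                         np.exp(-(self.beta * r) ** 2) / r)
            dvdr = np.where(r <= self.r_cut, dvdr, 0.0)
            efield += -KE_COULOMB * np.einsum("ij,ijk->ik", dvdr / r, d)
        return efield


def ewald_potential(substrate: Substrate, point, beta: float | None = None
                    ) -> float | np.ndarray:
    """Converged Ewald potential [eV/e] of the substrate at ``point``.

    Convenience wrapper around :class:`EwaldSum`; for repeated evaluations
    construct the class once.
    """
    es = EwaldSum(substrate, beta=beta)
    pts = np.asarray(point, dtype=float)
    v = es.potential(pts)
    return float(v[0]) if pts.ndim == 1 else v


# ---------------------------------------------------------------------------
# direct pairwise-sum reference
# ---------------------------------------------------------------------------

def substrate_images(substrate: Substrate, extent: float, n_images=None):
    """Lateral periodic image expansion of the substrate atom arrays.

    ``extent`` is the distance the images must cover (normally r_cut);
    ``n_images`` overrides the per-axis image count.
    """
    lat = substrate.lattice
    shifts = []
    counts = []
    for i in range(2):
        if substrate.periodic[i]:
            li = np.linalg.norm(lat[i])
            ni = n_images if n_images is not None else int(math.ceil(extent / li)) + 1
        else:
            ni = 0
        counts.append(ni)
    for a in range(-counts[0], counts[0] + 1):
        for b in range(-counts[1], counts[1] + 1):
            shifts.append(a * lat[0] + b * lat[1])
    shifts = np.array(shifts)
    pos = (substrate.positions[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    tile = len(shifts)
    return (pos, np.tile(substrate.charges, tile),
            np.tile(substrate.epsilons, tile), np.tile(substrate.radii, tile))


def direct_reference(mol: Molecule, sub: Substrate, params: GlobalParams,
                     n_images: int | None = None, coulomb: str = "images"):
    """Exact pairwise molecule-substrate sums: the all-atom baseline.

    Morse is truncated per pair at ``params.r_cut`` and summed over lateral
    periodic images; Coulomb is either image-summed over the same expansion
    (``coulomb='images'``) or evaluated with the converged Ewald solver
    (``coulomb='ewald'``).  Returns ``(E_morse, E_coul, F)`` with per-atom
    forces that are the exact gradients of the returned energy.
    """
    if coulomb not in ("images", "ewald"):
        raise ValueError(f"unknown coulomb mode {coulomb!r}")
    pos, qs, eps_s, rad_s = substrate_images(sub, params.r_cut, n_images)
    alpha = params.alpha
    e_morse = 0.0
    e_coul = 0.0
    forces = np.zeros_like(mol.positions)
    for i in range(mol.n_atoms):
        d = mol.positions[i] - pos
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        if np.any(r < 1e-6):
            raise OverlapError("molecule atom overlaps a substrate atom")
        mask = r <= params.r_cut
        eps_ij = np.sqrt(mol.epsilons[i] * eps_s[mask])
        r_ij = mol.radii[i] + rad_s[mask]
        e, dedr = morse_pair(r[mask], eps_ij, r_ij, alpha)
        e_morse += e.sum()
        forces[i] -= np.einsum("j,jk->k", dedr / r[mask], d[mask])
        if coulomb == "images" and mol.charges[i] != 0.0:
            e_coul += params.k_e * mol.charges[i] * (qs / r).sum()
            forces[i] += params.k_e * mol.charges[i] * \
                np.einsum("j,jk->k", qs / r ** 3, d)
    if coulomb == "ewald":
        es = EwaldSum(sub)
        v = es.potential(mol.positions)
        e_coul = float(np.dot(mol.charges, v))
        forces += mol.charges[:, None] * es.field(mol.positions)
    return float(e_morse), float(e_coul), forces


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def build_rocksalt_slab(nx: int, ny: int, nlayers: int, a: float = 4.0,
                        q_na: float = 0.9, q_cl: float = -0.9,
                        elements=("Na", "Cl"), table=None) -> Substrate:
    """Rocksalt (001) slab fixture.

    ``a`` is the surface lattice constant: the (1x1) surface cell is an
    ``a`` x ``a`` square holding one cation and one anion per layer (cation
    at the origin, anion at (a/2, a/2), in-plane anion-cation distance
    a/sqrt(2)); layers are stacked at spacing a/sqrt(2) with the two-ion
    basis swapped between consecutive layers, so every ion has six
    opposite-charge nearest neighbours at a/sqrt(2) -- the rocksalt
    geometry with conventional cubic constant a*sqrt(2).  The top layer sits
    at z = 0 and deeper layers at negative z.  An ``nx x ny x nlayers`` slab
    therefore has ``2*nx*ny*nlayers`` atoms (8x8x3 -> 384).
    """
    if nx < 1 or ny < 1 or nlayers < 1:
        raise ValueError("nx, ny, nlayers must be >= 1")
    if abs(q_na + q_cl) > 1e-12:
        raise ValueError("slab parameterization must be neutral (qNa = -qCl)")
    if table is None:
        table = default_element_table()
    cat, ani = elements
    p_cat, p_ani = table[cat], table[ani]
    elems, pos, chg, eps, rad = [], [], [], [], []
    dz = a / math.sqrt(2.0)
    for layer in range(nlayers):
        z = -dz * layer
        basis = [((0.0, 0.0), cat, q_na, p_cat), ((0.5 * a, 0.5 * a), ani, q_cl, p_ani)]
        if layer % 2 == 1:
            basis = [((0.0, 0.0), ani, q_cl, p_ani), ((0.5 * a, 0.5 * a), cat, q_na, p_cat)]
        for ix in range(nx):
            for iy in range(ny):
                for (dx, dy), el, q, par in basis:
                    elems.append(el)
                    pos.append((ix * a + dx, iy * a + dy, z))
                    chg.append(q)
                    eps.append(par.epsilon)
                    rad.append(par.radius)
    lattice = np.diag([nx * a, ny * a, nlayers * dz])
    return Substrate(elems, np.array(pos), np.array(chg), np.array(eps),
                     np.array(rad), lattice, (True, True, False))


def introduce_vacancy_pair(sub: Substrate) -> Substrate:
    """Remove one nearest-neighbour +/- ion pair from the topmost layer.

    The removed pair is the one closest to the lateral centre of the cell;
    the result keeps exact charge neutrality.
    """
    z_top = sub.positions[:, 2].max()
    top = np.where(np.abs(sub.positions[:, 2] - z_top) < 1e-6)[0]
    if len(top) < 2:
        raise ValueError("top layer has fewer than 2 atoms")
    center = 0.5 * (sub.lattice[0] + sub.lattice[1])[:2]
    pos_idx = top[sub.charges[top] > 0]
    if len(pos_idx) == 0 or not np.any(sub.charges[top] < 0):
        raise ValueError("no adjacent opposite-charge pair in top layer")
    d_center = np.linalg.norm(sub.positions[pos_idx, :2] - center, axis=1)
    i_cat = pos_idx[np.argmin(d_center)]
    neg_idx = top[sub.charges[top] < 0]
    # nearest opposite-charge neighbour including lateral wrap
    lat = sub.lattice
    best = None
    for j, base in zip(neg_idx, sub.positions[neg_idx]):
        for ax in (-1, 0, 1):
            for ay in (-1, 0, 1):
                r = np.linalg.norm(base + ax * lat[0] + ay * lat[1] -
                                   sub.positions[i_cat])
                if best is None or r < best[1]:
                    best = (j, r)
    j_ani, rmin = best
    # the pair must be truly adjacent: closer than half a lateral cell vector
    if rmin > 0.5 * min(np.linalg.norm(lat[0]), np.linalg.norm(lat[1])):
        raise ValueError("no adjacent opposite-charge pair found")
    keep = np.setdiff1d(np.arange(sub.n_atoms), [i_cat, j_ani])
    return Substrate([sub.elements[i] for i in keep], sub.positions[keep],
                     sub.charges[keep], sub.epsilons[keep], sub.radii[keep],
                     sub.lattice.copy(), sub.periodic)


def _chain_topology(n: int, bond_k=30.0, bond_r0=1.5, angle_k=3.0,
                    angle_theta0=math.radians(109.47), torsion_v=0.02,
                    torsion_n=3):
    bonds = np.array([(i, i + 1) for i in range(n - 1)], int).reshape(-1, 2)
    angles = np.array([(i, i + 1, i + 2) for i in range(n - 2)], int).reshape(-1, 3)
    torsions = np.array([(i, i + 1, i + 2, i + 3) for i in range(n - 3)],
                        int).reshape(-1, 4)
    excl = set()
    for (i, j) in bonds:
        excl.add((min(i, j), max(i, j)))
    for (i, j, k) in angles:
        excl.add((min(i, k), max(i, k)))
    return dict(
        bonds=bonds, bond_k=np.full(len(bonds), bond_k),
        bond_r0=np.full(len(bonds), bond_r0),
        angles=angles, angle_k=np.full(len(angles), angle_k),
        angle_theta0=np.full(len(angles), angle_theta0),
        torsions=torsions, torsion_v=np.full(len(torsions), torsion_v),
        torsion_n=np.full(len(torsions), torsion_n, int),
        torsion_phi0=np.zeros(len(torsions)),
        exclusions=frozenset(excl),
    )


def _zigzag_positions(n: int, r0: float, theta: float, rng) -> np.ndarray:
    """Planar zigzag chain with bond length r0 and bond angle theta + jitter."""
    pos = np.zeros((n, 3))
    half = 0.5 * theta
    step = np.array([math.sin(half), 0.0, 0.0]) * r0
    up = np.array([0.0, math.cos(half), 0.0]) * r0
    for i in range(1, n):
        pos[i] = pos[i - 1] + step + (up if i % 2 else -up)
    pos += rng.normal(scale=0.02, size=pos.shape)
    return pos


def make_probe_molecule(kind: str, n_atoms: int, seed: int,
                        table=None) -> Molecule:
    """Deterministic synthetic probe molecules.

    kinds:
      * ``rigid-planar``  : flat polyatomic plate of C-like atoms with
        alternating partial charges; meant to be used as a rigid body.
      * ``flexible-chain``: zigzag C-like chain with harmonic bonds/angles and
        soft threefold torsions; alternating partial charges.
      * ``polyol-chain``  : alternating C/O chain with larger opposite partial
        charges, emulating a hydroxylated flexible molecule.

    All kinds are exactly charge neutral; same seed -> identical molecule.
    """
    if n_atoms < 2:
        raise ValueError("n_atoms must be >= 2")
    if table is None:
        table = default_element_table()
    rng = np.random.default_rng(seed)
    if kind == "rigid-planar":
        side = int(math.ceil(math.sqrt(n_atoms)))
        pos = []
        for i in range(n_atoms):
            pos.append(((i % side) * 1.42, (i // side) * 1.42, 0.0))
        pos = np.array(pos) + rng.normal(scale=0.01, size=(n_atoms, 3))
        pos[:, 2] = 0.0
        elems = ["C"] * n_atoms
        charges = np.array([0.1 if i % 2 == 0 else -0.1
                            for i in range(n_atoms)])
        charges -= charges.sum() / n_atoms
        # proximity bonds on the square plate (used only for bookkeeping)
        bonds = []
        for i in range(n_atoms):
            for j in range(i + 1, n_atoms):
                if np.linalg.norm(pos[i] - pos[j]) < 1.6:
                    bonds.append((i, j))
        bonds = np.array(bonds, int).reshape(-1, 2)
        excl = frozenset((min(i, j), max(i, j)) for i, j in bonds)
        topo = dict(bonds=bonds, bond_k=np.full(len(bonds), 30.0),
                    bond_r0=np.array([np.linalg.norm(pos[i] - pos[j])
                                      for i, j in bonds]),
                    exclusions=excl)
    elif kind in ("flexible-chain", "polyol-chain"):
        if n_atoms < 4:
            raise ValueError(f"{kind} needs n_atoms >= 4 for a torsion")
        topo = _chain_topology(n_atoms)
        pos = _zigzag_positions(n_atoms, 1.5, math.radians(109.47), rng)
        if kind == "flexible-chain":
            elems = ["C"] * n_atoms
            charges = np.array([0.08 if i % 2 == 0 else -0.08
                                for i in range(n_atoms)])
        else:
            elems = ["C" if i % 2 == 0 else "O" for i in range(n_atoms)]
            charges = np.array([0.3 if e == "C" else -0.3 for e in elems])
        charges -= charges.sum() / n_atoms
    else:
        raise ValueError(f"unknown probe kind {kind!r}")
    eps = np.array([table[e].epsilon for e in elems])
    rad = np.array([table[e].radius for e in elems])
    masses = np.array([MASSES[e] for e in elems])
    return Molecule(elems, pos, charges, eps, rad, masses, **topo)
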