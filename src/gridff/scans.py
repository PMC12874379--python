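"""Experiment drivers: rigid scans, relaxed pulling/dragging, minima hopping.

All drivers work with either substrate backend (grid or direct-sum) and are
bitwise deterministic given their inputs and seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import (MMSystem, ReplicaBatch, fire_relax, langevin_step,
                     total_energy_force)

__all__ = [
    "ScanResult",
    "MinimaRecord",
    "MinimaSet",
    "rigid_z_scan",
    "rigid_lateral_scan",
    "relaxed_pull",
    "drag_scan",
    "rmsd_unique",
    "minima_hop",
]

_DECOMP_KEYS = ("bonded", "intra_nb", "surf_morse", "surf_coul", "total")


@dataclass
class ScanResult:
    """Profile of a scan: control coordinate, energy decomposition, geometries."""

    coord: np.ndarray  # (P,) control coordinate [A]
    energies: dict  # key -> (P,) eV
    geometries: list | None = None  # per-point (N, 3) or None for rigid scans
    converged: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        d = np.diff(self.coord)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("control coordinate must be strictly monotone")

    def to_xyz(self, path, elements) -> None:
        """Write stored per-point geometries as a multi-frame XYZ file.

        Each frame's comment carries the control coordinate, the energy
        decomposition and the convergence flag.
        """
        if self.geometries is None:
            raise ValueError("this scan stored no per-point geometries")
        from .io import Frame, write_xyz

        conv = (self.converged if self.converged is not None
                else np.ones(len(self.coord), dtype=bool))
        frames = []
        for p, geom in enumerate(self.geometries):
            comment = (f"coord={self.coord[p]:.4f} " +
                       " ".join(f"{k}={self.energies[k][p]:.9f}"
                                for k in _DECOMP_KEYS) +
                       f" converged={int(conv[p])}")
            frames.append(Frame(list(elements), geom, comment))
        write_xyz(frames, path)

    def to_tsv(self, path) -> None:
        cols = ["coord"] + list(_DECOMP_KEYS) + ["converged"]
        conv = (self.converged if self.converged is not None
                else np.ones(len(self.coord), dtype=bool))
        with open(path, "w") as fh:
            if self.meta:
                for k, v in sorted(self.meta.items()):
                    fh.write(f"# {k}: {v}\n")
            fh.write("\t".join(cols) + "\n")
            for p in range(len(self.coord)):
                row = [f"{self.coord[p]:.6f}"]
                row += [f"{self.energies[k][p]:.9f}" for k in _DECOMP_KEYS]
                row.append(str(int(conv[p])))
                fh.write("\t".join(row) + "\n")


def _empty_energies(n: int) -> dict:
    return {k: np.zeros(n) for k in _DECOMP_KEYS}


def _store(energies: dict, p: int, decomp: dict) -> None:
    for k in _DECOMP_KEYS:
        energies[k][p] = decomp[k]


def rigid_z_scan(system: MMSystem, z_range: tuple[float, float],
                 step: float = 0.1) -> ScanResult:
    """Rigid vertical scan: translate the whole molecule along z.

    The control coordinate is the height of the molecule's lowest atom above
    the grid/surface origin plane (z = 0 of the substrate frame).
    """
    lo, hi = z_range
    heights = np.arange(lo, hi + 0.5 * step, step)
    base = system.positions.copy()
    z_min = base[:, 2].min()
    energies = _empty_energies(len(heights))
    for p, z in enumerate(heights):
        pos = base.copy()
        pos[:, 2] += z - z_min
        decomp, _ = total_energy_force(system, pos)
        _store(energies, p, decomp)
    return ScanResult(heights, energies,
                      meta={"mode": "rigid-z", "step": step})


def rigid_lateral_scan(system: MMSystem, height: float, step: float = 0.1,
                       extent: tuple[float, float] | None = None):
    """Rigid lateral scan over one surface unit cell at constant height.

    Returns ``(xs, ys, emap)`` where ``emap[k]`` is an (nx, ny) map for each
    energy component; the molecule's lowest atom is placed at ``height``.
    """
    if extent is None:
        lat = _backend_lattice(system)
        extent = (np.linalg.norm(lat[0]), np.linalg.norm(lat[1]))
    xs = np.arange(0.0, extent[0] - 0.5 * step, step)
    ys = np.arange(0.0, extent[1] - 0.5 * step, step)
    base = system.positions.copy()
    base[:, 2] += height - base[:, 2].min()
    base[:, :2] -= base[:, :2].min(axis=0)
    emap = {k: np.zeros((len(xs), len(ys))) for k in _DECOMP_KEYS}
    for ix, x in enumerate(xs):
        for iy, y in enumerate(ys):
            pos = base.copy()
            pos[:, 0] += x
            pos[:, 1] += y
            decomp, _ = total_energy_force(system, pos)
            for k in _DECOMP_KEYS:
                emap[k][ix, iy] = decomp[k]
    return xs, ys, emap


def _backend_lattice(system: MMSystem) -> np.ndarray:
    be = system.backend
    if hasattr(be, "fieldset"):
        return be.fieldset.spec.lattice
    return be.substrate.lattice


def relaxed_pull(system: MMSystem, anchor: int, z_start: float, z_end: float,
                 step: float = 0.1, f_max: float = 1e-3,
                 max_steps: int = 20000, warm_start: bool = True
                 ) -> ScanResult:
    """Relaxed vertical pulling: anchor one atom, raise it stepwise, relax.

    At each step the anchor atom's position is displaced along z and held;
    all other atoms relax with FIRE, warm-started from the previous point's
    geometry (the default; ``warm_start=False`` restarts from the input
    geometry each point).  Non-convergence is recorded per point and the
    scan continues.
    """
    if not 0 <= anchor < system.molecule.n_atoms:
        raise ValueError("anchor index out of range")
    nsteps = int(round((z_end - z_start) / step))
    zs = z_start + step * np.arange(nsteps + 1)
    energies = _empty_energies(len(zs))
    geoms = []
    conv = np.zeros(len(zs), dtype=bool)
    work = system.copy()
    x0, y0 = system.positions[anchor, :2]
    start_positions = system.positions.copy()
    for p, z in enumerate(zs):
        if not warm_start:
            work.positions = start_positions.copy()
        work.positions[anchor] = (x0, y0, z)
        work.constraints = {**system.constraints,
                            anchor: np.array([x0, y0, z])}
        work, ok, _ = fire_relax(work, f_max=f_max, max_steps=max_steps)
        decomp, _ = total_energy_force(work)
        _store(energies, p, decomp)
        conv[p] = ok
        geoms.append(work.positions.copy())
    return ScanResult(zs, energies, geometries=geoms, converged=conv,
                      meta={"mode": "pull", "anchor": anchor, "step": step})


def drag_scan(system: MMSystem, anchor: int, direction, length: float,
              step: float = 0.1, f_max: float = 1e-3, max_steps: int = 20000,
              reference_atom: int | None = None) -> ScanResult:
    """Relaxed lateral dragging of the anchored atom along a surface vector.

    The anchor is displaced in increments of ``step`` along the (lateral,
    normalized) ``direction`` at its current height; the rest of the
    molecule relaxes at each point, warm-started.  The trajectory of the
    anchor and of a free ``reference_atom`` (default: the atom farthest from
    the anchor) is stored in ``meta``.
    """
    direction = np.asarray(direction, dtype=float)
    direction[2] = 0.0
    nrm = np.linalg.norm(direction)
    if nrm < 1e-12:
        raise ValueError("direction must be a nonzero lateral vector")
    direction = direction / nrm
    if reference_atom is None:
        d = np.linalg.norm(system.positions[:, :2] -
                           system.positions[anchor, :2], axis=1)
        reference_atom = int(np.argmax(d))
    nsteps = int(round(length / step))
    ss = step * np.arange(nsteps + 1)
    start = system.positions[anchor].copy()
    energies = _empty_energies(len(ss))
    conv = np.zeros(len(ss), dtype=bool)
    geoms = []
    anchor_trace = np.zeros((len(ss), 3))
    ref_trace = np.zeros((len(ss), 3))
    work = system.copy()
    for p, s in enumerate(ss):
        target = start + s * direction
        work.positions[anchor] = target
        work.constraints = {**system.constraints, anchor: target}
        work, ok, _ = fire_relax(work, f_max=f_max, max_steps=max_steps)
        decomp, _ = total_energy_force(work)
        _store(energies, p, decomp)
        conv[p] = ok
        geoms.append(work.positions.copy())
        anchor_trace[p] = work.positions[anchor]
        ref_trace[p] = work.positions[reference_atom]
    return ScanResult(ss, energies, geometries=geoms, converged=conv,
                      meta={"mode": "drag", "anchor": anchor,
                            "reference_atom": reference_atom,
                            "anchor_trace": anchor_trace,
                            "reference_trace": ref_trace})


# ---------------------------------------------------------------------------
# minima hopping
# ---------------------------------------------------------------------------

@dataclass
class MinimaRecord:
    """One relaxed configuration found by the sampler."""

    geometry: np.ndarray
    energy: float
    replica: int
    cycle: int
    relax_steps: int


@dataclass
class MinimaSet:
    """Catalogue of minima with RMSD-based uniqueness bookkeeping."""

    threshold: float = 0.1
    unique: list = field(default_factory=list)
    n_total: int = 0
    total_history: list = field(default_factory=list)
    unique_history: list = field(default_factory=list)

    def add(self, rec: MinimaRecord) -> bool:
        """Add a record; returns True if it is a new unique structure."""
        self.n_total += 1
        for u in self.unique:
            if u.geometry.shape != rec.geometry.shape:
                raise ValueError("mismatched atom counts between records")
            if structure_rmsd(u.geometry, rec.geometry) <= self.threshold:
                return False
        self.unique.append(rec)
        return True

    def checkpoint(self) -> None:
        self.total_history.append(self.n_total)
        self.unique_history.append(len(self.unique))


def structure_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD in the absolute surface frame: no superposition, no folding.

    Structures differing only by an adsorption-site translation or a rigid
    rotation therefore count as distinct, which is the convention used for
    surface-adsorption uniqueness.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("mismatched atom counts")
    d = a - b
    return math.sqrt(float(np.einsum("ij,ij->", d, d)) / len(a))


def rmsd_unique(records, threshold: float = 0.1) -> MinimaSet:
    """Greedy first-seen uniqueness filter over relaxed records."""
    ms = MinimaSet(threshold=threshold)
    for rec in records:
        ms.add(rec)
    ms.checkpoint()
    return ms


def minima_hop(system: MMSystem, batch: ReplicaBatch, cycles: int,
               temperature: float = 300.0, n_md: int = 1000,
               f_max: float = 1e-4, gamma: float = 0.02, dt: float = 0.5,
               relax_max_steps: int = 20000, rmsd_threshold: float = 0.1
               ) -> MinimaSet:
    """Replica minima hopping over the adsorption landscape.

    Each cycle thermally perturbs every replica (``n_md`` Langevin steps at
    ``temperature``), then relaxes it with FIRE until the maximum force
    drops below ``f_max`` [eV/A].  Converged geometries enter the catalogue;
    uniqueness is decided by the absolute-frame RMSD threshold.  Replicas
    restart the next cycle re-thermalized from their relaxed geometry.
    Fully deterministic given the batch seeds; failed replicas are excluded
    from the counts.
    """
    ms = MinimaSet(threshold=rmsd_threshold)
    for cycle in range(cycles):
        for _ in range(n_md):
            langevin_step(batch, system, temperature, gamma=gamma, dt=dt)
        for r in range(batch.n_replicas):
            if not batch.alive[r]:
                continue
            work = system.copy()
            work.positions = batch.positions[r].copy()
            work, ok, steps = fire_relax(work, f_max=f_max,
                                         max_steps=relax_max_steps)
            if not ok:
                continue
            decomp, _ = total_energy_force(work)
            ms.add(MinimaRecord(work.positions.copy(), decomp["total"],
                                r, cycle, steps))
            batch.positions[r] = work.positions
            batch.velocities[r] = 0.0
        ms.checkpoint()
    return ms
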