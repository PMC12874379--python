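"""File I/O: XYZ / MOL structures, bond perception, grid containers.

XYZ dialect: standard ``count / comment / element x y z`` records, with
optional extended columns ``charge [epsilon R]`` honoured on read and written
when present.  MOL files are read as minimal V2000 connection tables.  Grid
containers are single files holding a one-line JSON header followed by raw
little-endian float64 payloads in z-fastest C order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bspline import BSplineField, FieldSet
from .core import Molecule, Substrate
from .grids import GridSet, GridSpec, ScalarField
from .params import COVALENT_RADII, MASSES, default_element_table

__all__ = [
    "Frame",
    "read_xyz",
    "write_xyz",
    "read_mol",
    "detect_bonds",
    "topology_from_bonds",
    "molecule_from_frame",
    "substrate_from_frame",
    "save_gridset",
    "load_gridset",
    "save_fieldset",
    "load_fieldset",
]


@dataclass
class Frame:
    """One structure frame: elements, positions and optional extra columns."""

    elements: list[str]
    positions: np.ndarray
    comment: str = ""
    charges: np.ndarray | None = None
    epsilons: np.ndarray | None = None
    radii: np.ndarray | None = None


def read_xyz(path) -> list[Frame]:
    """Read a (possibly multi-frame) XYZ file; errors name the line."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{i + 1}: expected atom count") from None
        if i + 1 + count >= len(lines) + 1 and count > 0 and \
           i + 1 + count > len(lines):
            raise ValueError(f"{path}:{i + 1}: count {count} exceeds "
                             "remaining lines")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        elems, pos, extra = [], [], []
        for k in range(count):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ValueError(f"{path}:{ln + 1}: unexpected end of file")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{ln + 1}: expected 'element x y z [q eps R]'")
            try:
                xyz = [float(v) for v in parts[1:4]]
                cols = [float(v) for v in parts[4:7]]
            except ValueError:
                raise ValueError(f"{path}:{ln + 1}: malformed number") from None
            elems.append(parts[0])
            pos.append(xyz)
            extra.append(cols)
        ncols = max((len(e) for e in extra), default=0)
        kw = {}
        if ncols >= 1:
            kw["charges"] = np.array([e[0] if len(e) > 0 else 0.0
                                      for e in extra])
        if ncols >= 3:
            kw["epsilons"] = np.array([e[1] if len(e) > 2 else 0.0
                                       for e in extra])
            kw["radii"] = np.array([e[2] if len(e) > 2 else 1.0
                                    for e in extra])
        frames.append(Frame(elems, np.array(pos, dtype=float).reshape(-1, 3),
                            comment, **kw))
        i += 2 + count
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def write_xyz(frames, path, precision: int = 8) -> None:
    """Write one frame or a list of frames to an XYZ file."""
    if isinstance(frames, Frame):
        frames = [frames]
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{len(fr.elements)}\n{fr.comment}\n")
            for k, el in enumerate(fr.elements):
                row = [el] + [fmt.format(v) for v in fr.positions[k]]
                if fr.charges is not None:
                    row.append(fmt.format(fr.charges[k]))
                    if fr.epsilons is not None and fr.radii is not None:
                        row.append(fmt.format(fr.epsilons[k]))
                        row.append(fmt.format(fr.radii[k]))
                fh.write(" ".join(row) + "\n")


def read_mol(path) -> Frame:
    """Minimal MOL V2000 reader: atom block + bond block + charge properties."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 4:
        raise ValueError(f"{path}: truncated MOL file")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError:
        raise ValueError(f"{path}:4: malformed counts line") from None
    elems, pos = [], []
    for k in range(n_atoms):
        ln = lines[4 + k]
        pos.append([float(ln[0:10]), float(ln[10:20]), float(ln[20:30])])
        elems.append(ln[31:34].strip())
    bonds = []
    for k in range(n_bonds):
        ln = lines[4 + n_atoms + k]
        bonds.append((int(ln[0:3]) - 1, int(ln[3:6]) - 1))
    charges = np.zeros(n_atoms)
    for ln in lines[4 + n_atoms + n_bonds:]:
        if ln.startswith("M  CHG"):
            vals = ln.split()[3:]
            for idx, q in zip(vals[0::2], vals[1::2]):
                charges[int(idx) - 1] = float(q)
    fr = Frame(elems, np.array(pos), charges=charges)
    fr.bonds = np.array(bonds, dtype=int).reshape(-1, 2)
    return fr


def detect_bonds(elements, positions, scale: float = 1.2) -> np.ndarray:
    """Bond perception from covalent radii: bonded iff r < scale*(rc_i+rc_j)."""
    unknown = sorted({e for e in elements if e not in COVALENT_RADII})
    if unknown:
        raise ValueError(f"unknown element(s) for bond detection: {unknown}")
    positions = np.asarray(positions, dtype=float)
    rc = np.array([COVALENT_RADII[e] for e in elements])
    bonds = []
    for i, j in itertools.combinations(range(len(elements)), 2):
        if np.linalg.norm(positions[i] - positions[j]) < scale * (rc[i] + rc[j]):
            bonds.append((i, j))
    return np.array(bonds, dtype=int).reshape(-1, 2)


def topology_from_bonds(n_atoms: int, bonds: np.ndarray):
    """Derive angles, torsions and 1-2/1-3 exclusions from the bond graph."""
    neigh = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        neigh[i].append(int(j))
        neigh[j].append(int(i))
    angles = []
    for j in range(n_atoms):
        for a, b in itertools.combinations(sorted(neigh[j]), 2):
            angles.append((a, j, b))
    torsions = []
    for j, k in bonds:
        for i in neigh[j]:
            if i == k:
                continue
            for l in neigh[k]:
                if l == j or l == i:
                    continue
                torsions.append((int(i), int(j), int(k), int(l)))
    excl = set()
    for i, j in bonds:
        excl.add((min(i, j), max(i, j)))
    for a, j, b in angles:
        excl.add((min(a, b), max(a, b)))
    return (np.array(angles, int).reshape(-1, 3),
            np.array(torsions, int).reshape(-1, 4), frozenset(excl))


def molecule_from_frame(frame: Frame, table=None, detect: bool = True,
                        bond_k: float = 30.0, angle_k: float = 3.0,
                        torsion_v: float = 0.02) -> Molecule:
    """Build a Molecule from a structure frame.

    Nonbonded parameters come from the element table unless the frame
    carries explicit columns; bonded topology is perceived from covalent
    radii (or taken from the frame for MOL input) with equilibrium values
    set to the input geometry.
    """
    if table is None:
        table = default_element_table()
    n = len(frame.elements)
    eps = (frame.epsilons if frame.epsilons is not None
           else np.array([table[e].epsilon for e in frame.elements]))
    rad = (frame.radii if frame.radii is not None
           else np.array([table[e].radius for e in frame.elements]))
    chg = (frame.charges if frame.charges is not None
           else np.array([table[e].charge for e in frame.elements]))
    masses = np.array([MASSES[e] for e in frame.elements])
    bonds = getattr(frame, "bonds", None)
    if bonds is None and detect:
        bonds = detect_bonds(frame.elements, frame.positions)
    if bonds is None:
        bonds = np.zeros((0, 2), int)
    angles, torsions, excl = topology_from_bonds(n, bonds)
    pos = frame.positions
    b_r0 = np.array([np.linalg.norm(pos[i] - pos[j]) for i, j in bonds])
    a_t0 = np.zeros(len(angles))
    for k, (a, j, b) in enumerate(angles):
        u, v = pos[a] - pos[j], pos[b] - pos[j]
        a_t0[k] = np.arccos(np.clip(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    return Molecule(
        list(frame.elements), pos, chg, eps, rad, masses,
        bonds=bonds, bond_k=np.full(len(bonds), bond_k), bond_r0=b_r0,
        angles=angles, angle_k=np.full(len(angles), angle_k),
        angle_theta0=a_t0,
        torsions=torsions, torsion_v=np.full(len(torsions), torsion_v),
        torsion_n=np.full(len(torsions), 3, int),
        torsion_phi0=np.zeros(len(torsions)),
        exclusions=excl)


def substrate_from_frame(frame: Frame, lattice, table=None,
                         periodic=(True, True, False)) -> Substrate:
    if table is None:
        table = default_element_table()
    eps = (frame.epsilons if frame.epsilons is not None
           else np.array([table[e].epsilon for e in frame.elements]))
    rad = (frame.radii if frame.radii is not None
           else np.array([table[e].radius for e in frame.elements]))
    chg = (frame.charges if frame.charges is not None
           else np.array([table[e].charge for e in frame.elements]))
    return Substrate(list(frame.elements), frame.positions, chg, eps, rad,
                     np.asarray(lattice, dtype=float), periodic)


# ---------------------------------------------------------------------------
# grid containers: JSON header line + raw float64 payloads
# ---------------------------------------------------------------------------

_COMPONENTS = ("pauli", "london", "coulomb")


def _spec_to_dict(spec: GridSpec) -> dict:
    return {"origin": list(spec.origin), "spacing": spec.spacing,
            "dims": list(spec.dims), "lattice": spec.lattice.tolist(),
            "periodic": list(spec.periodic)}


def _spec_from_dict(d: dict) -> GridSpec:
    return GridSpec(tuple(d["origin"]), d["spacing"], tuple(d["dims"]),
                    np.array(d["lattice"]), tuple(d["periodic"]))


def _write_container(path, header: dict, arrays) -> None:
    with open(path, "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode())
        for arr in arrays:
            fh.write(np.ascontiguousarray(arr, dtype="<f8").tobytes())


def _read_container(path):
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        payload = fh.read()
    dims = tuple(header["spec"]["dims"])
    nbytes = int(np.prod(dims)) * 8
    ncomp = len(header["components"])
    if len(payload) != ncomp * nbytes:
        raise ValueError(
            f"{path}: payload length {len(payload)} != expected "
            f"{ncomp * nbytes} for dims {dims}")
    arrays = [np.frombuffer(payload[i * nbytes:(i + 1) * nbytes],
                            dtype="<f8").reshape(dims).copy()
              for i in range(ncomp)]
    return header, arrays


def save_gridset(gs: GridSet, path) -> None:
    header = {"representation": "node-values", "components": list(_COMPONENTS),
              "spec": _spec_to_dict(gs.spec), "alpha": gs.alpha,
              "dtype": "<f8", "meta": gs.meta}
    _write_container(path, header,
                     [getattr(gs, c).values for c in _COMPONENTS])


def load_gridset(path) -> GridSet:
    header, arrays = _read_container(path)
    if header["representation"] != "node-values":
        raise ValueError(f"{path}: not a node-value grid container")
    spec = _spec_from_dict(header["spec"])
    fields = [ScalarField(spec, a) for a in arrays]
    return GridSet(*fields, alpha=header["alpha"], meta=header.get("meta", {}))


def save_fieldset(fs: FieldSet, path) -> None:
    header = {"representation": "bspline-coeffs",
              "components": list(_COMPONENTS),
              "spec": _spec_to_dict(fs.spec), "alpha": fs.alpha,
              "boundary": list(fs.pauli.boundary), "dtype": "<f8",
              "meta": fs.meta,
              "fit_reports": {c: getattr(fs, c).fit_report
                              for c in _COMPONENTS}}
    _write_container(path, header,
                     [getattr(fs, c).coeffs for c in _COMPONENTS])


def load_fieldset(path) -> FieldSet:
    header, arrays = _read_container(path)
    if header["representation"] != "bspline-coeffs":
        raise ValueError(f"{path}: not a B-spline coefficient container")
    spec = _spec_from_dict(header["spec"])
    boundary = tuple(header["boundary"])
    reports = header.get("fit_reports", {})
    comps = {c: BSplineField(spec, a, boundary, reports.get(c, {}))
             for c, a in zip(header["components"], arrays)}
    return FieldSet(comps["pauli"], comps["london"], comps["coulomb"],
                    alpha=header["alpha"], meta=header.get("meta", {}))
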