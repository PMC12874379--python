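"""Scan drivers, dragging, minima hopping and RMSD uniqueness."""

import math

import numpy as np
import pytest

from gridff import (GlobalParams, MinimaRecord, Molecule, ReplicaBatch,
                    ScanResult, build_rocksalt_slab, drag_scan, fire_relax,
                    introduce_vacancy_pair, make_probe_molecule, minima_hop,
                    relaxed_pull, rigid_lateral_scan, rigid_z_scan,
                    rmsd_unique, structure_rmsd, total_energy_force)
from gridff.engine import DirectBackend, GridBackend, MMSystem
from gridff.grids import map_into_cell
from conftest import single_atom_molecule


class TestRigidZScan:
    def test_single_atom_minimum_and_decay(self, coarse_fieldset, params):
        """A neutral probe atom sees a Morse-like well and a vanishing
        far field."""
        mol = single_atom_molecule(3.0, q=0.0, x=2.0, y=2.0)
        system = MMSystem(mol, GridBackend(coarse_fieldset, params), params)
        res = rigid_z_scan(system, (2.6, 9.0), step=0.05)
        e = res.energies["total"]
        assert e.min() < -1e-3  # bound state, eps-scale depth
        assert abs(e[-1]) < 1e-4
        zmin = res.coord[np.argmin(e)]
        assert 2.8 < zmin < 4.5

    def test_step_halving_stable_minimum(self, coarse_fieldset, params):
        mol = single_atom_molecule(3.0, x=2.0, y=2.0)
        system = MMSystem(mol, GridBackend(coarse_fieldset, params), params)
        r1 = rigid_z_scan(system, (2.6, 6.0), step=0.1)
        r2 = rigid_z_scan(system, (2.6, 6.0), step=0.05)
        z1 = r1.coord[np.argmin(r1.energies["total"])]
        z2 = r2.coord[np.argmin(r2.energies["total"])]
        assert abs(z1 - z2) <= 0.05 + 1e-12

    def test_bitwise_reproducible(self, coarse_fieldset, params):
        mol = single_atom_molecule(3.0, q=0.1)
        system = MMSystem(mol, GridBackend(coarse_fieldset, params), params)
        r1 = rigid_z_scan(system, (3.0, 5.0), step=0.1)
        r2 = rigid_z_scan(system, (3.0, 5.0), step=0.1)
        assert np.array_equal(r1.energies["total"], r2.energies["total"])

    def test_monotone_coordinate_enforced(self):
        with pytest.raises(ValueError):
            ScanResult(np.array([1.0, 3.0, 2.0]),
                       {k: np.zeros(3) for k in
                        ("bonded", "intra_nb", "surf_morse", "surf_coul",
                         "total")})


class TestRigidLateralScan:
    def test_charge_probe_site_preference(self, coarse_fieldset, params):
        """A +q probe prefers the anion site and avoids the cation site."""
        mol = single_atom_molecule(3.3, q=1.0, x=0.0, y=0.0, eps=1e-10)
        system = MMSystem(mol, GridBackend(coarse_fieldset, params), params)
        xs, ys, emap = rigid_lateral_scan(system, height=3.3, step=0.4)
        coul = emap["surf_coul"]
        imin = np.unravel_index(np.argmin(coul), coul.shape)
        imax = np.unravel_index(np.argmax(coul), coul.shape)
        # Na sits at (0, 0), Cl at (2, 2) in the 4 A cell
        assert np.allclose([xs[imin[0]], ys[imin[1]]], [2.0, 2.0], atol=0.4)
        assert np.allclose([xs[imax[0]], ys[imax[1]]], [0.0, 0.0], atol=0.4)

    def test_periodic_edges_match(self, coarse_fieldset, params):
        """The PES at (0, y) equals the PES at (Lx, y) by folding."""
        mol = single_atom_molecule(3.3, q=0.3)
        system = MMSystem(mol, GridBackend(coarse_fieldset, params), params)
        p0 = system.positions.copy()
        e0, _ = total_energy_force(system, p0)
        p1 = p0 + np.array([4.0, 0.0, 0.0])
        e1, _ = total_energy_force(system, p1)
        assert e0["total"] == pytest.approx(e1["total"], abs=1e-10)


class TestRelaxedPull:
    def test_single_atom_pull_reduces_to_rigid_scan(self, coarse_fieldset,
                                                    params):
        """With no free atoms the pull is exactly a rigid scan."""
        mol = single_atom_molecule(3.0, q=0.1, x=1.0, y=1.0)
        system = MMSystem(mol, GridBackend(coarse_fieldset, params), params)
        pull = relaxed_pull(system, anchor=0, z_start=3.0, z_end=6.0,
                            step=0.25)
        rigid = rigid_z_scan(system, (3.0, 6.0), step=0.25)
        assert np.allclose(pull.energies["total"], rigid.energies["total"],
                           atol=1e-12)
        assert pull.converged.all()

    def test_detached_limit_equals_isolated_molecule(self, coarse_fieldset,
                                                     params):
        """Far above the surface the pulled molecule relaxes to its
        isolated minimum energy."""
        mol = make_probe_molecule("flexible-chain", 5, seed=8)
        pos = mol.positions.copy()
        pos[:, 2] += 3.0 - pos[:, 2].min()
        system = MMSystem(mol.with_positions(pos),
                          GridBackend(coarse_fieldset, params), params)
        res = relaxed_pull(system, anchor=0, z_start=3.0, z_end=20.0,
                           step=0.5, f_max=1e-3)
        assert res.converged.all()
        iso = MMSystem(mol.with_positions(res.geometries[-1]),
                       _null_backend(), params)
        iso, ok, _ = fire_relax(iso, f_max=1e-4)
        e_iso = total_energy_force(iso)[0]["total"]
        assert res.energies["total"][-1] - e_iso < 1e-3

    def test_trajectory_xyz_export(self, coarse_fieldset, params, tmp_path):
        from gridff.io import read_xyz

        mol = single_atom_molecule(3.0, q=0.1)
        system = MMSystem(mol, GridBackend(coarse_fieldset, params), params)
        res = relaxed_pull(system, anchor=0, z_start=3.0, z_end=3.6,
                           step=0.2)
        p = tmp_path / "traj.xyz"
        res.to_xyz(p, mol.elements)
        frames = read_xyz(p)
        assert len(frames) == 4
        assert "total=" in frames[0].comment
        assert "converged=1" in frames[0].comment

    def test_nonconvergence_recorded_not_raised(self, coarse_fieldset,
                                                params):
        mol = make_probe_molecule("flexible-chain", 5, seed=8)
        pos = mol.positions.copy()
        pos[:, 2] += 3.0 - pos[:, 2].min()
        system = MMSystem(mol.with_positions(pos),
                          GridBackend(coarse_fieldset, params), params)
        res = relaxed_pull(system, anchor=0, z_start=3.0, z_end=3.4,
                           step=0.2, f_max=1e-9, max_steps=5)
        assert not res.converged.any()
        assert len(res.coord) == 3


def _null_backend():
    class _NB:
        def surface_energy_force(self, mol, pos):
            return 0.0, 0.0, np.zeros_like(pos)
    return _NB()


class TestDragScan:
    def _flat_probe(self, n=4, seed=6, z=2.9):
        mol = make_probe_molecule("flexible-chain", n, seed=seed)
        pos = mol.positions.copy()
        pos[:, 2] += z - pos[:, 2].min()
        return mol.with_positions(pos)

    def test_pristine_profile_is_periodic(self, coarse_fieldset, params):
        """Away from the initial transient the drag profile repeats with
        the lattice diagonal period."""
        mol = self._flat_probe()
        system = MMSystem(mol, GridBackend(coarse_fieldset, params), params)
        period = 4.0 * math.sqrt(2.0)
        step = period / 16
        res = drag_scan(system, anchor=0, direction=(1.0, 1.0, 0.0),
                        length=3 * period, step=step, f_max=1e-3)
        e = res.energies["total"]
        # compare the 2nd and 3rd periods pointwise
        p2 = e[16:32]
        p3 = e[32:48]
        assert np.abs(p2 - p3).max() < 2e-3

    def test_free_atom_shows_stick_slip_deviation(self, coarse_fieldset,
                                                  params):
        """The free reference atom leaves the anchor's straight path."""
        mol = self._flat_probe(n=5, seed=9)
        system = MMSystem(mol, GridBackend(coarse_fieldset, params), params)
        res = drag_scan(system, anchor=0, direction=(1.0, 1.0, 0.0),
                        length=8.0, step=0.4, f_max=1e-3)
        ref = res.meta["reference_trace"][:, :2]
        d = ref - ref[0]
        direction = np.array([1.0, 1.0]) / math.sqrt(2.0)
        lateral = d - np.outer(d @ direction, direction)
        assert np.linalg.norm(lateral, axis=1).max() > 0.1

    def test_defect_pins_the_global_minimum(self, params):
        """With a vacancy pair under the path, the deepest point of the
        profile falls inside the defect's lattice cell."""
        sub = introduce_vacancy_pair(build_rocksalt_slab(4, 4, 2))
        backend = DirectBackend(sub, params, coulomb="ewald")
        mol = self._flat_probe(n=4, seed=6, z=2.9)
        pos = mol.positions.copy()
        pos[:, :2] += np.array([4.0, 4.0]) - pos[0, :2]  # start off-center
        system = MMSystem(mol.with_positions(pos), backend, params)
        res = drag_scan(system, anchor=0, direction=(1.0, 1.0, 0.0),
                        length=8.5, step=0.5, f_max=2e-3, max_steps=4000)
        e = res.energies["total"]
        s_min = res.coord[np.argmin(e)]
        # defect (removed pair) sits near the cell center (8, 8): the
        # anchor reaches it after ~ |(8,8)-(4,4)| = 5.66 A of dragging
        assert 4.2 < s_min < 7.2


class TestRmsdUnique:
    def _rec(self, geom, i=0):
        return MinimaRecord(np.asarray(geom, float), -1.0, i, 0, 10)

    def test_duplicates_collapse(self):
        g = np.zeros((3, 3))
        ms = rmsd_unique([self._rec(g), self._rec(g, 1)], threshold=0.1)
        assert len(ms.unique) == 1
        assert ms.n_total == 2

    def test_small_uniform_shift_merges(self):
        g = np.random.default_rng(0).normal(size=(4, 3))
        shifted = g + 0.05 / math.sqrt(3.0)  # rigid shift, RMSD = 0.05
        assert structure_rmsd(g, shifted) == pytest.approx(0.05, rel=1e-12)
        ms = rmsd_unique([self._rec(g), self._rec(shifted, 1)])
        assert len(ms.unique) == 1

    def test_lattice_translation_is_distinct(self):
        """A site change by one lattice vector counts as a new structure."""
        g = np.random.default_rng(1).normal(size=(4, 3))
        moved = g + np.array([4.0, 0.0, 0.0])
        assert structure_rmsd(g, moved) == pytest.approx(4.0, rel=1e-12)
        ms = rmsd_unique([self._rec(g), self._rec(moved, 1)])
        assert len(ms.unique) == 2

    def test_mismatched_atom_counts_rejected(self):
        with pytest.raises(ValueError):
            rmsd_unique([self._rec(np.zeros((3, 3))),
                         self._rec(np.zeros((4, 3)), 1)])


class TestMinimaHop:
    def _system(self, fieldset, params, q=0.2):
        mol = single_atom_molecule(3.2, q=q, x=1.0, y=1.0)
        return MMSystem(mol, GridBackend(fieldset, params), params)

    def test_zero_temperature_limit(self, coarse_fieldset, params):
        """With T = 0 all replicas refine the same start: one unique
        minimum."""
        system = self._system(coarse_fieldset, params)
        batch = ReplicaBatch.from_system(system, 4, seed=0)
        ms = minima_hop(system, batch, cycles=1, temperature=0.0, n_md=50,
                        f_max=1e-4, gamma=0.05)
        assert ms.n_total == 4
        assert len(ms.unique) == 1

    def test_counts_monotone_and_bounded(self, coarse_fieldset, params):
        system = self._system(coarse_fieldset, params)
        batch = ReplicaBatch.from_system(system, 3, seed=5)
        ms = minima_hop(system, batch, cycles=3, temperature=300.0, n_md=150,
                        f_max=1e-4)
        tot = np.array(ms.total_history)
        uni = np.array(ms.unique_history)
        assert np.all(np.diff(tot) >= 0)
        assert np.all(np.diff(uni) >= 0)
        assert np.all(uni <= tot)

    def test_deterministic_given_seeds(self, coarse_fieldset, params):
        system = self._system(coarse_fieldset, params)
        runs = []
        for _ in range(2):
            batch = ReplicaBatch.from_system(system, 2, seed=9)
            ms = minima_hop(system, batch, cycles=2, temperature=300.0,
                            n_md=100, f_max=1e-4)
            runs.append([rec.energy for rec in ms.unique])
        assert runs[0] == runs[1]

    def test_matches_exhaustive_start_relaxations(self, coarse_fieldset,
                                                  params):
        """Every minimum found by hopping coincides (site-folded) with a
        minimum from exhaustive relaxation off a dense start lattice."""
        lat = coarse_fieldset.spec.lattice
        system = self._system(coarse_fieldset, params)
        exhaustive = []
        for x in np.linspace(0.2, 3.8, 5):
            for y in np.linspace(0.2, 3.8, 5):
                work = system.copy()
                work.positions = np.array([[x, y, 3.2]])
                work, ok, _ = fire_relax(work, f_max=1e-4)
                if ok:
                    exhaustive.append(map_into_cell(work.positions[0], lat,
                                                    (True, True, False)))
        exhaustive = np.array(exhaustive)
        batch = ReplicaBatch.from_system(system, 3, seed=2)
        ms = minima_hop(system, batch, cycles=2, temperature=300.0, n_md=200,
                        f_max=1e-4)
        assert len(ms.unique) >= 1
        for rec in ms.unique:
            folded = map_into_cell(rec.geometry[0], lat, (True, True, False))
            d = np.linalg.norm(exhaustive - folded, axis=1)
            assert d.min() < 0.05
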