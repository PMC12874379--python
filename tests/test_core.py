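"""Pair laws, mixing, Ewald oracle, direct reference and fixtures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridff import (EwaldSum, GlobalParams, Molecule, Substrate,
                    build_rocksalt_slab, direct_reference, ewald_potential,
                    introduce_vacancy_pair, make_probe_molecule, mix_lb,
                    morse_pair)
from gridff.core import morse_factor_sums, substrate_images


class TestMixing:
    @pytest.mark.parametrize("args,expected", [
        ((0.04, 1.5, 0.25, 2.5), (0.10, 4.0)),
        ((0.2, 1.7, 0.2, 1.7), (0.2, 3.4)),
        ((0.0, 1.0, 0.3, 2.0), (0.0, 3.0)),
    ])
    def test_lorentz_berthelot_values(self, args, expected):
        eps, r = mix_lb(*args)
        assert eps == pytest.approx(expected[0], abs=1e-14)
        assert r == pytest.approx(expected[1], abs=1e-14)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            mix_lb(-0.1, 1.0, 0.1, 1.0)


class TestMorsePair:
    def test_minimum_at_equilibrium(self):
        e, dedr = morse_pair(3.4, 0.2, 3.4, 1.5)
        assert e == pytest.approx(-0.2, abs=1e-14)
        assert dedr == pytest.approx(0.0, abs=1e-14)

    def test_half_exponential_point(self):
        # at r = R + ln(2)/alpha the exponential halves: E = -0.75 eps
        alpha, eps, r0 = 1.5, 0.3, 3.0
        e, _ = morse_pair(r0 + math.log(2) / alpha, eps, r0, alpha)
        assert e == pytest.approx(-0.75 * eps, rel=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(1.0, 10.0), st.floats(1e-4, 0.5), st.floats(1.0, 5.0),
           st.floats(0.5, 3.0))
    def test_derivative_matches_finite_difference(self, r, eps, r0, alpha):
        h = 1e-6
        _, dedr = morse_pair(r, eps, r0, alpha)
        ep, _ = morse_pair(r + h, eps, r0, alpha)
        em, _ = morse_pair(r - h, eps, r0, alpha)
        fd = (ep - em) / (2 * h)
        assert abs(fd - dedr) < 1e-6 * max(1.0, abs(dedr))

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            morse_pair(0.0, 0.1, 3.0, 1.5)


class TestFactorization:
    def test_factorized_equals_direct_pair_sum(self, params):
        """The factorized Morse law is algebraically identical to the
        direct Lorentz-Berthelot pair sum (no grids involved)."""
        rng = np.random.default_rng(7)
        sub = build_rocksalt_slab(2, 2, 2)
        pts = np.column_stack([rng.uniform(0, 8, 12), rng.uniform(0, 8, 12),
                               rng.uniform(2.5, 6, 12)])
        eps_i, r_i = 0.01, 1.8
        a = params.alpha
        s_p, s_l = morse_factor_sums(pts, sub.positions, sub.epsilons,
                                     sub.radii, a)
        e_fact = (math.sqrt(eps_i) * np.exp(2 * a * r_i) * s_p -
                  2 * math.sqrt(eps_i) * np.exp(a * r_i) * s_l)
        for k, p in enumerate(pts):
            r = np.linalg.norm(p - sub.positions, axis=1)
            e_direct = morse_pair(r, np.sqrt(eps_i * sub.epsilons),
                                  r_i + sub.radii, a)[0].sum()
            assert e_fact[k] == pytest.approx(e_direct, rel=1e-12)


class TestDirectReference:
    def _one_pair(self, q=0.0):
        sub = Substrate(["Cl"], np.array([[0.0, 0.0, 0.0]]), np.array([-q]),
                        np.array([0.009844]), np.array([1.9735]),
                        np.diag([200.0, 200.0, 10.0]))
        mol = Molecule(["C"], np.array([[0.0, 0.0, 3.0]]), np.array([q]),
                       np.array([0.004553]), np.array([1.9255]),
                       np.array([12.011]))
        return mol, sub

    def test_single_pair_reduces_to_morse(self, params):
        mol, sub = self._one_pair()
        e_m, e_c, f = direct_reference(mol, sub, params, n_images=0)
        eps = math.sqrt(0.004553 * 0.009844)
        e_ref, dedr = morse_pair(3.0, eps, 1.9255 + 1.9735, params.alpha)
        assert e_m == pytest.approx(e_ref, rel=1e-14)
        assert e_c == 0.0
        assert f[0, 2] == pytest.approx(-dedr, rel=1e-12)

    def test_image_count_saturates_beyond_cutoff(self, params):
        mol = make_probe_molecule("rigid-planar", 4, seed=1)
        pos = mol.positions.copy()
        pos[:, 2] += 3.0 - pos[:, 2].min()
        mol = mol.with_positions(pos)
        sub = build_rocksalt_slab(2, 2, 2)
        n_min = math.ceil(params.r_cut / 8.0) + 1
        e1, _, _ = direct_reference(mol, sub, params, n_images=n_min)
        e2, _, _ = direct_reference(mol, sub, params, n_images=2 * n_min)
        assert e1 == pytest.approx(e2, abs=1e-15)

    def test_forces_match_finite_differences(self, params):
        mol = make_probe_molecule("rigid-planar", 5, seed=3)
        pos = mol.positions.copy()
        pos[:, 2] += 3.2 - pos[:, 2].min()
        mol = mol.with_positions(pos)
        sub = build_rocksalt_slab(2, 2, 1)
        e_m, e_c, f = direct_reference(mol, sub, params, n_images=5)
        h = 1e-5
        for i in range(mol.n_atoms):
            for ax in range(3):
                for sgn, store in ((1, "p"), (-1, "m")):
                    p = mol.positions.copy()
                    p[i, ax] += sgn * h
                    em, ec, _ = direct_reference(mol.with_positions(p), sub,
                                                 params, n_images=5)
                    if sgn == 1:
                        e_plus = em + ec
                    else:
                        e_minus = em + ec
                fd = -(e_plus - e_minus) / (2 * h)
                assert abs(fd - f[i, ax]) < 1e-6

    def test_overlap_rejected(self, params):
        mol, sub = self._one_pair()
        mol = mol.with_positions(np.array([[0.0, 0.0, 1e-8]]))
        with pytest.raises(ValueError):
            direct_reference(mol, sub, params, n_images=0)


class TestEwald:
    def test_antisymmetric_pair_plane(self):
        """On the mirror plane between +q and -q the potential vanishes."""
        sub = Substrate(["Na", "Cl"],
                        np.array([[5.0, 5.0, 6.0], [5.0, 5.0, 4.0]]),
                        np.array([1.0, -1.0]), np.array([1e-3, 1e-3]),
                        np.array([1.5, 1.5]), np.diag([10.0, 10.0, 10.0]),
                        (True, True, True))
        v = ewald_potential(sub, np.array([2.0, 7.0, 5.0]))
        assert abs(v) < 1e-10

    def test_isolated_pair_limit(self):
        """In a huge cell the Ewald potential approaches k_e q/r sums."""
        sub = Substrate(["Na", "Cl"],
                        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
                        np.array([1.0, -1.0]), np.array([1e-3, 1e-3]),
                        np.array([1.5, 1.5]), np.diag([200.0, 200.0, 200.0]),
                        (True, True, True))
        es = EwaldSum(sub, beta=0.1)
        pt = np.array([1.5, 0.0, 0.0])
        v = es.potential(pt)[0]
        exact = 14.399645 * (1.0 / 1.5 - 1.0 / np.linalg.norm(pt - [0, 0, 1]))
        assert v == pytest.approx(exact, rel=1e-3)

    def test_nacl_site_sign_antisymmetry(self, nacl):
        """V above a Na site and above a Cl site have opposite signs."""
        es = EwaldSum(nacl)
        v_na = es.potential(np.array([0.0, 0.0, 3.0]))[0]
        v_cl = es.potential(np.array([2.0, 2.0, 3.0]))[0]
        assert v_na > 0 > v_cl
        assert v_na == pytest.approx(-v_cl, rel=1e-9)

    def test_splitting_parameter_invariance(self, nacl):
        pts = np.array([[0.7, 1.3, 3.0], [2.2, 0.1, 4.5]])
        v1 = EwaldSum(nacl, beta=0.35).potential(pts)
        v2 = EwaldSum(nacl, beta=0.55).potential(pts)
        assert np.abs(v1 - v2).max() < 1e-7  # 1e-4 meV

    def test_field_is_potential_gradient(self, nacl):
        es = EwaldSum(nacl)
        pt = np.array([[1.1, 0.4, 3.2]])
        e = es.field(pt)[0]
        h = 1e-5
        for ax in range(3):
            d = np.zeros(3)
            d[ax] = h
            fd = -(es.potential(pt + d)[0] - es.potential(pt - d)[0]) / (2 * h)
            assert fd == pytest.approx(e[ax], abs=1e-7)

    def test_non_neutral_rejected(self):
        sub = Substrate(["Na"], np.array([[0.0, 0.0, 0.0]]), np.array([1.0]),
                        np.array([1e-3]), np.array([1.5]),
                        np.diag([10.0, 10.0, 10.0]))
        with pytest.raises(ValueError):
            ewald_potential(sub, np.array([1.0, 1.0, 1.0]))


class TestNewtonThirdLaw:
    def test_two_body_forces_cancel(self, params):
        """Total force of an isolated two-body system is zero."""
        mol, sub = (make_probe_molecule("rigid-planar", 2, seed=5), None)
        # use the intra nonbonded route: two atoms, no exclusions
        mol2 = Molecule(["C", "O"], np.array([[0.0, 0.0, 0.0],
                                              [1.1, 0.7, 2.2]]),
                        np.array([0.1, -0.1]), np.array([0.004553, 0.002602]),
                        np.array([1.9255, 1.75]), np.array([12.011, 15.999]))
        from gridff.engine import intramolecular_energy_force
        _, _, f = intramolecular_energy_force(mol2, params)
        assert np.abs(f.sum(axis=0)).max() < 1e-14


class TestRocksaltSlab:
    @pytest.mark.parametrize("dims,count", [
        ((8, 8, 3), 384), ((20, 20, 3), 2400), ((1, 1, 1), 2),
    ])
    def test_atom_counts(self, dims, count):
        sub = build_rocksalt_slab(*dims)
        assert sub.n_atoms == count
        assert sub.charges.sum() == 0.0

    def test_unit_case_composition(self):
        sub = build_rocksalt_slab(1, 1, 1)
        assert sorted(sub.elements) == ["Cl", "Na"]

    def test_rocksalt_nearest_neighbours(self):
        """Every ion has six opposite neighbours at a/sqrt(2)."""
        sub = build_rocksalt_slab(3, 3, 3)
        d_nn = 4.0 / math.sqrt(2.0)
        pos, q = sub.positions, sub.charges
        i = np.argmin(np.linalg.norm(pos - [4.0, 4.0, -d_nn], axis=1))
        d = np.linalg.norm(pos - pos[i], axis=1)
        nn = (d > 1e-9) & (d < d_nn + 1e-6)
        assert nn.sum() == 6
        assert np.all(q[nn] == -q[i])

    def test_non_neutral_parameterization_rejected(self):
        with pytest.raises(ValueError):
            build_rocksalt_slab(2, 2, 1, q_na=0.9, q_cl=-0.8)


class TestVacancyPair:
    def test_counts_charge_and_layer(self):
        sub = build_rocksalt_slab(4, 4, 3)
        z_top = sub.positions[:, 2].max()
        vac = introduce_vacancy_pair(sub)
        assert vac.n_atoms == sub.n_atoms - 2
        assert vac.charges.sum() == 0.0
        # the removed atoms came from the topmost layer
        n_top_before = (np.abs(sub.positions[:, 2] - z_top) < 1e-6).sum()
        n_top_after = (np.abs(vac.positions[:, 2] - z_top) < 1e-6).sum()
        assert n_top_before - n_top_after == 2

    def test_large_slab_count(self):
        vac = introduce_vacancy_pair(build_rocksalt_slab(6, 6, 3))
        assert vac.n_atoms == 214


class TestProbeMolecules:
    @pytest.mark.parametrize("kind,n", [
        ("rigid-planar", 6), ("flexible-chain", 8), ("polyol-chain", 9),
    ])
    def test_deterministic_and_neutral(self, kind, n):
        m1 = make_probe_molecule(kind, n, seed=11)
        m2 = make_probe_molecule(kind, n, seed=11)
        assert np.array_equal(m1.positions, m2.positions)
        assert np.array_equal(m1.charges, m2.charges)
        assert abs(m1.charges.sum()) < 1e-12

    def test_chain_topology_counts(self):
        mol = make_probe_molecule("flexible-chain", 8, seed=1)
        assert len(mol.bonds) == 7
        assert len(mol.angles) == 6
        assert len(mol.torsions) == 5

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_probe_molecule("cube", 8, seed=0)
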