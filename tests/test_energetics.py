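import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_residue, simple_structure

from bsfp.core_model import Trajectory
from bsfp.energetics import (
    COULOMB_CONSTANT,
    ForceFieldParams,
    binding_free_energy,
    effective_born_radii,
    energy_terms,
    gb_energy,
    mm_energy,
    read_params,
    sa_energy,
    total_sasa,
    write_params,
)
from bsfp.errors import (
    NumericalDegeneracyError,
    ParameterError,
    SelectionOverlapError,
)


def uniform_params(n, charge=0.0, eps=0.0, rmin=3.0, gb=2.0, **kw):
    return ForceFieldParams(np.full(n, charge), np.full(n, eps),
                            np.full(n, rmin), np.full(n, gb), **kw)


def structure_from_coords(coords, chains=None):
    residues = []
    for i, c in enumerate(np.asarray(coords, dtype=float)):
        chain = chains[i] if chains else "A"
        residues.append(make_residue(chain, i + 1, "ALA",
                                     [("CA", "C", tuple(c))]))
    return simple_structure(residues)


class TestMolecularMechanics:
    def test_coulomb_pair_closed_form(self):
        p = uniform_params(2)
        p.charge = np.array([1.0, -1.0])
        _, e_elec, _ = mm_energy(np.array([[0, 0, 0], [3.32, 0, 0.0]]), p)
        assert e_elec == pytest.approx(-COULOMB_CONSTANT / 3.32)

    def test_harmonic_bond_closed_form(self):
        p = uniform_params(2, bonds=[(0, 1, 100.0, 1.5)])
        e_int, e_elec, e_vdw = mm_energy(np.array([[0, 0, 0], [1.6, 0, 0.0]]), p)
        assert e_int == pytest.approx(1.0)
        assert e_elec == 0.0 and e_vdw == 0.0  # 1-2 pair excluded

    def test_lennard_jones_minimum(self):
        p = uniform_params(2, eps=0.2, rmin=3.4)
        _, _, e_vdw = mm_energy(np.array([[0, 0, 0], [3.4, 0, 0.0]]), p)
        assert e_vdw == pytest.approx(-0.2)

    def test_five_atom_molecule_matches_term_oracle(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 4, (5, 3))
        p = ForceFieldParams(
            charge=np.array([0.3, -0.2, 0.1, -0.15, -0.05]),
            lj_eps=np.full(5, 0.1), lj_rmin=np.full(5, 3.2),
            gb_radius=np.full(5, 1.8),
            bonds=[(0, 1, 300.0, 1.5), (1, 2, 300.0, 1.5),
                   (2, 3, 300.0, 1.5), (3, 4, 300.0, 1.5)],
            angles=[(0, 1, 2, 50.0, 109.5), (1, 2, 3, 50.0, 109.5),
                    (2, 3, 4, 50.0, 109.5)],
            dihedrals=[(0, 1, 2, 3, 1.4, 3, 0.0), (1, 2, 3, 4, 1.4, 3, 0.0)],
            scale14_elec=0.5, scale14_lj=0.5)
        e_int, e_elec, e_vdw = mm_energy(coords, p)

        # independent plain-loop oracle
        def dist(i, j):
            return float(np.linalg.norm(coords[i] - coords[j]))

        oracle_int = sum(k * (dist(i, j) - r0) ** 2 for i, j, k, r0 in p.bonds)
        for i, j, k, kt, t0 in p.angles:
            v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
            theta = math.acos(np.dot(v1, v2)
                              / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            oracle_int += kt * (theta - math.radians(t0)) ** 2
        for i, j, k, l, kp, n, d in p.dihedrals:
            b0 = coords[j] - coords[i]
            b1 = coords[k] - coords[j]
            b2 = coords[l] - coords[k]
            n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
            m1 = np.cross(n1, b1 / np.linalg.norm(b1))
            phi = math.atan2(np.dot(m1, n2), np.dot(n1, n2))
            oracle_int += kp * (1 + math.cos(n * phi - math.radians(d)))
        # topology of the 5-atom chain: |i-j| = separation in bonds
        oracle_elec = oracle_vdw = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                sep = j - i
                if sep < 3:
                    continue
                scale = 0.5 if sep == 3 else 1.0
                r = dist(i, j)
                oracle_elec += scale * COULOMB_CONSTANT \
                    * p.charge[i] * p.charge[j] / r
                ratio6 = (3.2 / r) ** 6
                oracle_vdw += scale * 0.1 * (ratio6 ** 2 - 2 * ratio6)
        assert e_int == pytest.approx(oracle_int, abs=1e-8)
        assert e_elec == pytest.approx(oracle_elec, abs=1e-8)
        assert e_vdw == pytest.approx(oracle_vdw, abs=1e-8)

    def test_missing_parameters_detected(self):
        p = uniform_params(2)
        with pytest.raises(ParameterError):
            mm_energy(np.zeros((3, 3)), p)
        with pytest.raises(ParameterError):
            ForceFieldParams(np.zeros(2), np.zeros(2), np.ones(2),
                             np.ones(2), bonds=[(0, 5, 1.0, 1.0)])


class TestGeneralizedBorn:
    def test_born_ion_closed_form(self):
        p = uniform_params(1, charge=1.0, gb=2.0)
        expected = -(1 - 1 / 78.5) * COULOMB_CONSTANT / (2 * 2.0)
        assert gb_energy(np.zeros((1, 3)), p) == pytest.approx(expected)

    def test_neutral_atoms_zero(self):
        p = uniform_params(2, charge=0.0)
        assert gb_energy(np.array([[0, 0, 0], [4.0, 0, 0]]), p) == 0.0

    def test_pair_matches_direct_formula(self):
        p = uniform_params(2, charge=1.0, gb=1.7)
        coords = np.array([[0, 0, 0], [4.0, 0, 0.0]])
        value = gb_energy(coords, p)
        b = effective_born_radii(coords, p)
        tau = (1.0 - 1.0 / 78.5) * COULOMB_CONSTANT
        f_cross = math.sqrt(16.0 + b[0] * b[1]
                            * math.exp(-16.0 / (4 * b[0] * b[1])))
        expected = -0.5 * tau * (1.0 / b[0] + 1.0 / b[1] + 2.0 / f_cross)
        assert value == pytest.approx(expected, abs=1e-10)

    def test_isolated_atom_effective_radius_is_intrinsic(self):
        p = uniform_params(1, gb=2.3)
        assert effective_born_radii(np.zeros((1, 3)), p)[0] == pytest.approx(2.3)

    def test_descreening_grows_effective_radius(self):
        p = uniform_params(2, gb=1.7)
        b = effective_born_radii(np.array([[0, 0, 0], [3.0, 0, 0.0]]), p)
        assert np.all(b > 1.7)

    def test_degenerate_radius_detected(self):
        # pairwise descreening overcounts overlapping engulfing neighbours;
        # a small atom surrounded by many huge ones drives 1/B negative
        n = 13
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(n - 1, 3))
        coords = np.vstack([np.zeros(3),
                            2.0 * dirs / np.linalg.norm(dirs, axis=1,
                                                        keepdims=True)])
        p = ForceFieldParams(np.zeros(n), np.zeros(n), np.ones(n),
                             np.array([1.0] + [8.0] * (n - 1)), gb_scale=1.0)
        with pytest.raises(NumericalDegeneracyError):
            effective_born_radii(coords, p)


class TestSurfaceArea:
    def test_zero_coefficients(self, toy_protein):
        p = uniform_params(len(toy_protein.all_atoms()), gamma=0.0, beta=0.0)
        assert sa_energy(toy_protein, p) == 0.0

    def test_single_atom_closed_form(self):
        s = structure_from_coords([[0, 0, 0]])
        p = uniform_params(1)
        expected = 0.00542 * 4 * math.pi * (1.7 + 1.4) ** 2 + 0.92
        assert sa_energy(s, p) == pytest.approx(expected, rel=1e-3)

    def test_dimer_composition(self):
        s = structure_from_coords([[0, 0, 0], [2.5, 0, 0]])
        p = uniform_params(2)
        assert sa_energy(s, p) == pytest.approx(
            0.00542 * total_sasa(s) + 0.92)


def two_body_trajectory(separations, chains=("A", "B")):
    frames = []
    for k, sep in enumerate(separations):
        s = structure_from_coords([[0, 0, 0], [sep, 0, 0]], chains=chains)
        s.residues[1].is_hetero = False
        s.frame_index = k
        frames.append(s)
    return Trajectory(frames)


class TestBindingFreeEnergy:
    def test_distant_neutral_particles_bind_zero(self):
        traj = two_body_trajectory([50.0] * 10)
        p = uniform_params(2, eps=0.1, rmin=3.4, gamma=0.0, beta=0.0,
                           eps_solv=1.0)
        result = binding_free_energy(traj, [0], [1], p)
        assert abs(result.mean) < 1e-6
        assert result.entropy_term == 0.0

    def test_charged_pair_reduces_to_coulomb(self):
        traj = two_body_trajectory([3.32] * 5)
        p = uniform_params(2, gamma=0.0, beta=0.0, eps_solv=1.0)
        p.charge = np.array([1.0, -1.0])
        result = binding_free_energy(traj, [0], [1], p)
        assert result.mean == pytest.approx(-COULOMB_CONSTANT / 3.32)
        assert result.sd == 0.0

    def test_oscillating_pair_matches_frame_loop_oracle(self):
        seps = [3.0 + 0.5 * math.sin(k) for k in range(20)]
        traj = two_body_trajectory(seps)
        p = uniform_params(2, eps=0.15, rmin=3.1, gamma=0.0, beta=0.0,
                           eps_solv=1.0)
        p.charge = np.array([0.4, -0.4])
        result = binding_free_energy(traj, [0], [1], p)
        oracle = []
        for sep in seps:
            elec = -COULOMB_CONSTANT * 0.16 / sep
            ratio6 = (3.1 / sep) ** 6
            lj = 0.15 * (ratio6 ** 2 - 2 * ratio6)
            oracle.append(elec + lj)
        assert result.mean == pytest.approx(np.mean(oracle), abs=1e-8)
        assert result.sd == pytest.approx(np.std(oracle, ddof=1), abs=1e-8)
        np.testing.assert_allclose(result.per_frame, oracle, atol=1e-8)

    def test_additivity_with_full_solvation(self):
        traj = two_body_trajectory([3.5, 4.0, 4.5])
        p = uniform_params(2, eps=0.1, rmin=3.2, gb=1.8)
        p.charge = np.array([0.5, -0.5])
        result = binding_free_energy(traj, [0], [1], p)
        for k, frame in enumerate(traj.frames):
            complex_terms = energy_terms(frame, p)
            rec = structure_from_coords([frame.coords()[0]])
            lig = structure_from_coords([frame.coords()[1]])
            rec_terms = energy_terms(rec, uniform_params(1, charge=0.5,
                                                         eps=0.1, rmin=3.2,
                                                         gb=1.8))
            lig_terms = energy_terms(lig, uniform_params(1, charge=-0.5,
                                                         eps=0.1, rmin=3.2,
                                                         gb=1.8))
            d_mm = complex_terms.E_MM - rec_terms.E_MM - lig_terms.E_MM
            d_sol = complex_terms.G_sol - rec_terms.G_sol - lig_terms.G_sol
            assert abs(result.per_frame[k] - (d_mm + d_sol)) < 1e-10

    def test_internal_energy_cancels_with_bonded_terms(self):
        # receptor is a bonded diatomic, ligand a lone atom
        frames = []
        for k in range(4):
            coords = [[0, 0, 0], [1.6 + 0.05 * k, 0, 0], [8.0, 0, 0]]
            s = structure_from_coords(coords, chains=["A", "A", "B"])
            frames.append(s)
        traj = Trajectory(frames)
        p = uniform_params(3, eps=0.05, rmin=3.0, gamma=0.0, beta=0.0,
                           eps_solv=1.0, bonds=[(0, 1, 200.0, 1.5)])
        result = binding_free_energy(traj, [0, 1], [2], p)
        assert result.components["dE_internal"] == 0.0

    def test_rigid_transform_invariance(self):
        traj = two_body_trajectory([3.5] * 2)
        p = uniform_params(2, eps=0.1, rmin=3.2, gb=1.8)
        p.charge = np.array([0.5, -0.5])
        before = binding_free_energy(traj, [0], [1], p).mean
        rot = Rotation.random(rng=np.random.default_rng(4)).as_matrix()
        for frame in traj.frames:
            frame.transform(rot, np.array([5.0, 6.0, 7.0]))
        after = binding_free_energy(traj, [0], [1], p).mean
        # MM and GB terms are analytic (1e-8); SASA adds point-grid noise
        assert after == pytest.approx(before, abs=1e-3)

    def test_gas_phase_terms_rigid_invariance(self):
        coords = np.random.default_rng(6).uniform(0, 5, (4, 3))
        p = uniform_params(4, eps=0.1, rmin=3.0, gb=1.8)
        p.charge = np.array([0.3, -0.1, -0.1, -0.1])
        rot = Rotation.random(rng=np.random.default_rng(7)).as_matrix()
        moved = coords @ rot.T + np.array([1.0, 2.0, 3.0])
        assert mm_energy(moved, p) == pytest.approx(mm_energy(coords, p),
                                                    abs=1e-8)
        assert gb_energy(moved, p) == pytest.approx(gb_energy(coords, p),
                                                    abs=1e-8)

    def test_selection_validation(self):
        traj = two_body_trajectory([4.0])
        p = uniform_params(2)
        with pytest.raises(SelectionOverlapError):
            binding_free_energy(traj, [0, 1], [1], p)
        with pytest.raises(SelectionOverlapError):
            binding_free_energy(traj, [0], [], p)
        p_bonded = uniform_params(2, bonds=[(0, 1, 1.0, 1.0)])
        with pytest.raises(SelectionOverlapError):
            binding_free_energy(traj, [0], [1], p_bonded)


class TestParameterFiles:
    def test_round_trip(self, tmp_path):
        p = ForceFieldParams(
            np.array([0.1, -0.1, 0.0]), np.array([0.1, 0.2, 0.3]),
            np.array([3.0, 3.1, 3.2]), np.array([1.5, 1.6, 1.7]),
            bonds=[(0, 1, 100.0, 1.5)], angles=[(0, 1, 2, 50.0, 109.5)],
            dihedrals=[], eps_solv=80.0, gamma=0.006, scale14_elec=0.5)
        path = tmp_path / "toy.ff.tsv"
        write_params(p, path)
        q = read_params(path, 3)
        np.testing.assert_array_equal(q.charge, p.charge)
        np.testing.assert_array_equal(q.lj_rmin, p.lj_rmin)
        assert q.bonds == p.bonds
        assert q.angles == p.angles
        assert q.eps_solv == 80.0 and q.gamma == 0.006
        assert q.scale14_elec == 0.5

    def test_atom_count_mismatch(self, tmp_path):
        p = uniform_params(2)
        path = tmp_path / "toy.ff.tsv"
        write_params(p, path)
        with pytest.raises(ParameterError):
            read_params(path, 5)

    def test_invalid_values_rejected(self):
        with pytest.raises(ParameterError):
            ForceFieldParams(np.zeros(1), np.zeros(1), np.ones(1),
                             np.array([-1.0]))
        with pytest.raises(ParameterError):
            ForceFieldParams(np.zeros(1), np.zeros(1), np.ones(1),
                             np.ones(1), eps_solv=0.5)
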