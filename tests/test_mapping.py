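"""Protein-surface mapping: max-over-residues rule, masks, orientation maps."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from halomif.fitting import MIFModel, MIFResults
from halomif.frames import build_residue_frame, lab_to_molecular
from halomif.grids import box_grid, spherical_to_cartesian
from halomif.mapping import (
    MapOptions,
    ligand_site_mask,
    map_protein_mif,
    residue_frames,
    strength_at_point,
    survey_halogen_bonds,
    survey_to_csv,
    theta_phi_map,
)
from halomif.structures_io import Atom, Structure

from conftest import amide_atoms


def brute_force_map(structure, fn, grid, options):
    """Independent per-voxel oracle: loop residues, apply every rule."""
    frames = residue_frames(structure)
    heavy = np.array([a.xyz for a in structure.protein_atoms() if a.element != "H"])
    coords = grid.point_coordinates()
    values = np.zeros(len(coords))
    winners = np.full(len(coords), -1)
    for i, p in enumerate(coords):
        if heavy.size and np.min(np.linalg.norm(heavy - p, axis=1)) <= options.steric_radius:
            continue
        for j, (_, frame, _) in enumerate(frames):
            local = lab_to_molecular(frame, p)
            r = np.linalg.norm(local)
            if r < options.r_min_domain or r > options.r_max_domain:
                continue
            s = float(np.clip(fn.evaluate(local), 0.0, 1.0))
            if s > values[i]:
                values[i] = s
                winners[i] = j
    return values.reshape(grid.dims), winners.reshape(grid.dims)


@pytest.fixture
def toy_grid():
    return box_grid((2.0, 1.0, 0.0), 8, 1.1)


class TestMapProteinMIF:
    def test_two_residue_map_equals_brute_force(self, two_residue_structure, small_fit, toy_grid):
        options = MapOptions()
        result = map_protein_mif(two_residue_structure, small_fit, toy_grid, options)
        oracle_vals, oracle_win = brute_force_map(two_residue_structure, small_fit, toy_grid, options)
        np.testing.assert_allclose(result.grid.values, oracle_vals, atol=1e-12)
        np.testing.assert_array_equal(result.contributor, oracle_win)

    def test_single_residue_map_is_clamped_direct_evaluation(self, single_residue_structure, small_fit, toy_grid):
        options = MapOptions()
        result = map_protein_mif(single_residue_structure, small_fit, toy_grid, options)
        (rid, frame, _), = residue_frames(single_residue_structure)
        coords = toy_grid.point_coordinates()
        heavy = np.array([a.xyz for a in single_residue_structure.protein_atoms()])
        for p, got in zip(coords, result.grid.values.reshape(-1)):
            local = lab_to_molecular(frame, p)
            r = np.linalg.norm(local)
            if np.min(np.linalg.norm(heavy - p, axis=1)) <= 2.0 or r > 7.0:
                assert got == 0.0
            else:
                assert got == pytest.approx(float(np.clip(small_fit.evaluate(local), 0, 1)), abs=1e-12)

    def test_steric_mask_zeroes_near_atoms(self, single_residue_structure, small_fit):
        # voxel 1.5 A from the carbonyl oxygen must be 0 whatever the function says
        grid = box_grid((1.5, 0.0, 0.0), 1, 0.5)
        result = map_protein_mif(single_residue_structure, small_fit, grid)
        assert result.grid.values.reshape(-1)[0] == 0.0

    def test_values_bounded_and_mask_invariant(self, two_residue_structure, small_fit, toy_grid):
        result = map_protein_mif(two_residue_structure, small_fit, toy_grid)
        vals = result.grid.values
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        heavy = np.array([a.xyz for a in two_residue_structure.protein_atoms()])
        coords = toy_grid.point_coordinates()
        near = np.array([np.min(np.linalg.norm(heavy - p, axis=1)) <= 2.0 for p in coords])
        assert np.all(vals.reshape(-1)[near] == 0.0)

    def test_residue_order_permutation_invariant_values(self, two_residue_structure, small_fit, toy_grid):
        reversed_atoms = (two_residue_structure.atoms[4:] + two_residue_structure.atoms[:4])
        flipped = Structure(atoms=reversed_atoms, name="flipped")
        a = map_protein_mif(two_residue_structure, small_fit, toy_grid)
        b = map_protein_mif(flipped, small_fit, toy_grid)
        np.testing.assert_allclose(a.grid.values, b.grid.values, atol=1e-12)

    def test_threshold_sets_nest(self, two_residue_structure, small_fit, toy_grid):
        vals = map_protein_mif(two_residue_structure, small_fit, toy_grid).grid.values
        s80 = vals >= 0.8
        s50 = vals >= 0.5
        s30 = vals >= 0.3
        assert np.all(s80 <= s50) and np.all(s50 <= s30)

    def test_no_carbonyl_raises(self, small_fit, toy_grid):
        bare = Structure(atoms=[Atom(serial=1, name="CA", element="C",
                                     residue_name="GLY", chain_id="A",
                                     residue_number=1, position=(0, 0, 0))])
        with pytest.raises(ValueError):
            map_protein_mif(bare, small_fit, toy_grid)


class TestStrengthAtPoint:
    def test_far_point_outside_domain_is_zero(self, single_residue_structure, small_fit):
        s, rid = strength_at_point(single_residue_structure, small_fit, (12.0, 0.0, 0.0))
        assert s == 0.0 and rid is None

    def test_peak_of_normalized_function_reaches_one(self, single_residue_structure, coarse_grid):
        # a function that is exactly 1 somewhere: fit strengths then query the argmax
        from halomif.synthetic import SurrogateParams, surrogate_mif
        from halomif.cgf_basis import enumerate_basis

        samples = surrogate_mif(coarse_grid, SurrogateParams())
        res = MIFModel.from_samples(samples, basis=enumerate_basis(max_degree=4)).fit()
        # dense molecular-frame search for the function's max inside the domain
        rng = np.random.default_rng(4)
        pts = rng.uniform(-6, 6, (4000, 3))
        pts = pts[np.linalg.norm(pts, axis=1) <= 7.0]
        vals = np.clip(res.evaluate(pts), 0, 1)
        best_local = pts[np.argmax(vals)]
        (rid, frame, _), = residue_frames(single_residue_structure)
        lab = frame.origin + best_local @ frame.rotation
        heavy = np.array([a.xyz for a in single_residue_structure.protein_atoms()])
        if np.min(np.linalg.norm(heavy - lab, axis=1)) > 2.0:
            s, rid_got = strength_at_point(single_residue_structure, res, lab)
            assert s == pytest.approx(float(np.max(vals)), abs=1e-9)
            assert rid_got == rid

    def test_matches_map_rule(self, two_residue_structure, small_fit, toy_grid):
        result = map_protein_mif(two_residue_structure, small_fit, toy_grid)
        coords = toy_grid.point_coordinates()
        rng = np.random.default_rng(6)
        for i in rng.choice(len(coords), size=12, replace=False):
            s, rid = strength_at_point(two_residue_structure, small_fit, coords[i])
            assert s == pytest.approx(result.grid.values.reshape(-1)[i], abs=1e-12)

    def test_rigid_body_invariance(self, two_residue_structure, small_fit):
        rng = np.random.default_rng(23)
        point = np.array([3.5, 0.5, 1.0])
        ref, _ = strength_at_point(two_residue_structure, small_fit, point)
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-20, 20, 3)
            moved_atoms = [
                Atom(serial=a.serial, name=a.name, element=a.element,
                     residue_name=a.residue_name, chain_id=a.chain_id,
                     residue_number=a.residue_number,
                     position=tuple(R @ a.xyz + t))
                for a in two_residue_structure.atoms
            ]
            moved = Structure(atoms=moved_atoms)
            s, _ = strength_at_point(moved, small_fit, R @ point + t)
            assert s == pytest.approx(ref, abs=1e-9)


class TestLigandMask:
    def _ligand(self, pos):
        return [Atom(serial=99, name="CL1", element="Cl", residue_name="LIG",
                     chain_id="A", residue_number=101, position=tuple(pos),
                     is_hetatm=True)]

    def test_matches_brute_force_sphere(self, toy_grid):
        lig = self._ligand((2.4, 1.1, 0.3))
        mask = ligand_site_mask(toy_grid, lig, radius=4.0)
        coords = toy_grid.point_coordinates()
        expect = (np.linalg.norm(coords - np.array([2.4, 1.1, 0.3]), axis=1) <= 4.0)
        np.testing.assert_array_equal(mask.reshape(-1), expect)

    def test_zero_radius_masks_nothing(self, toy_grid):
        mask = ligand_site_mask(toy_grid, self._ligand((2.0, 1.0, 0.0)), radius=0.0)
        assert not mask.any()

    def test_atom_on_grid_node_is_active(self):
        grid = box_grid((0.0, 0.0, 0.0), 3, 1.0)
        mask = ligand_site_mask(grid, self._ligand((0.0, 0.0, 0.0)), radius=0.5)
        assert mask[1, 1, 1]

    def test_empty_ligand_rejected(self, toy_grid):
        with pytest.raises(ValueError):
            ligand_site_mask(toy_grid, [], radius=4.0)

    def test_restricts_map_support(self, two_residue_structure, small_fit, toy_grid):
        lig = self._ligand((2.4, 1.1, 0.3))
        options = MapOptions(ligand_mask_radius=3.0)
        res = map_protein_mif(two_residue_structure, small_fit, toy_grid,
                              options, ligand_atoms=lig)
        mask = ligand_site_mask(toy_grid, lig, radius=3.0)
        assert np.all(res.grid.values[~mask] == 0.0)


class TestThetaPhiMap:
    def test_entries_match_pointwise_evaluation(self, small_fit):
        grid = theta_phi_map(small_fit, d=3.0, theta_step=30.0, phi_step=45.0)
        thetas = np.arange(0.0, 181.0, 30.0)
        phis = np.arange(0.0, 360.0, 45.0)
        assert grid.shape == (len(thetas), len(phis))
        for i, t in enumerate(thetas):
            for j, p in enumerate(phis):
                pt = spherical_to_cartesian(3.0, t, p)
                expect = float(np.clip(small_fit.evaluate(pt), 0, 1))
                assert grid[i, j] == pytest.approx(expect, abs=1e-12)

    def test_pole_rows_constant(self, small_fit):
        grid = theta_phi_map(small_fit, d=3.2, theta_step=10.0, phi_step=10.0)
        assert np.ptp(grid[0]) < 1e-12
        assert np.ptp(grid[-1]) < 1e-12

    def test_zero_function_gives_zero_map(self, full_basis):
        model = MIFModel(np.zeros(1), np.zeros((1, 3)), basis=full_basis)
        res = MIFResults(model=model, params=np.zeros(len(full_basis)),
                         delta=0.0, rsquared=0.0)
        assert not theta_phi_map(res, d=3.0).any()

    def test_invalid_radius_rejected(self, small_fit):
        with pytest.raises(ValueError):
            theta_phi_map(small_fit, d=0.0)


class TestSurvey:
    def _structure_with_ligand(self):
        atoms = amide_atoms(1, "A", 1, resname="VAL")
        atoms.append(Atom(serial=5, name="CL1", element="Cl", residue_name="ZES",
                          chain_id="A", residue_number=101,
                          position=tuple(spherical_to_cartesian(3.1, 70.0, 90.0)),
                          is_hetatm=True))
        x = np.asarray(atoms[-1].position)
        c_pos = x + 1.74 * (x / np.linalg.norm(x))
        atoms.append(Atom(serial=6, name="C7", element="C", residue_name="ZES",
                          chain_id="A", residue_number=101, position=tuple(c_pos),
                          is_hetatm=True))
        return Structure(atoms=atoms, name="toy-survey")

    def test_survey_reports_geometry_and_strength(self, small_fit, tmp_path):
        st = self._structure_with_ligand()
        records = survey_halogen_bonds(st, small_fit, "ZES")
        assert len(records) == 1
        rec = records[0]
        assert rec.d == pytest.approx(3.1, abs=1e-9)
        assert rec.theta2 == pytest.approx(110.0, abs=1e-9)  # theta = 70
        expect, _ = strength_at_point(st, small_fit, np.asarray(st.atoms[4].position))
        assert rec.strength == pytest.approx(expect)
        out = tmp_path / "survey.csv"
        survey_to_csv(records, out, protein="TOY")
        header = out.read_text().splitlines()[0]
        assert header == "protein,pdb_id,chain,residue,ligand,halogen,d,theta1,theta2,psi,strength"
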