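import numpy as np
import pytest
from scipy.spatial.distance import pdist

from coaclash.coa_geometry import (
    fit_mast_axis,
    generate_conformers,
    measure_arm_length,
    rotate_flag,
    split_coa,
)
from coaclash.errors import (
    DegenerateGeometryError,
    IncompleteLigandError,
    ParameterError,
)
from coaclash.structure_io import AtomRecord, StructureModel
from coaclash.synthetic_data import toy_coa_model


def _atom(serial, name, element, xyz):
    return AtomRecord(serial, name, element, "COA", 1, "A",
                      np.asarray(xyz, dtype=float), hetero=True)


class TestSplitCoa:
    def test_partition_is_complete_and_disjoint(self, toy_split):
        n = len(toy_split.flag) + len(toy_split.mast) + 1
        assert n == 20
        names = {a.name for a in toy_split.flag} | {a.name for a in toy_split.mast}
        names.add(toy_split.bridge.name)
        assert len(names) == 20  # no atom in two sets

    def test_thiol_in_mast_adenine_nitrogen_in_flag(self, toy_split):
        assert any(a.element == "S" for a in toy_split.mast)
        assert any(a.element == "N" for a in toy_split.flag)
        assert toy_split.bridge.name == "O3A"

    def test_phosphate_membership(self, toy_split):
        """The 5'-alpha phosphate is on the flag; the pantetheine-side
        phosphate is on the mast."""
        assert "P1A" in {a.name for a in toy_split.flag}
        assert "P2A" in {a.name for a in toy_split.mast}

    def test_full_coa_connectivity_partition(self):
        """Partition of a full 48-heavy-atom CoA built independently with
        RDKit from the molecular graph: flag = adenosine 3',5'-bisphosphate
        (26 atoms incl. two P), mast = 4'-phosphopantetheine (21 atoms
        incl. one P and the thiol S), bridge = the pyrophosphate oxygen."""
        from rdkit import Chem
        from rdkit.Chem import AllChem

        smiles = (
            "CC(C)(COP(=O)(O)OP(=O)(O)OCC1C(C(C(O1)n2cnc3c2ncnc3N)O)OP(=O)(O)O)"
            "C(C(=O)NCCC(=O)NCCS)O"
        )
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        params = AllChem.ETKDGv3()
        params.randomSeed = 17
        assert AllChem.EmbedMolecule(mol, params) == 0
        mol = Chem.RemoveHs(mol)
        conf = mol.GetConformer()
        atoms = [
            _atom(i + 1, f"{a.GetSymbol().upper()}{i + 1}", a.GetSymbol(),
                  list(conf.GetAtomPosition(i)))
            for i, a in enumerate(mol.GetAtoms())
        ]
        assert len(atoms) == 48
        split = split_coa(StructureModel("coa_ideal", atoms))
        assert split.n_atoms == 48
        assert len(split.flag) == 26
        assert len(split.mast) == 21
        assert sum(a.element == "P" for a in split.flag) == 2
        assert sum(a.element == "P" for a in split.mast) == 1
        assert sum(a.element == "S" for a in split.mast) == 1
        assert sum(a.element == "N" for a in split.flag) == 5

    def test_missing_adenine_is_incomplete(self):
        model = toy_coa_model()
        kept = [a for a in model.atoms if a.name not in ("N9A", "C8A")]
        with pytest.raises(IncompleteLigandError, match="nitrogen|adenine"):
            split_coa(StructureModel("broken", kept))

    def test_missing_phosphorus_is_incomplete(self):
        model = toy_coa_model()
        kept = [a for a in model.atoms if a.element != "P"]
        with pytest.raises(IncompleteLigandError, match="phosphorus"):
            split_coa(StructureModel("broken", kept))

    def test_serialized_round_trip_same_partition(self, toy_split, tmp_path):
        from coaclash.structure_io import extract_ligand, parse_structure

        model = toy_coa_model()
        path = tmp_path / "toy.pdb"
        model.write_pdb(path)
        again = split_coa(extract_ligand(parse_structure(path), "COA"))
        assert {a.name for a in again.flag} == {a.name for a in toy_split.flag}
        assert {a.name for a in again.mast} == {a.name for a in toy_split.mast}
        assert again.bridge.name == toy_split.bridge.name


class TestMastAxis:
    def test_collinear_points_along_z(self):
        mast = [_atom(i, f"C{i}", "C", (0, 0, 1.5 * i)) for i in range(5)]
        mast.append(_atom(9, "S1", "S", (0, 0, 7.5)))
        axis = fit_mast_axis(mast, _atom(99, "O3A", "O", (0, 0, -1.5)))
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=1e-9)

    def test_sign_oriented_toward_thiol(self):
        mast = [_atom(i, f"C{i}", "C", (0, 0, -1.5 * i)) for i in range(5)]
        mast.append(_atom(9, "S1", "S", (0, 0, -7.5)))
        axis = fit_mast_axis(mast, _atom(99, "O3A", "O", (0, 0, 1.5)))
        np.testing.assert_allclose(axis.direction, [0, 0, -1], atol=1e-9)

    def test_noisy_axis_matches_eigendecomposition(self):
        rng = np.random.default_rng(5)
        z = np.linspace(0, 15, 11)
        coords = np.column_stack([np.zeros(11), np.zeros(11), z])
        coords += rng.normal(0, 0.05, coords.shape)
        mast = [_atom(i, f"C{i}", "C", c) for i, c in enumerate(coords[:-1])]
        mast.append(_atom(11, "S1", "S", coords[-1]))
        axis = fit_mast_axis(mast, _atom(99, "O", "O", (0, 0, -1.5)))
        # independent principal axis: eigenvector of the covariance matrix
        cov = np.cov((coords - coords.mean(axis=0)).T)
        w, v = np.linalg.eigh(cov)
        principal = v[:, np.argmax(w)]
        cosang = abs(float(np.dot(axis.direction, principal)))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 2.0
        assert abs(np.degrees(np.arccos(abs(axis.direction[2])))) < 2.0

    def test_coincident_points_degenerate(self):
        mast = [_atom(i, f"C{i}", "C", (1, 2, 3)) for i in range(4)]
        with pytest.raises(DegenerateGeometryError):
            fit_mast_axis(mast, _atom(99, "O", "O", (0, 0, 0)))


class TestRotateFlag:
    def test_zero_rotation_identity(self, toy_split):
        np.testing.assert_allclose(
            rotate_flag(toy_split, 0.0), toy_split.flag_coords, atol=1e-12
        )

    def test_full_turn_identity(self, toy_split):
        np.testing.assert_allclose(
            rotate_flag(toy_split, 360.0), toy_split.flag_coords, atol=1e-9
        )

    def test_on_axis_atom_fixed_and_radii_conserved(self, toy_split):
        axis = toy_split.axis
        for theta in (13.0, 97.5, 251.0):
            rotated = rotate_flag(toy_split, theta)
            for x0, x1 in zip(toy_split.flag_coords, rotated):
                r0 = np.linalg.norm(np.cross(x0 - axis.anchor, axis.direction))
                r1 = np.linalg.norm(np.cross(x1 - axis.anchor, axis.direction))
                assert r1 == pytest.approx(r0, abs=1e-9)

    def test_composition(self, toy_split):
        import coaclash.coa_geometry as cg

        a, b = 37.0, 101.5
        once = rotate_flag(toy_split, a + b)
        split_b = cg.CoASplit(
            flag=[at.moved_to(x) for at, x in zip(toy_split.flag, rotate_flag(toy_split, b))],
            mast=toy_split.mast, bridge=toy_split.bridge, axis=toy_split.axis,
        )
        twice = rotate_flag(split_b, a)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_nonfinite_angle_rejected(self, toy_split):
        with pytest.raises(ParameterError):
            rotate_flag(toy_split, float("nan"))


class TestConformers:
    def test_one_degree_step_gives_360(self, toy_split):
        conf = generate_conformers(toy_split, 1.0)
        assert len(conf) == 360
        np.testing.assert_allclose(conf.angles[:3], [0, 1, 2])

    def test_ninety_degree_step(self, toy_split):
        conf = generate_conformers(toy_split, 90.0)
        np.testing.assert_allclose(conf.angles, [0, 90, 180, 270])

    def test_non_divisor_step_rejected(self, toy_split):
        with pytest.raises(ParameterError):
            generate_conformers(toy_split, 7.0)

    def test_rigidity_across_all_frames(self, toy_split):
        conf = generate_conformers(toy_split, 1.0)
        ref = pdist(toy_split.flag_coords)
        for frame in conf.flag_coords:
            np.testing.assert_allclose(pdist(frame), ref, atol=1e-6)

    def test_axis_distance_conserved_across_sweep(self, toy_split):
        conf = generate_conformers(toy_split, 5.0)
        axis = toy_split.axis
        rel = toy_split.flag_coords - axis.anchor
        r0 = np.linalg.norm(np.cross(rel, axis.direction), axis=1)
        for frame in conf.flag_coords:
            rel = frame - axis.anchor
            r = np.linalg.norm(np.cross(rel, axis.direction), axis=1)
            np.testing.assert_allclose(r, r0, atol=1e-9)

    def test_multimodel_pdb_export(self, toy_split, tmp_path):
        conf = generate_conformers(toy_split, 90.0)
        path = tmp_path / "sweep.pdb"
        conf.to_multimodel_pdb(path)
        text = path.read_text()
        assert text.count("MODEL ") == 4
        assert text.count("ENDMDL") == 4


class TestArmLength:
    def test_two_points(self):
        atoms = [_atom(1, "A", "C", (0, 0, 0)), _atom(2, "B", "C", (0, 0, 10))]
        assert measure_arm_length(atoms) == pytest.approx(10.0)

    def test_collinear_chain(self):
        atoms = [_atom(i, f"C{i}", "C", (0, 0, 1.5 * i)) for i in range(11)]
        assert measure_arm_length(atoms) == pytest.approx(15.0)

    def test_toy_mast_extent(self, toy_split):
        assert measure_arm_length(toy_split.mast) == pytest.approx(15.0)
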