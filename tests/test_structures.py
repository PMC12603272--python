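"""Complex parsing, lock/key splitting and backbone superposition."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from grooveqsar.structures import (
    DNA_BACKBONE_ATOMS,
    FormatError,
    StructureError,
    apply_superposition,
    merge_lock_key,
    read_complex,
    split_lock_key,
    superpose_backbone,
    write_complex,
)
from grooveqsar.synthetic import make_synthetic_complexes


def test_read_complex_partitions_by_residue_name(three_atom_pdb):
    cs = read_complex(three_atom_pdb, {"LIG"})
    assert len(cs.ligand_atoms) == 1
    assert len(cs.receptor_atoms) == 2
    assert cs.ligand_atoms[0].partial_charge == pytest.approx(-0.25)
    assert cs.receptor_atoms[0].name == "P"
    np.testing.assert_allclose(cs.ligand_atoms[0].coords, [0.5, 0.7, 0.9])


def test_write_read_round_trip_preserves_coords_and_charges(three_atom_pdb):
    cs = read_complex(three_atom_pdb, {"LIG"})
    cs2 = read_complex(write_complex(cs), {"LIG"})
    for a, b in zip(cs.all_atoms, cs2.all_atoms):
        np.testing.assert_allclose(a.coords, b.coords, atol=5e-4)
        assert a.partial_charge == pytest.approx(b.partial_charge, abs=5e-3)
        assert (a.name, a.element, a.res_seq, a.is_ligand) == (
            b.name, b.element, b.res_seq, b.is_ligand,
        )


def test_malformed_coordinate_reports_line_number(three_atom_pdb):
    bad = three_atom_pdb.replace("   2.500   2.500", "999x.999   2.500")
    with pytest.raises(FormatError, match="line 2"):
        read_complex(bad, {"LIG"})


def test_no_ligand_match_is_empty_ligand_error(three_atom_pdb):
    with pytest.raises(StructureError, match="empty ligand"):
        read_complex(three_atom_pdb, {"XYZ"})


def test_split_conserves_atoms_and_coordinates(three_atom_pdb):
    cs = read_complex(three_atom_pdb, {"LIG"})
    lock, key = split_lock_key(cs)
    assert len(lock.receptor_atoms) == 2 and not lock.ligand_atoms
    assert len(key.ligand_atoms) == 1 and not key.receptor_atoms
    merged = merge_lock_key(lock, key)
    orig = sorted(tuple(a.coords) for a in cs.all_atoms)
    back = sorted(tuple(a.coords) for a in merged.all_atoms)
    assert orig == back


def test_split_without_ligand_raises(three_atom_pdb):
    cs = read_complex(three_atom_pdb, {"LIG"})
    cs.ligand_atoms = []
    with pytest.raises(StructureError, match="empty ligand"):
        split_lock_key(cs)


def _reference_complex():
    records, _ = make_synthetic_complexes(n=5, noise_sd=0.0, seed=2)
    return records[0].structure


def _transformed(cs, rotation, translation):
    moved = apply_superposition(
        cs,
        type("T", (), {"transform": lambda self, c: c @ np.asarray(rotation).T + translation})(),
    )
    return moved


def test_superpose_identity_is_trivial():
    ref = _reference_complex()
    sup = superpose_backbone(ref, ref)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(sup.translation, 0.0, atol=1e-12)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-6)


def test_superpose_recovers_pure_translation():
    ref = _reference_complex()
    mobile = _transformed(ref, np.eye(3), np.array([1.0, 2.0, 3.0]))
    sup = superpose_backbone(mobile, ref)
    np.testing.assert_allclose(sup.translation, [-1.0, -2.0, -3.0], atol=1e-9)
    assert sup.rmsd < 1e-6


def test_superpose_recovers_known_rotation():
    ref = _reference_complex()
    rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    mobile = _transformed(ref, rot, np.zeros(3))
    sup = superpose_backbone(mobile, ref)
    np.testing.assert_allclose(sup.rotation, rot.T, atol=1e-8)
    assert sup.rmsd < 1e-8
    # ligand atoms follow the same rigid motion
    aligned = apply_superposition(mobile, sup)
    np.testing.assert_allclose(aligned.ligand_coords(), ref.ligand_coords(), atol=1e-8)


def test_superposition_determinant_is_plus_one():
    ref = _reference_complex()
    rng = np.random.default_rng(0)
    for _ in range(5):
        rot = Rotation.random(rng=rng).as_matrix()
        mobile = _transformed(ref, rot, rng.normal(size=3))
        sup = superpose_backbone(mobile, ref)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd < 1e-6


def _quaternion_bruteforce_rmsd(mob, ref):
    """Independent oracle: minimize RMSD over unit quaternions numerically."""
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)

    def cost(q):
        q = q / np.linalg.norm(q)
        R = Rotation.from_quat(q).as_matrix()
        return np.sqrt(np.mean(np.sum((mob_c @ R.T - ref_c) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(1)
    for _ in range(20):
        res = minimize(cost, rng.normal(size=4), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return best


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_kabsch_matches_quaternion_bruteforce_on_small_sets(seed):
    rng = np.random.default_rng(seed)
    n = 5
    ref = rng.normal(size=(n, 3)) * 3
    rot = Rotation.random(rng=rng).as_matrix()
    mob = ref @ rot.T + rng.normal(size=(n, 3)) * 0.3 + rng.normal(size=3)

    from grooveqsar.structures import Atom, ComplexStructure

    def as_cs(coords, cid):
        atoms = [
            Atom(element="P", name="P", coords=c, chain="A", res_name="DA", res_seq=i + 1)
            for i, c in enumerate(coords)
        ]
        lig = [Atom(element="C", name="C1", coords=coords.mean(axis=0),
                    is_ligand=True, res_name="LIG")]
        return ComplexStructure(cid, atoms, lig)

    sup = superpose_backbone(as_cs(mob, "m"), as_cs(ref, "r"))
    oracle = _quaternion_bruteforce_rmsd(mob, ref)
    assert sup.rmsd == pytest.approx(oracle, abs=1e-6)


def test_rmsd_invariant_under_common_rigid_motion():
    ref = _reference_complex()
    rng = np.random.default_rng(4)
    rot0 = Rotation.random(rng=rng).as_matrix()
    mobile = _transformed(ref, rot0, rng.normal(size=3))
    base = superpose_backbone(mobile, ref).rmsd
    common = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(size=3)
    rmsd2 = superpose_backbone(
        _transformed(mobile, common, shift), _transformed(ref, common, shift)
    ).rmsd
    assert rmsd2 == pytest.approx(base, abs=1e-9)


def test_collinear_backbone_is_degenerate_error():
    from grooveqsar.structures import Atom, ComplexStructure

    def line_cs(cid):
        atoms = [
            Atom(element="P", name="P", coords=[float(i), 0.0, 0.0],
                 chain="A", res_name="DA", res_seq=i + 1)
            for i in range(4)
        ]
        lig = [Atom(element="C", name="C1", coords=[0, 1, 0], is_ligand=True, res_name="LIG")]
        return ComplexStructure(cid, atoms, lig)

    with pytest.raises(StructureError, match="collinear"):
        superpose_backbone(line_cs("a"), line_cs("b"))


def test_too_few_matches_raise(three_atom_pdb):
    cs = read_complex(three_atom_pdb, {"LIG"})
    with pytest.raises(StructureError, match=">=3"):
        superpose_backbone(cs, cs, backbone_names=DNA_BACKBONE_ATOMS)


def test_synthetic_receptor_has_backbone_per_nucleotide():
    records, _ = make_synthetic_complexes(n=5, noise_sd=0.0, seed=3)
    cs = records[0].structure
    per_res = {}
    for a in cs.receptor_atoms:
        per_res.setdefault((a.chain, a.res_seq), set()).add(a.name)
    assert len(per_res) == 20  # two strands x 10 nucleotides
    for names in per_res.values():
        assert names >= DNA_BACKBONE_ATOMS
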