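"""Reading, writing, splitting and superposing ligand/DNA complexes.

A *complex* is a DNA duplex (the receptor, or "lock") plus a bound small
molecule (the ligand, or "key"), both in the same Cartesian frame.  All
downstream field and QSAR computations assume every complex in a dataset
has been rigidly superposed onto a common reference via the DNA backbone,
which this module performs with a least-squares (Kabsch) fit.

Coordinates are in Angstrom throughout.  Partial charges are read, by
default, from the PDB occupancy column (PQR-style convention), because the
standard PDB format has no field for fractional charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "ComplexStructure",
    "ComplexRecord",
    "SuperpositionResult",
    "StructureError",
    "FormatError",
    "DNA_BACKBONE_ATOMS",
    "read_complex",
    "write_complex",
    "split_lock_key",
    "merge_lock_key",
    "superpose_backbone",
    "apply_superposition",
    "align_dataset",
    "prepare_structure",
    "read_manifest",
    "write_manifest",
]

#: Standard nucleic-acid sugar-phosphate backbone atom names, one set per
#: nucleotide.  Used for superposition unless the caller overrides it.
DNA_BACKBONE_ATOMS = frozenset({"P", "O5'", "C5'", "C4'", "C3'", "O3'"})

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Invalid structure content (empty selections, bad matches, ...)."""


class FormatError(StructureError):
    """Unparseable structure file content."""


@dataclass
class Atom:
    """A single atom: element, name, position and partial charge."""

    element: str
    name: str
    coords: np.ndarray
    partial_charge: float = 0.0
    is_ligand: bool = False
    chain: str = "A"
    res_name: str = "UNK"
    res_seq: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not math.isfinite(self.partial_charge):
            raise StructureError(f"atom {self.name!r}: partial charge must be finite")
        el = gemmi.Element(self.element)
        if el.atomic_number == 0:
            raise StructureError(f"unrecognized element symbol {self.element!r}")
        self.element = el.name


@dataclass
class ComplexStructure:
    """A ligand/DNA complex partitioned into receptor and ligand atoms."""

    complex_id: str
    receptor_atoms: list[Atom]
    ligand_atoms: list[Atom]
    source: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.receptor_atoms) + len(self.ligand_atoms)

    @property
    def all_atoms(self) -> list[Atom]:
        return list(self.receptor_atoms) + list(self.ligand_atoms)

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms], dtype=float)

    def receptor_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.receptor_atoms], dtype=float)

    def ligand_charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.ligand_atoms], dtype=float)

    def ligand_elements(self) -> list[str]:
        return [a.element for a in self.ligand_atoms]


@dataclass
class ComplexRecord:
    """A complex with its measured dissociation constant.

    ``kd`` is in mol/L; ``pkd`` is -log10(kd).  The same ``ligand_id`` may
    appear in several records (one ligand crystallized with different
    duplexes), which is why train/test splitting is grouped by ligand.
    """

    structure: ComplexStructure
    kd: float
    ligand_id: str

    def __post_init__(self) -> None:
        if not (self.kd > 0 and math.isfinite(self.kd)):
            raise StructureError(f"record {self.structure.complex_id}: kd must be positive and finite")

    @property
    def pkd(self) -> float:
        return -math.log10(self.kd)


@dataclass
class SuperpositionResult:
    """Rigid transform mapping a mobile structure onto a reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def _validate_coordinate_fields(text: str) -> None:
    # gemmi is lenient about malformed numeric fields; enforce the format
    # contract ourselves so errors carry the offending line number.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise FormatError(f"line {lineno}: truncated coordinate record")
        for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fld = line[lo:hi]
            try:
                float(fld)
            except ValueError:
                raise FormatError(
                    f"line {lineno}: unparseable {label} coordinate field {fld.strip()!r}"
                ) from None


def read_complex(
    text: str,
    ligand_selector: Iterable[str],
    complex_id: str = "",
    source: str = "",
    charge_from: str | None = "occupancy",
) -> ComplexStructure:
    """Parse PDB-format ``text`` into a receptor/ligand complex.

    Atoms whose residue name is in ``ligand_selector`` become ligand atoms;
    everything else (waters excluded) is receptor.  Alternate locations other
    than blank or 'A' are dropped.  ``charge_from="occupancy"`` reads partial
    charges from the occupancy column; ``None`` leaves charges at zero.
    """
    selector = {s.strip().upper() for s in ligand_selector}
    if not selector:
        raise ValueError("ligand_selector must be non-empty")
    if charge_from not in (None, "occupancy"):
        raise ValueError(f"unknown charge_from={charge_from!r}")
    _validate_coordinate_fields(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise FormatError(f"PDB parse failure: {exc}") from exc
    receptor: list[Atom] = []
    ligand: list[Atom] = []
    if len(st) == 0:
        raise FormatError("no ATOM/HETATM records found")
    model = st[0]
    for chain in model:
        for res in chain:
            res_name = res.name.strip().upper()
            if res_name in _WATER_NAMES:
                continue
            is_lig = res_name in selector
            for at in res:
                if at.altloc not in ("\0", "", "A"):
                    continue
                atom = Atom(
                    element=at.element.name,
                    name=at.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    partial_charge=at.occ if charge_from == "occupancy" else 0.0,
                    is_ligand=is_lig,
                    chain=chain.name,
                    res_name=res.name,
                    res_seq=res.seqid.num,
                )
                (ligand if is_lig else receptor).append(atom)
    if not ligand:
        raise StructureError(
            f"empty ligand: no atoms matched residue names {sorted(selector)}"
        )
    return ComplexStructure(
        complex_id=complex_id or source or "complex",
        receptor_atoms=receptor,
        ligand_atoms=ligand,
        source=source,
    )


def write_complex(cs: ComplexStructure, charge_to: str | None = "occupancy") -> str:
    """Serialize a complex back to PDB text (ligand atoms as HETATM).

    The occupancy column carries the partial charge when
    ``charge_to="occupancy"`` so that a read/write round trip preserves it.
    """
    st = gemmi.Structure()
    st.name = cs.complex_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for atom in cs.all_atoms:
        key = atom.chain
        if key not in chains:
            chains[key] = gemmi.Chain(key)
        chain = chains[key]
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if last.seqid.num == atom.res_seq and last.name == atom.res_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = atom.res_name
            res.seqid = gemmi.SeqId(atom.res_seq, " ")
            res.het_flag = "H" if atom.is_ligand else "A"
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        ga = gemmi.Atom()
        ga.name = atom.name
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(*atom.coords)
        ga.occ = atom.partial_charge if charge_to == "occupancy" else 1.0
        ga.b_iso = 0.0
        res.add_atom(ga)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def split_lock_key(cs: ComplexStructure) -> tuple[ComplexStructure, ComplexStructure]:
    """Split into receptor-only ("lock") and ligand-only ("key") structures.

    Coordinates are untouched so both parts stay in the complex's frame.
    """
    if not cs.ligand_atoms:
        raise StructureError(f"empty ligand in complex {cs.complex_id}")
    if not cs.receptor_atoms:
        raise StructureError(f"empty receptor in complex {cs.complex_id}")
    lock = ComplexStructure(
        complex_id=cs.complex_id + "_lock",
        receptor_atoms=list(cs.receptor_atoms),
        ligand_atoms=[],
        source=cs.source,
    )
    key = ComplexStructure(
        complex_id=cs.complex_id + "_key",
        receptor_atoms=[],
        ligand_atoms=list(cs.ligand_atoms),
        source=cs.source,
    )
    return lock, key


def merge_lock_key(lock: ComplexStructure, key: ComplexStructure, complex_id: str | None = None) -> ComplexStructure:
    """Inverse of :func:`split_lock_key`."""
    return ComplexStructure(
        complex_id=complex_id or lock.complex_id.removesuffix("_lock"),
        receptor_atoms=list(lock.receptor_atoms),
        ligand_atoms=list(key.ligand_atoms),
        source=lock.source,
    )


def _backbone_map(cs: ComplexStructure, backbone_names: frozenset[str]) -> dict[tuple[str, int, str], np.ndarray]:
    out = {}
    for a in cs.receptor_atoms:
        if a.name in backbone_names:
            out[(a.chain, a.res_seq, a.name)] = a.coords
    return out


def superpose_backbone(
    mobile: ComplexStructure,
    reference: ComplexStructure,
    backbone_names: Iterable[str] = DNA_BACKBONE_ATOMS,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Backbone atoms are matched by (chain, residue number, atom name); the
    optimal proper rotation is the Kabsch solution (reflections rejected).
    Returns the transform and the RMSD over matched atoms after applying it.
    """
    names = frozenset(backbone_names)
    ref_map = _backbone_map(reference, names)
    mob_map = _backbone_map(mobile, names)
    keys = sorted(set(ref_map) & set(mob_map))
    if len(keys) < 3:
        raise StructureError(
            f"superposition needs >=3 matched backbone atoms, found {len(keys)}"
        )
    ref = np.array([ref_map[k] for k in keys])
    mob = np.array([mob_map[k] for k in keys])
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    # Collinear (or coincident) point sets leave the rotation under-determined.
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise StructureError("degenerate superposition: matched backbone atoms are collinear")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    translation = ref.mean(axis=0) - matrix @ mob.mean(axis=0)
    rmsd = float(rssd) / math.sqrt(len(keys))
    return SuperpositionResult(rotation=matrix, translation=translation, rmsd=rmsd)


def apply_superposition(cs: ComplexStructure, sup: SuperpositionResult) -> ComplexStructure:
    """Apply a rigid transform to every atom (receptor and ligand alike)."""
    def moved(atoms: list[Atom]) -> list[Atom]:
        return [replace(a, coords=sup.transform(a.coords)) for a in atoms]

    return ComplexStructure(
        complex_id=cs.complex_id,
        receptor_atoms=moved(cs.receptor_atoms),
        ligand_atoms=moved(cs.ligand_atoms),
        source=cs.source,
    )


def align_dataset(
    structures: Sequence[ComplexStructure],
    reference_id: str | None = None,
    backbone_names: Iterable[str] = DNA_BACKBONE_ATOMS,
) -> tuple[list[ComplexStructure], list[float]]:
    """Superpose every complex onto a common reference frame.

    The reference is the first structure in dataset order unless
    ``reference_id`` names another one.  Returns the aligned structures (the
    reference itself is returned untouched) and the per-complex backbone RMSD.
    """
    if not structures:
        raise StructureError("empty dataset")
    ref = structures[0]
    if reference_id is not None:
        matches = [s for s in structures if s.complex_id == reference_id]
        if not matches:
            raise StructureError(f"reference complex {reference_id!r} not in dataset")
        ref = matches[0]
    aligned, rmsds = [], []
    for s in structures:
        if s is ref:
            aligned.append(s)
            rmsds.append(0.0)
            continue
        sup = superpose_backbone(s, ref, backbone_names)
        aligned.append(apply_superposition(s, sup))
        rmsds.append(sup.rmsd)
    return aligned, rmsds


def prepare_structure(
    cs: ComplexStructure,
    minimizer: Callable[[ComplexStructure], ComplexStructure] | None = None,
) -> ComplexStructure:
    """Preparation hook (protonation / minimization plug-in point).

    The pipeline assumes inputs are already prepared; by default this is the
    identity.  A force-field minimizer can be supplied by the caller.
    """
    return minimizer(cs) if minimizer is not None else cs


MANIFEST_COLUMNS = ["complex_id", "pdb_id", "ligand_id", "kd_molar"]


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV (complex_id, pdb_id, ligand_id, kd_molar)."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if (df["kd_molar"] <= 0).any():
        raise ValueError("manifest contains non-positive kd_molar values")
    return df[MANIFEST_COLUMNS]


def write_manifest(records: Sequence[ComplexRecord], path) -> None:
    rows = [
        {
            "complex_id": r.structure.complex_id,
            "pdb_id": r.structure.source,
            "ligand_id": r.ligand_id,
            "kd_molar": f"{r.kd:.6e}",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_ligand_sdf(text: str) -> list[Atom]:
    """Read a standalone ligand from an SDF/MOL block.

    Partial charges are taken from a per-atom ``PartialCharge`` property when
    present, otherwise left at zero.  Requires rdkit.
    """
    from rdkit import Chem

    mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise FormatError("unparseable SDF/MOL block")
    conf = mol.GetConformer()
    atoms = []
    for rd_atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(rd_atom.GetIdx())
        charge = 0.0
        if rd_atom.HasProp("PartialCharge"):
            charge = float(rd_atom.GetProp("PartialCharge"))
        atoms.append(
            Atom(
                element=rd_atom.GetSymbol(),
                name=f"{rd_atom.GetSymbol()}{rd_atom.GetIdx() + 1}",
                coords=np.array([pos.x, pos.y, pos.z]),
                partial_charge=charge,
                is_ligand=True,
                res_name="LIG",
            )
        )
    if not atoms:
        raise StructureError("empty ligand in SDF block")
    return atoms
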