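"""Synthetic study inputs with the statistical structure the pipeline assumes.

The real study rests on 27 ligand/DNA-decamer crystal complexes with
published dissociation constants, docked pose sets, and photoluminescence
titrations.  None of those can ship with the package, so this module
generates stand-ins:

* toy ligand/duplex complexes in a shared aligned frame whose pK_D values
  are an exact linear function of their field descriptors plus Gaussian
  noise, spanning pK_D 5-9 (bracketing the 6.5-7.6 window typical of
  tight minor-groove binders);
* pose sets displaced from a reference by exactly known RMSDs;
* tight-binding titration panels at 10 uM ligand, dsDNA 0-10 uM.

Every generator is a pure function of its parameters and seed.  Toy
ligands are point-atom sets (C/N/O with fractional charges); no bond
topology is needed because fields and PLS consume only coordinates and
charges.  The duplex stand-in is a crude two-strand helix carrying the
standard backbone atom names so superposition and lock/key splitting run
unmodified on the fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .assays import TitrationSeries, simulate_titration
from .fields import GridSpec, ProbeParams, compute_probe_energies
from .poses import Pose
from .structures import (
    Atom,
    ComplexRecord,
    ComplexStructure,
    write_complex,
    write_manifest,
)

__all__ = [
    "SyntheticTruth",
    "default_grid",
    "make_decamer_receptor",
    "make_synthetic_complexes",
    "make_pose_set",
    "make_titration_panel",
    "write_dataset",
]

LIGAND_RESNAME = "LIG"

#: Backbone atoms laid down per synthetic nucleotide.
_BACKBONE = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic complex dataset.

    ``coefficients`` (over all grid columns, steric block then
    electrostatic block) and ``intercept`` give the noiseless pK_D of any
    ligand's full field row; ``noise_sd`` is the Gaussian sd added on top.
    """

    coefficients: np.ndarray
    intercept: float
    noise_sd: float
    seed: int
    pkd_range: tuple[float, float]
    noiseless_pkd_values: np.ndarray

    def noiseless_pkd(self, full_row: np.ndarray) -> float:
        full_row = np.asarray(full_row, dtype=float)
        if full_row.shape != self.coefficients.shape:
            raise ValueError("field row does not match the truth's grid layout")
        return float(self.intercept + full_row @ self.coefficients)


def default_grid() -> GridSpec:
    """The shared grid the synthetic frame lives in: 11 A box, 2 A steps."""
    return GridSpec(origin=(-5.0, -5.0, -5.0), spacing=2.0, dims=(6, 6, 6))


def make_decamer_receptor(rise: float = 3.4, radius: float = 9.0) -> list[Atom]:
    """A deterministic two-strand, 10-residue helical backbone stand-in.

    Geometry is a crude B-form caricature (10.5 residues/turn, 3.4 A
    rise) placed so it wraps around the ligand box without entering it.
    Only backbone atoms are laid down -- all the alignment machinery needs.
    """
    atoms: list[Atom] = []
    twist = 2 * math.pi / 10.5
    for chain, (phase, direction) in (("A", (0.0, 1)), ("B", (2.1, -1))):
        for res in range(1, 11):
            theta = phase + direction * twist * res
            z = direction * (res - 5.5) * rise
            base = np.array([radius * math.cos(theta), radius * math.sin(theta), z])
            for k, name in enumerate(_BACKBONE):
                # spread the six backbone atoms along the strand direction
                offs = np.array(
                    [0.4 * math.cos(theta + 0.3 * k), 0.4 * math.sin(theta + 0.3 * k),
                     direction * 0.45 * k]
                )
                atoms.append(
                    Atom(
                        element="P" if name == "P" else name[0],
                        name=name,
                        coords=base + offs,
                        partial_charge=0.0,
                        is_ligand=False,
                        chain=chain,
                        res_name="DA",
                        res_seq=res,
                    )
                )
    return atoms


def _scaffold_sites(
    rng: np.random.Generator, grid: GridSpec, n_sites: int
) -> tuple[np.ndarray, np.ndarray]:
    """Shared substitution-site geometry for a congeneric toy series.

    Real field-based QSAR datasets are congeneric: every ligand is the same
    aligned scaffold decorated differently.  Mirroring that keeps the
    descriptor rows on a low-dimensional manifold (fields are additive per
    atom), which is what makes a linear latent-variable model predictive
    across held-out analogs.  Sites sit on cell centers of a
    double-spacing sublattice: maximally far from grid nodes and >= 2
    cells apart, so no single probe energy saturates the caps and the
    additivity is exact.
    """
    axes = []
    for a in range(3):
        n_cells = grid.dims[a] - 1
        idx = np.arange(0, n_cells, 2)
        if idx.size == 0:
            raise ValueError("grid too small for atom placement")
        axes.append(grid.origin[a] + grid.spacing * (idx + 0.5))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    candidates = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if candidates.shape[0] < n_sites:
        raise ValueError(
            f"grid too small for atom placement: {candidates.shape[0]} candidate "
            f"sites < {n_sites} requested"
        )
    pick = rng.choice(candidates.shape[0], size=n_sites, replace=False)
    elements = rng.choice(["C", "N", "O"], size=n_sites)
    return candidates[np.sort(pick)], elements


def _toy_ligand(
    rng: np.random.Generator,
    site_coords: np.ndarray,
    site_elements: np.ndarray,
    min_atoms: int,
    occupancy_p: float = 0.75,
    charge_scale: float = 0.2,
) -> list[Atom]:
    n_sites = site_coords.shape[0]
    mask = rng.random(n_sites) < occupancy_p
    while mask.sum() < min_atoms:
        mask = rng.random(n_sites) < occupancy_p
    charges = rng.uniform(-charge_scale, charge_scale, size=n_sites)
    return [
        Atom(
            element=str(site_elements[i]),
            name=f"{site_elements[i]}{i + 1}",
            coords=site_coords[i],
            partial_charge=float(charges[i]),
            is_ligand=True,
            chain="X",
            res_name=LIGAND_RESNAME,
            res_seq=1,
        )
        for i in range(n_sites)
        if mask[i]
    ]


def make_synthetic_complexes(
    n: int = 27,
    grid: GridSpec | None = None,
    n_informative_columns: int = 8,
    noise_sd: float = 0.15,
    seed: int = 0,
    pkd_range: tuple[float, float] = (5.0, 9.0),
    atom_range: tuple[int, int] = (3, 9),
    params: ProbeParams = ProbeParams(),
) -> tuple[list[ComplexRecord], SyntheticTruth]:
    """Generate ``n`` aligned toy complexes with linear field->pK_D truth.

    The ligands form a congeneric series: a shared scaffold of
    ``atom_range[1]`` substitution sites, of which each analog occupies a
    random subset (at least ``atom_range[0]``) with its own partial
    charges.  pK_D is drawn as ``w . x + eps`` with
    ``eps ~ N(0, noise_sd^2)``, after an affine rescaling of ``w . x`` so
    the noiseless values span exactly ``pkd_range``.  Records carry
    ``kd = 10^-pkd``.  Reproducible for a fixed seed.
    """
    if n < 5:
        raise ValueError("need at least 5 synthetic complexes")
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    receptor = make_decamer_receptor()
    site_coords, site_elements = _scaffold_sites(rng, grid, atom_range[1])
    structures = []
    rows = []
    for i in range(n):
        lig = _toy_ligand(rng, site_coords, site_elements, atom_range[0])
        cs = ComplexStructure(
            complex_id=f"SYN{i + 1:03d}",
            receptor_atoms=list(receptor),
            ligand_atoms=lig,
            source=f"synthetic:{seed}",
        )
        structures.append(cs)
        rows.append(compute_probe_energies(cs, grid, params).row())
    X = np.vstack(rows)

    variable = np.flatnonzero(X.std(axis=0) > 1e-9)
    if variable.size < n_informative_columns:
        raise ValueError("grid too coarse: not enough variable columns for the truth")
    chosen = rng.choice(variable, size=n_informative_columns, replace=False)
    w = np.zeros(X.shape[1])
    w[chosen] = rng.normal(0.0, 1.0, size=n_informative_columns)
    raw = X @ w
    span = raw.max() - raw.min()
    if span < 1e-12:
        raise ValueError("degenerate truth: field signal has no spread across ligands")
    scale = (pkd_range[1] - pkd_range[0]) / span
    intercept = pkd_range[0] - scale * raw.min()
    coefficients = scale * w
    pkd0 = intercept + X @ coefficients
    pkd = pkd0 + rng.normal(0.0, noise_sd, size=n)

    records = [
        ComplexRecord(structure=cs, kd=10.0 ** (-p), ligand_id=f"L{i + 1:03d}")
        for i, (cs, p) in enumerate(zip(structures, pkd))
    ]
    truth = SyntheticTruth(
        coefficients=coefficients,
        intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
        pkd_range=pkd_range,
        noiseless_pkd_values=pkd0,
    )
    return records, truth


def make_pose_set(reference: Pose, target_rmsds, seed: int = 0) -> list[Pose]:
    """Poses rigidly translated from ``reference`` to exact target RMSDs.

    A uniform translation of magnitude d changes every atom's position by
    d, so the naive (and symmetry-corrected) RMSD equals d exactly.  The
    translation direction is drawn uniformly on the sphere per pose.
    """
    rng = np.random.default_rng(seed)
    poses = []
    for j, d in enumerate(target_rmsds):
        if d < 0:
            raise ValueError("target RMSD must be non-negative")
        if d == 0:
            shift = np.zeros(3)
        else:
            v = rng.standard_normal(3)
            shift = d * v / np.linalg.norm(v)
        atoms = [
            Atom(
                element=a.element,
                name=a.name,
                coords=a.coords + shift,
                partial_charge=a.partial_charge,
                is_ligand=True,
                chain=a.chain,
                res_name=a.res_name,
                res_seq=a.res_seq,
            )
            for a in reference.ligand_atoms
        ]
        poses.append(
            Pose(
                pose_id=f"{reference.pose_id}_d{j + 1}",
                ligand_atoms=atoms,
                engine=reference.engine,
                engine_score=float("nan"),
            )
        )
    return poses


def make_titration_panel(
    kds,
    seed: int = 0,
    ligand_total: float = 10e-6,
    dna_max: float = 10e-6,
    dna_step: float = 0.5e-6,
    fmax: float = 100.0,
    f0: float = 2.0,
    noise_cv: float = 0.02,
) -> list[TitrationSeries]:
    """Titration series mirroring the reference experiment's conditions.

    Defaults: ligand held at 10 uM, dsDNA stepped 0 -> 10 uM in 0.5 uM
    aliquots, 2% multiplicative intensity noise.  One series per Kd, each
    with its own derived seed so panels of different sizes stay
    reproducible element-wise.
    """
    kds = np.atleast_1d(np.asarray(kds, dtype=float))
    if np.any(kds <= 0):
        raise ValueError("all kds must be positive")
    n_steps = int(round(dna_max / dna_step))
    dna = np.arange(n_steps + 1) * dna_step  # exact endpoint, no float drift
    return [
        simulate_titration(
            ligand_total, dna, kd, fmax=fmax, f0=f0, noise_cv=noise_cv,
            seed=(seed * 1000 + i) % (2**31),
        )
        for i, kd in enumerate(kds)
    ]


def write_dataset(records, outdir) -> Path:
    """Write complexes as PDB files plus a manifest CSV; returns the dir.

    The files round-trip through the package's own readers, so generated
    fixtures exercise the real parsers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        (outdir / f"{rec.structure.complex_id}.pdb").write_text(
            write_complex(rec.structure)
        )
    write_manifest(records, outdir / "manifest.csv")
    return outdir
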