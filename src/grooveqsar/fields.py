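"""CoMFA-style molecular interaction fields on a shared rectangular grid.

Each aligned ligand is probed at every grid point with an sp3-carbon probe
bearing +1 e charge.  Two energies are recorded per point: a steric
Lennard-Jones 6-12 term and a Coulomb electrostatic term, both in kcal/mol
and clamped to +/- a cap so that points buried in an atom do not dominate
the regression.  Stacking the per-ligand fields row-wise and removing
near-constant columns yields the descriptor matrix for the PLS model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structures import ComplexRecord, ComplexStructure

__all__ = [
    "GridSpec",
    "ProbeParams",
    "FieldGrid",
    "DescriptorMatrix",
    "COULOMB_CONSTANT",
    "LJ_PARAMS",
    "compute_probe_energies",
    "assemble_descriptor_matrix",
    "export_dx",
]

#: Coulomb conversion constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.06

#: Per-element Lennard-Jones parameters: (vdW radius r_min/2 in A, well
#: depth epsilon in kcal/mol).  AMBER-like generic values; configurable by
#: passing an ``lj_params`` mapping to :func:`compute_probe_energies`.
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.0157),
    "C": (1.70, 0.1094),
    "N": (1.55, 0.0740),
    "O": (1.52, 0.0600),
    "F": (1.47, 0.0610),
    "P": (1.80, 0.2000),
    "S": (1.80, 0.2500),
    "CL": (1.75, 0.2650),
    "BR": (1.85, 0.3200),
    "I": (1.98, 0.4000),
}


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular grid: origin corner, spacing, point counts."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """Grid point coordinates, shape (n_points, 3), x fastest-varying."""
        nx, ny, nz = self.dims
        o = np.asarray(self.origin)
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        idx = np.stack([ix.ravel(order="F"), iy.ravel(order="F"), iz.ravel(order="F")], axis=1)
        return o + self.spacing * idx

    def max_corner(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (np.asarray(self.dims) - 1)

    def encloses(self, coords: np.ndarray) -> bool:
        coords = np.atleast_2d(coords)
        lo = np.asarray(self.origin)
        hi = self.max_corner()
        return bool(np.all(coords >= lo) and np.all(coords <= hi))

    @classmethod
    def from_coords(cls, coords: np.ndarray, spacing: float = 2.0, padding: float = 4.0) -> "GridSpec":
        """Smallest grid enclosing ``coords`` plus ``padding`` on every side."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        lo = coords.min(axis=0) - padding
        hi = coords.max(axis=0) + padding
        dims = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(origin=tuple(lo), spacing=spacing, dims=dims)

    @classmethod
    def from_structures(
        cls, structures: Sequence[ComplexStructure], spacing: float = 2.0, padding: float = 4.0
    ) -> "GridSpec":
        coords = np.vstack([s.ligand_coords() for s in structures])
        return cls.from_coords(coords, spacing=spacing, padding=padding)


@dataclass(frozen=True)
class ProbeParams:
    """Probe atom and field-evaluation settings.

    Defaults follow classical CoMFA practice: sp3-carbon probe (r_min 1.7 A,
    well depth 0.107 kcal/mol) with +1 e charge, energies capped at
    +/-30 kcal/mol, distance-dependent dielectric eps(r) = r.
    """

    charge: float = 1.0
    r_min: float = 1.7
    epsilon: float = 0.107
    steric_cap: float = 30.0
    elec_cap: float = 30.0
    dielectric: str = "distance"  # "distance" -> eps(r)=r; "constant" -> fixed
    dielectric_constant: float = 1.0

    def __post_init__(self):
        if self.dielectric not in ("distance", "constant"):
            raise ValueError("dielectric must be 'distance' or 'constant'")
        if self.steric_cap <= 0 or self.elec_cap <= 0:
            raise ValueError("energy caps must be positive")


@dataclass
class FieldGrid:
    """Steric and electrostatic probe energies for one ligand on a grid."""

    grid: GridSpec
    steric: np.ndarray
    electrostatic: np.ndarray

    def row(self) -> np.ndarray:
        """Concatenated (steric, electrostatic) descriptor row."""
        return np.concatenate([self.steric, self.electrostatic])


def _ligand_arrays(ligand) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(ligand, ComplexStructure):
        return ligand.ligand_coords(), ligand.ligand_charges(), ligand.ligand_elements()
    atoms = list(ligand)
    coords = np.array([a.coords for a in atoms], dtype=float)
    charges = np.array([a.partial_charge for a in atoms], dtype=float)
    elements = [a.element for a in atoms]
    return coords, charges, elements


def compute_probe_energies(
    ligand,
    grid: GridSpec,
    params: ProbeParams = ProbeParams(),
    lj_params: dict[str, tuple[float, float]] | None = None,
) -> FieldGrid:
    """Evaluate steric and electrostatic probe energies at every grid point.

    ``ligand`` may be a :class:`ComplexStructure` (its ligand atoms are used)
    or an iterable of :class:`~grooveqsar.structures.Atom`.

    Electrostatic: ``E(p) = sum_i k q_probe q_i / (eps(r_i) r_i)`` with
    ``k = 332.06 kcal*A/(mol*e^2)``.  Steric: Lennard-Jones 6-12 with
    ``r_min,ij = r_min,probe + r_vdw,i`` and ``eps_ij = sqrt(eps_probe eps_i)``.
    Both are clamped to the caps; a point inside an atom core saturates the
    steric term at +cap.
    """
    table = lj_params if lj_params is not None else LJ_PARAMS
    coords, charges, elements = _ligand_arrays(ligand)
    if coords.size == 0:
        raise ValueError("ligand has no atoms")
    try:
        lj = np.array([table[e.upper()] for e in elements], dtype=float)
    except KeyError as exc:
        raise KeyError(f"no Lennard-Jones parameters for element {exc.args[0]!r}") from None
    if not grid.encloses(coords):
        warnings.warn(
            "grid does not enclose all ligand atoms; field values near the "
            "boundary may truncate the molecule",
            stacklevel=2,
        )
    points = grid.points()
    d = cdist(points, coords)
    d = np.maximum(d, 1e-6)  # guard exact overlap; clamped to +cap anyway

    if params.dielectric == "distance":
        elec = COULOMB_CONSTANT * params.charge * charges / (d * d)
    else:
        elec = COULOMB_CONSTANT * params.charge * charges / (params.dielectric_constant * d)
    elec = np.clip(elec.sum(axis=1), -params.elec_cap, params.elec_cap)

    r_min_ij = params.r_min + lj[:, 0]
    eps_ij = np.sqrt(params.epsilon * lj[:, 1])
    s6 = (r_min_ij / d) ** 6
    steric = np.clip((eps_ij * (s6 * s6 - 2.0 * s6)).sum(axis=1), -params.steric_cap, params.steric_cap)
    return FieldGrid(grid=grid, steric=steric, electrostatic=elec)


@dataclass
class DescriptorMatrix:
    """Stacked, variance-filtered field descriptors for a dataset.

    ``X_full`` holds every column (2 * n_points: steric block then
    electrostatic block); ``kept_mask`` marks columns whose standard
    deviation is at least ``min_sigma``.  ``X`` is the filtered view the
    PLS model consumes.  Column metadata maps each column back to its grid
    point and probe type for field inspection.
    """

    grid: GridSpec
    X_full: np.ndarray
    kept_mask: np.ndarray
    min_sigma: float
    params: ProbeParams
    record_ids: list[str] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return self.X_full[:, self.kept_mask]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def column_probe_types(self) -> np.ndarray:
        n = self.grid.n_points
        return np.array(["steric"] * n + ["electrostatic"] * n)

    def column_point_indices(self) -> np.ndarray:
        n = self.grid.n_points
        return np.concatenate([np.arange(n), np.arange(n)])

    def row_for(self, ligand, lj_params=None) -> np.ndarray:
        """Full (unfiltered) descriptor row for a new ligand on this grid."""
        return compute_probe_energies(ligand, self.grid, self.params, lj_params).row()

    def filter_row(self, full_row: np.ndarray) -> np.ndarray:
        full_row = np.asarray(full_row, dtype=float)
        if full_row.shape != (self.X_full.shape[1],):
            raise ValueError(
                f"row length {full_row.shape} does not match descriptor layout "
                f"({self.X_full.shape[1]} columns)"
            )
        return full_row[self.kept_mask]

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        probes = self.column_probe_types()[self.kept_mask]
        pts = self.column_point_indices()[self.kept_mask]
        cols = [f"{p[0]}{i}" for p, i in zip(probes, pts)]
        return pd.DataFrame(self.X, index=self.record_ids or None, columns=cols)


def assemble_descriptor_matrix(
    dataset: Sequence[ComplexRecord],
    grid: GridSpec,
    params: ProbeParams = ProbeParams(),
    min_sigma: float = 0.05,
    lj_params: dict[str, tuple[float, float]] | None = None,
) -> DescriptorMatrix:
    """Stack per-record field rows and drop columns with std < ``min_sigma``.

    All records must already share the aligned frame; the grid is fixed
    across the dataset.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rows = [
        compute_probe_energies(rec.structure, grid, params, lj_params).row()
        for rec in dataset
    ]
    X_full = np.vstack(rows)
    std = X_full.std(axis=0, ddof=0)
    kept = std >= min_sigma
    return DescriptorMatrix(
        grid=grid,
        X_full=X_full,
        kept_mask=kept,
        min_sigma=min_sigma,
        params=params,
        record_ids=[rec.structure.complex_id for rec in dataset],
    )


def export_dx(fg: FieldGrid, which: str, path) -> None:
    """Write one field as an OpenDX scalar grid for visual inspection."""
    values = {"steric": fg.steric, "electrostatic": fg.electrostatic}[which]
    nx, ny, nz = fg.grid.dims
    sp = fg.grid.spacing
    # OpenDX expects z fastest-varying; our layout is x fastest.
    cube = values.reshape((nx, ny, nz), order="F").ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.4f} {:.4f} {:.4f}\n".format(*fg.grid.origin))
        fh.write(f"delta {sp:.4f} 0 0\ndelta 0 {sp:.4f} 0\ndelta 0 0 {sp:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} data follows\n"
        )
        for i in range(0, cube.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in cube[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')
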