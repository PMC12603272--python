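"""Docked-pose evaluation and QSAR rescoring.

Poses come from external docking engines (e.g. Smina/Vinardo or
PLANTS/ChemPLP); this module consumes them.  Pose quality is measured as a
symmetry-corrected RMSD against the crystallographic ligand: within each
chemical element class the atom correspondence minimizing the sum of
squared distances is found by optimal assignment, with no rigid refit
(docking convention -- both poses live in the fixed receptor frame).
Redocking accuracy is the fraction of poses within an RMSD threshold
(default 2.0 A, the field-standard success criterion).

Rescoring pushes a pose through the same field grid the QSAR models were
trained on and averages the per-model predicted pK_D, the pipeline's
"external scoring function" replacing the docking engine's native score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr, spearmanr

from .fields import GridSpec, ProbeParams, compute_probe_energies
from .qsar import PLSModel, predict
from .structures import Atom, read_complex

__all__ = [
    "Pose",
    "PoseEvaluation",
    "RescoringResult",
    "symmetry_rmsd",
    "naive_rmsd",
    "docking_accuracy",
    "score_affinity_correlation",
    "rescore_pose",
    "rescore_poses",
    "pkd_to_kd",
    "kd_to_pkd",
    "read_poses_pdb",
]


@dataclass
class Pose:
    """A docked ligand conformation in the receptor frame."""

    pose_id: str
    ligand_atoms: list[Atom]
    engine: str = ""
    engine_score: float = float("nan")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.ligand_atoms]


@dataclass
class PoseEvaluation:
    rmsd: float
    matched_permutation: np.ndarray  # pose atom i matched to reference atom perm[i]


@dataclass
class RescoringResult:
    per_model_pkd: dict[str, float]
    mean_pkd: float
    kd_nM: float


def naive_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def symmetry_rmsd(
    pose: Pose, reference_coords: np.ndarray, reference_elements: Sequence[str]
) -> PoseEvaluation:
    """Symmetry-corrected RMSD of a pose against the reference ligand.

    Minimizes RMSD over atom correspondences that preserve the element, via
    the Hungarian assignment within each element class on squared
    distances.  No rigid transform is refit.
    """
    coords = pose.coords()
    ref = np.asarray(reference_coords, dtype=float)
    elements = [e.upper() for e in pose.elements()]
    ref_el = [e.upper() for e in reference_elements]
    if coords.shape != ref.shape:
        raise ValueError(
            f"atom count mismatch: pose has {coords.shape[0]}, reference {ref.shape[0]}"
        )
    if sorted(elements) != sorted(ref_el):
        raise ValueError("element multisets of pose and reference differ")
    n = coords.shape[0]
    perm = np.empty(n, dtype=int)
    total = 0.0
    for el in set(elements):
        pi = np.flatnonzero([e == el for e in elements])
        ri = np.flatnonzero([e == el for e in ref_el])
        d2 = np.sum(
            (coords[pi][:, None, :] - ref[ri][None, :, :]) ** 2, axis=2
        )
        rows, cols = linear_sum_assignment(d2)
        perm[pi[rows]] = ri[cols]
        total += float(d2[rows, cols].sum())
    return PoseEvaluation(rmsd=math.sqrt(total / n), matched_permutation=perm)


def docking_accuracy(rmsds: Sequence[float], threshold: float = 2.0) -> float:
    """Fraction of poses with RMSD at or below ``threshold`` (A)."""
    rmsds = np.asarray(list(rmsds), dtype=float)
    if rmsds.size == 0:
        raise ValueError("empty RMSD list")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(np.mean(rmsds <= threshold))


def score_affinity_correlation(
    engine_scores: Sequence[float], pkds: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and Spearman rho between engine scores and measured pK_D."""
    s = np.asarray(list(engine_scores), dtype=float)
    p = np.asarray(list(pkds), dtype=float)
    if s.shape != p.shape or s.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.allclose(s, s[0]) or np.allclose(p, p[0]):
        raise ValueError("undefined correlation: constant input vector")
    r = pearsonr(s, p).statistic
    rho = spearmanr(s, p).statistic
    return float(r), float(rho)


def pkd_to_kd(pkd: float) -> float:
    """Convert pK_D to K_D in nM: ``10^(-pkd) * 1e9``."""
    if not math.isfinite(pkd):
        raise ValueError("pkd must be finite")
    return 10.0 ** (-pkd) * 1e9


def kd_to_pkd(kd_nM: float) -> float:
    """Convert K_D in nM to pK_D."""
    if not (kd_nM > 0 and math.isfinite(kd_nM)):
        raise ValueError("kd_nM must be positive and finite")
    return -math.log10(kd_nM * 1e-9)


def _pose_row(pose: Pose, grid: GridSpec, params: ProbeParams) -> np.ndarray:
    return compute_probe_energies(pose.ligand_atoms, grid, params).row()


def _model_pkd(model: PLSModel, full_row: np.ndarray) -> float:
    row = full_row if model.column_mask is None else full_row[model.column_mask]
    if row.shape[0] != model.x_mean.shape[0]:
        raise ValueError(
            "grid/layout mismatch between pose descriptor row and model columns"
        )
    return float(predict(model, row[None, :])[0])


def rescore_pose(
    models: dict[str, PLSModel] | Sequence[PLSModel],
    pose: Pose,
    grid: GridSpec,
    params: ProbeParams = ProbeParams(),
) -> RescoringResult:
    """Predict pK_D for one pose with each QSAR model and average.

    Models fitted through a :class:`~grooveqsar.fields.DescriptorMatrix`
    carry their column mask and must share the grid layout.  The average is
    the unweighted arithmetic mean across models; K_D is reported in nM.
    """
    if not isinstance(models, dict):
        models = {f"model{i + 1}": m for i, m in enumerate(models)}
    if not models:
        raise ValueError("no models supplied")
    full_row = _pose_row(pose, grid, params)
    per_model = {name: _model_pkd(m, full_row) for name, m in models.items()}
    mean_pkd = float(np.mean(list(per_model.values())))
    return RescoringResult(
        per_model_pkd=per_model, mean_pkd=mean_pkd, kd_nM=pkd_to_kd(mean_pkd)
    )


def rescore_poses(
    models: dict[str, PLSModel],
    poses: Sequence[Pose],
    grid: GridSpec,
    params: ProbeParams = ProbeParams(),
) -> tuple[list[RescoringResult], RescoringResult]:
    """Rescore a pose set; also average over all (model, pose) pairs."""
    if not poses:
        raise ValueError("no poses supplied")
    results = [rescore_pose(models, p, grid, params) for p in poses]
    all_pkds = [v for r in results for v in r.per_model_pkd.values()]
    per_model = {
        name: float(np.mean([r.per_model_pkd[name] for r in results]))
        for name in results[0].per_model_pkd
    }
    mean_pkd = float(np.mean(all_pkds))
    overall = RescoringResult(
        per_model_pkd=per_model, mean_pkd=mean_pkd, kd_nM=pkd_to_kd(mean_pkd)
    )
    return results, overall


def read_poses_pdb(
    text: str,
    ligand_selector: Sequence[str],
    engine: str = "",
    charge_from: str | None = "occupancy",
) -> list[Pose]:
    """Read a multi-MODEL PDB pose file; each MODEL becomes one Pose.

    An engine score may be carried per model in a ``REMARK SCORE <value>``
    line inside the MODEL block.
    """
    blocks: list[tuple[str, float]] = []
    current: list[str] | None = None
    score = float("nan")
    for line in text.splitlines():
        if line.startswith("MODEL"):
            current, score = [], float("nan")
        elif line.startswith("ENDMDL"):
            blocks.append(("\n".join(current or []), score))
            current = None
        elif current is not None:
            if line.startswith("REMARK SCORE"):
                score = float(line.split()[2])
            else:
                current.append(line)
    if not blocks:  # single-model file
        blocks = [(text, float("nan"))]
    poses = []
    for i, (block, sc) in enumerate(blocks):
        cs = read_complex(
            block + "\nEND\n", ligand_selector, complex_id=f"pose{i + 1}",
            charge_from=charge_from,
        ) if _has_receptor(block) else None
        if cs is None:
            cs_atoms = _ligand_only(block, ligand_selector, charge_from)
        else:
            cs_atoms = cs.ligand_atoms
        poses.append(Pose(pose_id=f"pose{i + 1}", ligand_atoms=cs_atoms, engine=engine, engine_score=sc))
    return poses


def _has_receptor(block: str) -> bool:
    return any(line.startswith("ATOM") for line in block.splitlines())


def _ligand_only(block: str, ligand_selector: Sequence[str], charge_from) -> list[Atom]:
    # pose files often hold only HETATM ligand records; reuse the parser by
    # padding with nothing and selecting ligand residues directly
    import gemmi

    from .structures import FormatError, _validate_coordinate_fields

    selector = {s.strip().upper() for s in ligand_selector}
    _validate_coordinate_fields(block)
    st = gemmi.read_pdb_string(block)
    atoms: list[Atom] = []
    if len(st) == 0:
        raise FormatError("no ATOM/HETATM records in pose block")
    for chain in st[0]:
        for res in chain:
            if res.name.strip().upper() not in selector:
                continue
            for at in res:
                if at.altloc not in ("\0", "", "A"):
                    continue
                atoms.append(
                    Atom(
                        element=at.element.name,
                        name=at.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        partial_charge=at.occ if charge_from == "occupancy" else 0.0,
                        is_ligand=True,
                        chain=chain.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                    )
                )
    if not atoms:
        raise ValueError("empty ligand: no pose atoms matched the selector")
    return atoms
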