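"""Pose RMSD, docking accuracy, correlations and QSAR rescoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grooveqsar.fields import compute_probe_energies
from grooveqsar.poses import (
    Pose,
    docking_accuracy,
    kd_to_pkd,
    naive_rmsd,
    pkd_to_kd,
    rescore_pose,
    score_affinity_correlation,
    symmetry_rmsd,
)
from grooveqsar.qsar import PLSModel, predict
from grooveqsar.structures import Atom


def _pose(coords, elements, pose_id="p"):
    atoms = [
        Atom(element=e, name=f"{e}{i+1}", coords=np.asarray(c, float),
             is_ligand=True, res_name="LIG")
        for i, (c, e) in enumerate(zip(coords, elements))
    ]
    return Pose(pose_id=pose_id, ligand_atoms=atoms)


def test_identical_pose_has_zero_rmsd():
    coords = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 1.0]])
    p = _pose(coords, ["C", "N", "O"])
    assert symmetry_rmsd(p, coords, ["C", "N", "O"]).rmsd == pytest.approx(0.0, abs=1e-12)


def test_uniform_translation_gives_exact_rmsd():
    coords = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 1.0]])
    p = _pose(coords + np.array([1.0, 0, 0]), ["C", "N", "O"])
    assert symmetry_rmsd(p, coords, ["C", "N", "O"]).rmsd == pytest.approx(1.0, abs=1e-12)


def test_swapped_equivalent_atoms_match_to_zero():
    coords = np.array([[0, 0, 0], [3, 0, 0], [1.5, 2, 0]])
    swapped = coords[[1, 0, 2]]
    p = _pose(swapped, ["C", "C", "N"])
    ev = symmetry_rmsd(p, coords, ["C", "C", "N"])
    assert ev.rmsd == pytest.approx(0.0, abs=1e-12)
    assert sorted(ev.matched_permutation.tolist()) == [0, 1, 2]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_assignment_equals_exhaustive_permutation_minimum(seed):
    rng = np.random.default_rng(seed)
    elements = ["C", "C", "C", "N", "N", "O", "O", "H"][: rng.integers(4, 9)]
    n = len(elements)
    ref = rng.normal(size=(n, 3)) * 2
    pose_coords = ref + rng.normal(size=(n, 3)) * 0.7
    order = rng.permutation(n)
    p = _pose(pose_coords[order], [elements[i] for i in order])
    got = symmetry_rmsd(p, ref, elements).rmsd

    # brute force over all element-preserving permutations
    groups = {}
    for i, e in enumerate(elements):
        groups.setdefault(e, []).append(i)
    pose_el = [elements[i] for i in order]
    pose_groups = {}
    for i, e in enumerate(pose_el):
        pose_groups.setdefault(e, []).append(i)
    best = np.inf
    per_el_perms = [
        [list(zip(pose_groups[e], perm)) for perm in itertools.permutations(groups[e])]
        for e in groups
    ]
    for combo in itertools.product(*per_el_perms):
        sq = 0.0
        for pairs in combo:
            for pi, ri in pairs:
                d = p.coords()[pi] - ref[ri]
                sq += float(d @ d)
        best = min(best, math.sqrt(sq / n))
    assert got == pytest.approx(best, abs=1e-9)


def test_symmetry_rmsd_never_exceeds_naive():
    rng = np.random.default_rng(9)
    ref = rng.normal(size=(6, 3))
    pose_coords = ref[[1, 0, 2, 3, 5, 4]] + 0.2 * rng.normal(size=(6, 3))
    elements = ["C", "C", "N", "O", "H", "H"]
    p = _pose(pose_coords, ["C", "C", "N", "O", "H", "H"])
    assert symmetry_rmsd(p, ref, elements).rmsd <= naive_rmsd(pose_coords, ref) + 1e-12


def test_mismatched_pose_errors():
    coords = np.array([[0, 0, 0], [1, 0, 0.0]])
    p = _pose(coords, ["C", "N"])
    with pytest.raises(ValueError, match="atom count"):
        symmetry_rmsd(p, coords[:1], ["C"])
    with pytest.raises(ValueError, match="element multisets"):
        symmetry_rmsd(p, coords, ["C", "C"])


def test_docking_accuracy_basic_fractions():
    assert docking_accuracy([0.5, 1.0, 1.9], 2.0) == 1.0
    assert docking_accuracy([1.0, 3.0], 2.0) == 0.5
    with pytest.raises(ValueError):
        docking_accuracy([], 2.0)
    with pytest.raises(ValueError):
        docking_accuracy([1.0], 0.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    rmsds=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=30),
    t1=st.floats(0.1, 10),
    t2=st.floats(0.1, 10),
)
def test_docking_accuracy_monotone_in_threshold_and_order_free(rmsds, t1, t2):
    lo, hi = sorted([t1, t2])
    assert docking_accuracy(rmsds, lo) <= docking_accuracy(rmsds, hi)
    assert docking_accuracy(rmsds, t1) == docking_accuracy(list(reversed(rmsds)), t1)


def test_perfect_anticorrelation():
    pkds = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
    r, rho = score_affinity_correlation(-2 * pkds, pkds)
    assert r == pytest.approx(-1.0, abs=1e-12)
    assert rho == pytest.approx(-1.0, abs=1e-12)


def test_independent_scores_rarely_correlate():
    rng = np.random.default_rng(17)
    n_small = 0
    n_draws = 200
    pkds = rng.uniform(5, 9, size=27)
    for _ in range(n_draws):
        scores = rng.normal(size=27)
        r, _ = score_affinity_correlation(scores, pkds)
        n_small += abs(r) < 0.5
    assert n_small >= 0.95 * n_draws


def test_pearson_matches_textbook_formula():
    s = np.array([1.0, 2.0, 4.0, 3.0, 7.0])
    p = np.array([5.5, 6.0, 8.0, 6.5, 9.0])
    r, _ = score_affinity_correlation(s, p)
    cov = np.mean((s - s.mean()) * (p - p.mean()))
    oracle = cov / (s.std() * p.std())
    assert r == pytest.approx(oracle, abs=1e-12)


def test_constant_vector_is_error():
    with pytest.raises(ValueError, match="undefined correlation"):
        score_affinity_correlation([1.0, 1.0, 1.0], [5.0, 6.0, 7.0])


def test_pkd_kd_conversions():
    assert pkd_to_kd(9.0) == pytest.approx(1.0, abs=1e-12)
    assert pkd_to_kd(7.59) == pytest.approx(25.70, abs=5e-3)  # 10^-7.59 * 1e9
    for x in np.linspace(4, 12, 9):
        assert kd_to_pkd(pkd_to_kd(x)) == pytest.approx(x, abs=1e-12)
    with pytest.raises(ValueError):
        kd_to_pkd(-1.0)


def _constant_model(value, n_cols, column_mask=None):
    return PLSModel(
        n_components=1,
        x_mean=np.zeros(n_cols),
        y_mean=value,
        coefficients=np.zeros(n_cols),
        x_weights=np.zeros((n_cols, 1)),
        x_loadings=np.zeros((n_cols, 1)),
        y_loadings=np.zeros(1),
        column_mask=column_mask,
    )


def test_mean_pkd_of_two_models_is_arithmetic_mean(grid):
    n_cols = 2 * grid.n_points
    models = {"a": _constant_model(6.54, n_cols), "b": _constant_model(7.59, n_cols)}
    pose = _pose(np.array([[0.0, 0.0, 0.0]]), ["C"])
    res = rescore_pose(models, pose, grid)
    assert res.mean_pkd == pytest.approx(7.065, abs=1e-12)
    assert res.kd_nM == pytest.approx(10 ** (-7.065) * 1e9, rel=1e-12)
    assert min(res.per_model_pkd.values()) <= res.mean_pkd <= max(res.per_model_pkd.values())


def test_identical_models_average_to_single_prediction(grid):
    n_cols = 2 * grid.n_points
    m = _constant_model(7.0, n_cols)
    pose = _pose(np.array([[0.0, 0.0, 0.0]]), ["C"])
    res = rescore_pose({"a": m, "b": m, "c": m}, pose, grid)
    assert res.mean_pkd == pytest.approx(7.0, abs=1e-12)


def test_rescoring_crystal_pose_reproduces_training_prediction(
    noiseless_dataset, noiseless_protocols, grid
):
    """The crystal ligand of a training record, pushed through the rescoring
    path, must reproduce that record's model-1 training prediction exactly
    (same field row, same model)."""
    records, _ = noiseless_dataset
    dm, y, reports = noiseless_protocols
    rec = records[4]
    model = reports["model1"].model
    pose = Pose("crystal", rec.structure.ligand_atoms)
    res = rescore_pose({"model1": model}, pose, grid)
    training_pred = predict(model, dm.X[4 : 5])[0]
    assert res.mean_pkd == pytest.approx(training_pred, abs=1e-9)


def test_rescore_known_coefficient_model_by_hand(grid):
    """One-component model with hand-set coefficients on a one-atom pose."""
    pose = _pose(np.array([[1.0, 1.0, 1.0]]), ["C"])
    full_row = compute_probe_energies(pose.ligand_atoms, grid).row()
    n_cols = full_row.size
    rng = np.random.default_rng(3)
    coef = rng.normal(size=n_cols) * 1e-3
    m = PLSModel(
        n_components=1,
        x_mean=np.zeros(n_cols),
        y_mean=7.0,
        coefficients=coef,
        x_weights=np.zeros((n_cols, 1)),
        x_loadings=np.zeros((n_cols, 1)),
        y_loadings=np.zeros(1),
    )
    expected = 7.0 + float(full_row @ coef)
    res = rescore_pose({"m": m}, pose, grid)
    assert res.mean_pkd == pytest.approx(expected, abs=1e-10)
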