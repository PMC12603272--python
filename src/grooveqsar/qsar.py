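"""PLS regression of pK_D on field descriptors, with internal and external
validation.

The regression is PLS1 via the NIPALS algorithm on mean-centered X and y
(no scaling by default, matching classical CoMFA practice).  Validation
statistics follow QSAR convention:

* r2        -- training coefficient of determination;
* q2, sdep  -- leave-one-out cross-validated r2 and sqrt(PRESS/n), where
               each left-out sample is predicted by a model refit without it;
* q2_ext, sdep_ext -- the same on an external held-out set, with the
               external SS_tot referenced to the training-set mean.

Three fitting protocols are provided: fit on the full dataset
("model1"), fit on a grouped 80/20 split with external validation
("model2"), and refit on the full dataset reusing model2's selected
component count ("model3").  The split is grouped by ligand id so that
replicate complexes of one ligand never straddle the train/test boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fields import DescriptorMatrix, GridSpec

__all__ = [
    "PLSModel",
    "ModelStats",
    "ProtocolReport",
    "fit_pls",
    "predict",
    "loo_validate",
    "select_components",
    "grouped_split",
    "run_protocols",
    "external_stats",
    "save_model",
    "load_model",
]


@dataclass
class PLSModel:
    """A fitted PLS1 model on (already filtered) descriptor columns."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    column_mask: np.ndarray | None = None  # layout tag when fitted via a DescriptorMatrix


@dataclass
class ModelStats:
    r2: float | None = None
    q2: float | None = None
    sdep: float | None = None
    q2_ext: float | None = None
    sdep_ext: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class ProtocolReport:
    protocol: str
    model: PLSModel
    stats: ModelStats
    train_ids: list[str]
    test_ids: list[str]


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"incompatible shapes X{X.shape} y{y.shape}")
    return X, y


def fit_pls(X, y, n_components: int, column_mask: np.ndarray | None = None) -> PLSModel:
    """Fit PLS1 by NIPALS on mean-centered X, y.

    Deterministic for fixed input.  ``n_components`` must lie in
    ``[1, min(n_samples - 1, n_columns)]``.  Deflation stops early if X or
    the residual covariance vanishes (remaining components carry nothing).
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.allclose(y, y[0]):
        raise ValueError("constant response: y has zero variance")
    max_comp = min(n - 1, p)
    if not (1 <= n_components <= max_comp):
        raise ValueError(
            f"n_components={n_components} out of range [1, {max_comp}] "
            f"for X{X.shape}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    a_used = 0
    for a in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break  # residual X carries no covariance with y
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        p_load = Xc.T @ t / tt
        q = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q * t
        W[:, a], P[:, a], Q[a] = w, p_load, q
        a_used += 1
    W, P, Q = W[:, :a_used], P[:, :a_used], Q[:a_used]
    if a_used == 0:
        raise ValueError("X carries no covariance with y; nothing to fit")
    # B = W (P^T W)^-1 q maps centered X to centered y.
    coefficients = W @ np.linalg.solve(P.T @ W, Q)
    return PLSModel(
        n_components=a_used,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=coefficients,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        column_mask=None if column_mask is None else np.asarray(column_mask, bool),
    )


def predict(model: PLSModel, X) -> np.ndarray:
    """Predict pK_D: ``y_mean + (x - x_mean) . coefficients``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"column layout mismatch: model expects {model.x_mean.shape[0]} "
            f"columns, got {X.shape[1]}"
        )
    out = model.y_mean + (X - model.x_mean) @ model.coefficients
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite prediction")
    return out


def training_r2(model: PLSModel, X, y) -> float:
    X, y = _as_xy(X, y)
    resid = y - predict(model, X)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / ss_tot


def loo_validate(X, y, n_components: int) -> tuple[float, float]:
    """Leave-one-out q2 and SDEP by literal per-sample refits.

    ``q2 = 1 - PRESS / SS_tot`` with each held-out sample predicted by a
    model refit on the other n-1 samples; the SS_tot term references each
    sample to its own fold's training mean.  ``sdep = sqrt(PRESS / n)``.
    """
    X, y = _as_xy(X, y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOO validation needs at least 3 samples")
    press = 0.0
    ss_tot = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        m = fit_pls(X[mask], y[mask], min(n_components, n - 2, X.shape[1]))
        yhat = float(predict(m, X[i : i + 1])[0])
        press += (y[i] - yhat) ** 2
        ss_tot += (y[i] - y[mask].mean()) ** 2
    q2 = 1.0 - press / ss_tot
    sdep = math.sqrt(press / n)
    return q2, sdep


def select_components(X, y, max_components: int) -> int:
    """Component count maximizing LOO q2; ties go to the smaller count."""
    X, y = _as_xy(X, y)
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    upper = min(max_components, X.shape[0] - 2, X.shape[1])
    upper = max(upper, 1)
    best_a, best_q2 = 1, -np.inf
    for a in range(1, upper + 1):
        q2, _ = loo_validate(X, y, a)
        if q2 > best_q2 + 1e-12:
            best_a, best_q2 = a, q2
    return best_a


def external_stats(model: PLSModel, X_train, y_train, X_test, y_test) -> tuple[float, float]:
    """q2_ext and SDEP_ext of a fitted model on a held-out set.

    SS_tot references the held-out responses to the training-set mean.
    """
    X_test, y_test = _as_xy(X_test, y_test)
    y_train = np.asarray(y_train, dtype=float)
    resid = y_test - predict(model, X_test)
    press = float(resid @ resid)
    ss_tot = float(np.sum((y_test - y_train.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("degenerate external set: zero variance about training mean")
    return 1.0 - press / ss_tot, math.sqrt(press / len(y_test))


def grouped_split(
    groups: Sequence[str], test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/test split keeping all records of one group together.

    Groups are shuffled and assigned to the test side until it holds at
    least ``round(test_fraction * n)`` records.
    """
    groups = np.asarray(groups)
    n = len(groups)
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    target = int(round(test_fraction * n))
    if target < 1:
        raise ValueError("test split empty for this test_fraction and dataset size")
    rng = np.random.default_rng(seed)
    uniq = sorted(set(groups.tolist()))
    order = rng.permutation(len(uniq))
    test_mask = np.zeros(n, dtype=bool)
    count = 0
    for gi in order:
        if count >= target:
            break
        sel = groups == uniq[gi]
        test_mask |= sel
        count += int(sel.sum())
    if test_mask.all():
        raise ValueError("test split swallowed the whole dataset; lower test_fraction")
    return ~test_mask, test_mask


def run_protocols(
    descriptors,
    y,
    ligand_ids: Sequence[str],
    split_seed: int,
    test_fraction: float = 0.2,
    max_components: int = 10,
    record_ids: Sequence[str] | None = None,
) -> dict[str, ProtocolReport]:
    """Run the three modelling protocols and collect their statistics.

    ``descriptors`` may be a :class:`~grooveqsar.fields.DescriptorMatrix`
    (its filtered columns are used and models are tagged with the column
    layout) or a plain 2-D array.

    * model1: fit on every record; report r2, LOO q2, SDEP.
    * model2: fit on ~(1-test_fraction) of records (grouped by ligand id);
      report external q2_ext/SDEP_ext on the held-out rest.
    * model3: fit on every record reusing model2's component count.
    """
    column_mask = None
    if isinstance(descriptors, DescriptorMatrix):
        column_mask = descriptors.kept_mask
        if record_ids is None:
            record_ids = descriptors.record_ids
        X = descriptors.X
    else:
        X = np.asarray(descriptors, dtype=float)
    X, y = _as_xy(X, y)
    n = X.shape[0]
    if n < 5:
        raise ValueError("protocols need at least 5 records")
    if record_ids is None:
        record_ids = [str(i) for i in range(n)]
    record_ids = list(record_ids)
    ligand_ids = list(ligand_ids)
    if len(ligand_ids) != n:
        raise ValueError("ligand_ids length mismatch")

    reports: dict[str, ProtocolReport] = {}

    # Model 1: full dataset.
    a1 = select_components(X, y, max_components)
    m1 = fit_pls(X, y, a1, column_mask)
    q2, sdep = loo_validate(X, y, a1)
    reports["model1"] = ProtocolReport(
        protocol="model1",
        model=m1,
        stats=ModelStats(r2=training_r2(m1, X, y), q2=q2, sdep=sdep),
        train_ids=record_ids,
        test_ids=[],
    )

    # Model 2: grouped 80/20 split with external validation.
    train_mask, test_mask = grouped_split(ligand_ids, test_fraction, split_seed)
    Xtr, ytr, Xte, yte = X[train_mask], y[train_mask], X[test_mask], y[test_mask]
    a2 = select_components(Xtr, ytr, max_components)
    m2 = fit_pls(Xtr, ytr, a2, column_mask)
    q2_tr, sdep_tr = loo_validate(Xtr, ytr, a2)
    q2_ext, sdep_ext = external_stats(m2, Xtr, ytr, Xte, yte)
    reports["model2"] = ProtocolReport(
        protocol="model2",
        model=m2,
        stats=ModelStats(
            r2=training_r2(m2, Xtr, ytr),
            q2=q2_tr,
            sdep=sdep_tr,
            q2_ext=q2_ext,
            sdep_ext=sdep_ext,
        ),
        train_ids=[r for r, m in zip(record_ids, train_mask) if m],
        test_ids=[r for r, m in zip(record_ids, test_mask) if m],
    )

    # Model 3: full dataset with model2's component count.
    m3 = fit_pls(X, y, m2.n_components, column_mask)
    q2_3, sdep_3 = loo_validate(X, y, m2.n_components)
    reports["model3"] = ProtocolReport(
        protocol="model3",
        model=m3,
        stats=ModelStats(r2=training_r2(m3, X, y), q2=q2_3, sdep=sdep_3),
        train_ids=record_ids,
        test_ids=[],
    )
    return reports


_SCHEMA_VERSION = 1


def save_model(
    model: PLSModel,
    path,
    stats: ModelStats | None = None,
    grid: GridSpec | None = None,
    protocol: str | None = None,
) -> None:
    """Serialize a model (and optional grid/stats context) to JSON."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "protocol": protocol,
        "n_components": model.n_components,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "coefficients": model.coefficients.tolist(),
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "column_mask": None if model.column_mask is None else model.column_mask.astype(int).tolist(),
        "stats": stats.to_dict() if stats is not None else None,
        "grid": None
        if grid is None
        else {"origin": list(grid.origin), "spacing": grid.spacing, "dims": list(grid.dims)},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> tuple[PLSModel, ModelStats | None, GridSpec | None]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {doc.get('schema_version')}")
    model = PLSModel(
        n_components=doc["n_components"],
        x_mean=np.asarray(doc["x_mean"], float),
        y_mean=float(doc["y_mean"]),
        coefficients=np.asarray(doc["coefficients"], float),
        x_weights=np.asarray(doc["x_weights"], float),
        x_loadings=np.asarray(doc["x_loadings"], float),
        y_loadings=np.asarray(doc["y_loadings"], float),
        column_mask=None
        if doc["column_mask"] is None
        else np.asarray(doc["column_mask"], dtype=bool),
    )
    stats = ModelStats(**doc["stats"]) if doc.get("stats") else None
    grid = None
    if doc.get("grid"):
        g = doc["grid"]
        grid = GridSpec(origin=tuple(g["origin"]), spacing=g["spacing"], dims=tuple(g["dims"]))
    return model, stats, grid
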