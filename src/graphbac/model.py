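"""Sparse linear model of the error in computed formation enthalpies.

The response is y = (reference - computed) formation enthalpy in
kcal/mol, so a positive value means the computation underpredicts.  The
model is an L1-regularized (LASSO) linear map from subgraph frequencies
to this error,

    L(w) = (1/2n) sum_i (x_i . w - y_i)^2 + lambda * ||w||_1,

fit on raw counts with no intercept and no column standardization by
default, so each coefficient stays interpretable as a per-occurrence
group energy in kcal/mol.  lambda is chosen by k-fold cross-validation
(tenfold by default), with ties broken toward the sparser (larger
lambda) model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold

from .molgraph import MasterGraph, parse_molecule
from .subgraphs import (
    DEFAULT_MAX_EDGES,
    FeatureTable,
    SubgraphPattern,
    build_feature_table,
    enumerate_subgraphs,
)

#: Coefficients below this magnitude (kcal/mol per occurrence) count as zero.
ZERO_TOL = 1e-8

#: Coordinate-descent convergence tolerance and iteration cap.
SOLVER_TOL = 1e-6
SOLVER_MAX_ITER = 100_000


class CoverageWarning(UserWarning):
    """A molecule contains patterns outside the model's registry."""


@dataclass
class ErrorDataset:
    """Feature matrix, error response, and optional enthalpy bookkeeping."""

    features: FeatureTable
    y: np.ndarray
    h_computed: np.ndarray | None = None
    graphs: tuple[MasterGraph, ...] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != len(self.features.frame):
            raise ValueError("response length must match feature-table rows")
        if self.h_computed is not None:
            self.h_computed = np.asarray(self.h_computed, dtype=float)
            if len(self.h_computed) != len(self.y):
                raise ValueError("h_computed length must match response")

    @property
    def ids(self) -> tuple[str, ...]:
        return self.features.molecule_ids

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, rows: Sequence[int]) -> "ErrorDataset":
        rows = list(rows)
        return ErrorDataset(
            FeatureTable(self.features.frame.iloc[rows], self.features.patterns),
            self.y[rows],
            None if self.h_computed is None else self.h_computed[rows],
            None if self.graphs is None else tuple(self.graphs[r] for r in rows),
        )

    @classmethod
    def from_csv(
        cls, path: str, max_edges: int = DEFAULT_MAX_EDGES
    ) -> "ErrorDataset":
        """Load the dataset CSV (id, smiles, h_computed_kcal_mol, h_reference_kcal_mol)."""
        df = pd.read_csv(path)
        required = {"id", "smiles", "h_computed_kcal_mol", "h_reference_kcal_mol"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing column(s): {sorted(missing)}")
        graphs = tuple(
            parse_molecule(s, id=str(i)) for i, s in zip(df["id"], df["smiles"])
        )
        table = build_feature_table(graphs, max_edges=max_edges)
        y = df["h_reference_kcal_mol"].to_numpy(float) - df["h_computed_kcal_mol"].to_numpy(float)
        return cls(table, y, df["h_computed_kcal_mol"].to_numpy(float), graphs)


@dataclass
class ErrorModel:
    """Sparse group-energy model: coefficients in kcal/mol per occurrence."""

    pattern_keys: tuple[str, ...]
    coefficients: np.ndarray
    lam: float
    intercept: float = 0.0
    max_edges: int = DEFAULT_MAX_EDGES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.pattern_keys):
            raise ValueError("coefficient vector must align with pattern registry")

    @property
    def active_keys(self) -> tuple[str, ...]:
        return tuple(
            k for k, w in zip(self.pattern_keys, self.coefficients) if abs(w) > ZERO_TOL
        )

    def coefficient(self, key: str) -> float:
        try:
            return float(self.coefficients[self.pattern_keys.index(key)])
        except ValueError:
            return 0.0

    def to_json(self, path: str) -> None:
        payload = {
            "pattern_keys": list(self.pattern_keys),
            "coefficients": [float(w) for w in self.coefficients],
            "lambda": self.lam,
            "intercept": self.intercept,
            "max_edges": self.max_edges,
            "metadata": self.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ErrorModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            tuple(payload["pattern_keys"]),
            np.asarray(payload["coefficients"], float),
            payload["lambda"],
            payload.get("intercept", 0.0),
            payload.get("max_edges", DEFAULT_MAX_EDGES),
            payload.get("metadata", {}),
        )


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, FeatureTable):
        return X.frame.to_numpy(float), X.keys
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), tuple(str(c) for c in X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D")
    return arr, tuple(f"x{j}" for j in range(arr.shape[1]))


def lambda_max(X, y) -> float:
    """Smallest lambda at which the intercept-free LASSO solution is all zero."""
    A, _ = _as_matrix(X)
    y = np.asarray(y, float)
    return float(np.max(np.abs(A.T @ y)) / len(y))


def default_grid(X, y, n_points: int = 60, ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced lambda grid from lambda_max down to ratio*lambda_max."""
    lmax = lambda_max(X, y)
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, ratio * lmax, n_points)


def fit_lasso(
    X,
    y,
    lam: float,
    *,
    fit_intercept: bool = False,
    tol: float = SOLVER_TOL,
    max_iter: int = SOLVER_MAX_ITER,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> ErrorModel:
    """Minimize (1/2n)||Xw - y||^2 + lam*||w||_1 by coordinate descent.

    ``lam = 0`` falls back to ordinary least squares (minimum-norm
    solution on rank-deficient designs).  All-zero columns are permitted
    and receive a zero coefficient.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    A, keys = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(y) != A.shape[0]:
        raise ValueError("X and y are not conformable")
    intercept = 0.0
    if lam == 0.0:
        design = np.hstack([A, np.ones((len(y), 1))]) if fit_intercept else A
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        if fit_intercept:
            w, intercept = sol[:-1], float(sol[-1])
        else:
            w = sol
    else:
        est = Lasso(alpha=lam, fit_intercept=fit_intercept, tol=tol, max_iter=max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter near lambda -> 0
            est.fit(A, y)
        w = est.coef_
        intercept = float(est.intercept_) if fit_intercept else 0.0
    return ErrorModel(
        keys,
        np.asarray(w, float),
        lam,
        intercept,
        max_edges,
        {"tol": tol, "max_iter": max_iter, "fit_intercept": fit_intercept},
    )


def select_lambda(
    X,
    y,
    folds: int = 10,
    grid: Sequence[float] | None = None,
    seed: int = 0,
    *,
    tol: float = SOLVER_TOL,
    max_iter: int = SOLVER_MAX_ITER,
) -> float:
    """Pick lambda minimizing mean out-of-fold squared error.

    Rows are partitioned into ``folds`` by a seeded shuffle; the full
    solution path over the descending grid is computed per fold.  Ties
    in CV error resolve toward the larger lambda (sparser model).
    """
    A, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(y) < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    if grid is None:
        grid = default_grid(A, y)
    grid = np.asarray(sorted(grid, reverse=True), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if grid.size == 1:
        return float(grid[0])
    if np.any(grid <= 0):
        raise ValueError("grid lambdas must be positive (use fit_lasso for lambda=0)")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_err = np.zeros(grid.size)
    for train_idx, val_idx in kf.split(A):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(
                A[train_idx], y[train_idx], alphas=grid, tol=tol, max_iter=max_iter
            )
        resid = A[val_idx] @ coefs - y[val_idx][:, None]
        cv_err += np.mean(resid**2, axis=0)
    cv_err /= folds
    best = np.flatnonzero(cv_err == cv_err.min())[0]  # grid descends: first = largest lambda
    return float(grid[best])


def train_error_model(
    data: ErrorDataset,
    test_fraction: float = 0.10,
    seed: int = 0,
    folds: int = 10,
    grid: Sequence[float] | None = None,
    *,
    fit_intercept: bool = False,
) -> tuple[ErrorModel, dict, tuple[str, ...]]:
    """Train/evaluate protocol: seeded 90/10 split, CV lambda, held-out metrics.

    Returns the model fit on the training rows at the CV-selected
    lambda, a metrics dict (test MAE and R2 in kcal/mol terms, active-set
    size, lambda), and the held-out molecule ids.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = data.n
    n_test = max(1, int(round(n * test_fraction)))
    if n - n_test < folds:
        raise ValueError("dataset too small for the requested split and folds")
    perm = rng.permutation(n)
    test_rows, train_rows = perm[:n_test], perm[n_test:]
    train = data.subset(train_rows)
    A_train = train.features.frame.to_numpy(float)
    lam = select_lambda(
        A_train, train.y, folds=folds, grid=grid, seed=int(rng.integers(2**31))
    )
    model = fit_lasso(
        train.features, train.y, lam, fit_intercept=fit_intercept,
    )
    model.metadata.update(
        {
            "seed": seed,
            "folds": folds,
            "test_fraction": test_fraction,
            "train_ids": list(train.ids),
        }
    )
    test = data.subset(test_rows)
    pred = test.features.frame.to_numpy(float) @ model.coefficients + model.intercept
    metrics = {
        "test_mae_kcal_mol": float(mean_absolute_error(test.y, pred)),
        "test_r2": float(r2_score(test.y, pred)),
        "lambda": lam,
        "n_active": len(model.active_keys),
        "n_train": int(n - n_test),
        "n_test": int(n_test),
    }
    return model, metrics, test.ids


def predict_error(m: ErrorModel, g: MasterGraph) -> float:
    """Predicted (reference - computed) enthalpy error for one molecule.

    Patterns of the molecule missing from the model registry contribute
    zero and trigger a :class:`CoverageWarning` naming the molecule.
    """
    counts = enumerate_subgraphs(g, max_edges=m.max_edges)
    known = dict(zip(m.pattern_keys, m.coefficients))
    uncovered = [p.label for p in counts if p.key not in known]
    if uncovered:
        warnings.warn(
            f"molecule {g.id!r}: {len(uncovered)} pattern(s) outside model registry "
            f"(e.g. {uncovered[:3]}) contribute zero",
            CoverageWarning,
            stacklevel=2,
        )
    total = m.intercept
    for p, c in counts.items():
        total += known.get(p.key, 0.0) * c
    return float(total)


def correct_enthalpy(h_computed: float, m: ErrorModel, g: MasterGraph) -> float:
    """A posteriori correction: computed enthalpy plus predicted error.

    Because the error is defined as (reference - computed), adding the
    predicted error moves the computed value toward the reference.
    """
    if not np.isfinite(h_computed):
        raise ValueError("computed enthalpy must be finite")
    return float(h_computed) + predict_error(m, g)


def reaction_error(
    m: ErrorModel,
    reactants: Sequence[tuple[MasterGraph, float]],
    products: Sequence[tuple[MasterGraph, float]],
) -> float:
    """Predicted error in a reaction enthalpy (products minus reactants).

    Net pattern counts are accumulated before multiplying by the
    coefficients, so with an atoms-only model and an element-balanced
    reaction the zeroth-order contributions cancel to exactly 0.0 —
    systematic atom-level error never leaks into balanced reaction
    enthalpies, only bond-level and higher groups can.
    """
    net: dict[str, float] = {}
    for graphs, sign in ((reactants, -1.0), (products, 1.0)):
        for g, nu in graphs:
            for p, c in enumerate_subgraphs(g, max_edges=m.max_edges).items():
                net[p.key] = net.get(p.key, 0.0) + sign * nu * c
    known = dict(zip(m.pattern_keys, m.coefficients))
    return float(sum(known.get(k, 0.0) * v for k, v in net.items() if v != 0.0))
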