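"""Bootstrap assessment of the error model.

The training partition is repeatedly split 60/40; the model (including
cross-validated lambda selection, by default) is refit on the 60% part
and scored on both parts.  Across iterations this yields distributions
of MAE and of P(eps < 2) — the probability that a random molecule's
error prediction lands within 2 kcal/mol — plus per-pattern coefficient
samples from which percentile confidence intervals and the normalized
model frequency (fraction of refits selecting the pattern) are computed.

All randomness flows from a single seed, so reports are bitwise
reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error

from .model import ZERO_TOL, ErrorDataset, fit_lasso, select_lambda


def p_epsilon(abs_errors: Sequence[float], threshold: float = 2.0) -> float:
    """Fraction of absolute errors within ``threshold`` kcal/mol.

    Computes (1/N) sum_i H[threshold - eps_i] with the Heaviside
    convention H[0] = 1: an error exactly at the threshold counts as a
    success.
    """
    eps = np.asarray(abs_errors, dtype=float)
    if eps.size == 0:
        raise ValueError("p_epsilon requires at least one error value")
    if np.any(eps < 0):
        raise ValueError("abs_errors must be nonnegative (pass absolute errors)")
    return float(np.mean(eps <= threshold))


def normalized_model_frequency(
    coefficient_samples: Sequence[float], zero_tol: float = ZERO_TOL
) -> float:
    """Fraction of refits in which a pattern's coefficient is nonzero.

    A value near 1 means the pattern is selected in essentially every
    bootstrap refit; near 0, that it is noise.  ``zero_tol`` guards
    against solvers that return tiny non-exact zeros.
    """
    w = np.asarray(coefficient_samples, dtype=float)
    if w.size == 0:
        raise ValueError("need at least one coefficient sample")
    return float(np.mean(np.abs(w) > zero_tol))


def coefficient_interval(
    samples: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Percentile confidence interval (linear-interpolation quantiles)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    w = np.asarray(samples, dtype=float)
    if w.size < 2:
        raise ValueError("need at least two samples for an interval")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(w, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class BootstrapReport:
    """Per-iteration bootstrap metrics and coefficient samples."""

    pattern_keys: tuple[str, ...]
    coef_samples: np.ndarray  # shape (iterations, n_patterns)
    train_mae: np.ndarray
    val_mae: np.ndarray
    train_p_eps: np.ndarray
    val_p_eps: np.ndarray
    lambdas: np.ndarray
    threshold: float = 2.0
    metadata: dict = field(default_factory=dict)

    @property
    def iterations(self) -> int:
        return len(self.train_mae)

    def frequencies(self, zero_tol: float = ZERO_TOL) -> dict[str, float]:
        """Normalized model frequency per pattern."""
        return {
            k: normalized_model_frequency(self.coef_samples[:, j], zero_tol)
            for j, k in enumerate(self.pattern_keys)
        }

    def intervals(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Percentile coefficient CI per pattern."""
        return {
            k: coefficient_interval(self.coef_samples[:, j], level)
            for j, k in enumerate(self.pattern_keys)
        }

    def summary(self, level: float = 0.95) -> dict:
        freq = self.frequencies()
        ci = self.intervals(level)
        return {
            "iterations": self.iterations,
            "threshold_kcal_mol": self.threshold,
            "train_mae_median": float(np.median(self.train_mae)),
            "val_mae_median": float(np.median(self.val_mae)),
            "train_p_eps_median": float(np.median(self.train_p_eps)),
            "val_p_eps_median": float(np.median(self.val_p_eps)),
            "coefficient_median": {
                k: float(np.median(self.coef_samples[:, j]))
                for j, k in enumerate(self.pattern_keys)
            },
            "normalized_model_frequency": freq,
            "coefficient_ci": {k: list(v) for k, v in ci.items()},
            "ci_level": level,
        }

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.iterations),
                "train_mae": self.train_mae,
                "val_mae": self.val_mae,
                "train_p_eps": self.train_p_eps,
                "val_p_eps": self.val_p_eps,
                "lambda": self.lambdas,
            }
        )

    def to_json(self, path: str, level: float = 0.95) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"summary": self.summary(level), "metadata": self.metadata}, fh, indent=1)


def bootstrap_evaluate(
    train: ErrorDataset,
    iterations: int = 1000,
    fit_fraction: float = 0.60,
    seed: int = 0,
    folds: int = 10,
    grid: Sequence[float] | None = None,
    *,
    with_replacement: bool = False,
    reselect_lambda: bool = True,
    fixed_lambda: float | None = None,
    threshold: float = 2.0,
) -> BootstrapReport:
    """Bootstrap the full fitting pipeline on the training partition.

    Per iteration a 60/40 split (default: without replacement; with
    ``with_replacement=True`` the fit rows are drawn with replacement and
    validation uses the unsampled rows), lambda re-selected by CV on the
    fit rows unless ``reselect_lambda`` is off (then ``fixed_lambda`` is
    required), and MAE / P(eps < threshold) recorded on both parts.
    """
    if not 0 < fit_fraction < 1:
        raise ValueError("fit_fraction must be in (0, 1)")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not reselect_lambda and fixed_lambda is None:
        raise ValueError("fixed_lambda required when reselect_lambda is off")
    rng = np.random.default_rng(seed)
    n = train.n
    n_fit = int(round(fit_fraction * n))
    if n_fit < folds or n_fit == 0 or n_fit == n:
        raise ValueError("fit_fraction yields a degenerate split for this dataset")
    A = train.features.frame.to_numpy(float)
    y = train.y
    keys = train.features.keys
    coef_samples = np.empty((iterations, len(keys)))
    tr_mae = np.empty(iterations)
    va_mae = np.empty(iterations)
    tr_pe = np.empty(iterations)
    va_pe = np.empty(iterations)
    lams = np.empty(iterations)
    for it in range(iterations):
        if with_replacement:
            fit_rows = rng.integers(0, n, size=n_fit)
            val_rows = np.setdiff1d(np.arange(n), np.unique(fit_rows))
            if val_rows.size == 0:  # pathological tiny-n draw
                val_rows = np.arange(n)
        else:
            perm = rng.permutation(n)
            fit_rows, val_rows = perm[:n_fit], perm[n_fit:]
        Af, yf = A[fit_rows], y[fit_rows]
        if reselect_lambda:
            lam = select_lambda(
                Af, yf, folds=folds, grid=grid, seed=int(rng.integers(2**31))
            )
        else:
            lam = float(fixed_lambda)
        model = fit_lasso(Af, yf, lam)
        coef_samples[it] = model.coefficients
        eps_fit = np.abs(Af @ model.coefficients - yf)
        eps_val = np.abs(A[val_rows] @ model.coefficients - y[val_rows])
        tr_mae[it] = eps_fit.mean()
        va_mae[it] = eps_val.mean()
        tr_pe[it] = p_epsilon(eps_fit, threshold)
        va_pe[it] = p_epsilon(eps_val, threshold)
        lams[it] = lam
    return BootstrapReport(
        keys,
        coef_samples,
        tr_mae,
        va_mae,
        tr_pe,
        va_pe,
        lams,
        threshold,
        {
            "seed": seed,
            "iterations": iterations,
            "fit_fraction": fit_fraction,
            "n_fit": int(n_fit),
            "n_val": int(n - n_fit),
            "folds": folds,
            "with_replacement": with_replacement,
            "reselect_lambda": reselect_lambda,
        },
    )


def learning_curve(
    train: ErrorDataset,
    test: ErrorDataset,
    fractions: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    seed: int = 0,
    replicates: int = 1,
    folds: int = 10,
    grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Test-set MAE of models trained on growing fractions of the training data.

    Returns a table of (fraction, n_train, mae_mean, mae_std); the spread
    comes from ``replicates`` seeded re-subsamplings per fraction.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    A_test = test.features.frame.to_numpy(float)
    rows = []
    for frac in fractions:
        n_sub = int(round(frac * train.n))
        if n_sub < folds:
            raise ValueError(
                f"fraction {frac} yields {n_sub} rows < {folds} folds"
            )
        maes = []
        for _ in range(replicates):
            sub_rows = rng.permutation(train.n)[:n_sub]
            sub = train.subset(sub_rows)
            A_sub = sub.features.frame.to_numpy(float)
            lam = select_lambda(
                A_sub, sub.y, folds=folds, grid=grid, seed=int(rng.integers(2**31))
            )
            model = fit_lasso(A_sub, sub.y, lam)
            pred = A_test @ model.coefficients
            maes.append(mean_absolute_error(test.y, pred))
        maes = np.asarray(maes)
        rows.append(
            {
                "fraction": float(frac),
                "n_train": n_sub,
                "mae_mean": float(maes.mean()),
                "mae_std": float(maes.std(ddof=1)) if replicates > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def group_correlation(X_active: pd.DataFrame) -> pd.DataFrame:
    """Absolute Pearson correlation between active patterns.

    Correlation and anti-correlation are treated equally (absolute
    value); near-zero off-diagonals justify reading coefficients as
    independent group energies.  Constant columns have undefined
    correlation and are reported as NaN with a warning, never silently
    zeroed.
    """
    if X_active.shape[1] < 2:
        raise ValueError("need at least two active patterns")
    if X_active.shape[0] < 3:
        raise ValueError("need at least three molecules")
    values = X_active.to_numpy(float)
    constant = X_active.columns[values.std(axis=0) == 0].tolist()
    if constant:
        warnings.warn(
            f"constant column(s) {constant}: correlation undefined (NaN)",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(values, rowvar=False))
    np.fill_diagonal(corr, 1.0)
    for col in constant:
        j = X_active.columns.get_loc(col)
        corr[j, :] = np.nan
        corr[:, j] = np.nan
        corr[j, j] = np.nan
    return pd.DataFrame(corr, index=X_active.columns, columns=X_active.columns)
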