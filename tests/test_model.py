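"""LASSO solver contracts, lambda selection, and the correction workflow."""

import warnings

import numpy as np
import pytest

import graphbac as gb
from graphbac.model import (
    CoverageWarning,
    default_grid,
    fit_lasso,
    lambda_max,
    predict_error,
    reaction_error,
    select_lambda,
    train_error_model,
)


def _toy_system(seed=0, n=30, p=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = np.array([2.0, -1.0, 0.5, 0.0])
    y = X @ w + 0.01 * rng.normal(size=n)
    return X, y, w


class TestFitLasso:
    def test_lambda_zero_matches_least_squares(self):
        X, y, _ = _toy_system()
        model = fit_lasso(X, y, 0.0)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(model.coefficients, ols, atol=1e-6)

    def test_lambda_max_nulls_all_coefficients(self):
        X, y, _ = _toy_system(seed=3)
        for lam in (lambda_max(X, y), 1.5 * lambda_max(X, y)):
            model = fit_lasso(X, y, lam)
            assert np.all(model.coefficients == 0.0)

    def test_exact_single_column_fit(self):
        model = fit_lasso(np.array([[1.0], [2.0], [3.0]]), np.array([2.0, 4.0, 6.0]), 0.0)
        assert model.coefficients[0] == pytest.approx(2.0, abs=1e-10)

    def test_soft_threshold_closed_form(self):
        """Single-column LASSO equals soft-thresholding of the OLS estimate."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = 1.7 * x + rng.normal(size=50) * 0.3
        for lam in (0.05, 0.5, 2.0):
            fitted = fit_lasso(x[:, None], y, lam).coefficients[0]
            rho = x @ y / len(y)
            expected = np.sign(rho) * max(abs(rho) - lam, 0.0) / (x @ x / len(y))
            assert fitted == pytest.approx(expected, abs=1e-8)

    def test_monotone_shrinkage_along_path(self):
        X, y, _ = _toy_system(seed=5)
        lams = np.geomspace(1e-3, lambda_max(X, y), 12)
        norms = [np.abs(fit_lasso(X, y, lam).coefficients).sum() for lam in lams]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_loss_is_minimal_under_random_perturbations(self):
        X, y, _ = _toy_system(seed=11)
        lam = 0.1
        w = fit_lasso(X, y, lam).coefficients

        def loss(v):
            return 0.5 * np.mean((X @ v - y) ** 2) + lam * np.abs(v).sum()

        rng = np.random.default_rng(0)
        base = loss(w)
        for _ in range(100):
            assert base <= loss(w + rng.normal(scale=0.05, size=w.shape)) + 1e-9

    def test_negative_lambda_rejected(self):
        X, y, _ = _toy_system()
        with pytest.raises(ValueError):
            fit_lasso(X, y, -0.1)

    def test_all_zero_column_gets_zero_coefficient(self):
        X, y, _ = _toy_system()
        X = np.hstack([X, np.zeros((len(y), 1))])
        model = fit_lasso(X, y, 0.05)
        assert model.coefficients[-1] == 0.0


class TestSelectLambda:
    def test_noiseless_linear_data_selects_sparse_near_zero_cv_error(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 5, size=(200, 6)).astype(float)
        w = np.array([3.0, 0.0, -2.0, 0.0, 1.0, 0.0])
        y = X @ w
        grid = default_grid(X, y, n_points=30, ratio=1e-6)
        lam = select_lambda(X, y, folds=5, grid=grid, seed=0)
        model = fit_lasso(X, y, lam)
        assert np.abs(X @ model.coefficients - y).mean() < 0.05
        # exact model is representable, so the chosen lambda sits low on the grid
        assert lam < grid[0] / 10

    def test_singleton_grid_returned_verbatim(self):
        X, y, _ = _toy_system()
        assert select_lambda(X, y, folds=3, grid=[0.7], seed=0) == 0.7

    def test_fewer_rows_than_folds_rejected(self):
        X, y, _ = _toy_system(n=5)
        with pytest.raises(ValueError):
            select_lambda(X, y, folds=10, grid=[0.1, 0.2], seed=0)

    def test_pure_noise_prefers_sparser_models(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 8))
        y = rng.normal(size=120)
        lam = select_lambda(X, y, folds=5, grid=default_grid(X, y, 20, 1e-3), seed=1)
        chosen = len(fit_lasso(X, y, lam).active_keys)
        densest = len(fit_lasso(X, y, default_grid(X, y, 20, 1e-3)[-1]).active_keys)
        assert chosen <= densest


class TestTrainErrorModel:
    def test_split_bookkeeping(self, small_dataset, small_grid):
        data, _, _ = small_dataset
        model, metrics, test_ids = train_error_model(
            data, test_fraction=0.5, seed=1, folds=5, grid=small_grid
        )
        assert metrics["n_test"] == len(test_ids) == 40
        assert metrics["n_train"] == 40
        assert set(test_ids).isdisjoint(model.metadata["train_ids"])

    def test_noiseless_data_fits_to_solver_tolerance(self):
        spec = gb.GeneratorSpec(n_molecules=120, max_heavy_atoms=6, seed=9)
        truth = gb.default_truth_model(noise_sd=0.0)
        data, _ = gb.simulate_dataset(spec, truth)
        grid = default_grid(data.features.frame.to_numpy(float), data.y, 20, 1e-6)
        _, metrics, _ = train_error_model(data, seed=2, folds=5, grid=grid)
        assert metrics["test_mae_kcal_mol"] < 1e-2 * np.abs(data.y).mean()

    def test_invalid_fraction_rejected(self, small_dataset):
        data, _, _ = small_dataset
        with pytest.raises(ValueError):
            train_error_model(data, test_fraction=1.5)


class TestPrediction:
    def test_atoms_only_model_worked_values(self, atoms_only_model):
        nh3 = gb.parse_molecule("N", id="nh3")
        assert predict_error(atoms_only_model, nh3) == pytest.approx(1.36, abs=1e-9)
        h2 = gb.parse_molecule("[H][H]", id="h2")
        assert predict_error(atoms_only_model, h2) == pytest.approx(-6.02, abs=1e-12)

    def test_empty_model_predicts_zero(self, benzene):
        empty = gb.ErrorModel((), np.array([]), lam=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CoverageWarning)
            assert predict_error(empty, benzene) == 0.0

    def test_uncovered_patterns_warn(self, atoms_only_model, ethane):
        with pytest.warns(CoverageWarning, match="ethane"):
            predict_error(atoms_only_model, ethane)  # C-C is outside the registry

    def test_correct_enthalpy_arithmetic(self, atoms_only_model):
        nh3 = gb.parse_molecule("N", id="nh3")
        assert gb.correct_enthalpy(-50.0, atoms_only_model, nh3) == pytest.approx(-48.64)
        empty = gb.ErrorModel((), np.array([]), lam=1.0)
        assert gb.correct_enthalpy(-50.0, empty, nh3) == -50.0
        with pytest.raises(ValueError):
            gb.correct_enthalpy(float("nan"), atoms_only_model, nh3)

    def test_sign_convention_round_trip(self, atoms_only_model, small_dataset):
        data, _, _ = small_dataset
        for g, h in zip(data.graphs[:10], data.h_computed[:10]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", CoverageWarning)
                assert gb.correct_enthalpy(h, atoms_only_model, g) - h == pytest.approx(
                    predict_error(atoms_only_model, g)
                )


class TestReactionError:
    def test_balanced_reaction_cancels_exactly(self, atoms_only_model):
        n2 = gb.parse_molecule("N#N", id="n2")
        h2 = gb.parse_molecule("[H][H]", id="h2")
        nh3 = gb.parse_molecule("N", id="nh3")
        assert reaction_error(atoms_only_model, [(n2, 1), (h2, 3)], [(nh3, 2)]) == 0.0

    def test_empty_model_gives_zero(self):
        empty = gb.ErrorModel((), np.array([]), lam=1.0)
        a = gb.parse_molecule("CCO", id="a")
        b = gb.parse_molecule("CC=O", id="b")
        h2 = gb.parse_molecule("[H][H]", id="h2")
        assert reaction_error(empty, [(a, 1)], [(b, 1), (h2, 1)]) == 0.0

    def test_bond_breaking_exposes_first_order_error(self):
        """2 CH3NH2 -> C2H6 + N2H4 breaks two C-N bonds."""
        w_cn = 1.15
        model = gb.ErrorModel((gb.pattern_from_fragment("C-N").key,), np.array([w_cn]), lam=0.1)
        mam = gb.parse_molecule("CN", id="methylamine")
        ethane = gb.parse_molecule("CC", id="ethane")
        hydrazine = gb.parse_molecule("NN", id="hydrazine")
        err = reaction_error(model, [(mam, 2)], [(ethane, 1), (hydrazine, 1)])
        assert err == pytest.approx(-2 * w_cn)


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path, atoms_only_model):
        path = tmp_path / "model.json"
        atoms_only_model.to_json(str(path))
        back = gb.ErrorModel.from_json(str(path))
        assert back.pattern_keys == atoms_only_model.pattern_keys
        assert np.array_equal(back.coefficients, atoms_only_model.coefficients)
        assert back.lam == atoms_only_model.lam

    def test_dataset_csv_missing_column_named(self, tmp_path, small_dataset):
        _, frame, _ = small_dataset
        broken = frame.drop(columns=["h_reference_kcal_mol"])
        path = tmp_path / "broken.csv"
        broken.to_csv(path, index=False)
        with pytest.raises(ValueError, match="h_reference_kcal_mol"):
            gb.ErrorDataset.from_csv(str(path))
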