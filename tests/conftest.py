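import numpy as np
import pytest

import graphbac as gb


@pytest.fixture(scope="session")
def ethane():
    return gb.parse_molecule("CC", id="ethane")


@pytest.fixture(scope="session")
def methane():
    return gb.parse_molecule("C", id="methane")


@pytest.fixture(scope="session")
def benzene():
    return gb.parse_molecule("c1ccccc1", id="benzene")


@pytest.fixture(scope="session")
def small_dataset():
    """Fast 80-molecule synthetic dataset for unit-level pipeline tests."""
    spec = gb.GeneratorSpec(n_molecules=80, max_heavy_atoms=7, seed=42)
    truth = gb.default_truth_model(noise_sd=0.5)
    data, frame = gb.simulate_dataset(spec, truth)
    return data, frame, truth


@pytest.fixture(scope="session")
def small_grid(small_dataset):
    data, _, _ = small_dataset
    A = data.features.frame.to_numpy(float)
    return gb.model.default_grid(A, data.y, n_points=8, ratio=1e-2)


@pytest.fixture(scope="session")
def atoms_only_model():
    """Zeroth-order model with the canonical atom energies (kcal/mol)."""
    keys = tuple(gb.pattern_from_fragment(f).key for f in ("C", "H", "O", "N"))
    return gb.ErrorModel(keys, np.array([11.65, -3.01, 14.59, 10.39]), lam=0.1)
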