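"""Run configuration shared by the CLI commands.

Defaults encode the standard protocol: 4-edge fragment cutoff, 90/10
train/test split, tenfold cross-validation, 1000 bootstrap iterations of
60/40 splits, a 2 kcal/mol accuracy threshold, and a 1e-8 numeric-zero
guard for "active" coefficients.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass


@dataclass
class RunConfig:
    max_edges: int = 4
    test_fraction: float = 0.10
    cv_folds: int = 10
    bootstrap_iterations: int = 1000
    fit_fraction: float = 0.60
    grid_points: int = 60
    grid_ratio: float = 1e-4
    seed: int = 0
    threshold_kcal_mol: float = 2.0
    zero_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not 0 < self.fit_fraction < 1:
            raise ValueError("fit_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_edges < 0:
            raise ValueError("max_edges must be nonnegative")
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be >= 1")

    @classmethod
    def from_toml(cls, path: str, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
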