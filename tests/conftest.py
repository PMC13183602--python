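"""Shared fixtures.

The replication-scale artifacts (8^4 training grids, trained surrogates,
250-point validations) are expensive, so they are built once per session
and shared by every test that needs them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from episurf.cellmodel import load_variant
from episurf.datagen import Dataset
from episurf.experiments import run_forward_matrix, run_inhibition, run_inverse
from episurf.surrogate import TrainConfig

warnings.filterwarnings("ignore", message="input outside the training")

ACCEPTANCE_SEED_A = 1
ACCEPTANCE_SEED_B = 2


@pytest.fixture(scope="session")
def variants():
    return {f"{ct}_{sex}": load_variant(f"{ct}_{sex}")
            for ct in ("pct", "mtal") for sex in ("male", "female")}


@pytest.fixture(scope="session")
def forward_matrix_a():
    """Full-scale forward matrices (8^4 grids, n_val=250), first seed set."""
    out = {}
    for ct in ("pct", "mtal"):
        result, artifacts = run_forward_matrix(ct, seed=ACCEPTANCE_SEED_A,
                                               return_artifacts=True)
        out[ct] = {"result": result, "artifacts": artifacts}
    return out


@pytest.fixture(scope="session")
def forward_matrix_b():
    """Second seed set for the ordering criteria."""
    return {ct: run_forward_matrix(ct, seed=ACCEPTANCE_SEED_B)
            for ct in ("pct", "mtal")}


@pytest.fixture(scope="session")
def inhibition_results(forward_matrix_a):
    out = {}
    for ct in ("pct", "mtal"):
        art = forward_matrix_a[ct]["artifacts"]
        reuse = {"variants": art["variants"],
                 "surrogates": {s: art["surrogates"][s]
                                for s in ("male", "female")}}
        out[ct] = run_inhibition(ct, seed=ACCEPTANCE_SEED_A, artifacts=reuse)
    return out


@pytest.fixture(scope="session")
def inverse_results():
    out = {}
    for ct in ("pct", "mtal"):
        for sex in ("male", "female"):
            result, _surr, _sc = run_inverse(ct, sex, seed=ACCEPTANCE_SEED_A)
            out[(ct, sex)] = result
    return out


def make_synthetic_dataset(n=400, seed=0, param_names=("a", "b", "c", "d")):
    """Small analytic stand-in dataset for surrogate unit tests: smooth
    synthetic outputs of four log-uniform inputs (no mechanistic solves)."""
    rng = np.random.default_rng(seed)
    X = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=(n, 4)))
    table = pd.DataFrame({f"frac_{p}": X[:, j]
                          for j, p in enumerate(param_names)})
    table["Na_cell"] = 15.0 + 5.0 * np.log(X[:, 0]) - 4.0 * np.log(X[:, 1])
    table["K_cell"] = 130.0 - 6.0 * np.log(X[:, 1]) + 2.0 * X[:, 2]
    table["Va"] = -70.0 + 8.0 * np.log(X[:, 3]) + X[:, 0] * X[:, 1]
    table["Vb"] = -71.0 + 7.0 * np.log(X[:, 3])
    table["J_Na_trans"] = 1e-5 * X[:, 1] * (1 + 0.2 * np.log(X[:, 0]))
    table["J_K_trans"] = -1e-6 * X[:, 1] / X[:, 3]
    table["converged"] = True
    table["iterations"] = 3
    meta = {"variant": "synthetic", "seed": seed,
            "design": {"mode": "random", "param_names": list(param_names),
                       "n": n, "seed": seed},
            "n_rows": n, "n_converged": n}
    return Dataset(table=table, metadata=meta)


@pytest.fixture()
def synthetic_dataset():
    return make_synthetic_dataset()


@pytest.fixture()
def fast_train_config():
    return TrainConfig(max_epochs=150, patience=40, seed=7)
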