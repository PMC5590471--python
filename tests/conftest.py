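"""Shared fixtures: small hand-built models and writable file fixtures."""

import numpy as np
import pandas as pd
import pytest

from fluxdiag import MetabolicModel


@pytest.fixture
def toy_model():
    """4 metabolites x 4 reactions, one measured exchange.

    EX_A imports A; R1 converts A->B, R2 B->C, R3 C->D+A (cycle closure).
    """
    S = np.array([
        # EX_A  R1   R2   R3
        [1.0, -1.0, 0.0, 1.0],   # A
        [0.0, 1.0, -1.0, 0.0],   # B
        [0.0, 0.0, 1.0, -1.0],   # C
        [0.0, 0.0, 0.0, 1.0],    # D
    ])
    return MetabolicModel(
        metabolite_ids=["A", "B", "C", "D"],
        reaction_ids=["EX_A", "R1", "R2", "R3"],
        S=S,
        exchange_reaction_ids=["EX_A"],
    )


@pytest.fixture
def toy_measurements():
    return pd.DataFrame({"reaction_id": ["EX_A"], "value": [2.0], "sd": [0.1]})


@pytest.fixture
def model_file(tmp_path, toy_model):
    from fluxdiag import write_model
    path = tmp_path / "model.tsv"
    write_model(toy_model, path)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_overdetermined(rng, n=12, k=5, noise=0.0):
    """A generic well-conditioned regression problem for statistical tests."""
    X = rng.normal(size=(n, k))
    beta = rng.normal(size=k)
    y = X @ beta + noise * rng.normal(size=n)
    return X, beta, y
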