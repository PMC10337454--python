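"""Shared fixtures: all test data are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import gradedcat as gc


@pytest.fixture(scope="session")
def default_dataset():
    """Default 3x7 generator conditions at a fixed seed, n=2000."""
    config = gc.GenerationConfig(n_respondents=2000, seed=0)
    bank, thetas, matrix = gc.generate_dataset(config)
    return config, bank, thetas, matrix


@pytest.fixture(scope="session")
def strong_bank():
    """Deterministic 7-item scale with strong discriminations (a in [2, 3])
    and positive ("peaked") thresholds, the regime of a well-behaved
    depression scale."""
    specs = [
        (2.6, (-0.2, 0.7, 1.6)),
        (2.1, (0.1, 0.9, 1.9)),
        (2.9, (-0.4, 0.5, 1.4)),
        (2.3, (0.3, 1.1, 2.1)),
        (2.7, (0.0, 0.8, 1.7)),
        (2.2, (-0.1, 0.6, 1.5)),
        (2.5, (0.2, 1.0, 2.0)),
    ]
    items = tuple(
        gc.ItemParameters(id=f"s{i+1}", a=a, b=b, scale="scale")
        for i, (a, b) in enumerate(specs)
    )
    return gc.ItemBank(items=items, name="strong", n_categories=4)


@pytest.fixture(scope="session")
def peaked_bank():
    """7-item scale with every threshold >= 0: informative only above the
    population mean, so low-theta respondents exhaust the bank."""
    specs = [
        (2.4, (0.0, 0.9, 1.8)),
        (2.0, (0.2, 1.1, 2.0)),
        (2.6, (0.1, 1.0, 1.9)),
        (2.2, (0.4, 1.3, 2.2)),
        (2.5, (0.3, 1.2, 2.1)),
        (2.1, (0.5, 1.4, 2.3)),
        (2.3, (0.6, 1.5, 2.4)),
    ]
    items = tuple(
        gc.ItemParameters(id=f"p{i+1}", a=a, b=b, scale="scale")
        for i, (a, b) in enumerate(specs)
    )
    return gc.ItemBank(items=items, name="peaked", n_categories=4)


@pytest.fixture(scope="session")
def depression_calibration(default_dataset):
    """One calibrated scale reused across diagnostics tests."""
    _config, bank, _thetas, matrix = default_dataset
    result = gc.calibrate_grm(matrix, scale="depression", bank=bank, se_method="none")
    return bank, matrix, result


def guttman_matrix(n: int, n_items: int = 6, n_categories: int = 4, seed: int = 0):
    """Perfect polytomous Guttman data: deterministic step items on one trait."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 1.0, size=n)
    cuts = np.sort(rng.uniform(0.05, 0.95, size=(n_items, n_categories - 1)), axis=1)
    x = (theta[:, None, None] >= cuts[None, :, :]).sum(axis=2)
    return x.astype(np.int64)
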