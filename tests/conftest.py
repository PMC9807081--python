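"""Shared fixtures: synthetic sequences and the planted-fixture training runs.

The training-run fixture is session-scoped because the scaled-down learning
study (3 seeds x 2 metrics x 300 epochs) is the most expensive computation in
the suite and several tests consume different aspects of the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

import minilearn as ml


@pytest.fixture(scope="session")
def random_seq():
    return ml.make_random_sequence(50_000, seed=11)


@pytest.fixture(scope="session")
def repeat_seq():
    """Pure tandem repeat: adversarial fixture for consistency checks."""
    return ml.make_repeat_sequence(unit_length=171, copies=40, mutation_rate=0.0, seed=5)


@pytest.fixture(scope="session")
def planted_seq():
    """Planted-periodic fixture: sentinel 8-mer at every 13th k-mer position."""
    return ml.make_planted_periodic_sequence(k=8, w=13, n_periods=500, seed=1)


@pytest.fixture(scope="session")
def planted_params(planted_seq):
    return ml.SketchParams.for_sequence(planted_seq, k=8, w=13)


@pytest.fixture(scope="session")
def planted_training_runs(planted_seq, planted_params):
    """Train on the planted fixture: 3 seeds x {dm, l2}, 300 epochs each.

    Returns {metric: [TrainResult, ...]} in seed order (0, 1, 2).
    """
    runs = {}
    for metric in ("dm", "l2"):
        runs[metric] = [
            ml.train(
                planted_seq,
                planted_params,
                objective_config=ml.ObjectiveConfig(metric=metric),
                train_config=ml.TrainConfig(epochs=300, seed=seed),
            )
            for seed in (0, 1, 2)
        ]
    return runs
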