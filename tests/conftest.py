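"""Shared fixtures: small systems and a seeded ensemble of folding runs."""

import numpy as np
import pytest

from redoxfold import fixtures
from redoxfold.controller import run_oxidative_folding
from redoxfold.model_core import ControllerConfig


@pytest.fixture(scope="session")
def guanylin():
    """Guanylin-like 15-residue chain (topology, initial frame)."""
    return fixtures.guanylin_chain(seed=11)


@pytest.fixture(scope="session")
def folding_ensemble():
    """Twenty seeded desk-scale oxidative-folding runs of the fixture chain.

    Session-scoped because each run propagates several nanoseconds; the
    results back both the controller contract tests and the trigger-distance
    checks.
    """
    results = []
    for seed in range(20):
        topo, frame = fixtures.guanylin_chain(seed=seed)
        cfg = ControllerConfig.desk(seed=seed)
        results.append(run_oxidative_folding(topo, frame, cfg))
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
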