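"""Shared fixtures: the default synthetic study and its derived datasets.

Heavy artefacts (the simulated study, the structure-learning run) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from rootgrn import bayes_network as bn
from rootgrn import synthetic_data as sd


@pytest.fixture(scope="session")
def default_truth():
    return sd.default_truth()


@pytest.fixture(scope="session")
def default_design():
    return sd.default_design()


@pytest.fixture(scope="session")
def default_study(default_truth, default_design):
    """One simulated draw of the full study design (learning + transfers)."""
    return sd.simulate_dataset(default_truth, default_design, seed=4)


@pytest.fixture(scope="session")
def learning_study(default_study):
    return sd.learning_subset(default_study)


@pytest.fixture(scope="session")
def learned_consensus(learning_study):
    """Structure learning on the default study; reused by several tests."""
    from rootgrn.pipeline import default_search_config

    data = sd.discretize_study(learning_study)
    topk = bn.learn_structures(
        data, bn.ScoreConfig(), default_search_config(seed=104)
    )
    return data, topk, bn.consensus_network(topk, 0.40, data)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
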