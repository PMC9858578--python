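"""Shared fixtures: seeded simulations at the study conditions and a trained
region classifier.  Everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from delinscan import classify
from delinscan.alignments import AlnStore
from delinscan.config import PipelineConfig, SimConfig
from delinscan.density import build_pileup, weight_vector
from delinscan.simdata import simulate


@pytest.fixture(scope="session")
def ensemble():
    """Default one-vs-one SVM ensemble trained on the seeded corpus."""
    return classify.default_ensemble(seed=7)


@pytest.fixture(scope="session")
def sim15():
    """200 kb diploid simulation at the 15% CLR error rate, depth 25."""
    cfg = SimConfig(
        ref_length=200_000, n_delins=4, n_ins=1, n_del=1,
        snv_rate=1e-3, depth=25, error_rate=0.15, seed=5,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def store15(sim15):
    return AlnStore.from_records(sim15.records, sim15.ref_name, len(sim15.reference))


@pytest.fixture(scope="session")
def pileup15(sim15, store15):
    return build_pileup(store15, sim15.reference)


@pytest.fixture(scope="session")
def sim0():
    """Zero-noise simulation (errors off, variants on)."""
    cfg = SimConfig(
        ref_length=300_000, n_delins=5, n_del=1, snv_rate=1e-3,
        depth=25, error_rate=0.0, seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def store0(sim0):
    return AlnStore.from_records(sim0.records, sim0.ref_name, len(sim0.reference))


@pytest.fixture(scope="session")
def weights50():
    return weight_vector(50)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
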