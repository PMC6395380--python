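"""Shared fixtures: small synthetic sessions and their derived objects.

Everything is generated at test time from seeded configs; session-scoped
fixtures are reused across test modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from premove import SimConfig, generate_session, simulate_session
from premove.pipeline import decompose, preprocess_session
from premove.simulate import truth_decomposition


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def session_and_truth(default_config):
    """One full default (visual) session with artifacts."""
    return simulate_session(default_config)


@pytest.fixture(scope="session")
def clean_session_and_truth(default_config):
    """Same session before artifact injection."""
    return generate_session(default_config)


@pytest.fixture(scope="session")
def epochs(session_and_truth):
    session, _ = session_and_truth
    return preprocess_session(session)


@pytest.fixture(scope="session")
def decomp(epochs):
    """Full pipeline ICA decomposition at 100 Hz (flags + areas set)."""
    return decompose(epochs, ica_seed=0)


@pytest.fixture(scope="session")
def oracle_decomp(session_and_truth):
    """Ground-truth decomposition (true mixing and sources) at 100 Hz,
    artifact-flagged and categorized."""
    from premove import categorize_components, identify_artifact_components

    session, truth = session_and_truth
    decomp = truth_decomposition(session, truth)
    identify_artifact_components(decomp)
    categorize_components(decomp)
    return decomp


@pytest.fixture(scope="session")
def small_session():
    """A 1-run session: 40 trials, cheap enough for repeated searches."""
    cfg = SimConfig(n_runs=1, seed=11)
    return simulate_session(cfg)
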