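"""Shared fixtures: the study system, fiber helices, and small ensembles.

Everything is generated programmatically; session scope keeps the heavier
constructions (30-mer fibers, Gaussian ensembles) to a single build.
"""

from __future__ import annotations

import numpy as np
import pytest

from triplexkit import (
    CANONICAL_A,
    CANONICAL_B,
    annotate_system,
    build_triplex,
    helix_step_table,
    rebuild_helix,
    triplex_30mer_system,
)


@pytest.fixture(scope="session")
def study_system():
    return triplex_30mer_system()


@pytest.fixture(scope="session")
def fiber_duplex_b(study_system):
    """30-mer duplex at canonical B step parameters."""
    return rebuild_helix(study_system.duplex_seq, CANONICAL_B)


@pytest.fixture(scope="session")
def fiber_duplex_a(study_system):
    return rebuild_helix(study_system.duplex_seq, CANONICAL_A)


@pytest.fixture(scope="session")
def fiber_triplex(fiber_duplex_b, study_system):
    return build_triplex(fiber_duplex_b, study_system.tfo_seq, 11)


@pytest.fixture(scope="session")
def duplex_annotation(fiber_duplex_b, study_system):
    return annotate_system(fiber_duplex_b, study_system)


@pytest.fixture(scope="session")
def triplex_annotation(fiber_triplex, study_system):
    return annotate_system(fiber_triplex, study_system)


@pytest.fixture(scope="session")
def step_table_b(fiber_duplex_b, duplex_annotation):
    return helix_step_table(fiber_duplex_b, duplex_annotation)


@pytest.fixture(scope="session")
def step_table_a(fiber_duplex_a, study_system):
    ann = annotate_system(
        rebuild_helix(study_system.duplex_seq, CANONICAL_A), study_system
    )
    return helix_step_table(rebuild_helix(study_system.duplex_seq, CANONICAL_A), ann)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
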