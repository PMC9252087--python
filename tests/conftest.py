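"""Shared synthetic fixtures; everything is generated at test time."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from phoscyc import aligner, synthdata


@pytest.fixture(scope="session")
def small_spec() -> synthdata.SynthSpec:
    """Three families of four 120-aa members plus six negatives."""
    return synthdata.SynthSpec(
        seed=11, n_families=3, members_per_family=4, ancestor_length=120,
        within_divergence=0.12, decoy_divergence=0.45, n_negatives=6,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """(db, queries, truth) with negatives appended to queries and truth."""
    db, queries, truth = synthdata.make_families(small_spec)
    negq, negt = synthdata.make_negatives(small_spec)
    return db, queries + negq, truth + negt


@pytest.fixture(scope="session")
def small_best_hits(small_dataset):
    db, queries, _ = small_dataset
    return aligner.search_best_hits(queries, db)
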