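"""Shared fixtures: synthetic communities and trained models.

The expensive fixtures (the study-condition community and its trained
classifier) are session-scoped and shared between the module tests and
the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import microtax as mt

SEED = 1


@pytest.fixture(scope="session")
def community():
    """Study-condition community: 50 genera, 5 groups, V-region structure."""
    spec = mt.default_community(seed=SEED)
    records, taxonomy = mt.generate_community(spec)
    return spec, records, taxonomy


@pytest.fixture(scope="session")
def model(community):
    _, records, taxonomy = community
    return mt.build_taxmachine(records, taxonomy, seed=SEED)


@pytest.fixture(scope="session")
def fragment_results(community, model):
    _, records, taxonomy = community
    return mt.evaluate_fragments(model, records, taxonomy, seed=SEED)


@pytest.fixture(scope="session")
def flat_community():
    """Well-separated flat community: 20 genera, 10% centroid divergence."""
    spec = mt.SyntheticCommunitySpec(
        n_genera=20,
        sequences_per_genus=5,
        sequence_length=1500,
        centroid_divergence=0.10,
        within_genus_rate=0.02,
        seed=SEED,
    )
    records, taxonomy = mt.generate_community(spec)
    return spec, records, taxonomy


@pytest.fixture(scope="session")
def flat_model(flat_community):
    _, records, taxonomy = flat_community
    labels = dict(zip(taxonomy["sequence_id"], taxonomy["genus"]))
    encoded = [mt.encode_sequence(s) for _, s in records]
    counts = mt.aggregate_taxon_counts(
        encoded, [labels[rid] for rid, _ in records], k=8
    )
    return mt.train_multinomial(counts, 100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
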