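import random

import pytest

from domarch.model import ConsolidationConfig, CurationMap
from domarch.consolidation import consolidate
from domarch.synthetic_fixtures import FixtureSpec, generate


@pytest.fixture(scope="session")
def fixture_bundle():
    """The standard 200-protein synthetic dataset: 35 planted architectures
    (8 characterized-style + 27 novel), 3 redundant sources per domain,
    decoys on."""
    return generate(FixtureSpec(seed=1, n_proteins=200))


@pytest.fixture(scope="session")
def consolidated(fixture_bundle):
    """Consolidated calls for every protein of the standard bundle."""
    curation = CurationMap(entries=dict(fixture_bundle.curation_entries))
    cfg = ConsolidationConfig()
    by_protein = {}
    for ann in fixture_bundle.annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)
    calls = {}
    drops = {}
    for rec in fixture_bundle.records:
        rec_calls, rec_drops = consolidate(
            rec, by_protein.get(rec.protein_id, []), curation, cfg
        )
        calls[rec.protein_id] = rec_calls
        drops[rec.protein_id] = rec_drops
    return calls, drops


@pytest.fixture()
def rng():
    return random.Random(20240101)
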