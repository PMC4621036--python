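import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from domex.fixtures import FixtureSpec, generate
from domex.pipeline import predict_chain
from domex.ppa import make_ppa_scorer
from domex.search import BuiltinBackend


@pytest.fixture(scope="session")
def backend():
    return BuiltinBackend()


@pytest.fixture(scope="session")
def small_fixture():
    """A small deterministic benchmark: 12 chains, half discontinuous."""
    return generate(FixtureSpec(seed=42, n_chains=12, library_decoys=12))


@pytest.fixture(scope="session")
def small_predictions(small_fixture, backend):
    fx = small_fixture
    ppa = make_ppa_scorer(fx.library)
    return [
        predict_chain(
            c.chain_id, c.sequence, fx.boundaries[c.chain_id], fx.library,
            backend=backend, ppa=ppa,
        )
        for c in fx.chains
    ]
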