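import numpy as np
import pytest

from structmap.pipeline import RunConfig
from structmap.synthetic import SyntheticSpec, generate_structure_set


@pytest.fixture(scope="session")
def structural_bundle(tmp_path_factory):
    """Synthetic structural bundle: 12 chains, 2 planted sites each,
    3 motif templates, one missing region per chain."""
    root = tmp_path_factory.mktemp("bundle")
    spec = SyntheticSpec(n_proteins=12, n_modified_per_protein=2, seed=7)
    manifest = generate_structure_set(spec, root)
    manifest["root"] = root
    manifest["spec"] = spec
    return manifest


@pytest.fixture(scope="session")
def parsed_chain(structural_bundle):
    from structmap.structure_model import parse_chain
    return parse_chain(structural_bundle["structures"][0], "A")


@pytest.fixture()
def fast_config():
    return RunConfig(bootstrap_reps=25, entropy_reps=40,
                     profile_halfwidth=20, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
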