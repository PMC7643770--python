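import numpy as np
import pytest

from qimcmda.semantic import SemanticParams, build_ss
from qimcmda.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def planted():
    """Default planted fixture (20 x 30, rank 2, density 0.1) plus its SS matrix."""
    A, fs, dags, L = generate_fixture(FixtureSpec(seed=7))
    ss = build_ss(dags, SemanticParams(), diseases=A.disease_names)
    return {"A": A, "fs": fs, "dags": dags, "latent": L, "ss": ss}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
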